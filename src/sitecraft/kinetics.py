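"""Single-channel gating kinetics for the one-site scheme A+C<->AC<->AO.

A is the agonist, C the closed unliganded receptor, AC the closed
liganded receptor and AO the open state.  The module simulates idealized
dwell sequences from the continuous-time Markov scheme, fits the four rate
constants by maximum likelihood across agonist concentrations using the
aggregated two-class (closed = {C, AC}, open = {AO}) interval
factorization, and derives equilibrium constants and binding free
energies:

* Kd = k_off / k_on (molar), or the dimensionless proxy E0/E1 valid for
  ddG-style comparisons,
* binding free energy = RT ln Kd, with RT = 0.59 kcal/mol at 23 C,
* phi-values from the log-log slope of opening rate vs gating equilibrium
  constant,
* two-mode (high/low affinity) segmentation of cluster sequences with a
  switching time constant.

No missed-event (dead-time) correction is applied: inputs are assumed
idealized.  Voltage is carried as metadata only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from sitecraft.errors import FormatError, UsageError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "GatingScheme",
    "EquilibriumConstants",
    "DwellDataset",
    "PhiInput",
    "MleFitResult",
    "ModeReport",
    "simulate_dwells",
    "mle_fit",
    "kd_from_rates",
    "kd_from_equilibrium",
    "estimate_E_from_cluster",
    "correct_background",
    "energy_from_kd",
    "fold_from_energy",
    "rt_kcal",
    "additivity_ledger",
    "phi_value",
    "segment_modes",
]

#: Molar gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.987204258640832e-3

#: Default temperature: 23 C, the recording temperature.
DEFAULT_TEMPERATURE_K = 296.15


@dataclass
class GatingScheme:
    """Rate constants of A+C<->AC<->AO.

    ``k_on`` in /M/s (association), ``k_off`` in /s (dissociation),
    ``f_open`` in /s (AC -> AO opening), ``b_close`` in /s (AO -> AC
    closing).
    """

    k_on: float
    k_off: float
    f_open: float
    b_close: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "f_open", "b_close"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")

    @property
    def kd_M(self) -> float:
        return self.k_off / self.k_on

    @property
    def e1(self) -> float:
        """Mono-liganded gating equilibrium constant f_open / b_close."""
        return self.f_open / self.b_close


@dataclass
class EquilibriumConstants:
    """Gating equilibrium constants and the (flagged) Kd they imply.

    ``kd_is_molar`` records provenance: True when Kd = k_off/k_on (molar),
    False when it is the dimensionless E0/E1 proxy, which is valid only
    for ddG-style comparisons in which the omitted open-state constant
    cancels.
    """

    E0: float
    E1: float
    Kd: float
    kd_is_molar: bool
    background_folds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.E0 <= 0 or self.E1 <= 0:
            raise UsageError("equilibrium constants must be positive")


@dataclass
class DwellDataset:
    """Alternating open/closed interval durations grouped into clusters."""

    clusters: list[list[tuple[str, float]]]
    conc_M: float
    voltage_mV: float = -100.0
    construct: str = ""

    def __post_init__(self) -> None:
        for ci, cluster in enumerate(self.clusters):
            prev = None
            for ri, (state, dur) in enumerate(cluster):
                if state not in ("open", "closed"):
                    raise FormatError(
                        f"cluster {ci} row {ri}: state must be open|closed"
                    )
                if dur <= 0:
                    raise FormatError(f"cluster {ci} row {ri}: duration must be > 0")
                if state == prev:
                    raise FormatError(
                        f"cluster {ci} row {ri}: consecutive {state!r} states"
                    )
                prev = state

    @property
    def n_events(self) -> int:
        return sum(len(c) for c in self.clusters)

    def durations(self, state: str) -> np.ndarray:
        return np.array(
            [d for c in self.clusters for s, d in c if s == state], dtype=float
        )

    def cluster_duration(self, index: int) -> float:
        return sum(d for _, d in self.clusters[index])


@dataclass
class PhiInput:
    """One construct's opening rate (/s) and gating equilibrium constant."""

    construct: str
    opening_rate: float
    gating_E: float

    def __post_init__(self) -> None:
        if self.opening_rate <= 0 or self.gating_E <= 0:
            raise UsageError("phi inputs must be positive")


@dataclass
class MleFitResult:
    """Maximum-likelihood estimate of a gating scheme."""

    scheme: GatingScheme
    log_likelihood: float
    standard_errors: dict
    n_events: int
    converged: bool


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


def simulate_dwells(
    scheme: GatingScheme,
    conc_M: float,
    n_events: int,
    seed: int | np.random.Generator = 0,
    events_per_cluster: int | None = None,
    voltage_mV: float = -100.0,
    construct: str = "sim",
    dead_time_s: float = 0.0,
) -> DwellDataset:
    """Sample idealized open/closed dwell sequences from the 3-state scheme.

    The chain starts in C; sojourns are aggregated by class (closed =
    {C, AC}, open = {AO}) and emitted as alternating closed/open dwells
    until ``n_events`` open intervals have completed.  ``events_per_cluster``
    splits the stream into clusters of that many open events (one cluster
    if None).  No dead-time censoring is applied; a nonzero ``dead_time_s``
    only triggers an "uncorrected" warning.
    """
    if n_events < 1:
        raise UsageError("n_events must be >= 1")
    if conc_M <= 0:
        raise UsageError("conc_M must be positive")
    if dead_time_s:
        warnings.warn(
            "dead_time_s is accepted but no missed-event correction is "
            "applied; dwells are idealized",
            stacklevel=2,
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    kon_c = scheme.k_on * conc_M
    koff, f, b = scheme.k_off, scheme.f_open, scheme.b_close
    p_open_from_ac = f / (koff + f)

    dwells: list[tuple[str, float]] = []
    n_open = 0
    state = "C"
    acc_closed = 0.0
    while n_open < n_events:
        if state == "C":
            acc_closed += rng.exponential(1.0 / kon_c)
            state = "AC"
        elif state == "AC":
            acc_closed += rng.exponential(1.0 / (koff + f))
            if rng.random() < p_open_from_ac:
                dwells.append(("closed", acc_closed))
                acc_closed = 0.0
                state = "AO"
            else:
                state = "C"
        else:  # AO
            dwells.append(("open", rng.exponential(1.0 / b)))
            n_open += 1
            state = "AC"

    if events_per_cluster is None:
        clusters = [dwells]
    else:
        if events_per_cluster < 1:
            raise UsageError("events_per_cluster must be >= 1")
        clusters = []
        per = 2 * events_per_cluster  # closed+open pairs
        for i in range(0, len(dwells), per):
            chunk = dwells[i : i + per]
            if chunk:
                clusters.append(chunk)
    return DwellDataset(
        clusters=clusters, conc_M=conc_M, voltage_mV=voltage_mV, construct=construct
    )


# --------------------------------------------------------------------------
# Likelihood and fitting
# --------------------------------------------------------------------------


def _closed_dwell_loglik(
    t: np.ndarray, entry_at_C: np.ndarray, kon_c: float, koff: float, f: float
) -> float:
    """Log-density of closed-class sojourn times for the aggregated scheme.

    The closed class {C, AC} has sub-generator
    ``S = [[-kon*c, kon*c], [koff, -(koff+f)]]`` and exit vector
    ``s = (0, f)``; the dwell density is the phase-type
    ``f(t) = pi exp(S t) s`` evaluated here in spectral form (S has two
    real, distinct, negative eigenvalues for positive rates).
    """
    a = kon_c
    d = koff + f
    # eigenvalues of S = [[-a, a], [koff, -d]]
    tr = -(a + d)
    det = a * d - a * koff  # = a*f
    disc = tr * tr - 4.0 * det
    disc = max(disc, 0.0)
    sq = math.sqrt(disc)
    l1 = 0.5 * (tr + sq)
    l2 = 0.5 * (tr - sq)
    if abs(l1 - l2) < 1e-12 * max(abs(l1), 1.0):
        # coincident eigenvalues: fall back to a tiny perturbation
        l2 = l1 - 1e-9 * max(abs(l1), 1.0)
    # spectral projectors: exp(St) = e^{l1 t} P1 + e^{l2 t} P2,
    # P1 = (S - l2 I)/(l1 - l2), P2 = (S - l1 I)/(l2 - l1)
    # density for entry pi: pi @ exp(St) @ s with s = (0, f)
    # component needed: (exp(St) @ s)_C = exp(St)[0,1]*f ; _AC = exp(St)[1,1]*f
    dl = l1 - l2
    # S[0,1] = a, S[1,1] = -d
    e01_1 = a / dl          # P1[0,1]
    e01_2 = -a / dl         # P2[0,1]
    e11_1 = (-d - l2) / dl  # P1[1,1]
    e11_2 = (l1 + d) / dl   # P2[1,1]
    exp1 = np.exp(l1 * t)
    exp2 = np.exp(l2 * t)
    dens_C = f * (e01_1 * exp1 + e01_2 * exp2)
    dens_AC = f * (e11_1 * exp1 + e11_2 * exp2)
    dens = np.where(entry_at_C, dens_C, dens_AC)
    dens = np.maximum(dens, 1e-300)
    return float(np.sum(np.log(dens)))


def _dataset_loglik(datasets: list[DwellDataset], scheme: GatingScheme) -> float:
    ll = 0.0
    for ds in datasets:
        kon_c = scheme.k_on * ds.conc_M
        closed_t = []
        entry_C = []
        open_t = []
        for cluster in ds.clusters:
            seen_open = False
            for state, dur in cluster:
                if state == "open":
                    open_t.append(dur)
                    seen_open = True
                else:
                    closed_t.append(dur)
                    # a cluster's first closed dwell starts from C (the
                    # unliganded channel); later closed dwells are entered
                    # at AC after an opening.
                    entry_C.append(not seen_open)
        if closed_t:
            ll += _closed_dwell_loglik(
                np.asarray(closed_t),
                np.asarray(entry_C, dtype=bool),
                kon_c,
                scheme.k_off,
                scheme.f_open,
            )
        if open_t:
            t = np.asarray(open_t)
            ll += float(
                t.size * math.log(scheme.b_close) - scheme.b_close * t.sum()
            )
    return ll


def log_likelihood(datasets: list[DwellDataset], scheme: GatingScheme) -> float:
    """Joint log-likelihood of dwell datasets under a gating scheme."""
    return _dataset_loglik(datasets, scheme)


def _initial_guesses(datasets: list[DwellDataset]) -> list[np.ndarray]:
    """Moment-based starting points in log10-rate space."""
    all_open = np.concatenate([ds.durations("open") for ds in datasets])
    b0 = 1.0 / max(all_open.mean(), 1e-12)
    hi = max(datasets, key=lambda d: d.conc_M)
    f0 = 1.0 / max(hi.durations("closed").mean(), 1e-12)
    lo = min(datasets, key=lambda d: d.conc_M)
    # crude: at low conc the long closed component ~ 1/(kon*c * P(open|AC))
    kon0 = 1.0 / max(lo.durations("closed").mean() * lo.conc_M, 1e-30)
    guesses = []
    for koff_scale in (0.3, 3.0, 30.0):
        guesses.append(
            np.log10([kon0, f0 * koff_scale, f0, b0])
        )
    return guesses


def mle_fit(
    datasets: list[DwellDataset],
    max_iter: int = 4000,
) -> MleFitResult:
    """Global maximum-likelihood fit of the four gating rates.

    All datasets share one :class:`GatingScheme`; agonist concentration
    enters through ``k_on * conc``.  At least two distinct concentrations
    are required for identifiability of (k_on, k_off).  Optimization runs
    in log10-rate space (Nelder-Mead, several moment-based restarts);
    standard errors come from the inverse of a finite-difference Hessian
    of the negative log-likelihood, delta-transformed to the rate scale.
    """
    if not datasets:
        raise UsageError("no datasets")
    concs = sorted({ds.conc_M for ds in datasets})
    if len(concs) < 2:
        raise UsageError(
            "mle_fit needs datasets at >=2 distinct agonist concentrations"
        )
    n_events = sum(ds.n_events for ds in datasets)
    if n_events < 100:
        warnings.warn(
            f"only {n_events} events; rate estimates will be poorly "
            "constrained",
            stacklevel=2,
        )

    def nll(logp: np.ndarray) -> float:
        if np.any(logp < -3) or np.any(logp > 12):
            return 1e12
        k_on, k_off, f_open, b_close = 10.0 ** logp
        try:
            scheme = GatingScheme(k_on, k_off, f_open, b_close)
        except UsageError:
            return 1e12
        return -_dataset_loglik(datasets, scheme)

    best = None
    for x0 in _initial_guesses(datasets):
        res = minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise UsageError("mle_fit failed to evaluate the likelihood")
    if best.fun >= 1e12:
        raise UsageError("mle_fit did not converge to a feasible scheme")
    logp = best.x
    k_on, k_off, f_open, b_close = (float(v) for v in 10.0 ** logp)
    scheme = GatingScheme(k_on, k_off, f_open, b_close)

    # finite-difference Hessian of the NLL in log10 space
    names = ("k_on", "k_off", "f_open", "b_close")
    h = 1e-4
    npar = 4
    hess = np.zeros((npar, npar))
    f0 = nll(logp)
    for i in range(npar):
        for j in range(i, npar):
            ei = np.zeros(npar)
            ej = np.zeros(npar)
            ei[i] = h
            ej[j] = h
            fpp = nll(logp + ei + ej)
            fpm = nll(logp + ei - ej)
            fmp = nll(logp - ei + ej)
            fmm = nll(logp - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    ses = {}
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        for i, name in enumerate(names):
            if diag[i] > 0:
                se_log10 = math.sqrt(diag[i])
                rate = getattr(scheme, name)
                ses[name] = rate * math.log(10.0) * se_log10
            else:
                ses[name] = float("nan")
    except np.linalg.LinAlgError:
        ses = {name: float("nan") for name in names}
    return MleFitResult(
        scheme=scheme,
        log_likelihood=-float(best.fun),
        standard_errors=ses,
        n_events=n_events,
        converged=bool(best.success or best.fun < f0 + 1e-9),
    )


# --------------------------------------------------------------------------
# Equilibrium constants and energies
# --------------------------------------------------------------------------


def kd_from_rates(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant k_off / k_on, in molar."""
    if k_off <= 0 or k_on <= 0:
        raise UsageError("rates must be positive")
    return k_off / k_on


def kd_from_equilibrium(E0: float, E1: float) -> float:
    """Dimensionless Kd proxy E0/E1 (unliganded over mono-liganded gating
    equilibrium constants).

    This is not a molar Kd — an open-state-affinity constant is omitted —
    but it is valid for ddG comparisons between constructs where that
    constant cancels.  Callers should keep the provenance flag (see
    :class:`EquilibriumConstants`).
    """
    if E0 <= 0 or E1 <= 0:
        raise UsageError("equilibrium constants must be positive")
    return E0 / E1


def estimate_E_from_cluster(dataset: DwellDataset) -> float:
    """Gating equilibrium constant from dwells in the two-state limit.

    At full agonist saturation (or for unliganded gating on a
    constitutively active background) the scheme reduces to C'<->O and
    E = mean open duration / mean closed duration.  Saturation is the
    caller's assertion, not checked here.
    """
    open_t = dataset.durations("open")
    closed_t = dataset.durations("closed")
    if open_t.size == 0 or closed_t.size == 0:
        raise UsageError("need both open and closed dwells")
    if open_t.size + closed_t.size < 10:
        warnings.warn("fewer than 10 events: E estimate is unreliable",
                      stacklevel=2)
    return float(open_t.mean() / closed_t.mean())


def correct_background(E0_measured: float, fold_changes: list[float]) -> float:
    """Remove known background enhancements from a measured E0.

    Background mutations multiply E0 by known, energetically independent
    fold changes; the corrected value divides the measurement by their
    product.  An empty list is the identity.
    """
    if E0_measured <= 0:
        raise UsageError("E0 must be positive")
    product = 1.0
    for fold in fold_changes:
        if fold <= 0:
            raise UsageError("fold changes must be positive")
        product *= fold
    return E0_measured / product


def rt_kcal(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT in kcal/mol (0.59 at 23 C to two decimals)."""
    return GAS_CONSTANT_KCAL * temperature_K


def energy_from_kd(
    kd_or_ratio: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Binding free energy RT ln(Kd) in kcal/mol.

    Accepts either a molar Kd or a dimensionless ratio (for ddG-style
    gaps); the RT coefficient is always derived from the gas constant,
    never hard-coded.
    """
    if kd_or_ratio <= 0:
        raise UsageError("argument must be positive")
    return rt_kcal(temperature_K) * math.log(kd_or_ratio)


def fold_from_energy(
    delta_kcal: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """exp(dG / RT): the Kd fold-change implied by an energy difference.

    Exact inverse of :func:`energy_from_kd`.
    """
    if not math.isfinite(delta_kcal):
        raise UsageError("energy must be finite")
    return math.exp(delta_kcal / rt_kcal(temperature_K))


def additivity_ledger(site_energies: dict[str, float]) -> dict:
    """Two-site totals and a pairwise ddG table from per-site energies.

    The two agonist sites act nearly independently, so combined binding
    energies are sums of single-site values.  Returns the total, all
    pairwise sums and a ddG table between sites.
    """
    total = float(sum(site_energies.values()))
    sites = sorted(site_energies)
    pair_totals = {
        f"{a}+{b}": site_energies[a] + site_energies[b]
        for i, a in enumerate(sites)
        for b in sites[i + 1 :]
    }
    ddg = {
        f"{a}-{b}": site_energies[a] - site_energies[b]
        for a in sites
        for b in sites
        if a != b
    }
    return {"total": total, "pair_totals": pair_totals, "ddG": ddg}


def percent_swap(e_construct: float, e_parent: float, e_target: float) -> float:
    """Effectiveness of an engineered swap on an energy scale.

    100 * (E_construct - E_parent) / (E_target - E_parent): 100 means the
    construct reached the target's energy, 0 means no change.
    """
    if e_target == e_parent:
        raise UsageError("target and parent energies coincide")
    return 100.0 * (e_construct - e_parent) / (e_target - e_parent)


def phi_value(points: list[PhiInput]) -> tuple[float, float, float]:
    """Slope of log10(opening rate) on log10(gating equilibrium constant).

    The slope (phi) maps the transition-state position of the perturbed
    residues on a 0-1 scale; values outside [0, 1] are warned about.
    Returns (slope, intercept, pearson_r); r is NaN for two points.
    """
    if len(points) < 2:
        raise UsageError("phi_value needs at least two constructs")
    x = np.log10([p.gating_E for p in points])
    y = np.log10([p.opening_rate for p in points])
    if np.allclose(x, x[0]):
        raise UsageError("gating equilibrium constants are all equal")
    slope, intercept = np.polyfit(x, y, 1)
    if len(points) > 2 and np.std(y) > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    elif np.std(y) == 0:
        r = float("nan")
    else:
        r = 1.0 if slope > 0 else -1.0
    if slope < -1e-9 or slope > 1.0 + 1e-9:
        warnings.warn(f"phi = {slope:.3f} outside the expected [0, 1] range",
                      stacklevel=2)
    return float(slope), float(intercept), r


# --------------------------------------------------------------------------
# Mode analysis
# --------------------------------------------------------------------------


@dataclass
class ModeReport:
    """Two-mode classification of a cluster sequence."""

    labels: list[int]
    n_modes: int
    prevalence: dict
    switching_tau_s: float
    mode_mean_open_s: dict


def segment_modes(dataset: DwellDataset, min_clusters: int = 10) -> ModeReport:
    """Classify clusters into two activity modes and estimate switching.

    Convention: a two-component Gaussian mixture is fitted to the
    per-cluster log10 mean open duration; a 2-vs-1-component BIC
    comparison decides whether the data are bimodal (unimodal data are
    reported as a single mode, never force-split).  Prevalence is the
    time-weighted fraction of each mode; the switching time constant is
    the mean total duration of runs of consecutive same-mode clusters
    (the ML estimate of an exponential run-length mean).
    """
    n = len(dataset.clusters)
    if n < min_clusters:
        raise UsageError(f"segment_modes needs >= {min_clusters} clusters")
    mean_open = []
    durations = []
    for i, cluster in enumerate(dataset.clusters):
        opens = [d for s, d in cluster if s == "open"]
        if not opens:
            raise UsageError(f"cluster {i} has no open dwells")
        mean_open.append(np.mean(opens))
        durations.append(dataset.cluster_duration(i))
    x = np.log10(mean_open).reshape(-1, 1)
    durations = np.asarray(durations)

    from sklearn.mixture import GaussianMixture

    gm1 = GaussianMixture(n_components=1, random_state=0).fit(x)
    gm2 = GaussianMixture(n_components=2, random_state=0, n_init=5).fit(x)
    if gm2.bic(x) >= gm1.bic(x):
        return ModeReport(
            labels=[0] * n,
            n_modes=1,
            prevalence={0: 1.0},
            switching_tau_s=float("nan"),
            mode_mean_open_s={0: float(np.mean(mean_open))},
        )
    labels = gm2.predict(x)
    # relabel so mode 0 is the short-lived-open (low E) mode
    means = gm2.means_.ravel()
    if means[0] > means[1]:
        labels = 1 - labels
    total = durations.sum()
    prevalence = {
        m: float(durations[labels == m].sum() / total) for m in (0, 1)
    }
    mode_mean = {
        m: float(np.mean([mo for mo, lb in zip(mean_open, labels) if lb == m]))
        for m in (0, 1)
    }
    # mean run duration over same-mode runs
    run_durs = []
    run_sum = durations[0]
    for i in range(1, n):
        if labels[i] == labels[i - 1]:
            run_sum += durations[i]
        else:
            run_durs.append(run_sum)
            run_sum = durations[i]
    run_durs.append(run_sum)
    tau = float(np.mean(run_durs))
    return ModeReport(
        labels=[int(v) for v in labels],
        n_modes=2,
        prevalence=prevalence,
        switching_tau_s=tau,
        mode_mean_open_s=mode_mean,
    )
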