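"""Config-driven orchestration of the figure-level analyses.

Three report builders mirror the headline comparisons:

* :func:`run_structure_report` — per-construct agonist-site metrics
  (hairpin twist/tilt, tau2 basins, H-bond occupancies, ring geometry,
  pocket volume) with histograms and a high-affinity vs low-affinity
  comparison table;
* :func:`run_affinity_report` — (alpha, beta) calibration, predicted vs
  experimental binding energies, and a ddG ledger with percent-swap
  effectiveness of engineered constructs;
* :func:`run_kinetics_report` — gating-rate fits across concentrations,
  Kd and binding energies with provenance flags, phi-values and two-mode
  segmentation.

Every number in a report traces to a module operation; the report layer
only aggregates and formats.  Reports are plain dicts, JSON-serializable
with sorted keys so reruns are byte-identical given identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from sitecraft import dynamics, geometry, kinetics, scoring
from sitecraft.errors import UsageError
from sitecraft.io import Ensemble, select_atoms

__all__ = [
    "RunConfig",
    "run_structure_report",
    "run_affinity_report",
    "run_kinetics_report",
    "save_report",
]


@dataclass
class RunConfig:
    """Declarative run description.

    ``roles`` maps construct label -> {"HA", "LA"} (affinity class) and
    optionally "parent"/"target" for swap accounting.  Selections are
    expression strings over the package's selection grammar.  The
    analysis window is the trailing fraction of each trajectory used for
    ensemble statistics.  All seeds are recorded into reports.
    """

    roles: dict = field(default_factory=dict)
    strand_beta5p: str = "resid 107-110"
    strand_beta6: str = "resid 115-118"
    loop_f_exclusion: str = ""
    hbonds: list = field(default_factory=list)
    tilt_reference: tuple = (0.0, 0.0, 1.0)
    analysis_window_fraction: float = 0.5
    histogram_bins: int = 30
    tau2_half_width_deg: float = 60.0
    grid_step: float = 0.01
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        if "tilt_reference" in raw:
            raw["tilt_reference"] = tuple(raw["tilt_reference"])
        return cls(**raw)

    def role_of(self, label: str) -> str:
        try:
            return self.roles[label]["role"]
        except KeyError as exc:
            raise UsageError(f"construct {label!r} has no role in config") from exc


def _analysis_window(ensemble: Ensemble, fraction: float) -> Ensemble:
    n = ensemble.n_snapshots
    start = int(np.floor(n * (1.0 - fraction)))
    start = min(max(start, 0), n - 1)
    return Ensemble(
        snapshots=ensemble.snapshots[start:],
        stride_ps=ensemble.stride_ps,
        label=ensemble.label,
    )


def _twist_series(ensemble: Ensemble, config: RunConfig) -> np.ndarray:
    s1 = select_atoms(ensemble, config.strand_beta5p)
    s2 = select_atoms(ensemble, config.strand_beta6)
    if not s1.resolved or not s2.resolved:
        raise UsageError("strand selections matched no atoms")
    vals = []
    for snap in ensemble.snapshots:
        a1 = geometry.strand_axis(snap.coords[s1.resolved])
        a2 = geometry.strand_axis(snap.coords[s2.resolved])
        vals.append(geometry.hairpin_twist(a1, a2))
    return np.array(vals)


def _histogram(values: np.ndarray, edges: np.ndarray) -> dict:
    counts, _ = np.histogram(values, bins=edges)
    return {"bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts]}


def run_structure_report(
    config: RunConfig, ensembles: dict[str, Ensemble]
) -> dict:
    """Per-construct structural metrics and the HA-vs-LA comparison table.

    Each construct's ensemble is restricted to the trailing analysis
    window, the hairpin twist is computed per snapshot, and configured
    H-bonds are scored for occupancy.  Histograms share fixed binning
    over the pooled range of all constructs so panels are comparable.
    """
    if not ensembles:
        raise UsageError("no ensembles supplied")
    for label in ensembles:
        config.role_of(label)  # raises on missing role
    windows = {
        lbl: _analysis_window(ens, config.analysis_window_fraction)
        for lbl, ens in ensembles.items()
    }
    twists = {lbl: _twist_series(ens, config) for lbl, ens in windows.items()}
    pooled = np.concatenate(list(twists.values()))
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        hi = lo + 1e-6
    edges = np.linspace(lo, hi, config.histogram_bins + 1)

    per_construct = {}
    for lbl, vals in twists.items():
        entry = {
            "role": config.role_of(lbl),
            "n_snapshots": int(windows[lbl].n_snapshots),
            "twist_deg": {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "histogram": _histogram(vals, edges),
            },
        }
        occs = {}
        for hb in config.hbonds:
            spec = geometry.HBondSpec(
                donor=hb["donor"], hydrogen=hb["hydrogen"],
                acceptor=hb["acceptor"], label=hb.get("label", ""),
            )
            occs[spec.label or f"{spec.donor}-{spec.acceptor}"] = (
                geometry.hbond_occupancy(windows[lbl], spec)
            )
        if occs:
            entry["hbond_occupancy"] = occs
        per_construct[lbl] = entry

    by_role: dict[str, list[float]] = {}
    for lbl, vals in twists.items():
        by_role.setdefault(config.role_of(lbl), []).append(float(vals.mean()))
    comparison = {}
    if "HA" in by_role and "LA" in by_role:
        ha = float(np.mean(by_role["HA"]))
        la = float(np.mean(by_role["LA"]))
        comparison["twist_deg"] = {"HA": ha, "LA": la, "delta_HA_minus_LA": ha - la}
    return {
        "seed": config.seed,
        "analysis_window_fraction": config.analysis_window_fraction,
        "constructs": per_construct,
        "comparison": comparison,
    }


def run_affinity_report(
    config: RunConfig,
    calibration_points: list[scoring.CalibrationPoint],
    construct_series: dict[str, scoring.EnergyComponentSeries] | None = None,
    experimental_energies: dict[str, float] | None = None,
    swaps: list[dict] | None = None,
) -> dict:
    """Calibration, predicted-vs-experimental energies and swap accounting.

    ``swaps`` entries are ``{"construct", "parent", "target"}`` label
    triples; percent-swap is evaluated on whichever energy scale
    (simulated or experimental) both endpoints provide, and is reported,
    never asserted.  Simulated and experimental energies are kept under
    separate keys throughout — they are compared, not conflated.
    """
    result = scoring.grid_calibrate(calibration_points, step=config.grid_step)
    report: dict = {
        "seed": config.seed,
        "calibration": {
            "alpha": result.alpha,
            "beta": result.beta,
            "rmse_kcal": result.rmse,
            "r_squared": result.r_squared,
            "pearson_r": result.pearson_r,
            "grid_step": result.grid_step,
            "n_points": len(calibration_points),
        },
    }
    energies: dict[str, dict] = {}
    if construct_series:
        for lbl, series in construct_series.items():
            mean, _ = scoring.ensemble_energy(series, result.alpha, result.beta)
            energies.setdefault(lbl, {})["simulated_kcal"] = mean
    if experimental_energies:
        for lbl, e in experimental_energies.items():
            energies.setdefault(lbl, {})["experimental_kcal"] = float(e)
    if energies:
        report["energies"] = energies
    if swaps:
        rows = []
        for swap in swaps:
            row = {k: swap[k] for k in ("construct", "parent", "target")}
            for scale in ("simulated_kcal", "experimental_kcal"):
                try:
                    e_c = energies[swap["construct"]][scale]
                    e_p = energies[swap["parent"]][scale]
                    e_t = energies[swap["target"]][scale]
                except KeyError:
                    continue
                row[f"percent_swap_{scale.split('_')[0]}"] = (
                    kinetics.percent_swap(e_c, e_p, e_t)
                )
            rows.append(row)
        report["swap_table"] = rows
    return report


def run_kinetics_report(
    config: RunConfig,
    datasets_by_construct: dict[str, list],
    phi_points: list | None = None,
    mode_datasets: dict[str, "kinetics.DwellDataset"] | None = None,
    temperature_K: float = kinetics.DEFAULT_TEMPERATURE_K,
) -> dict:
    """Rate fits, Kd, binding energies, phi and mode analysis.

    Every derived energy carries its provenance chain (rates -> Kd ->
    RT ln Kd) in the report.
    """
    if not datasets_by_construct and not phi_points and not mode_datasets:
        raise UsageError("no kinetics inputs supplied")
    report: dict = {"seed": config.seed, "temperature_K": temperature_K,
                    "rt_kcal": kinetics.rt_kcal(temperature_K)}
    fits = {}
    for lbl, datasets in datasets_by_construct.items():
        fit = kinetics.mle_fit(datasets)
        kd = kinetics.kd_from_rates(fit.scheme.k_off, fit.scheme.k_on)
        fits[lbl] = {
            "rates": {
                "k_on_per_M_s": fit.scheme.k_on,
                "k_off_per_s": fit.scheme.k_off,
                "f_open_per_s": fit.scheme.f_open,
                "b_close_per_s": fit.scheme.b_close,
            },
            "standard_errors": fit.standard_errors,
            "log_likelihood": fit.log_likelihood,
            "n_events": fit.n_events,
            "kd_M": kd,
            "binding_energy_kcal": kinetics.energy_from_kd(kd, temperature_K),
            "provenance": "k_off/k_on -> Kd (molar) -> RT ln Kd",
        }
    if fits:
        report["fits"] = fits
    if phi_points:
        slope, intercept, r = kinetics.phi_value(phi_points)
        report["phi"] = {"slope": slope, "intercept": intercept, "pearson_r": r,
                         "n_constructs": len(phi_points)}
    if mode_datasets:
        modes = {}
        for lbl, ds in mode_datasets.items():
            rep = kinetics.segment_modes(ds)
            modes[lbl] = {
                "n_modes": rep.n_modes,
                "prevalence": {str(k): v for k, v in rep.prevalence.items()},
                "switching_tau_s": rep.switching_tau_s,
                "mode_mean_open_s": {
                    str(k): v for k, v in rep.mode_mean_open_s.items()
                },
            }
        report["modes"] = modes
    return report


def save_report(report: dict, path: str | Path) -> None:
    """Write a report as deterministic (sorted-key) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
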