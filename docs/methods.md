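# Methods

## Scope and data model

The package analyses the agonist (neurotransmitter) binding site of
endplate nicotinic receptors at three levels: coordinate ensembles
(structure and dynamics), per-snapshot energy components (binding-energy
scoring), and single-channel dwell records (gating kinetics and
experimental affinity). The universal structural substrate is the
`Ensemble`: an ordered list of snapshots sharing one atom table.
Multi-model PDB is the canonical on-disk form (read/written through
biotite); a plain multi-frame XYZ dialect exists for lightweight
fixtures. Units are fixed throughout — Å, ps, kcal/mol, seconds, molar —
and conversions happen only at I/O boundaries. Residue numbers are
stored as they appear in the source structure (γ-subunit numbering in
the defaults); cross-subunit equivalences (e.g. γ104 ↔ δ106) belong in
run configuration, never in code.

Energy components are *consumed, never computed*: the electrostatic term
is expected to come from an upstream continuum (Poisson–Boltzmann)
calculation, and the van der Waals term from the force field. Nothing in
the scoring path implements a solver; the synthetic module's
screened-Coulomb surrogate exists only to draw fixture components of
plausible magnitude and is labelled as such.

## Binding-energy score and calibration

A construct's binding energy is the ensemble average

    ΔE = ⟨ α·E_vdW + β·ΔE_elec ⟩,

a deliberately simple two-parameter rescaling of force-field components
that absorbs, into β, physics the classical force field lacks (notably
cation–π stabilization of the quaternary ammonium by the aromatic core)
and, into α, the systematic overcounting of protein–ligand vdW contacts.
Calibration is an exhaustive grid scan of (α, β) over [0, 2]² minimizing

    RMSE = sqrt( mean_n ( α·Ē_vdW,n + β·Ē_elec,n − ΔE_exp,n )² )

over calibration constructs, where ΔE_exp = RT ln K_d from
electrophysiology. Design choices:

* **Grid step 0.01** (recorded in the result): resolves two printed
  decimals of the coefficients. A refined scan changes the optimum by at
  most one step (tested).
* **Ties break toward smaller α, then smaller β** — an arbitrary but
  fixed convention that matters only for degenerate designs (e.g. all
  electrostatic means zero), which are detected and warned about.
* R², Pearson r and RMSE are reported together; R² is NaN (with a
  warning) when the experimental energies have zero variance.
* Simulated ΔE and experimental RT ln K_d are *not* equivalent
  quantities; reports keep them under separate keys and compare, never
  conflate.

Per-residue energy partitions are ranked by |contribution| and the top
fraction's share of the summed magnitude is reported — the device used
to show that an excluded flexible region contributes nothing material to
affinity.

## Site geometry

* **Ring centroids** are unweighted means of ring-atom coordinates.
* **Pocket volume** joins the five core-ring centroids into two
  tetrahedra sharing a face and sums |det(b−a, c−a, d−a)|/6. The
  5-point → two-tetrahedron decomposition is not uniquely determined by
  the five labels; it is an explicit configuration input, with the
  package default `[αW149, αY198, αY190, αY93] + [αW149, αY93, W55,
  αY198]`. This is a reproducibility convention of this package, not a
  published one.
* **Strand axes** are dominant right-singular vectors of mean-centred
  backbone coordinates, sign-fixed first→last residue. **Hairpin twist**
  is the angle between the β5′ and β6 axes folded to [0, 90]° via |cos|,
  because the strands are antiparallel and the meaningful quantity is the
  small inter-strand angle. **Tilt** takes an explicit caller-supplied
  reference vector; no biological frame is assumed.
* **Torsions** are signed IUPAC dihedrals (cis = 0) in (−180, 180]°.
  τ2 basin fractions count angles within a half-width (default 60°) of
  the ±60° basin centres by sign; out-of-basin angles are excluded, so
  the two fractions sum to ≤1.
* **Hydrogen bonds** use donor–acceptor distance < 3.5 Å AND a
  donor-vertex angle (donor→H vs donor→acceptor) ≤ 30°. An explicit
  hydrogen is required; a distance-only fallback for heavy-atom-only
  ensembles can be enabled by passing the criterion parameters, and
  occupancy is simply the fraction of snapshots satisfying the
  criterion.
* **Ring-pair orientation** reports centroid distance and the angle
  between best-fit plane normals folded to [0, 90]°; the qualitative
  face-on (≤30°) / orthogonal (≥60°) labels are reporting conventions
  carried alongside the raw angle.

All metrics are rigid-motion invariant to 1e−6 (property-tested under
random rotations + translations).

## Trajectory stability and flexibility

RMSD is computed over a selection, optionally minus an exclusion (the
disordered loop F, residues 166–183 in γ / 164–177 in δ numbering, in
the motivating use), optionally after a Kabsch superposition. The
default is *no* superposition, because the motivating trajectories
restrained distal Cα atoms so frames share a lab frame; superposition
remains one flag away. Stationarity is diagnosed by a centred 5 ns
rolling mean (window shrunk symmetrically near the series ends so linear
trends are preserved exactly) and the OLS slope over the trailing 10 ns,
in Å/ns. RMSF is the per-atom RMS deviation from the coordinate-wise
mean structure, averaged per residue, computed over the trailing
analysis window (default: last half of the trajectory). HA−LA difference
profiles subtract over the shared residue set and warn about unmatched
residues.

## Gating kinetics

The one-site scheme A+C⇌AC⇌AO has four rates: k_on (/M/s), k_off (/s),
f_open (/s), b_close (/s). Observables aggregate the two closed states,
so:

* open dwells are exponential with rate b_close;
* closed dwells are phase-type with sub-generator
  S = [[−k_on·c, k_on·c], [k_off, −(k_off+f_open)]] and exit (0, f_open);
  the density is evaluated in spectral (two-exponential) form.

The likelihood multiplies these densities over all dwells and datasets,
with entry state C for a cluster's first closed dwell and AC for every
closed dwell that follows an opening. Fitting shares one scheme across
concentrations (k_on enters as k_on·c), requires ≥2 distinct
concentrations for identifiability, runs Nelder–Mead in log10-rate space
from three moment-based starts, and reports standard errors from a
finite-difference Hessian delta-transformed to the rate scale. **No
missed-event correction is applied**: inputs are assumed idealized, and
a nonzero dead-time parameter only triggers an "uncorrected" warning.
Cluster segmentation of raw streams is out of scope — dwell tables
arrive pre-clustered.

Derived quantities: K_d = k_off/k_on (molar); the dimensionless proxy
K_d ≈ E₀/E₁ is kept flagged (`kd_is_molar=False`) because a molar value
would require an open-state affinity constant that is not estimated —
the proxy is valid only where that constant cancels (ΔΔG-style
comparisons). Energies use RT ln K_d with R·T derived from the gas
constant at 296.15 K (23 °C), printing as the familiar 0.59 kcal/mol;
the coefficient is never hard-coded. Background-mutation corrections
divide a measured E₀ by the product of known fold changes (energetic
independence assumed). φ is the unweighted OLS slope of log10(opening
rate) on log10(gating equilibrium constant). Voltage is metadata only.

**Mode segmentation** (the two-mode single-channel phenotype) is a
package convention, since no published procedure exists: a two-component
Gaussian mixture on per-cluster log10 mean open duration, with a
2-vs-1-component BIC comparison deciding bimodality (unimodal data are
never force-split); prevalence is time-weighted; the switching constant
is the mean total duration of same-mode cluster runs, the ML mean of an
exponential run length. The estimate carries a small positive bias of
order one cluster duration (runs end only at cluster boundaries) and a
negative bias from occasional misclassification; both are kept small by
analysing records whose clusters are much shorter than the switching
constant.

## Synthetic generators

Generators define the conditions under which the pipeline is validated:

* **Hairpin ensembles**: two idealized antiparallel strands (straight
  axes, 3.4 Å rise, backbone N/CA/C placed along the axis) with an exact
  generating twist and optional mean-axis tilt; snapshots add i.i.d.
  Gaussian displacements with per-residue amplitudes, so the expected
  RMSF is amplitude·√3. Idealized geometry is sufficient because the
  axis, twist and RMSF operations consume coordinates, not chemistry.
* **Pocket snapshots**: five hexagonal rings at prescribed centroids and
  normals, a four-atom ligand fragment whose N–C–C–O torsion is placed
  exactly by internal coordinates, and a structural-water pair.
* **H-bond series**: exactly ⌊target·n⌋ snapshots satisfy the criterion,
  so measured occupancy equals the truth with no sampling error.
* **Calibration sets**: 13 points by default (the size of the real
  alanine-mutant design); vdW means uniform on [−12, −5] kcal/mol,
  electrostatic means from the screened-Coulomb surrogate over 3.5–6.5 Å
  (≈ −4.4 to −1.6 kcal/mol), chosen so rescaled totals span the −4 to
  −7 kcal/mol window of real site estimates; experimental energies are
  the exact linear combination plus Gaussian noise.
* **Dwell data**: exact continuous-time Markov simulation of the 3-state
  scheme (jump chain plus exponential sojourns), aggregated by class.
  The bimodal variant alternates exponential mode holds (default
  matching the observed ~20 ms switching) and fills each hold with ≥1
  cluster of that mode's scheme.

Every generator is seed-deterministic and emits a truth record; recovery
tests read expected values only from these records. What passing tests
show — and what they do not: synthetic ensembles have no force-field
correlations, no anharmonicity and no solvent, so recoveries demonstrate
the *estimators* are correct and calibrated under their stated models,
not that the models capture every feature of real MD or patch-clamp
data (real dwell records, for instance, would additionally need
missed-event correction).

## Problem sizes and numerical choices

* Calibration recovery: 13 points, noise sd 0.2 kcal/mol, 200 seeds;
  median |α̂−α*| and |β̂−β*| are within half a grid step (≤0.05).
* Kinetics recovery: 5,000 events at each of three concentrations
  (0.3×, 1×, 3× K_d), 20 seeds in the test suite and 9 in the acceptance
  script; all four rates and K_d recover within 10% (median).
* Geometry oracles: 1,000 random 5-point sets for the volume, 50
  hypothesis-driven random torsions/rotations, 1e−6 tolerances on
  constructed angles.
* RMSF: 2,000 snapshots (the ensemble size of the motivating analyses),
  5% tolerance on amplitude recovery.
* Mode segmentation: 500 clusters of 5 openings, 20 ms switching, 10×
  b_close separation; prevalence within ±0.1 of balance and switching
  constant within 20%.
* Degenerate inputs fail loudly with typed errors (`UsageError`,
  `FormatError`, `StructuralError`, `DegenerateGeometryError`);
  warnings, not errors, flag recoverable oddities (empty selections,
  stray exclusions, single-point calibrations, sub-100-event fits).

## Known limitations

* No binary trajectory formats, no topology/force-field parsing, no
  PB solver, no docking or homology modelling — components upstream of
  this package's scope.
* The dwell likelihood ignores missed events and treats the final
  (possibly censored) dwell of a record as complete; both are
  appropriate for idealized synthetic data only.
* The E₀/E₁ proxy is never converted to molar units.
* Mode segmentation assumes mode differences expressed in open-channel
  lifetime; modes differing only in closed-dwell structure would need a
  different feature.
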