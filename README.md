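# sitecraft

Analysis machinery for comparing the neurotransmitter binding sites of
fetal versus adult endplate nicotinic acetylcholine receptors (AChRs).
Muscle AChRs carry two agonist sites at subunit interfaces — αδ+αγ in the
fetal receptor, αδ+αε in the adult — built on the same five-residue
aromatic core, yet the fetal αγ site binds acetylcholine with ~30-fold
higher affinity. This package implements, as a tested and reusable
library, the three quantitative pillars of that comparison:

1. **Ensemble binding-energy scoring** (`sitecraft.scoring`).
   A construct's binding energy is scored from per-snapshot force-field
   components as ΔE = ⟨α·E_vdW + β·ΔE_elec⟩ over a coordinate ensemble,
   with the dimensionless coefficients (α, β) calibrated by an exhaustive
   grid scan over [0, 2]² that minimizes the RMSE against experimental
   energies (+RT ln K_d from single-channel kinetics). On the receptor's
   aromatic-core alanine-mutant set this calibration yields α = 0.22,
   β = 1.24.
2. **Agonist-site structure and dynamics** (`sitecraft.geometry`,
   `sitecraft.dynamics`). Ring centroids and the two-tetrahedron pocket
   volume, SVD strand axes and the β5′–β6 hairpin twist/tilt, the bimodal
   τ2 (N–C–C–O) ligand torsion, hydrogen bonds by the <3.5 Å / ≤30°
   criterion with ensemble occupancies, RMSD with region exclusion and
   drift slopes, and per-residue RMSF with HA−LA difference profiles.
3. **Single-channel gating kinetics** (`sitecraft.kinetics`).
   Simulation and maximum-likelihood rate estimation for the one-site
   scheme A+C⇌AC⇌AO (closed dwells are phase-type over {C, AC}, open
   dwells exponential), with K_d = k_off/k_on, the E₀/E₁ proxy, RT ln K_d
   energy conversions (0.59 kcal/mol per ln unit at 23 °C), background-
   mutation correction, two-site additivity ledgers, φ-values and
   two-mode cluster segmentation.

MD trajectories and patch-clamp records are not distributable, so
`sitecraft.synthetic` generates inputs with the statistical structure
each stage assumes — hairpin ensembles with known twist and fluctuation
amplitudes, calibration tables from known (α*, β*), dwell sequences from
known rate constants — and every generator returns a truth record so
recovery is checked against generator bookkeeping, never against magic
numbers.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on
synthetic inputs; each writes its tables under `results/`.

```sh
python analysis/01_simulate_inputs.py
python analysis/02_structure_metrics.py
python analysis/03_calibrate_affinity.py
python analysis/04_kinetics_affinity.py
python analysis/05_thermo_ledger.py
```

Output from a run of scripts 03–05:

```
calibrated alpha=0.23 beta=1.23 (truth 0.22/1.24); RMSE 0.13 kcal/mol, R^2 0.98, r 0.99
fitted rates: k_on 9.88e+07 /M/s, k_off 9.84e+03 /s, f_open 998 /s, b_close 999 /s
Kd 9.96e-05 M (truth 0.0001 M, 0.4% off); binding energy -5.42 kcal/mol
bimodal record: 2 modes, prevalences {'0': 0.406..., '1': 0.594...}, switching tau 16.7 ms (generated 20 ms)
RT at 23 C: 0.5885 kcal/mol (prints as 0.59)
two-site totals: adult -10.2, fetal -12.2 kcal/mol
fetal-vs-adult site energy gap 2.0 kcal/mol -> 30-fold Kd difference
unliganded gating: E0 ratio 14.2-fold -> +1.6 kcal/mol
```

Reading the numbers: the grid scan recovers the generating rescaling
coefficients to within one grid step under 0.2 kcal/mol measurement
noise; the dwell-time likelihood recovers all four gating rates (and
hence K_d) to ~1% from 15,000 events; the mode segmenter finds the two
planted activity modes and a switching constant near the generated
20 ms; and the thermodynamic ledger turns the published per-site
energies and gating constants into the familiar derived quantities — the
−10.2/−12.2 kcal/mol two-site totals, the ~30-fold fetal/adult K_d
ratio, and the +1.6 kcal/mol unliganded gating energy gap.

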