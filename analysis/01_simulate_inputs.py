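"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/:

* high-affinity (fetal-like) and low-affinity (adult-like) hairpin
  ensembles as multi-model PDB, with truth sidecars — the HA hairpin is
  built ~9 deg more twisted and with larger loop-E fluctuations, the
  structural contrast seen between the two site conformations;
* a 13-point (alpha, beta) calibration table as CSV;
* dwell-time tables at three agonist concentrations from a known gating
  scheme, plus a bimodal cluster sequence switching on a 20 ms time
  constant.
"""

import json
from pathlib import Path

from sitecraft.io import write_dwell_table, write_ensemble
from sitecraft.kinetics import GatingScheme
from sitecraft.synthetic import (
    CalibrationTruth,
    HairpinSpec,
    make_bimodal_dwells,
    make_calibration_set,
    make_dwell_data,
    make_hairpin_ensemble,
)

SEED = 2016
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"

# gating scheme used for the dwell simulations: one-site resting scheme
# with Kd = k_off/k_on = 100 uM
SCHEME = GatingScheme(k_on=1e8, k_off=1e4, f_open=1e3, b_close=1e3)
CONCS_M = [3e-5, 1e-4, 3e-4]

HA_MODE = GatingScheme(k_on=1e8, k_off=1e5, f_open=1e4, b_close=1e4)
LA_MODE = GatingScheme(k_on=1e8, k_off=1e5, f_open=1e4, b_close=1e3)


def dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # HA: more twisted hairpin, mobile loop-E residues; LA: straighter,
    # quieter loop E — amplitudes cycle over residues 107..
    specs = {
        "agWT": HairpinSpec(twist_deg=14.0, fluctuation_A=[0.2, 0.35, 0.35, 0.2],
                            n_snapshots=400, seed=SEED),
        "adWT": HairpinSpec(twist_deg=5.0, fluctuation_A=[0.2, 0.2, 0.2, 0.2],
                            n_snapshots=400, seed=SEED + 1),
    }
    for label, spec in specs.items():
        ens, truth = make_hairpin_ensemble(spec)
        ens.label = label
        write_ensemble(ens, OUT / f"hairpin_{label}.pdb")
        dump(truth, OUT / f"hairpin_{label}.truth.json")
        print(f"wrote hairpin_{label}.pdb  (twist {spec.twist_deg} deg, "
              f"{spec.n_snapshots} snapshots)")

    pts, truth = make_calibration_set(CalibrationTruth(noise_sd=0.2, seed=SEED))
    with open(OUT / "calibration.csv", "w") as fh:
        fh.write("construct,mean_e_vdw,mean_e_elec,experimental_kcal\n")
        for p in pts:
            fh.write(f"{p.construct},{p.mean_e_vdw:.6f},{p.mean_e_elec:.6f},"
                     f"{p.experimental_energy:.6f}\n")
    dump(truth, OUT / "calibration.truth.json")
    print(f"wrote calibration.csv  ({len(pts)} points, noise sd 0.2 kcal/mol)")

    datasets, truth = make_dwell_data(SCHEME, CONCS_M, n_events=5000, seed=SEED)
    for ds in datasets:
        write_dwell_table(ds, OUT / f"dwells_{ds.conc_M:.0e}M.csv")
    dump(truth, OUT / "dwells.truth.json")
    print(f"wrote dwell tables at {CONCS_M} M  (5000 events each)")

    bimodal, truth = make_bimodal_dwells(
        HA_MODE, LA_MODE, switch_tau_s=0.020, n_clusters=500,
        events_per_cluster=5, conc_M=1e-3, seed=SEED,
    )
    write_dwell_table(bimodal, OUT / "dwells_bimodal.csv")
    dump(truth, OUT / "dwells_bimodal.truth.json")
    print("wrote dwells_bimodal.csv  (500 clusters, 20 ms switching)")


if __name__ == "__main__":
    main()
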