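"""Estimate affinity from simulated single-channel dwell records.

Reads the dwell tables written by 01_simulate_inputs.py, fits the four
rate constants of A+C<->AC<->AO by maximum likelihood across the three
agonist concentrations, derives Kd = k_off/k_on and the resting binding
energy RT ln Kd, and segments the bimodal cluster sequence into its two
activity modes.  Writes results/kinetics_report.json.
"""

import json
from pathlib import Path

from sitecraft.io import read_dwell_table
from sitecraft.pipeline import RunConfig, run_kinetics_report, save_report

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs"
OUT = ROOT / "results"


def main():
    truth = json.load(open(INPUTS / "dwells.truth.json"))
    datasets = [
        read_dwell_table(INPUTS / f"dwells_{conc:.0e}M.csv")
        for conc in truth["concs_M"]
    ]
    bimodal = read_dwell_table(INPUTS / "dwells_bimodal.csv")
    bimodal_truth = json.load(open(INPUTS / "dwells_bimodal.truth.json"))

    config = RunConfig(seed=2016)
    report = run_kinetics_report(
        config, {"sim": datasets}, mode_datasets={"bimodal": bimodal}
    )

    fit = report["fits"]["sim"]
    kd_err = abs(fit["kd_M"] - truth["kd_M"]) / truth["kd_M"]
    print(f"fitted rates: k_on {fit['rates']['k_on_per_M_s']:.3g} /M/s, "
          f"k_off {fit['rates']['k_off_per_s']:.3g} /s, "
          f"f_open {fit['rates']['f_open_per_s']:.3g} /s, "
          f"b_close {fit['rates']['b_close_per_s']:.3g} /s")
    print(f"Kd {fit['kd_M']:.3g} M (truth {truth['kd_M']:.3g} M, "
          f"{100 * kd_err:.1f}% off); binding energy "
          f"{fit['binding_energy_kcal']:.2f} kcal/mol")

    modes = report["modes"]["bimodal"]
    print(f"bimodal record: {modes['n_modes']} modes, prevalences "
          f"{modes['prevalence']}, switching tau "
          f"{1000 * modes['switching_tau_s']:.1f} ms "
          f"(generated {1000 * bimodal_truth['switch_tau_s']:.0f} ms)")

    save_report(report, OUT / "kinetics_report.json")
    print("wrote kinetics_report.json")


if __name__ == "__main__":
    main()
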