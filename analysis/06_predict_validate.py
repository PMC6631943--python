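#!/usr/bin/env python
"""Predict each formulation's plasma exposure from its in-vitro release
rate alone (through the fitted power-law correlation and the population
model) and score the predictions by absolute % prediction error against
the simulated cohort's observed NCA summary.

Writes results/validation.csv and results/predicted_profiles.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

import popivivc as pv
from popivivc import defaults, io_cli

ROOT = Path(__file__).resolve().parent.parent / "results"

ivivc = io_cli.ivivc_model_from_dict(io_cli.load_json(ROOT / "ivivc_model.json")["refitted"])
pop = io_cli.population_model_from_dict(io_cli.load_json(ROOT / "popk_fit.json")["estimates"])
vitro = io_cli.load_json(ROOT / "invitro_fit.json")["fits"]

profiles, pred_cmax, pred_auc = [], {}, {}
for f in defaults.FORMULATIONS:
    inv = pv.InVitroDissolutionParams(vitro[f]["vmax_invitro"], vitro[f]["am50_invitro"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = pv.predict_from_invitro(
            ivivc, pop, inv, defaults.DOSES[f], formulation_id=f, mode="typical"
        )
    profiles.append(pred.profile)
    pred_cmax[f], pred_auc[f] = pred.cmax, pred.auc_all
io_cli.write_plasma_csv(profiles, ROOT / "predicted_profiles.csv")

nca = pd.read_csv(ROOT / "nca.csv")
means = nca[nca.subject_id == "mean"].set_index("formulation_id")
obs_cmax = {f: float(means.loc[f, "cmax_ng_ml"]) for f in defaults.FORMULATIONS}
obs_auc = {f: float(means.loc[f, "auc_all"]) for f in defaults.FORMULATIONS}

report = pv.validate(obs_cmax, pred_cmax, obs_auc, pred_auc, threshold=10.0)
rows = [
    {
        "formulation": f,
        "observed_cmax": round(report.observed_cmax[f], 1),
        "predicted_cmax": round(report.predicted_cmax[f], 1),
        "pe_cmax": report.pe_cmax[f],
        "observed_auc": round(report.observed_auc[f], 1),
        "predicted_auc": round(report.predicted_auc[f], 1),
        "pe_auc": report.pe_auc[f],
    }
    for f in report.formulations
]
pd.DataFrame(rows).to_csv(ROOT / "validation.csv", index=False)

print(pd.DataFrame(rows).to_string(index=False))
print(f"mean %PE: Cmax {report.mean_pe_cmax:.1f} +/- {report.sd_pe_cmax:.1f}, "
      f"AUC {report.mean_pe_auc:.1f} +/- {report.sd_pe_auc:.1f} "
      f"({'PASS' if report.passed else 'FAIL'} at {report.threshold:.0f}% average)")

# diagnose: how far did the 3-dog arms drift from the population they were
# drawn from?  The correlation can only be as good as the fitted in-vivo
# rates, and those track the realized arms, not the population.
print("\nfitted vs generating in-vivo release rates (population scale):")
for f in defaults.FORMULATIONS:
    fitted = pop.theta[f"vmax_invivo:{f}"]
    print(f"  {f:10s} fitted {fitted:6.3f}   generating {defaults.VMAX_INVIVO[f]:6.3f}")
obs_rank = sorted(obs_cmax, key=obs_cmax.get)
if obs_rank != sorted(defaults.VMAX_INVIVO, key=defaults.VMAX_INVIVO.get):
    print("note: the realized arms rank-invert the formulations' exposure — with "
          "3 subjects per arm and the reference between-subject variances "
          "(CVs up to ~100%), arm means scatter this much by sampling alone; "
          "a monotone rate correlation cannot reproduce an inverted ranking, "
          "so average internal predictability at the 10% level depends on "
          "drawing a low-variability cohort.")
print(f"-> {ROOT / 'validation.csv'}")
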