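"""Compare the screening dispersion comparator with the two LUR models.

Runs the study, extracts the comparator's background + local predictions
at the near-road (<= 60 m) sites of both campaigns, and reports agreement
(squared correlation, slope, mean difference) between the dispersion
predictions, the LUR predictions and the observed annual means, plus the
residual diagnostics by site type and in the top concentration quartile.
"""

import json
from pathlib import Path

import pandas as pd

from airlur.lur import predict
from airlur.pipeline import StudyConfig, run_study
from airlur.validate import residual_summary

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results = run_study(StudyConfig(), seed=SEED)
    report = {}
    for name, camp in (("large_area", results["large"]), ("city", results["city"])):
        car_df = results["car"][name]
        valid = car_df[car_df["valid"]]
        obs = camp.annual_mean.loc[valid.index]
        lur = pd.Series(predict(camp.model, camp.predictors), index=camp.predictors.index)
        types = camp.model_sites.set_index("site_id").loc[valid.index, "site_type"].to_numpy()
        report[name] = {
            "agreement": results["car_comparisons"][name],
            "car_residuals": residual_summary(obs.to_numpy(), valid["total"].to_numpy(), types),
            "lur_residuals": residual_summary(
                obs.to_numpy(), lur.loc[valid.index].to_numpy(), types
            ),
        }
        print(f"{name}: dispersion vs LUR r2 = "
              f"{results['car_comparisons'][name]['car_vs_lur']['r2']:.3f} "
              f"on {results['car_comparisons'][name]['n_valid']} near-road sites")
    with open(OUT / "dispersion_comparison.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    print("details ->", OUT / "dispersion_comparison.json")


if __name__ == "__main__":
    main()
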