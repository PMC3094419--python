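"""Run the full two-campaign study: impute, fit both LUR models, validate.

Re-runs everything from the master seed (stages share the seeds used by
01_generate_region.py, so the campaigns are identical), then writes all
model and validation artefacts under results/study/ and prints the
summary table juxtaposing in-sample, leave-one-out and cross-campaign
R-squared per model.
"""

from pathlib import Path

from airlur.pipeline import StudyConfig, run_study

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    results = run_study(StudyConfig(), seed=SEED, outdir=OUT)
    print(results["summary"].to_string(index=False))
    for camp in (results["large"], results["city"]):
        print(f"\n{camp.name}: per-IQR effects")
        print(camp.effects.round(3).to_string(index=False))
    print("\nall artefacts under", OUT)


if __name__ == "__main__":
    main()
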