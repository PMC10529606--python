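"""Linear (mixed) models of trip characteristics and descriptives.

One row per animal for trip frequency (plain linear model); one row per
complete trip, ln-transformed, with a pup random intercept for trip
distance, trip duration and post-trip haulout duration.  All by maximum
likelihood; ranked by AICc with a likelihood-ratio confirmation of each
winner against the highest-likelihood candidate.
"""

from pathlib import Path

import pandas as pd

from puptrack.pipeline import _animal_summary, run_trip_models

OUT = Path("results/analysis")


def main() -> None:
    trips = pd.read_csv(OUT / "trips.csv", parse_dates=["start", "end"])
    cohort = pd.read_csv(OUT / "cohort.csv")
    per_animal = _animal_summary(cohort, trips)
    per_animal.to_csv(OUT / "animal_summary.csv", index=False)

    tm = run_trip_models(trips, per_animal)
    for name, (table, lr) in tm["rankings"].items():
        table.to_csv(OUT / f"tripmodel_{name}.csv", index=False)
        line = f"{name}: best {table['model'].iloc[0]}"
        if lr is not None:
            line += (f"; LR vs highest-LL: chi2={lr['chi2']:.2f}, "
                     f"df={lr['df']}, p={lr['p']:.2f}")
        print(line)

    print("\ndescriptives (complete trips):")
    for key, s in tm["descriptives"].items():
        print(f"  {key}: mean {s['mean']:.1f} +/- {s['sd']:.1f} "
              f"(CV {s['cv_pct']:.0f}%, n={s['n']})")


if __name__ == "__main__":
    main()
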