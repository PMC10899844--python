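#!/usr/bin/env python
"""Generate the default synthetic CGM cohort (20 users x 60 days).

Writes streams, profiles and the ground-truth event log under
results/data/ and prints the cohort's basic shape: users, readings, and
how many latent hypo/hyper excursions the generator injected.
"""

from pathlib import Path

from cgmrisk.data_io import write_cohort
from cgmrisk.synthetic import emulate_city_defaults, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(emulate_city_defaults(seed=SEED))
    write_cohort(cohort, OUT / "streams.csv", OUT / "profiles.csv")
    truth.to_frame().to_csv(OUT / "truth_events.csv", index=False)
    n_readings = sum(len(s) for s in cohort.streams.values())
    print(f"cohort: {len(cohort)} users, {n_readings} readings")
    print(f"latent events: {truth.count('hypo')} hypo, {truth.count('hyper')} hyper")
    print(f"wrote streams/profiles/truth to {OUT}")


if __name__ == "__main__":
    main()
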