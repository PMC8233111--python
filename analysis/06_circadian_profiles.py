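#!/usr/bin/env python
"""Circadian profiles of network metrics and day/night bootstrap tests.

Pools per-window metric values (strength, degree, clustering, path length)
from the cohort by minute of day and state, writes the group profile
(bins with fewer than five values carry no mean), and runs the day
(11:00-13:00) vs night (23:00-01:00) bootstrap difference-of-means test for
each state/metric.  The cohort's staggered clock starts give group coverage
of the full 24-hr clock even though each recording is 6 hr long.
"""

import json

import pandas as pd

import cohort
from circanet import aggregate, circadian


def main() -> None:
    tcs = []
    for subject in cohort.load_cohort():
        series = aggregate.windowed_series(subject["tensor"])
        for metric in circadian.METRICS:
            tc = circadian.metric_timecourse(series, subject["schedule"],
                                             metric,
                                             clock_start=subject["clock_start"])
            tc.insert(0, "subject", subject["k"])
            tcs.append(tc)
    pooled = pd.concat(tcs, ignore_index=True)
    profile = circadian.build_profile(pooled)

    tests = {}
    for state in ("wake", "sleep"):
        for metric in circadian.METRICS:
            sub = pooled[pooled["metric"] == metric]
            day, night = circadian.select_pools(sub, state, window_s=300)
            if len(day) and len(night):
                t = circadian.day_night_test(day, night, seed=cohort.SEED)
                tests[f"{state}_{metric}"] = vars(t)

    cohort.RESULTS.mkdir(parents=True, exist_ok=True)
    pooled.to_csv(cohort.RESULTS / "circadian_timecourses.csv", index=False)
    profile.to_csv(cohort.RESULTS / "circadian_profile.csv", index=False)
    (cohort.RESULTS / "circadian_day_night.json").write_text(
        json.dumps(tests, indent=2, default=float))

    print(profile.groupby(["state", "metric"])["count"].sum())
    for name, t in tests.items():
        print(f"{name}: night-day = {t['difference']:+.4f} "
              f"CI [{t['ci_low']:+.4f}, {t['ci_high']:+.4f}] "
              f"{'significant' if t['significant'] else 'ns'}")


if __name__ == "__main__":
    main()
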