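#!/usr/bin/env python
"""Weighted graph metrics of the sleep and wake networks per subject.

Degree is computed on the raw fraction networks; the Onnela clustering
coefficient and the inverse-weight characteristic path length on the
max-normalized networks.  Writes results/graph_metrics.csv.
"""

import pandas as pd

import cohort
from circanet import aggregate, graphs


def main() -> None:
    rows = []
    for subject in cohort.load_cohort():
        tensor, schedule = subject["tensor"], subject["schedule"]
        for state in ("wake", "sleep"):
            W = aggregate.state_average(tensor, schedule, state,
                                        n_samp=1000, n_boot=100,
                                        seed=subject["config"].seed)
            gm = graphs.graph_metrics(W)
            rows.append({"subject": subject["k"], "state": state,
                         "mean_degree": gm.mean_degree,
                         "mean_clustering": gm.mean_clustering,
                         "char_path_length": gm.char_path_length})
    df = pd.DataFrame(rows)
    cohort.RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(cohort.RESULTS / "graph_metrics.csv", index=False)
    print(df.to_string(index=False))
    wide = df.pivot(index="subject", columns="state")
    print("\nDegree higher in sleep for",
          int((wide["mean_degree"]["sleep"] > wide["mean_degree"]["wake"]).sum()),
          "of", len(wide), "subjects")


if __name__ == "__main__":
    main()
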