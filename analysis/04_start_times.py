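#!/usr/bin/env python
"""Effect of delaying the MAP treatment start on the post-treatment tumor.

For small, medium, and large (steady-state) tumors in each cluster, start
two MAP cycles 1 week, 1 month, 3 months, or 6 months after diagnosis and
record the cancer population 3 days after the second cycle ends. Writes the
delay table under results/start_times/.
"""

import argparse
from pathlib import Path

import pandas as pd

from osteochemo import engine
from osteochemo.cohort import make_cluster_suite
from osteochemo.regimens import START_TIME_PRESETS, build_map


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results/start_times"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    suite = make_cluster_suite(seed=args.seed)
    rows = []
    for cid, sc in suite.items():
        scaling = engine.scaling_from(sc.steady_state, None, sc.chemo)
        for size in ("small", "medium", "large"):
            row = {"cluster": cid, "size": size,
                   "initial_cancer": sc.initial_states[size][8]}
            for label, start in START_TIME_PRESETS.items():
                reg = build_map(treatment_start=start)
                traj = engine.simulate(sc.initial_states[size], sc.params,
                                       sc.chemo, reg, horizon=start + 76.0,
                                       scaling=scaling, output_dt=2.0)
                row[label] = traj.value("C", start + 73.0)
            rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "delay_table.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3e}"))
    grow = table[table["size"] != "large"]
    worst = (grow["6mo"] / grow["1wk"]).max()
    print(f"\nfor growing tumors a 6-month delay inflates the post-treatment "
          f"cancer population by up to {worst:.1f}x; steady-state tumors are "
          f"delay-insensitive")


if __name__ == "__main__":
    main()
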