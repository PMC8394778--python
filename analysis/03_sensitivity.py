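#!/usr/bin/env python
"""Local sensitivity of cancer and total cell populations to the
chemotherapy parameters.

Integrates the augmented sensitivity system for all 18 chemotherapy
parameters on cluster 1 under one MAP cycle, then averages the
time-averaged sensitivities over a ±10% parameter neighborhood on a sparse
node set. Writes per-parameter scores (CSV) and the top-5 rankings (JSON)
under results/sensitivity/. The node count defaults to 7 (the star stencil
of the three most informative parameters plus center is already rank-stable;
pass --m 39 for the full-size neighborhood study).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from osteochemo.cohort import make_cluster_suite
from osteochemo.parameters import SENSITIVITY_PARAMETERS
from osteochemo.regimens import build_map
from osteochemo.sensitivity import (
    SensitivitySpec,
    neighborhood_average,
    sensitivity_trajectories,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--m", type=int, default=7, help="neighborhood node count")
    ap.add_argument("--cluster", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sensitivity"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sc = make_cluster_suite(seed=args.seed)[args.cluster]
    reg = build_map(treatment_start=7.0, n_cycles=1)
    spec = SensitivitySpec(parameters=SENSITIVITY_PARAMETERS,
                           outputs=("C", "total"), horizon=45.0,
                           omega_rel=0.10, n_nodes=args.m)

    point = sensitivity_trajectories(sc.steady_state, sc.params, sc.chemo,
                                     reg, spec)
    df = pd.DataFrame({
        "parameter": spec.parameters,
        "S_cancer": point.S["C"],
        "S_rel_cancer": point.S_rel["C"],
        "S_total": point.S["total"],
        "S_rel_total": point.S_rel["total"],
    })
    df.to_csv(args.out / f"cluster{args.cluster}_point_scores.csv", index=False)
    print("point-estimate top 5 (relative sensitivity of cancer population):")
    for name, score in point.ranking("C"):
        print(f"  {name:12s} {score:+.4f}")

    hood = neighborhood_average(sc.steady_state, sc.params, sc.chemo, reg, spec,
                                seed=args.seed)
    (args.out / f"cluster{args.cluster}_neighborhood_ranking.json").write_text(
        json.dumps({"n_nodes": hood["n_nodes"], "ranking": hood["ranking"]},
                   indent=2))
    print(f"\nneighborhood ({hood['n_nodes']} nodes) top 5:")
    for name, score in hood["ranking"]["C"]:
        print(f"  {name:12s} {score:+.4f}")

    # robustness of the two assumption-class parameters: sweep them and
    # report the spread of the post-treatment cancer population
    from osteochemo import engine

    scaling = engine.scaling_from(sc.steady_state, reg, sc.chemo)

    def terminal(chemo):
        traj = engine.simulate(sc.steady_state, sc.params, chemo, reg,
                               horizon=45.0, scaling=scaling, output_dt=2.0)
        return traj["C"][-1]

    base = terminal(sc.chemo)
    sweeps = {
        "alpha_NCA": [sc.chemo.replace(alpha_NCA=v) for v in (0.2, 0.4, 0.6, 1.0)],
        "delta_CTcA3": [sc.chemo.replace(delta_CTcA3=f * sc.chemo.delta_CTcA3)
                        for f in (0.2, 0.5, 2.0, 5.0)],
    }
    report = {}
    for name, variants in sweeps.items():
        vals = [terminal(ch) for ch in variants]
        spread = (max(vals + [base]) - min(vals + [base])) / base
        report[name] = spread
        print(f"assumed-parameter sweep {name}: terminal-cancer spread "
              f"{100 * spread:.2f}% of nominal")
    (args.out / f"cluster{args.cluster}_assumed_parameter_sweep.json").write_text(
        json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
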