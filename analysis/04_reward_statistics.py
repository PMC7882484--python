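#!/usr/bin/env python
"""Compare entropy rewards of matching vs mismatching maneuvers.

Joins rewards with maneuver labels, runs the two-sample K-S test on the
realized-reward distributions, bins rewards by hit rate and cumulative hits,
computes windowed RMSE between realized and expected rewards, and writes
report.json (plus optional figures with --plots).
"""

import argparse
from pathlib import Path

from mothtaxis import PipelineConfig
from mothtaxis.pipeline import analyze_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    cfg = PipelineConfig()
    rep = analyze_stage(cfg, args.out)
    print(f"included samples: {rep['group_sizes']}")
    if "ks" in rep:
        ks = rep["ks"]["dS"]
        print(f"K-S on dS (match vs mismatch): D={ks['D']:.4f} p={ks['p']:.3g}")
        print(f"mean dS: match={rep['mean_dS']['match']:.5f} "
              f"mismatch={rep['mean_dS']['mismatch']:.5f} nats")
    if "rmse" in rep:
        sp = rep["rmse"]["spearman_vs_cum_hits"]
        print(f"windowed RMSE: {rep['rmse']['n_windows']} windows, "
              f"mean {rep['rmse']['mean']:.4f} nats")
        print(f"Spearman(RMSE, cumulative hits): rho={sp['rho']:.3f} p={sp['p']:.3g}")
    if args.plots:
        from mothtaxis import plots
        plots.render_run(args.out)
        print(f"figures written under {args.out}")


if __name__ == "__main__":
    main()
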