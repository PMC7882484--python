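"""Optional figure rendering (entropy traces, reward CDFs, RMSE trends)."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["entropy_traces", "reward_cdfs", "rmse_trend", "render_run"]


def entropy_traces(reward_tables: list[pd.DataFrame], path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for rdf in reward_tables:
        ax.plot(rdf["t"], rdf["S"], color="0.6", lw=0.6)
    if reward_tables:
        grid = pd.concat([r.set_index("t")["S"] for r in reward_tables], axis=1)
        ax.plot(grid.index, grid.mean(axis=1), color="tab:blue", lw=2,
                label="mean")
        ax.legend()
    ax.set_xlabel("time (s)")
    ax.set_ylabel("belief entropy S (nats)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reward_cdfs(report: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for status, style in (("match", "tab:blue"), ("mismatch", "tab:red")):
        curve = report.get("ecdf", {}).get(status, {})
        if curve.get("x"):
            ax.plot(curve["x"], curve["F"], color=style, label=status)
    ax.set_xlabel(r"entropy reward $\Delta S$ (nats)")
    ax.set_ylabel("CDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rmse_trend(rmse_table: pd.DataFrame, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    for ax, cov in zip(axes, ("cum_hits", "hit_rate")):
        for status, color in (("match", "tab:blue"), ("mismatch", "tab:red")):
            sel = rmse_table[rmse_table["match"] == status]
            ax.scatter(sel[cov], sel["rmse"], s=8, color=color, label=status)
        ax.set_xlabel(cov.replace("_", " "))
    axes[0].set_ylabel("windowed RMSE (nats)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_run(outdir) -> None:
    """Render all figures available from one run directory."""
    outdir = Path(outdir)
    reward_files = sorted((outdir / "rewards").glob("trial_*.csv"))
    if reward_files:
        entropy_traces([pd.read_csv(p) for p in reward_files],
                       outdir / "fig_entropy_traces.png")
    report_path = outdir / "report.json"
    if report_path.exists():
        reward_cdfs(json.loads(report_path.read_text()), outdir / "fig_reward_cdfs.png")
    rmse_path = outdir / "rmse_windows.csv"
    if rmse_path.exists():
        rmse_trend(pd.read_csv(rmse_path), outdir / "fig_rmse_trend.png")
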