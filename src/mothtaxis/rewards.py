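"""Comparative statistics of entropy rewards by match/mismatch status.

Joins the per-sample entropy rewards (dS, E[dS]) of the infotaxis replay
with the maneuver labels, then compares the two behavioural classes with a
two-sample Kolmogorov-Smirnov test, empirical CDFs and histograms, binned
means of the rewards against the hit rate and the cumulative hit count, and
a windowed root-mean-square error between realized and expected rewards

    RMSE = sqrt( (1/N) * sum_i (dS_{i+1} - E[dS_i])^2 )

over non-overlapping windows of N samples (N = 20 by default, one second of
data at the 20 Hz sampling rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .maneuvers import EXCLUDED, MATCH, MISMATCH

__all__ = [
    "GroupedRewards", "join_records", "ks_two_sample", "ecdf_and_histogram",
    "binned_reward_stat", "rmse_windows", "windowed_rmse_table",
    "analysis_report", "report_to_json", "report_from_json",
]


@dataclass
class GroupedRewards:
    """Reward samples split by match status (excluded samples dropped)."""

    groups: dict[str, pd.DataFrame] = field(default_factory=dict)

    def samples(self, status: str, column: str = "dS") -> np.ndarray:
        df = self.groups.get(status)
        if df is None or len(df) == 0:
            return np.empty(0)
        return df[column].to_numpy()

    @property
    def n_included(self) -> int:
        return sum(len(df) for df in self.groups.values())

    @property
    def empty(self) -> bool:
        return self.n_included == 0


def join_records(rewards: pd.DataFrame, maneuvers: pd.DataFrame,
                 tol: float = 1e-9) -> GroupedRewards:
    """Align reward and maneuver records sample-by-sample on t.

    The reward table has one row per displacement (length n-1), the maneuver
    table one row per sample (length n); rows are matched on their shared
    times and excluded samples are dropped.  A time-base mismatch raises.
    """
    rt = rewards["t"].to_numpy(dtype=float)
    mt = maneuvers["t"].to_numpy(dtype=float)
    man = maneuvers.sort_values("t").reset_index(drop=True)
    rew = rewards.sort_values("t").reset_index(drop=True)
    rt, mt = rew["t"].to_numpy(float), man["t"].to_numpy(float)
    if rt.size > mt.size or not np.allclose(rt, mt[:rt.size], atol=tol):
        raise ValueError("reward and maneuver time bases do not match")
    lab = man["match"].to_numpy()[:rt.size]
    joined = rew.assign(match=lab)
    groups = {s: joined[joined["match"] == s].drop(columns="match")
              for s in (MATCH, MISMATCH)}
    return GroupedRewards(groups)


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ecdf_and_histogram(samples: np.ndarray, bins: int = 50
                       ) -> dict[str, np.ndarray]:
    """Empirical CDF (x sorted, F from 1/n to 1) and histogram counts."""
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size == 0:
        raise ValueError("samples must be nonempty")
    counts, edges = np.histogram(s, bins=bins)
    return {"x": s, "F": np.arange(1, s.size + 1) / s.size,
            "hist_counts": counts, "hist_edges": edges}


def binned_reward_stat(values: np.ndarray, covariate: np.ndarray,
                       edges: list[float] | np.ndarray) -> pd.DataFrame:
    """Per-bin mean and count of ``values`` grouped by ``covariate`` bins.

    Bins are [e_i, e_{i+1}) with the last bin closed; values whose covariate
    falls outside all edges are excluded and reported via the returned
    frame's ``n_outside`` attribute.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.size != covariate.size:
        raise ValueError("values and covariate must have equal length")
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.digitize(covariate, edges) - 1
    idx[covariate == edges[-1]] = edges.size - 2  # close the last bin
    inside = (idx >= 0) & (idx <= edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = inside & (idx == b)
        n = int(sel.sum())
        rows.append({"bin_lo": float(edges[b]), "bin_hi": float(edges[b + 1]),
                     "n": n,
                     "mean": float(values[sel].mean()) if n else float("nan")})
    out = pd.DataFrame(rows)
    out.attrs["n_outside"] = int((~inside).sum())
    return out


def rmse_windows(dS: np.ndarray, EdS: np.ndarray, n_window: int) -> np.ndarray:
    """Windowed RMSE between realized and expected rewards.

    Pairs (dS_{i+1}, E[dS_i]) are formed for i = 0..L-2 and grouped into
    non-overlapping blocks of ``n_window`` pairs (a trailing partial block is
    dropped); each block's RMSE is returned.  Series shorter than
    ``n_window + 1`` are rejected.
    """
    dS = np.asarray(dS, dtype=float)
    EdS = np.asarray(EdS, dtype=float)
    if dS.size != EdS.size:
        raise ValueError("series must be aligned")
    if dS.size < n_window + 1:
        raise ValueError(f"series of length {dS.size} shorter than N+1={n_window + 1}")
    err = dS[1:] - EdS[:-1]
    n_blocks = err.size // n_window
    blocks = err[:n_blocks * n_window].reshape(n_blocks, n_window)
    return np.sqrt(np.mean(blocks ** 2, axis=1))


def windowed_rmse_table(rewards: pd.DataFrame, maneuvers: pd.DataFrame,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-window RMSE with covariates and a majority-vote match status.

    Each non-overlapping window of N reward pairs reports its RMSE, its mean
    hit rate, its final cumulative hit count, and the majority match label of
    its samples (ties or majority-excluded windows are labelled excluded).
    """
    cfg = config or AnalysisConfig()
    n = cfg.rmse_window
    dS = rewards["dS"].to_numpy(float)
    EdS = rewards["EdS"].to_numpy(float)
    rmse = rmse_windows(dS, EdS, n)
    lab = maneuvers["match"].to_numpy()[:len(rewards)]
    rows = []
    for b, val in enumerate(rmse):
        sl = slice(b * n, (b + 1) * n)
        labels = lab[sl]
        n_match = int((labels == MATCH).sum())
        n_mis = int((labels == MISMATCH).sum())
        if n_match > n_mis and n_match >= n / 2:
            status = MATCH
        elif n_mis > n_match and n_mis >= n / 2:
            status = MISMATCH
        else:
            status = EXCLUDED
        rows.append({
            "window": b,
            "rmse": float(val),
            "hit_rate": float(rewards["hit_rate"].to_numpy(float)[sl].mean()),
            "cum_hits": float(rewards["cum_hits"].to_numpy(float)[sl][-1]),
            "match": status,
        })
    return pd.DataFrame(rows)


def analysis_report(groups: GroupedRewards,
                    rmse_table: pd.DataFrame | None = None,
                    config: AnalysisConfig | None = None) -> dict:
    """Structured summary of the match-vs-mismatch reward comparison."""
    cfg = config or AnalysisConfig()
    a = groups.samples(MATCH, "dS")
    b = groups.samples(MISMATCH, "dS")
    report: dict = {
        "group_sizes": {MATCH: int(a.size), MISMATCH: int(b.size)},
        "alpha": cfg.alpha,
    }
    if a.size and b.size:
        d_ds, p_ds = ks_two_sample(a, b)
        d_e, p_e = ks_two_sample(groups.samples(MATCH, "EdS"),
                                 groups.samples(MISMATCH, "EdS"))
        report["ks"] = {"dS": {"D": d_ds, "p": p_ds},
                        "EdS": {"D": d_e, "p": p_e}}
        report["mean_dS"] = {MATCH: float(a.mean()), MISMATCH: float(b.mean())}
        report["mean_EdS"] = {
            MATCH: float(groups.samples(MATCH, "EdS").mean()),
            MISMATCH: float(groups.samples(MISMATCH, "EdS").mean())}
        report["mean_dS_diff_sign"] = int(np.sign(b.mean() - a.mean()))
        report["significant"] = bool(p_ds < cfg.alpha)
        def _records(table: pd.DataFrame) -> list[dict]:
            # empty bins carry a NaN mean; serialize as null so the report
            # round-trips exactly through JSON
            recs = table.to_dict("records")
            for r in recs:
                if isinstance(r["mean"], float) and np.isnan(r["mean"]):
                    r["mean"] = None
            return recs

        report["binned"] = {}
        for status in (MATCH, MISMATCH):
            df = groups.groups[status]
            report["binned"][status] = {
                "dS_vs_hit_rate": _records(binned_reward_stat(
                    df["dS"], df["hit_rate"], cfg.hit_rate_edges)),
                "dS_vs_cum_hits": _records(binned_reward_stat(
                    df["dS"], df["cum_hits"], cfg.cum_hits_edges)),
                "EdS_vs_hit_rate": _records(binned_reward_stat(
                    df["EdS"], df["hit_rate"], cfg.hit_rate_edges)),
            }
        report["ecdf"] = {}
        for status in (MATCH, MISMATCH):
            s = groups.samples(status, "dS")
            if s.size == 0:
                report["ecdf"][status] = {"x": [], "F": []}
                continue
            curve = ecdf_and_histogram(s, cfg.histogram_bins)
            step = max(1, s.size // 256)  # keep the serialized report small
            report["ecdf"][status] = {"x": curve["x"][::step].tolist(),
                                      "F": curve["F"][::step].tolist()}
    if rmse_table is not None and len(rmse_table):
        rho, p_rho = stats.spearmanr(rmse_table["cum_hits"], rmse_table["rmse"])
        rho = None if np.isnan(rho) else float(rho)
        p_rho = None if np.isnan(p_rho) else float(p_rho)
        report["rmse"] = {
            "n_windows": int(len(rmse_table)),
            "mean": float(rmse_table["rmse"].mean()),
            "by_status": {
                s: float(rmse_table.loc[rmse_table["match"] == s, "rmse"].mean())
                for s in (MATCH, MISMATCH)
                if (rmse_table["match"] == s).any()},
            "spearman_vs_cum_hits": {"rho": rho, "p": p_rho},
        }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1)


def report_from_json(blob: str) -> dict:
    return json.loads(blob)
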