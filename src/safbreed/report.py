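"""Genetic gain, gain tables, inbreeding trajectories and plots.

Gain between consecutive parent sets is expressed in units of the cycle-1
GEBV standard deviation so the two traits are comparable:

    dG_k = (mean GEBV of cycle k+1 parents - mean GEBV of cycle k parents)
           / SD of GEBVs among the cycle-1 (initial) parents

computed per replicate per trait, then averaged over replicates.  A program
with five parent sets therefore yields four per-cycle gains, labeled c1..c4,
plus their Sum.  The reciprocal-recurrent expectation — the per-trait gain
expected when two independently improved single-trait streams are crossed —
is approximated by the arithmetic mean of the two streams' cumulative gains.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .founders import TRAITS
from .kinship import delta_F

__all__ = [
    "genetic_gain",
    "per_replicate_gains",
    "summarize_gains",
    "gain_table",
    "reciprocal_recurrent_expectation",
    "inbreeding_trajectory",
    "plot_results",
]


def genetic_gain(mean_i: float, mean_j: float, sigma_cycle1: float) -> float:
    """(mean_j - mean_i) / sigma_cycle1; positive under improvement."""
    if sigma_cycle1 <= 0:
        raise ValueError("sigma_cycle1 must be positive")
    return (mean_j - mean_i) / sigma_cycle1


def per_replicate_gains(result) -> pd.DataFrame:
    """Tidy per-replicate gains: columns (replicate, trait, transition, gain).

    Transition "c{k}" is the change from cycle k parents into cycle k+1
    parents; sigma is the SD of GEBVs among the replicate's cycle-1 parents.
    """
    df = result.to_frame()
    rows = []
    for rep, sub in df.groupby("replicate"):
        sub = sub.sort_values("cycle")
        for t in TRAITS:
            means = sub[f"mean_gebv_{t}"].to_numpy()
            sigma1 = float(sub[f"sd_gebv_{t}"].iloc[0])
            for k in range(len(means) - 1):
                rows.append(
                    {
                        "replicate": rep,
                        "trait": t,
                        "transition": f"c{k + 1}",
                        "gain": genetic_gain(means[k], means[k + 1], sigma1),
                    }
                )
    return pd.DataFrame(rows)


def summarize_gains(per_cycle: pd.DataFrame) -> pd.DataFrame:
    """Append a Sum row (column sums of the per-cycle rows) to a gain table
    whose rows are transitions and columns are strategies."""
    out = per_cycle.copy()
    out.loc["Sum"] = per_cycle.sum(axis=0)
    return out


def gain_table(results: dict) -> pd.DataFrame:
    """Replicate-mean gain table in the standard layout.

    ``results`` maps strategy name -> SimulationResult.  Rows are a
    MultiIndex (trait, transition incl. "Sum"); columns are strategies.
    Gains are averaged over replicates per transition; the Sum row is the
    column sum of the per-cycle averages.
    """
    blocks = []
    strategies = list(results)
    cycles = None
    for strat, res in results.items():
        g = per_replicate_gains(res)
        mean = g.groupby(["trait", "transition"])["gain"].mean()
        n_tr = g["transition"].nunique()
        if cycles is None:
            cycles = n_tr
        elif cycles != n_tr:
            raise ValueError("strategy arms cover different numbers of cycles")
        blocks.append(mean.rename(strat))
    wide = pd.concat(blocks, axis=1)
    parts = []
    for t in TRAITS:
        sub = wide.loc[t]
        sub = sub.reindex(sorted(sub.index, key=lambda c: int(c[1:])))
        sub = summarize_gains(sub)
        sub.index = pd.MultiIndex.from_product([[t], sub.index])
        parts.append(sub)
    table = pd.concat(parts)
    table.index.names = ["trait", "transition"]
    return table[strategies]


def reciprocal_recurrent_expectation(sum_under_a: float, sum_under_b: float) -> float:
    """Expected gain when two independent single-trait streams are crossed:
    the mean of the two streams' cumulative gains for the trait."""
    return (sum_under_a + sum_under_b) / 2.0


def inbreeding_trajectory(results) -> pd.DataFrame:
    """Replicate-averaged F per cycle (and dF between consecutive cycles).

    Accepts one SimulationResult or a {strategy: SimulationResult} mapping;
    returns a frame indexed by cycle with columns F_<strategy> and
    dF_<strategy>.
    """
    if not isinstance(results, dict):
        results = {"program": results}
    cols = {}
    for strat, res in results.items():
        f = res.to_frame().groupby("cycle")["F"].mean()
        cols[f"F_{strat}"] = f
        dfs = pd.Series(
            [delta_F(f.iloc[k], f.iloc[k + 1]) for k in range(len(f) - 1)],
            index=f.index[1:],
        )
        cols[f"dF_{strat}"] = dfs
    return pd.DataFrame(cols)


def plot_results(gain_tbl, trajectories, out_dir, results=None) -> list:
    """Write gain / GEBV-trajectory / inbreeding figures plus CSV sidecars.

    Returns the list of files written.  With no strategies to plot, warns and
    writes nothing.  The CSV sidecars hold exactly the plotted values, so a
    figure can always be re-derived from its data file.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if gain_tbl is None or gain_tbl.shape[1] == 0:
        warnings.warn("no strategies to plot; nothing written")
        return written

    gain_csv = out / "gain_table.csv"
    gain_tbl.to_csv(gain_csv)
    written.append(gain_csv)
    fig, axes = plt.subplots(1, len(TRAITS), figsize=(5 * len(TRAITS), 4), squeeze=False)
    for ax, trait in zip(axes[0], TRAITS):
        sub = gain_tbl.loc[trait].drop(index="Sum", errors="ignore")
        sub.plot(kind="bar", ax=ax)
        ax.set_title(f"Per-cycle genetic gain — {trait}")
        ax.set_ylabel("gain (cycle-1 GEBV SD units)")
    fig.tight_layout()
    gain_png = out / "gain_per_cycle.png"
    fig.savefig(gain_png, dpi=120)
    plt.close(fig)
    written.append(gain_png)

    if trajectories is not None:
        traj_csv = out / "inbreeding.csv"
        trajectories.to_csv(traj_csv)
        written.append(traj_csv)
        fcols = [c for c in trajectories.columns if c.startswith("F_")]
        fig, ax = plt.subplots(figsize=(6, 4))
        for c in fcols:
            ax.plot(trajectories.index, trajectories[c], marker="o", label=c[2:])
        ax.set_xlabel("cycle")
        ax.set_ylabel("inbreeding coefficient F")
        ax.legend()
        fig.tight_layout()
        traj_png = out / "inbreeding.png"
        fig.savefig(traj_png, dpi=120)
        plt.close(fig)
        written.append(traj_png)

    if results:
        rows = []
        for strat, res in results.items():
            df = res.to_frame()
            for t in TRAITS:
                g = df.groupby("cycle")[f"mean_gebv_{t}"].mean()
                s = df.groupby("cycle")[f"sd_gebv_{t}"].mean()
                for cyc in g.index:
                    rows.append(
                        {"strategy": strat, "trait": t, "cycle": cyc,
                         "mean_gebv": g[cyc], "sd_gebv": s[cyc]}
                    )
        gebv = pd.DataFrame(rows)
        gebv_csv = out / "gebv_by_cycle.csv"
        gebv.to_csv(gebv_csv, index=False)
        written.append(gebv_csv)
        fig, axes = plt.subplots(1, len(TRAITS), figsize=(5 * len(TRAITS), 4), squeeze=False)
        for ax, trait in zip(axes[0], TRAITS):
            for strat, sub in gebv[gebv["trait"] == trait].groupby("strategy"):
                ax.errorbar(
                    sub["cycle"], sub["mean_gebv"], yerr=sub["sd_gebv"],
                    marker="o", capsize=3, label=strat,
                )
            ax.set_title(f"Mean GEBV by cycle — {trait}")
            ax.set_xlabel("cycle")
            ax.legend()
        fig.tight_layout()
        gebv_png = out / "gebv_by_cycle.png"
        fig.savefig(gebv_png, dpi=120)
        plt.close(fig)
        written.append(gebv_png)
    return [str(p) for p in written]
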