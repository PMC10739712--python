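"""Idiosyncrasy statistics: spread, sign categories, wt-vs-average deviation.

A mutation (or interaction) is idiosyncratic when its effect varies with the
genetic background.  Three complementary metrics capture this across the
2^(n-1) (or 2^(n-k)) backgrounds of each position/combination:

* spread: twice the sample standard deviation of the log10 effects, deemed
  significant above the 1.5-fold threshold (additional 5- and 10-fold bins);
* sign category: whether the per-background effects are single-sign,
  neutral-negative, neutral-positive, or positive-negative;
* wt-vs-average: |wt-background effect - mean effect|, with a flag for the
  rare strictly opposite significant signs.

Combinations occurring in a single background (order n in an n-locus
landscape) have no spread and are marked non-viable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import FOLD_BINS, TAU

__all__ = [
    "sign_of",
    "category",
    "spread_2sd",
    "wt_vs_avg",
    "summarize",
    "HeterogeneitySummary",
]

SIGN_CATEGORIES = (
    "single-sign",
    "neutral-negative",
    "neutral-positive",
    "positive-negative",
)


def sign_of(value: float, tau: float = TAU) -> str:
    """'positive' above +tau, 'negative' below -tau, else 'neutral'."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if value > tau:
        return "positive"
    if value < -tau:
        return "negative"
    return "neutral"


def category(values: Sequence[float], tau: float = TAU) -> str:
    """Sign-change category of a set of per-background effects.

    positive-negative when both strict signs occur (neutrals irrelevant);
    neutral-positive / neutral-negative when neutrals plus exactly one strict
    sign; single-sign when only one sign class occurs, including all-neutral.
    """
    signs = {sign_of(v, tau) for v in values}
    if not signs:
        raise ValueError("need at least one value")
    if "positive" in signs and "negative" in signs:
        return "positive-negative"
    if signs == {"neutral", "positive"}:
        return "neutral-positive"
    if signs == {"neutral", "negative"}:
        return "neutral-negative"
    return "single-sign"


def spread_2sd(values: Sequence[float]) -> float:
    """2 x sample SD (n-1 denominator) of the log10 effects."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("spread undefined for < 2 values")
    return 2.0 * float(np.std(arr, ddof=1))


def wt_vs_avg(
    values: Sequence[float], wt_value: float, tau: float = TAU
) -> tuple[float, bool, bool]:
    """(|wt - mean|, deviant above tau, strictly-opposite significant signs)."""
    mean = float(np.mean(np.asarray(values, dtype=float)))
    abs_dev = abs(wt_value - mean)
    s_wt, s_avg = sign_of(wt_value, tau), sign_of(mean, tau)
    discrepant = {s_wt, s_avg} == {"positive", "negative"}
    return abs_dev, abs_dev > tau, discrepant


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Per-position / per-combination tables plus dataset-level aggregates."""

    positions: pd.DataFrame       # order-1 summaries
    combinations: pd.DataFrame    # order >= 2 summaries
    aggregates: pd.DataFrame      # one row per order


def _summarize_order(effects: pd.DataFrame, tau: float) -> pd.DataFrame:
    rows = []
    for (landscape, loci, order), grp in effects.groupby(
        ["landscape", "loci", "order"], sort=True
    ):
        vals = grp["value"].to_numpy(dtype=float)
        wt_rows = grp[grp["is_wt_background"]]
        wt_value = float(wt_rows["value"].iloc[0])
        viable = vals.size >= 2
        abs_dev, deviant, discrepant = wt_vs_avg(vals, wt_value, tau)
        rows.append(
            {
                "landscape": landscape,
                "loci": loci,
                "order": order,
                "n_backgrounds": vals.size,
                "viable": viable,
                "spread_2sd": spread_2sd(vals) if viable else np.nan,
                "sign_category": category(vals, tau),
                "wt_value": wt_value,
                "avg_value": float(np.mean(vals)),
                "wt_avg_abs_dev": abs_dev,
                "wt_deviant": deviant,
                "sign_discrepant": discrepant,
            }
        )
    return pd.DataFrame(rows)


def _aggregate(summary: pd.DataFrame, effects: pd.DataFrame, tau: float) -> dict:
    order = int(summary["order"].iloc[0])
    viable = summary[summary["viable"]]
    out: dict = {"order": order, "n_units": len(summary), "n_viable": len(viable)}
    for fold in FOLD_BINS:
        thr = np.log10(fold)
        out[f"pct_spread_gt_{fold:g}fold"] = (
            100.0 * float((viable["spread_2sd"] > thr).mean()) if len(viable) else np.nan
        )
    counts = summary["sign_category"].value_counts()
    for cat in SIGN_CATEGORIES:
        out[f"pct_{cat}"] = 100.0 * counts.get(cat, 0) / len(summary)
    out["pct_wt_deviant"] = 100.0 * float(summary["wt_deviant"].mean())
    out["pct_sign_discrepant"] = 100.0 * float(summary["sign_discrepant"].mean())
    # per-background deviation: each background's effect vs the unit mean
    eff = effects[effects["order"] == order].merge(
        summary[["landscape", "loci", "avg_value"]], on=["landscape", "loci"]
    )
    out["pct_backgrounds_deviant"] = 100.0 * float(
        ((eff["value"] - eff["avg_value"]).abs() > tau).mean()
    )
    return out


def summarize(effects: pd.DataFrame, tau: float = TAU) -> HeterogeneitySummary:
    """Summarise an effect table (output of :func:`epiland.effects.all_effects`,
    any mix of orders) into position/combination tables and aggregates.

    Positions are order-1 units (one mutation x one condition); combinations
    are order >= 2 locus sets.  Aggregate percentages per order: significant
    spread at each fold bin (viable units only), the four sign categories
    (which partition the units), wt deviation, per-background deviation, and
    sign discrepancy.
    """
    if effects.empty:
        raise ValueError("empty effect table")
    summaries, aggs = [], []
    for order in sorted(effects["order"].unique()):
        sub = effects[effects["order"] == order]
        summary = _summarize_order(sub, tau)
        summaries.append(summary)
        aggs.append(_aggregate(summary, effects, tau))
    all_units = pd.concat(summaries, ignore_index=True)
    return HeterogeneitySummary(
        positions=all_units[all_units["order"] == 1].reset_index(drop=True),
        combinations=all_units[all_units["order"] >= 2].reset_index(drop=True),
        aggregates=pd.DataFrame(aggs),
    )
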