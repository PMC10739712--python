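"""Epistasis-rewiring transitions along order-raising mutational steps.

The wt-background EE of an order-n locus set measures how the added n-th
mutation changes the order-(n-1) interaction among the others.  For every
locus set S with |S| >= 3 and every removable element j, the pair
(EE_wt(S \\ {j}), EE_wt(S)) is one transition, classified against the
significance threshold tau:

* no_epistasis:  neither effect significant;
* no_change:     significant before, not after (pre-existing epistasis is
                 untouched by the new mutation);
* new_epistasis: not significant before, significant after;
* change:        both significant -- constructive when the new higher-order
                 term has the same sign as the pre-existing interaction,
                 disruptive when opposite.

A landscape of n loci yields sum_{k=3..n} C(n,k) * k transitions.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .constants import TAU
from .effects import _ee_recursive
from .landscape_io import Landscape

__all__ = ["enumerate_transitions", "classify", "transition_frequencies"]

CATEGORIES = ("no_epistasis", "no_change", "new_epistasis", "change")


def classify(ee_prev: float, ee_new: float, tau: float = TAU) -> tuple[str, str]:
    """(category, subcategory) for one (n-1 -> n)-order transition."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    prev_sig = abs(ee_prev) > tau
    new_sig = abs(ee_new) > tau
    if not prev_sig and not new_sig:
        return "no_epistasis", "none"
    if prev_sig and not new_sig:
        return "no_change", "none"
    if not prev_sig and new_sig:
        return "new_epistasis", "none"
    sub = "constructive" if (ee_prev > 0) == (ee_new > 0) else "disruptive"
    return "change", sub


def enumerate_transitions(
    landscape: Landscape, tau: float = TAU, classified: bool = True
) -> pd.DataFrame:
    """All (n-1)->n wt-background EE transitions of one landscape.

    Empty for n < 3.  Columns: landscape, order, base_set (semicolon-joined
    labels), added_locus (label), ee_prev, ee_new, and, when ``classified``,
    category and subcategory.
    """
    n = landscape.n
    rows = []
    for k in range(3, n + 1):
        for loci in combinations(range(n), k):
            ee_new = _ee_recursive(landscape.values, loci, 0)
            for j in loci:
                base = tuple(i for i in loci if i != j)
                ee_prev = _ee_recursive(landscape.values, base, 0)
                row = {
                    "landscape": landscape.label,
                    "order": k,
                    "base_set": ";".join(landscape.loci[i] for i in base),
                    "added_locus": landscape.loci[j],
                    "ee_prev": ee_prev,
                    "ee_new": ee_new,
                }
                if classified:
                    row["category"], row["subcategory"] = classify(
                        ee_prev, ee_new, tau
                    )
                rows.append(row)
    columns = ["landscape", "order", "base_set", "added_locus",
               "ee_prev", "ee_new"]
    if classified:
        columns += ["category", "subcategory"]
    return pd.DataFrame(rows, columns=columns)


def transition_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category (and change subcategory).

    Percentages over categories sum to 100; the constructive/disruptive split
    is reported as a percentage of the 'change' category.
    """
    if records.empty:
        raise ValueError("no transitions to summarise")
    total = len(records)
    rows = []
    for cat in CATEGORIES:
        count = int((records["category"] == cat).sum())
        rows.append({
            "category": cat, "subcategory": "all",
            "count": count, "percent": 100.0 * count / total,
        })
    changes = records[records["category"] == "change"]
    for sub in ("constructive", "disruptive"):
        count = int((changes["subcategory"] == sub).sum())
        rows.append({
            "category": "change", "subcategory": sub, "count": count,
            "percent": 100.0 * count / len(changes) if len(changes) else 0.0,
        })
    return pd.DataFrame(rows)
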