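"""Single mutational effects (SMEs) and epistatic effects (EEs).

The SME of locus i in background b is the log10 fold-change caused by
mutating i:  SME_i(b) = log10 F(b, i->1) - log10 F(b, i->0).  The order-k EE
of a locus set S in background b (b ancestral at all of S) is defined
recursively as the change that one more mutation imposes on the order-(k-1)
effect:

    EE_S(b) = EE_{S\\{j}}(b, j->1) - EE_{S\\{j}}(b),   any j in S,

and is independent of the pivot j.  Expanding the recursion gives the
equivalent inclusion-exclusion (alternating) sum over all subsets of S, which
is implemented separately as an oracle.  A landscape of n loci contains
n * 2^(n-1) SMEs and C(n,k) * 2^(n-k) order-k EEs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape_io import Landscape, bits_to_index, index_to_bits

__all__ = [
    "sme",
    "epistatic_effect",
    "inclusion_exclusion",
    "all_effects",
    "wt_effect_map",
    "effect_background_label",
]


def _as_index(genotype: str | int) -> int:
    return genotype if isinstance(genotype, int) else bits_to_index(genotype)


def _check_background(landscape: Landscape, loci: Sequence[int], bg: int) -> None:
    for locus in loci:
        if not 0 <= locus < landscape.n:
            raise ValueError(f"locus {locus} out of range for n={landscape.n}")
        if (bg >> locus) & 1:
            raise ValueError(
                f"background {index_to_bits(bg, landscape.n)} is mutated at "
                f"locus {locus}"
            )


def sme(landscape: Landscape, locus: int, background: str | int) -> float:
    """log10 SME of `locus` in `background` (ancestral at `locus`)."""
    bg = _as_index(background)
    _check_background(landscape, (locus,), bg)
    return float(landscape.values[bg | (1 << locus)] - landscape.values[bg])


def epistatic_effect(
    landscape: Landscape, loci: Iterable[int], background: str | int = 0
) -> float:
    """Order-|loci| EE in `background`, by the difference recursion.

    With a single locus this degenerates to the SME.  The pivot is the lowest
    locus index; the result is pivot-independent (see the oracle test).
    """
    loci = tuple(sorted(set(loci)))
    if not loci:
        raise ValueError("locus set must be non-empty")
    bg = _as_index(background)
    _check_background(landscape, loci, bg)
    return _ee_recursive(landscape.values, loci, bg)


def _ee_recursive(values: np.ndarray, loci: tuple[int, ...], bg: int) -> float:
    if len(loci) == 1:
        return float(values[bg | (1 << loci[0])] - values[bg])
    pivot, rest = loci[0], loci[1:]
    return _ee_recursive(values, rest, bg | (1 << pivot)) - _ee_recursive(
        values, rest, bg
    )


def inclusion_exclusion(
    landscape: Landscape, loci: Iterable[int], background: str | int = 0
) -> float:
    """EE as the full alternating sum over all subsets of the locus set.

    sum over T subset of S of (-1)^(|S|-|T|) * log10 F(background with T->1).
    Algebraically identical to the recursion; kept as an independent route.
    """
    loci = tuple(sorted(set(loci)))
    if not loci:
        raise ValueError("locus set must be non-empty")
    bg = _as_index(background)
    _check_background(landscape, loci, bg)
    k = len(loci)
    total = 0.0
    for mask in range(2 ** k):
        t_bits = sum(1 << loci[i] for i in range(k) if (mask >> i) & 1)
        size = bin(mask).count("1")
        total += (-1) ** (k - size) * float(landscape.values[bg | t_bits])
    return total


def effect_background_label(n: int, loci: Sequence[int], bg: int) -> str:
    """Bitstring of the background with 'x' markers at the transition loci."""
    chars = list(index_to_bits(bg, n))
    for locus in loci:
        chars[locus] = "x"
    return "".join(chars)


def all_effects(landscape: Landscape, order: int) -> pd.DataFrame:
    """Every order-k effect in every background, deterministically ordered.

    Exactly C(n, k) * 2^(n-k) rows; locus sets in lexicographic order,
    backgrounds by the integer value of the free loci.  Columns: landscape,
    order, loci (semicolon-joined labels), locus_set (tuple of indices),
    background (bitstring with 'x' at transition loci), background_index,
    is_wt_background, value.
    """
    n = landscape.n
    if not 1 <= order <= n:
        raise ValueError(f"order {order} outside 1..{n}")
    from itertools import combinations

    rows = []
    for loci in combinations(range(n), order):
        free = [i for i in range(n) if i not in loci]
        for b in range(2 ** len(free)):
            bg = sum(1 << free[i] for i in range(len(free)) if (b >> i) & 1)
            rows.append(
                {
                    "landscape": landscape.label,
                    "order": order,
                    "loci": ";".join(landscape.loci[i] for i in loci),
                    "locus_set": loci,
                    "background": effect_background_label(n, loci, bg),
                    "background_index": bg,
                    "is_wt_background": bg == 0,
                    "value": _ee_recursive(landscape.values, loci, bg),
                }
            )
    return pd.DataFrame(rows)


def wt_effect_map(landscape: Landscape, max_order: int) -> dict[tuple[int, ...], float]:
    """Wild-type-background effects for every locus set up to `max_order`.

    These are the coefficients of the biochemical model; at max_order = n they
    decompose every genotype value exactly.
    """
    from itertools import combinations

    n = landscape.n
    if not 1 <= max_order <= n:
        raise ValueError(f"max_order {max_order} outside 1..{n}")
    out: dict[tuple[int, ...], float] = {}
    for k in range(1, max_order + 1):
        for loci in combinations(range(n), k):
            out[loci] = _ee_recursive(landscape.values, loci, 0)
    return out
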