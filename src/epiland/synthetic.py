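"""Synthetic landscape generator with known ground truth.

Every pipeline stage is testable without any measured data: a latent log10
fold-change per genotype is built from per-locus additive effects plus
planted interaction coefficients, optionally squashed through the
four-parameter logistic (emulating non-specific epistasis), and observed
through replicate measurements with Gaussian noise on the log10 scale.

Two coefficient codings are supported because the two decompositions use
different bases:

* ``wt_background``: a subset's term contributes only when all its loci are
  mutated (the product of 0/1 states).  These coefficients are exactly the
  wt-background SMEs/EEs that the effects module extracts.
* ``plus_minus_one``: the term is the product of -1/+1 states.  These are
  exactly the background-averaged (Walsh) coefficients that the linear fit
  recovers.

A documented linear conversion maps one coding onto the other.  Raw
replicate values are 10**(latent + noise), rescaled so the wt raw mean is 1;
a single seeded generator draws additive effects (when distributional) first
and noise second, so identical (spec, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .global_epistasis import LogisticParams, logistic
from .landscape_io import RawMeasurementTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "latent_values",
    "convert_coding",
    "recovery_report",
]

CODINGS = ("wt_background", "plus_minus_one")


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint of one synthetic landscape.

    additive_effects: per-locus log10 values (length n) or a distribution
    ("normal", mean, sd) sampled once per locus.  planted: locus-subset ->
    log10 coefficient, interpreted under ``coding``.  noise_sd: Gaussian SD
    on the log10 scale, applied independently per replicate.
    """

    n: int
    additive_effects: Sequence[float] | tuple[str, float, float] = ("normal", 0.3, 0.3)
    planted: Mapping[tuple[int, ...], float] = field(default_factory=dict)
    coding: str = "wt_background"
    squash: LogisticParams | None = None
    noise_sd: float = 0.0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 loci")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.coding not in CODINGS:
            raise ValueError(f"coding must be one of {CODINGS}")
        for subset in self.planted:
            if not subset or any(not 0 <= i < self.n for i in subset):
                raise ValueError(f"planted subset {subset} outside loci 0..{self.n - 1}")
            if len(set(subset)) != len(subset):
                raise ValueError(f"planted subset {subset} has repeats")


@dataclass(frozen=True)
class GroundTruth:
    """Latent values and coefficients behind one generated landscape."""

    spec: SyntheticSpec
    seed: int
    coefficients: dict[tuple[int, ...], float]  # additive + planted, spec coding
    latent: np.ndarray          # log10 F before squash and noise
    latent_squashed: np.ndarray  # after squash (== latent when no squash)


def _basis_matrix(n: int, subsets: list[tuple[int, ...]], coding: str) -> np.ndarray:
    g = np.arange(2 ** n)[:, None]
    bits = ((g >> np.arange(n)[None, :]) & 1).astype(float)
    states = bits if coding == "wt_background" else 2.0 * bits - 1.0
    cols = []
    for sub in subsets:
        if sub:
            cols.append(np.prod(states[:, list(sub)], axis=1))
        else:
            cols.append(np.ones(2 ** n))
    return np.column_stack(cols)


def latent_values(
    coefficients: Mapping[tuple[int, ...], float], n: int, coding: str
) -> np.ndarray:
    """Evaluate a coefficient map over the full genotype lattice."""
    subsets = [tuple(sorted(s)) for s in coefficients]
    X = _basis_matrix(n, subsets, coding)
    return X @ np.array([coefficients[s] for s in coefficients], dtype=float)


def convert_coding(
    coefficients: Mapping[tuple[int, ...], float], n: int, to: str
) -> dict[tuple[int, ...], float]:
    """Re-express a coefficient map in the other basis.

    Implemented by evaluating the latent surface on the lattice and
    re-extracting coefficients: inclusion-exclusion from the wt corner for
    the wt_background coding, the normalised Walsh-Hadamard transform for the
    plus_minus_one coding.  The input map's coding is inferred as the one it
    is *not* converted to, so converting twice round-trips.
    """
    if to not in CODINGS:
        raise ValueError(f"coding must be one of {CODINGS}")
    source = CODINGS[1 - CODINGS.index(to)]
    phi = latent_values(coefficients, n, source)
    out: dict[tuple[int, ...], float] = {}
    if to == "wt_background":
        # c_S = sum_{T subseteq S} (-1)^{|S|-|T|} phi(genotype T)
        for k in range(0, n + 1):
            for sub in combinations(range(n), k):
                total = 0.0
                for j in range(2 ** k):
                    t_bits = sum(1 << sub[i] for i in range(k) if (j >> i) & 1)
                    total += (-1) ** (k - bin(j).count("1")) * phi[t_bits]
                out[sub] = total
    else:
        signs = 2.0 * (
            (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        ) - 1.0
        for k in range(0, n + 1):
            for sub in combinations(range(n), k):
                chi = np.prod(signs[:, list(sub)], axis=1) if sub else np.ones(2 ** n)
                out[sub] = float(phi @ chi) / 2 ** n
    return {s: v for s, v in out.items() if abs(v) > 1e-300 or s == ()}


def generate(spec: SyntheticSpec, seed: int) -> tuple[RawMeasurementTable, GroundTruth]:
    """Deterministically generate one landscape and its ground truth."""
    rng = np.random.default_rng(seed)
    if isinstance(spec.additive_effects, tuple) and spec.additive_effects[0] == "normal":
        _, mean, sd = spec.additive_effects
        additive = rng.normal(mean, sd, spec.n)
    else:
        additive = np.asarray(spec.additive_effects, dtype=float)
        if additive.shape != (spec.n,):
            raise ValueError("additive_effects must have one value per locus")

    coefficients: dict[tuple[int, ...], float] = {
        (i,): float(additive[i]) for i in range(spec.n)
    }
    for sub, coef in spec.planted.items():
        sub = tuple(sorted(sub))
        coefficients[sub] = coefficients.get(sub, 0.0) + float(coef)

    latent = latent_values(coefficients, spec.n, spec.coding)
    latent = latent - latent[0]  # wt-relative scale
    squashed = (
        logistic(latent, spec.squash) if spec.squash is not None else latent.copy()
    )

    noise = rng.normal(0.0, spec.noise_sd, size=(2 ** spec.n, spec.replicates))
    raw = 10.0 ** (squashed[:, None] + noise)
    raw = raw / float(np.mean(raw[0]))  # wt raw mean = 1

    table = RawMeasurementTable(
        enzyme="synthetic",
        condition=f"seed{seed}",
        trait="simulated activity",
        loci=tuple(f"m{i + 1}" for i in range(spec.n)),
        replicates=tuple(tuple(float(v) for v in row) for row in raw),
    )
    truth = GroundTruth(
        spec=spec, seed=seed, coefficients=coefficients,
        latent=latent, latent_squashed=squashed,
    )
    return table, truth


def recovery_report(
    truth: GroundTruth, estimates: Mapping[tuple[int, ...], float]
) -> pd.DataFrame:
    """Bias and RMSE of estimated coefficients against the plant, per order.

    ``estimates`` maps locus subsets to estimated coefficients in the same
    coding as the ground truth (wt-background effects from the effects
    module, or betas from the background-averaged fit with the intercept
    dropped).
    """
    rows = []
    errors: dict[int, list[float]] = {}
    for sub, true_val in truth.coefficients.items():
        est = estimates.get(tuple(sorted(sub)))
        if est is None:
            continue
        errors.setdefault(len(sub), []).append(est - true_val)
    for order in sorted(errors):
        err = np.array(errors[order])
        rows.append({
            "order": order,
            "n_coefficients": err.size,
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err ** 2))),
        })
    return pd.DataFrame(rows)
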