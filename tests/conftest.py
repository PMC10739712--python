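import math

import numpy as np
import pytest

from epiland.landscape_io import Landscape


@pytest.fixture
def toy2() -> Landscape:
    """2-locus fold-changes {00: 1, 10: 2, 01: 5, 11: 30}."""
    return Landscape(
        "toy", "cond", "fold", ("a", "b"),
        np.log10([1.0, 2.0, 5.0, 30.0]),
    )


@pytest.fixture
def toy3() -> Landscape:
    """3-locus fold-changes 1 / 2 / 8 / 16 by mutation count."""
    by_count = [1.0, 2.0, 8.0, 16.0]
    values = np.array(
        [math.log10(by_count[bin(g).count("1")]) for g in range(8)]
    )
    return Landscape("toy3", "cond", "fold", ("a", "b", "c"), values)


def make_additive(n: int, effects=None, seed: int = 0) -> Landscape:
    rng = np.random.default_rng(seed)
    beta = np.asarray(effects, float) if effects is not None else rng.normal(0.3, 0.4, n)
    g = np.arange(2 ** n)[:, None]
    bits = ((g >> np.arange(n)[None, :]) & 1).astype(float)
    return Landscape(
        "additive", f"seed{seed}", "fold",
        tuple(f"m{i}" for i in range(n)), bits @ beta,
    )


def make_random(n: int, seed: int = 0, scale: float = 1.0) -> Landscape:
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, scale, 2 ** n)
    values[0] = 0.0
    return Landscape(
        "random", f"seed{seed}", "fold",
        tuple(f"m{i}" for i in range(n)), values,
    )


def landscape_csv_text(
    reps: dict[str, list[float]], enzyme="E", condition="c", loci="a,b", trait="act"
) -> str:
    n_rep = max(len(v) for v in reps.values())
    lines = [
        f"# enzyme={enzyme}", f"# condition={condition}",
        f"# loci={loci}", f"# trait={trait}",
        "genotype," + ",".join(f"rep{i + 1}" for i in range(n_rep)),
    ]
    for bits, vals in reps.items():
        cells = [str(v) for v in vals] + [""] * (n_rep - len(vals))
        lines.append(bits + "," + ",".join(cells))
    return "\n".join(lines) + "\n"
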