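"""Parsing, preprocessing and cataloguing of combinatorial fitness landscapes.

A combinatorially complete landscape measures one enzyme function for all 2^n
genotypes formed by presence/absence of n focal mutations.  Genotypes are
bitstrings over {0, 1} in the locus order declared by the landscape header:
'0' is the ancestral state, '1' the derived one, the wild type (wt) is all
zeros and the most derived endpoint all ones.  Internally genotypes are
integers where bit i carries the state of locus i, so ``values[g]`` indexes a
dense array of length 2^n.

The canonical CSV dialect is::

    # enzyme=<text>
    # condition=<text>
    # loci=<comma-separated mutation labels>
    # trait=<text>
    genotype,rep1[,rep2,...]
    00,1.0,1.1
    10,2.0,2.1
    ...

Raw trait values are kept on their native scale until
:func:`normalize_and_log` divides by the wt mean and takes log10, producing a
:class:`Landscape` of dimensionless log10 fold-changes with value(wt) = 0.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RawMeasurementTable",
    "Landscape",
    "LandscapeDescriptor",
    "LandscapeRegistry",
    "ReplicateErrorSummary",
    "bits_to_index",
    "index_to_bits",
    "parse_landscape",
    "write_landscape_csv",
    "pre_exponentiate",
    "average_replicates",
    "normalize_and_log",
    "derive_significance_threshold",
    "registry_census",
    "builtin_registry",
    "load_registry",
]


# ---------------------------------------------------------------------------
# genotype encoding


def bits_to_index(bits: str) -> int:
    """Convert a 0/1 genotype string to its integer index (bit i = locus i)."""
    if not bits or any(c not in "01" for c in bits):
        raise ValueError(f"malformed genotype bitstring: {bits!r}")
    return sum(1 << i for i, c in enumerate(bits) if c == "1")


def index_to_bits(index: int, n: int) -> str:
    """Inverse of :func:`bits_to_index` for an n-locus landscape."""
    return "".join("1" if (index >> i) & 1 else "0" for i in range(n))


# ---------------------------------------------------------------------------
# raw measurements


@dataclass(frozen=True)
class RawMeasurementTable:
    """All 2^n genotypes of one landscape with raw replicate trait values."""

    enzyme: str
    condition: str
    trait: str
    loci: tuple[str, ...]
    replicates: tuple[tuple[float, ...], ...]  # indexed by genotype integer
    flags: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.loci)

    @property
    def label(self) -> str:
        return f"{self.enzyme}:{self.condition}"

    def __post_init__(self) -> None:
        if len(self.replicates) != 2 ** self.n:
            raise ValueError(
                f"{self.label}: expected {2 ** self.n} genotypes, "
                f"got {len(self.replicates)}"
            )
        for reps in self.replicates:
            if len(reps) == 0:
                raise ValueError(f"{self.label}: empty replicate list")


@dataclass
class Landscape:
    """One condition's complete genotype -> log10 fold-change map."""

    enzyme: str
    condition: str
    trait: str
    loci: tuple[str, ...]
    values: np.ndarray  # shape (2^n,), log10 F relative to wt
    flags: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.loci)

    @property
    def label(self) -> str:
        return f"{self.enzyme}:{self.condition}"

    def value(self, genotype: str | int) -> float:
        g = genotype if isinstance(genotype, int) else bits_to_index(genotype)
        return float(self.values[g])

    def genotypes(self) -> Iterable[str]:
        return (index_to_bits(g, self.n) for g in range(2 ** self.n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype": list(self.genotypes()), "log10F": self.values}
        )


def parse_landscape(source: str | Path | io.TextIOBase) -> RawMeasurementTable:
    """Read a landscape CSV in the canonical dialect.

    Rejects incomplete landscapes (any of the 2^n genotypes missing),
    duplicate genotypes, malformed bitstrings and non-numeric values.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()

    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        elif line.strip():
            body_lines.append(line)
    for key in ("enzyme", "condition", "loci", "trait"):
        if key not in meta:
            raise ValueError(f"missing header line '# {key}=...'")
    loci = tuple(s.strip() for s in meta["loci"].split(","))
    n = len(loci)

    try:
        df = pd.read_csv(io.StringIO("\n".join(body_lines)), dtype={"genotype": str})
    except ValueError as exc:
        raise ValueError(f"parse error in landscape CSV: {exc}") from exc
    if "genotype" not in df.columns or df.shape[1] < 2:
        raise ValueError("expected columns genotype,rep1[,rep2,...]")

    replicates: list[tuple[float, ...] | None] = [None] * (2 ** n)
    rep_cols = [c for c in df.columns if c != "genotype"]
    for _, row in df.iterrows():
        bits = row["genotype"]
        if not isinstance(bits, str) or len(bits) != n:
            raise ValueError(f"malformed genotype bitstring: {bits!r}")
        g = bits_to_index(bits)
        if replicates[g] is not None:
            raise ValueError(f"duplicate genotype {bits}")
        vals = [row[c] for c in rep_cols if pd.notna(row[c])]
        if not vals:
            raise ValueError(f"genotype {bits}: no replicate values")
        try:
            vals = tuple(float(v) for v in vals)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"genotype {bits}: non-numeric value") from exc
        replicates[g] = vals
    missing = [index_to_bits(g, n) for g, r in enumerate(replicates) if r is None]
    if missing:
        raise ValueError(f"incomplete landscape: missing genotypes {missing}")

    return RawMeasurementTable(
        enzyme=meta["enzyme"],
        condition=meta["condition"],
        trait=meta["trait"],
        loci=loci,
        replicates=tuple(replicates),  # type: ignore[arg-type]
    )


def write_landscape_csv(table: RawMeasurementTable, path: str | Path) -> None:
    """Emit a RawMeasurementTable in the canonical CSV dialect."""
    n_rep = max(len(r) for r in table.replicates)
    lines = [
        f"# enzyme={table.enzyme}",
        f"# condition={table.condition}",
        f"# loci={','.join(table.loci)}",
        f"# trait={table.trait}",
        "genotype," + ",".join(f"rep{i + 1}" for i in range(n_rep)),
    ]
    for g, reps in enumerate(table.replicates):
        cells = [f"{v!r}" for v in reps] + [""] * (n_rep - len(reps))
        lines.append(index_to_bits(g, table.n) + "," + ",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def pre_exponentiate(table: RawMeasurementTable) -> RawMeasurementTable:
    """Replace every raw value v by 10**v.

    Applied to additive-scale traits (growth rates) so that downstream wt
    normalization and log-transform treat them multiplicatively.
    """
    if table.flags.get("pre_exponentiated"):
        raise ValueError(f"{table.label}: already pre-exponentiated")
    reps = tuple(tuple(10.0 ** v for v in r) for r in table.replicates)
    flags = dict(table.flags, pre_exponentiated=True)
    return replace(table, replicates=reps, flags=flags)


def average_replicates(table: RawMeasurementTable) -> RawMeasurementTable:
    """Collapse replicates to their arithmetic mean on the raw scale."""
    reps = tuple((float(np.mean(r)),) for r in table.replicates)
    return replace(table, replicates=reps)


def normalize_and_log(table: RawMeasurementTable) -> Landscape:
    """Divide genotype means by the wt mean and log10-transform.

    The wt value is exactly 0 afterwards.  Non-positive means are rejected:
    flooring them would fabricate epistasis.
    """
    means = np.array([np.mean(r) for r in table.replicates], dtype=float)
    wt = means[0]
    if wt <= 0:
        raise ValueError(f"{table.label}: log undefined, wt mean {wt} <= 0")
    if np.any(means <= 0):
        bad = index_to_bits(int(np.argmax(means <= 0)), table.n)
        raise ValueError(f"{table.label}: log undefined, non-positive mean at {bad}")
    values = np.log10(means / wt)
    values[0] = 0.0
    return Landscape(
        enzyme=table.enzyme,
        condition=table.condition,
        trait=table.trait,
        loci=table.loci,
        values=values,
        flags=dict(table.flags),
    )


# ---------------------------------------------------------------------------
# replicate-derived significance threshold


@dataclass(frozen=True)
class ReplicateErrorSummary:
    """Per-genotype 2 SD of log10 replicate fold-changes and its median."""

    per_genotype: pd.DataFrame  # columns: landscape, genotype, two_sd_log10
    median_log10: float

    @property
    def median_fold(self) -> float:
        return 10.0 ** self.median_log10


def derive_significance_threshold(
    tables: Iterable[RawMeasurementTable],
) -> ReplicateErrorSummary:
    """Median replicate error (2 SD of log10 fold-changes) over a dataset.

    This reproduces the justification of the fixed analysis threshold
    tau = log10(1.5); analyses themselves always use the constant
    :data:`epiland.constants.TAU`.
    """
    rows = []
    for table in tables:
        wt_mean = float(np.mean(table.replicates[0]))
        if wt_mean <= 0:
            raise ValueError(f"{table.label}: wt mean must be positive")
        for g, reps in enumerate(table.replicates):
            if len(reps) < 2:
                continue
            logs = np.log10(np.asarray(reps, dtype=float) / wt_mean)
            rows.append(
                {
                    "landscape": table.label,
                    "genotype": index_to_bits(g, table.n),
                    "two_sd_log10": 2.0 * float(np.std(logs, ddof=1)),
                }
            )
    if not rows:
        raise ValueError("no genotype has >= 2 replicates")
    df = pd.DataFrame(rows)
    return ReplicateErrorSummary(
        per_genotype=df, median_log10=float(df["two_sd_log10"].median())
    )


# ---------------------------------------------------------------------------
# landscape registry and census


@dataclass(frozen=True)
class LandscapeDescriptor:
    """Structural metadata for one landscape, with or without a data file."""

    enzyme: str
    condition: str
    n_loci: int
    trait: str = ""
    source: str = ""
    path: str | None = None
    pre_exponentiate: bool = False
    reduced: bool = False
    structural: bool = False
    adaptive: bool = False

    @property
    def label(self) -> str:
        return f"{self.enzyme}:{self.condition}"


@dataclass(frozen=True)
class LandscapeRegistry:
    entries: tuple[LandscapeDescriptor, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, which: str = "full") -> "LandscapeRegistry":
        """Restrict to a flagged subset: full, reduced, structural or adaptive."""
        if which == "full":
            return self
        if which not in ("reduced", "structural", "adaptive"):
            raise ValueError(f"unknown subset {which!r}")
        return LandscapeRegistry(
            tuple(e for e in self.entries if getattr(e, which))
        )


def _per_landscape_counts(entry: LandscapeDescriptor) -> dict:
    n = entry.n_loci
    counts = {
        "landscape": entry.label,
        "enzyme": entry.enzyme,
        "n_loci": n,
        "genotypes": 2 ** n,
        "non_wt_values": 2 ** n - 1,
        "positions": n,
        "smes": n * 2 ** (n - 1),
    }
    for k in (2, 3, 4):
        combos = math.comb(n, k) if k <= n else 0
        backgrounds = 2 ** (n - k) if k <= n else 0
        counts[f"combinations_order{k}"] = combos
        counts[f"single_background_order{k}"] = combos if backgrounds == 1 else 0
        counts[f"ee_values_order{k}"] = combos * backgrounds
    counts["transitions"] = sum(
        math.comb(n, k) * k for k in range(3, n + 1)
    )
    return counts


def registry_census(registry: LandscapeRegistry) -> pd.DataFrame:
    """Per-landscape structural counts with a 'total' row.

    For each landscape of n loci: 2^n genotype-phenotype points, n positions,
    n * 2^(n-1) SMEs, C(n,k) order-k combinations of which those occurring in
    a single background (2^(n-k) = 1) are flagged non-viable for spread
    statistics, C(n,k) * 2^(n-k) order-k EE values, and
    sum_{k>=3} C(n,k) * k order-raising transitions.  Transitions totals are
    additionally reported for the structural subset.
    """
    rows = [_per_landscape_counts(e) for e in registry.entries]
    df = pd.DataFrame(rows)
    total = df.drop(columns=["landscape", "enzyme", "n_loci"]).sum()
    total["landscape"] = "total"
    total["enzyme"] = ""
    total["n_loci"] = 0
    df = pd.concat([df, total.to_frame().T], ignore_index=True)
    return df


def census_totals(registry: LandscapeRegistry) -> dict[str, int]:
    """Dataset-wide census as a flat dict (the headline numbers)."""
    df = registry_census(registry)
    tot = df[df["landscape"] == "total"].iloc[0]
    structural = registry.subset("structural")
    struct_transitions = sum(
        _per_landscape_counts(e)["transitions"] for e in structural.entries
    )
    struct_points = sum(2 ** e.n_loci for e in structural.entries)
    out = {
        "landscapes": len(registry),
        "genotype_phenotype_points": int(tot["genotypes"]),
        "non_wt_values": int(tot["non_wt_values"]),
        "positions": int(tot["positions"]),
        "smes": int(tot["smes"]),
        "pairwise_combinations": int(tot["combinations_order2"]),
        "threeway_combinations": int(tot["combinations_order3"]),
        "fourway_combinations": int(tot["combinations_order4"]),
        "fourway_single_background": int(tot["single_background_order4"]),
        "fourway_viable": int(
            tot["combinations_order4"] - tot["single_background_order4"]
        ),
        "ee_values_orders_2_4": int(
            tot["ee_values_order2"] + tot["ee_values_order3"] + tot["ee_values_order4"]
        ),
        "structural_landscapes": len(structural),
        "structural_measurements": struct_points,
        "structural_transitions": struct_transitions,
    }
    return out


def _mk(enzyme, condition, n, trait, source, **flags) -> LandscapeDescriptor:
    return LandscapeDescriptor(
        enzyme=enzyme, condition=condition, n_loci=n, trait=trait,
        source=source, **flags,
    )


def builtin_registry() -> LandscapeRegistry:
    """The 41-landscape compilation of published combinatorial enzyme studies.

    Seven enzymes: OXA-48 (three trajectories, two inhibitors each), TEM-1
    (one five-mutation MIC landscape and eleven four-mutation growth-rate
    conditions), AP, NfsA (two seven-mutation trajectories), DHFR (four sets),
    MPH (eight metal environments) and PTE (two substrates).  Condition labels
    not printed in the compiled table are placeholders; only the structural
    counts (loci per landscape, conditions per study) matter for the census.

    Flags: ``pre_exponentiate`` marks the additive-scale TEM-1 growth rates;
    ``reduced`` marks the cross-correlation-free subset; ``structural`` marks
    the mechanistic-readout subset (kcat/KM, Ki, lysate activity) used for
    transition analysis; ``adaptive`` marks landscapes whose condition is the
    presumed selection pressure, used for path predictions.
    """
    e: list[LandscapeDescriptor] = []
    # OXA-48 beta-lactamase: three engineered trajectories, two inhibitors each
    for traj, n in (("traj1", 4), ("traj2", 6), ("traj3", 6)):
        for cond in ("ceftazidime", "imipenem"):
            e.append(_mk(
                "OXA-48", f"{traj}/{cond}", n, "IC50", "Fröhlich et al.",
                reduced=(cond == "ceftazidime"), adaptive=(cond == "ceftazidime"),
            ))
    # TEM-1 beta-lactamase: five cefotaxime-resistance mutations (MIC)
    e.append(_mk("TEM-1", "cefotaxime", 5, "MIC", "Weinreich et al.",
                 reduced=True, adaptive=True))
    # TEM-1: four mutations, growth rates under 11 beta-lactams (of 15 measured;
    # AMC, AMP, CAZ and TZP collapse to binary values after global-epistasis
    # correction and are excluded from the registry)
    for cond in ("AM", "SAM", "CEC", "CF", "CXM", "CTX", "CRO",
                 "FEP", "ZOX", "CPD", "CTT"):
        e.append(_mk("TEM-1", f"growth/{cond}", 4, "growth rate",
                     "Mira et al.", pre_exponentiate=True,
                     reduced=(cond == "AM")))
    # Alkaline phosphatase: five active-site mutations, kcat/KM
    e.append(_mk("AP", "pNPP", 5, "kcat/KM", "Sunden et al.",
                 reduced=True, structural=True, adaptive=True))
    # NfsA nitroreductase: two seven-mutation trajectories
    for traj in ("20_39", "traj2"):
        e.append(_mk("NfsA", f"{traj}/nitrofurazone", 7, "EC50",
                     "directed evolution study", reduced=(traj == "20_39"),
                     adaptive=True))
    # DHFR: four mutations under five antifolate conditions
    for cond in ("TMP", "PYR", "MTX", "2,4-DAP", "SMX"):
        e.append(_mk("DHFR", f"IC/{cond}", 4, "IC50/IC75", "clinical-mutation study"))
    # DHFR c57 trajectory, six mutations
    e.append(_mk("DHFR", "c57/TMP", 6, "IC50", "Lozovsky et al.",
                 reduced=True, adaptive=True))
    # DHFR: two five-mutation trajectories, kcat/KM and Ki each
    for traj in ("Arg", "traj2"):
        for trait in ("kcat/KM", "Ki"):
            e.append(_mk(
                "DHFR", f"{traj}/{trait}", 5, trait, "Tamer et al.",
                structural=True,
                reduced=(traj == "Arg" and trait == "kcat/KM"),
                adaptive=(traj == "Arg" and trait == "kcat/KM"),
            ))
    # MPH methyl-parathion hydrolase: five mutations, eight metal environments
    for metal in ("Zn", "Co", "Ni", "Cd", "Mn", "Cu", "Fe", "Ca"):
        e.append(_mk("MPH", f"metal/{metal}", 5, "lysate activity",
                     "ancestral-reconstruction study", structural=True,
                     reduced=(metal == "Zn"), adaptive=(metal == "Zn")))
    # PTE phosphotriesterase: six mutations, two aryl-ester substrates
    for cond, src in (("2NH", "this compilation"), ("2NO", "Miton et al.")):
        e.append(_mk("PTE", cond, 6, "lysate activity", src,
                     structural=True, reduced=(cond == "2NH"),
                     adaptive=(cond == "2NH")))
    return LandscapeRegistry(tuple(e))


def load_registry(path: str | Path) -> LandscapeRegistry:
    """Read a registry config (YAML) listing per-landscape files and flags.

    Schema::

        landscapes:
          - path: relative/or/absolute.csv
            enzyme: <optional override>
            condition: <optional override>
            n_loci: <required if no path>
            trait: <text>
            pre_exponentiate: false
            reduced: false
            structural: false
            adaptive: false
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(cfg, dict) or "landscapes" not in cfg:
        raise ValueError("registry config must contain a 'landscapes' list")
    entries = []
    for item in cfg["landscapes"]:
        file_path = item.get("path")
        meta: dict = {}
        if file_path is not None:
            file_path = str((path.parent / file_path).resolve())
            table = parse_landscape(file_path)
            meta = {
                "enzyme": table.enzyme,
                "condition": table.condition,
                "n_loci": table.n,
                "trait": table.trait,
            }
        for key in ("enzyme", "condition", "n_loci", "trait", "source"):
            if key in item:
                meta[key] = item[key]
        if "n_loci" not in meta:
            raise ValueError("registry entry needs a path or an n_loci")
        entries.append(LandscapeDescriptor(
            enzyme=meta.get("enzyme", "?"),
            condition=meta.get("condition", "?"),
            n_loci=int(meta["n_loci"]),
            trait=meta.get("trait", ""),
            source=meta.get("source", ""),
            path=file_path,
            pre_exponentiate=bool(item.get("pre_exponentiate", False)),
            reduced=bool(item.get("reduced", False)),
            structural=bool(item.get("structural", False)),
            adaptive=bool(item.get("adaptive", False)),
        ))
    return LandscapeRegistry(tuple(entries))


def load_landscape(entry: LandscapeDescriptor) -> Landscape:
    """Run the preprocessing chain for one registry entry with a data file."""
    if entry.path is None:
        raise ValueError(f"{entry.label}: registry entry has no data file")
    table = parse_landscape(entry.path)
    if entry.pre_exponentiate:
        table = pre_exponentiate(table)
    table = average_replicates(table)
    landscape = normalize_and_log(table)
    landscape.flags.update(
        reduced_set_member=entry.reduced,
        structural_set_member=entry.structural,
        adaptive_set_member=entry.adaptive,
    )
    return landscape
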