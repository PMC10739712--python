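"""End-to-end orchestration: ingest -> correct -> effects -> summaries.

Runs every registry landscape through preprocessing and global-epistasis
correction, extracts SMEs/EEs at all requested orders, and assembles the
heterogeneity, prediction and transition reports together with the
structural census.  Re-running with identical inputs and config produces
identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .constants import TAU
from .effects import all_effects
from .global_epistasis import correct_global_epistasis
from .heterogeneity import summarize
from .landscape_io import (
    Landscape,
    LandscapeRegistry,
    load_landscape,
    load_registry,
    registry_census,
)
from .prediction import prediction_report
from .transitions import enumerate_transitions, transition_frequencies

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    registry: str | Path
    out_dir: str | Path
    tau: float = TAU
    max_order: int = 4
    subset: str = "full"  # full / reduced / structural / adaptive

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _round(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(4)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict of the in-memory tables.  Any landscape-level failure
    aborts with the failing landscape identified.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(config.registry).subset(config.subset)

    census = registry_census(registry)
    _round(census).to_csv(out / "census.tsv", sep="\t", index=False)

    landscapes: list[Landscape] = []
    model_log: list[dict] = []
    for entry in registry.entries:
        try:
            landscape = load_landscape(entry)
            report = correct_global_epistasis(landscape)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at landscape {entry.label}: {exc}") from exc
        sel = report.selection
        model_log.append({
            "landscape": entry.label,
            "chosen": sel.chosen,
            "aic_linear": sel.aic_linear,
            "aic_logistic": sel.aic_logistic,
            "degenerate": report.degenerate,
            **({"U": sel.params.U, "L": sel.params.L,
                "m": sel.params.m, "s": sel.params.s} if sel.params else {}),
        })
        if report.degenerate:
            log.warning("%s: degenerate, excluded", entry.label)
            continue
        landscapes.append(report.landscape)
    (out / "model_selection.json").write_text(
        json.dumps(model_log, indent=2, default=float), encoding="utf-8"
    )
    if not landscapes:
        raise RuntimeError("no usable landscapes after degeneracy filtering")

    effect_tables = []
    for landscape in landscapes:
        for order in range(1, min(config.max_order, landscape.n) + 1):
            effect_tables.append(all_effects(landscape, order))
    effects = pd.concat(effect_tables, ignore_index=True)
    eff_out = effects.drop(columns=["locus_set"])
    _round(eff_out).to_csv(out / "effects.tsv", sep="\t", index=False)

    het = summarize(effects, config.tau)
    _round(het.positions).to_csv(out / "positions_summary.tsv", sep="\t", index=False)
    _round(het.combinations).to_csv(
        out / "combinations_summary.tsv", sep="\t", index=False
    )
    het.aggregates.round(1).to_csv(out / "aggregates.tsv", sep="\t", index=False)

    predictions = pd.concat(
        [
            prediction_report(l, model, tuple(range(1, config.max_order + 1)),
                              include_path=l.flags.get("adaptive_set_member", False))
            for l in landscapes
            for model in ("biochemical", "background_averaged")
        ],
        ignore_index=True,
    )
    _round(predictions).to_csv(out / "predictions.tsv", sep="\t", index=False)

    structural = [
        l for l in landscapes if l.flags.get("structural_set_member", False)
    ] or landscapes
    trans = pd.concat(
        [enumerate_transitions(l, config.tau) for l in structural],
        ignore_index=True,
    )
    bundle: dict = {
        "census": census,
        "effects": effects,
        "heterogeneity": het,
        "predictions": predictions,
        "model_selection": model_log,
    }
    if not trans.empty:
        _round(trans).to_csv(out / "transitions.tsv", sep="\t", index=False)
        freq = transition_frequencies(trans)
        freq.round(1).to_csv(out / "transition_frequencies.tsv", sep="\t", index=False)
        bundle["transitions"] = trans
        bundle["transition_frequencies"] = freq
    return bundle
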