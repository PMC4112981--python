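"""Similarity as a triage classifier for cross-reactivity.

Cross-reactive compounds cluster at high 2D similarity to the assay target,
so a similarity cutoff can prioritize which compounds to test in the wet
lab. This module computes per-category similarity statistics (the numbers
behind similarity-vs-category strip plots), sweeps cutoffs to get
sensitivity/specificity, and flags candidates above a cutoff.

For sensitivity/specificity the positive class is strong-or-weak
cross-reactivity and the negative class is no cross-reactivity; the
ambiguous very-weak bin is excluded by default (configurable to count as
positive or negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .crossreactivity import Category, CrossReactivityRecord
from .fingerprint_similarity import SimilarityScore

VeryWeakPolicy = Literal["exclude", "positive", "negative"]

#: default cutoff sweep grid: 0.00-1.00 in steps of 0.05
DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class CategoryStats:
    category: Category
    n: int
    mean: float
    min: float
    max: float


@dataclass(frozen=True)
class TriageResult:
    assay_name: str
    cutoff: float
    counts_at_or_above: dict[Category, int]
    counts_below: dict[Category, int]
    sensitivity: float | None  # None when there are no positives
    specificity: float | None  # None when there are no negatives


def _join(
    scores: Sequence[SimilarityScore],
    records: Sequence[CrossReactivityRecord],
    exclude_target: bool = True,
) -> list[tuple[str, float, Category]]:
    """Match records to scores by compound name; the target itself (the
    reference compound of the scores) is dropped when ``exclude_target``."""
    by_name = {s.query_name: s.tanimoto for s in scores}
    reference_names = {s.reference_name for s in scores}
    joined = []
    missing = []
    for record in records:
        if exclude_target and record.compound_name in reference_names:
            continue
        if record.compound_name not in by_name:
            missing.append(record.compound_name)
            continue
        joined.append((record.compound_name, by_name[record.compound_name], record.category))
    if missing:
        raise ValueError(f"no similarity score for: {', '.join(sorted(missing))}")
    return joined


def category_similarity_stats(
    scores: Sequence[SimilarityScore],
    records: Sequence[CrossReactivityRecord],
    exclude_target: bool = True,
) -> dict[Category, CategoryStats]:
    """n / mean / min / max similarity per cross-reactivity category."""
    joined = _join(scores, records, exclude_target)
    stats: dict[Category, CategoryStats] = {}
    for category in Category:
        values = [sim for _, sim, cat in joined if cat == category]
        if values:
            stats[category] = CategoryStats(
                category=category,
                n=len(values),
                mean=float(np.mean(values)),
                min=float(np.min(values)),
                max=float(np.max(values)),
            )
    return stats


def _classes(
    joined: list[tuple[str, float, Category]], very_weak: VeryWeakPolicy
) -> tuple[list[float], list[float]]:
    positives, negatives = [], []
    for _, sim, cat in joined:
        if cat in (Category.strong, Category.weak):
            positives.append(sim)
        elif cat == Category.none:
            negatives.append(sim)
        elif very_weak == "positive":
            positives.append(sim)
        elif very_weak == "negative":
            negatives.append(sim)
    return positives, negatives


def threshold_sweep(
    scores: Sequence[SimilarityScore],
    records: Sequence[CrossReactivityRecord],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    very_weak: VeryWeakPolicy = "exclude",
    exclude_target: bool = True,
) -> list[TriageResult]:
    """Sensitivity/specificity and per-category counts at each cutoff.

    A compound exactly at the cutoff counts as flagged (>=).
    """
    if any(not 0 <= c <= 1 for c in cutoffs):
        raise ValueError("cutoffs must lie in [0, 1]")
    joined = _join(scores, records, exclude_target)
    assay = records[0].assay_name if records else ""
    positives, negatives = _classes(joined, very_weak)
    results = []
    for cutoff in cutoffs:
        above = {cat: sum(1 for _, s, c in joined if c == cat and s >= cutoff) for cat in Category}
        below = {cat: sum(1 for _, s, c in joined if c == cat and s < cutoff) for cat in Category}
        sens = sum(1 for s in positives if s >= cutoff) / len(positives) if positives else None
        spec = sum(1 for s in negatives if s < cutoff) / len(negatives) if negatives else None
        results.append(
            TriageResult(
                assay_name=assay,
                cutoff=float(cutoff),
                counts_at_or_above=above,
                counts_below=below,
                sensitivity=sens,
                specificity=spec,
            )
        )
    return results


def flag_candidates(scores: Sequence[SimilarityScore], cutoff: float) -> list[str]:
    """Names with similarity >= cutoff, descending similarity, ties alphabetical."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    hits = [(s.query_name, s.tanimoto) for s in scores if s.tanimoto >= cutoff]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return [name for name, _ in hits]


def stats_to_frame(stats: dict[Category, CategoryStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": str(cat),
                "n": s.n,
                "mean_similarity": s.mean,
                "min_similarity": s.min,
                "max_similarity": s.max,
            }
            for cat, s in sorted(stats.items(), key=lambda kv: -kv[0])
        ]
    )


def sweep_to_frame(results: list[TriageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"assay": r.assay_name, "cutoff": r.cutoff,
               "sensitivity": r.sensitivity, "specificity": r.specificity}
        for cat in Category:
            row[f"n_{cat.name}_at_or_above"] = r.counts_at_or_above[cat]
            row[f"n_{cat.name}_below"] = r.counts_below[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_similarity_by_category(
    scores: Sequence[SimilarityScore],
    records: Sequence[CrossReactivityRecord],
    path: str,
    exclude_target: bool = True,
) -> None:
    """Strip plot of similarity by category with per-category mean bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joined = _join(scores, records, exclude_target)
    fig, ax = plt.subplots(figsize=(6, 4))
    order = [Category.strong, Category.weak, Category.very_weak, Category.none]
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for x, cat in enumerate(order):
        values = [sim for _, sim, c in joined if c == cat]
        if not values:
            continue
        ax.scatter(x + rng.uniform(-0.12, 0.12, len(values)), values, s=18, alpha=0.8)
        ax.hlines(float(np.mean(values)), x - 0.25, x + 0.25, color="black")
    ax.set_xticks(range(len(order)), [c.name for c in order])
    ax.set_ylabel("2D similarity to assay target")
    ax.set_ylim(0, 1.02)
    ax.set_title(records[0].assay_name if records else "")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
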