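"""Apparent-concentration interference estimates and clinical likelihood grades.

A cross-reactant circulating at concentration *C* with cross-reactivity
*CR%* adds roughly ``CR/100 x C`` of apparent target analyte to an
immunoassay result. Combining measured cross-reactivities with published
plasma/serum concentration ranges therefore bounds the false signal each
compound can produce, and comparing that bound to the assay's reference
interval grades how likely the interference is to matter clinically.

Grading rule
------------
For each (compound, population) estimate the rule computes

    R = apparent_high / upper bound of the applicable reference interval

where the applicable interval is the assay reference interval whose
population matches the plasma-range population (sex/pregnancy/infancy token
match), falling back to the least-sensitive (widest) interval. The grade is
``high`` when R >= 0.25 (the false signal reaches a quarter of the upper
reference limit), ``possible`` when R >= 0.02, else ``low``; compounds with
no published plasma data grade ``unknown``. Both thresholds are
config-exposed. Grading against the interval *upper* bound, rather than the
lower, keeps the rule stable for assays whose reference intervals extend to
(or near) zero, such as testosterone in females.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .compound_library import AssayDefinition, PlasmaRange, ReferenceInterval
from .crossreactivity import CrossReactivityRecord

log = logging.getLogger(__name__)

LIKELIHOODS = ("high", "possible", "low", "unknown")


@dataclass(frozen=True)
class GradingThresholds:
    """Ratio-to-upper-reference-bound cutoffs for the likelihood grade."""

    possible: float = 0.02
    high: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.possible < self.high:
            raise ValueError("need 0 < possible < high")


@dataclass(frozen=True)
class InterferenceEstimate:
    assay_name: str
    compound_name: str
    population: str
    apparent_low: float | None
    apparent_high: float | None
    reference_interval_used: ReferenceInterval | None
    likelihood: str
    citation: str = ""

    def __post_init__(self) -> None:
        if self.likelihood not in LIKELIHOODS:
            raise ValueError(f"bad likelihood {self.likelihood!r}")
        if (self.likelihood == "unknown") != (self.apparent_high is None):
            raise ValueError("likelihood is 'unknown' iff no plasma data was available")


def apparent_concentration(
    cr: CrossReactivityRecord, plasma: PlasmaRange
) -> tuple[float, float]:
    """Apparent-analyte bounds ``CR/100 x plasma bound`` for one compound.

    An absent plasma low bound maps to an apparent low of 0.
    """
    if cr.compound_name != plasma.compound_name:
        raise ValueError(
            f"compound mismatch: record {cr.compound_name!r} vs plasma {plasma.compound_name!r}"
        )
    factor = cr.cross_reactivity_pct / 100.0
    low = 0.0 if plasma.low is None else factor * plasma.low
    return low, factor * plasma.high


# --- population -> reference-interval matching -----------------------------

_TOKEN_SYNONYMS = {
    "men": "male", "man": "male", "male": "male", "males": "male",
    "women": "female", "woman": "female", "female": "female", "females": "female",
    "pregnancy": "pregnancy", "pregnant": "pregnancy", "parturition": "pregnancy",
    "infant": "infant", "infants": "infant", "premature": "infant",
    "morning": "morning", "afternoon": "afternoon",
}


def _tokens(text: str) -> set[str]:
    # drop negated phrases ("non-pregnant") before tokenizing
    text = re.sub(r"\bnon-\S+", " ", text.lower())
    words = re.findall(r"[a-z]+", text)
    return {_TOKEN_SYNONYMS[w] for w in words if w in _TOKEN_SYNONYMS}


def select_reference_interval(
    assay: AssayDefinition, population: str
) -> ReferenceInterval:
    """The reference interval applicable to a plasma-range population.

    Prefers the interval sharing the most population tokens (male/female/
    pregnancy/infancy); with no match the least-sensitive interval (largest
    upper bound) is used, so an interference is only flagged when it is
    large even against the widest normal range.
    """
    pop_tokens = _tokens(population or "")
    best, best_score = None, 0
    for interval in assay.reference_intervals:
        score = len(pop_tokens & _tokens(interval.population))
        if score > best_score:
            best, best_score = interval, score
    if best is None:
        best = max(assay.reference_intervals, key=lambda iv: iv.high)
    return best


def grade_likelihood(
    apparent_high: float | None,
    assay: AssayDefinition,
    population: str = "",
    thresholds: GradingThresholds = GradingThresholds(),
) -> tuple[str, ReferenceInterval | None]:
    """Grade one estimate; returns ``(likelihood, interval used)``.

    ``unknown`` only when no plasma bound exists.
    """
    if not assay.reference_intervals:
        raise ValueError(f"assay {assay.assay_name!r} has no reference intervals")
    if apparent_high is None:
        return "unknown", None
    interval = select_reference_interval(assay, population)
    ratio = apparent_high / interval.high
    if ratio >= thresholds.high:
        return "high", interval
    if ratio >= thresholds.possible:
        return "possible", interval
    return "low", interval


def interference_report(
    assay: AssayDefinition,
    panel: list[CrossReactivityRecord],
    ranges: list[PlasmaRange],
    thresholds: GradingThresholds = GradingThresholds(),
    include_target: bool = False,
) -> list[InterferenceEstimate]:
    """One estimate per (compound, population) with plasma data, plus
    unknown-graded rows for cross-reactive compounds lacking plasma data.

    Sorted by descending apparent_high; unknown rows follow. The assay's own
    target (apparent == its plasma concentration by definition) is excluded
    unless ``include_target``.
    """
    ranges_by_compound: dict[str, list[PlasmaRange]] = {}
    for pr in ranges:
        ranges_by_compound.setdefault(pr.compound_name, []).append(pr)

    estimates: list[InterferenceEstimate] = []
    for record in panel:
        if not include_target and record.compound_name == assay.target_compound.name:
            continue
        compound_ranges = ranges_by_compound.get(record.compound_name, [])
        if not compound_ranges:
            estimates.append(
                InterferenceEstimate(
                    assay_name=assay.assay_name,
                    compound_name=record.compound_name,
                    population="",
                    apparent_low=None,
                    apparent_high=None,
                    reference_interval_used=None,
                    likelihood="unknown",
                )
            )
            continue
        for plasma in compound_ranges:
            low, high = apparent_concentration(record, plasma)
            likelihood, interval = grade_likelihood(
                high, assay, plasma.population, thresholds
            )
            estimates.append(
                InterferenceEstimate(
                    assay_name=assay.assay_name,
                    compound_name=record.compound_name,
                    population=plasma.population,
                    apparent_low=low,
                    apparent_high=high,
                    reference_interval_used=interval,
                    likelihood=likelihood,
                    citation=plasma.citation,
                )
            )
    estimates.sort(
        key=lambda e: (e.apparent_high is None, -(e.apparent_high or 0.0), e.compound_name)
    )
    return estimates


def report_to_frame(estimates: list[InterferenceEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        iv = e.reference_interval_used
        rows.append(
            {
                "assay": e.assay_name,
                "compound": e.compound_name,
                "population": e.population,
                "apparent_low_ng_ml": e.apparent_low,
                "apparent_high_ng_ml": e.apparent_high,
                "reference_population": iv.population if iv else None,
                "reference_low_ng_ml": iv.low if iv else None,
                "reference_high_ng_ml": iv.high if iv else None,
                "likelihood": e.likelihood,
                "citation": e.citation,
            }
        )
    return pd.DataFrame(rows)


def report_to_json(estimates: list[InterferenceEstimate], path: str | Path) -> None:
    frame = report_to_frame(estimates)
    records = json.loads(frame.to_json(orient="records"))
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
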