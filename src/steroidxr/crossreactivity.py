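"""Percent cross-reactivity from spiked-sample measurements.

An interference study spikes a known concentration of a test compound into
normal plasma and measures the apparent target-analyte concentration in the
spiked and unadulterated samples on the same immunoassay. Percent
cross-reactivity is the baseline-corrected apparent analyte divided by the
amount of compound added, times 100; it can exceed 100% when the antibody
binds the interferent more avidly than its own hapten.

Measured values fall into four reporting bins: strong (>= 5%), weak
(0.5-4.9%), very weak (0.05-0.49%) and not cross-reactive (< 0.05%),
implemented as half-open intervals at 0.05 / 0.5 / 5 so every non-negative
value has exactly one category.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass

log = logging.getLogger(__name__)

#: category bin edges in percent, ascending
BIN_EDGES = (0.05, 0.5, 5.0)


class Category(enum.IntEnum):
    """Cross-reactivity category, ordered none < very_weak < weak < strong."""

    none = 0
    very_weak = 1
    weak = 2
    strong = 3

    def __str__(self) -> str:  # CSV-friendly
        return self.name


@dataclass(frozen=True)
class SpikedMeasurement:
    """One compound x assay spiked-sample readout (all concentrations ng/mL)."""

    assay_name: str
    compound_name: str
    spike_concentration: float
    apparent_spiked: float
    apparent_baseline: float

    def __post_init__(self) -> None:
        if self.spike_concentration <= 0:
            raise ValueError(
                f"{self.compound_name}: spike_concentration must be > 0, "
                f"got {self.spike_concentration}"
            )
        if self.apparent_spiked < 0 or self.apparent_baseline < 0:
            raise ValueError(f"{self.compound_name}: apparent concentrations must be >= 0")


@dataclass(frozen=True)
class CrossReactivityRecord:
    """One compound x assay cross-reactivity result with its category."""

    assay_name: str
    compound_name: str
    cross_reactivity_pct: float
    category: Category
    provenance: str = "measured"  # measured | package insert | simulated | fixture

    def __post_init__(self) -> None:
        if self.category != categorize(self.cross_reactivity_pct):
            raise ValueError(
                f"{self.compound_name}: category {self.category.name} inconsistent with "
                f"CR {self.cross_reactivity_pct}%"
            )


def percent_cross_reactivity(m: SpikedMeasurement) -> float:
    """100 x (apparent_spiked - apparent_baseline) / spike, clipped at zero.

    The spiked sample is compared to the unadulterated sample by subtraction;
    a negative difference (readout noise) is clipped to 0 and logged.
    """
    delta = m.apparent_spiked - m.apparent_baseline
    if delta < 0:
        log.info(
            "%s on %s: spiked reading below baseline (%.4g ng/mL); clipping CR to 0",
            m.compound_name, m.assay_name, delta,
        )
        delta = 0.0
    return 100.0 * delta / m.spike_concentration


def categorize(cr: float) -> Category:
    """Assign the four-bin category for a non-negative CR percentage."""
    if cr < 0:
        raise ValueError(f"cross-reactivity must be >= 0, got {cr}")
    if cr >= BIN_EDGES[2]:
        return Category.strong
    if cr >= BIN_EDGES[1]:
        return Category.weak
    if cr >= BIN_EDGES[0]:
        return Category.very_weak
    return Category.none


def classify_panel(
    records: list[CrossReactivityRecord],
    exclude_target: bool = True,
    target_name: str | None = None,
) -> dict[Category, int]:
    """Per-category counts for one assay's panel.

    The assay's own target analyte (cross-reactivity 100% by definition) is
    excluded when ``exclude_target`` is true; it is identified by
    ``target_name`` or, failing that, by the packaged assay definition.
    """
    counts: Counter[Category] = Counter()
    assays = {r.assay_name for r in records}
    if len(assays) > 1:
        raise ValueError(f"records span multiple assays: {sorted(assays)}")
    if records and exclude_target and target_name is None:
        from .compound_library import load_assay_definition

        target_name = load_assay_definition(records[0].assay_name).target_compound.name
    for record in records:
        if exclude_target and record.compound_name == target_name:
            continue
        counts[record.category] += 1
    return {cat: counts.get(cat, 0) for cat in Category}


def classify_measurements(measurements: list[SpikedMeasurement]) -> list[CrossReactivityRecord]:
    """Compute CR% and category for a batch of spiked measurements."""
    records = []
    for m in measurements:
        cr = percent_cross_reactivity(m)
        records.append(
            CrossReactivityRecord(
                assay_name=m.assay_name,
                compound_name=m.compound_name,
                cross_reactivity_pct=cr,
                category=categorize(cr),
                provenance="measured",
            )
        )
    return records
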