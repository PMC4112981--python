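"""Synthetic assay panels with a similarity-linked cross-reactivity model.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage (CR estimation, categorization,
interference grading, triage sweeps) can be exercised offline:

* per-compound 2D similarities drawn uniform on [0, 1] (similarities are
  simulated directly — fingerprints of invented molecules are out of scope);
* a monotone logistic link from similarity to expected cross-reactivity,
  capturing the empirical threshold-like relation in which strong
  cross-reactivity appears only at high similarity;
* per-compound true CR = expected CR x lognormal noise;
* spiked/baseline readouts with multiplicative Gaussian noise of fixed
  coefficient of variation (the standard immunoassay imprecision model).

Defaults emulate a progesterone-like interference study: spike 1000 ng/mL,
baseline apparent analyte 5 ng/mL, 5% assay CV, and a steep link centred at
similarity 0.8 so that weak-or-strong cross-reactivity is essentially
confined to compounds near or above the midpoint — the threshold-like
relation observed empirically, where compounds below ~0.6 similarity are
unlikely to show even weak cross-reactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .crossreactivity import (
    Category,
    SpikedMeasurement,
    categorize,
    percent_cross_reactivity,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated panel.

    ``link_midpoint`` is the similarity at which expected CR is half of
    ``link_max``; ``noise_sd_log`` is the SD of the lognormal scatter of true
    CR around the link; ``assay_cv`` is the fractional imprecision of each
    concentration readout.
    """

    seed: int
    n_compounds: int = 500
    spike_concentration: float = 1000.0  # ng/mL
    assay_cv: float = 0.05
    baseline_level: float = 5.0  # ng/mL apparent analyte in neat plasma
    link_midpoint: float = 0.8
    link_slope: float = 40.0
    link_max: float = 150.0  # percent; CR can exceed 100%
    noise_sd_log: float = 0.2

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if min(self.spike_concentration, self.baseline_level, self.link_slope, self.link_max) <= 0:
            raise ValueError("spike, baseline, link_slope and link_max must be > 0")
        if self.assay_cv < 0 or self.noise_sd_log < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.link_midpoint <= 1:
            raise ValueError("link_midpoint must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedPanel:
    config: SimulationConfig
    compound_names: tuple[str, ...]
    similarities: np.ndarray  # [0, 1] per compound
    true_cr: np.ndarray  # percent per compound
    measurements: tuple[SpikedMeasurement, ...]

    def true_categories(self) -> list[Category]:
        return [categorize(cr) for cr in self.true_cr]

    def to_frame(self) -> pd.DataFrame:
        """Measurements in the same CSV schema the classify pipeline reads."""
        return pd.DataFrame(
            {
                "assay": [m.assay_name for m in self.measurements],
                "compound": [m.compound_name for m in self.measurements],
                "spike_ng_ml": [m.spike_concentration for m in self.measurements],
                "apparent_spiked_ng_ml": [m.apparent_spiked for m in self.measurements],
                "apparent_baseline_ng_ml": [m.apparent_baseline for m in self.measurements],
            }
        )


def expected_cr(similarity: np.ndarray | float, config: SimulationConfig) -> np.ndarray | float:
    """Logistic link: link_max / (1 + exp(-slope * (s - midpoint)))."""
    return config.link_max / (1.0 + np.exp(-config.link_slope * (np.asarray(similarity) - config.link_midpoint)))


def _noisy_readout(value: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise with coefficient of variation ``cv``,
    floored at zero (an analyzer never reports negative concentrations)."""
    noisy = value * (1.0 + cv * rng.standard_normal(value.shape))
    return np.maximum(noisy, 0.0)


def simulate_panel(config: SimulationConfig, assay_name: str = "simulated") -> SimulatedPanel:
    """Draw one panel, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    similarities = rng.uniform(0.0, 1.0, n)
    mean_cr = expected_cr(similarities, config)
    if config.noise_sd_log > 0:
        true_cr = mean_cr * rng.lognormal(0.0, config.noise_sd_log, n)
    else:
        true_cr = np.asarray(mean_cr, dtype=float)
    names = tuple(f"cmpd-{i:04d}" for i in range(n))
    spiked_true = config.baseline_level + true_cr / 100.0 * config.spike_concentration
    baseline_true = np.full(n, config.baseline_level)
    spiked = _noisy_readout(spiked_true, config.assay_cv, rng)
    baseline = _noisy_readout(baseline_true, config.assay_cv, rng)
    measurements = tuple(
        SpikedMeasurement(
            assay_name=assay_name,
            compound_name=names[i],
            spike_concentration=config.spike_concentration,
            apparent_spiked=float(spiked[i]),
            apparent_baseline=float(baseline[i]),
        )
        for i in range(n)
    )
    return SimulatedPanel(
        config=config,
        compound_names=names,
        similarities=similarities,
        true_cr=true_cr,
        measurements=measurements,
    )


@dataclass(frozen=True)
class RecoveryStats:
    """Replicate-level recovery of true CR and category per compound."""

    compound_names: tuple[str, ...]
    true_cr: np.ndarray
    mean_estimated_cr: np.ndarray
    sd_estimated_cr: np.ndarray | None  # None when n_replicates == 1
    bias: np.ndarray  # mean estimated - true, per compound
    category_agreement: float  # fraction with category(mean est) == category(true)

    def agreement_for(self, mask: np.ndarray) -> float:
        """Category agreement restricted to a boolean compound mask."""
        est = [categorize(cr) for cr in self.mean_estimated_cr[mask]]
        true = [categorize(cr) for cr in self.true_cr[mask]]
        return float(np.mean([e == t for e, t in zip(est, true)])) if est else float("nan")


def recovery_experiment(config: SimulationConfig, n_replicates: int = 10) -> RecoveryStats:
    """Re-measure one panel ``n_replicates`` times and summarize recovery.

    The panel (similarities and true CR) is drawn once from ``config.seed``;
    each replicate redraws only the readout noise. Estimated CR per replicate
    comes from the same estimator the real pipeline uses
    (:func:`percent_cross_reactivity`).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    panel = simulate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_compounds
    spiked_true = config.baseline_level + panel.true_cr / 100.0 * config.spike_concentration
    baseline_true = np.full(n, config.baseline_level)
    estimates = np.empty((n_replicates, n))
    for rep in range(n_replicates):
        spiked = _noisy_readout(spiked_true, config.assay_cv, rng)
        baseline = _noisy_readout(baseline_true, config.assay_cv, rng)
        estimates[rep] = 100.0 * np.maximum(spiked - baseline, 0.0) / config.spike_concentration
    mean_est = estimates.mean(axis=0)
    sd_est = estimates.std(axis=0, ddof=1) if n_replicates > 1 else None
    est_cat = [categorize(cr) for cr in mean_est]
    true_cat = panel.true_categories()
    agreement = float(np.mean([e == t for e, t in zip(est_cat, true_cat)]))
    return RecoveryStats(
        compound_names=panel.compound_names,
        true_cr=panel.true_cr,
        mean_estimated_cr=mean_est,
        sd_estimated_cr=sd_est,
        bias=mean_est - panel.true_cr,
        category_agreement=agreement,
    )


def far_from_bin_edges(true_cr: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Mask of compounds whose true CR is a multiplicative ``factor`` away
    from every category bin edge (edges are log-spaced, so a factor is the
    natural safety margin)."""
    from .crossreactivity import BIN_EDGES

    cr = np.asarray(true_cr, dtype=float)
    mask = np.ones(cr.shape, dtype=bool)
    for edge in BIN_EDGES:
        mask &= (cr <= edge / factor) | (cr >= edge * factor)
    return mask
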