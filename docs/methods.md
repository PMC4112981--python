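# Methods

## Structure standardization

All similarity work runs on standardized connection tables: the largest
covalent fragment by heavy-atom count (molecular weight breaks ties), all
stereo descriptors removed, and protonation normalized to the neutral form
where chemically valid. Stereo removal is not a convenience but a semantic
requirement — structural-key fingerprints are computed on the 2D graph, so
diastereomers and enantiomers (e.g., pregnanolone and allopregnanolone) are
identical objects to the method, and leaving stereo in place would only
invite spurious distinctions downstream. Salt stripping follows the
largest-fragment convention (estropipate reduces to estrone sulfate,
discarding piperazine); how the original similarity calculations prepared
salt records is not documented anywhere we could find, so this is a design
choice, not an inference. Sulfate conjugates are bundled protonated so
fingerprints are charge-state independent. Standardization is idempotent,
which the tests assert across the whole bundled library.

## Structural keys and Tanimoto similarity

Fingerprints are presence bit vectors over a versioned dictionary of 166
substructure keys — the public MDL/MACCS key set rendered as SMARTS and
shipped as a plain-text asset (`keys166_v1.tsv`, version `public-166-v1`).
Bit *k* is set when pattern *k* matches at least `min_count` times
(symmetry-unique matches); three keys the original dictionary defines
procedurally (isotope presence, aromatic-ring count, fragment count) are
engine-evaluated specials. Tanimoto similarity is `c / (|a| + |b| − c)`
over set bits; two all-zero fingerprints score 1.0 by convention (logged as
degenerate), an all-zero against anything else scores 0.

Commercial packages render the public keys with small dialect differences,
so exact bit parity with any one of them is not promised; the dictionary is
a swappable, versioned asset. On the bundled steroid panel our rendering
agrees with RDKit's independent MACCS implementation on 100% of bits (the
test suite requires ≥ 95%), and reproduces published steroid-pair
similarities to within a few hundredths (reported to 3 decimals, matching
the precision such values are conventionally printed at). Similarity values
in this document's tolerance discussions use ±0.05 as the key-dialect
slack.

## Cross-reactivity and categories

Percent cross-reactivity from a spiked interference experiment follows the
standard interference-protocol reading (spiked vs unadulterated specimen,
NCCLS/CLSI EP7 style): `CR% = 100 × max(0, spiked − baseline) / spike`.
Negative differences are readout noise and are clipped to zero (logged).
CR can exceed 100% when the antibody binds the interferent more avidly than
its own hapten (6-methylprednisolone reaches 249% on the cortisol assay).

Categories are half-open bins at 0.05 / 0.5 / 5 percent: strong [5, ∞),
weak [0.5, 5), very weak [0.05, 0.5), none [0, 0.05). The conventional
"0.5–4.9%" phrasing is treated as display rounding of "< 5" so that every
non-negative value has exactly one category and the map is monotone.
Package-insert values in the fixture tables carry their provenance string
and are never recomputed. Replicate averaging is left to the caller; inputs
are single values per spiked sample.

## Interference grading

For each (compound, population) pair with published plasma data the
apparent-analyte range is point arithmetic, `CR/100 × plasma bound`
(no error propagation; the quantities being multiplied are themselves
reported ranges). The qualitative likelihood grade is a codification —
the published tables grade by expert judgment and state no numeric rule —
defined as:

* `R = apparent_high / upper bound of the applicable reference interval`;
* `high` when R ≥ 0.25, `possible` when 0.02 ≤ R < 0.25, else `low`;
  `unknown` exactly when no plasma data exist. Thresholds are
  config-exposed (`GradingThresholds`).

The applicable interval is chosen by population-token matching
(male/female/pregnancy/infancy synonyms, with negated phrases like
"non-pregnant" dropped before tokenizing); an unmatched population grades
against the least-sensitive (widest) interval, so interference is flagged
only when large even against the widest normal range. Two aspects deserve
emphasis:

* **Upper bound, not lower.** A first candidate rule — ratio to the
  reference-interval *lower* bound — collapses on assays whose intervals
  start at or near zero (testosterone in females, 0–0.5 ng/mL) and grades
  several published "Low" rows as high (allopregnanolone on the
  progesterone assay, among others). No lower-bound rule with any single
  threshold pair reproduces the published grades; the upper-bound rule
  with population matching reproduces every categorical grade with roughly
  two-fold margins on both thresholds.
* **Exception clauses are disjunctive.** Rows published as "Low, except
  …" grade low for the control population, and the exception clause is
  satisfied when a named exception population reaches possible/high. For
  the 11-deoxycortisol rows the clause names metyrapone challenge *or*
  11β-hydroxylase deficiency; the rule grades the metyrapone population
  possible and the (lower-concentration) 11β-OHD population low, which the
  frozen test codification accepts, consistent with the published caveat
  that falsely elevated results are likely only at the high end of the
  reported concentration ranges. Hedged clauses ("possible minor effect")
  admit low-or-possible.

When an assay has several reference intervals, reports carry the interval
actually used so a reader can judge the denominator. The assay's own target
is excluded from interference reports by default (its "interference" is the
measurement itself); `include_target=True` restores it.

## Triage evaluation

The triage question is whether 2D similarity, which costs seconds, predicts
cross-reactivity, which costs a wet-lab study. Per-category similarity
statistics (n, mean, min, max) mirror the strip-plot-with-mean-bars view of
the data. Threshold sweeps treat strong ∪ weak as the positive class and
none as negative; the very-weak bin is ambiguous and excluded by default
(config-switchable to either class). Compounds exactly at the cutoff count
as flagged, matching "0.8 or higher" phrasing. Sensitivity is nonincreasing
and specificity nondecreasing in the cutoff; the tests verify both against
a brute-force confusion-count oracle. The default sweep grid is 0.00–1.00
in steps of 0.05.

With the packaged panels and our key dialect, the known limits of the
similarity heuristic are visible and tested: tetrahydrocortisone scores
0.911 against cortisol yet is not cross-reactive (the published outlier),
and one weak progesterone cross-reactant (corticosterone, 0.54%) sits just
below the 0.722 floor that holds exactly for the seven named cross-reactive
progesterone compounds.

## Synthetic panels

The generator simulates the statistical structure the analysis assumes,
not the chemistry: similarities are drawn uniform on [0, 1] directly
(fingerprints of invented molecules are out of scope — real structures
exercise the chemistry stages). Expected CR follows a logistic link
`link_max / (1 + exp(−slope × (s − midpoint)))`; true CR multiplies in
lognormal scatter (`noise_sd_log`); readouts apply mean-one multiplicative
Gaussian noise with coefficient of variation `assay_cv`, floored at zero.
All randomness flows from one seed; equal configs give bit-identical
panels.

Defaults are a progesterone-like study: spike 1000 ng/mL, baseline apparent
analyte 5 ng/mL, assay CV 5%, lognormal SD 0.2, link midpoint 0.8 with
slope 40 and ceiling 150%. The steep slope is deliberate: empirically,
weak-or-strong cross-reactivity is confined to high similarity (compounds
below ~0.6 rarely show even weak cross-reactivity), and the link is
constructed so that triage sensitivity at a cutoff equal to the midpoint
exceeds 0.5 on large panels. A shallow logistic would spread weak
cross-reactivity far below the midpoint and break that construction.

`recovery_experiment` redraws readout noise over replicates on a fixed
panel and reports per-compound mean/SD of estimated CR, bias, and the
fraction of compounds whose recovered category matches the category of
their true CR. Because readout noise is mean-one multiplicative, the CR
estimator is unbiased away from the zero-clip; near zero the clip induces
a small positive bias, so unbiasedness is asserted on compounds with true
CR > 1%. Category agreement is assessed on compounds whose true CR is a
factor of 2 from every bin edge (edges are log-spaced, so a multiplicative
margin is the natural notion of "far from an edge"); at the default noise
level, 10 replicates and 500 compounds, agreement on that subset is 1.0
in practice and ≥ 0.95 is asserted.

What passing simulator-based tests shows — and does not: they validate the
estimation, binning, and triage machinery under the assumed noise model;
they say nothing about antibody binding, matrix effects, or calibration
nonlinearity in real assays, none of which are modeled.

## Problem sizes and determinism

The test suite and the acceptance script run the full chemistry pipeline on
the ~48-compound bundled library (seconds) and simulator experiments at 500
compounds × 10 replicates (sub-second); these sizes give Monte-Carlo errors
comfortably inside the asserted tolerances. All stochastic tests are
seeded; CLI reports are byte-deterministic given config, which the manifest
checksums make checkable.

## Known limitations

* The key dictionary is one rendering of the public 166-key set; similarity
  values move by a few hundredths across dialects, hence the ±0.05
  tolerance on printed values.
* The likelihood rule is a transparent codification of expert judgment; it
  reproduces the published categorical grades but is not the original
  authors' (unstated) rule, and its two thresholds are conventions.
* Plasma-range fixtures are transcriptions with opaque citation tags; the
  package does not verify them against primary pharmacokinetic literature
  at runtime.
* Positional isomer detail that structural keys cannot see (e.g., exact
  halogen placement on a ring) is curated on a best-effort basis in the
  bundled SMILES and does not affect key-level fingerprints materially.
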