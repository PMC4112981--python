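# steroidxr

Structural-similarity analysis of steroid hormone immunoassay
cross-reactivity.

Clinical immunoassays for cortisol, DHEA sulfate, estradiol, progesterone
and testosterone are vulnerable to interference from compounds that resemble
the assay's target hapten: synthetic glucocorticoids, anabolic steroids,
progestins, and endogenous precursors that accumulate in disorders such as
21-hydroxylase deficiency. `steroidxr` packages the quantitative workflow a
clinical-chemistry or cheminformatics group uses to study this problem:

* **2D similarity** — 166-key structural fingerprints (the public MDL/MACCS
  key set, shipped as a versioned plain-text dictionary) with the Tanimoto
  coefficient `T(A,B) = c / (|A| + |B| − c)`, where `c` is the number of
  shared set bits. Structures are standardized first (largest covalent
  fragment, stereo stripped, neutralized) because structural keys cannot
  distinguish diastereomers or salt forms.
* **Cross-reactivity** — percent cross-reactivity from spiked-sample
  measurements, `CR% = 100 × max(0, apparent_spiked − apparent_baseline) /
  spike`, binned into strong (≥ 5%), weak (0.5–4.9%), very weak
  (0.05–0.49%) and not cross-reactive (< 0.05%).
* **Interference risk** — apparent-analyte concentration bounds
  `CR/100 × plasma concentration` from published plasma ranges, graded
  high / possible / low against the applicable reference interval (or
  unknown when no pharmacokinetic data exist).
* **Triage** — per-category similarity statistics and cutoff sweeps
  (sensitivity/specificity) quantifying how well a similarity threshold
  such as 0.8 prioritizes compounds for wet-lab cross-reactivity testing.
* **Simulation** — a seeded generator of synthetic assay panels with a
  monotone similarity→cross-reactivity link and CV-based readout noise, so
  every downstream stage is testable offline.

The package bundles curated structures and the transcribed cross-reactivity
/ plasma-concentration tables for five marketed electrochemiluminescence
assays as fixtures.

## Worked example

Similarity of the estrogen panel to the estradiol assay target:

```sh
$ steroidxr similarity estrogens.smi --target estradiol --out sim.csv
$ cat sim.csv
query,reference,tanimoto
estradiol,estradiol,1.000
estrone,estradiol,0.879
ethinyl estradiol,estradiol,0.970
estriol,estradiol,0.914
letrozole,estradiol,0.096
```

The three steroidal estrogens score 0.88–0.97 against estradiol — all were
measurably cross-reactive on the estradiol immunoassay — while the
non-steroidal aromatase inhibitor letrozole (0.096) was not. Interference
report for the cortisol assay:

```sh
$ steroidxr risk --assay cortisol --out risk.csv
$ head -4 risk.csv
assay,compound,population,apparent_low_ng_ml,apparent_high_ng_ml,reference_population,reference_low_ng_ml,reference_high_ng_ml,likelihood,citation
cortisol,6-methylprednisolone,after oral or intravenous administration,0.0,2490.0,morning,62.0,194.0,high,lit-ref-20
cortisol,prednisolone,pediatric transplant patients,0.0,592.0,morning,62.0,194.0,high,lit-ref-21
cortisol,21-deoxycortisol,21-hydroxylase deficiency,0.0,63.559999999999995,morning,62.0,194.0,high,lit-ref-22
```

6-Methylprednisolone (249% cross-reactivity) at therapeutic plasma levels of
up to 1000 ng/mL can masquerade as 2490 ng/mL of apparent cortisol — more
than ten times the upper morning reference limit — so it is graded a high
interference risk; 21-deoxycortisol is a risk only in the 21-hydroxylase
deficiency population where it accumulates. The same analysis is available
as library calls (`steroidxr.similarity_panel`, `steroidxr.classify_panel`,
`steroidxr.interference_report`, `steroidxr.threshold_sweep`), and
`steroidxr report --assay <name> --out-dir <dir>` writes the full
interference + triage report with a reproducibility manifest.

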