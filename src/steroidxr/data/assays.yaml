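# Packaged immunoassay definitions for the five Roche Elecsys steroid assays.
# spike_ng_ml is the interference-challenge concentration of each test
# compound; reference_intervals are the target-analyte serum/plasma intervals
# (ng/mL) used for interference grading.
cortisol:
  target: cortisol
  spike_ng_ml: 1000
  reference_intervals:
    - {population: morning, low: 62, high: 194}
    - {population: afternoon, low: 23, high: 119}
dhea_sulfate:
  target: DHEA sulfate
  spike_ng_ml: 50000
  reference_intervals:
    - {population: infants, low: null, high: 6070}
    - {population: females older than 1 year, low: 5, high: 4070}
    - {population: males older than 1 year, low: 5, high: 4920}
estradiol:
  target: estradiol
  spike_ng_ml: 1000
  reference_intervals:
    - {population: males, low: 0.01, high: 0.04}
    - {population: premenopausal females, low: 0.013, high: 0.50}
    - {population: pregnancy, low: null, high: 4.3}
progesterone:
  target: progesterone
  spike_ng_ml: 1000
  reference_intervals:
    - {population: males, low: 0.2, high: 1.4}
    - {population: women, low: null, high: 27}
testosterone:
  target: testosterone
  spike_ng_ml: 100
  reference_intervals:
    - {population: males, low: 0, high: 10}
    - {population: females, low: 0, high: 0.5}
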