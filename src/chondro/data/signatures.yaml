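# Marker signatures used to label attractors.  A profile matches a signature
# when every "high" component's global activity exceeds 1 - band and every
# "low" component's falls below band.
band: 0.2
signatures:
  - label: Healthy
    high: [SOX9, NKX3.2, COL-II]
    low: [RUNX2, COL-X, MMP13]
  - label: Hypertrophic
    high: [RUNX2, COL-X, MMP13, IHH]
    low: [SOX9]
  - label: "None"
    low: [SOX9, NKX3.2, COL-II, RUNX2, COL-X, MMP13, IHH]
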