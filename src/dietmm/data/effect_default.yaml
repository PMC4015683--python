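# Default intervention effect: fixed relative risks of incidence in the
# At Risk state, applied identically to both sexes and all age bands.
# Values are the published simulation means for a 0.5 portion/day increase
# in fruit and vegetable consumption.
mode: fixed_rr
fixed_rr:
  DM: 0.965
  CHD: 0.959
  STR: 0.975
  CRC: 0.997
portion_mean: 0.5
portion_ci: [0.13, 0.87]
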