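# Precursor schemes for the 13C6-glucose / pyruvate tracing design.
# Every packaged product is assembled from the well-mixed pyruvate pool:
# valine and its immediate precursor condense two pyruvate units (3 + 2
# carbons, one CO2 lost), alanine is a single transaminated pyruvate.
pools:
  pyruvate:
    unit_carbon_count: 3
schemes:
  valine:
    formula: C5H11NO2
    units: [[pyruvate, 3], [pyruvate, 2]]
  alanine:
    formula: C3H7NO2
    units: [[pyruvate, 3]]
  dihydroxy_isovalerate:
    formula: C5H10O4
    units: [[pyruvate, 3], [pyruvate, 2]]
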