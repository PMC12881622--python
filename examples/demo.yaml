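# Demo pipeline configuration: two small synthetic regions, three years.
# Scalar defaults (windows, splits, k, MMU, tree count) follow the method;
# the sampling density is raised to suit the ~1.6 km² demo scenes — at the
# operational 2 pts/km² such a small extent yields almost no points
# (see docs/methods.md, "Scaling of test scenes").
seed: 7
years: [2020, 2021, 2022]
density_per_km2: 150.0
regions:
  - name: region-a
    rows: 128
    cols: 128
    n_clearings: 1
    n_burns: 1
  - name: region-b
    rows: 128
    cols: 128
    n_clearings: 2
    n_burns: 1
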