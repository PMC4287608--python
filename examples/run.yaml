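# Demo configuration for `noiseqtl run-all --config examples/run.yaml`.
# Study-scale defaults live in the RunConfig schema (src/noiseqtl/pipeline.py);
# this file keeps the run desk-sized.
seed: 1
out_dir: out
simulate:
  n_lines: 100
  n_metabolites: 40
  n_defense: 6
  n_growth: 2
scan:
  cofactors: 3
  window: 10
  step: 1
  n_perm: 0        # > 0 adds per-trait permutation LOD thresholds
  lod_min: 2
hotspots:
  window: 5
  step: 1
  alpha: 0.05
  n_perm: 500
anova:
  edge_min: 0.10
  fdr: 0.05
null_census:
  enabled: true
  n_perm: 5
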