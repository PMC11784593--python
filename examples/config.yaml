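# Example run configuration for the mscolor command-line interface.
#
# Every command takes this file as its first argument; --seed, --method and
# --out-dir flags override the corresponding fields.
#
#   mscolor simulate examples/config.yaml          # write synthetic inputs
#   mscolor fit      examples/config.yaml --lam 1  # fit one model
#   mscolor cv       examples/config.yaml          # nested cross-validation
#   mscolor evaluate examples/config.yaml          # CV + selection + statistics

seed: 0
method: mscolor          # one of: mscolor, msmml, smml, smtr
out_dir: runs/example

# Synthetic-study settings used by `simulate` (see mscolor.synthetic.SimConfig
# for the full list and defaults).
sim:
  n_per_stage: [120, 120, 120]
  stage_slope_profile: [1.0, 1.8, 0.7]
  d: 60
  c: 4
  m: 3
  n_causal: 8
  n_gwas: 8000
  n_ref: 1000

# Input files used by `fit` / `cv` / `evaluate`.  `simulate` writes exactly
# these files into out_dir; point the paths there (or at your own data).
# Instead of genotype+alleles you may give `plink: <prefix>` for a
# .bed/.bim/.fam triplet.
paths:
  genotype: runs/example/genotype.tsv
  alleles: runs/example/alleles.tsv
  qts: runs/example/qts.tsv
  covariates: runs/example/covariates.tsv
  sumstats: runs/example/sumstats.tsv
  ld: runs/example/ld.tsv
  truth: runs/example/truth.json      # optional; enables recovery metrics

# Solver settings (mscolor.solver.SolverConfig fields).
solver:
  gamma: 0.5
  max_iter: 200

# Cross-validation: the penalty grid is 10^e for each exponent listed.
cv:
  grid_exponents: [-3, -2, -1, 0, 1, 2, 3]
  k_outer: 5
  k_inner: 3

top_k: 8
score_columns: [MMSE, ADAS, RAVLT]
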