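# Focal study grid: every breeding goal x between-trait correlation,
# null worker-queen correlation, 24 selected parents per path.
# Run with:  apisim run --config examples/scenario.yaml --seed 1 \
#                       --mode reml --out results/
weights:
  - [1.0, 0.0]
  - [0.75, 0.25]
  - [0.5, 0.5]
  - [0.25, 0.75]
  - [0.0, 1.0]
r_T1T2: [-0.6, -0.3, 0.0, 0.3, 0.6]
r_WQ: [0.0]
variant: [24]
replicates: 50
evaluation_mode: reml
# save_details: true   # per-replicate pedigree/performance/ledger CSVs
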