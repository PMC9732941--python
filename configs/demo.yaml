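# Demonstration run: a 1 Mb single-chromosome genome, 10 TE families with
# one family planted at 3-fold peak enrichment, 400 regulatory peaks,
# 3 simulated TFBS peak sets, 500 genes evolving on a 10-taxon tree, and a
# full 89-construct reporter screen. Completes in well under a minute.
outdir: scratch/demo_run
seed: 1
n_reps: 1000
n_tf_factors: 3
alpha: 0.05
min_fold: 1.5
tpm_threshold: 2
merge_gap: 100
mds_dims: 4
kmeans_k: 4
focal_tip: Human
simulate:
  peak_spec:
    n_peaks: 400
    mean_length: 300
    per_family_enrichment_multiplier:
      FAM1: 3.0
  expression_spec:
    n_genes: 500
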