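# Demo pipeline configuration: a small AIL with one pleiotropic QTL.
# Run with:  ailqtl run --config examples/demo_config.yaml --outdir out/demo
seed: 1
outdir: out/demo
stages: [simulate, qc, scan, causal, de, prioritize]

simulate:
  n_individuals: 200
  n_generations: 10
  chromosomes: [["1", 100000000], ["2", 100000000]]
  markers_per_chromosome: 80
  genes_per_chromosome: 40
  qtl:
    # a locus on chromosome 1 with a direct effect on adipose weight,
    # which in turn drives blood glucose (causal chain)
    - {chrom: "1", pos: 50000000, trait: gonat_weight, additive: -0.8, noise_sd: 1.0}
    - {trait: blood_glucose, mediation: [gonat_weight, -0.7], noise_sd: 1.0}
    # liver weight: no planted QTL, but influenced by litter size below
    - {trait: liver_weight, noise_sd: 0.6}
  covariate:
    traits: [liver_weight]
    effect: 0.15
  expression:
    n_probes: 400
    de_fraction: 0.1
    effect_size_log2: 1.0
    noise_sd: 0.3

scan:
  traits: [gonat_weight, blood_glucose]
  selection_traits: [gonat_weight]
  n_select: 120
  simplem_window: 820
  lod_drop: 1.5
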