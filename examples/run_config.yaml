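# Full-pipeline config for `pxgs run --config examples/run_config.yaml`.
# A small, fast polycross trial exercising every stage: simulation, QC,
# relationship matrices, pedigree reconstruction, model fits, selection.
seed: 11
outdir: pxgs_demo_run
sim:
  n_females: 5
  n_males: 4
  n_snps: 600
  offspring_per_family: 60
  n_sites: 2
  reps_per_site: 5
  sets_per_rep: 2
  male_weights: [0.4, 0.3, 0.2, 0.1]
  maternal_mislabel_rate: 0.10
  dual_genotype_mother_fraction: 0.2
  contamination_rate: 0.05
  selfing_rate: 0.02
traits:
  - name: HT
    sigma2_a: 0.3
    sigma2_sa: 0.1
    sigma2_rep: 0.05
    sigma2_e_by_site: [0.5, 0.6]
    site_means: [100.0, 120.0]
  - name: W.AT
    sigma2_a: 0.2
    sigma2_e_by_site: 0.6
    site_means: [1.0, 1.2]
    lognormal: true
models: [gblup-a, ablup-px]
selection_fraction: 0.05
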