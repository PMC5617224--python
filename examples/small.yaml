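n_individuals: 120
n_families: 20
offspring_per_family: 2
n_snps: 800
n_cpgs: 150
n_biomarkers: 5
maf_range: [0.05, 0.5]
ld_block_size: 10
haplotype_pool: 8
chrom_layout: [["1", 120000000], ["2", 120000000], ["3", 100000000], ["4", 100000000]]
scenario_counts: {SNP_CONFOUNDED: 1, PROTEIN_TO_CPG: 1, CPG_TO_PROTEIN: 1, SMOKING_CONFOUNDED: 1, NULL: 1}
noise_scale: 1.0
plate_sd: 0.15
detection_limit_quantile: 0.02
plate_count: 3
smoking_prevalence: 0.2
methylation_failure_rate: 0.002
low_info_fraction: 0.02
dosage_error_scale: 0.3
cross_hybridizing_fraction: 0.01
n_mz_pairs: 0
seed: 0
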