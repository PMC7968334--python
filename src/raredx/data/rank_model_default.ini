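# Default SNV/INDEL rank model shipped with raredx.
#
# Point values are implementer-chosen, hand-auditable defaults covering the
# standard prioritization axes (rarity, consequence, conservation, predicted
# impact, inheritance, clinical assertions, local observations, call
# quality). They are NOT calibrated production weights; supply your own
# config for clinical use.

[category.frequency]
default = 0
rule.1 = population_af missing => 4
rule.2 = population_af in [0.0, 0.0001) => 4
rule.3 = population_af in [0.0001, 0.001) => 3
rule.4 = population_af in [0.001, 0.005) => 1
rule.5 = population_af in [0.005, 0.02) => -6
rule.6 = population_af in [0.02, 1.01) => -12

[category.consequence]
default = 0
rule.1 = consequence is {transcript_ablation, stop_gained, frameshift_variant, stop_lost, start_lost, splice_acceptor_variant, splice_donor_variant} => 5
rule.2 = consequence is {missense_variant, inframe_insertion, inframe_deletion, protein_altering_variant} => 3
rule.3 = consequence is {splice_region_variant, incomplete_terminal_codon_variant} => 2
rule.4 = consequence is {synonymous_variant, stop_retained_variant} => -2
rule.5 = consequence is {intron_variant, intergenic_variant, upstream_gene_variant, downstream_gene_variant} => -4

[category.conservation]
default = 0
rule.1 = conservation_score missing => 0
rule.2 = conservation_score in [0.8, inf) => 2
rule.3 = conservation_score in [0.5, 0.8) => 1

[category.deleteriousness]
default = 0
rule.1 = deleteriousness_score missing => 0
rule.2 = deleteriousness_score in [25.0, inf) => 3
rule.3 = deleteriousness_score in [15.0, 25.0) => 2
rule.4 = deleteriousness_score in [10.0, 15.0) => 1

[category.inheritance]
default = -6
rule.1 = models is {AD_dn, AR_hom_dn, XD_dn, XR_dn, AR_comp_dn} => 3
rule.2 = models is {AR_hom, AR_comp, XR, MT} => 2
rule.3 = models is {AD, XD} => 1

[category.clinical_significance]
default = 0
rule.1 = clinical_significance is {pathogenic, likely_pathogenic} => 4
rule.2 = clinical_significance is {benign, likely_benign} => -8

[category.local_observations]
default = 0
rule.1 = local_obs missing => 0
rule.2 = local_obs in [0, 3) => 1
rule.3 = local_obs in [3, 10) => -2
rule.4 = local_obs in [10, inf) => -8

[category.call_quality]
default = 0
rule.1 = filter_status is {PASS} => 1
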