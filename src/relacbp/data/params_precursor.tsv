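# Precursor-model default parameter set for the IKK–IκB–NF-κB module.
# Reconstruction following the published precursor model family (flagged below);
# units: concentrations µM (cytoplasm-referenced), time min.
# mRNA degradation rates here are the PRE-adaptation values; the 1.8-fold
# increase is applied by relacbp.params.apply_model_adaptations.
provenance	precursor_default
modified	false
tx_k_basal_a	1e-05
tx_k_induced_max_a	0.45
tx_K_half_a	1.5
tx_h_a	2.0
tx_k_basal_b	1e-05
tx_k_induced_max_b	0.0
tx_K_half_b	1.5
tx_h_b	2.0
tx_k_basal_e	2e-06
tx_k_induced_max_e	0.0315
tx_K_half_e	1.5
tx_h_e	2.0
translation_rate_a	0.2
translation_rate_b	0.2
translation_rate_e	0.2
mrna_degradation_a	0.03
mrna_degradation_b	0.02
mrna_degradation_e	0.02
deg_free_basal_a	0.12
deg_free_basal_b	0.18
deg_free_basal_e	0.18
deg_free_ikk_a	0.3
deg_free_ikk_b	0.045
deg_free_ikk_e	0.045
deg_bound_basal_a	2.25e-05
deg_bound_basal_b	2.25e-05
deg_bound_basal_e	2.25e-05
deg_bound_ikk_a	1.2
deg_bound_ikk_b	0.12
deg_bound_ikk_e	0.18
assoc_a	30.0
assoc_b	30.0
assoc_e	30.0
dissoc_a	0.03
dissoc_b	0.03
dissoc_e	0.03
ikb_import_a	0.09
ikb_import_b	0.009
ikb_import_e	0.045
ikb_export_a	0.012
ikb_export_b	0.012
ikb_export_e	0.012
complex_export_a	0.83
complex_export_b	0.83
complex_export_e	0.83
nfkb_import	5.4
nfkb_export	0.0048
volume_ratio	5.0
total_nfkb	0.1
nfkb_scale	1.0
kmrna_scale	1.0
mrna_degradation_factor	1.8
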