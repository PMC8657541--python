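[
 {
  "name": "optic_nerve_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "optic_nerve_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "frontal_lobe_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "frontal_lobe_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "midbrain_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "midbrain_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "globus_pallidus_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "globus_pallidus_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "olfactory_bulb_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "olfactory_bulb_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "subcortical_region_frontal_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "subcortical_region_frontal_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "anterior_commissure_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "anterior_commissure_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "mamilothalamic_tract_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "mammilothalamic_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "corpus_callosum_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "stria_medullaris_thalami_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "stria_medullaris_thalami_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "parietal_temporal_cortex_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "subcortical_region_parieto_temopal_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "subcortical_region_parieto_temopal_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "internal_capsule_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "internal_capsule_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "fasciculus_retroflexus_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "cerebellum_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "cerebellum_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "left_pons_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "pons_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "fornix_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "amygdala_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "left_amygdala_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "medulla_R",
  "hemisphere": "R",
  "is_reference": true
 },
 {
  "name": "medulla_L",
  "hemisphere": "L",
  "is_reference": true
 },
 {
  "name": "ventricle_sum_sup_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "ventricle_sum_sup_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "ventricle_sum_lat_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "ventricle_sum_lat_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "hippocampus_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "striatum_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "striatum_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "occipital_cortex_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "thalamus_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "hypothalamus_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "parietal_temporal_cortex_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "occipital_cortex_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "thalamus_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "hypothalamus_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "hippocampus_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "fasciculus_retroflexus_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "fornix_L",
  "hemisphere": "L",
  "is_reference": false
 },
 {
  "name": "corpus_callosum_R",
  "hemisphere": "R",
  "is_reference": false
 },
 {
  "name": "mammilothalamic_L",
  "hemisphere": "L",
  "is_reference": false
 }
]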