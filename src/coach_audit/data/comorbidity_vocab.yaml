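# Comorbidity vocabulary, version 1.
#
# Weights are data, not code: `charlson` carries the original (non-age-adjusted)
# Charlson weights, `cote` the COPD-specific comorbidity (COTE) weights.
# `cote_sex: female` marks the one COTE condition scored in women only.
# `groups` lists the audit's comorbidity groupings a condition belongs to;
# coronary artery disease deliberately appears in both cardiac and vascular.
version: 1
conditions:
  coronary_artery_disease:      {charlson: 1, cote: 1, groups: [cardiac, vascular]}
  myocardial_infarction:        {charlson: 1, cote: 1, groups: [cardiac, vascular]}
  congestive_heart_failure:     {charlson: 1, cote: 1, groups: [cardiac]}
  atrial_fibrillation:          {charlson: 0, cote: 2, groups: [cardiac]}
  peripheral_vascular_disease:  {charlson: 1, cote: 0, groups: [vascular]}
  cerebrovascular_disease:      {charlson: 1, cote: 0, groups: [vascular]}
  dementia:                     {charlson: 1, cote: 0, groups: []}
  chronic_pulmonary_disease:    {charlson: 1, cote: 0, groups: []}
  pulmonary_fibrosis:           {charlson: 0, cote: 2, groups: []}
  connective_tissue_disease:    {charlson: 1, cote: 0, groups: []}
  peptic_ulcer_disease:         {charlson: 1, cote: 1, groups: []}
  mild_liver_disease:           {charlson: 1, cote: 0, groups: []}
  liver_cirrhosis:              {charlson: 3, cote: 4, groups: []}
  diabetes:                     {charlson: 1, cote: 0, groups: []}
  diabetes_with_neuropathy:     {charlson: 2, cote: 2, groups: []}
  hemiplegia:                   {charlson: 2, cote: 0, groups: []}
  renal_disease:                {charlson: 2, cote: 0, groups: []}
  lung_cancer:                  {charlson: 2, cote: 6, groups: [neoplasm]}
  esophageal_cancer:            {charlson: 2, cote: 6, groups: [neoplasm]}
  pancreatic_cancer:            {charlson: 2, cote: 6, groups: [neoplasm]}
  breast_cancer:                {charlson: 2, cote: 2, groups: [neoplasm]}
  other_cancer:                 {charlson: 2, cote: 2, groups: [neoplasm]}
  leukemia:                     {charlson: 2, cote: 2, groups: [neoplasm]}
  lymphoma:                     {charlson: 2, cote: 2, groups: [neoplasm]}
  metastatic_solid_tumor:       {charlson: 6, cote: 2, groups: [neoplasm]}
  aids:                         {charlson: 6, cote: 0, groups: []}
  anxiety:                      {charlson: 0, cote: 6, cote_sex: female, groups: []}
  sleep_apnea:                  {charlson: 0, cote: 0, groups: [sleep_apnea]}
  prostatic_hyperplasia:        {charlson: 0, cote: 0, groups: [prostatic_hyperplasia]}
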