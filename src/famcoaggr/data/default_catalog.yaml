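# Default condition catalog: 35 common adult physical conditions in 8 disease
# groups following ICD-10 chapter structure.
#
# The ICD code lists below are PROVISIONAL chapter-standard ranges chosen by this
# package; register studies typically curate bespoke lists per condition, so any
# production analysis should override this file with its own curated catalog
# (famcoaggr.catalog.load_catalog accepts any file with this schema).
# ICD-9/ICD-8 prefixes are supplied only where the mapping is unambiguous;
# a condition with no prefix list for a version simply cannot be triggered by
# records coded in that version.
min_age_years: 18
inpatient_window: [1973, 2013]
outpatient_window: [2001, 2013]
adhd_rule:
  icd_prefixes:
    9: ["314"]
    10: ["F90"]
  atc_codes: [N06BA01, N06BA02, N06BA04, N06BA09, N06BA12]
conditions:
  - {name: hypertension,                group: circulatory,         icd10: [I10, I11, I12, I13, I15], icd9: ["401", "402", "403", "404", "405"], icd8: ["400", "401", "402", "403", "404"]}
  - {name: ischaemic_heart_disease,     group: circulatory,         icd10: [I20, I21, I22, I23, I24, I25], icd9: ["410", "411", "412", "413", "414"], icd8: ["410", "411", "412", "413", "414"]}
  - {name: pulmonary_heart_disease,     group: circulatory,         icd10: [I26, I27, I28], icd9: ["415", "416", "417"], icd8: ["426"]}
  - {name: atrial_fibrillation,         group: circulatory,         icd10: [I48], icd9: ["4273"], icd8: ["4274"]}
  - {name: heart_failure,               group: circulatory,         icd10: [I50], icd9: ["428"], icd8: ["427.0", "4270"]}
  - {name: stroke,                      group: circulatory,         icd10: [I60, I61, I62, I63, I64], icd9: ["430", "431", "432", "433", "434", "436"], icd8: ["430", "431", "432", "433", "434", "436"]}
  - {name: peripheral_vascular_disease, group: circulatory,         icd10: [I70, I71, I72, I73], icd9: ["440", "441", "442", "443"], icd8: ["440", "441", "442", "443"]}
  - {name: type1_diabetes,              group: endocrine_metabolic, icd10: [E10], icd9: ["2500"], icd8: []}
  - {name: type2_diabetes,              group: endocrine_metabolic, icd10: [E11], icd9: ["2501", "2502"], icd8: []}
  - {name: thyroid_disorders,           group: endocrine_metabolic, icd10: [E00, E01, E02, E03, E04, E05, E06, E07], icd9: ["240", "241", "242", "243", "244", "245", "246"], icd8: ["240", "241", "242", "243", "244", "245", "246"]}
  - {name: obesity,                     group: endocrine_metabolic, icd10: [E66], icd9: ["2780"], icd8: ["277"]}
  - {name: gout,                        group: endocrine_metabolic, icd10: [M10], icd9: ["2740"], icd8: ["274"]}
  - {name: coeliac_disease,             group: gastrointestinal,    icd10: [K900], icd9: ["5790"], icd8: ["2690"]}
  - {name: ulcer_chronic_gastritis,     group: gastrointestinal,    icd10: [K25, K26, K27, K28, K29], icd9: ["531", "532", "533", "534", "535"], icd8: ["531", "532", "533", "534", "535"]}
  - {name: acute_appendicitis,          group: gastrointestinal,    icd10: [K35], icd9: ["540"], icd8: ["540"]}
  - {name: fatty_liver_disease,         group: gastrointestinal,    icd10: [K760], icd9: ["5718"], icd8: []}
  - {name: alcohol_liver_disease,       group: gastrointestinal,    icd10: [K70], icd9: ["5710", "5711", "5712", "5713"], icd8: ["5710"]}
  - {name: inflammatory_bowel_disease,  group: gastrointestinal,    icd10: [K50, K51], icd9: ["555", "556"], icd8: ["563", "5690"]}
  - {name: gallstone_disease,           group: gastrointestinal,    icd10: [K80], icd9: ["574"], icd8: ["574"]}
  - {name: glomerular_disease,          group: genitourinary,       icd10: [N00, N01, N02, N03, N04, N05, N06, N07, N08], icd9: ["580", "581", "582", "583"], icd8: ["580", "581", "582", "583"]}
  - {name: urolithiasis,                group: genitourinary,       icd10: [N20, N21, N22, N23], icd9: ["592", "594"], icd8: ["592", "594"]}
  - {name: kidney_infections,           group: genitourinary,       icd10: [N10, N11, N12], icd9: ["590"], icd8: ["590"]}
  - {name: rheumatoid_arthritis,        group: musculoskeletal,     icd10: [M05, M06], icd9: ["714"], icd8: ["712"]}
  - {name: arthrosis,                   group: musculoskeletal,     icd10: [M15, M16, M17, M18, M19], icd9: ["715"], icd8: ["713"]}
  - {name: connective_tissue_disease,   group: musculoskeletal,     icd10: [M30, M31, M32, M33, M34, M35], icd9: ["7100", "7101", "7102", "7103", "7104", "446"], icd8: ["734", "446"]}
  - {name: dorsalgia,                   group: musculoskeletal,     icd10: [M54], icd9: ["724"], icd8: ["728"]}
  - {name: parkinsons_disease,          group: nervous_system,      icd10: [G20], icd9: ["3320"], icd8: ["342"]}
  - {name: dementia,                    group: nervous_system,      icd10: [F00, F01, F02, F03, G30], icd9: ["290", "3310"], icd8: ["290"]}
  - {name: epilepsy,                    group: nervous_system,      icd10: [G40], icd9: ["345"], icd8: ["345"]}
  - {name: migraine,                    group: nervous_system,      icd10: [G43], icd9: ["346"], icd8: ["346"]}
  - {name: sleep_disorders,             group: nervous_system,      icd10: [G47, F51], icd9: ["307.4", "3074", "7805"], icd8: ["306.4", "3064"], exclude_icd10: [G474]}
  - {name: asthma,                      group: respiratory,         icd10: [J45, J46], icd9: ["493"], icd8: ["493"]}
  - {name: copd,                        group: respiratory,         icd10: [J44], icd9: ["491", "492", "496"], icd8: ["491", "492"]}
  - {name: eczema,                      group: skin,                icd10: [L20, L21, L22, L23, L24, L25], icd9: ["691", "692"], icd8: ["691", "692"]}
  - {name: psoriasis,                   group: skin,                icd10: [L40], icd9: ["6961"], icd8: ["696"]}
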