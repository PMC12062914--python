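# All-ages cancer site grouping, CI5 / Indian-registry report convention.
# Exactly 53 entries partitioning ICD-10 C00-C97 at 3-character category level.
# codes: semicolon-separated single categories or inclusive ranges.
# residual=1 marks the entry that additionally absorbs any C00-C97 category
# not claimed by another entry.
label,codes,residual
Lip,C00,0
Tongue,C01-C02,0
Mouth,C03-C06,0
Salivary glands,C07-C08,0
Tonsil,C09,0
Other oropharynx,C10,0
Nasopharynx,C11,0
Hypopharynx,C12-C13,0
Pharynx unspecified,C14,0
Oesophagus,C15,0
Stomach,C16,0
Small intestine,C17,0
Colon,C18,0
Rectum,C19-C20,0
Anus,C21,0
Liver,C22,0
Gallbladder etc.,C23-C24,0
Pancreas,C25,0
Other digestive organs,C26,0
"Nose, sinuses etc.",C30-C31,0
Larynx,C32,0
"Trachea, bronchus & lung",C33-C34,0
Other thoracic organs,C37-C38,0
Bone,C40-C41,0
Melanoma of skin,C43,0
Other skin,C44,0
Mesothelioma,C45,0
Kaposi sarcoma,C46,0
Connective & soft tissue,C47;C49,0
Breast,C50,0
Vulva,C51,0
Vagina,C52,0
Cervix uteri,C53,0
Corpus uteri,C54,0
Uterus unspecified,C55,0
Ovary,C56,0
Other female genital,C57-C58,0
Penis,C60,0
Prostate,C61,0
Testis,C62,0
Other male genital,C63,0
"Kidney, renal pelvis & ureter",C64-C66,0
Bladder,C67,0
Other urinary organs,C68,0
Eye,C69,0
"Brain, central nervous system",C70-C72,0
Thyroid,C73,0
Adrenal & other endocrine,C74-C75,0
Hodgkin lymphoma,C81,0
Non-Hodgkin lymphoma,C82-C86;C96,0
Multiple myeloma,C88;C90,0
Leukaemia,C91-C95,0
Other and unspecified,C39;C48;C76-C80;C97,1
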