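icd9,icd9_string,phecode,phewas_string,category,excl_phecodes
401.0,Malignant essential hypertension,401.1,Essential hypertension,circulatory system,401-405.99
402.90,Unspecified hypertensive heart disease,401.21,Hypertensive heart disease,circulatory system,401-405.99
403.11,Hypertensive chronic kidney disease benign with CKD I-IV,401.22,Hypertensive chronic kidney disease,circulatory system,401-405.99
405.99,Other unspecified secondary hypertension,401.2,Hypertensive heart and/or renal disease,circulatory system,401-405.99
425.4,Other primary cardiomyopathies,425,Cardiomyopathy,circulatory system,425-429.99
427.31,Atrial fibrillation,427.21,Atrial fibrillation,circulatory system,425-429.99
428.0,Congestive heart failure unspecified,428,Congestive heart failure,circulatory system,425-429.99
433.10,Occlusion and stenosis of carotid artery,433,Cerebrovascular disease,circulatory system,430-438.99
434.91,Cerebral artery occlusion with cerebral infarction,433.21,Cerebral artery occlusion,circulatory system,430-438.99
415.19,Other pulmonary embolism and infarction,415.11,Pulmonary embolism and infarction acute,circulatory system,415-417.99
440.9,Generalized and unspecified atherosclerosis,440,Atherosclerosis,circulatory system,440-459.99
443.9,Peripheral vascular disease unspecified,443.9,Peripheral vascular disease,circulatory system,440-459.99
453.40,Acute venous embolism and thrombosis of deep vessels,452,Other venous embolism and thrombosis,circulatory system,440-459.99
584.9,Acute kidney failure unspecified,585.1,Acute renal failure,genitourinary,580-589.99
585.9,Chronic kidney disease unspecified,585.3,Renal failure chronic,genitourinary,580-589.99
V45.11,Renal dialysis status,585.31,Renal dialysis,genitourinary,580-589.99
585.6,End stage renal disease,585.32,End stage renal disease,genitourinary,580-589.99
580.0,Acute glomerulonephritis with proliferative glomerulonephritis,580.1,Glomerulonephritis,genitourinary,580-589.99
V42.0,Kidney replaced by transplant,587,Kidney replaced by transplant,genitourinary,580-589.99
590.80,Pyelonephritis unspecified,590,Pyelonephritis,genitourinary,580-599.99
486,Pneumonia organism unspecified,480,Pneumonia,respiratory,480-488.99
482.9,Bacterial pneumonia unspecified,480.1,Bacterial pneumonia,respiratory,480-488.99
511.9,Unspecified pleural effusion,507,Pleurisy; pleural effusion,respiratory,507-519.99
112.9,Candidiasis of unspecified site,112,Candidiasis,infectious diseases,110-118.99
790.7,Bacteremia,038.3,Bacteremia,infectious diseases,038-041.99
038.9,Unspecified septicemia,994.2,Sepsis and SIRS,infectious diseases,994-994.99
682.9,Cellulitis and abscess of unspecified site,681,Superficial cellulitis and abscess,dermatologic,680-686.99
682.2,Cellulitis and abscess of trunk,681.7,Cellulitis and abscess of trunk,dermatologic,680-686.99
710.0,Systemic lupus erythematosus,695.42,Systemic lupus erythematosus,dermatologic,690-698.99
714.0,Rheumatoid arthritis,714.1,Rheumatoid arthritis,musculoskeletal,714-714.99
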