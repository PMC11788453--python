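pt_name,pt_code,category
Acute adrenocortical insufficiency,,Adrenal insufficiency
Addison's disease,10001130,Adrenal insufficiency
Adrenal insufficiency,,Adrenal insufficiency
Adrenocorticotropic hormone deficiency,,Adrenal insufficiency
Glucocorticoid deficiency,,Adrenal insufficiency
Immune-mediated adrenal insufficiency,,Adrenal insufficiency
Primary adrenal insufficiency,,Adrenal insufficiency
Secondary adrenocortical insufficiency,,Adrenal insufficiency
Steroid withdrawal syndrome,10042028,Adrenal insufficiency
Autoimmune colitis,10075761,Colitis
Colitis,10009887,Colitis
Colitis erosive,10058358,Colitis
Colitis ischaemic,10009895,Colitis
Colitis microscopic,10056979,Colitis
Colitis ulcerative,10009900,Colitis
Diarrhea,10012735,Colitis
Diarrhoea haemorrhagic,10012741,Colitis
Enteritis,10014866,Colitis
Enterocolitis,10014893,Colitis
Enterocolitis hemorrhagic,10014896,Colitis
Inflammatory bowel disease,10021972,Colitis
Neutropenic colitis,10062959,Colitis
Encephalitis,10014581,Encephalitis/Meningitis
Encephalitis autoimmune,10072378,Encephalitis/Meningitis
Immune-mediated encephalitis,10083074,Encephalitis/Meningitis
Meningitis,10027199,Encephalitis/Meningitis
Autoimmune uveitis,10075690,Eye disease
Immune-mediated uveitis,10083069,Eye disease
Uveitis,10046851,Eye disease
Gastritis,10017853,Gastritis
Immune-mediated gastritis,10084296,Gastritis
Agranulocytosis,10001507,Hematological disorder
Aplasia pure red cell,10002965,Hematological disorder
Autoimmune hemolytic anemia,10073785,Hematological disorder
Febrile neutropenia,10016288,Hematological disorder
Immune thrombocytopenia,10083842,Hematological disorder
Neutropenia,10029354,Hematological disorder
Neutrophil count decreased,10029366,Hematological disorder
Platelet count decreased,10035528,Hematological disorder
Thrombocytopenia,10043554,Hematological disorder
Thrombocytopenic purpura,10043561,Hematological disorder
Haemophagocytic lymphohistiocytosis,10071583,Hemophagocytic syndrome
Acute hepatic failure,10000804,Hepatitis
Alanine aminotransferase increased,10001551,Hepatitis
Aspartate aminotransferase increased,10003481,Hepatitis
Autoimmune hepatitis,10003827,Hepatitis
Drug-induced liver injury,10072268,Hepatitis
Hepatic enzyme increased,10060795,Hepatitis
Hepatic failure,10019663,Hepatitis
Hepatic function abnormal,10019670,Hepatitis
Hepatitis,10019717,Hepatitis
Hepatitis acute,10019727,Hepatitis
Hepatotoxicity,10019851,Hepatitis
Immune-mediated hepatic disorder,10083521,Hepatitis
Immune-mediated hepatitis,10078962,Hepatitis
Liver disorder,10024670,Hepatitis
Liver function test abnormal,10024690,Hepatitis
Liver injury,10067125,Hepatitis
Transaminases increased,10054889,Hepatitis
Hyperthyroidism,10020850,Hyperthyroidism
Immune-mediated hyperthyroidism,10083517,Hyperthyroidism
Primary hyperthyroidism,10075899,Hyperthyroidism
Thyrotoxic crisis,10043786,Hyperthyroidism
Toxic nodular goitre,10044242,Hyperthyroidism
Hypophysitis,,Hypopituitarism
Hypopituitarism,,Hypopituitarism
Immune-mediated hypophysitis,,Hypopituitarism
Autoimmune myositis,10082418,Myositis/Rhabdomyolysis
Immune-mediated myositis,10083073,Myositis/Rhabdomyolysis
Myositis,10028653,Myositis/Rhabdomyolysis
Polymyositis,10036102,Myositis/Rhabdomyolysis
Rhabdomyolysis,10039020,Myositis/Rhabdomyolysis
Autoimmune hypothyroidism,10076644,Hypothyroidism
Central hypothyroidism,,Hypothyroidism
Hypothyroidism,10021114,Hypothyroidism
Immune-mediated hypothyroidism,10083075,Hypothyroidism
Primary hypothyroidism,10036697,Hypothyroidism
Myasthenia gravis,10028417,Myasthenia gravis
Autoimmune myocarditis,10064539,Myocarditis
Eosinophilic myocarditis,10014961,Myocarditis
Immune-mediated myocarditis,10082606,Myocarditis
Myocarditis,10028606,Myocarditis
Acute kidney injury,10069339,Nephritis/renal dysfunction
Autoimmune nephritis,10077087,Nephritis/renal dysfunction
Glomerulonephritis,10018364,Nephritis/renal dysfunction
Glomerulonephritis acute,10018366,Nephritis/renal dysfunction
Glomerulonephritis rapidly progressive,10018378,Nephritis/renal dysfunction
Immune-mediated nephritis,10083070,Nephritis/renal dysfunction
Immune-mediated renal disorder,10083522,Nephritis/renal dysfunction
Nephritis,10029117,Nephritis/renal dysfunction
Renal disorder,10038428,Nephritis/renal dysfunction
Renal failure,10038435,Nephritis/renal dysfunction
Renal impairment,10062237,Nephritis/renal dysfunction
Tubulointerstitial nephritis,10048302,Nephritis/renal dysfunction
Tubulointerstitial nephritis and uveitis syndrome,10069034,Nephritis/renal dysfunction
Guillain-Barre syndrome,10018767,Neurological disorder
Autoimmune pancreatitis,10069002,Pancreatitis
Immune-mediated pancreatitis,10083072,Pancreatitis
Pancreatitis,10033645,Pancreatitis
Pancreatitis acute,10033647,Pancreatitis
Interstitial lung disease,10022611,Pneumonitis
Pneumonia,10035664,Pneumonitis
Pneumonitis,10035742,Pneumonitis
Erythema,10015150,Rash
Erythema multiforme,10015218,Rash
Oculomucocutaneous syndrome,10030081,Rash
Pemphigoid,10034277,Rash
Pruritus,10037087,Rash
Pruritus allergic,10063438,Rash
Rash,10037844,Rash
Rash erythematous,10037855,Rash
Rash macular,10037867,Rash
Rash maculo-papular,10037868,Rash
Rash papular,10037876,Rash
Rash pruritic,10037884,Rash
Toxic epidermal necrolysis,10044223,Rash
Autoimmune thyroid disorder,10079165,Thyroid dysfunction
Autoimmune thyroiditis,10049046,Thyroid dysfunction
Immune-mediated thyroiditis,10083071,Thyroid dysfunction
Thyroid disorder,10043709,Thyroid dysfunction
Thyroiditis,10043778,Thyroid dysfunction
Diabetic ketoacidosis,10012671,Type 1 diabetes mellitus
Fulminant type 1 diabetes mellitus,10072628,Type 1 diabetes mellitus
Latent autoimmune diabetes in adults,10066389,Type 1 diabetes mellitus
Type 1 diabetes mellitus,10067584,Type 1 diabetes mellitus
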