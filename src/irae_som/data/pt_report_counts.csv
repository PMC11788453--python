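pt_name,case,total,ratio
Acute adrenocortical insufficiency,142,241,58.9
Addison's disease,32,42,76.2
Adrenal insufficiency,2858,3621,78.9
Adrenocorticotropic hormone deficiency,629,662,95.0
Glucocorticoid deficiency,2,15,13.3
Immune-mediated adrenal insufficiency,472,472,100.0
Primary adrenal insufficiency,55,70,78.6
Secondary adrenocortical insufficiency,523,611,85.6
Steroid withdrawal syndrome,3,102,2.9
Autoimmune colitis,62,63,98.4
Colitis,1078,1519,71.0
Colitis erosive,1,9,11.1
Colitis ischaemic,22,1117,2.0
Colitis microscopic,30,719,4.2
Colitis ulcerative,120,992,12.1
Diarrhea,1250,11910,10.5
Diarrhoea haemorrhagic,4,61,6.6
Enteritis,74,267,27.7
Enterocolitis,562,2147,26.2
Enterocolitis hemorrhagic,18,971,1.9
Inflammatory bowel disease,4,54,7.4
Neutropenic colitis,1,71,1.4
Encephalitis,285,754,37.8
Encephalitis autoimmune,134,237,56.5
Immune-mediated encephalitis,107,112,95.5
Meningitis,151,648,23.3
Autoimmune uveitis,1,1,100.0
Immune-mediated uveitis,66,66,100.0
Uveitis,250,846,29.6
Gastritis,39,221,17.6
Immune-mediated gastritis,54,54,100.0
Agranulocytosis,65,4359,1.5
Aplasia pure red cell,33,608,5.4
Autoimmune hemolytic anemia,80,380,21.1
Febrile neutropenia,943,11781,8.0
Immune thrombocytopenia,233,1353,17.2
Neutropenia,469,13328,3.5
Neutrophil count decreased,726,17276,4.2
Platelet count decreased,616,21368,2.9
Thrombocytopenia,255,7545,3.4
Thrombocytopenic purpura,8,545,1.5
Haemophagocytic lymphohistiocytosis,245,1389,17.6
Acute hepatic failure,29,629,4.6
Alanine aminotransferase increased,260,3996,6.5
Aspartate aminotransferase increased,272,3715,7.3
Autoimmune hepatitis,104,549,18.9
Drug-induced liver injury,471,5968,7.9
Hepatic enzyme increased,96,1039,9.2
Hepatic failure,169,1655,10.2
Hepatic function abnormal,1633,20649,7.9
Hepatitis,245,763,32.1
Hepatitis acute,17,1113,1.5
Hepatotoxicity,43,235,18.3
Immune-mediated hepatic disorder,775,783,99.0
Immune-mediated hepatitis,272,275,98.9
Liver disorder,862,12066,7.1
Liver function test abnormal,4,627,0.6
Liver injury,25,240,10.4
Transaminases increased,10,193,5.2
Hyperthyroidism,1141,2069,55.1
Immune-mediated hyperthyroidism,197,197,100.0
Primary hyperthyroidism,1,2,50.0
Thyrotoxic crisis,25,114,21.9
Toxic nodular goitre,1,3,33.3
Hypophysitis,350,362,96.7
Hypopituitarism,616,673,91.5
Immune-mediated hypophysitis,92,93,98.9
Autoimmune myositis,14,19,73.7
Immune-mediated myositis,199,372,53.5
Myositis,401,593,67.6
Polymyositis,60,179,33.5
Rhabdomyolysis,209,7668,2.7
Autoimmune hypothyroidism,33,33,100.0
Central hypothyroidism,47,345,13.6
Hypothyroidism,2981,4587,65.0
Immune-mediated hypothyroidism,831,832,99.9
Primary hypothyroidism,19,28,67.9
Myasthenia gravis,515,774,66.5
Autoimmune myocarditis,6,6,100.0
Eosinophilic myocarditis,1,57,1.8
Immune-mediated myocarditis,208,215,96.7
Myocarditis,498,1846,27.0
Acute kidney injury,407,9890,4.1
Autoimmune nephritis,11,24,45.8
Glomerulonephritis,10,113,8.8
Glomerulonephritis acute,5,35,14.3
Glomerulonephritis rapidly progressive,24,272,8.8
Immune-mediated nephritis,45,46,97.8
Immune-mediated renal disorder,112,112,100.0
Nephritis,60,230,26.1
Renal disorder,192,3113,6.2
Renal failure,136,3085,4.4
Renal impairment,984,15205,6.5
Tubulointerstitial nephritis,481,2891,16.6
Tubulointerstitial nephritis and uveitis syndrome,1,100,1.0
Guillain-Barre syndrome,114,884,12.9
Autoimmune pancreatitis,78,120,65.0
Immune-mediated pancreatitis,116,116,100.0
Pancreatitis,254,1645,15.4
Pancreatitis acute,100,2561,3.9
Interstitial lung disease,7586,38932,19.5
Pneumonia,1201,17751,6.8
Pneumonitis,1976,3357,58.9
Erythema,130,6011,2.2
Erythema multiforme,583,7006,8.3
Oculomucocutaneous syndrome,9,1124,0.8
Pemphigoid,364,2701,13.5
Pruritus,156,3827,4.1
Pruritus allergic,1,4,25.0
Rash,935,12818,7.3
Rash erythematous,32,437,7.3
Rash macular,1,54,1.9
Rash maculo-papular,74,318,23.3
Rash papular,12,183,6.6
Rash pruritic,33,240,13.8
Toxic epidermal necrolysis,133,3672,3.6
Autoimmune thyroid disorder,4,5,80.0
Autoimmune thyroiditis,66,171,38.6
Immune-mediated thyroiditis,94,94,100.0
Thyroid disorder,115,193,59.6
Thyroiditis,313,475,65.9
Diabetic ketoacidosis,256,1359,18.8
Fulminant type 1 diabetes mellitus,617,791,78.0
Latent autoimmune diabetes in adults,2,16,12.5
Type 1 diabetes mellitus,880,1320,66.7
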