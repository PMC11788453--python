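category,Atezolizumab,Avelumab,Cemiplimab,Durvalumab,Ipilimumab,Nivolumab,Pembrolizumab,Tremelimumab
Adrenal insufficiency,5.2,0.9,0.0,0.8,36.4,51.6,22.2,0.2
Colitis,1.5,0.2,0.0,0.5,6.1,9.5,4.4,0.3
Encephalitis/Meningitis,11.3,0.1,0.0,1.3,9.3,14.8,11.5,0.1
Eye disease,0.8,0.0,0.0,0.2,14.5,23.7,10.4,0.1
Gastritis,0.7,0.0,0.0,0.7,13.8,18.5,13.8,0.4
Hematological disorder,1.4,0.0,0.0,0.6,0.8,1.3,1.1,0.0
Hemophagocytic syndrome,0.0,0.0,0.0,0.6,5.2,7.3,5.3,0.4
Hepatitis,1.0,0.2,0.0,0.3,4.2,5.6,2.6,0.1
Hyperthyroidism,0.8,0.8,0.0,0.5,17.4,29.1,26.2,0.0
Hypopituitarism,4.0,0.6,0.0,2.4,57.6,67.4,16.6,0.5
Myositis/Rhabdomyolysis,1.1,0.2,0.0,0.4,3.1,5.3,3.1,0.1
Hypothyroidism,1.1,1.2,0.1,0.5,18.2,29.4,34.9,0.1
Myasthenia gravis,4.8,1.0,0.1,2.7,19.4,37.9,20.2,0.1
Myocarditis,2.8,0.4,0.0,1.4,10.5,17.6,11.4,0.2
Nephritis/renal dysfunction,0.9,0.1,0.0,0.1,2.0,3.3,2.7,0.0
Neurological disorder,3.1,0.3,0.0,0.5,3.6,4.5,4.3,0.0
Pancreatitis,1.2,0.1,0.0,0.4,3.9,6.0,4.7,0.2
Pneumonitis,1.6,0.1,0.0,3.0,3.4,7.9,5.6,0.0
Rash,0.6,0.0,0.0,0.2,2.8,3.8,1.8,0.1
Thyroid dysfunction,2.9,1.1,0.0,1.6,28.7,35.9,21.1,0.0
Type 1 diabetes mellitus,4.3,0.5,0.0,0.8,13.1,29.9,15.0,0.1
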