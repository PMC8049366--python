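site,mean_usv_per_mbq,sd_usv_per_mbq,min_usv_per_mbq,max_usv_per_mbq
Adrenals,12.2,1.4,10.7,14.2
Brain,2.4,0.5,1.9,3.3
"Colon, left",8.3,0.8,7.2,9.3
"Colon, right",8.4,0.8,7.3,9.4
Esophagus,6.9,0.8,5.9,8.0
Eyes,5.9,0.7,4.8,6.9
Gallbladder wall,8.7,0.9,7.7,9.8
Heart wall,11.5,1.3,10.0,13.3
Kidneys,54.4,14.9,36.0,72.5
Liver,12.7,1.6,9.4,13.7
Lungs,6.8,1.2,5.8,8.5
Osteogenic cells,9.9,1.2,8.4,11.7
Pancreas,8.5,1.4,6.8,10.0
Prostate,17.4,0.5,16.7,17.9
Rectum,14.1,0.1,14.0,14.3
Red marrow,8.6,0.8,7.7,10.0
Salivary glands,4.5,0.3,4.0,5.0
Small intestine,9.5,0.6,8.5,10.3
Spleen,12.8,1.2,11.5,14.6
Stomach wall,7.5,0.8,6.4,8.7
Testes,8.8,0.5,8.0,9.5
Thymus,6.8,0.8,5.7,8.0
Thyroid,6.7,0.8,5.5,7.8
Urinary bladder wall,383.2,48.5,316.0,449.0
Whole body,10.1,0.5,9.4,10.7
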