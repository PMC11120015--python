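dataset	dt_accuracy	npulud_accuracy
adult	86.10	86.90
australian-credit-approval	86.09	87.97
bank-marketing	91.20	91.43
blogger	74.00	74.00
blood-transfusion-service	77.81	80.88
breast-cancer-wisconsin	94.56	95.14
climate-simulation-craches	92.59	93.89
fertility-diagnosis	85.00	94.00
german-credit	70.50	75.20
habermans-survival	71.90	84.64
heart-statlog	76.67	84.44
hepatitis	83.87	85.81
ionosphere	91.45	93.45
kr-vs-kp	99.44	98.12
molecular-promotor-gene	81.13	77.36
parkinsons	80.51	85.64
pima-indians-diabetes	73.83	79.04
planning-relax	71.43	81.32
rice_cammeo_osmancik	92.49	93.75
seismic-bumps	93.34	97.29
sonar	71.15	74.04
spambase	92.98	92.68
thoracic-surgery	84.47	92.13
wdbc	93.15	94.55
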