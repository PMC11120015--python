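dataset	mask_05	mask_10	mask_15	mask_20
adult	86.90	86.71	86.51	86.55
australian-credit-approval	87.97	85.94	85.94	86.52
bank-marketing	91.43	91.43	91.43	91.43
blogger	74.00	74.00	74.00	74.00
blood-transfusion-service	80.88	78.61	76.34	77.81
breast-cancer-wisconsin	95.14	95.14	95.14	95.14
climate-simulation-craches	93.89	92.59	93.33	93.33
fertility-diagnosis	94.00	92.00	92.00	92.00
german-credit	75.20	74.90	74.40	75.10
habermans-survival	84.64	82.35	81.37	82.35
heart-statlog	84.44	85.56	85.93	85.93
hepatitis	85.81	84.52	83.87	80.65
ionosphere	93.45	91.17	89.46	90.31
kr-vs-kp	98.12	97.65	98.37	98.44
molecular-promotor-gene	77.36	74.53	77.36	77.36
parkinsons	85.64	85.64	85.64	85.64
pima-indians-diabetes	79.04	76.17	77.86	76.56
planning-relax	81.32	81.32	79.67	78.02
rice_cammeo_osmancik	93.75	93.60	92.99	92.99
seismic-bumps	97.29	96.36	96.05	95.24
sonar	74.04	74.04	74.04	74.04
spambase	92.68	92.68	92.68	92.68
thoracic-surgery	92.13	91.28	90.00	89.36
wdbc	94.55	93.85	93.85	94.20
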