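dataset	adasingle_svm	adaensemble_svm	adasingle_knn	adaensemble_knn	npulud
breast-cancer-wisconsin	95.10	95.20	96.00	96.00	95.14
ionosphere	88.20	89.30	75.00	76.90	93.45
pima-indians-diabetes	65.50	66.00	61.10	62.40	79.04
sonar	67.00	68.50	62.00	63.20	74.04
wdbc	93.20	93.20	88.10	88.10	94.55
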