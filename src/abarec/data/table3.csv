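Metric,Similar participant A,Similar participant B,Similar participant C
Precision,0.64,0.71,0.92
Recall,1.0,1.0,1.0
Accuracy,0.72,0.77,0.94
F1 score,0.78,0.83,0.96
AUC score,0.65,0.78,0.74
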