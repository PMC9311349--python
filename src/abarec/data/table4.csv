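Metric,Similar participant A,Similar participant B,Similar participant C
Precision,0.85,0.87,0.90
Recall,0.96,0.96,0.96
Accuracy,0.83,0.84,0.87
F1 score,0.90,0.91,0.93
AUC score,0.78,0.80,0.80
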