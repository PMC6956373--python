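method,avg_accuracy
pca_knn,65.62
all_features_knn,69.26
proposed,73.38
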