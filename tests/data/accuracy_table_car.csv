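participant,mu_erd_lda_acc,mu_erd_lda_auc,mu_erd_svm_acc,mu_erd_svm_auc,mu_erd_knn_acc,mu_erd_knn_auc,beta_erd_lda_acc,beta_erd_lda_auc,beta_erd_svm_acc,beta_erd_svm_auc,beta_erd_knn_acc,beta_erd_knn_auc,beta_ers_lda_acc,beta_ers_lda_auc,beta_ers_svm_acc,beta_ers_svm_auc,beta_ers_knn_acc,beta_ers_knn_auc
P1,69.2,80.0,67.0,79.0,65.3,74.0,75.4,85.0,72.0,85.0,79.1,85.0,83.4,85.0,82.0,82.0,81.3,86.0
P2,74.0,82.0,68.3,79.0,60.2,69.0,67.2,80.0,61.2,69.0,70.2,81.0,73.5,82.0,71.1,81.0,74.2,82.0
P3,64.2,75.0,57.9,66.0,59.4,69.0,65.3,80.0,64.4,72.0,69.1,81.0,64.2,79.0,63.1,69.0,66.2,78.0
P4,69.1,80.0,62.2,72.0,61.0,69.0,63.2,69.0,62.2,72.0,67.0,79.0,67.4,80.0,65.4,72.0,76.4,84.0
P5,65.2,74.0,62.6,73.0,57.5,65.0,64.1,80.0,61.1,71.0,65.3,81.0,62.5,72.0,63.5,71.0,71.2,81.0
P6,66.3,71.0,61.0,69.0,68.1,78.0,64.3,79.0,60.5,69.0,69.1,84.0,67.7,80.0,67.1,79.0,69.1,80.0
P7,64.0,74.0,57.8,66.0,66.1,75.0,63.0,79.0,58.0,69.0,66.2,77.0,68.0,80.0,65.3,72.0,78.3,83.0
P8,68.0,79.0,61.0,69.0,57.6,65.0,61.1,69.0,57.5,66.0,69.0,83.0,61.0,69.0,58.0,68.0,77.0,84.0
P9,67.1,79.0,62.3,72.0,62.2,69.0,60.1,79.0,59.0,69.0,68.1,79.0,67.0,80.0,69.2,80.0,80.4,85.0
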