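participant,mu_erd_lda_acc,mu_erd_lda_auc,mu_erd_svm_acc,mu_erd_svm_auc,mu_erd_knn_acc,mu_erd_knn_auc,beta_erd_lda_acc,beta_erd_lda_auc,beta_erd_svm_acc,beta_erd_svm_auc,beta_erd_knn_acc,beta_erd_knn_auc,beta_ers_lda_acc,beta_ers_lda_auc,beta_ers_svm_acc,beta_ers_svm_auc,beta_ers_knn_acc,beta_ers_knn_auc
P1,72.3,81.0,68.2,79.0,70.3,81.0,61.1,69.0,61.0,69.0,64.2,79.0,72.2,82.0,70.0,80.0,80.4,85.0
P2,70.1,79.0,67.3,79.0,64.5,76.0,67.3,79.0,60.2,71.0,69.0,80.0,69.4,79.0,66.0,79.0,73.0,81.0
P3,65.1,78.0,57.6,66.0,59.0,71.0,62.2,69.0,60.1,69.0,70.0,81.0,63.4,69.0,61.0,69.0,72.1,82.0
P4,73.0,82.0,62.2,71.0,65.1,79.0,65.3,75.0,61.1,79.0,60.3,74.0,71.1,81.0,70.1,80.0,71.1,81.0
P5,66.2,78.0,60.1,70.0,59.2,71.0,63.0,69.0,59.3,68.0,68.1,80.0,64.4,76.0,66.0,79.0,69.2,80.0
P6,63.1,69.0,61.1,69.0,68.0,77.0,57.5,67.0,57.7,67.0,71.1,81.0,62.4,72.0,60.1,71.0,76.0,84.0
P7,70.2,79.0,59.0,69.0,66.3,80.0,58.4,67.0,60.0,69.0,64.2,78.0,61.3,69.0,61.0,69.0,70.1,81.0
P8,69.4,79.0,58.0,69.0,61.1,71.0,67.2,79.0,60.3,80.0,74.0,83.0,67.4,78.0,69.0,80.0,74.0,83.0
P9,71.0,80.0,62.3,71.0,64.1,77.0,69.1,80.0,60.1,79.0,69.0,80.0,74.1,83.0,68.0,79.0,69.2,81.0
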