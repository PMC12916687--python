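dataset,method,acc_mean,acc_sd,f1_mean,f1_sd,n_folds
SEED,KNN,49.26,14.89,48.89,24.91,15
SEED,SVM,51.68,17.86,50.31,28.76,15
SEED,DGCNN,72.48,14.89,61.95,13.14,15
SEED,RGNN,79.07,14.82,80.26,13.34,15
SEED,DMATN,77.29,15.46,77.16,16.32,15
SEED,TSception,66.22,18.11,62.18,28.34,15
SEED,TCN,76.54,14.08,73.77,21.96,15
SEED,PGCN,75.87,18.36,74.08,19.01,15
SEED,LSTM,73.39,15.88,67.05,27.47,15
SEED,BiDANN,79.39,16.45,77.65,15.92,15
SEED,EmT,80.20,11.50,82.10,9.30,15
SEED,MSGM,83.43,11.42,85.03,9.09,15
THU-EP,KNN,23.45,4.82,30.93,4.85,10
THU-EP,SVM,24.72,5.91,33.28,8.70,10
THU-EP,DGCNN,56.71,3.37,64.74,5.22,10
THU-EP,RGNN,57.23,3.07,69.51,5.49,10
THU-EP,DMATN,60.34,5.41,69.22,6.38,10
THU-EP,TSception,59.18,5.93,70.72,6.01,10
THU-EP,TCN,57.79,3.13,67.71,3.12,10
THU-EP,PGCN,56.92,4.31,65.14,9.06,10
THU-EP,LSTM,55.83,3.52,62.69,6.22,10
THU-EP,BiDANN,61.44,5.51,69.71,6.87,10
THU-EP,EmT,59.50,4.70,72.40,4.40,10
THU-EP,MSGM,62.39,3.13,73.28,4.39,10
FACED,KNN,22.71,5.34,31.89,4.37,10
FACED,SVM,25.58,7.43,32.32,9.23,10
FACED,DGCNN,56.26,4.55,69.78,4.36,10
FACED,RGNN,58.71,5.05,72.27,72.16,10
FACED,DMATN,61.41,4.91,68.31,6.87,10
FACED,TSception,61.92,8.81,70.26,23.76,10
FACED,TCN,55.26,3.56,67.31,3.53,10
FACED,PGCN,55.77,7.81,66.54,8.52,10
FACED,LSTM,56.84,6.31,70.07,6.44,10
FACED,BiDANN,63.36,7.01,73.82,6.36,10
FACED,EmT,60.80,6.50,74.00,5.80,10
FACED,MSGM,63.17,3.62,76.01,3.74,10
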