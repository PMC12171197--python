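features,regressor,n_wavelengths,r2_cal,rmse_cal,r2_pred,rmsep
NISDI,Linear,3,0.9623,0.0362,0.9636,0.0356
CARS,ANN,12,0.9907,0.0180,0.9849,0.0228
CARS,RF,12,0.9979,0.0085,0.9861,0.0219
CARS,PLSR,12,0.9644,0.0352,0.9614,0.0365
CARS,MLR,12,0.9831,0.0244,0.9798,0.0259
SPA,ANN,18,0.9878,0.0204,0.9857,0.0223
SPA,RF,18,0.9979,0.0086,0.9853,0.0225
SPA,PLSR,18,0.9699,0.0324,0.9650,0.0349
SPA,MLR,18,0.9830,0.0245,0.9810,0.0257
UVE,ANN,23,0.9863,0.0217,0.9828,0.0244
UVE,RF,23,0.9974,0.0095,0.9842,0.0234
UVE,PLSR,23,0.9499,0.0418,0.9489,0.0420
UVE,MLR,23,0.9842,0.0237,0.9820,0.0244
Full,ANN,224,0.9757,0.0290,0.9723,0.0310
Full,RF,224,0.9957,0.0123,0.9705,0.0319
Full,PLSR,224,0.9665,0.0341,0.9669,0.0338
Full,MLR,224,0.9902,0.0207,0.9834,0.0241
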