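{
  "weights": [
    0.03180499421770633,
    0.3651195273138413,
    -0.49818978337469055,
    0.005182222853793966,
    -0.012435027624664863,
    0.540655206249544,
    -0.11915320932953416,
    0.08117413815692459,
    0.5027031888163582,
    -0.10231636443400324,
    -0.0055202353357263634
  ],
  "bias": 0.01938666892210177,
  "center": [
    7000.046853511435,
    7000.050671112151,
    -0.006445755899017058,
    2.636040726523644,
    1.0006771304514568,
    -0.0006383913325397544,
    7000.060424261803,
    -0.00011290980085744351,
    0.0024267525546569084,
    7000.041074325695,
    0.6075260148179876
  ],
  "scale": [
    3.328801599640643,
    5.22941582800917,
    1.6934208224240457,
    0.05712871251809878,
    0.00016269490224848207,
    0.2562905494810155,
    3.351829097483512,
    0.0022344195582207275,
    0.26056766311916324,
    3.224052780222493,
    0.4988743654042987
  ],
  "feature_names": [
    "mean_third1",
    "mean_third3",
    "diff_mean_t1_t2",
    "entropy",
    "pct_ratio_95_5",
    "lin_slope_t2t3",
    "lin_intercept_t2t3",
    "quad_a2",
    "quad_a1",
    "quad_a0",
    "band_power_ratio"
  ],
  "meta": {
    "C": 1.0,
    "n_train": 800,
    "n_sv": 6,
    "training_seed": 20260925,
    "n_per_class": 400
  }
}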