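{
  "version": 1,
  "description": "Default per-etiology synthetic cohort specifications: three Gaussian components over (age years, major Cobb deg, kyphosis deg, levels in major curve, levels in kyphosis), ordered by ascending mean Cobb. Neuromuscular and syndromic each contain exactly one kyphosis-dominant component (mean kyphosis > mean Cobb, expected deformity index < 1); congenital and idiopathic components are all Cobb-dominant, with the severe component carrying marked kyphosis yet a deformity index still above one, and (clinically typical of congenital EOS) a short sharp severe curve spanning fewer levels than the mid cluster's long sweeping curve. Values are plausible clinical magnitudes within the generator's valid ranges, not measurements from any registry.",
  "n_subjects": 250,
  "outlier_fraction": 0.05,
  "etiologies": {
    "congenital": {
      "clusters": [
        {"weight": 0.35, "mean": [2.0, 35.0, 22.0, 5.0, 5.0], "sd": [0.45, 4.5, 4.0, 0.6, 0.6]},
        {"weight": 0.35, "mean": [4.5, 60.0, 30.0, 10.0, 9.0], "sd": [0.5, 5.0, 4.5, 0.7, 0.7]},
        {"weight": 0.30, "mean": [7.0, 92.0, 62.0, 6.0, 5.0], "sd": [0.55, 6.0, 6.0, 0.7, 0.7]}
      ]
    },
    "idiopathic": {
      "clusters": [
        {"weight": 0.35, "mean": [1.8, 32.0, 20.0, 5.0, 4.0], "sd": [0.45, 4.5, 4.0, 0.6, 0.6]},
        {"weight": 0.35, "mean": [4.5, 58.0, 28.0, 10.0, 9.0], "sd": [0.5, 5.0, 4.5, 0.7, 0.7]},
        {"weight": 0.30, "mean": [7.2, 90.0, 60.0, 7.0, 6.0], "sd": [0.55, 6.0, 6.0, 0.7, 0.7]}
      ]
    },
    "neuromuscular": {
      "clusters": [
        {"weight": 0.35, "mean": [2.5, 36.0, 26.0, 5.0, 4.0], "sd": [0.45, 4.5, 4.5, 0.6, 0.6]},
        {"weight": 0.35, "mean": [5.0, 62.0, 85.0, 8.0, 10.0], "sd": [0.5, 5.0, 6.0, 0.7, 0.7]},
        {"weight": 0.30, "mean": [7.5, 92.0, 50.0, 12.0, 7.0], "sd": [0.55, 6.0, 5.0, 0.7, 0.7]}
      ]
    },
    "syndromic": {
      "clusters": [
        {"weight": 0.35, "mean": [2.2, 34.0, 24.0, 5.0, 4.0], "sd": [0.45, 4.5, 4.5, 0.6, 0.6]},
        {"weight": 0.35, "mean": [4.8, 60.0, 82.0, 8.0, 10.0], "sd": [0.5, 5.0, 6.0, 0.7, 0.7]},
        {"weight": 0.30, "mean": [7.6, 90.0, 52.0, 11.0, 7.0], "sd": [0.55, 6.0, 5.0, 0.7, 0.7]}
      ]
    }
  }
}
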