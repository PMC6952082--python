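schema: mothnav-policy-v1
features: [osd, osd0, osd05, of, history, energy]
weights:
  osd: 0.0000
  osd0: -0.0817
  osd05: 0.1234
  of: 0.7644
  history: -1.1349
  energy: 0.7546
meta:
  name: moth
  description: >-
    Reference policy regressed from 62,651 recorded hawkmoth state-action
    pairs by l1-penalized multinomial logistic regression (penalty selected
    by 80/20 cross-validation at lambda = 0.0053).  The weights refer to
    dataset-standardized features; feature_scale carries the per-feature
    standard deviations used to apply them to raw features.
  reference_average_reward: 0.1006
  normalization: dataset-standardized features
  feature_scale: [0.019193, 0.217469, 0.015164, 28.068200, 0.472267, 0.293869]
  feature_scale_provenance: >-
    SYNTHETIC stand-in for the unavailable source-dataset statistics:
    per-feature standard deviations over 20,000 uniform-policy decision
    epochs (all candidate actions pooled) in a synthetic analog of the
    experimental forest (100 trees of diameter 0.0811 m placed uniformly in
    139.98 x 139.69 m, fog 6.66, seed 20200109).
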