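schema: mothnav-policy-v1
features: [osd, osd0, osd05, of, history, energy]
weights:
  osd: 1.2590
  osd0: 38.8491
  osd05: -8.6711
  of: 66.5153
  history: -9.2061
  energy: 15.7742
meta:
  name: refined
  description: >-
    Reference policy obtained by LSTD actor-critic refinement of the moth
    policy against the constructed one-step reward in the experimental
    forest (best of 1000 restarts, top 10 re-simulated).  Shares the moth
    policy's standardized-feature convention and scale reference.
  reference_average_reward: 0.1668
  normalization: dataset-standardized features
  feature_scale: [0.019193, 0.217469, 0.015164, 28.068200, 0.472267, 0.293869]
  feature_scale_provenance: >-
    SYNTHETIC stand-in for the unavailable source-dataset statistics:
    per-feature standard deviations over 20,000 uniform-policy decision
    epochs (all candidate actions pooled) in a synthetic analog of the
    experimental forest (100 trees of diameter 0.0811 m placed uniformly in
    139.98 x 139.69 m, fog 6.66, seed 20200109).
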