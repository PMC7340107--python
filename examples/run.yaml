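seed: 1
output_dir: runs/demo
features: [pca, wavelet]
algorithms: [kmeans, kmedoids, gmm, fcm, dbscan, meanshift]
datasets:
  - label: E
    similarity: low
    n_classes: 3
    n_spikes: 600
    noise_sd: 0.05
  - label: D
    similarity: high
    n_classes: 3
    n_spikes: 600
    noise_sd: 0.05
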