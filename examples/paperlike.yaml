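# Full pipeline run on the paperlike synthetic fixture:
#   htsrepurpose run --config examples/paperlike.yaml --seed 1 --out out/
stages: [screen, qpcr, microct, stain, nuclei]

screen:
  simulate:
    paperlike: true          # 4 activators (3.0x) + 18 inhibitors (0.3x)
  hit_calling:
    low_threshold: 40.0      # inhibitor: <= 0.4-fold of vehicle
    high_threshold: 240.0    # activator: >= 2.4-fold of vehicle
    viability_min: 70.0
    replicate_rule: all
    qc_threshold: 0.5

qpcr:
  simulate:
    true_folds: {untreated: 1.0, dipy_20uM: 0.8, dipy_50uM: 0.4}
    ct_noise_sd: 0.1
    replicates: 3
  calibrator: untreated

microct:
  simulate:
    shape: [48, 48, 48]
    semiaxes_mm: [0.8, 0.7, 0.6]
    noise_sd: 30.0
  hu_threshold: 600.0

stain:
  simulate:
    true_fraction: 0.18

nuclei:
  simulate:
    n_nuclei: 180
    radius: 5
  intensity_threshold: 100
  min_size: 4
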