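# Default end-to-end run: simulate train/calibration/test corpora from one
# code universe, train associations, select the max-F1 threshold on the
# calibration discordant-laterality claims, evaluate on the test corpus.
out_dir: lateraleye_run
seed: 20170101
n_train: 100000
n_calibration: 40000
n_test: 40000
alpha: 1.0
mode: confidence
threshold_rule: max_f1
calibration_labels: ground_truth
evaluation_labels: ground_truth
suppress: true
generator:
  n_claims: 100000
  n_body_parts: 24
  p_wrong_site: 0.02
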