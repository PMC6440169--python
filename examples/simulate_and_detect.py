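"""Train an adaptive-threshold detector on one session, detect on another.

Generates two short synthetic sessions, fits per-(muscle, feature)
two-component Gaussian mixtures unsupervised on the first, then runs the
multi-muscle majority-voting detector over the second and compares every
detected onset with the generator's true EMG-onset times.
"""

import numpy as np

import emgonset as eo

cfg = eo.SynthConfig(n_trials=6, n_sessions=2, seed=42)
(rec_train, _), (rec_test, truth) = eo.simulate_subject(cfg)
rec_train, rec_test = rec_train.preprocessed(), rec_test.preprocessed()

feats_train = eo.feature_matrix(rec_train, names=eo.OPERATING_SET)
trials = [t for t in eo.segment_trials(rec_train, drop_truncated=True)
          if t.event == eo.Event.GO_FORWARD]
models = eo.train_models(feats_train, trials, rec_train.sample_rate,
                         eo.OPERATING_SET)

feats_test = eo.feature_matrix(rec_test, names=eo.OPERATING_SET)
detector = eo.DetectorConfig(
    detector_type=eo.DetectorType.TYPE2,
    muscles=("AnteriorDeltoid", "PosteriorDeltoid", "Biceps"),
    debounce=3,
)
result = eo.run_detector(feats_test, models, detector, L=1000)

print(f"detected {result.onsets.size} onsets over {cfg.n_trials} reach trials")
print("trial  true EMG onset  nearest detection  delta")
for k in range(truth.n_trials):
    t_true = truth.t_emg_forward[k]
    near = result.onsets[np.argmin(np.abs(result.onsets - t_true))]
    print(f"{k:5d}  {t_true:13.3f}  {near:16.3f}  {near - t_true:+.3f} s")
print("\na positive delta is the detector's reaction to the EMG burst;")
print("it stays well below the ~0.4 s it takes the arm to visibly move.")
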