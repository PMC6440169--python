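"""Session-wise cross-validated benchmark of the info-based detector.

Simulates a 3-session synthetic subject, rotates training across
sessions, and reports event-wise sensitivity, sample-wise specificity
and detection latency against kinematic reference onsets.
"""

import emgonset as eo

cfg = eo.SynthConfig(n_trials=8, n_sessions=3, seed=5)
pairs = eo.simulate_subject(cfg)
recs = [rec.preprocessed() for rec, _ in pairs]
truths = [gt for _, gt in pairs]

detector = eo.DetectorConfig(
    detector_type=eo.DetectorType.TYPE2_INFO,
    muscles=("AnteriorDeltoid", "PosteriorDeltoid", "Biceps"),
    subset_size=3,
)
cv = eo.session_cross_validation(
    recs, detector, eo.Event.GO_FORWARD, ground_truths=truths
)

print(f"rotations: {len(cv.reports)} (each session trains once, "
      f"tests on the others)")
print(cv.pooled().summary())
print(f"\nmean over rotations: sensitivity {cv.sensitivity:.1f}%, "
      f"specificity {cv.specificity:.1f}%")
print("negative median latency = the EMG burst is detected before the")
print("10%-of-peak kinematic onset, early enough to trigger assistance.")
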