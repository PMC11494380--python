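"""Time-resolved TF activity from a reconstructed expression series.

Uses the bundled regulation fixture: two transcription factors drive their
own target blocks in disjoint time windows.  The time-lagged masked
regression recovers when each TF is active.
"""

import lineagevae as lv

series, reg, windows = lv.make_regulation_fixture(
    n_tfs=2, n_targets_per_tf=4, n_times=8, n_samples=60, seed=0)
act = lv.tf_activity(series, reg.tf_names + reg.tg_names, reg, ridge=1e-3)

print("planted active windows:", windows)
print("\nnormalized TF activity (rows = time step):")
print(act.activity.round(3).to_string())
for tf in reg.tf_names:
    print(f"{tf}: peak activity at step {int(act.activity[tf].idxmax())}, "
          f"planted window {windows[tf]}")
# Activities lie in [0, 1] with the strongest TF per step at 1; each TF's
# peak falls inside its planted driving window, and weights for absent
# regulatory edges are exact zeros.
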