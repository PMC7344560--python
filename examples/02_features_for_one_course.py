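"""Filter, window and featurise one simulated course.

Each 320-sample (10 s) window yields 16 features per knee: ten statistical
summaries of the acceleration magnitude and six spatiotemporal gait
parameters from detected heel strikes.
"""

import gaitstate as gs
from gaitstate.pipeline import FeaturizeConfig, window_features
from gaitstate.preprocess import FilterSpec, lowpass_filter, segment_windows

left, right, _ = gs.simulate_course(gs.ON_DEFAULT, seed=2)
left = left.replace(subject_id="demo", state="on", course_id="demo_on")
right = right.replace(subject_id="demo", state="on", course_id="demo_on")

spec = FilterSpec()  # 4th-order low-pass Butterworth, 15 Hz cutoff, 32 Hz
windows = segment_windows(lowpass_filter(left, spec), lowpass_filter(right, spec))
print(f"{len(left)} samples -> {len(windows)} windows "
      f"(last window {windows[-1].n_samples} samples)")

row = window_features(windows[0], FeaturizeConfig())
for name in gs.FEATURE_NAMES[:16]:  # left-knee block
    print(f"  {name}: {row[name]:.4f}")

# Mean sits near the 1 g gravity baseline; stride time should be close to
# the generating 1.2 s; step length comes from the inverted-pendulum model.
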