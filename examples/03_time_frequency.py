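"""Morlet time-frequency decomposition and dB baselining of one epoch.

Decomposes a noise-free epoch with a -4 dB execution depth, normalizes
against the -2.5 to -2.2 s baseline, and prints the mean dB at 20 Hz per
analysis window — showing the injected depth coming back out.
"""

import numpy as np

from betadesync import NeuralSimConfig, TrialTimeline, synth_epoch
from betadesync.tfr import db_normalize, morlet_transform, window_columns

timeline = TrialTimeline()
config = NeuralSimConfig(
    background_rms=0.0,
    amp_mod_sd=0.0,
    execution_depth={k: -4.0 for k in NeuralSimConfig().execution_depth},
)
epoch = synth_epoch(config, "P0", "older", "1:1", seed=3)
raw = morlet_transform(epoch, "C3")
db = db_normalize(raw, [raw], timeline=timeline)

row = np.argmin(np.abs(db.freqs - 20.0))
valid = db.valid_or_all()[row]  # skip cells touching the epoch edge
for name, window in [
    ("rest      (-3..-2 s)", timeline.rest_window),
    ("planning  (-2..0 s) ", timeline.plan_window),
    ("execution (1..3 s)  ", timeline.exec_window),
]:
    cols = window_columns(db.times, window)
    cols = cols[valid[cols]]
    print(f"{name}: {db.power[row, cols].mean():6.2f} dB at 20 Hz")
print(
    "\nThe execution window sits at the injected -4 dB; rest sits at 0 dB\n"
    "by construction of the baseline. Planning shows the default C3\n"
    "planning depth, which only develops ~0.8 s after the cue, so the\n"
    "window mean is shallower than the plateau."
)
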