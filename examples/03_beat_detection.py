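"""Detect heartbeats in 20 Hz PPG and recover interbeat intervals.

At 20 Hz a raw sample-index peak quantizes IBIs to 50 ms steps, so peak
positions are refined to sub-sample precision by parabolic interpolation.
"""

import numpy as np

from nighthrv import IbiProfile, render_ppg, simulate_ibi_series
from nighthrv.pulse import bandpass, detect_peaks, extract_ibis

fs = 20.0
true_beats, _ = simulate_ibi_series(IbiProfile(900, 40, 30, 5, 300), seed=4)
rec = render_ppg(true_beats, fs=fs)

detected = detect_peaks(bandpass(rec)) / fs
interior = true_beats[(true_beats > 1) & (true_beats < rec.duration_s - 1)]
dist = np.abs(interior[:, None] - detected[None, :]).min(axis=1)
print(f"{interior.size} true beats in a 5-min segment; "
      f"{(dist <= 1 / fs).mean():.1%} recovered within one sample")

series = extract_ibis(rec)
true_mean = np.diff(true_beats).mean() * 1000
est_mean = series.ibis_ms[series.accepted].mean()
print(f"mean IBI: true {true_mean:.1f} ms, estimated {est_mean:.1f} ms "
      f"(error {abs(est_mean - true_mean):.2f} ms; the sample period "
      f"is {1000 / fs:.0f} ms — sub-sample refinement beats the grid)")
print(f"30% rejection rule kept {series.accepted.mean():.1%} of IBIs "
      "on this clean segment")
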