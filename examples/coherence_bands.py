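"""Wavelet coherence of two coupled BOLD-like series, split into bands.

Two series share a slow 0.04 Hz oscillation (the band where resting-state
coupling lives) on top of independent noise.  Their wavelet coherence,
averaged inside the cone of influence, is high in the low-frequency band
(0.01-0.1 Hz) and near the estimator floor in the high-frequency band
(above 0.1 Hz) — the separation the HF-content and frequency-FCC metrics
are built on.
"""

import numpy as np

from denoisebench import band_average, wavelet_coherence

tr = 2.5
rng = np.random.default_rng(0)
t = np.arange(400) * tr
shared = np.sin(2 * np.pi * 0.04 * t)
x = shared + 0.8 * rng.standard_normal(t.size)
y = shared + 0.8 * rng.standard_normal(t.size)

field = wavelet_coherence(x, y, tr)
tone = band_average(field, (0.03, 0.05))
lf = band_average(field, (0.01, 0.1))
hf = band_average(field, (0.1, 0.5 / tr), closed_low=False)
print(f"frequency axis: {field.freqs.min():.4f} - {field.freqs.max():.3f} Hz")
print(f"mean coherence at the shared tone (0.03-0.05 Hz): {tone:.3f}")
print(f"mean LF coherence (0.01-0.1 Hz):                  {lf:.3f}")
print(f"mean HF coherence (>0.1 Hz):                      {hf:.3f}")
print("coherence peaks where the series actually couple; the HF level is the")
print("estimator floor set by the smoothing windows, not real coupling")
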