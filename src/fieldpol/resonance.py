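"""Resonance detection on frequency-sweep curves.

A location "resonates" when its field sensitivity has an interior maximum in
frequency.  The resonance amplitude is the peak sensitivity minus the
sensitivity at the 0.5 Hz baseline.  The peak is refined by local quadratic
interpolation in log-frequency; a peak sitting on the lowest swept frequency,
or an amplitude below 1% of the peak value, counts as absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class ResonanceSummary:
    location: str
    present: bool
    f_res_hz: Optional[float]
    amplitude: Optional[float]  # peak - baseline, sensitivity units
    baseline: float  # sensitivity at the baseline frequency


def detect_resonance(
    frequencies_hz: np.ndarray,
    amplitudes: np.ndarray,
    baseline_hz: float = 0.5,
    location: str = "",
) -> ResonanceSummary:
    f = np.asarray(frequencies_hz, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    order = np.argsort(f)
    f, a = f[order], a[order]
    pos = f > 0
    f, a = f[pos], a[pos]
    if len(f) < 3:
        raise ValueError("need at least three positive frequencies")
    ib = int(np.argmin(np.abs(f - baseline_hz)))
    if not np.isclose(f[ib], baseline_hz, rtol=1e-6):
        raise ValueError(f"sweep does not contain the {baseline_hz} Hz baseline")
    baseline = float(a[ib])
    i = int(np.argmax(a))
    if i == 0:
        return ResonanceSummary(location, False, None, None, baseline)
    if i == len(f) - 1:
        f_res, peak = float(f[i]), float(a[i])
    else:
        lf = np.log10(f[i - 1:i + 2])
        ya = a[i - 1:i + 2]
        denom = (ya[0] - 2 * ya[1] + ya[2])
        if denom >= 0:  # flat or degenerate: keep grid maximum
            f_res, peak = float(f[i]), float(a[i])
        else:
            shift = 0.5 * (ya[0] - ya[2]) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            lpk = lf[1] + shift * (lf[2] - lf[1] if shift > 0 else lf[1] - lf[0])
            f_res = float(10.0 ** lpk)
            peak = float(ya[1] - 0.25 * (ya[0] - ya[2]) * shift)
    amplitude = peak - baseline
    present = f_res > f[0] and amplitude > 0.01 * peak
    if not present:
        return ResonanceSummary(location, False, None, None, baseline)
    return ResonanceSummary(location, True, f_res, amplitude, baseline)


def default_frequency_grid(n: int = 30, f_max: float = 1000.0) -> np.ndarray:
    """{0} plus n log-spaced frequencies over [0.5, f_max] Hz."""
    return np.concatenate([[0.0], np.logspace(np.log10(0.5), np.log10(f_max), n)])
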