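"""Beat-sequence FFT power spectrum of RR intervals with VLF/LF/HF bands.

The spectrum is computed directly on the beat-indexed RR sequence (the
tachogram), not on an evenly resampled signal.  A fixed-length window
(2048 intervals) is mean-centred, transformed with an FFT, and the
squared magnitudes are divided by the mean interval length in seconds.
The per-beat frequency axis (cycles/beat) is converted to Hz by
dividing by the mean RR, so for a mouse at ~10 beats/s the per-beat
Nyquist (0.5 cycles/beat) lands at ~5 Hz — matching the band edges
VLF 0–0.4, LF 0.4–1.5, HF 1.5–5.0 Hz.

Ectopic positions arrive zero-replaced and enter the FFT as zeros; the
mean used for centring and for the Hz mapping is taken over the nonzero
entries only.  Linear interpolation across ectopic positions is
available behind ``interpolate_ectopics=True`` but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import CleanSegment

#: (low, high) Hz edges; VLF/LF half-open [low, high), HF closed at the top.
DEFAULT_BANDS = {"vlf": (0.0, 0.4), "lf": (0.4, 1.5), "hf": (1.5, 5.0)}


@dataclass
class SpectralSummary:
    freq_hz: np.ndarray     # one-sided analysis frequencies, DC first
    power: np.ndarray       # per-bin one-sided power (|X|^2-scaled / mean RR s)
    vlf: float
    lf: float
    hf: float
    total_power: float      # all bins with 0 < f <= top band edge
    band_edges_hz: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    mean_rr_s: float = 0.0
    n_fft: int = 2048


def rr_power_spectrum(
    seg: CleanSegment | np.ndarray,
    n_fft: int = 2048,
    bands: dict | None = None,
    window: str = "rectangular",
    interpolate_ectopics: bool = False,
) -> SpectralSummary:
    """One-sided RR power spectrum with band powers.

    Pipeline: mean of nonzero entries -> subtract from nonzero entries
    (zeros untouched) -> length-``n_fft`` FFT -> per-bin power
    ``|X_k|^2 / T`` where ``T`` is the mean RR in seconds, folded
    one-sided (interior bins doubled; DC and Nyquist not) -> band sums
    over half-open bins [low, high) Hz with the top band closed above.
    The DC bin is reported but excluded from every band and from
    ``total_power``.

    ``window="hann"`` applies a Hann taper after centring (off by
    default).  ``interpolate_ectopics=True`` replaces zeros by linear
    interpolation before analysis instead of passing them through.
    """
    if isinstance(seg, CleanSegment):
        if seg.cleaning_mode == "remove":
            raise ValueError(
                "spectral analysis needs a zero_replace (or uncleaned) segment of "
                "fixed length; removal-cleaned segments break the beat grid"
            )
        x = seg.rr
    else:
        x = np.asarray(seg, dtype=float)
    if x.size != n_fft:
        raise ValueError(f"segment has {x.size} positions; spectral stage needs exactly {n_fft}")
    bands = dict(bands or DEFAULT_BANDS)

    nonzero = x != 0
    if not np.any(nonzero):
        raise ValueError("segment is all zeros")
    t_bar = float(x[nonzero].mean()) / 1000.0  # mean RR, seconds
    if t_bar <= 0:
        raise ValueError("mean RR must be positive")

    if interpolate_ectopics and not nonzero.all():
        idx = np.arange(x.size)
        x = x.copy()
        x[~nonzero] = np.interp(idx[~nonzero], idx[nonzero], x[nonzero])
        nonzero = np.ones(x.size, dtype=bool)

    centred = np.where(nonzero, x - x[nonzero].mean(), 0.0)
    if window == "hann":
        centred = centred * np.hanning(n_fft)
    elif window != "rectangular":
        raise ValueError(f"unknown window {window!r}")

    spec = np.fft.rfft(centred, n=n_fft)
    p = np.abs(spec) ** 2 / t_bar
    # one-sided folding: double interior bins; DC and (even-n) Nyquist stay single
    fold = np.full(p.size, 2.0)
    fold[0] = 1.0
    if n_fft % 2 == 0:
        fold[-1] = 1.0
    p = p * fold

    k = np.arange(p.size)
    freq_hz = (k / n_fft) / t_bar

    def band_power(lo: float, hi: float, closed_hi: bool) -> float:
        sel = (freq_hz >= lo) & ((freq_hz <= hi) if closed_hi else (freq_hz < hi))
        sel &= k > 0  # DC excluded everywhere
        return float(p[sel].sum())

    top = max(hi for _, hi in bands.values())
    names = sorted(bands, key=lambda b: bands[b][0])
    out = {}
    for name in names:
        lo, hi = bands[name]
        out[name] = band_power(lo, hi, closed_hi=(hi == top))
    total = band_power(0.0, top, closed_hi=True)

    return SpectralSummary(
        freq_hz=freq_hz,
        power=p,
        vlf=out.get("vlf", 0.0),
        lf=out.get("lf", 0.0),
        hf=out.get("hf", 0.0),
        total_power=total,
        band_edges_hz=bands,
        mean_rr_s=t_bar,
        n_fft=n_fft,
    )
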