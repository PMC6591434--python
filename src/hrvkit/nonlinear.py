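"""Nonlinear HRV metrics: Poincaré SD1/SD2 and (multiscale) sample entropy.

Poincaré SD1/SD2 are the short- and long-axis dispersions of the lag-1
return map, computed from successive differences and sums:
``SD1 = sqrt(var(rr[i+1] - rr[i]) / 2)``,
``SD2 = sqrt(var(rr[i+1] + rr[i]) / 2)`` (sample variance, n-1).

Sample entropy (SampEn) is ``-ln(A/B)`` where B counts pairs of
m-length templates within Chebyshev distance r and A the same for
(m+1)-length templates, self-matches excluded.  The multiscale curve
coarse-grains by non-overlapping means and re-evaluates SampEn with r
held fixed at its scale-1 value; E1 is the scale-1 point of that curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import CleanSegment


@dataclass
class PoincareSummary:
    sd1: float  # ms, short-term (successive-difference) axis
    sd2: float  # ms, long-term (successive-sum) axis
    ratio: float | None  # sd1/sd2; None when sd2 == 0


@dataclass
class EntropySummary:
    e1: float | None  # SampEn value; None when undefined (no matches)
    m: int
    r: float          # absolute tolerance actually used, ms
    scale: int
    n_templates_a: int  # A: (m+1)-template match count
    n_templates_b: int  # B: m-template match count


def _as_array(seg) -> np.ndarray:
    if isinstance(seg, CleanSegment):
        if seg.cleaning_mode == "zero_replace":
            raise ValueError("nonlinear metrics need a removal-cleaned segment")
        return seg.rr
    return np.asarray(seg, dtype=float)


def poincare_summary(seg: CleanSegment | np.ndarray, literal_sums_for_sd1: bool = False) -> PoincareSummary:
    """Poincaré SD1/SD2 of an RR segment.

    Default follows the universal convention (SD1 from successive
    differences = short-term variability).  ``literal_sums_for_sd1``
    swaps the two, assigning the successive-sum statistic to SD1.
    """
    x = _as_array(seg)
    if x.size < 3:
        raise ValueError("need at least 3 intervals")
    d = np.diff(x)
    s = x[1:] + x[:-1]
    sd_diff = float(np.sqrt(d.var(ddof=1) / 2.0))
    sd_sum = float(np.sqrt(s.var(ddof=1) / 2.0))
    sd1, sd2 = (sd_sum, sd_diff) if literal_sums_for_sd1 else (sd_diff, sd_sum)
    return PoincareSummary(sd1=sd1, sd2=sd2, ratio=(sd1 / sd2 if sd2 > 0 else None))


def _template_match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered-pair match counts (A, B) for (m+1)- and m-length templates.

    Both counts run over the same N-m template start positions so the
    ratio A/B is a conditional probability; distances are Chebyshev and
    matches require distance <= r; self-pairs excluded.  Vectorized
    over the full pairwise distance matrix: O(n^2) memory, fine for the
    n = 2048 segments this package analyzes.
    """
    n = x.size
    n_templ = n - m
    if n_templ < 2:
        raise ValueError("series too short for template length m")
    # max over the first m lags of |x[i+k] - x[j+k]|, i, j < n_templ
    d = np.abs(x[:n_templ, None] - x[None, :n_templ])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n_templ, None] - x[None, k : k + n_templ]), out=d)
    b_mat = d <= r
    np.fill_diagonal(b_mat, False)
    np.maximum(d, np.abs(x[m : m + n_templ, None] - x[None, m : m + n_templ]), out=d)
    a_mat = d <= r
    np.fill_diagonal(a_mat, False)
    return int(a_mat.sum()), int(b_mat.sum())


def sample_entropy(
    seg: CleanSegment | np.ndarray,
    m: int = 2,
    r_fraction: float = 0.2,
    r_absolute: float | None = None,
    scale: int = 1,
) -> EntropySummary:
    """Sample entropy of an RR segment.

    r defaults to ``r_fraction`` times the segment's sample SD, making
    the statistic invariant to affine rescaling of the series;
    ``r_absolute`` overrides it (used by the multiscale curve to hold r
    fixed across scales).  A constant series has SD 0, hence r = 0, and
    every template still matches at distance 0: A = B and e1 = 0.
    Returns an undefined (None) e1 when either count is zero.
    """
    x = _as_array(seg)
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} intervals")
    r = float(r_absolute) if r_absolute is not None else r_fraction * float(x.std(ddof=1))
    if r < 0:
        raise ValueError("r must be >= 0")
    a, b = _template_match_counts(x, m, r)
    e1 = None if (a == 0 or b == 0) else float(-np.log(a / b))
    if a == b and a > 0:
        e1 = 0.0  # exact, avoids -log(1) rounding
    return EntropySummary(e1=e1, m=m, r=r, scale=scale, n_templates_a=a, n_templates_b=b)


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping means of length ``scale``; the trailing remainder is dropped."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale == 1:
        return np.asarray(x, dtype=float)
    n = (x.size // scale) * scale
    return np.asarray(x[:n], dtype=float).reshape(-1, scale).mean(axis=1)


def multiscale_entropy_e1(
    seg: CleanSegment | np.ndarray,
    m: int = 2,
    r_fraction: float = 0.2,
    scale: int = 1,
) -> EntropySummary:
    """Sample entropy at one coarse-graining scale of the multiscale curve.

    r is fixed at ``r_fraction`` times the SD of the *original* series
    for every scale, so scale 1 is bit-identical to
    :func:`sample_entropy` and coarser scales are comparable to it.
    """
    x = _as_array(seg)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    cg = coarse_grain(x, scale)
    if cg.size < m + 2:
        raise ValueError(f"coarse-grained length {cg.size} < m + 2 = {m + 2}")
    r = r_fraction * float(x.std(ddof=1))
    out = sample_entropy(cg, m=m, r_absolute=r, scale=scale)
    return out


def multiscale_entropy_curve(
    seg: CleanSegment | np.ndarray,
    m: int = 2,
    r_fraction: float = 0.2,
    max_scale: int = 4,
) -> list[EntropySummary]:
    """The multiscale entropy curve over scales 1..max_scale."""
    return [multiscale_entropy_e1(seg, m=m, r_fraction=r_fraction, scale=s) for s in range(1, max_scale + 1)]
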