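"""Time-domain HRV metrics: mean RR, RR range, SDRR and CV."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import CleanSegment


@dataclass
class TimeDomainSummary:
    mean_rr: float   # ms
    range_rr: float  # ms, max - min
    sdrr: float      # ms, sample SD (n-1)
    cv: float        # sdrr / mean_rr, dimensionless
    n: int


def time_domain_summary(seg: CleanSegment | np.ndarray) -> TimeDomainSummary:
    """Summarize a removal-cleaned segment.

    Sample (n-1) standard deviation throughout.  Zero-replaced segments
    are rejected: embedded zeros would corrupt every statistic here.
    """
    if isinstance(seg, CleanSegment):
        if seg.cleaning_mode == "zero_replace":
            raise ValueError(
                "time-domain metrics need a removal-cleaned segment; "
                "zero-replaced intervals would bias mean and SD"
            )
        x = seg.rr
    else:
        x = np.asarray(seg, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    mean = float(x.mean())
    sdrr = float(x.std(ddof=1))
    return TimeDomainSummary(
        mean_rr=mean,
        range_rr=float(x.max() - x.min()),
        sdrr=sdrr,
        cv=sdrr / mean,
        n=int(x.size),
    )
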