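"""Reading and writing beat-time / RR-interval tables.

Input convention: beat occurrence times in **seconds**, RR intervals in
**milliseconds**.  A table carries either a time column or an interval
column, never both; rows are grouped into one series per
(animal_id, condition) pair.  Tables are delimited text with a header
row (comma by default, tab via ``delimiter="\\t"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "TGAC8", "other")

#: canonical column names; a ``column_map`` maps these keys to the
#: actual column names in a file.
STANDARD_COLUMNS = ("animal_id", "genotype", "condition", "time_s", "rr_ms", "epoch")


@dataclass
class BeatSeries:
    """Beat occurrence times for one animal under one condition.

    Parameters
    ----------
    animal_id : str
        Opaque animal label.
    genotype : str
        ``"WT"``, ``"TGAC8"`` or ``"other"``.
    condition : str
        Free label, e.g. ``basal``, ``atropine``, ``dual_blockade``.
    beat_times : ndarray
        Strictly increasing beat times in seconds, length >= 2.
    epoch : str, optional
        Optional sub-recording label (e.g. a pre/post drug window).
    """

    animal_id: str
    genotype: str
    condition: str
    beat_times: np.ndarray
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or self.beat_times.size < 2:
            raise ValueError("beat_times must be a 1-D sequence of length >= 2")
        d = np.diff(self.beat_times)
        if np.any(d <= 0):
            bad = int(np.argmax(d <= 0)) + 1
            raise ValueError(
                f"beat times must be strictly increasing; violation at row {bad} "
                f"(t={self.beat_times[bad]:g} after t={self.beat_times[bad - 1]:g})"
            )
        if self.genotype not in GENOTYPES:
            self.genotype = "other" if self.genotype else "other"

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass
class RRSeries:
    """Inter-beat (RR) intervals in milliseconds, with series metadata."""

    animal_id: str
    genotype: str
    condition: str
    rr: np.ndarray
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1 or self.rr.size < 1:
            raise ValueError("rr must be a non-empty 1-D sequence")
        if np.any(self.rr <= 0):
            bad = int(np.argmax(self.rr <= 0))
            raise ValueError(f"all RR intervals must be > 0; rr[{bad}] = {self.rr[bad]:g} ms")

    def __len__(self) -> int:
        return self.rr.size


def beats_to_rr(b: BeatSeries) -> RRSeries:
    """Difference beat times (s) into RR intervals (ms).

    ``rr[i] = (beat_times[i+1] - beat_times[i]) * 1000``; the result has
    one fewer element than the beat series.
    """
    if len(b) < 2:
        raise ValueError("need at least 2 beats to form an RR interval")
    rr = np.diff(b.beat_times) * 1000.0
    return RRSeries(b.animal_id, b.genotype, b.condition, rr, epoch=b.epoch)


def rr_to_beats(r: RRSeries, t0: float = 0.0) -> BeatSeries:
    """Cumulate RR intervals (ms) back into beat times (s) starting at ``t0``."""
    times = t0 + np.concatenate([[0.0], np.cumsum(r.rr) / 1000.0])
    return BeatSeries(r.animal_id, r.genotype, r.condition, times, epoch=r.epoch)


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None):
    cmap = {k: k for k in STANDARD_COLUMNS}
    if column_map:
        cmap.update(column_map)
    have = {k: v for k, v in cmap.items() if v in df.columns}
    for required in ("animal_id",):
        if required not in have:
            raise ValueError(f"missing required column: {cmap[required]!r} (for {required})")
    has_time = "time_s" in have
    has_rr = "rr_ms" in have
    if has_time and has_rr:
        raise ValueError(
            "table has both a time column and an interval column; supply exactly one"
        )
    if not (has_time or has_rr):
        raise ValueError(
            f"missing value column: need {cmap['time_s']!r} (beat times, s) "
            f"or {cmap['rr_ms']!r} (RR intervals, ms)"
        )
    return have, has_time


def _iter_groups(df: pd.DataFrame, have: Mapping[str, str]):
    keys = [have["animal_id"]]
    if "condition" in have:
        keys.append(have["condition"])
    if "epoch" in have:
        keys.append(have["epoch"])
    for _, g in df.groupby(keys, sort=True, dropna=False):
        yield g


def _meta(g: pd.DataFrame, have: Mapping[str, str]):
    row = g.iloc[0]
    return dict(
        animal_id=str(row[have["animal_id"]]),
        genotype=str(row[have["genotype"]]) if "genotype" in have else "other",
        condition=str(row[have["condition"]]) if "condition" in have else "unknown",
        epoch=str(row[have["epoch"]]) if "epoch" in have else None,
    )


def load_beat_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[BeatSeries]:
    """Load a delimited beat-time table into one BeatSeries per group.

    Rows are grouped by (animal_id, condition[, epoch]) and sorted by
    time within each group as read; non-monotone times raise with the
    offending row index.  The table must carry a time column (seconds);
    use :func:`load_rr_table` for interval tables or :func:`load_series`
    to dispatch on whichever column is present.
    """
    df = pd.read_csv(path, sep=delimiter)
    have, has_time = _resolve_columns(df, column_map)
    if not has_time:
        raise ValueError("table has an interval column, not beat times; use load_rr_table")
    out = []
    for g in _iter_groups(df, have):
        out.append(BeatSeries(beat_times=g[have["time_s"]].to_numpy(float), **_meta(g, have)))
    return out


def load_rr_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[RRSeries]:
    """Load a delimited RR-interval table (ms) into one RRSeries per group."""
    df = pd.read_csv(path, sep=delimiter)
    have, has_time = _resolve_columns(df, column_map)
    if has_time:
        raise ValueError("table has a time column, not intervals; use load_beat_table")
    out = []
    for g in _iter_groups(df, have):
        out.append(RRSeries(rr=g[have["rr_ms"]].to_numpy(float), **_meta(g, have)))
    return out


def load_series(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[RRSeries]:
    """Load either table flavour and return RR series (beat tables are differenced)."""
    df = pd.read_csv(path, sep=delimiter)
    have, has_time = _resolve_columns(df, column_map)
    if has_time:
        return [beats_to_rr(b) for b in load_beat_table(path, column_map, delimiter)]
    return load_rr_table(path, column_map, delimiter)


def write_beat_table(series: Iterable[BeatSeries], path: str | Path, delimiter: str = ",") -> None:
    """Write BeatSeries out in the canonical beat-table format."""
    frames = []
    for b in series:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": b.animal_id,
                    "genotype": b.genotype,
                    "condition": b.condition,
                    "time_s": b.beat_times,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False)


@dataclass
class HRVRecord:
    """One metric value for one analyzed segment (tidy long format)."""

    animal_id: str
    genotype: str
    condition: str
    metric: str
    value: float
    segment_index: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.metric!r} has non-finite value {self.value!r}")


_RECORD_COLUMNS = [
    "animal_id", "genotype", "condition", "metric", "value", "segment_index", "provenance",
]


def records_to_frame(records: Sequence[HRVRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no records to tabulate")
    return pd.DataFrame([vars(r) for r in records], columns=_RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[HRVRecord]:
    df = df.fillna({"provenance": ""})
    return [
        HRVRecord(
            animal_id=str(r.animal_id),
            genotype=str(r.genotype),
            condition=str(r.condition),
            metric=str(r.metric),
            value=float(r.value),
            segment_index=int(r.segment_index),
            provenance=str(r.provenance),
        )
        for r in df.itertuples()
    ]


def write_metrics_table(
    records: Sequence[HRVRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write a tidy metrics table; round-trips losslessly through load.

    Values are serialized with ``repr`` precision so that
    ``load_metrics_table(write_metrics_table(x)) == x`` to machine
    precision.
    """
    df = records_to_frame(records)
    df.to_csv(path, sep=delimiter, index=False)


def load_metrics_table(path: str | Path, delimiter: str = ",") -> list[HRVRecord]:
    df = pd.read_csv(path, sep=delimiter, keep_default_na=False, na_values=[])
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    return frame_to_records(df)
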