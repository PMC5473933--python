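"""Response traces, cycle segmentation and kinetic feature extraction.

One introduction–purge cycle of a surface-stress sensor trace is summarised
by five anchor readings — *a* at cycle onset ``t_a``, *b* one second later,
*c* at the end of injection (``t_a + 10`` s), *d* one second into the purge
and *e*, the cycle maximum — from which four kinetic parameters follow:

* ``p1 = (b - a) / (t_b - t_a)`` — initial adsorption slope,
* ``p2 = (c - b) / (t_c - t_b)`` — quasi-equilibrium slope,
* ``p3 = (d - c) / (t_d - t_c)`` — initial desorption slope,
* ``p4 = e - a`` — maximum response height.

Anchors are read at the sample instant nearest the requested time (the
default schedule puts all anchor times exactly on the 20 Hz grid), with no
interpolation and no baseline correction — constant offsets cancel in all
four parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schedule import AcquisitionSchedule

#: Offsets (seconds) of anchors b, c, d relative to the cycle onset t_a.
ANCHOR_OFFSETS = {"b": 1.0, "c": 10.0, "d": 11.0}

#: Cycle onsets (seconds) of the three reproducible late cycles.
DEFAULT_T_A = (60.0, 80.0, 100.0)

_TIME_COLUMN = "time_s"
_FLOAT_FMT = "%.17g"


@dataclass
class ResponseSignal:
    """One channel's sampled trace for one sample."""

    channel_name: str
    sample_name: str
    times: np.ndarray
    values: np.ndarray
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError(
                    "non-uniform sampling detected (spread %.3g s); resampling "
                    "is refused — provide a uniformly sampled trace" % np.ptp(dt)
                )

    @property
    def dt(self) -> float:
        return 1.0 / self.schedule.sampling_rate


@dataclass(frozen=True)
class CyclePoints:
    """Anchor times and values for one response cycle."""

    t_a: float
    t_b: float
    t_c: float
    t_d: float
    a: float
    b: float
    c: float
    d: float
    e: float


@dataclass(frozen=True)
class FeatureVector:
    """The four kinetic parameters of one cycle of one channel."""

    channel_name: str
    t_a: float
    p1: float
    p2: float
    p3: float
    p4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4])


@dataclass
class FeatureMatrix:
    """Observations (one per sample-cycle) by (channel, parameter) features.

    Attributes
    ----------
    X : pandas.DataFrame
        N x d feature table; columns labelled ``"<channel>:p<1-4>"``,
        channel-major, parameter-minor.
    A : numpy.ndarray
        Alcohol content (vol %) per row.
    sample_names : numpy.ndarray
        Sample identity per row.
    t_a : numpy.ndarray
        Cycle onset (s) per row.
    known : numpy.ndarray of bool
        True for training samples, False for held-out unknowns.
    normalization_sds : pandas.Series or None
        Per-column standard deviations used for normalization; ``None``
        while the matrix is raw.
    """

    X: pd.DataFrame
    A: np.ndarray
    sample_names: np.ndarray
    t_a: np.ndarray
    known: np.ndarray
    normalization_sds: pd.Series | None = None

    def __post_init__(self) -> None:
        n = len(self.X)
        self.A = np.asarray(self.A, dtype=float)
        self.sample_names = np.asarray(self.sample_names, dtype=object)
        self.t_a = np.asarray(self.t_a, dtype=float)
        self.known = np.asarray(self.known, dtype=bool)
        for name, arr in [
            ("A", self.A),
            ("sample_names", self.sample_names),
            ("t_a", self.t_a),
            ("known", self.known),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} rows")

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def column_labels(self) -> list[str]:
        return list(self.X.columns)

    @property
    def channels(self) -> list[str]:
        seen: list[str] = []
        for label in self.X.columns:
            ch = label.rsplit(":", 1)[0]
            if ch not in seen:
                seen.append(ch)
        return seen

    def channel_columns(self, channel: str) -> list[str]:
        cols = [c for c in self.X.columns if c.rsplit(":", 1)[0] == channel]
        if not cols:
            raise KeyError(f"no columns for channel {channel!r}")
        return cols

    def subset_rows(self, rows: np.ndarray) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            X=self.X.iloc[rows].reset_index(drop=True),
            A=self.A[rows],
            sample_names=self.sample_names[rows],
            t_a=self.t_a[rows],
            known=self.known[rows],
            normalization_sds=self.normalization_sds,
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "sample": self.sample_names,
                "alcohol_content": self.A,
                "t_a": self.t_a,
                "known": self.known,
            }
        )
        return pd.concat([meta, self.X.reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# Signal I/O: plain-text delimited tables, column time_s then one per channel.
# ---------------------------------------------------------------------------

def write_signals(signals: Sequence[ResponseSignal], path: str | Path) -> None:
    """Write one sample's channels as a delimited table (time_s, <channels>)."""
    signals = list(signals)
    if not signals:
        raise ValueError("no signals to write")
    ref = signals[0]
    for s in signals[1:]:
        if len(s.times) != len(ref.times) or abs(s.times[0] - ref.times[0]) > 1e-9:
            raise ValueError("all channels must share one time base")
    table = pd.DataFrame({_TIME_COLUMN: ref.times})
    for s in signals:
        table[s.channel_name] = s.values
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_signals(
    path: str | Path,
    sample_name: str | None = None,
    schedule: AcquisitionSchedule | None = None,
) -> list[ResponseSignal]:
    """Read all channels of one sample from a delimited table."""
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty signal file: {path}") from exc
    if _TIME_COLUMN not in table.columns:
        raise ValueError(f"missing {_TIME_COLUMN!r} column in {path}")
    channels = [c for c in table.columns if c != _TIME_COLUMN]
    if not channels:
        raise ValueError(f"no channel columns in {path}")
    times = table[_TIME_COLUMN].to_numpy(dtype=float)
    if len(times) == 0:
        raise ValueError(f"empty signal file: {path}")
    if schedule is None:
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.05
        schedule = AcquisitionSchedule(sampling_rate=1.0 / dt)
    name = sample_name if sample_name is not None else path.stem
    return [
        ResponseSignal(
            channel_name=ch,
            sample_name=name,
            times=times,
            values=table[ch].to_numpy(dtype=float),
            schedule=schedule,
        )
        for ch in channels
    ]


def read_signal(
    path: str | Path,
    channel: str | None = None,
    sample_name: str | None = None,
    schedule: AcquisitionSchedule | None = None,
) -> ResponseSignal:
    """Read a single channel; ``channel`` may be omitted for one-channel files."""
    signals = read_signals(path, sample_name=sample_name, schedule=schedule)
    if channel is None:
        if len(signals) > 1:
            raise ValueError(
                "file has %d channels; pass channel=..." % len(signals)
            )
        return signals[0]
    for s in signals:
        if s.channel_name == channel:
            return s
    raise ValueError(f"channel {channel!r} not in file")


# ---------------------------------------------------------------------------
# Cycle segmentation and parameter extraction
# ---------------------------------------------------------------------------

def _nearest_index(signal: ResponseSignal, t: float) -> int:
    idx = int(round((t - signal.times[0]) * signal.schedule.sampling_rate))
    if idx < 0 or idx >= len(signal.times):
        raise ValueError(f"time {t} s outside trace span")
    return idx


def extract_cycle_points(signal: ResponseSignal, t_a: float) -> CyclePoints:
    """Read the anchors a, b, c, d, e of the cycle starting at ``t_a``.

    ``a``–``d`` are the trace values at the samples nearest ``t_a``,
    ``t_a + 1``, ``t_a + 10`` and ``t_a + 11`` s; ``e`` is the maximum over
    the half-open cycle window ``[t_a, t_a + period)``.
    """
    period = signal.schedule.period
    t_end = t_a + period
    if t_a < signal.times[0] - 1e-9 or t_end > signal.times[-1] + signal.dt + 1e-9:
        raise ValueError(
            f"cycle [{t_a}, {t_end}) s not contained in trace "
            f"[{signal.times[0]}, {signal.times[-1]}] s"
        )
    i_a = _nearest_index(signal, t_a)
    i_b = _nearest_index(signal, t_a + ANCHOR_OFFSETS["b"])
    i_c = _nearest_index(signal, t_a + ANCHOR_OFFSETS["c"])
    i_d = _nearest_index(signal, t_a + ANCHOR_OFFSETS["d"])
    in_window = (signal.times >= t_a - 1e-9) & (signal.times < t_end - 1e-9)
    e = float(np.max(signal.values[in_window]))
    return CyclePoints(
        t_a=t_a,
        t_b=t_a + ANCHOR_OFFSETS["b"],
        t_c=t_a + ANCHOR_OFFSETS["c"],
        t_d=t_a + ANCHOR_OFFSETS["d"],
        a=float(signal.values[i_a]),
        b=float(signal.values[i_b]),
        c=float(signal.values[i_c]),
        d=float(signal.values[i_d]),
        e=e,
    )


def compute_parameters(
    points: CyclePoints, channel_name: str = ""
) -> FeatureVector:
    """Turn one cycle's anchors into the four kinetic parameters."""
    for t0, t1, which in [
        (points.t_a, points.t_b, "t_b - t_a"),
        (points.t_b, points.t_c, "t_c - t_b"),
        (points.t_c, points.t_d, "t_d - t_c"),
    ]:
        if t1 == t0:
            raise ValueError(f"coincident anchor times ({which} == 0)")
    return FeatureVector(
        channel_name=channel_name,
        t_a=points.t_a,
        p1=(points.b - points.a) / (points.t_b - points.t_a),
        p2=(points.c - points.b) / (points.t_c - points.t_b),
        p3=(points.d - points.c) / (points.t_d - points.t_c),
        p4=points.e - points.a,
    )


def extract_features(
    signals: Sequence[ResponseSignal],
    metadata: pd.DataFrame,
    t_a_list: Sequence[float] = DEFAULT_T_A,
) -> FeatureMatrix:
    """Build the observation matrix from a signal collection.

    Parameters
    ----------
    signals : sequence of ResponseSignal
        One trace per (sample, channel).
    metadata : pandas.DataFrame
        Columns ``sample``, ``alcohol_content`` and optionally ``known``
        (defaults to all True).
    t_a_list : sequence of float
        Cycle onsets to extract; one observation row per (sample, t_a).

    Rows are ordered sample-major (metadata order), cycle-minor
    (``t_a_list`` order); columns channel-major, parameter-minor.
    """
    if "known" not in metadata.columns:
        metadata = metadata.assign(known=True)
    by_sample: dict[str, dict[str, ResponseSignal]] = {}
    channel_order: list[str] = []
    for s in signals:
        by_sample.setdefault(s.sample_name, {})[s.channel_name] = s
        if s.channel_name not in channel_order:
            channel_order.append(s.channel_name)

    missing = []
    for sample in metadata["sample"]:
        have = by_sample.get(sample, {})
        for ch in channel_order:
            if ch not in have:
                missing.append((sample, ch))
    if missing:
        raise ValueError(f"missing signals for (sample, channel): {missing}")

    columns = [f"{ch}:p{i}" for ch in channel_order for i in (1, 2, 3, 4)]
    rows, a_vals, names, onsets, known = [], [], [], [], []
    for _, rec in metadata.iterrows():
        sample = rec["sample"]
        for t_a in t_a_list:
            row = []
            for ch in channel_order:
                fv = compute_parameters(
                    extract_cycle_points(by_sample[sample][ch], t_a), ch
                )
                row.extend(fv.as_array())
            rows.append(row)
            a_vals.append(float(rec["alcohol_content"]))
            names.append(sample)
            onsets.append(float(t_a))
            known.append(bool(rec["known"]))

    return FeatureMatrix(
        X=pd.DataFrame(rows, columns=columns),
        A=np.array(a_vals),
        sample_names=np.array(names, dtype=object),
        t_a=np.array(onsets),
        known=np.array(known),
    )


def normalize_features(
    matrix: FeatureMatrix,
    reference_rows: np.ndarray | None = None,
    sds: pd.Series | None = None,
) -> FeatureMatrix:
    """Scale each column to unit standard deviation.

    The per-column sd is computed over ``reference_rows`` (default: the
    ``known`` rows, or all rows if none are flagged) with the population
    (divisor *n*) convention, then applied to every row, so held-out rows
    are scaled with the training statistics.  Pass precomputed ``sds`` to
    reuse a previous normalization on new data.
    """
    if sds is None:
        if reference_rows is None:
            reference_rows = (
                np.flatnonzero(matrix.known)
                if matrix.known.any()
                else np.arange(matrix.n_obs)
            )
        reference_rows = np.asarray(reference_rows)
        ref = matrix.X.iloc[reference_rows]
        sds = ref.std(axis=0, ddof=0)
        zero = sds[sds <= 0]
        if len(zero):
            raise ValueError(
                "zero-variance column(s) over reference rows: "
                + ", ".join(zero.index)
            )
    else:
        sds = sds.reindex(matrix.X.columns)
        if sds.isna().any() or (sds <= 0).any():
            raise ValueError("provided sds must be positive for every column")
    return replace(
        matrix,
        X=matrix.X / sds,
        normalization_sds=sds.copy(),
    )


def write_features(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features(path: str | Path) -> FeatureMatrix:
    table = pd.read_csv(path, float_precision="round_trip")
    meta_cols = ["sample", "alcohol_content", "t_a", "known"]
    for col in meta_cols:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    feat_cols = [c for c in table.columns if c not in meta_cols]
    return FeatureMatrix(
        X=table[feat_cols].copy(),
        A=table["alcohol_content"].to_numpy(dtype=float),
        sample_names=table["sample"].to_numpy(dtype=object),
        t_a=table["t_a"].to_numpy(dtype=float),
        known=table["known"].to_numpy(dtype=bool),
    )
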