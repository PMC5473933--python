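"""Acquisition schedule for alternating sample-introduction / purge cycles.

A measurement alternates a 10 s headspace-vapour introduction with a 10 s
clean-air purge, repeated five times, sampled at 20 Hz.  Injections do not
start at t = 0: a pre-injection baseline (default 20 s) precedes the first
cycle, so cycle onsets fall at 20, 40, 60, 80 and 100 s and the three
reproducible "late" cycles start at 60, 80 and 100 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing of one multi-cycle sensing run.

    Parameters
    ----------
    baseline_duration : float
        Seconds of clean-air baseline before the first injection.
    inject_duration, purge_duration : float
        Seconds of vapour introduction / clean-air purge per cycle.
    n_cycles : int
        Number of introduction–purge cycles.
    sampling_rate : float
        Samples per second (Hz).
    """

    baseline_duration: float = 20.0
    inject_duration: float = 10.0
    purge_duration: float = 10.0
    n_cycles: int = 5
    sampling_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.inject_duration <= 0 or self.purge_duration <= 0:
            raise ValueError("inject/purge durations must be positive")
        if self.baseline_duration < 0:
            raise ValueError("baseline_duration must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def period(self) -> float:
        """Length of one injection+purge cycle in seconds."""
        return self.inject_duration + self.purge_duration

    @property
    def total_duration(self) -> float:
        """Trace length in seconds (baseline plus all cycles)."""
        return self.baseline_duration + self.n_cycles * self.period

    @property
    def injection_start_times(self) -> tuple[float, ...]:
        return tuple(
            self.baseline_duration + i * self.period for i in range(self.n_cycles)
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    def times(self) -> np.ndarray:
        """Sampling instants on the half-open interval [0, total_duration)."""
        return np.arange(self.n_samples) / self.sampling_rate
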