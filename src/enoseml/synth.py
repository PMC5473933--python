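"""Synthetic sensor-array responses with first-order sorption kinetics.

The raw traces behind the alcohol-content study were never deposited, so
this module generates response collections with the same statistical
structure: each channel's noiseless response is a sum of independent
first-order sorption relaxations, one per headspace component,

    injection:  ds_j/dt = (S_mj * c_j - s_j) / tau_ads_mj
    purge:      ds_j/dt = -s_j / tau_des_mj

evaluated in closed form on the sampling grid, plus linear drift and
i.i.d. Gaussian noise; the first two cycles are scaled by an instability
factor emulating the initial fluctuation of a fresh measurement.

The default component library is ethanol, water and six "flavor"
components whose concentrations vary between samples of equal alcohol
content — this is what makes single-parameter prediction fail and what the
kernel regression has to see through.  Ethanol concentration equals the
alcohol content in vol %; water activity is nearly flat in alcohol content
with per-vial jitter.  Hydrophobic channel archetypes (C18-like,
phenyl-like) have ethanol-to-water sensitivity ratio > 1, hydrophilic ones
(aminopropyl-like, vinyl-like) < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import AcquisitionSchedule
from .signals import ResponseSignal

#: Component library: ethanol and water first, then flavor components.
COMPONENTS = (
    "ethanol",
    "water",
    "flavor1",
    "flavor2",
    "flavor3",
    "flavor4",
    "flavor5",
    "flavor6",
)
N_COMPONENTS = len(COMPONENTS)

#: (name, alcohol vol %) of the 26 named liquids.
NAMED_LIQUIDS: tuple[tuple[str, float], ...] = (
    ("ultrapure water", 0.0),
    ("bottled water", 0.0),
    ("tap water", 0.0),
    ("PBS", 0.0),
    ("green tea", 0.0),
    ("oolong tea", 0.0),
    ("shochu and green tea", 4.0),
    ("beer", 5.0),
    ("shochu and oolong tea", 6.0),
    ("sangria", 9.0),
    ("ume-shu", 12.0),
    ("red wine", 12.0),
    ("junmai ryori-shu", 14.0),
    ("mirin", 14.5),
    ("Japanese sake", 15.0),
    ("shoko-shu", 17.5),
    ("mugi-shochu", 20.0),
    ("cassis liqueur", 20.0),
    ("plant worm-shochu", 25.0),
    ("imo-shochu", 25.0),
    ("vodka", 40.0),
    ("gin", 40.0),
    ("palinka", 40.0),
    ("rum", 40.0),
    ("brandy", 40.0),
    ("whisky", 40.0),
)

#: water/EtOH volume ratios of the 9 calibration mixtures.
MIXTURE_RATIOS: tuple[tuple[int, int], ...] = (
    (95, 5), (90, 10), (85, 15), (80, 20), (75, 25),
    (70, 30), (65, 35), (60, 40), (55, 45),
)

#: Samples held out as "unknown liquors".
UNKNOWN_SAMPLES = ("red wine", "imo-shochu", "whisky")

# Composition model constants (arbitrary units; ethanol a.u. == vol %).
_WATER_BASE = 100.0
_WATER_ALC_SLOPE = 0.3     # weak decrease of water activity with alcohol
_WATER_JITTER = 10.0       # per-vial uniform jitter half-width
_FLAVOR_LOG_MEAN = np.log(3.0)
_FLAVOR_LOG_SD = 0.8


@dataclass
class SampleSpec:
    """One liquid sample: identity, alcohol content and headspace makeup."""

    name: str
    alcohol_content: float
    component_concentrations: np.ndarray
    known: bool = True

    def __post_init__(self) -> None:
        self.component_concentrations = np.asarray(
            self.component_concentrations, dtype=float
        )
        if not 0.0 <= self.alcohol_content <= 100.0:
            raise ValueError("alcohol_content must be in [0, 100] vol %")
        if self.component_concentrations.shape != (N_COMPONENTS,):
            raise ValueError(
                f"component_concentrations must have length {N_COMPONENTS}"
            )
        if np.any(self.component_concentrations < 0):
            raise ValueError("component concentrations must be nonnegative")


@dataclass
class ChannelModel:
    """Sensing characteristics of one coated channel.

    ``sensitivity`` maps component concentration (a.u.) to signal (mV);
    ``tau_ads`` / ``tau_des`` are per-component sorption/desorption time
    constants in seconds.
    """

    name: str
    sensitivity: np.ndarray
    tau_ads: np.ndarray
    tau_des: np.ndarray
    noise_sd: float = 0.05
    drift_rate: float = 0.002
    instability_factor: float = 0.9

    def __post_init__(self) -> None:
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.tau_ads = np.asarray(self.tau_ads, dtype=float)
        self.tau_des = np.asarray(self.tau_des, dtype=float)
        for arr, what in [
            (self.sensitivity, "sensitivity"),
            (self.tau_ads, "tau_ads"),
            (self.tau_des, "tau_des"),
        ]:
            if arr.shape != (N_COMPONENTS,):
                raise ValueError(f"{what} must have length {N_COMPONENTS}")
        if np.any(self.tau_ads <= 0) or np.any(self.tau_des <= 0):
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def hydrophobic(self) -> bool:
        """Ethanol-to-water sensitivity ratio above 1."""
        return self.sensitivity[0] > self.sensitivity[1]


@dataclass
class GeneratorConfig:
    """Everything needed to reproduce one synthetic dataset."""

    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    channels: list[ChannelModel] = field(default_factory=lambda: default_channels())
    samples: list[SampleSpec] = field(default_factory=list)
    seed: int = 0


def build_default_sample_table(seed: int = 0) -> list[SampleSpec]:
    """The 35-sample study set: 26 named liquids + 9 water/EtOH mixtures.

    Named liquids carry a sample-specific log-normal flavor background
    (so equal-alcohol liquors still smell different); the water/EtOH
    mixtures carry none.  Red wine, imo-shochu and whisky are flagged as
    held-out unknowns.  ``seed`` fixes the composition draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A11]))
    specs: list[SampleSpec] = []

    def water_conc(alcohol: float) -> float:
        jitter = rng.uniform(-_WATER_JITTER, _WATER_JITTER)
        return max(0.0, _WATER_BASE - _WATER_ALC_SLOPE * alcohol + jitter)

    for name, alcohol in NAMED_LIQUIDS:
        conc = np.zeros(N_COMPONENTS)
        conc[0] = alcohol
        conc[1] = water_conc(alcohol)
        conc[2:] = rng.lognormal(_FLAVOR_LOG_MEAN, _FLAVOR_LOG_SD, N_COMPONENTS - 2)
        specs.append(
            SampleSpec(
                name=name,
                alcohol_content=alcohol,
                component_concentrations=conc,
                known=name not in UNKNOWN_SAMPLES,
            )
        )
    for water, etoh in MIXTURE_RATIOS:
        alcohol = float(etoh)
        conc = np.zeros(N_COMPONENTS)
        conc[0] = alcohol
        conc[1] = water_conc(alcohol)
        specs.append(
            SampleSpec(
                name=f"water/EtOH {water}/{etoh}",
                alcohol_content=alcohol,
                component_concentrations=conc,
                known=True,
            )
        )
    return specs


def default_channels() -> list[ChannelModel]:
    """Four nanoparticle-coating archetypes: two hydrophobic, two hydrophilic.

    Sorption is fast for ethanol/water (sub-second) and slower for the
    heavier flavor components; desorption is retarded relative to sorption,
    emulating porous-coating hysteresis.  With these kinetics the
    quasi-equilibrium slope (parameter 2) carries essentially no ethanol
    information while the rise slope, decay slope and peak height do.
    """
    tau_ads = np.array([0.2, 0.2, 1.2, 0.9, 1.5, 1.0, 1.3, 0.8])
    tau_des = np.array([2.0, 1.8, 4.5, 3.8, 5.0, 4.2, 4.8, 3.5])
    flavors_hb1 = [0.06, 0.03, 0.05, 0.04, 0.07, 0.05]
    flavors_hb2 = [0.05, 0.06, 0.03, 0.05, 0.04, 0.06]
    flavors_hl1 = [0.12, 0.15, 0.10, 0.14, 0.11, 0.13]
    flavors_hl2 = [0.10, 0.12, 0.13, 0.09, 0.12, 0.10]
    return [
        ChannelModel("C18-like", np.array([0.50, 0.05, *flavors_hb1]),
                     tau_ads, tau_des),
        ChannelModel("Phenyl-like", np.array([0.40, 0.06, *flavors_hb2]),
                     tau_ads * 1.1, tau_des * 0.9),
        ChannelModel("Aminopropyl-like", np.array([0.06, 0.50, *flavors_hl1]),
                     tau_ads * 0.9, tau_des * 1.1),
        ChannelModel("Vinyl-like", np.array([0.10, 0.35, *flavors_hl2]),
                     tau_ads, tau_des),
    ]


HYDROPHOBIC_CHANNELS = ("C18-like", "Phenyl-like")
HYDROPHILIC_CHANNELS = ("Aminopropyl-like", "Vinyl-like")


def default_config(seed: int = 0) -> GeneratorConfig:
    """Default study conditions: 35 samples x 4 archetype channels."""
    return GeneratorConfig(
        schedule=AcquisitionSchedule(),
        channels=default_channels(),
        samples=build_default_sample_table(seed=seed),
        seed=int(seed),
    )


def _component_trace(
    times: np.ndarray,
    schedule: AcquisitionSchedule,
    amplitude: float,
    tau_a: float,
    tau_d: float,
    steady_from_cycle: int = 2,
) -> np.ndarray:
    """Closed-form piecewise-exponential relaxation of one component.

    The state at the start of ``steady_from_cycle`` (0-based) is set to the
    exact fixed point of the per-cycle affine map, so all later cycles are
    strictly periodic regardless of the time constants; the preceding
    cycles carry the natural adsorption transient.
    """
    out = np.zeros_like(times)
    if amplitude == 0.0:
        return out
    e_a = np.exp(-schedule.inject_duration / tau_a)
    e_d = np.exp(-schedule.purge_duration / tau_d)
    # fixed point of s -> (A(1-e_a) + s e_a) e_d  (state at cycle start)
    s_star = amplitude * (1.0 - e_a) * e_d / (1.0 - e_a * e_d)
    state = 0.0
    for k, t0 in enumerate(schedule.injection_start_times):
        if k == steady_from_cycle:
            state = s_star
        # injection segment [t0, t0 + Ti)
        t1 = t0 + schedule.inject_duration
        m = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
        out[m] = amplitude + (state - amplitude) * np.exp(-(times[m] - t0) / tau_a)
        state = amplitude + (state - amplitude) * e_a
        # purge segment [t1, t1 + Tp)
        t2 = t1 + schedule.purge_duration
        m = (times >= t1 - 1e-12) & (times < t2 - 1e-12)
        out[m] = state * np.exp(-(times[m] - t1) / tau_d)
        state = state * e_d
    return out


def simulate_response(
    sample: SampleSpec,
    channel: ChannelModel,
    schedule: AcquisitionSchedule,
    seed: int | np.random.SeedSequence = 0,
) -> ResponseSignal:
    """Simulate one channel's trace for one sample.

    The noiseless trace is the sum of the per-component relaxations, the
    first two cycles scaled by the channel's instability factor; linear
    drift and i.i.d. Gaussian noise are added on top.
    """
    times = schedule.times()
    clean = np.zeros_like(times)
    amplitudes = channel.sensitivity * sample.component_concentrations
    for j in range(N_COMPONENTS):
        clean += _component_trace(
            times, schedule, amplitudes[j], channel.tau_ads[j], channel.tau_des[j]
        )
    if channel.instability_factor != 1.0 and schedule.n_cycles >= 1:
        t0 = schedule.injection_start_times[0]
        n_unstable = min(2, schedule.n_cycles)
        t_end = t0 + n_unstable * schedule.period
        m = (times >= t0 - 1e-12) & (times < t_end - 1e-12)
        clean[m] *= channel.instability_factor

    rng = np.random.default_rng(seed)
    values = clean + channel.drift_rate * times
    if channel.noise_sd > 0:
        values = values + rng.normal(0.0, channel.noise_sd, size=len(times))
    return ResponseSignal(
        channel_name=channel.name,
        sample_name=sample.name,
        times=times,
        values=values,
        schedule=schedule,
    )


def simulate_dataset(
    config: GeneratorConfig,
) -> tuple[list[ResponseSignal], pd.DataFrame]:
    """Simulate one trace per (sample, channel) plus a metadata table.

    Deterministic under a fixed config: per-signal noise streams are
    spawned from the config seed, so the trace of a given (sample,
    channel) does not depend on the others.
    """
    names = [s.name for s in config.samples]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sample names: {dupes}")
    root = np.random.SeedSequence([int(config.seed), 0x51D])
    children = iter(root.spawn(len(config.samples) * len(config.channels)))
    signals = [
        simulate_response(sample, channel, config.schedule, seed=next(children))
        for sample in config.samples
        for channel in config.channels
    ]
    metadata = pd.DataFrame(
        {
            "sample": names,
            "alcohol_content": [s.alcohol_content for s in config.samples],
            "known": [s.known for s in config.samples],
        }
    )
    return signals, metadata
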