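"""Simulation configuration.

One global seed; each generator draws from an independent named substream so
identical (seed, config) always reproduces identical output regardless of
which generators run or in what order.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "FragmentationParams",
    "QpcrParams",
    "GrowthParams",
    "TracePeak",
    "TraceParams",
    "LuciferaseParams",
    "FlowParams",
    "SimulationConfig",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class FragmentationParams:
    """Alkaline fragmentation + size selection model."""

    n_molecules: int = 50_000
    p_cleave: float = 0.05
    fragment_min: int = 20
    fragment_max: int = 40
    quality_char: str = "I"
    chunk_size: int = 2000

    def __post_init__(self) -> None:
        _check(self.n_molecules > 0, "n_molecules must be positive")
        _check(0 <= self.p_cleave <= 1, "p_cleave must be in [0, 1]")
        _check(1 <= self.fragment_min <= self.fragment_max,
               "need 1 <= fragment_min <= fragment_max")
        _check(len(self.quality_char) == 1, "quality_char must be one character")


@dataclass
class QpcrParams:
    efficiency: float = 2.0          # per-cycle amplification factor E in (1, 2]
    noise_sd: float = 0.0            # Cq units
    cq_base: float = 20.0            # Cq of a unit-level template
    n_replicates: int = 3
    dropoff: float = 0.9             # low-dNTP RT drop-off probability per methylated site

    def __post_init__(self) -> None:
        _check(1 < self.efficiency <= 2, "qPCR efficiency must be in (1, 2]")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(0 <= self.dropoff <= 1, "dropoff must be in [0, 1]")


@dataclass
class GrowthParams:
    n0: float = 0.02                 # inoculum OD600
    carrying_capacity: float | None = None   # None -> pure exponential
    doubling_time: float = 90.0      # intrinsic T_d, minutes
    interval: float = 20.0           # sampling interval, minutes
    duration: float = 1200.0         # minutes
    noise_sd: float = 0.0            # sd of multiplicative log-normal noise

    def __post_init__(self) -> None:
        _check(self.n0 > 0, "n0 must be positive")
        _check(self.doubling_time > 0, "doubling_time must be positive")
        _check(self.interval > 0, "sampling interval must be positive")
        _check(self.duration >= self.interval, "duration must cover >= 1 interval")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        if self.carrying_capacity is not None:
            _check(math.isinf(self.carrying_capacity) or self.carrying_capacity > self.n0,
                   "carrying capacity must exceed n0")


@dataclass
class TracePeak:
    """One Gaussian peak of an A260 gradient trace.

    Specify either ``height`` or ``area`` (analytic area = height * width *
    sqrt(2*pi)).
    """

    center: float
    width: float
    height: float | None = None
    area: float | None = None
    label: str = "polysome"

    def __post_init__(self) -> None:
        _check(self.width > 0, "peak width must be positive")
        if self.area is None and self.height is None:
            raise ValueError("peak needs height or area")
        if self.height is None:
            self.height = self.area / (self.width * math.sqrt(2 * math.pi))
        if self.area is None:
            self.area = self.height * self.width * math.sqrt(2 * math.pi)


def _default_peaks() -> list[TracePeak]:
    return [
        TracePeak(center=1.5, width=0.12, area=0.5, label="40S"),
        TracePeak(center=2.5, width=0.12, area=0.7, label="60S"),
        TracePeak(center=3.5, width=0.12, area=3.0, label="80S"),
        TracePeak(center=5.0, width=0.12, area=1.2, label="polysome"),
        TracePeak(center=6.0, width=0.12, area=0.8, label="polysome"),
        TracePeak(center=7.0, width=0.12, area=0.5, label="polysome"),
    ]


@dataclass
class TraceParams:
    start: float = 0.0
    stop: float = 10.0
    step: float = 0.01
    baseline: float = 0.05
    noise_sd: float = 0.0
    peaks: list[TracePeak] = field(default_factory=_default_peaks)

    def __post_init__(self) -> None:
        _check(self.stop > self.start, "trace stop must exceed start")
        _check(self.step > 0, "trace step must be positive")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        self.peaks = [
            TracePeak(**p) if isinstance(p, dict) else p for p in self.peaks
        ]


@dataclass
class LuciferaseParams:
    cv: float = 0.1                  # multiplicative noise CV on each signal
    n_replicates: int = 6
    renilla_base: float = 1.0e5
    base_ratio: float = 2.0          # control-plasmid Firefly/Renilla ratio

    def __post_init__(self) -> None:
        _check(self.cv >= 0, "cv must be >= 0")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(self.renilla_base > 0 and self.base_ratio > 0,
               "luciferase baselines must be positive")


@dataclass
class FlowParams:
    median: float = 1000.0           # calibrator median intensity
    sigma: float = 0.5               # log-normal shape
    n_events: int = 50_000
    min_events: int = 50_000
    max_events: int = 100_000

    def __post_init__(self) -> None:
        _check(self.median > 0, "flow median must be positive")
        _check(self.sigma >= 0, "flow sigma must be >= 0")
        _check(self.n_events > 0, "n_events must be positive")
        _check(self.min_events <= self.max_events, "min_events must be <= max_events")


@dataclass
class SimulationConfig:
    seed: int = 0
    fragmentation: FragmentationParams = field(default_factory=FragmentationParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    trace: TraceParams = field(default_factory=TraceParams)
    luciferase: LuciferaseParams = field(default_factory=LuciferaseParams)
    flow: FlowParams = field(default_factory=FlowParams)

    _SECTIONS = {
        "fragmentation": FragmentationParams,
        "qpcr": QpcrParams,
        "growth": GrowthParams,
        "trace": TraceParams,
        "luciferase": LuciferaseParams,
        "flow": FlowParams,
    }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        kwargs: dict[str, Any] = {}
        d = dict(d)
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        for name, typ in cls._SECTIONS.items():
            if name in d:
                sect = d.pop(name)
                kwargs[name] = sect if isinstance(sect, typ) else typ(**sect)
        if d:
            raise ValueError(f"unknown config sections: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
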