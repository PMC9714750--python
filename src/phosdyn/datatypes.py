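"""Typed containers for decay traces, lifetime mixtures and transition parameters.

All containers are frozen-ish dataclasses with eager validation: invalid
physical values (non-positive lifetimes, negative counts, unsorted
temperature grids, ...) are rejected at construction time with a message
naming the violated precondition, so downstream numerics never see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Maximum number of discrete exponential components considered physical here.
N_MAX_COMPONENTS = 5


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class LifetimeMixture:
    """Discrete heterogeneous decay: amplitudes A_i >= 0 and lifetimes tau_i > 0 (ms).

    Canonical form keeps lifetimes strictly increasing; near-degenerate
    lifetimes (relative separation < 1e-6) are rejected because they make the
    amplitude split non-identifiable.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = _as_float_array(self.amplitudes, "amplitudes")
        self.lifetimes = _as_float_array(self.lifetimes, "lifetimes")
        if self.amplitudes.size == 0:
            raise ValueError("empty mixture: at least one component required")
        if self.amplitudes.size != self.lifetimes.size:
            raise ValueError("amplitudes and lifetimes must have equal length")
        if self.amplitudes.size > N_MAX_COMPONENTS:
            raise ValueError(
                f"at most {N_MAX_COMPONENTS} components supported, got {self.amplitudes.size}"
            )
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")
        if not np.any(self.amplitudes > 0):
            raise ValueError("all-zero amplitudes: at least one amplitude must be positive")
        if np.any(self.lifetimes <= 0):
            raise ValueError("nonpositive lifetime: all lifetimes must be > 0")
        order = np.argsort(self.lifetimes)
        self.amplitudes = self.amplitudes[order]
        self.lifetimes = self.lifetimes[order]
        if self.lifetimes.size > 1:
            rel_gap = np.diff(self.lifetimes) / self.lifetimes[:-1]
            if np.any(rel_gap < 1e-6):
                raise ValueError("lifetimes closer than relative 1e-6 are degenerate")

    @property
    def n(self) -> int:
        return int(self.amplitudes.size)

    def scaled(self, factor: float) -> "LifetimeMixture":
        """All lifetimes multiplied by ``factor`` (amplitudes untouched)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return LifetimeMixture(self.amplitudes.copy(), self.lifetimes * factor)


@dataclass
class DecayTrace:
    """Binned photon-count time series at one temperature.

    ``times`` are bin-start times in ms on a uniform grid; ``counts`` are the
    (nonnegative, possibly non-integer for noiseless traces) counts per bin.
    """

    times: np.ndarray
    counts: np.ndarray
    temperature: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.counts = _as_float_array(self.counts, "counts")
        if self.times.size != self.counts.size:
            raise ValueError("times and counts must have equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two bins")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("non-uniform binning: bin spacing must be constant")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_bins(self) -> int:
        return int(self.times.size)


@dataclass
class DecayFitResult:
    """Outcome of a multi-exponential decay fit."""

    mixture: LifetimeMixture
    background: float
    reduced_chi2: float
    tau_avg: float
    n_tried: list[int]
    selection_trace: list[dict[str, float]]
    converged: bool

    def __post_init__(self) -> None:
        if self.reduced_chi2 < 0:
            raise ValueError("reduced chi-square must be nonnegative")
        if self.background < 0:
            raise ValueError("background must be nonnegative")


@dataclass
class TwoStateParams:
    """Two-state (frozen/molten) activation parameters.

    delta_E : molar energy difference, kJ/mol (> 0)
    delta_S : molar entropy difference, J/(mol K) (> 0)
    K_d     : dimensionless speed-up of the decay under dynamic quenching (>= 1)
    tau0    : frozen-state reference ensemble-average lifetime, ms (> 0)
    """

    delta_E: float
    delta_S: float
    K_d: float
    tau0: float

    def __post_init__(self) -> None:
        if not self.delta_E > 0:
            raise ValueError("delta_E must be > 0 (kJ/mol)")
        if not self.delta_S > 0:
            raise ValueError("delta_S must be > 0 (J/(mol K))")
        if not self.K_d >= 1:
            raise ValueError("K_d must be >= 1")
        if not self.tau0 > 0:
            raise ValueError("tau0 must be > 0 (ms)")
        denom = self.delta_S + R_GAS * np.log(self.K_d)
        if not denom > 0:
            raise ValueError("midpoint temperature non-identifiable: dS + R ln K_d <= 0")


@dataclass
class TemperatureSeries:
    """Per-temperature ensemble-average lifetimes and/or normalized ratios.

    At least one of ``tau_avg`` (ms) and ``ratio`` (dimensionless, tau/tau0)
    must be present. If both are present together with a ``tau0`` entry in
    provenance, they must be mutually consistent.
    """

    temperatures: np.ndarray
    tau_avg: np.ndarray | None = None
    ratio: np.ndarray | None = None
    sd: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_float_array(self.temperatures, "temperatures")
        if self.temperatures.size == 0:
            raise ValueError("empty temperature list")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be > 0 K")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        n = self.temperatures.size
        for name in ("tau_avg", "ratio", "sd"):
            val = getattr(self, name)
            if val is not None:
                val = _as_float_array(val, name)
                if val.size != n:
                    raise ValueError(f"{name} length must match temperatures")
                setattr(self, name, val)
        if self.tau_avg is None and self.ratio is None:
            raise ValueError("series needs at least one of tau_avg / ratio")
        tau0 = self.provenance.get("tau0_ms")
        if self.tau_avg is not None and self.ratio is not None and tau0 is not None:
            if not np.allclose(self.ratio * tau0, self.tau_avg, rtol=1e-9, atol=0.0):
                raise ValueError("ratio * tau0 inconsistent with tau_avg")

    @property
    def n_points(self) -> int:
        return int(self.temperatures.size)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.temperatures >= lo) & (self.temperatures <= hi)

    def with_ratio(self, ratio: np.ndarray, tau0: float | None = None,
                   sd: np.ndarray | None = None) -> "TemperatureSeries":
        prov = dict(self.provenance)
        if tau0 is not None:
            prov["tau0_ms"] = float(tau0)
        return replace(self, ratio=ratio, sd=self.sd if sd is None else sd,
                       provenance=prov)


@dataclass
class RoiConfig:
    """Baseline and transition-fit temperature windows, K.

    Defaults: the frozen plateau 10-180 K defines the normalisation baseline;
    the protein-specific activation step is fitted over 180-245 K, which stops
    short of the higher-temperature solvent step.
    """

    baseline_window: tuple[float, float] = (10.0, 180.0)
    fit_window: tuple[float, float] = (180.0, 245.0)

    def __post_init__(self) -> None:
        b_lo, b_hi = self.baseline_window
        f_lo, f_hi = self.fit_window
        if not b_lo < b_hi:
            raise ValueError("baseline_window must satisfy T_lo < T_hi")
        if not f_lo < f_hi:
            raise ValueError("fit_window must satisfy T_lo < T_hi")
        if f_lo < b_hi:
            raise ValueError("fit_window must start at or above the baseline window end")


@dataclass
class TransitionFitResult:
    """Fitted two-state parameters with uncertainties and diagnostics."""

    params: TwoStateParams
    sd: dict[str, float]
    T_MP: float
    T_MP_sd: float
    reduced_chi2: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    method_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.sd.items():
            if val < 0:
                raise ValueError(f"standard deviation for {key} must be >= 0")
        denom = self.params.delta_S + R_GAS * np.log(self.params.K_d)
        t_mp = self.params.delta_E * 1000.0 / denom
        if not np.isclose(self.T_MP, t_mp, rtol=1e-9, atol=0.0):
            raise ValueError("stored T_MP inconsistent with the midpoint relation")
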