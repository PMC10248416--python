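"""Acquisition protocol: b-value scheme, signal averages and diffusion gradient timing.

b-values are exposed in the conventional scanner units of s/mm² and converted
internally to ms/μm² (``b' = b / 1000``) so that ``b'·D`` is dimensionless with
diffusivities in μm²/ms, matching the parameter units the study reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DomainError, TimingError

#: conversion from s/mm² to ms/μm²
B_INTERNAL_SCALE = 1.0e-3

#: proton gyromagnetic ratio, rad · ms⁻¹ · mT⁻¹
GAMMA_PROTON = 267.513

DEFAULT_B_VALUES = (0.0, 200.0, 600.0, 1000.0, 2000.0, 3000.0)
DEFAULT_AVERAGES = (1, 1, 1, 2, 4, 6)
DEFAULT_MONO_B_SUBSET = (0.0, 600.0, 1000.0)


def b_internal(b_s_per_mm2):
    """Convert b from s/mm² to the internal ms/μm² scale."""
    return np.asarray(b_s_per_mm2, dtype=float) * B_INTERNAL_SCALE


@dataclass(frozen=True)
class GradientTiming:
    """Diffusion gradient timing for the fractional-order-calculus model.

    Parameters
    ----------
    gamma : float
        Gyromagnetic ratio in rad·ms⁻¹·mT⁻¹.
    big_delta : float
        Gradient lobe separation Δ in ms.
    small_delta : float
        Diffusion gradient pulse width δ in ms.

    The diffusion gradient amplitude G_d (mT/μm) is not stored: it is derived
    per b-value from ``b' = (γ G_d δ)² (Δ − δ/3)``.
    """

    gamma: float = GAMMA_PROTON
    big_delta: float = 30.0
    small_delta: float = 15.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise TimingError("gamma must be positive")
        if not (self.big_delta > self.small_delta > 0):
            raise TimingError("need big_delta > small_delta > 0")

    @property
    def effective_diffusion_time(self) -> float:
        """Δ − δ/3 in ms."""
        return self.big_delta - self.small_delta / 3.0

    def gradient_amplitude(self, b_s_per_mm2):
        """Back-solve G_d (mT/μm) from a b-value in s/mm².

        Inverts ``b' = (γ G_d δ)² (Δ − δ/3)``; round-trips through
        :meth:`b_value` to 1e-9 relative.
        """
        b = np.asarray(b_s_per_mm2, dtype=float)
        if np.any(b < 0):
            raise DomainError("b must be non-negative")
        td = self.effective_diffusion_time
        if td <= 0:
            raise TimingError("big_delta must exceed small_delta/3")
        return np.sqrt(b * B_INTERNAL_SCALE / td) / (self.gamma * self.small_delta)

    def b_value(self, g_d):
        """Forward b (s/mm²) from a gradient amplitude in mT/μm."""
        g = np.asarray(g_d, dtype=float)
        b_int = (self.gamma * g * self.small_delta) ** 2 * self.effective_diffusion_time
        return b_int / B_INTERNAL_SCALE


@dataclass(frozen=True)
class AcquisitionProtocol:
    """The multi-b DWI scheme: b-values, per-b averages, mono-fit subset, timing.

    Defaults reproduce the study protocol: b = 0, 200, 600, 1000, 2000,
    3000 s/mm² with 1, 1, 1, 2, 4, 6 averages, and ADC fitted on b = 0, 600,
    1000 only.
    """

    b_values: tuple = DEFAULT_B_VALUES
    averages: tuple = DEFAULT_AVERAGES
    mono_b_subset: tuple = DEFAULT_MONO_B_SUBSET
    timing: GradientTiming = field(default_factory=GradientTiming)

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or b[0] != 0:
            raise ConfigError("b_values must start at 0 and contain >= 2 values")
        if np.any(np.diff(b) <= 0) or np.any(b < 0):
            raise ConfigError("b_values must be strictly increasing and non-negative")
        av = np.asarray(self.averages)
        if av.size != b.size:
            raise ConfigError("averages must have one entry per b-value")
        if np.any(av <= 0) or not np.issubdtype(av.dtype, np.integer):
            raise ConfigError("averages must be positive integers")
        if not set(map(float, self.mono_b_subset)) <= set(map(float, self.b_values)):
            raise ConfigError("mono_b_subset must be a subset of b_values")

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    def mono_indices(self):
        """Indices of the b-values used for the monoexponential (ADC) fit."""
        subset = set(map(float, self.mono_b_subset))
        return [i for i, b in enumerate(self.b_values) if float(b) in subset]

    def weights(self):
        """Least-squares weights proportional to the per-b number of averages."""
        return np.asarray(self.averages, dtype=float)
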