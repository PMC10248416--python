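"""Synthetic cohort and phantom generation.

The study measured two things that this module emulates so the downstream
statistics are testable without patient data:

* patient-level marker tables — 11 diffusion markers for 46 VETC-negative and
  40 VETC-positive hepatocellular carcinomas, drawn from truncated normals
  with the published per-group means/SDs, read by two simulated raters;
* voxel-level 4D DWI phantoms — a lesion embedded in background tissue,
  signals generated from any of the five models with Rician noise and the
  protocol's per-b signal averaging, plus two slightly different lesion masks
  standing in for independent manual delineation by two radiologists.

Only the published marginal means/SDs are known; markers default to
independent draws (a correlation matrix hook exists but the true joint
distribution is unknowable from group summaries).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import DwiVolume, VoiMask
from .exceptions import ConfigError, GeometryError
from .models import ModelParams, signal
from .protocol import AcquisitionProtocol

__all__ = [
    "GROUP_DISTRIBUTIONS",
    "MARKER_TRUNCATION",
    "CohortConfig",
    "PatientRecord",
    "PhantomSpec",
    "sample_patients",
    "cohort_frame",
    "generate_phantom",
]

#: published per-group marker distributions: marker -> (negative mean, SD,
#: positive mean, SD). Diffusivities in μm²/ms, FROC_mu in μm.
GROUP_DISTRIBUTIONS: Dict[str, Tuple[float, float, float, float]] = {
    "ADC": (1.05, 0.18, 1.03, 0.19),
    "DKI_D": (1.49, 0.35, 1.49, 0.33),
    "DKI_K": (0.55, 0.08, 0.61, 0.09),
    "SEM_DDC": (1.65, 0.52, 1.51, 0.48),
    "SEM_alpha": (0.55, 0.14, 0.58, 0.12),
    "FROC_D": (1.01, 0.22, 0.99, 0.21),
    "FROC_beta": (0.67, 0.12, 0.66, 0.10),
    "FROC_mu": (3.48, 0.54, 3.66, 0.34),
    "CTRW_D": (1.31, 0.27, 1.27, 0.27),
    "CTRW_alpha": (0.87, 0.07, 0.91, 0.04),
    "CTRW_beta": (0.65, 0.13, 0.64, 0.12),
}

#: physical truncation bounds per marker (the fitting bounds)
MARKER_TRUNCATION: Dict[str, Tuple[float, float]] = {
    "ADC": (0.01, 5.0),
    "DKI_D": (0.01, 5.0),
    "DKI_K": (0.0, 3.0),
    "SEM_DDC": (0.01, 5.0),
    "SEM_alpha": (0.1, 1.0),
    "FROC_D": (0.01, 5.0),
    "FROC_beta": (0.1, 1.0),
    "FROC_mu": (0.5, 20.0),
    "CTRW_D": (0.01, 5.0),
    "CTRW_alpha": (0.1, 1.0),
    "CTRW_beta": (0.1, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Sampling configuration for the patient-level synthetic cohort.

    rater_noise_scale is the SD of the additive rater-2 measurement error as
    a fraction of the marker's group SD; 0 makes the raters identical (and
    downstream ICC exactly 1).
    """

    n_negative: int = 46
    n_positive: int = 40
    distributions: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(GROUP_DISTRIBUTIONS)
    )
    truncation: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(MARKER_TRUNCATION)
    )
    correlation: Optional[np.ndarray] = None
    rater_noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_negative <= 0 or self.n_positive <= 0:
            raise ConfigError("group sizes must be positive")
        for m, (m0, s0, m1, s1) in self.distributions.items():
            if s0 <= 0 or s1 <= 0:
                raise ConfigError(f"SDs must be positive ({m})")
        if self.rater_noise_scale < 0:
            raise ConfigError("rater_noise_scale must be >= 0")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(self.distributions)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ConfigError("correlation must be a symmetric k x k matrix")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ConfigError("correlation matrix must be positive definite")


@dataclass
class PatientRecord:
    """One simulated patient: group label and 11 markers per rater."""

    id: str
    vetc_status: str  # "positive" | "negative"
    markers_rater1: Dict[str, float]
    markers_rater2: Dict[str, float]

    @property
    def markers_mean(self) -> Dict[str, float]:
        return {
            m: 0.5 * (self.markers_rater1[m] + self.markers_rater2[m])
            for m in self.markers_rater1
        }


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling; resamples only the out-of-bounds draws."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _correlated_truncated(rng, means, sds, los, his, corr, n):
    """Gaussian copula-ish draw: correlated normals, rows rejected out of bounds."""
    chol = np.linalg.cholesky(corr)
    out = np.empty((n, len(means)))
    filled = 0
    while filled < n:
        m = n - filled
        z = rng.standard_normal((m, len(means))) @ chol.T
        x = means + sds * z
        ok = np.all((x >= los) & (x <= his), axis=1)
        k = int(ok.sum())
        out[filled:filled + k] = x[ok]
        filled += k
    return out


def sample_patients(config: CohortConfig,
                    rng: Optional[np.random.Generator] = None) -> List[PatientRecord]:
    """Draw a full synthetic cohort; reproducible for a fixed config.seed.

    Rater-1 values are the latent truncated-normal draws; rater-2 values add
    independent zero-mean noise (re-truncated to the physical bounds),
    emulating a second independent VOI delineation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers = list(config.distributions)
    records: List[PatientRecord] = []
    for status, n, mcol in (("negative", config.n_negative, 0),
                            ("positive", config.n_positive, 2)):
        means = np.array([config.distributions[m][mcol] for m in markers])
        sds = np.array([config.distributions[m][mcol + 1] for m in markers])
        los = np.array([config.truncation[m][0] for m in markers])
        his = np.array([config.truncation[m][1] for m in markers])
        if config.correlation is None:
            r1 = np.column_stack([
                _truncated_normal(rng, means[j], sds[j], los[j], his[j], n)
                for j in range(len(markers))
            ])
        else:
            r1 = _correlated_truncated(rng, means, sds, los, his,
                                       np.asarray(config.correlation), n)
        noise = rng.normal(0.0, 1.0, r1.shape) * (config.rater_noise_scale * sds)
        r2 = np.clip(r1 + noise, los, his)
        for i in range(n):
            records.append(PatientRecord(
                id=f"{status[:3]}-{i + 1:03d}",
                vetc_status=status,
                markers_rater1=dict(zip(markers, r1[i])),
                markers_rater2=dict(zip(markers, r2[i])),
            ))
    return records


def cohort_frame(records: List[PatientRecord]) -> pd.DataFrame:
    """Flatten records to a table: one row per patient, rater-suffixed columns."""
    rows = []
    for r in records:
        row = {"id": r.id, "vetc_status": r.vetc_status}
        for m, v in r.markers_rater1.items():
            row[f"{m}_r1"] = v
        for m, v in r.markers_rater2.items():
            row[f"{m}_r2"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, generating models and noise for a 4D DWI phantom.

    noise_sigma is the Rician channel SD as a fraction of the lesion s0;
    per-b, each stored voxel value is the mean of ``averages[b]`` independent
    magnitude draws sqrt((S + ε₁)² + ε₂²), ε ~ N(0, σ·s0).
    """

    shape: Tuple[int, int, int] = (12, 12, 4)
    lesion_center: Tuple[float, float, float] = (5.5, 5.5, 1.5)
    lesion_radii: Tuple[float, float, float] = (3.5, 3.5, 1.2)
    lesion_params: ModelParams = field(default_factory=lambda: ModelParams(
        "DKI", s0=1000.0, values={"D": 1.49, "K": 0.61}))
    background_params: ModelParams = field(default_factory=lambda: ModelParams(
        "MONO", s0=800.0, values={"ADC": 1.05}))
    noise_sigma: float = 0.01
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    rater2_flip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist <= 1.0


def _perturb_mask(mask: np.ndarray, flip_prob: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Second-rater mask: flip a seeded subset of inner/outer boundary voxels."""
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    out = mask.copy()
    out[inner & (rng.random(mask.shape) < flip_prob)] = False
    out[outer & (rng.random(mask.shape) < flip_prob)] = True
    if not out.any():
        out = mask.copy()
    return out


def generate_phantom(spec: PhantomSpec):
    """Build (DwiVolume, rater-1 VoiMask, rater-2 VoiMask) from a spec.

    Rater 1's mask is the exact lesion ellipsoid; rater 2's is a seeded
    boundary perturbation of it (dilated/eroded voxel pattern), emulating
    independent manual delineation.
    """
    lesion = _ellipsoid_mask(spec.shape, spec.lesion_center, spec.lesion_radii)
    if not lesion.any():
        raise GeometryError("lesion does not intersect the grid")

    proto = spec.protocol
    b = np.asarray(proto.b_values, dtype=float)
    rng = np.random.default_rng(spec.seed)

    true = np.empty(spec.shape + (proto.n_b,))
    sig_lesion = signal(spec.lesion_params, b, proto.timing)
    sig_bg = signal(spec.background_params, b, proto.timing)
    true[...] = sig_bg
    true[lesion, :] = sig_lesion

    sigma = spec.noise_sigma * spec.lesion_params.s0
    data = np.empty_like(true)
    if sigma == 0:
        data[...] = true
    else:
        for j, n_avg in enumerate(proto.averages):
            draws = np.empty(spec.shape + (int(n_avg),))
            for a in range(int(n_avg)):
                e1 = rng.normal(0.0, sigma, spec.shape)
                e2 = rng.normal(0.0, sigma, spec.shape)
                draws[..., a] = np.sqrt((true[..., j] + e1) ** 2 + e2 ** 2)
            data[..., j] = draws.mean(axis=-1)

    mask1 = VoiMask(lesion)
    mask2 = VoiMask(_perturb_mask(lesion, spec.rater2_flip_prob, rng))
    return DwiVolume(data=data, protocol=proto), mask1, mask2
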