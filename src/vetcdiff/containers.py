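"""In-memory containers for image-path data: 4D DWI volumes, VOI masks, maps."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, ConfigError
from .protocol import AcquisitionProtocol


@dataclass
class DwiVolume:
    """A 4D diffusion-weighted stack: one 3D volume per protocol b-value.

    ``data`` has shape (x, y, z, n_b) with the last axis ordered as
    ``protocol.b_values``.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ConfigError("DwiVolume data must be 4D (x, y, z, b)")
        if self.data.shape[-1] != self.protocol.n_b:
            raise AlignmentError(
                f"last axis ({self.data.shape[-1]}) must match the protocol's "
                f"{self.protocol.n_b} b-values"
            )

    @property
    def spatial_shape(self):
        return self.data.shape[:3]


@dataclass
class VoiMask:
    """A binary volume of interest on the same voxel grid as its DwiVolume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ConfigError("VoiMask data must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, volume: DwiVolume):
        if self.data.shape != volume.spatial_shape:
            raise AlignmentError(
                f"mask shape {self.data.shape} != volume grid {volume.spatial_shape}"
            )


@dataclass
class ParameterMap:
    """One fitted parametric map (e.g. DKI_K) on the source voxel grid.

    ``values`` is NaN outside ``mask``; ``converged`` marks voxels whose fit
    converged — non-converged voxels keep their value but are excluded from
    VOI summaries.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    converged: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.converged is None:
            self.converged = self.mask.copy()
        else:
            self.converged = np.asarray(self.converged).astype(bool)
        if not (self.values.shape == self.mask.shape == self.converged.shape):
            raise AlignmentError("values, mask and converged must share a grid")

    @property
    def n_fitted(self) -> int:
        return int(self.mask.sum())

    @property
    def n_converged(self) -> int:
        return int((self.mask & self.converged).sum())
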