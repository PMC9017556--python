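"""In-memory containers for image stacks and smoothing kernels.

Arrays are ordered ``(z, y, x)`` with 0-based indices and voxel-centered
coordinates; ``spacing`` is ``(dz, dy, dx)`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError

#: admissible intensity interpretations of a volume
VALUE_KINDS = ("ct_value", "gray8", "gray_float")


@dataclass
class ImageVolume:
    """A 2-D/3-D grayscale image with voxel spacing and value-range metadata.

    ``voxels`` is always stored 3-D with shape ``(nz, ny, nx)``; a single
    2-D slice is a volume with ``nz = 1`` (see :meth:`from_slice`).
    ``value_kind`` tags the intensity scale: raw CT values, quantized 8-bit
    gray, or floating-point gray in ``[0, 255]``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    value_kind: str = "gray_float"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InvalidParameterError(
                f"voxels must be a 2-D or 3-D array, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.value_kind not in VALUE_KINDS:
            raise InvalidParameterError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.value_kind == "gray8":
            v = self.voxels
            if v.size and (v.min() < 0 or v.max() > 255):
                raise InvalidParameterError("gray8 volume must lie within [0, 255]")

    @classmethod
    def from_slice(cls, image2d, spacing_yx=(1.0, 1.0), value_kind="gray_float"):
        """Wrap a single 2-D slice as a 1-slice volume."""
        dy, dx = spacing_yx
        return cls(np.asarray(image2d)[np.newaxis], (1.0, dy, dx), value_kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def nz(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels, value_kind=None, spacing=None) -> "ImageVolume":
        """Copy of this volume with new voxel data (metadata preserved)."""
        return replace(
            self,
            voxels=np.asarray(voxels),
            value_kind=value_kind or self.value_kind,
            spacing=spacing or self.spacing,
        )


@dataclass
class WindowSpec:
    """CT display window: center ``L`` and width ``W`` in CT-value units.

    The interval ``[L - W/2, L + W/2]`` is mapped linearly onto 8-bit gray.
    """

    L: float
    W: float

    def __post_init__(self):
        if self.W <= 0:
            raise InvalidParameterError(f"window width must be positive, got {self.W}")


@dataclass
class SmoothingKernel:
    """Square odd-sized array of non-negative weights for neighborhood averaging."""

    weights: np.ndarray = field(default_factory=lambda: np.ones((3, 3)))

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
            raise InvalidParameterError(f"kernel must be square and odd-sized, got {w.shape}")
        if (w < 0).any():
            raise InvalidParameterError("kernel weights must be non-negative")
        if not (w > 0).any():
            raise InvalidParameterError("kernel must have at least one positive weight")

    @property
    def half_width(self) -> int:
        return self.weights.shape[0] // 2

    @classmethod
    def uniform(cls, size: int = 3) -> "SmoothingKernel":
        return cls(np.ones((size, size)))
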