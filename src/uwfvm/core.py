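"""Core containers shared across the pipeline.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` pairs;
* grayscale images are 2-D numpy arrays, 8-bit by default (16-bit TIFF
  supported by :mod:`uwfvm.io`);
* binary vessel masks and skeletons are 2-D boolean arrays of the same
  shape as their source image;
* angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Severity vocabulary: healthy controls plus the five myopic-maculopathy
#: grades (no lesion, tessellated fundus, diffuse atrophy, patchy atrophy,
#: macular atrophy).
GRADES = ("HC", "C0", "C1", "C2", "C3", "C4")

#: The graded (non-control) arms in increasing severity order.
MYOPIA_GRADES = ("C0", "C1", "C2", "C3", "C4")


class UwfvmError(Exception):
    """Base class for package errors."""


class ImageFormatError(UwfvmError):
    """Raised when an on-disk image cannot be read or round-tripped."""


class MissingSidecarError(UwfvmError):
    """Raised when a landmark sidecar JSON is absent or malformed."""


@dataclass(frozen=True)
class Landmarks:
    """Macula and optic-disc centers plus the circular field of view.

    ``fov_radius`` is the radius (px) of the imaged disc around
    ``fov_center``; pixels outside it are the dark corners of an
    ultra-widefield frame and are excluded from every measurement.
    """

    disc_center: tuple[float, float]
    macula_center: tuple[float, float]
    fov_center: tuple[float, float]
    fov_radius: float

    def __post_init__(self) -> None:
        if tuple(self.disc_center) == tuple(self.macula_center):
            raise ValueError("disc_center and macula_center must differ")
        if self.fov_radius <= 0:
            raise ValueError("fov_radius must be positive")

    def fov_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the circular field of view for an image shape."""
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        r0, c0 = self.fov_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.fov_radius**2

    def to_dict(self) -> dict:
        return {
            "disc_center": [float(v) for v in self.disc_center],
            "macula_center": [float(v) for v in self.macula_center],
            "fov_center": [float(v) for v in self.fov_center],
            "fov_radius": float(self.fov_radius),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        return cls(
            disc_center=tuple(d["disc_center"]),
            macula_center=tuple(d["macula_center"]),
            fov_center=tuple(d["fov_center"]),
            fov_radius=float(d["fov_radius"]),
        )


@dataclass
class FundusImage:
    """A grayscale fundus frame with its landmarks and metadata.

    ``pixels`` emulates the green-laser channel of an ultra-widefield
    scanning-laser ophthalmoscope, chosen for its vessel/background
    contrast; corners outside the circular field of view are zero.
    """

    pixels: np.ndarray
    landmarks: Landmarks
    grade: Optional[str] = None
    eye_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}; expected one of {GRADES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def fov_mask(self) -> np.ndarray:
        return self.landmarks.fov_mask(self.pixels.shape)


def as_bool_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and coerce a binary mask to boolean."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)
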