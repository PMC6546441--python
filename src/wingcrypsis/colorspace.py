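"""Color-space primitives for wing colorimetry.

Scanned wing colors are compared in the CIE-xy chromaticity plane: linear
RGB is converted to CIE XYZ (sRGB primaries, D65 white, 2 degree observer),
then projected to chromaticity coordinates ``x = X/(X+Y+Z)``,
``y = Y/(X+Y+Z)``.  All pattern-element contrast and crypsis scores are
Euclidean distances in that (x, y) plane; relative luminance Y is carried
along but never enters a distance.

The primary matrix is an isolated module constant so a different scanner
characterisation can be substituted without touching callers.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SRGB_TO_XYZ",
    "D65_WHITE_XY",
    "ChromaticityPoint",
    "rgb_to_xyY",
    "hsb_to_rgb",
    "chromatic_distance",
]

# Linear sRGB -> CIE XYZ (D65 white point, 2 degree standard observer).
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Chromaticity of the D65 white point, i.e. of linear RGB (1, 1, 1).
_white_xyz = SRGB_TO_XYZ @ np.ones(3)
D65_WHITE_XY = (
    float(_white_xyz[0] / _white_xyz.sum()),
    float(_white_xyz[1] / _white_xyz.sum()),
)


@dataclass(frozen=True)
class ChromaticityPoint:
    """A color as CIE chromaticity (x, y) plus relative luminance Y.

    ``degenerate`` marks colors with X+Y+Z == 0 (pure black); by convention
    these carry the white-point chromaticity with Y = 0 and are excluded
    from crypsis-score means.
    """

    x: float
    y: float
    Y: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.x >= 0 and self.y >= 0 and self.x + self.y <= 1 + 1e-12):
            raise ValueError(f"invalid chromaticity ({self.x}, {self.y})")
        if self.Y < 0:
            raise ValueError("luminance Y must be non-negative")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def rgb_to_xyY(rgb) -> ChromaticityPoint:
    """Convert a linear RGB triple (components in [0, 1]) to CIE xyY.

    Black maps, by convention, to the white-point chromaticity with Y = 0
    and is flagged degenerate.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("expected an RGB triple")
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError(f"RGB components outside [0, 1]: {rgb}")
    xyz = SRGB_TO_XYZ @ rgb
    total = xyz.sum()
    if total <= 0:
        return ChromaticityPoint(*D65_WHITE_XY, Y=0.0, degenerate=True)
    return ChromaticityPoint(
        float(xyz[0] / total), float(xyz[1] / total), float(xyz[1])
    )


def hsb_to_rgb(h: float, s: float, b: float) -> np.ndarray:
    """Standard HSB/HSV -> RGB. Hue in degrees [0, 360); s, b in [0, 1].

    Used for the behavioral-assay reference patches, e.g. the brown patch
    HSB(25, 0.60, 0.50) -> RGB (0.500, 0.325, 0.200).  The result is taken
    to be on the linear scale of the pipeline.
    """
    if not (0 <= h < 360):
        raise ValueError("hue must be in [0, 360) degrees")
    if not (0 <= s <= 1 and 0 <= b <= 1):
        raise ValueError("saturation and brightness must be in [0, 1]")
    return np.array(colorsys.hsv_to_rgb(h / 360.0, s, b))


def chromatic_distance(a: ChromaticityPoint, b: ChromaticityPoint) -> float:
    """Euclidean distance between two colors in the CIE-xy plane (Y ignored)."""
    return float(np.hypot(a.x - b.x, a.y - b.y))
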