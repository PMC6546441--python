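"""Landmark transects and pattern-element color scores.

The ventral hindwing is scored along two contiguous transect segments
defined by five landmarks (the shared landmark sits at the eyespot
center).  At every pixel of the rasterized transect the unweighted mean
linear RGB of the 3x3 neighbourhood is recorded.  Half-open index
intervals on the transect label the wing background, the central band and
the three eyespot rings (outer ring, dark disc, pale focus).

Two scores are derived, both Euclidean distances in the CIE-xy plane:

* internal contrast — distance between an element's mean color and the
  wing-background mean color (conspicuousness proxy);
* crypsis score — mean distance of every transect sample to a reference
  patch chromaticity (inverse background-matching proxy).

Element means average RGB first and convert to chromaticity second
(robust near black); the alternative order is available via
``element_mean_colors(..., convert_first=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _raster_line

from .colorspace import ChromaticityPoint, chromatic_distance, rgb_to_xyY

ELEMENT_LABELS = (
    "wing_background",
    "central_band",
    "eyespot_outer_ring",
    "eyespot_dark_disc",
    "eyespot_focus",
)

__all__ = [
    "ELEMENT_LABELS",
    "LandmarkSet",
    "TransectProfile",
    "SegmentBoundaries",
    "ContrastScore",
    "CrypsisScore",
    "rasterize_transect",
    "sample_transect",
    "element_mean_colors",
    "internal_contrast",
    "crypsis_score",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Five (row, col) pixel landmarks, 0-based.

    Landmarks 0-2 bound the first transect segment (a polyline through
    points 0, 1, 2) and landmarks 2-4 the second; the two segments share
    exactly landmark 2.
    """

    points: tuple

    def __post_init__(self):
        pts = tuple((int(r), int(c)) for r, c in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) != 5:
            raise ValueError("exactly five landmarks required")
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise ValueError("consecutive landmarks must be distinct")


@dataclass
class TransectProfile:
    """Ordered transect samples: index, pixel coordinate, mean 3x3 linear RGB."""

    positions: np.ndarray  # (n,) strictly increasing sample indices
    coords: np.ndarray  # (n, 2) row/col of the transect pixel
    rgb: np.ndarray  # (n, 3) neighbourhood-mean linear RGB

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SegmentBoundaries:
    """Half-open [start, end) transect-index intervals per element label."""

    intervals: dict

    def validate(self, n_samples: int) -> None:
        seen = np.zeros(n_samples, dtype=int)
        for label, spans in self.intervals.items():
            if label not in ELEMENT_LABELS:
                raise ValueError(f"unknown element label {label!r}")
            total = 0
            for start, end in spans:
                if not (0 <= start < end <= n_samples):
                    raise ValueError(f"{label}: interval [{start}, {end}) outside transect")
                seen[start:end] += 1
                total += end - start
            if total == 0:
                raise ValueError(f"{label}: empty interval set")
        if np.any(seen > 1):
            raise ValueError("intervals of distinct labels overlap")

    def indices(self, label: str) -> np.ndarray:
        spans = self.intervals.get(label)
        if not spans:
            raise ValueError(f"no intervals for element {label!r}")
        return np.concatenate([np.arange(s, e) for s, e in spans])


@dataclass(frozen=True)
class ContrastScore:
    element: str
    distance: float


@dataclass(frozen=True)
class CrypsisScore:
    reference: ChromaticityPoint
    score: float
    n_samples: int


def rasterize_transect(landmarks: LandmarkSet) -> np.ndarray:
    """8-connected pixel chain through the five landmarks; each pixel once
    at polyline joints (the shared landmark is sampled a single time)."""
    pts = landmarks.points
    chain = []
    for a, b in zip(pts, pts[1:]):
        rr, cc = _raster_line(a[0], a[1], b[0], b[1])
        seg = np.column_stack([rr, cc])
        if chain:
            seg = seg[1:]  # joint pixel already emitted
        chain.append(seg)
    return np.concatenate(chain)


def sample_transect(image: np.ndarray, landmarks: LandmarkSet) -> TransectProfile:
    """Mean linear RGB of the 3x3 square centred on each transect pixel.

    The image must already be linearized, float in [0, 1]; every transect
    pixel must sit at least 1 px from the border so its window fits.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    coords = rasterize_transect(landmarks)
    h, w = image.shape[:2]
    if (
        coords[:, 0].min() < 1
        or coords[:, 1].min() < 1
        or coords[:, 0].max() > h - 2
        or coords[:, 1].max() > w - 2
    ):
        raise ValueError("transect runs within 1 px of the image border")
    rgb = np.empty((len(coords), 3))
    for i, (r, c) in enumerate(coords):
        rgb[i] = image[r - 1 : r + 2, c - 1 : c + 2].reshape(-1, 3).mean(axis=0)
    return TransectProfile(np.arange(len(coords)), coords, rgb)


def element_mean_colors(
    profile: TransectProfile,
    bounds: SegmentBoundaries,
    convert_first: bool = False,
) -> dict:
    """Per-element mean color as a ChromaticityPoint.

    Default order is mean-then-convert: average linear RGB over the
    element's interval(s), then convert to xyY.  ``convert_first`` instead
    averages per-sample chromaticities (excluding degenerate black).
    """
    bounds.validate(len(profile))
    out = {}
    for label, spans in bounds.intervals.items():
        idx = bounds.indices(label)
        if convert_first:
            pts = [rgb_to_xyY(profile.rgb[i]) for i in idx]
            ok = [p for p in pts if not p.degenerate]
            if not ok:
                raise ValueError(f"{label}: all samples degenerate")
            out[label] = ChromaticityPoint(
                float(np.mean([p.x for p in ok])),
                float(np.mean([p.y for p in ok])),
                float(np.mean([p.Y for p in pts])),
            )
        else:
            out[label] = rgb_to_xyY(profile.rgb[idx].mean(axis=0))
    return out


def internal_contrast(profile: TransectProfile, bounds: SegmentBoundaries) -> list:
    """Distance of each pattern element's mean color to the wing background's.

    One ContrastScore per labelled non-background element; requires a
    wing_background label.
    """
    if "wing_background" not in bounds.intervals:
        raise ValueError("wing_background must be labeled to compute contrast")
    means = element_mean_colors(profile, bounds)
    background = means["wing_background"]
    return [
        ContrastScore(label, chromatic_distance(means[label], background))
        for label in ELEMENT_LABELS
        if label != "wing_background" and label in means
    ]


def crypsis_score(profile: TransectProfile, reference: ChromaticityPoint) -> CrypsisScore:
    """Mean CIE-xy distance of every transect sample to a reference patch.

    Degenerate black samples (X+Y+Z = 0) are excluded from the mean.
    """
    if len(profile) == 0:
        raise ValueError("empty transect profile")
    pts = [rgb_to_xyY(c) for c in profile.rgb]
    usable = [p for p in pts if not p.degenerate]
    if not usable:
        raise ValueError("all transect samples are degenerate black")
    score = float(np.mean([chromatic_distance(p, reference) for p in usable]))
    return CrypsisScore(reference=reference, score=score, n_samples=len(usable))
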