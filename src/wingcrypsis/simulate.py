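"""Synthetic study data: wing images, behavioral cohorts, gray standards.

Raw images and observation tables for this assay design are not
available, so ground-truth substitutes are generated here with known
geometry, colors and effect sizes.

* Wing images are stylized: a uniform brown background field, a pale
  central band stripe, and a concentric eyespot (outer ring, dark disc,
  pale focus) centred on the transect.  Only colors along the landmark
  transect matter downstream, so morphological realism beyond
  landmark/boundary placement is deliberately not attempted.  Development
  at the cooler, dry-season temperature (Td = 19) yields smaller pattern
  elements with colors closer to the wing background and to the brown
  assay patch — the directions the real wings show.
* Cohort series emulate the behavioral assay: cohorts of 20 same-sex
  individuals photographed 15 times; arrivals to brown vs green follow a
  logit-linear model in Td, Ta and Sex with cohort and (crossed)
  time-point random intercepts, and relocation follows its own logit
  model.  Departure patches are drawn uniformly over perched individuals.
* Calibration standards follow a power-law scanner response
  ``raw = reflectance**(1/gamma) + noise`` clipped to [0, 1].

Everything is reproducible from the integer seeds carried in the
parameter objects; pixel noise is i.i.d. gaussian in linear RGB, clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.draw import disk as _disk

from .colorspace import rgb_to_xyY
from .transect import ELEMENT_LABELS, LandmarkSet, SegmentBoundaries, rasterize_transect

__all__ = [
    "WingSimParams",
    "AnnotatedWing",
    "CohortSimParams",
    "GeometryError",
    "generate_wing_image",
    "generate_cohort_series",
    "generate_calibration_standards",
    "derive_seeds",
]

LABEL_CODES = {label: i for i, label in enumerate(ELEMENT_LABELS)}


class GeometryError(ValueError):
    pass


def derive_seeds(master_seed: int, n: int) -> list:
    """Split one master seed into independent per-purpose substreams."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# wing images
# ---------------------------------------------------------------------------

# Default element colors (linear RGB) per developmental temperature.  The
# dry-season (Td=19) palette is constructed browner: every element sits
# closer in CIE-xy both to its own wing background and to the brown assay
# patch than its wet-season (Td=27) counterpart.
DEFAULT_COLORS = {
    19: {
        "wing_background": (0.340, 0.235, 0.130),
        "central_band": (0.520, 0.400, 0.260),
        "eyespot_outer_ring": (0.500, 0.370, 0.190),
        "eyespot_dark_disc": (0.150, 0.100, 0.060),
        "eyespot_focus": (0.520, 0.430, 0.310),
    },
    27: {
        "wing_background": (0.320, 0.220, 0.120),
        "central_band": (0.700, 0.620, 0.480),
        "eyespot_outer_ring": (0.780, 0.570, 0.130),
        "eyespot_dark_disc": (0.060, 0.045, 0.040),
        "eyespot_focus": (0.800, 0.790, 0.760),
    },
}

# radii in px: dry-season pattern elements are smaller
DEFAULT_RADII = {19: {"focus": 3, "disc": 6, "ring": 10}, 27: {"focus": 5, "disc": 10, "ring": 16}}


@dataclass
class WingSimParams:
    """Geometry, palette and noise of the stylized wing generator."""

    colors_by_Td: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COLORS.items()})
    radii_by_Td: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RADII.items()})
    band_width_px: int = 8
    pixel_noise_sd: float = 0.01
    image_size_px: tuple = (96, 128)
    seed: int = 0

    def __post_init__(self):
        for td, palette in self.colors_by_Td.items():
            for label, rgb in palette.items():
                pt = rgb_to_xyY(rgb)  # validates range and chromaticity
                if not (pt.x >= 0 and pt.y >= 0 and pt.x + pt.y <= 1):
                    raise ValueError(f"invalid chromaticity for {label} at Td={td}")
        for td, radii in self.radii_by_Td.items():
            if not (0 < radii["focus"] < radii["disc"] < radii["ring"]):
                raise ValueError(f"radii at Td={td} must satisfy 0 < focus < disc < ring")
        if all(td in self.radii_by_Td for td in (19, 27)):
            for part in ("focus", "disc", "ring"):
                if not self.radii_by_Td[19][part] < self.radii_by_Td[27][part]:
                    raise ValueError("Td=19 radii must be strictly smaller than Td=27 radii")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")


@dataclass
class AnnotatedWing:
    """A generated wing image plus its ground-truth annotation."""

    image: np.ndarray  # (H, W, 3) linear RGB in [0, 1]
    landmarks: LandmarkSet
    boundaries: SegmentBoundaries
    element_colors: dict  # label -> true linear RGB triple
    label_image: np.ndarray  # (H, W) int codes per LABEL_CODES
    Td: int
    sex: str


def _true_boundaries(label_image: np.ndarray, landmarks: LandmarkSet) -> SegmentBoundaries:
    """Interior intervals per element along the transect.

    A sample index belongs to an element only when its full 3x3
    neighbourhood lies inside that element, so neighbourhood means are
    uncontaminated by neighbouring elements (a conservative annotator).
    """
    coords = rasterize_transect(landmarks)
    interior = np.full(len(coords), -1)
    for i, (r, c) in enumerate(coords):
        window = label_image[r - 1 : r + 2, c - 1 : c + 2]
        if window.size == 9 and np.all(window == window.flat[0]):
            interior[i] = window.flat[0]
    intervals: dict = {label: [] for label in ELEMENT_LABELS}
    start = 0
    for i in range(1, len(interior) + 1):
        if i == len(interior) or interior[i] != interior[start]:
            if interior[start] >= 0:
                intervals[ELEMENT_LABELS[interior[start]]].append((start, i))
            start = i
    missing = [label for label, spans in intervals.items() if not spans]
    if missing:
        raise GeometryError(f"elements too small for interior samples: {missing}")
    return SegmentBoundaries({k: v for k, v in intervals.items() if v})


def generate_wing_image(params: WingSimParams, Td_level: int, sex: str = "F") -> AnnotatedWing:
    """Render one annotated wing for a developmental-temperature level.

    The transect runs horizontally through the eyespot center: landmarks
    0 and 1 bracket the band on the left background, landmark 2 is the
    eyespot center, 3 and 4 sit on the right background.  Deterministic:
    same params + seed give a bit-identical image.
    """
    if Td_level not in params.colors_by_Td:
        raise ValueError(f"no palette for Td={Td_level}")
    colors = params.colors_by_Td[Td_level]
    radii = params.radii_by_Td[Td_level]
    h, w = params.image_size_px
    cy, cx = h // 2, int(w * 0.62)
    if cy - radii["ring"] < 2 or cy + radii["ring"] > h - 3 or cx + radii["ring"] > w - 10:
        raise GeometryError("eyespot radii exceed image bounds")
    band_left = int(w * 0.14)
    band_right = band_left + params.band_width_px
    if band_right >= cx - radii["ring"] - 4:
        raise GeometryError("band overlaps the eyespot")

    label_image = np.full((h, w), LABEL_CODES["wing_background"], dtype=int)
    label_image[:, band_left:band_right] = LABEL_CODES["central_band"]
    for part, label in (
        ("ring", "eyespot_outer_ring"),
        ("disc", "eyespot_dark_disc"),
        ("focus", "eyespot_focus"),
    ):
        rr, cc = _disk((cy, cx), radii[part] + 0.5, shape=(h, w))
        label_image[rr, cc] = LABEL_CODES[label]

    image = np.empty((h, w, 3))
    for label, code in LABEL_CODES.items():
        image[label_image == code] = colors[label]
    if params.pixel_noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence((params.seed, Td_level, 0 if sex == "F" else 1))
        )
        image = np.clip(image + rng.normal(0.0, params.pixel_noise_sd, image.shape), 0.0, 1.0)

    landmarks = LandmarkSet(
        (
            (cy, 4),
            (cy, (band_right + cx - radii["ring"]) // 2),
            (cy, cx),
            (cy, cx + radii["ring"] + 3),
            (cy, w - 5),
        )
    )
    boundaries = _true_boundaries(label_image, landmarks)
    return AnnotatedWing(
        image=image,
        landmarks=landmarks,
        boundaries=boundaries,
        element_colors={k: np.array(v) for k, v in colors.items()},
        label_image=label_image,
        Td=Td_level,
        sex=sex,
    )


# ---------------------------------------------------------------------------
# behavioral cohorts
# ---------------------------------------------------------------------------

# Effect keys use treatment coding against the reference cell
# (Td=27, Ta=27, Sex=M), matching the model design matrix, so injected
# coefficients are directly comparable with fitted ones.
EFFECT_KEYS = ("intercept", "Td[19]", "Ta[19]", "Sex[F]", "Td[19]:Ta[19]", "Td[19]:Sex[F]", "Ta[19]:Sex[F]")


@dataclass
class CohortSimParams:
    """Generative model of the cage assay.

    ``preference_effects`` and ``activity_effects`` are logit-scale
    coefficient dicts over EFFECT_KEYS (missing keys are 0).  The default
    preference effects encode the study's qualitative structure: dry-season
    development (Td=19) raises brown preference, females prefer brown more,
    and the sex effect strengthens at the cooler testing temperature.
    """

    n_cohorts_per_cell: int = 8
    cohort_size: int = 20
    n_timepoints: int = 15
    preference_effects: dict = field(
        default_factory=lambda: {"intercept": -0.3, "Td[19]": 0.8, "Sex[F]": 0.6, "Ta[19]:Sex[F]": 0.4}
    )
    activity_effects: dict = field(
        default_factory=lambda: {"Td[19]": 0.4, "Ta[19]": 0.5, "Td[19]:Sex[F]": -0.4, "Ta[19]:Sex[F]": -0.5}
    )
    mean_relocations_per_photo: float = 5.0
    sigma_cohort: float = 0.5
    sigma_timepoint: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.sigma_cohort < 0 or self.sigma_timepoint < 0:
            raise ValueError("random-intercept sds must be >= 0")
        if self.cohort_size < 1 or self.n_timepoints < 2:
            raise ValueError("cohort_size >= 1 and n_timepoints >= 2 required")
        for effects in (self.preference_effects, self.activity_effects):
            unknown = set(effects) - set(EFFECT_KEYS)
            if unknown:
                raise ValueError(f"unknown effect keys {sorted(unknown)}")


def _cell_logit(effects: dict, Td: int, Ta: int, sex: str) -> float:
    d, c, f = float(Td == 19), float(Ta == 19), float(sex == "F")
    return (
        effects.get("intercept", 0.0)
        + effects.get("Td[19]", 0.0) * d
        + effects.get("Ta[19]", 0.0) * c
        + effects.get("Sex[F]", 0.0) * f
        + effects.get("Td[19]:Ta[19]", 0.0) * d * c
        + effects.get("Td[19]:Sex[F]", 0.0) * d * f
        + effects.get("Ta[19]:Sex[F]", 0.0) * c * f
    )


def generate_cohort_series(params: CohortSimParams) -> pd.DataFrame:
    """Simulate every cohort x time point of the full-factorial assay.

    Mechanics per cohort: at the first photo each individual perches on
    brown with the preference probability; at each later photo each
    perched individual relocates with the activity probability, and each
    mover independently re-chooses brown vs green with the preference
    probability.  Arrivals are movers by destination, so occupancy change
    equals arrivals minus departures by construction.  Time-point random
    intercepts are shared across cohorts (crossed design); each response
    has its own independent intercepts.
    """
    rng = np.random.default_rng(params.seed)
    n_t = params.n_timepoints
    size = params.cohort_size
    base_act = float(np.log(params.mean_relocations_per_photo / (size - params.mean_relocations_per_photo)))
    # crossed time-point intercepts, one set per response
    bt_pref = rng.normal(0.0, params.sigma_timepoint, n_t)
    bt_act = rng.normal(0.0, params.sigma_timepoint, n_t)
    rows = []
    cohort_id = 0
    for Td in (19, 27):
        for Ta in (19, 27):
            for sex in ("F", "M"):
                lp_cell = _cell_logit(params.preference_effects, Td, Ta, sex)
                la_cell = base_act + _cell_logit(params.activity_effects, Td, Ta, sex)
                for _ in range(params.n_cohorts_per_cell):
                    cohort_id += 1
                    bc_pref = rng.normal(0.0, params.sigma_cohort)
                    bc_act = rng.normal(0.0, params.sigma_cohort)
                    on_brown_state = rng.random(size) < expit(lp_cell + bc_pref + bt_pref[0])
                    rows.append(
                        dict(
                            cohort_id=f"C{cohort_id:04d}", sex=sex, Td=Td, Ta=Ta, timepoint=1,
                            on_brown=int(on_brown_state.sum()),
                            on_green=int(size - on_brown_state.sum()),
                            arrivals_brown=pd.NA, arrivals_green=pd.NA,
                            stationary=pd.NA, relocated=pd.NA,
                        )
                    )
                    for t in range(1, n_t):
                        p_move = expit(la_cell + bc_act + bt_act[t])
                        movers = rng.random(size) < p_move
                        p_brown = expit(lp_cell + bc_pref + bt_pref[t])
                        dest = rng.random(size) < p_brown
                        on_brown_state = np.where(movers, dest, on_brown_state)
                        n_mov = int(movers.sum())
                        rows.append(
                            dict(
                                cohort_id=f"C{cohort_id:04d}", sex=sex, Td=Td, Ta=Ta, timepoint=t + 1,
                                on_brown=int(on_brown_state.sum()),
                                on_green=int(size - on_brown_state.sum()),
                                arrivals_brown=int((movers & dest).sum()),
                                arrivals_green=int((movers & ~dest).sum()),
                                stationary=int(size - n_mov),
                                relocated=n_mov,
                            )
                        )
    df = pd.DataFrame(rows)
    for col in ("on_brown", "on_green", "arrivals_brown", "arrivals_green", "stationary", "relocated"):
        df[col] = df[col].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# gray calibration standards
# ---------------------------------------------------------------------------


def generate_calibration_standards(
    true_gamma: float = 2.2, n_levels: int = 8, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """(known reflectance, raw scanner value) pairs per channel.

    The emulated response is ``raw = reflectance**(1/gamma) + noise``
    clipped to [0, 1]; gamma = 1 is a perfectly linear device.
    """
    if true_gamma <= 0:
        raise ValueError("true_gamma must be > 0")
    if n_levels < 3:
        raise ValueError("need at least 3 reflectance levels")
    rng = np.random.default_rng(seed)
    reflectance = np.linspace(0.0, 1.0, n_levels)
    rows = []
    for channel in ("R", "G", "B"):
        raw = reflectance ** (1.0 / true_gamma)
        if noise_sd > 0:
            raw = raw + rng.normal(0.0, noise_sd, n_levels)
        raw = np.clip(raw, 0.0, 1.0)
        for refl, r in zip(reflectance, raw):
            rows.append({"channel": channel, "reflectance": float(refl), "raw": float(r)})
    return pd.DataFrame(rows)
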