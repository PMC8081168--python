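"""Study-level configuration objects.

The generator's defaults describe one fixed "stated world": a weekend-night
EMA study of roughly 210 young adults documenting ~2,400 drinking situations
across seven location types, with per-location ambiance distributions
calibrated so that nightclubs are the darkest and loudest venues and private
places the quietest and least attended, and with alcohol choice driven by a
participant-level random-intercept logistic model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The seven fine-grained location types, in canonical order.
LOCATIONS = (
    "bars/pubs",
    "nightclubs",
    "restaurants",
    "events",
    "streets/parks",
    "travelling",
    "private",
)

#: Deterministic fine -> coarse mapping.
COARSE_MAP: Mapping[str, str] = {
    "bars/pubs": "commercial",
    "nightclubs": "commercial",
    "restaurants": "commercial",
    "events": "commercial",
    "streets/parks": "public",
    "travelling": "public",
    "private": "private",
}

COARSE_LEVELS = ("commercial", "public", "private")

SOURCES = ("participants", "annotators", "algorithms")


@dataclass
class LocationProfile:
    """Ground-truth ambiance distribution for one location type.

    luminance is physical scene luminance on a 0-100 scale (pre
    lightness transform); sound level is a calibrated dB figure;
    attendance is the true number of people present besides the
    participant.
    """

    luminance_mean: float
    luminance_sd: float
    db_mean: float
    db_sd: float
    attendance_mean: float
    attendance_disp: float = 1.5  # negative-binomial dispersion (size)
    clip_prob: float = 0.4

    def validate(self) -> None:
        if self.luminance_sd < 0 or self.db_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.clip_prob <= 1.0:
            raise ValueError("clip_prob must lie in [0, 1]")
        if self.attendance_mean < 0:
            raise ValueError("attendance_mean must be non-negative")


@dataclass
class AlcoholModel:
    """Random-intercept logistic model generating the alcohol flag.

    P(alcohol) = logistic(intercept_loc + b_bright*brightness_bin
                 + b_loud*loudness_bin + b_att*attendance
                 + b_prior*prior_drinks + u_j),  u_j ~ N(0, sigma_u^2).

    Context enters on the same scales the sources report: 0-4 bins for
    brightness and loudness, a raw head count for attendance.
    Coefficients vary by coarse location; intercepts by fine location
    (needed to reproduce the very different alcohol rates of nightclubs
    and restaurants, which share the commercial coefficients).
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "bars/pubs": 2.39,
            "nightclubs": 1.55,
            "restaurants": 0.12,
            "events": 1.78,
            "streets/parks": 1.97,
            "travelling": 1.22,
            "private": -0.80,
        }
    )
    coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "commercial": {
                "brightness": -0.55,
                "loudness": 0.45,
                "attendance": 0.0,
                "prior_drinks": 0.10,
            },
            "public": {
                "brightness": -0.40,
                "loudness": 0.15,
                "attendance": 0.05,
                "prior_drinks": 0.10,
            },
            "private": {
                "brightness": -0.45,
                "loudness": 0.95,
                "attendance": 0.13,
                "prior_drinks": 0.02,
            },
        }
    )
    sigma_u: float = 1.0

    def validate(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        for loc in LOCATIONS:
            if loc not in self.intercepts:
                raise ValueError(f"missing intercept for location {loc!r}")
        for coarse in COARSE_LEVELS:
            if coarse not in self.coefficients:
                raise ValueError(f"missing coefficients for {coarse!r}")


@dataclass
class RatingNoise:
    """Noise model for the two human rating channels.

    Participants rate from lived experience with idiosyncratic anchors:
    a positive mean bias and a wide rating SD.  Annotators rate the clip
    under controlled instructions: small negative bias (video flattens
    extremes) and tighter SD.  Attendance noise is relative (people are
    miscounted proportionally to how many there are).
    """

    participant_bias: float = 0.3
    participant_sd: float = 0.9
    participant_attendance_cv: float = 0.5
    annotator_bias: float = -0.2
    annotator_sd: float = 0.35
    annotator_attendance_cv: float = 0.15

    def validate(self) -> None:
        for name in ("participant_sd", "participant_attendance_cv", "annotator_sd", "annotator_attendance_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MediaParams:
    """Rendering parameters for synthetic 10-second clips."""

    fps: float = 2.0
    duration_s: float = 10.0
    height: int = 120
    width: int = 160
    sample_rate: int = 8000
    blob_contrast: float = 60.0  # minimum |blob - background| in 8-bit units
    max_render_people: int = 10  # people beyond this are off-camera

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be at least 8 kHz")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.duration_s))


def _default_profiles() -> dict[str, LocationProfile]:
    # Calibrated so the per-location means of the *algorithmic* bins land on
    # the study's reported ordering: nightclubs darkest & loudest, restaurants
    # and travelling brightest, private places quietest and least attended.
    return {
        "bars/pubs": LocationProfile(8.4, 3.5, 78.0, 7.0, 7.0, 2.0, 0.36),
        "nightclubs": LocationProfile(5.5, 2.5, 84.0, 6.0, 7.0, 2.0, 0.50),
        "restaurants": LocationProfile(30.0, 9.0, 69.0, 7.0, 10.0, 3.0, 0.33),
        "events": LocationProfile(26.5, 9.0, 77.0, 6.5, 20.0, 2.5, 0.55),
        "streets/parks": LocationProfile(7.0, 3.0, 67.0, 8.0, 5.0, 1.5, 0.39),
        "travelling": LocationProfile(28.0, 9.0, 65.0, 8.0, 8.0, 2.0, 0.56),
        "private": LocationProfile(26.5, 9.0, 55.0, 9.0, 3.0, 1.2, 0.30),
    }


def _default_location_probs() -> dict[str, float]:
    # Relative frequencies of the seven location types among reported
    # situations (dominated by private places, then bars and public spaces).
    counts = {
        "bars/pubs": 345,
        "nightclubs": 86,
        "restaurants": 129,
        "events": 74,
        "streets/parks": 324,
        "travelling": 114,
        "private": 1286,
    }
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class GeneratorConfig:
    """Everything needed to synthesize one study."""

    n_participants: int = 210
    # situations per participant ~ 1 + NegBinom(size=nb_size, mean=nb_mean-1):
    # heavy-tailed so ~20% of participants contribute ~half the situations.
    situations_nb_mean: float = 11.2
    situations_nb_size: float = 1.05
    location_probs: dict[str, float] = field(default_factory=_default_location_probs)
    profiles: dict[str, LocationProfile] = field(default_factory=_default_profiles)
    alcohol: AlcoholModel = field(default_factory=AlcoholModel)
    noise: RatingNoise = field(default_factory=RatingNoise)
    media: MediaParams = field(default_factory=MediaParams)
    prior_drinks_mean: float = 2.0
    n_raters: int = 5
    seed: int = 0

    def validate(self) -> None:
        probs = np.array([self.location_probs[loc] for loc in LOCATIONS])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("location_probs must sum to 1 within 1e-9")
        if (probs < 0).any():
            raise ValueError("location_probs must be non-negative")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for loc in LOCATIONS:
            if loc not in self.profiles:
                raise ValueError(f"missing profile for location {loc!r}")
            self.profiles[loc].validate()
        self.alcohol.validate()
        self.noise.validate()
        self.media.validate()

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunConfig:
    """One end-to-end pipeline run: a root seed plus stage parameters."""

    out_dir: str = "report"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    calibration_db: float = 94.0
    detector_k: float = 3.0
    detector_min_area: int = 9
    hl_groups: int = 10
    quadrature_nodes: int = 15
    inference_mode: str = "leakage_safe"
    n_trees: int = 300
    inference_iterations: int = 10
    write_figures: bool = False

    def validate(self) -> None:
        self.generator.validate()
        if self.inference_mode not in ("leakage_safe", "paper_mode"):
            raise ValueError("inference_mode must be 'leakage_safe' or 'paper_mode'")
        if self.hl_groups < 3:
            raise ValueError("need at least 3 Hosmer-Lemeshow groups")


def coarse_location(fine: str) -> str:
    """Map a fine location label to its coarse category."""
    try:
        return COARSE_MAP[fine]
    except KeyError:
        raise ValueError(f"unknown location {fine!r}") from None
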