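"""Algorithmic extraction of brightness, loudness and attendance from clips.

Brightness: pixel intensities are averaged over all pixels and frames,
rescaled to physical luminance on 0-100, mapped to perceived lightness with
the cube-root lightness transform L = 25.29 * Y**(1/3) - 18.38 (Glasser's
formula), and binned in 20-point increments to the 0-4 scale the human
sources use.

Loudness: the waveform is A-weighted (the standard frequency weighting for
human hearing sensitivity, ~0 dB at 1 kHz), squared to instantaneous power,
temporally smoothed with a 125 ms exponential moving average (the "fast"
sound-level-meter convention), averaged, converted to dB with a calibration
constant, and binned to 0-4 with the cut-offs <40 / 40-50 / 50-70 / 70-85 /
>=85 dB.

Attendance: people are counted as identity clusters produced by a
deterministic tracker — temporal-median background subtraction, connected
components, and greedy nearest-centroid association across frames.  This is
a deterministic surrogate for a trained detector+tracker; it preserves the
contract (count the distinct tracked identities in the clip).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from clipcontext.synthetic import Clip

# Rec.601 luma weights for RGB -> grayscale reduction.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Cube-root lightness constants, on a 0-100 luminance domain.
GLASSER_A = 25.29
GLASSER_B = -18.38

#: dB bin edges: [-inf,40) -> 0, [40,50) -> 1, [50,70) -> 2, [70,85) -> 3, [85,inf) -> 4
DB_EDGES = (40.0, 50.0, 70.0, 85.0)

#: Default calibration: RMS 1.0 == 94 dB (arbitrary for uncalibrated phone mics).
DEFAULT_CALIBRATION_DB = 94.0

#: Power floor below which a signal is treated as digital silence.
SILENCE_POWER = 1e-12
SILENCE_DB = 0.0


@dataclass
class AlgoRating:
    """Algorithmic measurements for one clip."""

    situation_id: int
    raw_luminance: float
    perceived_lightness: float
    brightness_bin: int
    raw_db: float
    loudness_bin: int
    person_count: int


def _as_gray(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4 and frames.shape[-1] == 3:
        frames = frames @ _LUMA
    if frames.ndim != 3:
        raise ValueError(f"expected frames of shape (T,H,W) or (T,H,W,3), got {frames.shape}")
    return frames


def mean_luminance(frames: np.ndarray) -> float:
    """Average pixel intensity over all pixels and frames, on a 0-100 scale.

    RGB stacks are first reduced with Rec.601 luma weights.
    """
    frames = _as_gray(frames)
    if frames.size == 0:
        raise ValueError("empty frame stack")
    if frames.min() < 0 or frames.max() > 255:
        raise ValueError("pixel intensities must lie in [0, 255]")
    return float(frames.mean() / 2.55)


def glasser_lightness(y: float) -> float:
    """Cube-root perceived lightness of a 0-100 luminance, clamped to [0, 100]."""
    y = float(y)
    if not 0.0 <= y <= 100.0:
        raise ValueError(f"luminance must lie in [0, 100], got {y}")
    return float(np.clip(GLASSER_A * y ** (1.0 / 3.0) + GLASSER_B, 0.0, 100.0))


def brightness_bin(lightness: float) -> int:
    """0-4 bin of a 0-100 lightness with 20-point increments; 100 maps to 4."""
    lightness = float(lightness)
    if not 0.0 <= lightness <= 100.0:
        raise ValueError(f"lightness must lie in [0, 100], got {lightness}")
    return min(int(lightness // 20), 4)


def a_weight(audio: np.ndarray, sample_rate: float) -> np.ndarray:
    """Apply A-weighting in the frequency domain.

    Uses the analog A-weighting magnitude response (IEC 61672), normalised
    to 0 dB at 1 kHz, applied via the real FFT.  Gain at 1 kHz is exact to
    within numerical precision, well inside the +/-0.2 dB contract.
    """
    audio = np.asarray(audio, dtype=float)
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8 kHz")
    if audio.size < int(0.05 * sample_rate):
        raise ValueError("signal too short for A-weighting (< 50 ms)")
    n = audio.size
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    f2 = freqs**2
    num = (12194.0**2) * f2**2
    den = (
        (f2 + 20.6**2)
        * np.sqrt((f2 + 107.7**2) * (f2 + 737.9**2))
        * (f2 + 12194.0**2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.where(den > 0, num / den, 0.0)
    # normalise so the response is exactly 1 at 1 kHz
    f1k = 1000.0**2
    ra_1k = (12194.0**2 * f1k**2) / (
        (f1k + 20.6**2)
        * np.sqrt((f1k + 107.7**2) * (f1k + 737.9**2))
        * (f1k + 12194.0**2)
    )
    spec = np.fft.rfft(audio) * (ra / ra_1k)
    return np.fft.irfft(spec, n=n)


def smoothed_power_db(
    audio: np.ndarray,
    sample_rate: float,
    window_s: float = 0.125,
    calibration_db: float = DEFAULT_CALIBRATION_DB,
    weighted: bool = True,
) -> float:
    """Mean temporally-smoothed instantaneous power, in calibrated dB.

    Instantaneous power is the squared (A-weighted) sample; smoothing is an
    exponential moving average with time constant ``window_s``; the mean
    smoothed power is converted to 10*log10(power) + calibration_db.
    Digital silence returns the 0 dB floor.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("empty audio")
    x = a_weight(audio, sample_rate) if weighted else audio
    power = x**2
    alpha = 1.0 - np.exp(-1.0 / (sample_rate * window_s))
    # EMA via lfilter: y[t] = alpha*p[t] + (1-alpha)*y[t-1], initialised at the
    # signal's mean power so stationary signals measure without warm-up bias
    from scipy.signal import lfilter

    smoothed, _ = lfilter(
        [alpha], [1.0, -(1.0 - alpha)], power, zi=[(1.0 - alpha) * power.mean()]
    )
    mean_power = float(smoothed.mean())
    if mean_power < SILENCE_POWER:
        return SILENCE_DB
    return 10.0 * np.log10(mean_power) + calibration_db


def loudness_bin(db: float) -> int:
    """0-4 bin of a calibrated dB level with cut-offs at 40/50/70/85 dB."""
    db = float(db)
    if np.isnan(db):
        raise ValueError("dB value is NaN")
    return int(np.searchsorted(DB_EDGES, db, side="right"))


def count_people(
    frames: np.ndarray,
    k: float = 3.0,
    min_area: int = 9,
    max_disp: Optional[float] = None,
    min_track_frames: Optional[int] = None,
) -> int:
    """Count distinct moving-object identities across a frame stack.

    Pipeline: (1) background = per-pixel temporal median; (2) per-frame
    foreground mask = |frame - background| > k * robust spread (floored at
    one 8-bit step); (3) connected components with area >= min_area are
    detections; (4) detections are linked frame-to-frame by greedy
    nearest-centroid matching under a max-displacement gate; (5) the count
    is the number of tracks covering at least ``min_track_frames`` frames.
    """
    frames = _as_gray(frames)
    t, h, w = frames.shape
    if t < 2:
        raise ValueError("need at least 2 frames")
    background = np.median(frames, axis=0)
    resid = np.abs(frames - background)
    # robust spread of the residuals (MAD -> sigma), floored at one 8-bit step
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = max(1.4826 * mad, 1.0)
    thresh = k * sigma
    if max_disp is None:
        max_disp = 0.35 * float(min(h, w))
    if min_track_frames is None:
        min_track_frames = max(2, t // 2)

    tracks: list[dict] = []  # each: {'pos': (y,x), 'frames': int, 'last': frame idx}
    for ti in range(t):
        mask = resid[ti] > thresh
        labels, n_lab = ndimage.label(mask)
        cents = []
        if n_lab:
            areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_lab + 1))
            keep = np.flatnonzero(areas >= min_area) + 1
            if keep.size:
                cents = ndimage.center_of_mass(mask, labels, keep.tolist())
        # greedy matching: nearest (track, detection) pairs first
        open_tracks = [tr for tr in tracks if tr["last"] == ti - 1]
        pairs = []
        for a, tr in enumerate(open_tracks):
            for b, c in enumerate(cents):
                d = np.hypot(tr["pos"][0] - c[0], tr["pos"][1] - c[1])
                if d <= max_disp:
                    pairs.append((d, a, b))
        pairs.sort(key=lambda p: p[0])
        used_tr: set[int] = set()
        used_det: set[int] = set()
        for d, a, b in pairs:
            if a in used_tr or b in used_det:
                continue
            used_tr.add(a)
            used_det.add(b)
            tr = open_tracks[a]
            tr["pos"] = cents[b]
            tr["frames"] += 1
            tr["last"] = ti
        for b, c in enumerate(cents):
            if b not in used_det:
                tracks.append({"pos": c, "frames": 1, "last": ti})
    return sum(1 for tr in tracks if tr["frames"] >= min_track_frames)


def rate_clip(
    clip: "Clip",
    calibration_db: float = DEFAULT_CALIBRATION_DB,
    k: float = 3.0,
    min_area: int = 9,
) -> AlgoRating:
    """Run all three extraction algorithms on one clip."""
    lum = mean_luminance(clip.frames)
    light = glasser_lightness(lum)
    db = smoothed_power_db(clip.audio, clip.sample_rate, calibration_db=calibration_db)
    return AlgoRating(
        situation_id=clip.situation_id,
        raw_luminance=lum,
        perceived_lightness=light,
        brightness_bin=brightness_bin(light),
        raw_db=db,
        loudness_bin=loudness_bin(db),
        person_count=count_people(clip.frames, k=k, min_area=min_area),
    )
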