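"""Synthetic study generator.

Builds a complete synthetic weekend-night drinking study: participants with
heavy-tailed situation counts, per-situation ground-truth ambiance drawn from
location-specific distributions, alcohol choice from a participant-level
random-intercept logistic model, rendered audio/video clips for a subset of
situations, and noisy participant and five-annotator rating channels.

Rendered clips honour a measurement contract: the algorithmic mean luminance
of the frames lands within 1 luminance unit of the generating target, the
calibrated smoothed-power level within 0.5 dB of the target (in fact both are
exact up to 8-bit/PCM quantisation), and each rendered person is a moving
elliptical blob in its own horizontal lane, so identities never overlap and a
deterministic tracker can recover the exact count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.special import expit

from clipcontext import media as _media
from clipcontext.config import (
    COARSE_MAP,
    LOCATIONS,
    GeneratorConfig,
    MediaParams,
    RatingNoise,
    coarse_location,
)
from clipcontext.fusion import attendance_category

# Blob geometry (pixels): semi-axes and the lane padding that guarantees
# vertically disjoint trajectories.
_BLOB_RX = 4
_BLOB_RY = 3
_LANE_H = 2 * _BLOB_RY + 4


@dataclass
class Situation:
    """One drinking event."""

    situation_id: int
    participant_id: int
    location_fine: str
    location_coarse: str
    alcohol: int
    prior_drinks: float
    p_brightness: int
    p_loudness: int
    p_attendance: int
    has_clip: int
    true_luminance: float
    true_db: float
    true_people: int
    rendered_people: int


@dataclass
class Clip:
    """Rendered (or loaded) media for one situation."""

    situation_id: int
    frames: np.ndarray  # (T, H, W) uint8
    fps: float
    audio: np.ndarray  # mono float in [-1, 1]
    sample_rate: int


@dataclass
class AnnotatorPanel:
    """Five raters' raw ratings for one clip."""

    situation_id: int
    brightness: np.ndarray  # (5,) ints 0-4
    music: np.ndarray
    chatter: np.ndarray
    attendance_cat: list = field(default_factory=list)  # 5 category labels


def _lane_capacity(height: int) -> int:
    return max((height - 2) // _LANE_H, 0)


def render_clip(
    luminance_target: float,
    level_target_db: float,
    n_people: int,
    media_params: Optional[MediaParams] = None,
    seed: int | np.random.SeedSequence = 0,
    situation_id: int = 0,
    calibration_db: float = _media.DEFAULT_CALIBRATION_DB,
) -> Clip:
    """Render one clip whose algorithmic measurements match the targets."""
    mp = media_params or MediaParams()
    mp.validate()
    if not 0.0 <= luminance_target <= 100.0:
        raise ValueError("luminance_target must lie in [0, 100]")
    if n_people < 0:
        raise ValueError("n_people must be non-negative")
    cap = _lane_capacity(mp.height)
    if n_people > cap:
        raise ValueError(
            f"{n_people} people do not fit a {mp.height}px-high frame "
            f"({cap} lanes available); use a taller frame"
        )
    rng = np.random.default_rng(seed)
    t, h, w = mp.n_frames, mp.height, mp.width

    # --- video -----------------------------------------------------------
    bg0 = float(np.clip(luminance_target * 2.55, 0, 255))
    if bg0 <= 127.5:
        blob_val = min(bg0 + mp.blob_contrast, 255.0)
    else:
        blob_val = max(bg0 - mp.blob_contrast, 0.0)
    blob_val = int(round(blob_val))

    mask = np.zeros((t, h, w), dtype=bool)
    if n_people > 0:
        lanes = rng.permutation(cap)[:n_people]
        ys = 1 + lanes * _LANE_H + _LANE_H // 2
        x_lo, x_hi = _BLOB_RX + 1, w - _BLOB_RX - 2
        xs = rng.uniform(x_lo, x_hi, size=n_people)
        speeds = rng.uniform(2.0, 6.0, size=n_people) * rng.choice([-1.0, 1.0], size=n_people)
        yy, xx = np.mgrid[0:h, 0:w]
        span = x_hi - x_lo
        for ti in range(t):
            pos = xs + speeds * ti
            # reflect at lane borders
            ref = np.mod(pos - x_lo, 2 * span)
            ref = np.where(ref > span, 2 * span - ref, ref) + x_lo
            for b in range(n_people):
                ell = ((xx - ref[b]) / _BLOB_RX) ** 2 + ((yy - ys[b]) / _BLOB_RY) ** 2 <= 1.0
                mask[ti] |= ell

    f_blob = mask.mean()
    f_bg = 1.0 - f_blob
    # choose the background value so the stack mean hits the luminance target
    bg = (luminance_target * 2.55 - blob_val * f_blob) / f_bg
    bg = int(np.clip(round(bg), 0, 255))
    frames = np.full((t, h, w), bg, dtype=np.uint8)
    frames[mask] = blob_val

    # --- audio -----------------------------------------------------------
    n = mp.n_samples
    tone = np.sin(2 * np.pi * 1000.0 * np.arange(n) / mp.sample_rate)
    pink = _pink_noise(n, rng)
    # pink noise 10 dB below the tone's power; excursions clipped at 2.5x RMS
    # so loud targets near the top bin stay reachable without clipping
    rms_target = np.sqrt(0.5 * 10 ** (-1.0))
    pink *= rms_target / max(np.sqrt(np.mean(pink**2)), 1e-30)
    pink = np.clip(pink, -2.5 * rms_target, 2.5 * rms_target)
    base = tone + pink
    measured = _media.smoothed_power_db(base, mp.sample_rate, calibration_db=calibration_db)
    gain = 10 ** ((level_target_db - measured) / 20.0)
    audio = base * gain
    if np.max(np.abs(audio)) > 1.0:
        raise ValueError(
            f"level target {level_target_db} dB is unreachable without clipping "
            f"(calibration {calibration_db} dB)"
        )
    return Clip(situation_id=situation_id, frames=frames, fps=mp.fps, audio=audio, sample_rate=mp.sample_rate)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pink (1/f) noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n)
    return out / max(np.max(np.abs(out)), 1e-30)


def _true_bins(luminance: float, db: float) -> tuple[int, int]:
    b = _media.brightness_bin(_media.glasser_lightness(luminance))
    l = _media.loudness_bin(db)
    return b, l


def simulate_participant_ratings(
    truth: tuple[float, float, int],
    noise: Optional[RatingNoise] = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[int, int, int]:
    """Participant's in-situ (brightness, loudness, attendance) ratings.

    Ordinal ratings are the algorithmic bin of the true ambiance plus bias
    and Gaussian noise, rounded and clamped to {0..4}; attendance is the
    true head count under multiplicative noise.  Zero noise and zero bias
    reproduce the algorithmic bins exactly.
    """
    noise = noise or RatingNoise()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lum, db, n_people = truth
    b_bin, l_bin = _true_bins(lum, db)
    b = _noisy_ordinal(b_bin, noise.participant_bias, noise.participant_sd, rng)
    l = _noisy_ordinal(l_bin, noise.participant_bias, noise.participant_sd, rng)
    att = max(0, int(round(n_people * (1.0 + noise.participant_attendance_cv * rng.standard_normal()))))
    return b, l, att


def _noisy_ordinal(true_bin: int, bias: float, sd: float, rng: np.random.Generator) -> int:
    eps = rng.standard_normal() * sd if sd > 0 else 0.0
    return int(np.clip(np.floor(true_bin + bias + eps + 0.5), 0, 4))


def simulate_annotator_panel(
    truth: tuple[float, float, int],
    noise: Optional[RatingNoise] = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    situation_id: int = 0,
    n_raters: int = 5,
) -> AnnotatorPanel:
    """Five annotators' raw ratings of one clip.

    Music and chatter loudness are generated so that each rater's maximum
    tracks the true dB bin (music at the bin, chatter one step below);
    attendance is reported as the category containing the (noisily
    perceived) head count visible in the clip.
    """
    noise = noise or RatingNoise()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lum, db, n_people = truth
    b_bin, l_bin = _true_bins(lum, db)
    brightness = np.array(
        [_noisy_ordinal(b_bin, noise.annotator_bias, noise.annotator_sd, rng) for _ in range(n_raters)]
    )
    music = np.array(
        [_noisy_ordinal(l_bin, noise.annotator_bias, noise.annotator_sd, rng) for _ in range(n_raters)]
    )
    chatter = np.array(
        [_noisy_ordinal(max(l_bin - 1, 0), noise.annotator_bias, noise.annotator_sd, rng) for _ in range(n_raters)]
    )
    cats = []
    for _ in range(n_raters):
        if noise.annotator_attendance_cv > 0:
            seen = max(0, int(round(n_people * (1.0 + noise.annotator_attendance_cv * rng.standard_normal()))))
        else:
            seen = n_people
        cats.append(attendance_category(seen))
    return AnnotatorPanel(
        situation_id=situation_id,
        brightness=brightness,
        music=music,
        chatter=chatter,
        attendance_cat=cats,
    )


def generate_situations(config: GeneratorConfig) -> list[Situation]:
    """Draw the situation table (no media) for one study."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_struct, ss_truth, ss_alcohol, ss_ratings, _ss_media, _ss_panels = root.spawn(6)
    rng_struct = np.random.default_rng(ss_struct)
    rng_truth = np.random.default_rng(ss_truth)
    rng_alc = np.random.default_rng(ss_alcohol)
    rng_rate = np.random.default_rng(ss_ratings)

    # heavy-tailed per-participant situation counts
    mean_extra = max(config.situations_nb_mean - 1.0, 0.01)
    size = config.situations_nb_size
    p_nb = size / (size + mean_extra)
    counts = 1 + rng_struct.negative_binomial(size, p_nb, size=config.n_participants)

    u = rng_alc.standard_normal(config.n_participants) * config.alcohol.sigma_u
    probs = np.array([config.location_probs[loc] for loc in LOCATIONS])
    probs = probs / probs.sum()

    cap = min(_lane_capacity(config.media.height), config.media.max_render_people)
    situations: list[Situation] = []
    sid = 0
    for pid in range(config.n_participants):
        for _ in range(int(counts[pid])):
            loc = LOCATIONS[rng_struct.choice(len(LOCATIONS), p=probs)]
            prof = config.profiles[loc]
            lum = float(np.clip(rng_truth.normal(prof.luminance_mean, prof.luminance_sd), 0.0, 100.0))
            # cap below the clipping ceiling of the default 94 dB calibration
            db = float(np.clip(rng_truth.normal(prof.db_mean, prof.db_sd), 20.0, 87.0))
            m, disp = prof.attendance_mean, prof.attendance_disp
            if m > 0:
                n_people = int(rng_truth.negative_binomial(disp, disp / (disp + m)))
            else:
                n_people = 0
            prior = float(rng_truth.poisson(config.prior_drinks_mean))
            b_bin, l_bin = _true_bins(lum, db)
            coefs = config.alcohol.coefficients[coarse_location(loc)]
            eta = (
                config.alcohol.intercepts[loc]
                + coefs["brightness"] * b_bin
                + coefs["loudness"] * l_bin
                + coefs["attendance"] * n_people
                + coefs["prior_drinks"] * prior
                + u[pid]
            )
            alcohol = int(rng_alc.random() < expit(eta))
            pb, pl, pa = simulate_participant_ratings((lum, db, n_people), config.noise, rng_rate)
            has_clip = int(rng_struct.random() < prof.clip_prob)
            situations.append(
                Situation(
                    situation_id=sid,
                    participant_id=pid,
                    location_fine=loc,
                    location_coarse=coarse_location(loc),
                    alcohol=alcohol,
                    prior_drinks=prior,
                    p_brightness=pb,
                    p_loudness=pl,
                    p_attendance=pa,
                    has_clip=has_clip,
                    true_luminance=lum,
                    true_db=db,
                    true_people=n_people,
                    rendered_people=min(n_people, cap) if has_clip else 0,
                )
            )
            sid += 1
    return situations


def iter_clips(
    situations: list[Situation], config: GeneratorConfig
) -> Iterator[tuple[Clip, AnnotatorPanel]]:
    """Lazily render clip + annotator panel for each has_clip situation.

    Media and panel randomness are keyed on (root seed, situation id), so the
    stream is deterministic and independent of iteration interleaving.
    """
    root = np.random.SeedSequence(config.seed)
    _, _, _, _, ss_media, ss_panels = root.spawn(6)
    for s in situations:
        if not s.has_clip:
            continue
        clip = render_clip(
            s.true_luminance,
            s.true_db,
            s.rendered_people,
            config.media,
            seed=np.random.SeedSequence(entropy=ss_media.entropy, spawn_key=(s.situation_id,)),
            situation_id=s.situation_id,
        )
        panel = simulate_annotator_panel(
            (s.true_luminance, s.true_db, s.rendered_people),
            config.noise,
            seed=np.random.default_rng(
                np.random.SeedSequence(entropy=ss_panels.entropy, spawn_key=(s.situation_id,))
            ),
            situation_id=s.situation_id,
            n_raters=config.n_raters,
        )
        yield clip, panel


def generate_study(
    config: GeneratorConfig,
) -> tuple[list[Situation], list[Clip], list[AnnotatorPanel]]:
    """Generate a full study, with clips materialised in memory."""
    situations = generate_situations(config)
    clips, panels = [], []
    for clip, panel in iter_clips(situations, config):
        clips.append(clip)
        panels.append(panel)
    return situations, clips, panels


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SITUATION_COLUMNS = [
    "situation_id",
    "participant_id",
    "location_fine",
    "location_coarse",
    "alcohol",
    "prior_drinks",
    "p_brightness",
    "p_loudness",
    "p_attendance",
    "has_clip",
]

ANNOTATION_COLUMNS = ["situation_id", "rater_id", "brightness", "music", "chatter", "attendance_cat"]


def situations_to_frame(situations: list[Situation], truth: bool = False) -> pd.DataFrame:
    cols = SITUATION_COLUMNS + (
        ["true_luminance", "true_db", "true_people", "rendered_people"] if truth else []
    )
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in situations])


def panels_to_frame(panels: list[AnnotatorPanel]) -> pd.DataFrame:
    rows = []
    for p in panels:
        for r in range(len(p.brightness)):
            rows.append(
                {
                    "situation_id": p.situation_id,
                    "rater_id": r,
                    "brightness": int(p.brightness[r]),
                    "music": int(p.music[r]),
                    "chatter": int(p.chatter[r]),
                    "attendance_cat": p.attendance_cat[r],
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def frame_to_panels(df: pd.DataFrame) -> list[AnnotatorPanel]:
    panels = []
    for sid, grp in df.groupby("situation_id", sort=True):
        grp = grp.sort_values("rater_id")
        panels.append(
            AnnotatorPanel(
                situation_id=int(sid),
                brightness=grp["brightness"].to_numpy(),
                music=grp["music"].to_numpy(),
                chatter=grp["chatter"].to_numpy(),
                attendance_cat=grp["attendance_cat"].tolist(),
            )
        )
    return panels


def write_clip(clip: Clip, clip_dir: Path, frame_format: str = "npy") -> None:
    """Write one clip: frames (dense .npy or PNG sequence) + 16-bit PCM WAV."""
    clip_dir.mkdir(parents=True, exist_ok=True)
    if frame_format == "npy":
        np.save(clip_dir / "frames.npy", clip.frames)
    elif frame_format == "png":
        import imageio.v3 as iio

        for i, frame in enumerate(clip.frames):
            iio.imwrite(clip_dir / f"frame_{i:04d}.png", frame.astype(np.uint8))
    else:
        raise ValueError(f"unknown frame_format {frame_format!r}")
    pcm = np.clip(np.round(clip.audio * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(clip_dir / "audio.wav", clip.sample_rate, pcm)
    (clip_dir / "meta.json").write_text(
        json.dumps({"fps": clip.fps, "sample_rate": clip.sample_rate, "situation_id": clip.situation_id})
    )


def read_clip(clip_dir: Path) -> Clip:
    clip_dir = Path(clip_dir)
    if not clip_dir.is_dir():
        raise FileNotFoundError(f"clip directory not found: {clip_dir}")
    meta = json.loads((clip_dir / "meta.json").read_text())
    if (clip_dir / "frames.npy").exists():
        frames = np.load(clip_dir / "frames.npy")
    else:
        import imageio.v3 as iio

        pngs = sorted(clip_dir.glob("frame_*.png"))
        if not pngs:
            raise FileNotFoundError(f"no frames.npy or frame_*.png in {clip_dir}")
        frames = np.stack([iio.imread(p) for p in pngs])
    rate, pcm = wavfile.read(clip_dir / "audio.wav")
    if pcm.ndim == 2:  # stereo: downmix by averaging
        pcm = pcm.mean(axis=1)
    audio = pcm.astype(float) / 32767.0
    return Clip(
        situation_id=int(meta["situation_id"]),
        frames=frames,
        fps=float(meta["fps"]),
        audio=audio,
        sample_rate=int(rate),
    )


def write_dataset(
    situations: list[Situation],
    clips: list[Clip],
    panels: list[AnnotatorPanel],
    out_dir: str | Path,
    config: Optional[GeneratorConfig] = None,
) -> Path:
    """Write situations.csv, annotations.csv, per-clip media and a manifest."""
    out = Path(out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {out.parent}")
    out.mkdir(parents=True, exist_ok=True)
    situations_to_frame(situations).to_csv(out / "situations.csv", index=False)
    panels_to_frame(panels).to_csv(out / "annotations.csv", index=False)
    for clip in clips:
        write_clip(clip, out / "clips" / str(clip.situation_id))
    manifest = {
        "n_situations": len(situations),
        "n_clips": len(clips),
        "seed": config.seed if config is not None else None,
        "config": _config_dict(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _config_dict(config: GeneratorConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(config)


def read_dataset(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the tabular half of a written study (clips load via read_clip)."""
    d = Path(in_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"study directory not found: {d}")
    situations = pd.read_csv(d / "situations.csv")
    annotations = pd.read_csv(d / "annotations.csv")
    return situations, annotations
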