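"""Annotator-side measures: ordinal fusion, attendance recoding, ICC(2,k).

Five annotators rate each clip on brightness, music loudness, chatter
loudness (all 0-4 Likert) and an attendance category.  Per-clip fusion
follows a majority-then-mean rule: if three or more annotators agree on one
value it is selected, otherwise the mean of the five ratings is rounded to
the nearest integer.  Overall loudness is the per-rater maximum of music and
chatter loudness, fused across raters.  Attendance categories are recoded to
midpoints {0, 1, 3, 7.5, 15} and averaged.  Agreement is quantified with the
Shrout-Fleiss ICC(2,k): two-way random effects, absolute agreement, average
of k raters.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

#: Attendance category -> midpoint recoding.
ATTENDANCE_CODES = {"0": 0.0, "1": 1.0, "2-4": 3.0, "5-10": 7.5, ">10": 15.0}

#: Likert interpretation bands for agreement/correlation coefficients.
CICCHETTI_BANDS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"), (np.inf, "excellent"))


def cicchetti_label(r: float) -> str:
    """Qualitative label for a reliability/correlation coefficient."""
    for upper, label in CICCHETTI_BANDS:
        if r < upper:
            return label
    raise AssertionError("unreachable")


def attendance_category(n_people: float) -> str:
    """Category containing a head count, among {'0','1','2-4','5-10','>10'}."""
    if n_people < 0:
        raise ValueError("head count must be non-negative")
    n = int(round(n_people))
    if n == 0:
        return "0"
    if n == 1:
        return "1"
    if n <= 4:
        return "2-4"
    if n <= 10:
        return "5-10"
    return ">10"


def _check_panel(ratings, k: int = 5) -> np.ndarray:
    arr = np.asarray(ratings)
    if arr.shape != (k,):
        raise ValueError(f"expected exactly {k} ratings, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == arr.astype(int)):
            raise ValueError("ordinal ratings must be integers")
        arr = arr.astype(int)
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("ordinal ratings must lie in {0,...,4}")
    return arr


def fuse_ordinal(ratings) -> int:
    """Majority-then-mean fusion of five 0-4 ratings.

    A value held by >= 3 raters wins; otherwise the mean is rounded half
    away from zero (with five integer ratings the mean is a multiple of
    0.2, so exact .5 ties cannot occur; the convention is fixed anyway).
    """
    arr = _check_panel(ratings)
    value, count = Counter(arr.tolist()).most_common(1)[0]
    if count >= 3:
        return int(value)
    mean = arr.mean()
    return int(np.floor(mean + 0.5))  # half away from zero (mean >= 0 here)


def overall_loudness(music, chatter) -> int:
    """Fused overall loudness: per-rater max of music and chatter, then fuse."""
    m = _check_panel(music)
    c = _check_panel(chatter)
    return fuse_ordinal(np.maximum(m, c))


def fuse_attendance(categories) -> float:
    """Mean of the five recoded attendance categories."""
    cats = list(categories)
    if len(cats) != 5:
        raise ValueError(f"expected exactly 5 categories, got {len(cats)}")
    try:
        return float(np.mean([ATTENDANCE_CODES[c] for c in cats]))
    except KeyError as exc:
        raise ValueError(f"unknown attendance category {exc.args[0]!r}") from None


def _recode_count(code) -> float:
    if isinstance(code, str):
        if code == ">10":
            return 15.0
        code = int(code)
    if code == 15:  # already-recoded '>10'
        return 15.0
    if not 0 <= code <= 10:
        raise ValueError(f"count code must be 0..10 or '>10', got {code!r}")
    return float(code)


def participant_attendance_total(partner, family, male_friends, female_friends, others) -> int:
    """Total people present: sum of the five company categories.

    Each category is an integer 0..10 or '>10' (recoded as 15); partner is
    0 or 1.
    """
    p = _recode_count(partner)
    if p not in (0.0, 1.0):
        raise ValueError("partner must be 0 or 1")
    return int(p + sum(_recode_count(c) for c in (family, male_friends, female_friends, others)))


def icc_2k(ratings: np.ndarray) -> float:
    """Shrout-Fleiss ICC(2,k): two-way random, absolute agreement, average of k.

    ``ratings`` is an (n_subjects, k_raters) complete matrix.  Returns
    (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n); degenerate inputs (zero
    between-subject variance) yield a value <= 0, not an exception.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (ms_c - ms_e) / n
    if denom == 0:
        return 0.0
    return float((ms_r - ms_e) / denom)


def icc_21(ratings: np.ndarray) -> float:
    """Single-rater counterpart ICC(2,1), from the same ANOVA decomposition."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 0.0
    return float((ms_r - ms_e) / denom)


def fuse_panel(panel) -> dict:
    """Fuse one AnnotatorPanel into the per-situation annotator measures.

    Returns a dict with keys situation_id, a_brightness, a_loudness,
    a_attendance.
    """
    return {
        "situation_id": panel.situation_id,
        "a_brightness": fuse_ordinal(panel.brightness),
        "a_loudness": overall_loudness(panel.music, panel.chatter),
        "a_attendance": fuse_attendance(panel.attendance_cat),
    }
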