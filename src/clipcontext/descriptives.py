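"""Source comparison and location x drink contrasts.

Compares the three measurement sources (participants, annotators,
algorithms) on brightness, loudness and attendance: correspondence
matrices, Pearson correlations and paired mean differences with inference
adjusted for the nesting of situations within participants (cluster-robust
sandwich standard errors, clustered on participant), and location-specific
alcohol vs. no-alcohol contrasts as Cohen's d with Hedges-Olkin confidence
intervals.
"""

from __future__ import annotations

import itertools
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from clipcontext.config import LOCATIONS, SOURCES
from clipcontext.fusion import attendance_category

_SOURCE_PREFIX = {"participants": "p", "annotators": "a", "algorithms": "g"}
DIMENSIONS = ("brightness", "loudness", "attendance")

ATTENDANCE_BIN_ORDER = ("0", "1", "2-4", "5-10", ">10")


class CorrResult(NamedTuple):
    r: float
    pvalue: float


class TTestResult(NamedTuple):
    t: float
    pvalue: float


class CohensD(NamedTuple):
    d: float
    ci_lo: float
    ci_hi: float


def attendance_to_bin(counts) -> np.ndarray:
    """Map head counts to the 0-4 index of the five annotator categories."""
    cats = [attendance_category(c) for c in np.asarray(counts, dtype=float)]
    lookup = {c: i for i, c in enumerate(ATTENDANCE_BIN_ORDER)}
    return np.array([lookup[c] for c in cats])


def correspondence_matrix(x, y) -> np.ndarray:
    """5x5 cross-tabulation of two ordinal 0-4 ratings over the same items."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    xi = np.rint(x).astype(int)
    yi = np.rint(y).astype(int)
    if xi.min() < 0 or xi.max() > 4 or yi.min() < 0 or yi.max() > 4:
        raise ValueError("ordinal values must lie in 0..4 (bin attendance first)")
    m = np.zeros((5, 5), dtype=int)
    np.add.at(m, (xi, yi), 1)
    return m


def cluster_pearson(x, y, cluster_ids) -> CorrResult:
    """Pearson r with a cluster-robust p-value.

    The point estimate is the ordinary correlation; the p-value comes from
    regressing standardized y on standardized x with sandwich standard
    errors clustered on ``cluster_ids``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(cluster_ids)
    if np.unique(g).size < 3:
        raise ValueError("need at least 3 clusters")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    r = float(np.mean(zx * zy))
    ols = sm.OLS(zy, sm.add_constant(zx)).fit(cov_type="cluster", cov_kwds={"groups": g})
    return CorrResult(r, float(ols.pvalues[1]))


def cluster_paired_ttest(x, y, cluster_ids) -> TTestResult:
    """Paired mean-difference test with cluster-robust standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(cluster_ids)
    if np.unique(g).size < 3:
        raise ValueError("need at least 3 clusters")
    d = x - y
    if np.allclose(d, d[0]) and d[0] == 0:
        return TTestResult(0.0, 1.0)
    ols = sm.OLS(d, np.ones((d.size, 1))).fit(cov_type="cluster", cov_kwds={"groups": g})
    return TTestResult(float(ols.tvalues[0]), float(ols.pvalues[0]))


def cohens_d(n1: int, m1: float, s1: float, n2: int, m2: float, s2: float) -> CohensD:
    """Cohen's d = (m2 - m1) / pooled SD, with the Hedges-Olkin 95% CI.

    Pooled SD uses the (n-1)-weighted variances; the CI uses the
    large-sample variance (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = (m2 - m1) / np.sqrt(sp2)
    var_d = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    half = 1.959963984540054 * np.sqrt(var_d)
    return CohensD(float(d), float(d - half), float(d + half))


def cohens_d_from_samples(a, b) -> CohensD:
    """Cohen's d computed from the raw samples (b relative to a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d(a.size, a.mean(), a.std(ddof=1), b.size, b.mean(), b.std(ddof=1))


def _letters_from_pmatrix(means: np.ndarray, pmat: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Compact letter display: groups sharing a letter do not differ at alpha.

    Means are ranked ascending; a new letter starts whenever a group differs
    significantly from the first member of the current letter run.
    """
    order = np.argsort(means)
    letters = [""] * means.size
    current = 0
    anchor = order[0]
    for idx in order:
        if pmat[anchor, idx] < alpha:
            current += 1
            anchor = idx
        letters[idx] += chr(ord("a") + current)
    return letters


def table1_report(source_table: pd.DataFrame) -> dict:
    """Source-comparison report: means, correlations, paired tests, matrices.

    Returns a dict with keys ``means`` (per source x dimension mean/SD with
    paired-contrast letters), ``correlations`` (per dimension, source-pair r
    and cluster-robust p), and ``correspondence`` (per dimension and source
    pair, a 5x5 matrix as DataFrame).
    """
    g = source_table["participant_id"].to_numpy()
    mean_rows = []
    pair_letters: dict[str, list[str]] = {}
    for dim in DIMENSIONS:
        cols = {s: f"{_SOURCE_PREFIX[s]}_{dim}" for s in SOURCES}
        vals = {s: source_table[c].to_numpy(dtype=float) for s, c in cols.items()}
        means = np.array([vals[s].mean() for s in SOURCES])
        pmat = np.ones((3, 3))
        for i, j in itertools.combinations(range(3), 2):
            t = cluster_paired_ttest(vals[SOURCES[i]], vals[SOURCES[j]], g)
            pmat[i, j] = pmat[j, i] = t.pvalue
        pair_letters[dim] = _letters_from_pmatrix(means, pmat)
        for i, s in enumerate(SOURCES):
            mean_rows.append(
                {
                    "dimension": dim,
                    "source": s,
                    "mean": vals[s].mean(),
                    "sd": vals[s].std(ddof=1),
                    "letter": pair_letters[dim][i],
                }
            )
    corr_rows = []
    for dim in DIMENSIONS:
        for s1, s2 in itertools.combinations(SOURCES, 2):
            x = source_table[f"{_SOURCE_PREFIX[s1]}_{dim}"].to_numpy(dtype=float)
            y = source_table[f"{_SOURCE_PREFIX[s2]}_{dim}"].to_numpy(dtype=float)
            res = cluster_pearson(x, y, g)
            corr_rows.append(
                {"dimension": dim, "source_1": s1, "source_2": s2, "r": res.r, "p": res.pvalue}
            )
    matrices = {}
    for dim in DIMENSIONS:
        for s1, s2 in itertools.combinations(SOURCES, 2):
            x = source_table[f"{_SOURCE_PREFIX[s1]}_{dim}"].to_numpy(dtype=float)
            y = source_table[f"{_SOURCE_PREFIX[s2]}_{dim}"].to_numpy(dtype=float)
            if dim == "attendance":
                x = attendance_to_bin(x)
                y = attendance_to_bin(y)
            else:
                x = np.rint(x)
                y = np.rint(y)
            matrices[(dim, s1, s2)] = pd.DataFrame(
                correspondence_matrix(x, y),
                index=[f"{s1}_{v}" for v in range(5)],
                columns=[f"{s2}_{v}" for v in range(5)],
            )
    return {
        "means": pd.DataFrame(mean_rows),
        "correlations": pd.DataFrame(corr_rows),
        "correspondence": matrices,
    }


def table2_report(
    source_table: pd.DataFrame,
    situations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-location x source x drink summary with alcohol-contrast effect sizes.

    For each fine location, data source, and dimension: N and % of
    (non-)alcoholic situations, mean and SD per drink type, and the Cohen's d
    (with CI) of the alcoholic vs non-alcoholic contrast.  The participant
    source additionally draws on the full situation table (participants rated
    every situation, not just those with a clip).  Cells with fewer than two
    observations in either drink group report blank effect sizes.
    """
    rows = []
    for loc in LOCATIONS:
        for source in SOURCES:
            if source == "participants" and situations is not None:
                sub = situations[situations["location_fine"] == loc]
                pre = "p"
            else:
                sub = source_table[source_table["location_fine"] == loc]
                pre = _SOURCE_PREFIX[source]
            n_total = len(sub)
            alc = sub[sub["alcohol"] == 1]
            non = sub[sub["alcohol"] == 0]
            for dim in DIMENSIONS:
                col = f"{pre}_{dim}"
                if col not in sub.columns:
                    continue
                row = {
                    "location": loc,
                    "source": source,
                    "dimension": dim,
                    "n_total": n_total,
                    "n_alc": len(alc),
                    "pct_alc": 100.0 * len(alc) / n_total if n_total else np.nan,
                    "mean_total": sub[col].mean() if n_total else np.nan,
                    "sd_total": sub[col].std(ddof=1) if n_total > 1 else np.nan,
                    "mean_non": non[col].mean() if len(non) else np.nan,
                    "sd_non": non[col].std(ddof=1) if len(non) > 1 else np.nan,
                    "mean_alc": alc[col].mean() if len(alc) else np.nan,
                    "sd_alc": alc[col].std(ddof=1) if len(alc) > 1 else np.nan,
                    "d": np.nan,
                    "d_ci_lo": np.nan,
                    "d_ci_hi": np.nan,
                }
                if len(alc) >= 2 and len(non) >= 2:
                    try:
                        eff = cohens_d_from_samples(non[col].to_numpy(), alc[col].to_numpy())
                        row.update({"d": eff.d, "d_ci_lo": eff.ci_lo, "d_ci_hi": eff.ci_hi})
                    except ValueError:
                        pass
                rows.append(row)
    return pd.DataFrame(rows)


def assemble_source_table(
    situations: pd.DataFrame,
    fused: pd.DataFrame,
    algo: pd.DataFrame,
) -> pd.DataFrame:
    """Join the three sources into one per-situation table (clip rows only).

    ``fused`` carries a_brightness/a_loudness/a_attendance per situation;
    ``algo`` carries the algorithmic brightness_bin/loudness_bin/person_count.
    """
    base = situations[situations["has_clip"] == 1][
        [
            "situation_id",
            "participant_id",
            "location_fine",
            "location_coarse",
            "alcohol",
            "prior_drinks",
            "p_brightness",
            "p_loudness",
            "p_attendance",
        ]
    ]
    algo_renamed = algo.rename(
        columns={
            "brightness_bin": "g_brightness",
            "loudness_bin": "g_loudness",
            "person_count": "g_attendance",
        }
    )[["situation_id", "g_brightness", "g_loudness", "g_attendance"]]
    out = base.merge(fused, on="situation_id", how="inner").merge(
        algo_renamed, on="situation_id", how="inner"
    )
    return out.reset_index(drop=True)
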