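"""Annotator behaviour analyses.

Three questions about how annotators worked, mirrored from the study design:

* did throughput (images per one-hour session) change between sessions?
  — a two-sided Mann-Whitney U test;
* did annotators who place many outline points analyse fewer images?
  — Pearson correlation between mean points per image and images analysed;
* did accuracy vary with age? — Pearson correlation plus a least-squares
  slope expressed per decade of age.

Conventions: tests are two-sided; tied observations receive midranks.  The
U statistic follows the rank-sum convention ``U = R_a - n_a(n_a+1)/2`` for
the first sample.  When both samples have at most 8 observations the
p-value comes from exact enumeration of the permutation null (ties
included); otherwise from the tie- and continuity-corrected normal
approximation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mann_whitney_u",
    "session_throughput_test",
    "points_vs_images_correlation",
    "covariate_accuracy_regression",
    "session_counts",
    "build_annotator_summaries",
]

_EXACT_MAX_N = 8


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a`` under the rank-sum convention, with midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def _exact_p_two_sided(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided p by full enumeration of group assignments (handles ties).

    Enumerates all C(n_a + n_b, n_a) splits of the pooled data into the two
    groups; p is the fraction of splits whose U deviates from the null mean
    n_a*n_b/2 at least as much as the observed U.
    """
    n_a, n_b = len(a), len(b)
    pooled_ranks = stats.rankdata(np.concatenate([a, b]))
    const = n_a * (n_a + 1) / 2.0
    center = n_a * n_b / 2.0
    dev_obs = abs(u_obs - center)
    hits = total = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        u = pooled_ranks[list(idx)].sum() - const
        total += 1
        if abs(u - center) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], *, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    ``method`` is ``"exact"`` (full enumeration, feasible for small
    samples), ``"asymptotic"`` (tie-corrected, continuity-corrected normal
    approximation) or ``"auto"`` (exact when both samples have <= 8
    observations).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    if method == "auto":
        method = "exact" if max(a.size, b.size) <= _EXACT_MAX_N else "asymptotic"
    if method == "exact":
        p = _exact_p_two_sided(a, b, u)
    elif method == "asymptotic":
        # scipy handles the tie correction and continuity correction; its U1
        # matches the rank-sum convention used here.
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert math.isclose(float(res.statistic), u, abs_tol=1e-9)
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return u, min(p, 1.0)


def session_throughput_test(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> tuple[float, float]:
    """Compare per-annotator image counts between two sessions.

    A two-sided Mann-Whitney U test on the two sets of per-annotator
    throughput counts; returns (U, p) with U for the first session.
    """
    return mann_whitney_u(counts_a, counts_b)


def points_vs_images_correlation(summaries: pd.DataFrame) -> tuple[float, float]:
    """Pearson r between mean points per image and total images analysed.

    Expects a summary frame with columns ``mean_points_per_image`` and
    ``total_images`` (one row per annotator).  Returns (r, p) with a
    two-sided t-test p-value on n - 2 degrees of freedom.
    """
    df = summaries.dropna(subset=["mean_points_per_image", "total_images"])
    if len(df) < 3:
        raise ValueError("need at least 3 annotators with defined values")
    x = df["mean_points_per_image"].to_numpy(float)
    y = df["total_images"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def covariate_accuracy_regression(summaries: pd.DataFrame) -> tuple[float, float, float]:
    """Relate annotator age to segmentation accuracy.

    Pearson r between ``age`` and ``accuracy_median`` (each annotator's
    median Dice against the reference consensus) plus the least-squares
    slope rescaled to Dice change per 10 years.  Annotators with missing
    age are excluded with a warning.  Returns (r, p, slope_per_decade).
    """
    n_all = len(summaries)
    df = summaries.dropna(subset=["age", "accuracy_median"])
    if len(df) < n_all:
        warnings.warn(f"{n_all - len(df)} annotator(s) without age excluded", stacklevel=2)
    if len(df) < 3:
        raise ValueError("need at least 3 annotators with age and accuracy")
    x = df["age"].to_numpy(float)
    y = df["accuracy_median"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.pvalue), float(fit.slope * 10.0)


def session_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Images segmented per annotator per session (duplicates included).

    Takes the canonical annotation table (one row per vertex) and counts
    distinct (image, submission) events; a repeat segmentation of the same
    image in a different session counts again, matching how throughput was
    tallied.  Sessions lost to e.g. software failure simply have no rows and
    appear as missing, not zero.
    """
    events = annotations[["annotator_id", "session", "image_id"]].drop_duplicates()
    out = (
        events.groupby(["annotator_id", "session"], dropna=False)["image_id"]
        .size()
        .rename("n_images")
        .reset_index()
    )
    return out


def build_annotator_summaries(
    annotations: pd.DataFrame,
    metadata: Optional[pd.DataFrame] = None,
    accuracy_by_annotator: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row per annotator: throughput, point usage, age, accuracy.

    ``total_images`` counts every submission including duplicates;
    ``n_unique_images`` counts distinct images (the accuracy denominator).
    ``mean_points_per_image`` averages the per-submission total vertex
    count.  ``metadata`` (annotator_id, age, group) and
    ``accuracy_by_annotator`` (id, median — the per-annotator summary of an
    AgreementTable) are merged in when given.
    """
    events = annotations.groupby(
        ["annotator_id", "image_id", "session"], dropna=False
    ).size().rename("n_points").reset_index()
    per_ann = events.groupby("annotator_id").agg(
        total_images=("image_id", "size"),
        n_unique_images=("image_id", "nunique"),
        mean_points_per_image=("n_points", "mean"),
    ).reset_index()
    if metadata is not None:
        per_ann = per_ann.merge(
            metadata[[c for c in ("annotator_id", "age", "group") if c in metadata.columns]],
            on="annotator_id", how="left",
        )
    else:
        per_ann["age"] = np.nan
        per_ann["group"] = pd.NA
    if accuracy_by_annotator is not None:
        acc = accuracy_by_annotator.rename(columns={"id": "annotator_id"})
        per_ann = per_ann.merge(
            acc[["annotator_id", "median"]].rename(columns={"median": "accuracy_median"}),
            on="annotator_id", how="left",
        )
    else:
        per_ann["accuracy_median"] = np.nan
    return per_ann
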