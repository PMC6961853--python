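"""Feature-rating correlation analyses.

Population-level Spearman ranking with Bonferroni control, per-individual
correlation profiles and their pairwise similarity, and chronological
half-split stability testing of within-person feature-rating correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS = 3


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks and a t-approximate p.

    Pairs with a missing value in either series are dropped. Returns
    (NaN, NaN) with fewer than three complete pairs or when either series
    is constant (ranks undefined for correlation purposes).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < MIN_PAIRS or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


@dataclass
class CorrelationReport:
    """Per-feature population correlations with Bonferroni flags.

    ``table`` columns: feature, rho, p, significant — sorted by |rho|
    descending. The Bonferroni threshold is alpha / (number of features
    tested).
    """

    table: pd.DataFrame
    n_samples: int
    alpha: float
    mean_abs_rho: float

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / len(self.table)

    def top(self, n: int = 15) -> pd.DataFrame:
        return self.table.head(n)


def population_feature_correlations(
    table: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    rating_col: str = "provider_rating",
    alpha: float = 0.05,
) -> CorrelationReport:
    """Spearman correlation of every feature with the rating, pooled.

    All rated calls are pooled across participants. Requires at least
    three rated calls. Significance uses the Bonferroni threshold
    alpha / n_features.
    """
    ratings = np.asarray(table[rating_col], dtype=np.float64)
    if np.isfinite(ratings).sum() < MIN_PAIRS:
        raise ValueError("need at least 3 rated calls for correlation analysis")
    if feature_names is None:
        meta = {"participant_id", "call_time", "window_index", "n_calls", rating_col}
        feature_names = [c for c in table.columns if c not in meta]
    rows = []
    threshold = alpha / len(feature_names)
    for name in feature_names:
        rho, p = spearman(table[name], ratings)
        rows.append(
            {
                "feature": name,
                "rho": rho,
                "p": p,
                "significant": bool(np.isfinite(p) and p < threshold),
            }
        )
    report = pd.DataFrame(rows)
    report = report.reindex(
        report["rho"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    finite = report["rho"].abs().dropna()
    return CorrelationReport(
        table=report,
        n_samples=int(np.isfinite(ratings).sum()),
        alpha=alpha,
        mean_abs_rho=float(finite.mean()) if len(finite) else math.nan,
    )


@dataclass
class IndividualProfile:
    """Within-individual feature-rating correlation profile."""

    participant_id: str
    rho_vector: np.ndarray
    n_calls: int


def profile_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two rho-profiles (missing dropped pairwise)."""
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < MIN_PAIRS:
        return math.nan
    a, b = a[keep], b[keep]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def individual_profiles(
    table: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    rating_col: str = "provider_rating",
    min_calls: int = 35,
) -> tuple[list[IndividualProfile], float]:
    """Per-participant correlation profiles and their mean pairwise similarity.

    Only participants with at least ``min_calls`` rated calls qualify.
    Similarity is the Pearson correlation between two participants'
    rho-vectors, averaged over all pairs; NaN with fewer than two
    qualifying participants.
    """
    if feature_names is None:
        meta = {"participant_id", "call_time", "window_index", "n_calls", rating_col}
        feature_names = [c for c in table.columns if c not in meta]
    profiles: list[IndividualProfile] = []
    for pid, sub in table.groupby("participant_id", sort=True):
        rated = sub[np.isfinite(sub[rating_col])]
        if len(rated) < min_calls:
            continue
        ratings = np.asarray(rated[rating_col], dtype=np.float64)
        rho_vec = np.array(
            [spearman(rated[name], ratings)[0] for name in feature_names]
        )
        profiles.append(
            IndividualProfile(
                participant_id=str(pid), rho_vector=rho_vec, n_calls=len(rated)
            )
        )
    if len(profiles) < 2:
        return profiles, math.nan
    sims = [
        profile_similarity(profiles[i].rho_vector, profiles[j].rho_vector)
        for i in range(len(profiles))
        for j in range(i + 1, len(profiles))
    ]
    sims = [s for s in sims if np.isfinite(s)]
    return profiles, (float(np.mean(sims)) if sims else math.nan)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-tailed test of equality of two independent correlations.

    Fisher r-to-z: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    if min(n1, n2) < 4 or not (np.isfinite(r1) and np.isfinite(r2)):
        return math.nan, math.nan
    r1 = min(1 - 1e-12, max(-1 + 1e-12, r1))
    r2 = min(1 - 1e-12, max(-1 + 1e-12, r2))
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return z, 2.0 * stats.norm.sf(abs(z))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < MIN_PAIRS or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def williams_compare(
    rating1: np.ndarray,
    feat1: np.ndarray,
    rating2: np.ndarray,
    feat2: np.ndarray,
) -> tuple[float, float]:
    """Williams/Steiger-style test for two dependent correlations.

    The half-series are paired by index (truncated to equal length) and
    the correlations r(rating1, feat1) vs r(rating2, feat2) compared with
    the Pearson-Filon/Steiger statistic for dependent, nonoverlapping
    correlations. Offered for fidelity to the classical naming; the
    disjoint-halves design is better served by :func:`fisher_z_compare`.
    """
    m = min(rating1.size, feat1.size, rating2.size, feat2.size)
    if m < 4:
        return math.nan, math.nan
    x1, y1 = rating1[:m], feat1[:m]
    x2, y2 = rating2[:m], feat2[:m]
    r12 = _pearson(x1, y1)
    r34 = _pearson(x2, y2)
    r13 = _pearson(x1, x2)
    r14 = _pearson(x1, y2)
    r23 = _pearson(y1, x2)
    r24 = _pearson(y1, y2)
    if not (abs(r12) < 1 and abs(r34) < 1):
        return math.nan, 0.0
    psi = (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r34 * r13 * r23 + r34 * r14 * r24)
    )
    c = psi / ((1.0 - r12**2) * (1.0 - r34**2))
    c = min(0.99, max(-0.99, c))
    z = (math.atanh(r12) - math.atanh(r34)) * math.sqrt((m - 3) / (2.0 - 2.0 * c))
    return z, 2.0 * stats.norm.sf(abs(z))


@dataclass
class StabilityReport:
    """Half-split stability of within-person feature-rating correlations."""

    p_values: pd.Series
    stable_fraction: float
    n_first_half: int
    n_second_half: int
    method: str


def half_split_stability(
    table: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    rating_col: str = "provider_rating",
    method: str = "fisher_z",
    min_half: int = 10,
    alpha: float = 0.05,
) -> StabilityReport:
    """Test whether feature-rating correlations change between halves.

    The participant's calls are split chronologically into halves; each
    feature's rating correlation is computed in each half and the halves
    compared with ``fisher_z`` (default; the halves are disjoint samples)
    or ``williams`` (Steiger-style dependent-correlation variant).
    stable_fraction is the share of testable features with p >= alpha.
    Requires at least 2 * min_half calls.
    """
    if method not in {"fisher_z", "williams"}:
        raise ValueError(f"unknown method {method!r}")
    table = table.sort_values("call_time") if "call_time" in table.columns else table
    rated = table[np.isfinite(table[rating_col])]
    n = len(rated)
    if n < 2 * min_half:
        raise ValueError(
            f"need at least {2 * min_half} rated calls for half-split, got {n}"
        )
    if feature_names is None:
        meta = {"participant_id", "call_time", "window_index", "n_calls", rating_col}
        feature_names = [c for c in rated.columns if c not in meta]
    half = n // 2
    first, second = rated.iloc[:half], rated.iloc[half:]
    ratings1 = np.asarray(first[rating_col], dtype=np.float64)
    ratings2 = np.asarray(second[rating_col], dtype=np.float64)
    p_values = {}
    for name in feature_names:
        f1 = np.asarray(first[name], dtype=np.float64)
        f2 = np.asarray(second[name], dtype=np.float64)
        r1, _ = spearman(f1, ratings1)
        r2, _ = spearman(f2, ratings2)
        if not (np.isfinite(r1) and np.isfinite(r2)):
            p_values[name] = math.nan
            continue
        if method == "fisher_z":
            n1 = int((np.isfinite(f1) & np.isfinite(ratings1)).sum())
            n2 = int((np.isfinite(f2) & np.isfinite(ratings2)).sum())
            if r1 == r2:
                p_values[name] = 1.0
            else:
                _, p_values[name] = fisher_z_compare(r1, n1, r2, n2)
        else:
            if r1 == r2:
                p_values[name] = 1.0
            else:
                _, p_values[name] = williams_compare(ratings1, f1, ratings2, f2)
    series = pd.Series(p_values)
    testable = series.dropna()
    stable = float((testable >= alpha).mean()) if len(testable) else math.nan
    return StabilityReport(
        p_values=series,
        stable_fraction=stable,
        n_first_half=half,
        n_second_half=n - half,
        method=method,
    )
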