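"""Assemble per-response features into per-call rows; windowing and alignment.

Each call yields 210 features: the 70-feature per-response manifest (36
norm functionals + 15 category percentages + 8 complexity + 2 coherence +
9 acoustic) applied to each of the three responses, keyed
``q{1,2,3}__{feature}``. Non-overlapping moving-average windows and
nearest-call assessment alignment prepare the table for modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from speechstate.acoustic_features import (
    ACOUSTIC_FEATURES,
    AcousticConfig,
    acoustic_feature_set,
)
from speechstate.corpus_io import (
    AssessmentRecord,
    CallRecord,
    CategoryLexicon,
    Cohort,
    NormLexicon,
)
from speechstate.semantic_coherence import (
    LsaSpace,
    coherence_features,
    fit_lsa_for_cohort,
)
from speechstate.text_features import (
    COMPLEXITY_FEATURES,
    NORM_FUNCTIONALS,
    lexical_feature_set,
    tokenize,
)
from speechstate.corpus_io import NORM_NAMES

logger = logging.getLogger(__name__)

#: The 15 default word-category percentages (affect, religion, health and
#: related LIWC-style categories).
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "posemo",
    "negemo",
    "anx",
    "anger",
    "sad",
    "affect",
    "religion",
    "health",
    "body",
    "assent",
    "negate",
    "swear",
    "social",
    "cogmech",
    "percept",
)

COHERENCE_FEATURES: tuple[str, ...] = ("coherence_mean", "coherence_std")

N_RESPONSES = 3
N_PER_RESPONSE = 70
N_CALL_FEATURES = N_RESPONSES * N_PER_RESPONSE


class ManifestError(ValueError):
    """A feature manifest does not satisfy the 70-feature contract."""


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered names of the 70 per-response features."""

    names: tuple[str, ...]
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.names) != N_PER_RESPONSE:
            raise ManifestError(
                f"manifest must have exactly {N_PER_RESPONSE} features, "
                f"got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ManifestError("manifest feature names must be unique")

    def call_feature_names(self) -> list[str]:
        """The 210 per-call column names, q1 block then q2 then q3."""
        return [
            f"q{q}__{name}" for q in range(1, N_RESPONSES + 1) for name in self.names
        ]

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_manifest(
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> FeatureManifest:
    """The default 70-feature manifest: 36 norms + 15 categories + 8 + 2 + 9."""
    names = (
        [f"{norm}_{fn}" for norm in NORM_NAMES for fn in NORM_FUNCTIONALS]
        + [f"{cat}_pct" for cat in categories]
        + list(COMPLEXITY_FEATURES)
        + list(COHERENCE_FEATURES)
        + list(ACOUSTIC_FEATURES)
    )
    return FeatureManifest(names=tuple(names), categories=tuple(categories))


@dataclass
class CallFeatureRow:
    """One call's 210 feature values (NaN = missing) plus metadata."""

    participant_id: str
    call_time: pd.Timestamp
    provider_rating: int | None
    values: np.ndarray
    manifest: FeatureManifest

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_CALL_FEATURES,):
            raise ManifestError(
                f"call feature row must have {N_CALL_FEATURES} values, "
                f"got {self.values.shape}"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.manifest.call_feature_names())


@dataclass
class WindowedSeries:
    """One non-overlapping window of ``window_size`` consecutive calls."""

    participant_id: str
    window_index: int
    window_size: int
    mean_rating: float
    mean_features: np.ndarray
    n_calls_in_window: int


def _response_features(
    response,
    norm_lexicon: NormLexicon,
    category_lexicon: CategoryLexicon,
    lsa_space: LsaSpace | None,
    manifest: FeatureManifest,
    acoustic_config: AcousticConfig,
    pseudo_sentence_length: int | None,
    difficult_syllables: int,
) -> np.ndarray:
    values = np.full(N_PER_RESPONSE, np.nan)
    if response.rejected:
        return values
    lex = lexical_feature_set(
        response.transcript,
        norm_lexicon,
        category_lexicon,
        pseudo_sentence_length=pseudo_sentence_length,
        difficult_syllables=difficult_syllables,
    )
    pos = 0
    for norm in NORM_NAMES:
        for fn in NORM_FUNCTIONALS:
            values[pos] = lex.norm_functionals[(norm, fn)]
            pos += 1
    for cat in manifest.categories:
        values[pos] = lex.category_percentages.get(cat, np.nan)
        pos += 1
    for name in COMPLEXITY_FEATURES:
        values[pos] = lex.readability[name]
        pos += 1
    if lsa_space is not None:
        coh = coherence_features(tokenize(response.transcript), lsa_space)
        values[pos] = coh.mean_coherence
        values[pos + 1] = coh.std_coherence
    pos += 2
    try:
        audio = response.load_audio()
    except Exception as exc:  # unreadable audio -> response treated as rejected
        logger.warning(
            "audio for prompt %d unreadable (%s); acoustic features missing",
            response.prompt_index,
            exc,
        )
        audio = None
    if audio is not None:
        acoustic = acoustic_feature_set(audio, config=acoustic_config)
        for name in ACOUSTIC_FEATURES:
            values[pos] = acoustic.as_dict()[name]
            pos += 1
    return values


def extract_call_features(
    call: CallRecord,
    norm_lexicon: NormLexicon,
    category_lexicon: CategoryLexicon,
    lsa_space: LsaSpace | None = None,
    manifest: FeatureManifest | None = None,
    acoustic_config: AcousticConfig = AcousticConfig(),
    pseudo_sentence_length: int | None = None,
    difficult_syllables: int = 7,
) -> CallFeatureRow:
    """Extract the full 210-feature row for one call.

    Features of rejected (or audio-unreadable) responses stay missing;
    two runs on the same call are bitwise identical.
    """
    manifest = manifest or default_manifest()
    blocks = [
        _response_features(
            resp,
            norm_lexicon,
            category_lexicon,
            lsa_space,
            manifest,
            acoustic_config,
            pseudo_sentence_length,
            difficult_syllables,
        )
        for resp in call.responses
    ]
    return CallFeatureRow(
        participant_id=call.participant_id,
        call_time=call.call_time,
        provider_rating=call.provider_rating,
        values=np.concatenate(blocks),
        manifest=manifest,
    )


def extract_cohort_features(
    cohort: Cohort,
    norm_lexicon: NormLexicon,
    category_lexicon: CategoryLexicon,
    lsa_space: LsaSpace | None = None,
    lsa_k: int = 50,
    manifest: FeatureManifest | None = None,
    acoustic_config: AcousticConfig = AcousticConfig(),
) -> tuple[list[CallFeatureRow], LsaSpace]:
    """Extract feature rows for every call in a cohort.

    When no pretrained LSA space is supplied, one is fitted on all
    (non-rejected) responses of the cohort itself, which keeps the
    pipeline self-contained.
    """
    manifest = manifest or default_manifest()
    if lsa_space is None:
        documents = [
            tokenize(resp.transcript)
            for call in cohort.all_calls()
            for resp in call.responses
            if not resp.rejected and resp.transcript.strip()
        ]
        lsa_space = fit_lsa_for_cohort(documents, k=lsa_k)
    rows = [
        extract_call_features(
            call,
            norm_lexicon,
            category_lexicon,
            lsa_space=lsa_space,
            manifest=manifest,
            acoustic_config=acoustic_config,
        )
        for call in cohort.all_calls()
    ]
    return rows, lsa_space


def rows_to_frame(rows: Sequence[CallFeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame: metadata columns + 210 feature columns."""
    if not rows:
        raise ValueError("no rows")
    manifest = rows[0].manifest
    data = {
        "participant_id": [r.participant_id for r in rows],
        "call_time": [r.call_time for r in rows],
        "provider_rating": [
            np.nan if r.provider_rating is None else float(r.provider_rating)
            for r in rows
        ],
    }
    matrix = np.vstack([r.values for r in rows])
    frame = pd.DataFrame(data)
    return pd.concat(
        [frame, pd.DataFrame(matrix, columns=manifest.call_feature_names())], axis=1
    )


def window_average(
    rows: Sequence[CallFeatureRow], w: int = 4
) -> list[WindowedSeries]:
    """Non-overlapping w-call moving averages of features and ratings.

    Rows must belong to one participant and be time-sorted. Means are
    mask-aware (missing values ignored; a window's feature is missing only
    if all w values are). The trailing remainder of fewer than w calls is
    dropped to keep windows independent.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    pids = {r.participant_id for r in rows}
    if len(pids) > 1:
        raise ValueError(f"rows span multiple participants: {sorted(pids)}")
    out: list[WindowedSeries] = []
    n_windows = len(rows) // w
    for i in range(n_windows):
        block = rows[i * w : (i + 1) * w]
        matrix = np.vstack([r.values for r in block])
        ratings = np.array(
            [np.nan if r.provider_rating is None else r.provider_rating for r in block],
            dtype=np.float64,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mean_features = np.nanmean(matrix, axis=0)
            mean_rating = float(np.nanmean(ratings))
        out.append(
            WindowedSeries(
                participant_id=block[0].participant_id,
                window_index=i,
                window_size=w,
                mean_rating=mean_rating,
                mean_features=mean_features,
                n_calls_in_window=w,
            )
        )
    return out


def windowed_frame(rows: Sequence[CallFeatureRow], w: int = 4) -> pd.DataFrame:
    """Window every participant's rows and stack into one DataFrame."""
    if not rows:
        raise ValueError("no rows")
    manifest = rows[0].manifest
    by_pid: dict[str, list[CallFeatureRow]] = {}
    for r in rows:
        by_pid.setdefault(r.participant_id, []).append(r)
    records, features = [], []
    for pid, prows in by_pid.items():
        prows = sorted(prows, key=lambda r: r.call_time)
        for win in window_average(prows, w):
            records.append(
                {
                    "participant_id": pid,
                    "window_index": win.window_index,
                    "rating": win.mean_rating,
                    "n_calls": win.n_calls_in_window,
                }
            )
            features.append(win.mean_features)
    frame = pd.DataFrame(records)
    if not records:
        return frame
    return pd.concat(
        [
            frame,
            pd.DataFrame(np.vstack(features), columns=manifest.call_feature_names()),
        ],
        axis=1,
    )


def align_nearest_assessment(
    calls: Sequence[CallRecord],
    assessments: Sequence[AssessmentRecord],
    max_gap_days: int = 14,
) -> list[tuple[AssessmentRecord, CallRecord]]:
    """Match each assessment to the temporally nearest call within the gap.

    Assessments with no call within ``max_gap_days`` are dropped (logged).
    Equidistant candidates resolve to the earlier call.
    """
    pairs: list[tuple[AssessmentRecord, CallRecord]] = []
    by_pid: dict[str, list[CallRecord]] = {}
    for call in calls:
        by_pid.setdefault(call.participant_id, []).append(call)
    for assessment in assessments:
        candidates = by_pid.get(assessment.participant_id, [])
        best = None
        best_gap = None
        for call in sorted(candidates, key=lambda c: c.call_time):
            gap = abs((call.call_time - assessment.date).total_seconds())
            if best_gap is None or gap < best_gap:  # strict: ties keep earlier
                best, best_gap = call, gap
        if best is None or best_gap > max_gap_days * 86400:
            logger.info(
                "assessment %s/%s at %s has no call within %d days; dropped",
                assessment.participant_id,
                assessment.scale_name,
                assessment.date,
                max_gap_days,
            )
            continue
        pairs.append((assessment, best))
    return pairs


def impute_for_model(
    matrix: np.ndarray, medians: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Median-fill missing cells of a feature matrix.

    ``medians`` supplies training-split statistics; when omitted they are
    computed from ``matrix`` itself (use this only on a training fold —
    the model layer passes training medians when transforming test folds).
    Columns that are all-missing with no usable median are filled with 0
    and a warning is logged. Returns (filled matrix, medians used).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise ValueError("empty feature matrix")
    if medians is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(matrix, axis=0)
    dead = ~np.isfinite(medians)
    if dead.any():
        logger.warning(
            "%d all-missing feature column(s); filled with 0", int(dead.sum())
        )
    medians = np.where(dead, 0.0, medians)
    filled = np.where(np.isfinite(matrix), matrix, medians[None, :])
    return filled, medians
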