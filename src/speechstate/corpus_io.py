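"""Data model and readers/writers for cohorts, audio, lexicons and feature tables.

A cohort lives on disk as a flat manifest (CSV or JSON-lines) with one row
per (call, prompt) plus WAV files; in memory it is a :class:`Cohort` of
time-sorted :class:`CallRecord` objects, each holding exactly three
:class:`ResponseRecord` responses. Lexicon resources are a word-norm CSV
(:class:`NormLexicon`) and a LIWC-style category dictionary
(:class:`CategoryLexicon`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: The nine psycholinguistic word norms carried by a :class:`NormLexicon`.
NORM_NAMES: tuple[str, ...] = (
    "arousal",
    "valence",
    "positivity",
    "negativity",
    "objectivity",
    "concreteness",
    "age_of_acquisition",
    "pronounceability",
    "gender_ladenness",
)

MANIFEST_COLUMNS = (
    "participant_id",
    "call_time",
    "prompt_index",
    "transcript",
    "audio_path",
    "provider_rating",
    "diagnosis",
    "rejected",
)


class SchemaError(ValueError):
    """An on-disk table or dictionary does not match the documented schema."""


class MalformedCallError(ValueError):
    """A call in the manifest does not have exactly three prompt rows."""


class AudioFormatError(ValueError):
    """A file is not readable PCM WAV audio."""


@dataclass
class AudioSegment:
    """Mono audio as float samples in [-1, 1] plus its sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int = 8000

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise AudioFormatError("audio segment has no samples")
        if self.sample_rate <= 0:
            raise AudioFormatError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class ResponseRecord:
    """One open-ended spoken response: transcript plus its audio.

    ``rejected`` marks responses whose audio was unintelligible to the
    transcriber; rejected responses contribute no features. ``audio`` may
    hold an in-memory :class:`AudioSegment`, which takes precedence over
    ``audio_path``.
    """

    prompt_index: int
    transcript: str
    audio_path: Path | None = None
    rejected: bool = False
    audio: AudioSegment | None = None

    def load_audio(self) -> AudioSegment | None:
        if self.audio is not None:
            return self.audio
        if self.audio_path is None:
            return None
        return read_wav(self.audio_path)


@dataclass
class CallRecord:
    """One patient call: three responses and the provider's 1-10 rating."""

    participant_id: str
    call_time: pd.Timestamp
    responses: list[ResponseRecord]
    provider_rating: int | None = None

    def __post_init__(self) -> None:
        self.call_time = pd.Timestamp(self.call_time)
        self.responses = sorted(self.responses, key=lambda r: r.prompt_index)
        if [r.prompt_index for r in self.responses] != [1, 2, 3]:
            raise MalformedCallError(
                f"call ({self.participant_id}, {self.call_time}) must have "
                f"prompt rows 1, 2, 3; got "
                f"{[r.prompt_index for r in self.responses]}"
            )
        if self.provider_rating is not None and not 1 <= self.provider_rating <= 10:
            raise ValueError(
                f"provider rating {self.provider_rating} outside [1, 10]"
            )


@dataclass
class AssessmentRecord:
    """A periodic assessment score (e.g. a symptom-scale summary) with date."""

    participant_id: str
    date: pd.Timestamp
    scale_name: str
    score: float

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if not np.isfinite(self.score):
            raise ValueError("assessment score must be finite")


@dataclass
class Cohort:
    """A longitudinal cohort: calls per participant, diagnoses, assessments."""

    participants: dict[str, list[CallRecord]]
    diagnoses: dict[str, str] = field(default_factory=dict)
    assessments: list[AssessmentRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, calls in self.participants.items():
            if not pid:
                raise ValueError("participant_id must be nonempty")
            calls.sort(key=lambda c: c.call_time)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants)

    @property
    def n_calls(self) -> int:
        return sum(len(c) for c in self.participants.values())

    def all_calls(self) -> Iterable[CallRecord]:
        for calls in self.participants.values():
            yield from calls


class NormLexicon:
    """Case-insensitive word -> nine-norm lookup (values as float arrays)."""

    def __init__(self, entries: Mapping[str, Sequence[float]]):
        self.entries: dict[str, np.ndarray] = {}
        for word, vals in entries.items():
            arr = np.asarray(vals, dtype=np.float64)
            if arr.shape != (len(NORM_NAMES),):
                raise SchemaError(
                    f"norm entry for {word!r} has {arr.size} values, "
                    f"expected {len(NORM_NAMES)}"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"norm entry for {word!r} has non-finite values")
            self.entries[word.lower()] = arr

    def get(self, word: str) -> np.ndarray | None:
        return self.entries.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


class CategoryLexicon:
    """LIWC-style category dictionary: literal words and ``stem*`` prefixes."""

    def __init__(self, categories: Mapping[str, Iterable[str]]):
        self.literals: dict[str, frozenset[str]] = {}
        self.prefixes: dict[str, tuple[str, ...]] = {}
        for name, patterns in categories.items():
            pats = [p.lower() for p in patterns]
            if not pats:
                raise SchemaError(f"category {name!r} has no entries")
            self.literals[name] = frozenset(p for p in pats if not p.endswith("*"))
            self.prefixes[name] = tuple(
                sorted({p[:-1] for p in pats if p.endswith("*") and len(p) > 1})
            )

    @property
    def categories(self) -> list[str]:
        return list(self.literals)

    def matches(self, category: str, token: str) -> bool:
        token = token.lower()
        if token in self.literals[category]:
            return True
        prefixes = self.prefixes[category]
        return bool(prefixes) and token.startswith(prefixes)

    def __len__(self) -> int:
        return len(self.literals)


# ---------------------------------------------------------------------------
# readers / writers


def read_wav(path: str | Path) -> AudioSegment:
    """Read a PCM WAV file; multichannel is averaged to mono.

    Integer PCM is rescaled to [-1, 1] by the type's full scale
    (e.g. int16 by 32768); float WAV is taken as-is.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path} contains no samples")
    dtype = data.dtype
    if data.ndim > 1:
        data = data.astype(np.float64).mean(axis=1)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        scale = float(max(abs(info.min), info.max + 1))
        offset = 0.0
        if info.min == 0:  # unsigned PCM (e.g. uint8) is offset-binary
            offset = (info.max + 1) / 2.0
            scale = (info.max + 1) / 2.0
        data = (data.astype(np.float64) - offset) / scale
    else:
        data = data.astype(np.float64)
    return AudioSegment(samples=data, sample_rate=int(rate))


def write_wav(path: str | Path, segment: AudioSegment) -> Path:
    """Write an :class:`AudioSegment` as 16-bit PCM WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clipped = np.clip(segment.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, segment.sample_rate, pcm)
    return path


def _coerce_rating(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return int(round(float(value)))


def _coerce_rejected(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes"}
    return bool(value)


def read_cohort(
    manifest_path: str | Path,
    audio_root: str | Path | None = None,
    assessments_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort manifest (CSV or JSON-lines, one row per call-prompt).

    Rows sharing (participant_id, call_time) merge into one
    :class:`CallRecord`; calls are returned time-sorted per participant.
    Relative audio paths are resolved against ``audio_root`` (default: the
    manifest's directory).
    """
    manifest_path = Path(manifest_path)
    audio_root = Path(audio_root) if audio_root is not None else manifest_path.parent
    if manifest_path.suffix.lower() in {".jsonl", ".json"}:
        table = pd.read_json(manifest_path, lines=True, dtype={"participant_id": str})
    else:
        table = pd.read_csv(manifest_path, dtype={"participant_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    # transcripts may live in separate files referenced by transcript_path
    if "transcript" in missing and "transcript_path" in table.columns:
        missing.remove("transcript")
    if missing:
        raise SchemaError(
            f"manifest {manifest_path} is missing required column(s): {missing}"
        )
    if "transcript" not in table.columns:
        table["transcript"] = [
            Path(audio_root, p).read_text() for p in table["transcript_path"]
        ]

    participants: dict[str, list[CallRecord]] = {}
    diagnoses: dict[str, str] = {}
    # preserve file order for the stable tie-break on equal call times
    table = table.reset_index(drop=True)
    for (pid, call_time), group in table.groupby(
        ["participant_id", "call_time"], sort=False
    ):
        if len(group) != 3:
            raise MalformedCallError(
                f"call ({pid}, {call_time}) has {len(group)} prompt rows, expected 3"
            )
        responses = []
        for _, row in group.iterrows():
            audio_path = row["audio_path"]
            if isinstance(audio_path, str) and audio_path.strip():
                audio_path = audio_root / audio_path
            else:
                audio_path = None
            transcript = row["transcript"]
            responses.append(
                ResponseRecord(
                    prompt_index=int(row["prompt_index"]),
                    transcript="" if pd.isna(transcript) else str(transcript),
                    audio_path=audio_path,
                    rejected=_coerce_rejected(row["rejected"]),
                )
            )
        ratings = {_coerce_rating(v) for v in group["provider_rating"]}
        if len(ratings) != 1:
            raise MalformedCallError(
                f"call ({pid}, {call_time}) has conflicting provider ratings"
            )
        call = CallRecord(
            participant_id=str(pid),
            call_time=pd.Timestamp(call_time),
            responses=responses,
            provider_rating=ratings.pop(),
        )
        participants.setdefault(str(pid), []).append(call)
        diag = group["diagnosis"].iloc[0]
        if isinstance(diag, str) and diag.strip():
            diagnoses[str(pid)] = diag

    for calls in participants.values():
        calls.sort(key=lambda c: c.call_time)

    assessments: list[AssessmentRecord] = []
    if assessments_path is not None:
        atab = pd.read_csv(assessments_path, dtype={"participant_id": str})
        needed = {"participant_id", "date", "scale_name", "score"}
        if not needed.issubset(atab.columns):
            raise SchemaError(
                f"assessments table missing column(s): {needed - set(atab.columns)}"
            )
        assessments = [
            AssessmentRecord(
                participant_id=str(r.participant_id),
                date=pd.Timestamp(r.date),
                scale_name=str(r.scale_name),
                score=float(r.score),
            )
            for r in atab.itertuples()
        ]
    return Cohort(
        participants=participants, diagnoses=diagnoses, assessments=assessments
    )


def write_cohort(cohort: Cohort, out_dir: str | Path, write_audio: bool = True) -> Path:
    """Write a cohort to the standard on-disk layout (manifest.csv + audio/).

    In-memory audio segments are serialized as 16-bit PCM WAV under
    ``audio/``; the manifest references them relatively. Returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in cohort.participant_ids:
        for i, call in enumerate(cohort.participants[pid]):
            for resp in call.responses:
                rel_audio = ""
                segment = resp.audio
                if segment is None and resp.audio_path is not None:
                    segment = read_wav(resp.audio_path)
                if segment is not None and write_audio:
                    rel_audio = f"audio/{pid}_call{i:03d}_q{resp.prompt_index}.wav"
                    write_wav(out_dir / rel_audio, segment)
                rows.append(
                    {
                        "participant_id": pid,
                        "call_time": call.call_time.isoformat(),
                        "prompt_index": resp.prompt_index,
                        "transcript": resp.transcript,
                        "audio_path": rel_audio,
                        "provider_rating": (
                            "" if call.provider_rating is None else call.provider_rating
                        ),
                        "diagnosis": cohort.diagnoses.get(pid, ""),
                        "rejected": int(resp.rejected),
                    }
                )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False
    )
    if cohort.assessments:
        pd.DataFrame(
            [
                {
                    "participant_id": a.participant_id,
                    "date": a.date.isoformat(),
                    "scale_name": a.scale_name,
                    "score": a.score,
                }
                for a in cohort.assessments
            ]
        ).to_csv(out_dir / "assessments.csv", index=False)
    return manifest_path


def read_norm_lexicon(path: str | Path) -> NormLexicon:
    """Read a word-norm CSV (columns: word + the nine norm names).

    Duplicate words: last row wins, with a logged warning.
    """
    table = pd.read_csv(path)
    missing = [c for c in ("word", *NORM_NAMES) if c not in table.columns]
    if missing:
        raise SchemaError(f"norm lexicon {path} missing column(s): {missing}")
    entries: dict[str, np.ndarray] = {}
    seen_dupes = []
    for row in table.itertuples():
        word = str(row.word).lower()
        if word in entries:
            seen_dupes.append(word)
        entries[word] = np.array(
            [getattr(row, n) for n in NORM_NAMES], dtype=np.float64
        )
    if seen_dupes:
        logger.warning(
            "norm lexicon %s: %d duplicate word(s) (last occurrence kept): %s",
            path,
            len(seen_dupes),
            ", ".join(sorted(set(seen_dupes))[:10]),
        )
    return NormLexicon(entries)


def write_norm_lexicon(lexicon: NormLexicon, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"word": w, **dict(zip(NORM_NAMES, vals))}
        for w, vals in sorted(lexicon.entries.items())
    ]
    pd.DataFrame(rows, columns=["word", *NORM_NAMES]).to_csv(path, index=False)
    return path


def read_category_lexicon(path: str | Path) -> CategoryLexicon:
    """Read a category dictionary: LIWC-style ``.dic`` or a YAML mapping.

    The ``.dic`` layout is a ``%``-delimited header mapping numeric IDs to
    category names, followed by ``word id [id ...]`` lines; a trailing ``*``
    on a word denotes prefix match. YAML files map category name to a word
    list directly.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise SchemaError(f"category YAML {path} must map category -> word list")
        for name, words in data.items():
            if not words:
                raise SchemaError(f"category {name!r} in {path} is empty")
        return CategoryLexicon({str(k): [str(w) for w in v] for k, v in data.items()})

    text = path.read_text()
    parts = text.split("%")
    if len(parts) < 3:
        raise SchemaError(
            f"{path}: expected %%-delimited LIWC-style header (%% ... %% body)"
        )
    header, body = parts[1], "%".join(parts[2:])
    id_to_name: dict[str, str] = {}
    for line in header.splitlines():
        line = line.strip()
        if not line:
            continue
        ident, name = line.split(None, 1)
        id_to_name[ident] = name.strip()
    categories: dict[str, list[str]] = {name: [] for name in id_to_name.values()}
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        word, *ids = line.split()
        for ident in ids:
            if ident not in id_to_name:
                raise SchemaError(f"{path}: word {word!r} uses unknown category id {ident}")
            categories[id_to_name[ident]].append(word)
    for name, words in categories.items():
        if not words:
            raise SchemaError(f"category {name!r} in {path} has zero entries")
    return CategoryLexicon(categories)


def write_category_lexicon(lexicon: CategoryLexicon, path: str | Path) -> Path:
    """Write a :class:`CategoryLexicon` as YAML."""
    path = Path(path)
    data = {
        name: sorted(lexicon.literals[name]) + [p + "*" for p in lexicon.prefixes[name]]
        for name in lexicon.categories
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def write_feature_table(rows: Sequence, path: str | Path) -> Path:
    """Write call-feature rows as a wide CSV.

    Columns: participant_id, call_time, provider_rating, then the 210 named
    features in manifest order. Missing values become empty cells. All rows
    must share one manifest.
    """
    if not rows:
        raise ValueError("no feature rows to write")
    manifest = rows[0].manifest
    for row in rows[1:]:
        if row.manifest != manifest:
            raise SchemaError("feature rows come from different manifests")
    path = Path(path)
    records = []
    for row in rows:
        rec = {
            "participant_id": row.participant_id,
            "call_time": pd.Timestamp(row.call_time).isoformat(),
            "provider_rating": (
                np.nan if row.provider_rating is None else row.provider_rating
            ),
        }
        rec.update(zip(manifest.call_feature_names(), row.values))
        records.append(rec)
    frame = pd.DataFrame(
        records,
        columns=["participant_id", "call_time", "provider_rating"]
        + manifest.call_feature_names(),
    )
    frame.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV back as a DataFrame (metadata + features)."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    frame["call_time"] = pd.to_datetime(frame["call_time"])
    return frame
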