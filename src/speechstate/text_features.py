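"""Per-response lexical features.

Tokenization, heuristic syllable counting, LIWC-style category
percentages, norm functionals (mean/min/max/std of the nine word norms
over in-vocabulary tokens), and readability / complexity indices.

Spontaneous-speech transcripts frequently lack punctuation; sentence-based
formulas therefore fall back to treating the whole response as one
sentence, or optionally to fixed-length pseudo-sentences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from speechstate.corpus_io import NORM_NAMES, CategoryLexicon, NormLexicon

#: Functionals applied to each norm's in-vocabulary values.
NORM_FUNCTIONALS: tuple[str, ...] = ("mean", "min", "max", "std")

#: Complexity / readability feature names, in manifest order.
COMPLEXITY_FEATURES: tuple[str, ...] = (
    "flesch_reading_ease",
    "flesch_kincaid_grade",
    "smog_index",
    "automated_readability_index",
    "coleman_liau_index",
    "difficult_word_count",
    "mean_syllables_per_word",
    "word_count",
)

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
_STRIP_PUNCT = re.compile(r"^\W+|\W+$", re.UNICODE)
_VOWEL_GROUP = re.compile(r"[aeiouy]+")


@dataclass
class TokenSequence:
    """Lowercased word tokens plus sentence boundaries as token-index ranges."""

    tokens: list[str]
    sentence_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    def sentences(self) -> list[list[str]]:
        return [self.tokens[a:b] for a, b in self.sentence_bounds]

    @property
    def n_sentences(self) -> int:
        return sum(1 for a, b in self.sentence_bounds if b > a) or (
            1 if self.sentence_bounds else 0
        )


def tokenize(text: str, pseudo_sentence_length: int | None = None) -> TokenSequence:
    """Split text into lowercased word tokens and sentence ranges.

    Sentences split on ``. ! ?``. If the text has no terminal punctuation
    the whole response is one sentence, unless ``pseudo_sentence_length``
    is given, in which case it is chunked into fixed-length
    pseudo-sentences of that many words.
    """
    if not text or not text.strip():
        return TokenSequence(tokens=[], sentence_bounds=[(0, 0)])
    tokens: list[str] = []
    bounds: list[tuple[int, int]] = []
    chunks = _SENTENCE_SPLIT.split(text)
    has_punct = len(chunks) > 1
    start = 0
    for chunk in chunks:
        words = [
            w
            for w in (_STRIP_PUNCT.sub("", t).lower() for t in chunk.split())
            if w
        ]
        if not words:
            continue
        tokens.extend(words)
        bounds.append((start, start + len(words)))
        start += len(words)
    if not tokens:
        return TokenSequence(tokens=[], sentence_bounds=[(0, 0)])
    if not has_punct and pseudo_sentence_length:
        bounds = [
            (i, min(i + pseudo_sentence_length, len(tokens)))
            for i in range(0, len(tokens), pseudo_sentence_length)
        ]
    return TokenSequence(tokens=tokens, sentence_bounds=bounds)


def count_syllables(word: str) -> int:
    """Heuristic syllable count: vowel-letter groups, silent-e, minimum 1.

    Counts maximal runs of ``aeiouy``, subtracts a trailing silent 'e'
    (unless that would give zero), and never returns less than 1. This is
    the standard dictionary-free approximation used by readability tools.
    """
    word = word.lower()
    groups = _VOWEL_GROUP.findall(word)
    count = len(groups)
    if count > 1 and word.endswith("e") and groups[-1] == "e":
        count -= 1  # silent trailing 'e'
    return max(count, 1)


def category_percentages(
    tokens: TokenSequence, lexicon: CategoryLexicon
) -> dict[str, float]:
    """Percentage of tokens matching each dictionary category.

    Returns 0.0 for every category when the token list is empty.
    """
    n = len(tokens)
    if n == 0:
        return {c: 0.0 for c in lexicon.categories}
    out = {}
    for category in lexicon.categories:
        hits = sum(1 for t in tokens.tokens if lexicon.matches(category, t))
        out[category] = 100.0 * hits / n
    return out


def norm_functionals(
    tokens: TokenSequence, lexicon: NormLexicon
) -> tuple[dict[tuple[str, str], float], float]:
    """Mean/min/max/std of each norm over in-vocabulary tokens.

    Only tokens found in the lexicon contribute. With no in-vocabulary
    token every functional is missing (NaN). Std is the population
    standard deviation, so a single in-vocabulary token gives 0. Returns
    (functionals, coverage) where coverage is the in-vocabulary fraction.
    """
    vals = [lexicon.get(t) for t in tokens.tokens]
    found = [v for v in vals if v is not None]
    coverage = len(found) / len(tokens) if len(tokens) else 0.0
    out: dict[tuple[str, str], float] = {}
    if not found:
        for norm in NORM_NAMES:
            for fn in NORM_FUNCTIONALS:
                out[(norm, fn)] = math.nan
        return out, coverage
    matrix = np.vstack(found)  # (n_in_vocab, 9)
    means = matrix.mean(axis=0)
    mins = matrix.min(axis=0)
    maxs = matrix.max(axis=0)
    stds = matrix.std(axis=0)  # population (ddof=0): single token -> 0
    for j, norm in enumerate(NORM_NAMES):
        out[(norm, "mean")] = float(means[j])
        out[(norm, "min")] = float(mins[j])
        out[(norm, "max")] = float(maxs[j])
        out[(norm, "std")] = float(stds[j])
    return out, coverage


def readability(
    tokens: TokenSequence, difficult_syllables: int = 7
) -> dict[str, float]:
    """Readability and complexity indices for one response.

    W = words, S = sentences, Y = total syllables, C = letter characters,
    P = words with >= 3 syllables:

    - Flesch reading ease   = 206.835 - 1.015 (W/S) - 84.6 (Y/W)
    - Flesch-Kincaid grade  = 0.39 (W/S) + 11.8 (Y/W) - 15.59
    - SMOG                  = 1.0430 sqrt(30 P / S) + 3.1291
    - Automated Readability = 4.71 (C/W) + 0.5 (W/S) - 21.43
    - Coleman-Liau          = 0.0588 (100 C/W) - 0.296 (100 S/W) - 15.8

    ``difficult_word_count`` counts words with at least
    ``difficult_syllables`` syllables (default 7, i.e. more than six; pass
    3 for the conventional polysyllable rule). Empty input yields NaN for
    everything except the zero word count.
    """
    W = len(tokens)
    if W == 0:
        out = {name: math.nan for name in COMPLEXITY_FEATURES}
        out["word_count"] = 0.0
        return out
    S = tokens.n_sentences
    syllables = np.array([count_syllables(t) for t in tokens.tokens])
    Y = int(syllables.sum())
    C = sum(sum(ch.isalnum() for ch in t) for t in tokens.tokens)
    P = int((syllables >= 3).sum())
    w_per_s = W / S
    y_per_w = Y / W
    return {
        "flesch_reading_ease": 206.835 - 1.015 * w_per_s - 84.6 * y_per_w,
        "flesch_kincaid_grade": 0.39 * w_per_s + 11.8 * y_per_w - 15.59,
        "smog_index": 1.0430 * math.sqrt(30.0 * P / S) + 3.1291,
        "automated_readability_index": 4.71 * (C / W) + 0.5 * w_per_s - 21.43,
        "coleman_liau_index": 0.0588 * (100.0 * C / W) - 0.296 * (100.0 * S / W) - 15.8,
        "difficult_word_count": float((syllables >= difficult_syllables).sum()),
        "mean_syllables_per_word": y_per_w,
        "word_count": float(W),
    }


@dataclass
class LexicalFeatureSet:
    """All lexical features for one response."""

    category_percentages: dict[str, float]
    norm_functionals: dict[tuple[str, str], float]
    readability: dict[str, float]
    norm_coverage: float


def lexical_feature_set(
    text: str,
    norm_lexicon: NormLexicon,
    category_lexicon: CategoryLexicon,
    pseudo_sentence_length: int | None = None,
    difficult_syllables: int = 7,
) -> LexicalFeatureSet:
    """Tokenize a response and compute every lexical feature group."""
    tokens = tokenize(text, pseudo_sentence_length=pseudo_sentence_length)
    norms, coverage = norm_functionals(tokens, norm_lexicon)
    return LexicalFeatureSet(
        category_percentages=category_percentages(tokens, category_lexicon),
        norm_functionals=norms,
        readability=readability(tokens, difficult_syllables=difficult_syllables),
        norm_coverage=coverage,
    )
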