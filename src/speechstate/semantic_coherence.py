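"""Latent-semantic-analysis space and phrase-to-phrase coherence features.

An LSA space is a truncated SVD of the weighted term-document matrix of a
corpus (documents = individual responses). Coherence of a response is the
cosine similarity between the semantic vectors of consecutive phrases —
sentences when the transcript is punctuated, fixed-length word windows
otherwise — summarized by its mean and standard deviation. Low, erratic
coherence is the classical LSA proxy for disorganized speech.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from speechstate.text_features import TokenSequence

WINDOW_PHRASE_LENGTH = 10


class LsaParameterError(ValueError):
    """Invalid LSA construction parameters (e.g. k larger than the data)."""


@dataclass
class LsaSpace:
    """Word vectors from a truncated SVD of the weighted term-doc matrix."""

    vocabulary: list[str]
    word_vectors: np.ndarray  # (|V|, k)
    k: int
    weighting: str

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        if self.word_vectors.shape != (len(self.vocabulary), self.k):
            raise ValueError("word_vectors shape inconsistent with vocabulary/k")
        if not np.all(np.isfinite(self.word_vectors)):
            raise ValueError("word vectors must be finite")

    def vector(self, word: str) -> np.ndarray | None:
        i = self._index.get(word)
        return None if i is None else self.word_vectors[i]

    def phrase_vector(self, words: list[str]) -> np.ndarray | None:
        """Mean of in-vocabulary word vectors; None if all words are OOV."""
        rows = [self._index[w] for w in words if w in self._index]
        if not rows:
            return None
        return self.word_vectors[rows].mean(axis=0)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "vocabulary.txt").write_text(
            "\n".join(self.vocabulary) + "\n"
        )
        np.savetxt(directory / "word_vectors.tsv", self.word_vectors, delimiter="\t")
        (directory / "meta.txt").write_text(f"k={self.k}\nweighting={self.weighting}\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "LsaSpace":
        directory = Path(directory)
        vocab = (directory / "vocabulary.txt").read_text().splitlines()
        vectors = np.atleast_2d(
            np.loadtxt(directory / "word_vectors.tsv", delimiter="\t")
        )
        meta = dict(
            line.split("=", 1)
            for line in (directory / "meta.txt").read_text().splitlines()
        )
        return cls(
            vocabulary=vocab,
            word_vectors=vectors.reshape(len(vocab), -1),
            k=int(meta["k"]),
            weighting=meta["weighting"],
        )


@dataclass
class CoherenceFeatures:
    """Mean and spread of consecutive-phrase cosine similarity."""

    mean_coherence: float
    std_coherence: float
    n_phrase_pairs: int


def _term_document_counts(
    corpus: list[TokenSequence],
) -> tuple[list[str], np.ndarray]:
    vocab = sorted({t for doc in corpus for t in doc.tokens})
    index = {w: i for i, w in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(corpus)))
    for j, doc in enumerate(corpus):
        for t in doc.tokens:
            counts[index[t], j] += 1.0
    return vocab, counts


def _log_entropy_weight(counts: np.ndarray) -> np.ndarray:
    """Classic LSA weighting: log(1+tf) times the word's global entropy weight."""
    n_docs = counts.shape[1]
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    if n_docs > 1:
        global_weight = 1.0 + plogp.sum(axis=1) / math.log(n_docs)
    else:
        global_weight = np.ones(counts.shape[0])
    return np.log1p(counts) * global_weight[:, None]


def _tfidf_weight(counts: np.ndarray) -> np.ndarray:
    n_docs = counts.shape[1]
    df = (counts > 0).sum(axis=1)
    idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    return counts * idf[:, None]


def build_lsa_space(
    corpus: list[TokenSequence], k: int = 50, weighting: str = "log_entropy"
) -> LsaSpace:
    """Build an LSA space from a corpus of tokenized responses.

    The term-document count matrix is weighted (``log_entropy`` default,
    ``tfidf`` optional) and factored with a deterministic full SVD; word
    vectors are the left singular vectors scaled by the singular values.
    ``k`` is clipped to min(|V|, #documents) - 1 when it exceeds the data,
    but must be >= 1.
    """
    if not corpus:
        raise LsaParameterError("corpus must be nonempty")
    vocab, counts = _term_document_counts(corpus)
    max_k = min(len(vocab), counts.shape[1])
    if max_k == 0:
        raise LsaParameterError("corpus contains no tokens")
    if k < 1:
        raise LsaParameterError(f"k must be >= 1, got {k}")
    if k > max_k:
        raise LsaParameterError(f"k={k} exceeds min(|V|, #docs)={max_k}")
    if weighting == "log_entropy":
        weighted = _log_entropy_weight(counts)
    elif weighting == "tfidf":
        weighted = _tfidf_weight(counts)
    elif weighting == "none":
        weighted = counts
    else:
        raise LsaParameterError(f"unknown weighting {weighting!r}")
    # dense deterministic SVD: vocabularies here are small (thousands at most)
    u, s, _ = np.linalg.svd(weighted, full_matrices=False)
    word_vectors = u[:, :k] * s[:k]
    return LsaSpace(vocabulary=vocab, word_vectors=word_vectors, k=k, weighting=weighting)


def fit_lsa_for_cohort(
    documents: list[TokenSequence], k: int = 50, weighting: str = "log_entropy"
) -> LsaSpace:
    """Build the default self-contained space, clipping k to the corpus size."""
    vocab_size = len({t for doc in documents for t in doc.tokens})
    max_k = max(1, min(vocab_size, len(documents)) - 1)
    return build_lsa_space(documents, k=min(k, max_k), weighting=weighting)


def _phrases(tokens: TokenSequence, phrase_mode: str) -> list[list[str]]:
    if phrase_mode == "sentence":
        sentences = [s for s in tokens.sentences() if s]
        if len(sentences) > 1:
            return sentences
        # unpunctuated speech: fall back to fixed-length word windows
        phrase_mode = "window"
    if phrase_mode == "window":
        return [
            tokens.tokens[i : i + WINDOW_PHRASE_LENGTH]
            for i in range(0, len(tokens), WINDOW_PHRASE_LENGTH)
        ]
    raise ValueError(f"phrase_mode must be 'sentence' or 'window', got {phrase_mode!r}")


def coherence_features(
    tokens: TokenSequence, space: LsaSpace, phrase_mode: str = "sentence"
) -> CoherenceFeatures:
    """Cosine similarity between consecutive phrase vectors, mean and std.

    Phrases whose words are all out of vocabulary are skipped (a zero
    vector has no direction). Fewer than two usable phrases yields missing
    features (NaN, n_phrase_pairs = 0). Std is the population standard
    deviation of the similarity series.
    """
    vectors = [
        v
        for phrase in _phrases(tokens, phrase_mode)
        if phrase and (v := space.phrase_vector(phrase)) is not None
        and np.linalg.norm(v) > 0
    ]
    if len(vectors) < 2:
        return CoherenceFeatures(math.nan, math.nan, 0)
    sims = []
    for a, b in zip(vectors[:-1], vectors[1:]):
        cos = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        sims.append(min(1.0, max(-1.0, cos)))
    series = np.asarray(sims)
    return CoherenceFeatures(
        mean_coherence=float(series.mean()),
        std_coherence=float(series.std()),
        n_phrase_pairs=len(sims),
    )
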