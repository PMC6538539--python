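"""Word-vector I/O, tokenization, and fixed-shape embedded inputs.

Vectors are exchanged in the two classic word2vec dialects: a text file whose
first line is ``"<vocab_size> <dim>"`` followed by one ``token v1 ... vk``
line per word, and the packed binary form with the same ASCII header and
little-endian float32 payloads.  Pre-trained biomedical vectors (for example
skip-gram models induced from PubMed abstracts, conventionally 200
dimensional) are consumed as-is; for tests and simulations a seeded random
matrix stands in.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_DIM = 200
DEFAULT_FIXED_LEN = 64  # ~256 characters at ~4 characters/token


class EmbeddingFormatError(ValueError):
    """A word-vector file does not satisfy its declared header."""


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace; hyphens stay inside tokens.

    Deterministic and aligned with how group texts are assembled (fields
    joined by single spaces), so entity names like ``"ubiquinone-9"`` survive
    as single tokens.
    """
    return text.lower().split()


@dataclass
class EmbeddingMatrix:
    """A vocabulary with its V x k vector matrix and an OOV policy.

    ``oov_policy`` controls what out-of-vocabulary tokens map to when texts
    are embedded: ``"zero"`` gives the all-zero vector, ``"random_seeded"``
    draws one uniform [-0.25, 0.25] vector per distinct token, derived
    deterministically from ``oov_seed`` and the token, and caches it for the
    lifetime of the matrix.
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray
    oov_policy: str = "random_seeded"
    oov_seed: int = 0
    _oov_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vocabulary size must match vector row count")
        if self.oov_policy not in ("zero", "random_seeded"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    @property
    def tokens(self) -> list[str]:
        out = [""] * len(self.vocabulary)
        for tok, idx in self.vocabulary.items():
            out[idx] = tok
        return out

    def vector(self, token: str) -> np.ndarray:
        """The vector for `token`, applying the OOV policy if absent."""
        idx = self.vocabulary.get(token)
        if idx is not None:
            return self.vectors[idx]
        if self.oov_policy == "zero":
            return np.zeros(self.k, dtype=np.float32)
        cached = self._oov_cache.get(token)
        if cached is None:
            token_seed = (self.oov_seed * 2654435761 + zlib.crc32(token.encode())) % (2**31)
            rng = np.random.default_rng(token_seed)
            cached = rng.uniform(-0.25, 0.25, self.k).astype(np.float32)
            self._oov_cache[token] = cached
        return cached


@dataclass(frozen=True)
class EmbeddedText:
    """A fixed-length n x k embedding of one text.

    Rows 0..len(tokens)-1 hold token vectors; padded rows are all-zero and
    flagged False in ``mask``.
    """

    matrix: np.ndarray
    mask: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_real(self) -> int:
        return int(self.mask.sum())


def random_embeddings(tokens: Iterable[str], k: int = DEFAULT_DIM, seed: int = 0) -> EmbeddingMatrix:
    """A seeded random embedding matrix: i.i.d. uniform entries in [-0.25, 0.25]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tokens = list(dict.fromkeys(tokens))  # de-duplicate, order-preserving
    rng = np.random.default_rng(seed)
    vectors = rng.uniform(-0.25, 0.25, (len(tokens), k)).astype(np.float32)
    vocab = {tok: i for i, tok in enumerate(tokens)}
    return EmbeddingMatrix(vocabulary=vocab, vectors=vectors, oov_seed=seed)


def vocabulary_of(texts: Iterable[str]) -> list[str]:
    """All distinct tokens across `texts`, in first-appearance order."""
    seen: dict[str, None] = {}
    for text in texts:
        for tok in tokenize(text):
            seen.setdefault(tok, None)
    return list(seen)


def load_word_vectors(
    path: str | Path,
    format: str = "word2vec_text",
    expected_dim: int | None = None,
) -> EmbeddingMatrix:
    """Load word vectors in word2vec text or binary format.

    The file must start with the header line ``"<vocab_size> <dim>"``.  A
    vector count short of the header is a format error; a dimension other
    than `expected_dim` (when given) logs a warning and the file's dimension
    wins.
    """
    path = Path(path)
    if format == "word2vec_text":
        vocab, vectors = _load_text(path)
    elif format == "word2vec_binary":
        vocab, vectors = _load_binary(path)
    else:
        raise ValueError(f"unknown embedding format {format!r}")
    if expected_dim is not None and vectors.shape[1] != expected_dim:
        logger.warning(
            "%s: dimension %d differs from expected %d; using the file's",
            path, vectors.shape[1], expected_dim,
        )
    return EmbeddingMatrix(vocabulary=vocab, vectors=vectors)


def _parse_header(line: str, path: Path) -> tuple[int, int]:
    parts = line.split()
    if len(parts) != 2:
        raise EmbeddingFormatError(f"{path}: malformed word2vec header {line!r}")
    try:
        v, k = int(parts[0]), int(parts[1])
    except ValueError:
        raise EmbeddingFormatError(f"{path}: non-integer word2vec header {line!r}")
    if v < 0 or k < 1:
        raise EmbeddingFormatError(f"{path}: invalid header sizes {v} {k}")
    return v, k


def _load_text(path: Path) -> tuple[dict[str, int], np.ndarray]:
    with path.open(encoding="utf-8") as fh:
        v, k = _parse_header(fh.readline().rstrip("\n"), path)
        vocab: dict[str, int] = {}
        vectors = np.empty((v, k), dtype=np.float32)
        for i in range(v):
            line = fh.readline()
            if not line:
                raise EmbeddingFormatError(
                    f"{path}: header promises {v} vectors, found {i}"
                )
            parts = line.rstrip("\n").split(" ")
            if len(parts) != k + 1:
                raise EmbeddingFormatError(
                    f"{path}: vector {i} has {len(parts) - 1} values, expected {k}"
                )
            vocab[parts[0]] = i
            vectors[i] = np.asarray(parts[1:], dtype=np.float32)
    return vocab, vectors


def _load_binary(path: Path) -> tuple[dict[str, int], np.ndarray]:
    with path.open("rb") as fh:
        header = b""
        while not header.endswith(b"\n"):
            ch = fh.read(1)
            if not ch:
                raise EmbeddingFormatError(f"{path}: missing word2vec header")
            header += ch
        v, k = _parse_header(header.decode("utf-8").strip(), path)
        vocab: dict[str, int] = {}
        vectors = np.empty((v, k), dtype=np.float32)
        for i in range(v):
            token = b""
            while True:
                ch = fh.read(1)
                if not ch:
                    raise EmbeddingFormatError(
                        f"{path}: header promises {v} vectors, found {i}"
                    )
                if ch == b" ":
                    break
                if ch != b"\n":  # tolerate newline between entries
                    token += ch
            payload = fh.read(4 * k)
            if len(payload) != 4 * k:
                raise EmbeddingFormatError(
                    f"{path}: truncated vector payload for token {i}"
                )
            vocab[token.decode("utf-8")] = i
            vectors[i] = np.frombuffer(payload, dtype="<f4")
    return vocab, vectors


def save_word_vectors(
    emb: EmbeddingMatrix, path: str | Path, format: str = "word2vec_text"
) -> Path:
    """Companion writer: emit `emb` in either word2vec dialect."""
    path = Path(path)
    tokens = emb.tokens
    if format == "word2vec_text":
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(tokens)} {emb.k}\n")
            for tok, row in zip(tokens, emb.vectors):
                values = " ".join(np.format_float_positional(x, trim="0") for x in row)
                fh.write(f"{tok} {values}\n")
    elif format == "word2vec_binary":
        with path.open("wb") as fh:
            fh.write(f"{len(tokens)} {emb.k}\n".encode("utf-8"))
            for tok, row in zip(tokens, emb.vectors):
                fh.write(tok.encode("utf-8") + b" ")
                fh.write(np.asarray(row, dtype="<f4").tobytes())
                fh.write(b"\n")
    else:
        raise ValueError(f"unknown embedding format {format!r}")
    return path


def embed(
    texts: Sequence,
    emb: EmbeddingMatrix,
    fixed_len: int = DEFAULT_FIXED_LEN,
) -> list[EmbeddedText]:
    """Embed texts into fixed-shape ``fixed_len x k`` matrices.

    Accepts plain strings or objects with a ``.text`` attribute.  Tokens
    beyond `fixed_len` are dropped; shorter texts are zero-padded, with the
    mask flagging real rows.  OOV tokens follow ``emb.oov_policy``.
    """
    if fixed_len < 1:
        raise ValueError("fixed_len must be >= 1")
    out: list[EmbeddedText] = []
    for item in texts:
        text = getattr(item, "text", item)
        tokens = tokenize(text)[:fixed_len]
        matrix = np.zeros((fixed_len, emb.k), dtype=np.float32)
        for i, tok in enumerate(tokens):
            matrix[i] = emb.vector(tok)
        mask = np.zeros(fixed_len, dtype=bool)
        mask[: len(tokens)] = True
        out.append(EmbeddedText(matrix=matrix, mask=mask))
    return out
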