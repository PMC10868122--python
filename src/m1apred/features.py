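"""The 522-value feature encoding of an RNA window.

Six feature groups are concatenated in a frozen order:

================  =====  =========================================================
group             size   content
================  =====  =========================================================
PRIM              90     30 moments of the position-relative incidence matrix at
                         k-mer levels 1, 2, 3 (4x4, 16x16, 64x64)
RPRIM             90     the same on the reversed sequence
FV                84     overlapping k-mer counts, k = 1, 2, 3 (4 + 16 + 64)
AAPIV             84     accumulative absolute position incidence vectors: per
                         k-mer sum of 1-based occurrence start positions
RAAPIV            84     AAPIV of the reversed sequence
SEQMAT            90     30 moments of the row-major sequence matrix at k = 1, 2, 3
================  =====  =========================================================

PRIM cell rule (frozen): ``V[i -> j]`` accumulates the forward pairwise
distance ``q - p`` over every ordered pair of stream positions ``p < q``
with ``token_p = i`` and ``token_q = j``.  Any fixed rule that preserves
relative-position information would serve; this one is simple,
order-sensitive and directly testable by pair enumeration.

k-mers are indexed lexicographically with A < C < G < U, consistent with
the base codes of :mod:`m1apred.seqio`; the occurrence position of a
di-/tri-nucleotide is the 1-based index of its first base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from m1apred.moments import MOMENT_ORDERS, moment_set
from m1apred.seqio import BASE_TO_CODE, CODE_TO_BASE, RnaWindow, encode, reverse

#: Total encoding length and named group slices, in concatenation order.
FEATURE_LENGTH = 522
GROUP_SLICES: dict[str, slice] = {
    "PRIM": slice(0, 90),
    "RPRIM": slice(90, 180),
    "FV": slice(180, 264),
    "AAPIV": slice(264, 348),
    "RAAPIV": slice(348, 432),
    "SEQMAT": slice(432, 522),
}

KMER_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class KmerTokenStream:
    """Overlapping k-mer tokens of a sequence as lexicographic codes in [1, 4^k]."""

    k: int
    tokens: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 522-value encoding of one window."""

    values: np.ndarray
    source_id: str = ""
    label: str | None = None

    def group(self, name: str) -> np.ndarray:
        return self.values[GROUP_SLICES[name]]


def kmer_code(kmer: str, k: int | None = None) -> int:
    """Lexicographic 1-based code of a k-mer (AA..A -> 1, UU..U -> 4^k)."""
    k = k or len(kmer)
    code = 0
    for b in kmer:
        code = code * 4 + (BASE_TO_CODE[b] - 1)
    return code + 1


def code_kmer(code: int, k: int) -> str:
    """Inverse of :func:`kmer_code`."""
    code -= 1
    out = []
    for _ in range(k):
        out.append(CODE_TO_BASE[code % 4 + 1])
        code //= 4
    return "".join(reversed(out))


def _tokenize_codes(codes: np.ndarray, k: int) -> KmerTokenStream:
    if k not in KMER_LEVELS:
        raise ValueError(f"k must be one of {KMER_LEVELS}, got {k}")
    if len(codes) < k:
        raise ValueError(f"sequence length {len(codes)} shorter than k={k}")
    toks = np.zeros(len(codes) - k + 1, dtype=np.int64)
    for off in range(k):
        toks = toks * 4 + (codes[off : off + len(toks)] - 1)
    return KmerTokenStream(k=k, tokens=tuple(int(t) + 1 for t in toks))


def tokenize(window: RnaWindow, k: int) -> KmerTokenStream:
    """Overlapping k-mer token stream of a window, stride 1."""
    return _tokenize_codes(encode(window).as_array(), k)


def sequence_matrix(stream: KmerTokenStream) -> np.ndarray:
    """Row-major square fill of the token stream, zero-padded to d^2 cells.

    d is the smallest integer with d^2 >= token count; cell (1,1) holds the
    first token's code.
    """
    n = len(stream)
    if n == 0:
        raise ValueError("empty token stream")
    d = math.isqrt(n - 1) + 1
    M = np.zeros(d * d)
    M[:n] = stream.tokens
    return M.reshape(d, d)


def prim(stream: KmerTokenStream) -> np.ndarray:
    """Forward position-relative incidence matrix (4^k x 4^k).

    Cell (i, j) sums the distances q - p over ordered pairs p < q of stream
    positions with token i at p and token j at q.  A stream with fewer than
    two tokens yields the zero matrix.
    """
    side = 4**stream.k
    V = np.zeros((side, side))
    t = np.asarray(stream.tokens, dtype=np.int64) - 1
    n = len(t)
    if n >= 2:
        p, q = np.triu_indices(n, k=1)
        np.add.at(V, (t[p], t[q]), (q - p).astype(float))
    return V


def _codes_of(seq: str) -> np.ndarray:
    """Integer codes of an arbitrary ACGU string (no window invariants)."""
    return np.array([BASE_TO_CODE[b] for b in seq], dtype=np.int64)


def rprim(window: RnaWindow, k: int) -> np.ndarray:
    """PRIM of the reversed (not complemented) window at level k."""
    return prim(_tokenize_codes(_codes_of(reverse(window)), k))


def frequency_vector(window: RnaWindow) -> np.ndarray:
    """84 overlapping k-mer counts over k = 1, 2, 3, lexicographic within level."""
    codes = encode(window).as_array()
    parts = []
    for k in KMER_LEVELS:
        stream = _tokenize_codes(codes, k)
        counts = np.bincount(np.asarray(stream.tokens) - 1, minlength=4**k).astype(float)
        parts.append(counts)
    return np.concatenate(parts)


def _position_sums(codes: np.ndarray) -> np.ndarray:
    """Per-k-mer sums of 1-based occurrence start positions, k = 1, 2, 3 (84 values)."""
    parts = []
    for k in KMER_LEVELS:
        stream = _tokenize_codes(codes, k)
        acc = np.zeros(4**k)
        np.add.at(acc, np.asarray(stream.tokens) - 1, np.arange(1, len(stream) + 1, dtype=float))
        parts.append(acc)
    return np.concatenate(parts)


def aapiv(window: RnaWindow) -> np.ndarray:
    """Accumulative absolute position incidence vectors (forward), 84 values."""
    return _position_sums(encode(window).as_array())


def raapiv(window: RnaWindow) -> np.ndarray:
    """AAPIV computed on the reversed symbol sequence, 84 values."""
    return _position_sums(_codes_of(reverse(window)))


def _moments_or_zero(M: np.ndarray, u: float, v: float) -> np.ndarray:
    # A zero matrix (token stream with < 2 tokens) has no centroid; its
    # moments are taken as the zero limit.  Cannot occur for 41-nt windows.
    if not M.any():
        return np.zeros(3 * len(MOMENT_ORDERS))
    return moment_set(M, u=u, v=v).values()


def assemble(window: RnaWindow, u: float = 0.0, v: float = 0.0) -> FeatureVector:
    """Build the full 522-value feature vector of one window.

    ``u`` and ``v`` are the Hahn polynomial shape parameters applied to every
    matrix-valued group.
    """
    codes = encode(window).as_array()
    rev_codes = codes[::-1]

    blocks: list[np.ndarray] = []
    for k in KMER_LEVELS:  # PRIM: 90
        blocks.append(_moments_or_zero(prim(_tokenize_codes(codes, k)), u, v))
    for k in KMER_LEVELS:  # RPRIM: 90
        blocks.append(_moments_or_zero(prim(_tokenize_codes(rev_codes, k)), u, v))
    blocks.append(frequency_vector(window))  # FV: 84
    blocks.append(_position_sums(codes))  # AAPIV: 84
    blocks.append(_position_sums(rev_codes))  # RAAPIV: 84
    for k in KMER_LEVELS:  # SEQMAT: 90
        blocks.append(_moments_or_zero(sequence_matrix(_tokenize_codes(codes, k)), u, v))

    values = np.concatenate(blocks)
    assert values.shape == (FEATURE_LENGTH,)
    return FeatureVector(values=values, source_id=window.id, label=window.label)


def feature_names() -> list[str]:
    """Column names for the 522 features: group.k.family.jk or group.kmer."""
    names: list[str] = []
    families = ["raw", "central", "hahn"]
    for group in ("PRIM", "RPRIM"):
        for k in KMER_LEVELS:
            for fam in families:
                for j, kk in MOMENT_ORDERS:
                    names.append(f"{group}.k{k}.{fam}.{j}{kk}")
    for k in KMER_LEVELS:
        names.extend(f"FV.{code_kmer(c, k)}" for c in range(1, 4**k + 1))
    for group in ("AAPIV", "RAAPIV"):
        for k in KMER_LEVELS:
            names.extend(f"{group}.{code_kmer(c, k)}" for c in range(1, 4**k + 1))
    for k in KMER_LEVELS:
        for fam in families:
            for j, kk in MOMENT_ORDERS:
                names.append(f"SEQMAT.k{k}.{fam}.{j}{kk}")
    assert len(names) == FEATURE_LENGTH
    return names


def feature_table(windows: list[RnaWindow], u: float = 0.0, v: float = 0.0):
    """Encode many windows into a pandas DataFrame with named columns.

    The ``id`` index and a trailing ``label`` column (1 positive, 0 negative,
    NA unlabeled) frame the 522 feature columns.
    """
    import pandas as pd

    rows = [assemble(w, u=u, v=v).values for w in windows]
    df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, FEATURE_LENGTH)), columns=feature_names())
    df.insert(0, "id", [w.id for w in windows])
    lab = {"positive": 1, "negative": 0, "unlabeled": pd.NA}
    df["label"] = [lab[w.label] for w in windows]
    return df
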