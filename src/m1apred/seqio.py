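"""Reading, validation and integer encoding of RNA windows.

A *window* is a fixed, odd-length fragment (default 41 nt) over the RNA
alphabet {A, C, G, U} whose central base is the candidate adenosine.  All
feature extraction downstream operates on windows produced here.

Conventions frozen in this module (moment values depend on them):

* base codes A=1, C=2, G=3, U=4 (alphabetical over the RNA alphabet);
* positions are 1-based throughout;
* ``T``/``t`` on input is transcribed to ``U``; any other non-ACGU symbol
  (including ``N``) is rejected rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from Bio import SeqIO

DEFAULT_WINDOW = 41

BASE_TO_CODE = {"A": 1, "C": 2, "G": 3, "U": 4}
CODE_TO_BASE = {v: k for k, v in BASE_TO_CODE.items()}

Label = Literal["positive", "negative", "unlabeled"]


class FastaFormatError(ValueError):
    """Raised for empty FASTA files or records with empty sequences."""


class WindowError(ValueError):
    """Base class for window-validation failures."""


class LengthError(WindowError):
    pass


class CenterError(WindowError):
    pass


class AlphabetError(WindowError):
    pass


@dataclass(frozen=True)
class RnaWindow:
    """A validated RNA fragment of odd length W with adenosine at its center.

    Construct via :func:`validate_window`; direct construction skips checks.
    """

    id: str
    bases: str
    label: Label = "unlabeled"

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def center(self) -> int:
        """1-based index of the central position."""
        return (len(self.bases) + 1) // 2


@dataclass(frozen=True)
class IndexedSequence:
    """Positional integer codes of a window under A=1, C=2, G=3, U=4."""

    codes: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.codes)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.codes, dtype=np.int64)


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U").replace(" ", "").replace("\t", "")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs, order preserved.

    Sequences are uppercased, whitespace-stripped, and DNA-style T is
    transcribed to U.  Raises :class:`FileNotFoundError` for a missing file
    and :class:`FastaFormatError` for an empty file or an empty record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = [(rec.description, _normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    for rid, seq in records:
        if not seq:
            raise FastaFormatError(f"record {rid!r} has an empty sequence")
    return records


def validate_window(seq: str, W: int = DEFAULT_WINDOW, id: str = "", label: Label = "unlabeled") -> RnaWindow:
    """Validate a raw sequence as an RNA window of length ``W``.

    ``W`` must be odd.  The sequence must have length ``W``, alphabet within
    {A, C, G, U} (after T->U transcription) and adenosine at the central
    1-based position ``(W+1)/2``.
    """
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window length must be a positive odd integer, got {W}")
    seq = _normalize(seq)
    if len(seq) != W:
        raise LengthError(f"expected length {W}, got {len(seq)}")
    bad = set(seq) - set(BASE_TO_CODE)
    if bad:
        raise AlphabetError(f"invalid symbols {sorted(bad)}; alphabet is A,C,G,U")
    center = (W + 1) // 2
    if seq[center - 1] != "A":
        raise CenterError(f"central base (position {center}) must be A, got {seq[center - 1]!r}")
    return RnaWindow(id=id, bases=seq, label=label)


def encode(window: RnaWindow) -> IndexedSequence:
    """Map a window to positional integer codes (A=1, C=2, G=3, U=4)."""
    return IndexedSequence(tuple(BASE_TO_CODE[b] for b in window.bases))


def decode(indexed: IndexedSequence) -> str:
    """Inverse of :func:`encode`."""
    return "".join(CODE_TO_BASE[c] for c in indexed.codes)


def reverse(window: RnaWindow) -> str:
    """Plain order reversal of the window's bases (no complementation)."""
    return window.bases[::-1]


def scan_sites(seq: str, W: int = DEFAULT_WINDOW, id: str = "") -> list[tuple[int, RnaWindow]]:
    """Enumerate candidate adenosine sites in an arbitrary-length sequence.

    Returns one ``(position, window)`` pair per A whose ±(W−1)/2 flanks lie
    entirely inside the sequence; positions are 1-based on the input.  A
    sequence shorter than ``W`` yields an empty list with a warning.
    """
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window length must be a positive odd integer, got {W}")
    seq = _normalize(seq)
    if len(seq) < W:
        warnings.warn(f"sequence shorter than window ({len(seq)} < {W}); no sites scanned")
        return []
    half = (W - 1) // 2
    sites = []
    for pos0 in range(half, len(seq) - half):
        if seq[pos0] == "A":
            frag = seq[pos0 - half : pos0 + half + 1]
            try:
                win = validate_window(frag, W, id=f"{id}|pos={pos0 + 1}" if id else f"pos={pos0 + 1}")
            except WindowError:
                continue
            sites.append((pos0 + 1, win))
    return sites
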