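"""Synthetic labeled RNA windows for end-to-end testing of the toolkit.

The generator emulates the compositional structure that experimentally
verified m1A window sets exhibit: 41-nt windows over {A, C, G, U} with the
central adenosine fixed, an overall U/A-rich background, G spread evenly
across positions, and C confined to a narrow band around the center
(positions 19-23 of a 41-nt window).

Class signal is a planted positional dinucleotide: positive windows
receive, with probability ``min(1, effect / 3)``, the motif (default
``AG``) written immediately upstream of the central adenosine.  A
dinucleotide rather than a single-base shift is planted so that the
position-sensitive feature groups (PRIM, AAPIV), not just composition
counts, carry discriminative information.  ``effect = 0`` makes the
classes exactly exchangeable; at the nominal strong setting
``effect = 3`` every positive carries the consensus motif, the way
genuine modification contexts (e.g. the GUUCRA T-loop consensus around
tRNA m1A58) accompany essentially all modified sites.

The generator is a testing device, not a statistical model of any real
m1A dataset: real windows carry long-range dependence, species mixture
and label noise that per-position sampling does not emulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from m1apred.seqio import CODE_TO_BASE, RnaWindow, validate_window

#: Background per-position base probabilities (A, C, G, U).
_BG_NO_C = (0.35, 0.0, 0.25, 0.40)
_BG_C_BAND = (0.30, 0.20, 0.20, 0.30)
#: Half-width of the C-bearing band around the center (positions 19-23 at W=41).
_C_BAND_HALF = 2


def default_profile(W: int = 41) -> np.ndarray:
    """Per-position base probability rows (W x 4, order A, C, G, U).

    U/A-enriched everywhere, G uniform, C nonzero only within +/-2 positions
    of the center, and the center row forcing A with probability 1.
    """
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window length must be a positive odd integer, got {W}")
    center = (W + 1) // 2
    profile = np.empty((W, 4))
    for pos in range(1, W + 1):
        if pos == center:
            profile[pos - 1] = (1.0, 0.0, 0.0, 0.0)
        elif abs(pos - center) <= _C_BAND_HALF:
            profile[pos - 1] = _BG_C_BAND
        else:
            profile[pos - 1] = _BG_NO_C
    return profile


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``effect`` scales the planted class signal: the enrichment motif is
    written into a positive window with probability ``min(1, effect / 3)``.
    """

    n_pos: int = 1000
    n_neg: int = 1000
    W: int = 41
    effect: float = 3.0
    seed: int = 0
    motif: str = "AG"
    profile: np.ndarray | None = None

    def resolved_profile(self) -> np.ndarray:
        prof = default_profile(self.W) if self.profile is None else np.asarray(self.profile, float)
        if prof.shape != (self.W, 4):
            raise ValueError(f"profile must be {self.W} x 4")
        if not np.allclose(prof.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")
        if prof[(self.W + 1) // 2 - 1, 0] != 1.0:
            raise ValueError("center row must force A")
        return prof


def generate(config: GeneratorConfig) -> list[RnaWindow]:
    """Draw ``n_pos`` positive and ``n_neg`` negative labeled windows.

    Each position is sampled independently from the positional profile;
    positives then receive the enrichment motif immediately 5' of the
    center with probability ``min(1, effect / 3)``.  Deterministic per seed;
    every returned window satisfies the window invariants.
    """
    if config.effect < 0:
        raise ValueError("effect must be nonnegative")
    prof = config.resolved_profile()
    motif = config.motif.upper().replace("T", "U")
    center = (config.W + 1) // 2
    if len(motif) >= center:
        raise ValueError("motif does not fit upstream of the center")
    rng = np.random.default_rng(config.seed)
    p_plant = min(1.0, config.effect / 3.0)
    cum = prof.cumsum(axis=1)

    windows: list[RnaWindow] = []
    for i, label in enumerate(["positive"] * config.n_pos + ["negative"] * config.n_neg):
        draws = (rng.random(config.W)[:, None] < cum).argmax(axis=1)
        bases = [CODE_TO_BASE[c + 1] for c in draws]
        if label == "positive" and rng.random() < p_plant:
            start = center - 1 - len(motif)  # 0-based; motif ends just before the center
            bases[start : start + len(motif)] = list(motif)
        win = validate_window("".join(bases), config.W, id=f"synth_{i}", label=label)
        windows.append(win)
    return windows


def write_fasta(windows: list[RnaWindow], path) -> None:
    """Write windows as FASTA with the label encoded in each header.

    Headers take the form ``<id>|label=pos`` / ``|label=neg`` (omitted for
    unlabeled windows) and round-trip through :func:`m1apred.seqio.read_fasta`.
    """
    if not windows:
        warnings.warn("writing an empty FASTA file")
    tag = {"positive": "|label=pos", "negative": "|label=neg", "unlabeled": ""}
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.id}{tag[w.label]}\n{w.bases}\n")


def parse_label(header: str) -> str:
    """Recover a window label from a FASTA header written by :func:`write_fasta`."""
    if "|label=pos" in header:
        return "positive"
    if "|label=neg" in header:
        return "negative"
    return "unlabeled"
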