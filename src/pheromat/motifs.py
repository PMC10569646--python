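"""Residue-class motif primitives for pheromone screens and receptor QC.

The motifs here are the sequence rules that define fungal mating
pheromones and their processing: the C-terminal CAAX/CPAX prenylation box
of the a-factor, the KEX1/2 (KR/RR/KK) and STE13 (XA/XP) proteolytic
processing sites of the α-factor pro-protein, S/T-rich regions, the GY
dipeptide near the a-factor C-terminus, and Kyte–Doolittle hydropathy
segments used for signal-peptide and transmembrane detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "U": 0.0, "*": 0.0,
}

KEX_DIPEPTIDES = ("KR", "RR", "KK")


@dataclass(frozen=True)
class ResidueClasses:
    """Configurable aliphatic / polar residue classes for box matching.

    Defaults cover every terminal box observed among Leotiomycete
    a-factors (CTVM, CVVM, CIVM, CTIL, CSIM, CSVM) while leaving
    G, P, W and F outside both classes.
    """

    aliphatic: frozenset = frozenset("AVLIM")
    polar: frozenset = frozenset("STCNQYHKRDE")

    def __post_init__(self) -> None:
        std = set("ACDEFGHIKLMNPQRSTVWY")
        if not (set(self.aliphatic) <= std and set(self.polar) <= std):
            raise ValueError("residue classes must contain standard amino acids only")


DEFAULT_CLASSES = ResidueClasses()


@dataclass
class MotifHit:
    """A located motif, [start, end) in 0-based protein coordinates."""

    kind: str  # STE13 | KEX | GY | CAAX | CPAX | signal | TM
    start: int
    end: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad motif interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def terminal_caax_class(protein: str, classes: ResidueClasses = DEFAULT_CLASSES) -> str:
    """Classify the last four residues as ``CAAX``, ``CPAX`` or ``none``.

    The box is C, then aliphatic (CAAX) or polar (CPAX), then aliphatic,
    then any residue; CAAX takes precedence when a residue is in both
    classes.  Only the final four residues are inspected.
    """
    if len(protein) < 4:
        logger.warning("protein of length %d too short for a CAAX/CPAX box", len(protein))
        return "none"
    box = protein[-4:].upper()
    if box[0] != "C":
        return "none"
    if box[2] not in classes.aliphatic:
        return "none"
    if box[1] in classes.aliphatic:
        return "CAAX"
    if box[1] in classes.polar:
        return "CPAX"
    return "none"


def find_kex_sites(protein: str) -> list[MotifHit]:
    """All KEX1/2 dibasic sites (KR, RR, KK), overlaps included."""
    protein = protein.upper()
    hits = [
        MotifHit("KEX", i, i + 2)
        for i in range(len(protein) - 1)
        if protein[i : i + 2] in KEX_DIPEPTIDES
    ]
    return hits


def _is_xap(pair: str) -> bool:
    return len(pair) == 2 and pair[1] in "AP"


def find_ste13_sites(protein: str) -> list[MotifHit]:
    """STE13 processing sites: XA/XP dipeptides and XAXA/XPXP/XAXP runs.

    A run is a maximal chain of X[AP] dipeptides stepping by two from the
    run start; each maximal run (including singletons) is one hit.  Runs
    starting at different parities may overlap and are both reported.
    """
    protein = protein.upper()
    n = len(protein)
    hits: list[MotifHit] = []
    matched = [False] * n  # start positions already inside a same-parity run
    for i in range(n - 1):
        if matched[i] or not _is_xap(protein[i : i + 2]):
            continue
        j = i
        while j + 2 <= n and _is_xap(protein[j : j + 2]):
            matched[j] = True
            j += 2
        hits.append(MotifHit("STE13", i, j))
    hits.sort(key=lambda h: h.start)
    return hits


def st_fraction(protein: str, window: int = 20) -> float:
    """Fraction of S+T residues in the first ``min(window, len)`` residues."""
    if not protein:
        raise ValueError("empty protein")
    if window < 1:
        raise ValueError("window must be >= 1")
    prefix = protein[: min(window, len(protein))].upper()
    return (prefix.count("S") + prefix.count("T")) / len(prefix)


def find_gy_motif(protein: str, tail_window: int = 15) -> MotifHit | None:
    """Last GY dipeptide within ``tail_window`` residues of the terminal box C.

    The caller is responsible for having verified the CAAX/CPAX terminal
    class; the window is measured upstream of the box cysteine at -4.
    """
    protein = protein.upper()
    c_pos = len(protein) - 4
    if c_pos < 0:
        return None
    lo = max(0, c_pos - tail_window)
    best = None
    for i in range(lo, c_pos):
        if protein[i : i + 2] == "GY":
            best = i
    if best is None:
        return None
    return MotifHit("GY", best, best + 2)


def hydropathy_profile(protein: str, window: int) -> np.ndarray:
    """Sliding-window mean Kyte–Doolittle hydropathy (one value per window centre)."""
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein.upper()], dtype=float)
    if len(vals) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def hydropathy_segments(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_run: int = 15,
    merge_gap: int = 3,
    signal_zone: int = 30,
) -> list[MotifHit]:
    """Hydrophobic segments by sliding-window Kyte–Doolittle averaging.

    Positions (window centres, reported as full-window [start, end)
    protein intervals) whose mean hydropathy exceeds ``threshold`` are
    collected into maximal runs; runs separated by gaps of at most
    ``merge_gap`` are merged, and merged runs spanning fewer than
    ``min_run`` residues are dropped.  Segments whose interval starts
    within the first ``signal_zone`` residues carry ``meta['signal_like']``.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    prof = hydropathy_profile(protein, window)
    if prof.size == 0:
        return []
    above = prof > threshold
    runs: list[list[int]] = []  # [first_centre, last_centre] in profile coords
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if runs and i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    hits = []
    for a, b in runs:
        start, end = a, b + window  # full-window protein interval
        if end - start < min_run:
            continue
        hit = MotifHit("TM", start, end)
        if start < signal_zone:
            hit.meta["signal_like"] = True
        hits.append(hit)
    return hits


def find_signal_region(
    protein: str,
    window: int = 9,
    threshold: float = 1.6,
    signal_zone: int = 30,
    min_run: int = 6,
) -> MotifHit | None:
    """Signal-peptide-like hydrophobic region in the protein prefix.

    Uses a short hydropathy window; the first qualifying segment starting
    within ``signal_zone`` residues of the N-terminus is returned with
    kind ``signal``.
    """
    for hit in hydropathy_segments(
        protein, window=window, threshold=threshold, min_run=min_run, merge_gap=2,
        signal_zone=signal_zone,
    ):
        if hit.start < signal_zone:
            return MotifHit("signal", hit.start, hit.end)
    return None
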