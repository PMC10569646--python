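"""Protein-vs-protein and translated-genome local alignment search.

This is the internal stand-in for BLASTn/tBLASTn searches: Smith–Waterman
local alignment with affine gaps and BLOSUM62 scoring, applied to protein
queries against protein targets or against six-frame translations of
genome contigs, with an approximate Karlin–Altschul E-value used for the
0.05 acceptance cutoff.  No seeding heuristics are used; the full dynamic
programme runs per frame, which is adequate for desk-scale contigs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, six_frame_translate

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

#: report columns for the tab-separated hit table
HIT_COLUMNS = (
    "query_id",
    "target_id",
    "score",
    "evalue",
    "target_start",
    "target_end",
    "frame",
    "identity",
)


@dataclass
class SearchParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    evalue_max: float = 0.05
    score_min: int | None = None
    min_segment_aa: int = 8


@dataclass
class AlignmentHit:
    """A local alignment hit, coordinates on the forward strand of the target."""

    query_id: str
    target_id: str
    score: float
    target_interval: tuple[int, int]
    frame: int  # 0 for protein-protein; +-1..3 for translated searches
    identity_fraction: float
    evalue_approx: float
    query_interval: tuple[int, int] = (0, 0)
    meta: dict = field(default_factory=dict)


_STANDARD = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def _sanitise(protein: str) -> str:
    protein = protein.upper()
    if set(protein) <= _STANDARD:
        return protein
    return "".join(c if c in _STANDARD else "X" for c in protein)


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # Affine convention: a gap of length k costs gap_open + k * gap_extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def evalue(score: float, query_len: int, db_len: int) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def local_align(
    query: str | SequenceRecord,
    target: str | SequenceRecord,
    params: SearchParams | None = None,
) -> AlignmentHit:
    """Optimal Smith–Waterman local alignment of two proteins.

    Unknown residues are treated as X.  The traceback (and hence the
    reported intervals and identity) is the aligner's deterministic
    first-optimal path; the score is the optimum.
    """
    params = params or SearchParams()
    qid = query.id if isinstance(query, SequenceRecord) else "query"
    tid = target.id if isinstance(target, SequenceRecord) else "target"
    q = _sanitise(query.residues if isinstance(query, SequenceRecord) else query)
    t = _sanitise(target.residues if isinstance(target, SequenceRecord) else target)
    if not q or not t:
        raise ValueError("empty sequence in local_align")
    aligner = _make_aligner(params)
    score = aligner.score(q, t)
    if score <= 0:
        return AlignmentHit(qid, tid, 0.0, (0, 0), 0, 0.0, evalue(0.0, len(q), len(t)))
    aln = aligner.align(q, t)[0]
    qa, ta = aln.aligned
    q_start, q_end = int(qa[0][0]), int(qa[-1][1])
    t_start, t_end = int(ta[0][0]), int(ta[-1][1])
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(qa, ta):
        for k in range(qe - qs):
            aligned_cols += 1
            if q[qs + k] == t[ts + k]:
                matches += 1
    ident = matches / aligned_cols if aligned_cols else 0.0
    return AlignmentHit(
        qid, tid, float(score), (t_start, t_end), 0, ident,
        evalue(float(score), len(q), len(t)), (q_start, q_end),
    )


def _passes(hit: AlignmentHit, params: SearchParams) -> bool:
    if params.score_min is not None and hit.score < params.score_min:
        return False
    return hit.evalue_approx <= params.evalue_max


def search_genome(
    query: SequenceRecord | str,
    genome: Sequence[SequenceRecord],
    params: SearchParams | None = None,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Search a protein against six-frame translations of genome contigs.

    Each frame translation is split at stop codons; every segment of at
    least ``min_segment_aa`` residues is aligned, so hits never cross a
    stop.  Hit intervals are mapped back to forward-strand contig DNA
    coordinates.  E-values use the total translated database size.
    Hits are returned sorted by descending score.
    """
    params = params or SearchParams()
    if isinstance(query, str):
        query = SequenceRecord(query_id, query, "protein")
    q = _sanitise(query.residues)
    aligner = _make_aligner(params)
    db_len = sum(2 * len(c) // 3 for c in genome)  # both strands, aa units
    hits: list[AlignmentHit] = []
    for contig in genome:
        for frame in six_frame_translate(contig):
            prot = frame.protein
            seg_start = 0
            for segment in prot.split("*"):
                if len(segment) >= params.min_segment_aa:
                    score = aligner.score(q, _sanitise(segment))
                    if score > 0:
                        ev = evalue(float(score), len(q), db_len)
                        if _passes(AlignmentHit("", "", score, (0, 0), 0, 0, ev), params):
                            sub = local_align(query, segment, params)
                            p_start = seg_start + sub.target_interval[0]
                            p_end = seg_start + sub.target_interval[1]
                            d_start, d_end = frame.protein_to_contig(p_start, p_end)
                            hits.append(
                                AlignmentHit(
                                    query.id,
                                    contig.id,
                                    float(score),
                                    (d_start, d_end),
                                    frame.frame,
                                    sub.identity_fraction,
                                    ev,
                                    sub.query_interval,
                                )
                            )
                seg_start += len(segment) + 1
    hits.sort(key=lambda h: (-h.score, h.target_id, h.target_interval))
    return hits


def microsynteny_window(
    anchor_a: AlignmentHit, anchor_b: AlignmentHit
) -> tuple[str, tuple[int, int]] | dict:
    """Inter-anchor interval on one contig, for intergenic ORF scanning.

    Returns ``(contig_id, (start, end))`` with the anchors themselves
    excluded, orientation-normalised so the leftmost anchor comes first.
    Anchors on different contigs return a split-locus flag dictionary.
    """
    if anchor_a.target_id != anchor_b.target_id:
        return {"split_locus": True, "contigs": (anchor_a.target_id, anchor_b.target_id)}
    first, second = sorted([anchor_a, anchor_b], key=lambda h: h.target_interval)
    start = first.target_interval[1]
    end = second.target_interval[0]
    if end <= start:
        logger.warning(
            "anchors overlap on %s: [%d,%d) vs [%d,%d)",
            anchor_a.target_id, *first.target_interval, *second.target_interval,
        )
        return anchor_a.target_id, (start, start)
    return anchor_a.target_id, (start, end)


def conservation_count(
    candidate: SequenceRecord | str,
    genomes: Iterable[Sequence[SequenceRecord]],
    params: SearchParams | None = None,
) -> int:
    """Number of genomes containing at least one passing hit of ``candidate``."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("at least one genome is required")
    params = params or SearchParams()
    count = 0
    for genome in genomes:
        hits = search_genome(candidate, genome, params)
        if hits:
            count += 1
    return count


def hits_to_tsv(hits: Iterable[AlignmentHit]) -> str:
    """Render hits as the fixed-column tab-separated report."""
    lines = ["\t".join(HIT_COLUMNS)]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.target_id,
                    f"{h.score:.1f}",
                    f"{h.evalue_approx:.3g}",
                    str(h.target_interval[0]),
                    str(h.target_interval[1]),
                    str(h.frame),
                    f"{h.identity_fraction:.3f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
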