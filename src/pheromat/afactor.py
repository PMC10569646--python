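"""BLAST-independent a-factor pheromone candidate screen.

The a-factor precursor is a very short protein (here ≤ 100 aa) whose only
strictly conserved feature is a C-terminal CAAX/CPAX prenylation box, so
candidates cannot be found by homology alone.  The screen filters an
annotated proteome down to short box-terminated proteins, then ranks the
survivors by cross-genome conservation (a real pheromone is conserved in
relatives; spurious short CAAX ORFs are not), breaking ties with
supporting evidence: an S/T-rich N-terminal region and a GY dipeptide
near the C-terminal box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .homology import SearchParams, conservation_count
from .motifs import (
    DEFAULT_CLASSES,
    MotifHit,
    ResidueClasses,
    find_gy_motif,
    st_fraction,
    terminal_caax_class,
)
from .seqio import SequenceRecord, orfs_in_dna


@dataclass
class AFactorConfig:
    max_len: int = 100
    st_window: int = 20
    st_min: float = 0.30
    gy_tail_window: int = 15
    w_st: float = 1.0
    w_gy: float = 1.0
    rescue_min_aa: int = 20  # ORF-rescue mode lower length bound


@dataclass
class AFactorCandidate:
    protein_id: str
    protein: str
    length_aa: int
    terminal_class: str      # CAAX | CPAX
    terminal_box: str        # e.g. CTVM
    st_frac: float
    gy_hit: MotifHit | None
    conservation: int = 0
    rank: int = 0
    meta: dict = field(default_factory=dict)

    def evidence_score(self, config: AFactorConfig) -> float:
        return (
            config.w_st * (self.st_frac >= config.st_min)
            + config.w_gy * (self.gy_hit is not None)
        )


def filter_proteome(
    proteins: Sequence[SequenceRecord],
    classes: ResidueClasses = DEFAULT_CLASSES,
    config: AFactorConfig | None = None,
) -> list[AFactorCandidate]:
    """Retain proteins ≤ max_len aa ending in a CAAX or CPAX box.

    Both rules are applied exactly (the length bound is inclusive); each
    surviving protein is wrapped as a candidate with its S/T fraction and
    GY hit populated.  Output is sorted by protein id, so it is invariant
    to input order.
    """
    config = config or AFactorConfig()
    out: list[AFactorCandidate] = []
    for rec in proteins:
        prot = rec.residues.rstrip("*")
        if not prot or len(prot) > config.max_len:
            continue
        klass = terminal_caax_class(prot, classes)
        if klass == "none":
            continue
        out.append(
            AFactorCandidate(
                protein_id=rec.id,
                protein=prot,
                length_aa=len(prot),
                terminal_class=klass,
                terminal_box=prot[-4:],
                st_frac=st_fraction(prot, config.st_window),
                gy_hit=find_gy_motif(prot, config.gy_tail_window),
            )
        )
    out.sort(key=lambda c: c.protein_id)
    return out


def rescue_orfs(
    genome: Sequence[SequenceRecord],
    classes: ResidueClasses = DEFAULT_CLASSES,
    config: AFactorConfig | None = None,
) -> list[AFactorCandidate]:
    """Optional annotation-independent rescue: six-frame ORFs of 20–100 aa
    ending in a CAAX/CPAX box, for genomes whose annotation misses short
    genes."""
    config = config or AFactorConfig()
    records = []
    for contig in genome:
        for start, end, strand, prot in orfs_in_dna(contig.residues, min_aa=config.rescue_min_aa):
            if len(prot) <= config.max_len:
                records.append(
                    SequenceRecord(f"{contig.id}:{start}-{end}({strand})", prot, "protein")
                )
    return filter_proteome(records, classes, config)


def rank_candidates(
    candidates: Sequence[AFactorCandidate],
    relative_genomes: Sequence[Sequence[SequenceRecord]],
    config: AFactorConfig | None = None,
    search_params: SearchParams | None = None,
) -> list[AFactorCandidate]:
    """Rank candidates by conservation across relative genomes.

    Conservation is the number of relative genomes with a passing
    translated-search hit.  Sort order: conservation descending, evidence
    score descending, length ascending, then protein id — fully
    deterministic.
    """
    if not relative_genomes:
        raise ValueError("supply at least one relative genome to rank against")
    config = config or AFactorConfig()
    ranked = []
    for cand in candidates:
        cons = conservation_count(
            SequenceRecord(cand.protein_id, cand.protein, "protein"),
            relative_genomes,
            search_params,
        )
        cand.conservation = cons
        ranked.append(cand)
    ranked.sort(
        key=lambda c: (
            -c.conservation,
            -c.evidence_score(config),
            c.length_aa,
            c.protein_id,
        )
    )
    for i, cand in enumerate(ranked, 1):
        cand.rank = i
    return ranked


EVIDENCE_COLUMNS = ("protein_id", "length_aa", "terminal_box", "st_frac", "gy", "conservation")


def evidence_report(candidate: AFactorCandidate) -> dict:
    """Structured evidence record for one candidate (6 fixed fields)."""
    return {
        "protein_id": candidate.protein_id,
        "length_aa": candidate.length_aa,
        "terminal_box": candidate.terminal_box,
        "st_frac": round(candidate.st_frac, 3),
        "gy": "yes" if candidate.gy_hit is not None else "no",
        "conservation": candidate.conservation,
    }


def evidence_tsv(candidates: Sequence[AFactorCandidate]) -> str:
    lines = ["\t".join(EVIDENCE_COLUMNS)]
    for c in candidates:
        rec = evidence_report(c)
        lines.append("\t".join(str(rec[k]) for k in EVIDENCE_COLUMNS))
    return "\n".join(lines) + "\n"
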