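"""Pheromone-receptor (STE2/STE3) gene-model quality control.

The two pheromone receptors are G-protein-coupled receptors with a strict
structure–function relationship: seven transmembrane helices, an
extracellular N-terminus and an intracellular C-terminus.  A gene model
that translates with an internal stop, or whose protein does not show
seven hydrophobic membrane-spanning segments, is flagged as defective.
TM counting uses Kyte–Doolittle hydropathy segments; profile-HMM domain
confirmation is deliberately out of scope, with homology to a supplied
reference receptor standing in for the domain check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .motifs import hydropathy_segments
from .seqio import GeneModel, SequenceRecord, extract_cds_and_translate


@dataclass
class ReceptorConfig:
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_run: int = 15
    tm_merge_gap: int = 3
    # opt-in: flag gene models far shorter than the expected receptor length
    # (receptors are ~350-450 aa) as truncated instead of counting helices
    truncated_min_aa: int | None = None


@dataclass
class ReceptorCall:
    gene_id: str
    receptor: str  # STE2 | STE3
    tm_count: int
    internal_stop: bool
    verdict: str  # intact | wrong_tm_count | premature_stop | truncated | deleted | unannotatable
    meta: dict = field(default_factory=dict)


VERDICTS = ("intact", "wrong_tm_count", "premature_stop", "truncated", "deleted", "unannotatable")


def count_tm_segments(protein: str, config: ReceptorConfig | None = None) -> int:
    config = config or ReceptorConfig()
    segments = hydropathy_segments(
        protein,
        window=config.tm_window,
        threshold=config.tm_threshold,
        min_run=config.tm_min_run,
        merge_gap=config.tm_merge_gap,
    )
    return len(segments)


def qc_receptor(
    gene: GeneModel | None,
    genome: Sequence[SequenceRecord] | dict[str, SequenceRecord],
    receptor: str,
    config: ReceptorConfig | None = None,
) -> ReceptorCall:
    """Classify a receptor gene model as intact or defective.

    ``gene`` may be None (or on a missing contig) for a receptor deleted
    from the genome; that yields a ``deleted`` verdict rather than an
    exception.
    """
    config = config or ReceptorConfig()
    receptor = receptor.upper()
    if receptor not in ("STE2", "STE3"):
        raise ValueError(f"receptor must be STE2 or STE3, got {receptor!r}")
    if gene is None:
        return ReceptorCall("absent", receptor, 0, False, "deleted")
    try:
        rec = extract_cds_and_translate(genome, gene)
    except (KeyError, ValueError):
        return ReceptorCall(gene.gene_id, receptor, 0, False, "deleted")
    protein = rec.residues
    flags = getattr(rec, "flags", {})
    if not protein or flags.get("phase_error"):
        return ReceptorCall(gene.gene_id, receptor, 0, False, "unannotatable")
    if "*" in protein:
        return ReceptorCall(gene.gene_id, receptor, 0, True, "premature_stop")
    if config.truncated_min_aa is not None and len(protein) < config.truncated_min_aa:
        tm = count_tm_segments(protein, config)
        return ReceptorCall(gene.gene_id, receptor, tm, False, "truncated")
    tm = count_tm_segments(protein, config)
    verdict = "intact" if tm == 7 else "wrong_tm_count"
    return ReceptorCall(gene.gene_id, receptor, tm, False, verdict)


RECEPTOR_COLUMNS = ("genome", "receptor", "gene_id", "tm_count", "verdict")


def receptor_tsv(calls: Sequence[tuple[str, ReceptorCall]]) -> str:
    """Per-genome receptor report: genome, receptor, gene, TM count, verdict."""
    lines = ["\t".join(RECEPTOR_COLUMNS)]
    for genome_id, call in calls:
        lines.append(
            "\t".join([genome_id, call.receptor, call.gene_id, str(call.tm_count), call.verdict])
        )
    return "\n".join(lines) + "\n"
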