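"""α-factor pro-pheromone repeat-grammar annotation.

A typical α-factor pro-protein is a signal peptide followed by multiple
copies of a short (9–14 aa) mature pheromone peptide, each copy excised
by proteolysis at flanking processing sites: STE13 sites (XA/XP
dipeptides, often repeated as XAXA-type runs) before a repeat and KEX1/2
dibasic sites (KR/RR/KK) after it.  The first residue of a mature repeat
is the residue directly following the XA/XP site.

Annotation here is a deterministic formalisation of that grammar.  The
protein is scanned left to right between KEX sites; within each inter-KEX
region the repeat is anchored at the first STE13 run whose downstream
span admits a candidate inside the configured length bounds, choosing the
longest in-bounds candidate (candidate ends are the next STE13 run start,
the next KEX site, or the protein end).  Where no in-bounds candidate
exists, the natural span to the next KEX is kept and, when other repeats
establish a consistent length (mode of in-bounds lengths, ties towards
the shorter), trimmed to that length and flagged.  Out-of-bounds repeats
are flagged but retained, since real pro-pheromones stray slightly
outside the typical bounds.  The signal peptide is annotated when
detectable but is advisory: parsing proceeds without one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .motifs import (
    MotifHit,
    find_kex_sites,
    find_signal_region,
    find_ste13_sites,
)
from .seqio import GeneModel, orfs_in_dna

logger = logging.getLogger(__name__)


@dataclass
class AlphaConfig:
    min_len: int = 9          # soft lower bound on mature-repeat length
    max_len: int = 14         # soft upper bound
    min_total: int = 40       # minimum pro-protein length worth parsing
    min_emit: int = 6         # spans shorter than this are linkers, not repeats
    min_orf_aa: int = 40      # minimum ORF length in intergenic scans
    scan_classes: tuple = ("typical",)  # classes an intergenic scan reports
    gq_fallback: bool = False  # anchor repeats on GQ when sites are not proximal


@dataclass
class MatureRepeat:
    """One annotated mature-pheromone repeat."""

    sequence: str
    interval: tuple[int, int]
    beta_turn: str = "none"       # GQ | PG | none
    preceded_by: str = "none"     # STE13 | KEX | none
    followed_by: str = "none"     # KEX | STE13 | none
    in_bounds: bool = True
    adjusted: bool = False        # end trimmed to the consistent length

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("mature repeat must be at least 2 residues")
        if "GQ" in self.sequence:
            self.beta_turn = "GQ"
        elif "PG" in self.sequence:
            self.beta_turn = "PG"
        else:
            self.beta_turn = "none"


@dataclass
class AlphaAnnotation:
    """Parsed pro-pheromone: signal, processing sites, ordered repeats, class."""

    protein_id: str
    protein: str
    signal: MotifHit | None
    sites: list[MotifHit]
    repeats: list[MatureRepeat]
    klass: str  # typical | atypical_single_repeat | ste13_dominant | unparseable

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def repeat_sequences(self) -> list[str]:
        return [r.sequence for r in self.repeats]


def _classify(repeats: list[MatureRepeat], n_kex: int) -> str:
    if not repeats:
        return "unparseable"
    if len(repeats) == 1 and n_kex == 0:
        return "atypical_single_repeat"
    if len(repeats) >= 2 and all(r.followed_by == "KEX" for r in repeats):
        return "typical"
    return "ste13_dominant"


def annotate_repeats(
    protein: str, config: AlphaConfig | None = None, protein_id: str = "protein"
) -> AlphaAnnotation:
    """Annotate mature repeats and processing sites of a pro-pheromone."""
    config = config or AlphaConfig()
    protein = protein.upper().rstrip("*")
    if len(protein) < config.min_total:
        logger.warning(
            "%s: length %d below min_total %d", protein_id, len(protein), config.min_total
        )
    kex = find_kex_sites(protein)
    ste = find_ste13_sites(protein)
    signal = find_signal_region(protein)
    sites: list[MotifHit] = sorted(kex + ste, key=lambda h: (h.start, h.kind))
    n = len(protein)

    raw: list[dict] = []
    pos = 0
    preceded = "none"
    guard = 0
    while pos < n and guard < 4 * (len(sites) + 2):
        guard += 1
        next_kex = next((k for k in kex if k.start >= pos), None)
        limit = next_kex.start if next_kex else n
        region_runs = [r for r in ste if pos <= r.start and r.end <= limit]

        chosen = None  # (start, end, preceded_by)
        for ai, run in enumerate(region_runs):
            start = run.end
            end_opts = [r.start for r in region_runs[ai + 1 :] if r.start > start]
            end_opts.append(limit)
            in_bounds = [
                e for e in end_opts if config.min_len <= e - start <= config.max_len
            ]
            if in_bounds:
                chosen = (start, max(in_bounds), "STE13")
                break
        if chosen is None and preceded == "KEX" and not region_runs:
            # repeat starting immediately after the KEX site
            if config.min_len <= limit - pos <= config.max_len:
                chosen = (pos, limit, "KEX")
        if chosen is None:
            # no in-bounds candidate anywhere in the region: keep the natural
            # span from the last anchoring site to the KEX, flagged
            start_opts = [(r.end, "STE13") for r in region_runs if limit - r.end >= config.min_emit]
            if preceded == "KEX" and limit - pos >= config.min_emit:
                start_opts.append((pos, "KEX"))
            if start_opts:
                # the repeat starts right after the first processing site;
                # the surplus before the KEX is handled by the mode trim
                start, pre = min(start_opts)
                chosen = (start, limit, pre)

        if chosen is not None and chosen[1] - chosen[0] >= config.min_emit:
            start, end, pre = chosen
            followed = "none"
            if next_kex and end == limit:
                followed = "KEX"
            elif any(r.start == end for r in ste):
                followed = "STE13"
            raw.append(
                {"start": start, "end": end, "preceded": pre, "followed": followed}
            )
            if end == limit:
                pos = next_kex.end if next_kex else n
                preceded = "KEX"
            else:
                pos = end
                preceded = "none"
        else:
            pos = next_kex.end if next_kex else n
            preceded = "KEX"

    # length-consistency pass: trim oversize natural spans to the mode of
    # the in-bounds repeat lengths (ties resolved towards the shorter)
    in_bounds_lengths = [
        r["end"] - r["start"]
        for r in raw
        if config.min_len <= r["end"] - r["start"] <= config.max_len
    ]
    mode_len = None
    if in_bounds_lengths:
        counts = Counter(in_bounds_lengths)
        top = max(counts.values())
        mode_len = min(l for l, c in counts.items() if c == top)
    repeats: list[MatureRepeat] = []
    for r in raw:
        start, end = r["start"], r["end"]
        adjusted = False
        if end - start > config.max_len and mode_len is not None:
            # extra residues intervene before the KEX site: keep the
            # protein-wide consistent repeat length
            end = start + mode_len
            adjusted = True
        length = end - start
        repeats.append(
            MatureRepeat(
                protein[start:end],
                (start, end),
                preceded_by=r["preceded"],
                followed_by=r["followed"],
                in_bounds=config.min_len <= length <= config.max_len,
                adjusted=adjusted,
            )
        )

    repeats = _enforce_sequence_consistency(protein, repeats, kex, ste)
    klass = _classify(repeats, len(kex))
    return AlphaAnnotation(protein_id, protein, signal, sites, repeats, klass)


def _enforce_sequence_consistency(
    protein: str,
    repeats: list[MatureRepeat],
    kex: list[MotifHit],
    ste: list[MotifHit],
) -> list[MatureRepeat]:
    """Re-anchor outlier repeats onto the protein's majority repeat sequence.

    Mature repeats are copies of one peptide; when most annotated units
    share a sequence, a unit that disagrees but overlaps an exact
    occurrence of the shared sequence is re-anchored onto that occurrence
    (this resolves units where extra residues sit between the repeat and
    its KEX site).  Genuinely unique repeats are left untouched.
    """
    if len(repeats) < 2:
        return repeats
    counts = Counter(r.sequence for r in repeats if r.in_bounds)
    if not counts:
        return repeats
    majority, m_count = counts.most_common(1)[0]
    if m_count < 2:
        return repeats
    occurrences = []
    start = protein.find(majority)
    while start != -1:
        occurrences.append((start, start + len(majority)))
        start = protein.find(majority, start + 1)

    def flank_before(pos: int) -> str:
        if any(h.end == pos for h in ste):
            return "STE13"
        if any(h.end == pos for h in kex):
            return "KEX"
        return "none"

    def flank_after(pos: int) -> str:
        if any(h.start == pos for h in kex):
            return "KEX"
        if any(h.start == pos for h in ste):
            return "STE13"
        return "none"

    out = list(repeats)
    for idx, r in enumerate(out):
        if r.sequence == majority:
            continue
        prev_end = out[idx - 1].interval[1] if idx > 0 else -1
        next_start = out[idx + 1].interval[0] if idx + 1 < len(out) else len(protein) + 1
        for o_s, o_e in occurrences:
            overlaps = o_s < r.interval[1] and r.interval[0] < o_e
            if overlaps and o_s >= prev_end and o_e <= next_start:
                out[idx] = MatureRepeat(
                    majority, (o_s, o_e),
                    preceded_by=flank_before(o_s),
                    followed_by=flank_after(o_e),
                    in_bounds=True,
                    adjusted=True,
                )
                break
    return out


def scan_intergenic_for_alpha(
    window_dna: str,
    config: AlphaConfig | None = None,
    contig_id: str = "window",
    window_offset: int = 0,
) -> list[tuple[GeneModel, AlphaAnnotation]]:
    """Scan an inter-anchor DNA window for α-factor-like ORFs.

    All ORFs of at least ``min_orf_aa`` residues on both strands are
    translated and parsed; ORFs whose annotation class is in
    ``config.scan_classes`` (by default only the canonical multi-repeat
    ``typical`` structure, since random open reading frames routinely
    parse as degenerate site-rich patterns) are returned ranked by repeat
    count, then protein length, then position.  Coordinates are shifted
    by ``window_offset`` so gene models land in contig coordinates.
    """
    config = config or AlphaConfig()
    results = []
    for start, end, strand, prot in orfs_in_dna(window_dna, min_aa=config.min_orf_aa):
        ann = annotate_repeats(prot, config, protein_id=f"{contig_id}:{start}-{end}({strand})")
        if ann.klass not in config.scan_classes:
            continue
        gene = GeneModel(
            gene_id=f"alpha_cand_{window_offset + start}_{strand}",
            contig_id=contig_id,
            strand=strand,
            exons=[(window_offset + start, window_offset + end)],
            tag="alpha_pheromone",
        )
        results.append((gene, ann))
    results.sort(key=lambda t: (-t[1].n_repeats, -len(t[1].protein), t[0].start))
    return results


def repeat_sharing_matrix(annotations: dict[str, AlphaAnnotation]) -> pd.DataFrame:
    """Species × mature-repeat incidence matrix (exact uppercase strings).

    Entry (s, r) is 1 when species ``s`` carries at least one copy of the
    mature repeat ``r``; the per-repeat species counts used to describe
    repeat sharing are the column sums.
    """
    if not annotations:
        raise ValueError("at least one annotation is required")
    all_repeats = sorted({seq.upper() for a in annotations.values() for seq in a.repeat_sequences})
    data = {
        species: [int(rep in {s.upper() for s in ann.repeat_sequences}) for rep in all_repeats]
        for species, ann in annotations.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=all_repeats).sort_index()


def annotation_to_tsv_row(ann: AlphaAnnotation) -> str:
    """One TSV line: protein_id, n_repeats, ';'-joined repeats, class."""
    return "\t".join(
        [ann.protein_id, str(ann.n_repeats), ";".join(ann.repeat_sequences), ann.klass]
    )
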