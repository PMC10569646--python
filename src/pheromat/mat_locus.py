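"""MAT-locus assembly and sexual-strategy (thallism) classification.

The mating-type locus of filamentous ascomycetes carries one of two
dissimilar idiomorphs: MAT1-1 (principal gene *MAT1-1-1*, an α-box
protein, plus secondary genes *MAT1-1-3*, *MAT1-1-5*, *MAT1-1-13*) or
MAT1-2 (*MAT1-2-1*, an HMG protein, plus *MAT1-2-10*), conventionally
flanked by the *APN2* and *SLA2* genes.  The gene content and layout of
the locus predicts the species' sexual strategy:

* genes from a single idiomorph → heterothallic;
* both idiomorphs at one locus, principal genes intact → primary
  homothallism;
* MAT1-2 genes flanked by *MAT1-1-1* fragments carrying identical
  250-bp-scale repeats → mating-type switching (inverted repeats →
  bidirectional switching by inversion; direct repeats → unidirectional
  switching by deletion);
* an intact *MAT1-1-3* (HMG) as the only MAT1-1 gene with no *MAT1-1-1*
  anywhere → the HMG-only strategy described in *Lachnellula*;
* both idiomorphs on separate loci → possibly a mixed culture;
* truncated principal genes without a switching signature → undetermined.

Gene fragments embedded in the opposite idiomorph are common and do not
count towards idiomorph presence unless intact; without this rule every
heterothallic *Botrytis*-type idiomorph would misclassify as homothallic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .homology import AlignmentHit, SearchParams, microsynteny_window, search_genome
from .seqio import SequenceRecord, orfs_in_dna, revcomp

logger = logging.getLogger(__name__)

MAT1_1_GENES = ("MAT1-1-1", "MAT1-1-3", "MAT1-1-5", "MAT1-1-13")
MAT1_2_GENES = ("MAT1-2-1", "MAT1-2-10")
ANCHOR_GENES = ("APN2", "SLA2")

#: per-gene statuses
STATUSES = ("intact", "truncated_5prime", "truncated_3prime", "fragment", "pseudogenised", "absent")

STRATEGIES = (
    "heterothallic_MAT1_1",
    "heterothallic_MAT1_2",
    "primary_homothallic",
    "switching_inversion",
    "switching_deletion",
    "lachnellula_HMG_only",
    "undetermined",
    "possible_mixed_culture",
)


@dataclass
class LocusConfig:
    coverage_intact: float = 0.9
    coverage_fragment: float = 0.5
    min_identity: float = 0.4  # discard borderline random hits a curator would reject
    cluster_gap_bp: int = 1500
    repeat_len_min: int = 100
    repeat_identity_min: float = 1.0


@dataclass
class LocusGene:
    """One located (or absent) locus gene with its annotation status."""

    name: str
    status: str
    contig_id: str | None = None
    interval: tuple[int, int] | None = None
    orientation: int = 0  # sign of the best hit's frame
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class RepeatPair:
    """Two identical (direct or inverted) repeat copies in a locus window."""

    seq_a_interval: tuple[int, int]
    seq_b_interval: tuple[int, int]
    length_bp: int
    orientation: str  # direct | inverted
    identity: float = 1.0

    def __post_init__(self) -> None:
        a, b = sorted([self.seq_a_interval, self.seq_b_interval])
        if a[1] > b[0]:
            raise ValueError("repeat copies must not overlap")
        self.seq_a_interval, self.seq_b_interval = a, b


@dataclass
class ThallismCall:
    """Sexual-strategy verdict for one genome, with its evidence trail."""

    strategy: str
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES + ("unknown",):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class MatLocusModel:
    """Result of locating the MAT locus in one genome."""

    genes: list[LocusGene]
    window: tuple[str, tuple[int, int]] | None = None
    split_anchors: bool = False
    novel_orfs: list[tuple[str, int, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# locating the locus
# ---------------------------------------------------------------------------

def _cluster_hits(hits: list[AlignmentHit], gap: int) -> list[list[AlignmentHit]]:
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.target_id, []).append(h)
    clusters = []
    for contig_hits in by_contig.values():
        contig_hits.sort(key=lambda h: h.target_interval)
        current = [contig_hits[0]]
        for h in contig_hits[1:]:
            if h.target_interval[0] - current[-1].target_interval[1] <= gap:
                current.append(h)
            else:
                clusters.append(current)
                current = [h]
        clusters.append(current)
    return clusters


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total, prev_end = 0, -1
    for a, b in sorted(intervals):
        a = max(a, prev_end)
        if b > a:
            total += b - a
            prev_end = b
        prev_end = max(prev_end, b)
    return total


def _cluster_to_gene(name: str, ref_len: int, cluster: list[AlignmentHit], cfg: LocusConfig) -> LocusGene:
    q_intervals = [h.query_interval for h in cluster]
    cov = _union_len(q_intervals) / ref_len
    q_min = min(a for a, _ in q_intervals)
    q_max = max(b for _, b in q_intervals)
    d_start = min(h.target_interval[0] for h in cluster)
    d_end = max(h.target_interval[1] for h in cluster)
    best = max(cluster, key=lambda h: h.score)
    single_cov = max((b - a) for a, b in q_intervals) / ref_len
    if cov >= cfg.coverage_intact:
        status = "intact" if single_cov >= cfg.coverage_intact else "pseudogenised"
    elif cov >= cfg.coverage_fragment:
        missing_5, missing_3 = q_min, ref_len - q_max
        status = "truncated_5prime" if missing_5 >= missing_3 else "truncated_3prime"
    else:
        status = "fragment"
    return LocusGene(
        name, status, best.target_id, (d_start, d_end),
        1 if best.frame > 0 else -1, round(cov, 3),
    )


def locate_mat_locus(
    genome: Sequence[SequenceRecord],
    references: dict[str, SequenceRecord],
    params: SearchParams | None = None,
    config: LocusConfig | None = None,
) -> MatLocusModel:
    """Locate MAT and anchor genes in a genome by translated homology search.

    Every reference protein is searched genome-wide; per-reference hit
    clusters become :class:`LocusGene` records with a coverage-based
    status.  When no MAT gene is found, the APN2/SLA2 anchors define a
    locus window which is scanned for unannotated ORFs (novel-gene
    discovery, reported but never used in strategy calls).
    """
    params = params or SearchParams()
    config = config or LocusConfig()
    genes: list[LocusGene] = []
    anchor_clusters: dict[str, list[AlignmentHit]] = {}
    mat_found = False
    for name, ref in references.items():
        hits = [
            h for h in search_genome(ref, genome, params)
            if h.identity_fraction >= config.min_identity
        ]
        if not hits:
            genes.append(LocusGene(name, "absent"))
            continue
        clusters = _cluster_hits(hits, config.cluster_gap_bp)
        if name in ANCHOR_GENES:
            best = max(clusters, key=lambda c: max(h.score for h in c))
            anchor_clusters[name] = best
            genes.append(_cluster_to_gene(name, len(ref), best, config))
        else:
            for cluster in clusters:
                genes.append(_cluster_to_gene(name, len(ref), cluster, config))
            if name in MAT1_1_GENES + MAT1_2_GENES:
                mat_found = True

    window = None
    split = False
    novel: list[tuple[str, int, int, str]] = []
    if len(anchor_clusters) == 2:
        a = max(anchor_clusters["APN2"], key=lambda h: h.score)
        b = max(anchor_clusters["SLA2"], key=lambda h: h.score)
        result = microsynteny_window(a, b)
        if isinstance(result, dict):
            split = True
        else:
            contig_id, (ws, we) = result
            if we > ws:
                window = (contig_id, (ws, we))
    if window is not None and not mat_found:
        contig = {c.id: c for c in genome}[window[0]]
        win_dna = contig.residues[window[1][0] : window[1][1]]
        occupied = [
            g.interval for g in genes
            if g.contig_id == window[0] and g.interval is not None
        ]
        for s, e, strand, prot in orfs_in_dna(win_dna, min_aa=30):
            abs_s, abs_e = window[1][0] + s, window[1][0] + e
            if not any(abs_s < ge and gs < abs_e for gs, ge in occupied):
                novel.append((window[0], abs_s, abs_e, strand))
    if not genes or all(g.status == "absent" for g in genes):
        logger.warning("no MAT or anchor homology found in genome")
    return MatLocusModel(genes, window, split, novel)


# ---------------------------------------------------------------------------
# repeat pairs
# ---------------------------------------------------------------------------

def detect_repeat_pairs(
    dna: str, min_len: int = 100, identity_min: float = 1.0
) -> list[RepeatPair]:
    """All maximal pairs of identical substrings ≥ min_len, direct or inverted.

    Direct pairs are two identical forward-strand copies; inverted pairs
    are a copy and its reverse complement.  Copies must not overlap.
    Only exact identity is implemented (``identity_min`` below 1.0 is
    rejected); identical repeats are what drive mating-type switching.
    """
    if identity_min < 1.0:
        raise NotImplementedError("only exact repeat pairs (identity 1.0) are supported")
    dna = dna.upper()
    n = len(dna)
    if n < 2 * min_len:
        return []
    pairs: set[tuple[int, int, int, str]] = set()

    # direct: identical k-mers at two positions, maximally extended
    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        kmer_pos.setdefault(dna[i : i + min_len], []).append(i)
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                a, b, length = _extend_direct(dna, i, j, min_len)
                if b >= a + length:  # disjoint
                    pairs.add((a, b, length, "direct"))

    # inverted: forward k-mer equal to a k-mer of the reverse complement
    rc = revcomp(dna)
    rc_pos: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        rc_pos.setdefault(rc[i : i + min_len], []).append(i)
    for i in range(n - min_len + 1):
        for r in rc_pos.get(dna[i : i + min_len], ()):
            j = n - r - min_len  # forward-strand start of the rc copy
            a, b, length = _extend_inverted(dna, rc, i, r, min_len)
            if a is None:
                continue
            if b >= a + length:
                pairs.add((a, b, length, "inverted"))

    out = [
        RepeatPair((a, a + length), (b, b + length), length, orient)
        for a, b, length, orient in pairs
    ]
    out.sort(key=lambda p: (p.seq_a_interval, p.seq_b_interval, p.orientation))
    return out


def _extend_direct(dna: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    while i > 0 and j > 0 and dna[i - 1] == dna[j - 1]:
        i, j = i - 1, j - 1
    e1, e2 = i + k, j + k
    n = len(dna)
    while e1 < n and e2 < n and e1 < j and dna[e1] == dna[e2]:
        e1, e2 = e1 + 1, e2 + 1
    return i, j, e1 - i


def _extend_inverted(dna: str, rc: str, i: int, r: int, k: int):
    """Extend a forward/rc k-mer match maximally; return forward coords."""
    n = len(dna)
    while i > 0 and r > 0 and dna[i - 1] == rc[r - 1]:
        i, r = i - 1, r - 1
    e_i, e_r = i + k, r + k
    while e_i < n and e_r < n and dna[e_i] == rc[e_r]:
        e_i, e_r = e_i + 1, e_r + 1
    length = e_i - i
    j = n - (r + length)  # forward-strand start of the partner copy
    a, b = min(i, j), max(i, j)
    if a == b:  # perfect palindrome centred on itself
        return None, None, 0
    return a, b, length


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_PRESENT = {"intact", "truncated_5prime", "truncated_3prime"}


def classify_thallism(
    genes: Sequence[LocusGene],
    repeat_pairs: Sequence[RepeatPair] = (),
    split_locus: bool | None = None,
) -> ThallismCall:
    """Decide the sexual strategy from locus gene content, repeats and layout.

    Decision order: (1) HMG-only (*Lachnellula*) pattern; (2) single
    idiomorph → heterothallic, unless a switching signature makes the
    het-vs-switched distinction impossible; (3) both idiomorphs at one
    locus → switching (by repeat orientation), primary homothallism
    (intact principals) or undetermined; (4) both idiomorphs on separate
    loci → possible mixed culture; (5) anything else → undetermined.
    """
    ev: list[str] = []
    by_name: dict[str, list[LocusGene]] = {}
    for g in genes:
        by_name.setdefault(g.name, []).append(g)
        if g.status != "absent":
            ev.append(f"{g.name}:{g.status}@{g.contig_id}:{g.interval} cov={g.coverage}")
    if not ev:
        ev.append("no MAT or anchor homology detected")
        return ThallismCall("unknown", ev)
    for p in repeat_pairs:
        ev.append(
            f"repeat_pair:{p.orientation} len={p.length_bp} at {p.seq_a_interval}/{p.seq_b_interval}"
        )

    def present(names) -> list[LocusGene]:
        return [
            g for name in names for g in by_name.get(name, []) if g.status in _PRESENT
        ]

    def intact(name) -> bool:
        return any(g.status == "intact" for g in by_name.get(name, []))

    p11 = present(MAT1_1_GENES)
    p12 = present(MAT1_2_GENES)
    mat111_pieces = [
        g for g in by_name.get("MAT1-1-1", [])
        if g.status in ("fragment", "truncated_5prime", "truncated_3prime", "pseudogenised")
    ]
    inverted = [p for p in repeat_pairs if p.orientation == "inverted"]
    direct = [p for p in repeat_pairs if p.orientation == "direct"]

    # (1) Lachnellula HMG-only: intact MAT1-1-3 is the only MAT1-1 gene,
    # no MAT1-1-1 region at all, and no MAT1-2 gene in the genome.
    any_mat111 = any(g.status != "absent" for g in by_name.get("MAT1-1-1", []))
    any_mat12 = any(
        g.status != "absent" for name in MAT1_2_GENES for g in by_name.get(name, [])
    )
    if (
        intact("MAT1-1-3")
        and not any_mat111
        and not any_mat12
        and all(g.name == "MAT1-1-3" for g in p11)
    ):
        ev.append("rule: intact MAT1-1-3 only, no MAT1-1-1 or MAT1-2 anywhere")
        return ThallismCall("lachnellula_HMG_only", ev)

    # (2) single idiomorph
    if p11 and not p12:
        if len(mat111_pieces) >= 2 and (inverted or direct):
            ev.append("rule: single idiomorph but switching-like repeats; ambiguous")
            return ThallismCall("undetermined", ev)
        ev.append("rule: MAT1-1 genes only")
        return ThallismCall("heterothallic_MAT1_1", ev)
    if p12 and not p11:
        ev.append("rule: MAT1-2 genes only")
        return ThallismCall("heterothallic_MAT1_2", ev)
    if not p11 and not p12:
        ev.append("rule: no intact or truncated MAT gene")
        return ThallismCall("undetermined", ev)

    # (3)/(4) both idiomorphs: layout check
    if split_locus is None:
        c11 = {g.contig_id for g in p11}
        c12 = {g.contig_id for g in p12}
        split_locus = c11.isdisjoint(c12)
    if split_locus:
        ev.append("rule: idiomorphs on separate loci/contigs")
        return ThallismCall("possible_mixed_culture", ev)

    if len(mat111_pieces) >= 2 and inverted:
        ev.append("rule: MAT1-2 genes flanked by MAT1-1-1 pieces with inverted repeats")
        return ThallismCall("switching_inversion", ev)
    if direct:
        ev.append("rule: direct repeat pair within fused locus")
        return ThallismCall("switching_deletion", ev)
    if intact("MAT1-1-1") and intact("MAT1-2-1"):
        ev.append("rule: both principal MAT genes intact at one locus")
        return ThallismCall("primary_homothallic", ev)
    ev.append("rule: both idiomorphs but principal gene(s) not intact; no switching signature")
    return ThallismCall("undetermined", ev)
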