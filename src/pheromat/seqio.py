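"""Sequence and annotation I/O shared by all pipeline stages.

Internal coordinates are 0-based half-open on the forward strand
throughout; GFF3 1-based inclusive coordinates are converted at the I/O
boundary only.  Only the standard genetic code is supported; codons
containing ambiguity characters translate to ``X``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXU*")

#: functional tags a gene model may carry
GENE_TAGS = (
    "MAT1-1-1",
    "MAT1-1-3",
    "MAT1-1-5",
    "MAT1-1-13",
    "MAT1-2-1",
    "MAT1-2-10",
    "APN2",
    "SLA2",
    "alpha_pheromone",
    "a_pheromone",
    "ste2",
    "ste3",
    "other",
)


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header or empty sequence)."""


class GffFormatError(ValueError):
    """Malformed GFF3 input (bad coordinates or orphan features)."""


@dataclass
class SequenceRecord:
    """A named DNA or protein sequence."""

    id: str
    residues: str
    alphabet: Literal["dna", "protein"] = "dna"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """An exon-structured gene on a contig.

    ``exons`` are [start, end) intervals on the forward strand of
    ``contig_id``, sorted and non-overlapping.  For minus-strand genes the
    exons are still given in forward-strand coordinates; transcription
    order is derived at extraction time.
    """

    gene_id: str
    contig_id: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    tag: str = "other"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"gene {self.gene_id!r}: empty exon [{a},{b})")
            if a < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = b
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _guess_alphabet(residues: str) -> str:
    return "dna" if set(residues.upper()) <= DNA_ALPHABET else "protein"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file.

    Order is preserved; sequence-line whitespace is stripped by the parser.
    An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).strip()
        if not rec.id:
            raise FastaFormatError(f"{path}: record {i + 1} has an empty header")
        if not seq:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} (number {i + 1}) has an empty sequence"
            )
        records.append(
            SequenceRecord(rec.id, seq, alphabet or _guess_alphabet(seq))
        )
    if not records:
        logger.warning("no records found in FASTA file %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with ``width``-column line wrapping."""
    path = Path(path)
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _feature_gene_id(attrs: dict) -> str | None:
    # NCBI dialects use locus_tag, ab initio annotators use ID/Parent.
    for key in ("ID", "locus_tag", "Name"):
        if key in attrs:
            return attrs[key]
    return None


def read_gff3(
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> list[GeneModel]:
    """Parse gene models from GFF3 ``gene``/``mRNA``/``CDS`` features.

    CDS segments are grouped per gene (via Parent chains or locus_tag) and
    become the gene's exon list; 1-based inclusive coordinates become
    0-based half-open.  When ``contig_lengths`` is supplied, features on
    unknown contigs or beyond contig bounds raise :class:`GffFormatError`.
    """
    path = Path(path)
    parents: dict[str, str] = {}  # feature ID -> parent feature ID
    gene_meta: dict[str, dict] = {}
    cds_segments: dict[str, list[tuple[str, str, int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffFormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GffFormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            if contig_lengths is not None and contig not in contig_lengths:
                raise GffFormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            attrs = _parse_attributes(attr_s)
            fid = attrs.get("ID")
            parent = attrs.get("Parent")
            if fid and parent:
                parents[fid] = parent
            if ftype == "gene":
                gid = _feature_gene_id(attrs)
                if gid is None:
                    raise GffFormatError(f"{path}:{lineno}: gene feature without ID/locus_tag")
                gene_meta[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "tag": attrs.get("tag", attrs.get("gene", "other")),
                    "attrs": attrs,
                }
            elif ftype == "CDS":
                owner = parent or _feature_gene_id(attrs)
                if owner is None:
                    raise GffFormatError(
                        f"{path}:{lineno}: CDS without Parent or identifying attribute"
                    )
                cds_segments.setdefault(owner, []).append((contig, strand, start1 - 1, end1))

    # resolve CDS owners (possibly mRNA IDs) up to gene IDs
    genes: dict[str, GeneModel] = {}
    for owner, segs in cds_segments.items():
        gid = owner
        seen = set()
        while gid not in gene_meta and gid in parents and gid not in seen:
            seen.add(gid)
            gid = parents[gid]
        if gid not in gene_meta:
            if owner in parents or owner in gene_meta:
                gid = owner
            else:
                raise GffFormatError(
                    f"{path}: CDS parent {owner!r} does not resolve to a gene feature"
                )
        meta = gene_meta[gid]
        contigs = {s[0] for s in segs}
        if len(contigs) != 1:
            raise GffFormatError(f"{path}: gene {gid!r} has CDS on multiple contigs")
        contig = segs[0][0]
        if contig != meta["contig"]:
            raise GffFormatError(f"{path}: gene {gid!r} CDS contig differs from gene contig")
        exons = sorted((a, b) for _, _, a, b in segs)
        if contig_lengths is not None:
            clen = contig_lengths[contig]
            for a, b in exons:
                if b > clen:
                    raise GffFormatError(
                        f"{path}: gene {gid!r} exon [{a},{b}) exceeds contig "
                        f"{contig!r} length {clen}"
                    )
        tag = meta["tag"] if meta["tag"] in GENE_TAGS else "other"
        genes[gid] = GeneModel(gid, contig, meta["strand"], exons, tag, meta["attrs"])
    return [genes[g] for g in genes]


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "pheromat") -> None:
    """Write gene models as GFF3 (gene + CDS rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};tag={g.tag}"
            fh.write(
                f"{g.contig_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig_id}\t{source}\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate_dna(cds: str) -> str:
    """Translate a CDS with the standard code; ambiguous codons give X."""
    n = len(cds) - len(cds) % 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return str(Seq(cds[:n]).translate(table=1))


def extract_cds(genome: dict[str, SequenceRecord] | list[SequenceRecord], gene: GeneModel) -> str:
    """Spliced CDS of ``gene`` in transcription order (revcomp on minus strand)."""
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    if gene.contig_id not in genome:
        raise KeyError(f"gene {gene.gene_id!r}: contig {gene.contig_id!r} not in genome")
    contig = genome[gene.contig_id].residues
    if gene.end > len(contig):
        raise ValueError(
            f"gene {gene.gene_id!r} extends beyond contig {gene.contig_id!r}"
        )
    cds = "".join(contig[a:b] for a, b in gene.exons)
    if gene.strand == "-":
        cds = revcomp(cds)
    return cds


def extract_cds_and_translate(
    genome: dict[str, SequenceRecord] | list[SequenceRecord], gene: GeneModel
) -> SequenceRecord:
    """Translate a gene model's spliced CDS.

    The trailing stop codon is removed; internal stops are retained as
    ``*`` and flagged in ``attributes['internal_stop']``.  A CDS length not
    divisible by 3 is flagged as a phase error rather than raised.
    """
    cds = extract_cds(genome, gene)
    phase_error = len(cds) % 3 != 0
    if phase_error:
        logger.warning("gene %s: CDS length %d not divisible by 3", gene.gene_id, len(cds))
    prot = translate_dna(cds)
    if prot.endswith("*"):
        prot = prot[:-1]
    rec = SequenceRecord(gene.gene_id, prot, "protein") if prot else None
    if rec is None:
        raise ValueError(f"gene {gene.gene_id!r}: zero-length translation")
    rec_attrs = {
        "internal_stop": "*" in prot,
        "phase_error": phase_error,
    }
    rec.__dict__["flags"] = rec_attrs
    return rec


@dataclass
class FrameTranslation:
    """One of the six reading-frame translations of a contig.

    ``frame`` is +1..+3 or -1..-3.  ``offset`` is the 0-based position on
    the *reading* strand where the frame starts, so protein position ``p``
    maps back to reading-strand DNA ``offset + 3p``.
    """

    contig_id: str
    frame: int
    offset: int
    protein: str
    contig_length: int

    def protein_to_contig(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Map a protein [start, end) interval to forward-strand contig coordinates."""
        s = self.offset + 3 * p_start
        e = self.offset + 3 * p_end
        if self.frame > 0:
            return s, e
        return self.contig_length - e, self.contig_length - s


def six_frame_translate(contig: SequenceRecord) -> list[FrameTranslation]:
    """All six reading-frame translations, stops rendered as ``*``."""
    out: list[FrameTranslation] = []
    fwd = contig.residues
    rev = revcomp(fwd)
    n = len(fwd)
    for offset in range(3):
        out.append(FrameTranslation(contig.id, offset + 1, offset, translate_dna(fwd[offset:]), n))
    for offset in range(3):
        out.append(FrameTranslation(contig.id, -(offset + 1), offset, translate_dna(rev[offset:]), n))
    return out


def orfs_in_dna(dna: str, min_aa: int = 20) -> list[tuple[int, int, str, str]]:
    """ATG-to-stop open reading frames on both strands.

    Returns tuples ``(start, end, strand, protein)`` with [start, end)
    forward-strand coordinates covering the CDS including the stop codon
    when present.  The protein excludes the stop.
    """
    results = []
    n = len(dna)
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        for offset in range(3):
            prot = translate_dna(seq[offset:])
            i = 0
            while i < len(prot):
                if prot[i] == "M":
                    j = prot.find("*", i)
                    end_aa = j if j != -1 else len(prot)
                    if end_aa - i >= min_aa:
                        s = offset + 3 * i
                        e = offset + 3 * (end_aa + (1 if j != -1 else 0))
                        if strand == "-":
                            s, e = n - e, n - s
                        results.append((s, e, strand, prot[i:end_aa]))
                    i = end_aa + 1
                else:
                    i += 1
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    return results
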