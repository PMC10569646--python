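"""Synthetic genomes with planted ground truth.

Every structure the pipeline detects can be generated here with a known
answer: grammar-valid α-factor pro-pheromone genes (2–18 mature repeats
of 9–14 aa), short CAAX/CPAX-terminated a-factor genes and decoy ORFs,
the named MAT-locus architectures (heterothallic idiomorphs, fused
homothallic loci, 250-bp direct/inverted repeat switching structures,
HMG-only loci, split and fragmented loci), seven-transmembrane receptor
constructs, birth–death species trees with thallism states, and
read-count tables.  All generators are deterministic given a seed, and
each returns the planted truth alongside the sequence so recovery can be
scored without re-deriving it.

Design notes.  Background sequence is order-0 random DNA at 45% GC.
MAT-locus genes are stand-ins: random reference proteins mutated at 20%
of sites, so homology stays detectable but non-identical; locus genes
carry no introns so that homology coverage directly reflects gene
integrity (intron handling is exercised through the gene-model
extraction path, in particular the two-exon 330-bp construct).  Mature
pheromone repeats are sampled avoiding internal KEX dipeptides and
avoiding A/P at the second position — a repeat violating either would be
cleaved or re-anchored by the very processing grammar that defines it —
and signal peptides are built from non-A/P hydrophobics so that the only
STE13 sites present are the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .asr import Mk2Params, PhyloTree, simulate_mk2
from .seqio import GeneModel, SequenceRecord, revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: synonymous codons of the standard code (stop codons excluded)
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
STOPS = ["TAA", "TAG", "TGA"]

A_FACTOR_BOXES = ("CTVM", "CVVM", "CIVM", "CTIL", "CSIM", "CSVM")

MAT_ARCHITECTURES = (
    "het_MAT1_1",
    "het_MAT1_2",
    "fused_homothallic",
    "inversion_switch",
    "deletion_switch",
    "lachnellula_MAT1_1",
    "lachnellula_MAT1_2",
    "split_mixed",
    "truncated_undetermined",
    "sborealis_fragmented",
)

#: the strategy each architecture is built to exhibit
ARCHITECTURE_STRATEGY = {
    "het_MAT1_1": "heterothallic_MAT1_1",
    "het_MAT1_2": "heterothallic_MAT1_2",
    "fused_homothallic": "primary_homothallic",
    "inversion_switch": "switching_inversion",
    "deletion_switch": "switching_deletion",
    "lachnellula_MAT1_1": "lachnellula_HMG_only",
    "lachnellula_MAT1_2": "heterothallic_MAT1_2",
    "split_mixed": "possible_mixed_culture",
    "truncated_undetermined": "undetermined",
    "sborealis_fragmented": "undetermined",
}


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_dna(n: int, rng, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ATGC"), size=n, p=p / p.sum()))


def random_protein(n: int, rng, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def reverse_translate(protein: str, rng, stop: bool = True) -> str:
    """DNA encoding ``protein`` with uniformly random synonymous codons."""
    codons = [CODONS[a][rng.integers(len(CODONS[a]))] for a in protein.upper()]
    if stop:
        codons.append(STOPS[rng.integers(len(STOPS))])
    return "".join(codons)


def mutate_protein(protein: str, rng, fraction: float = 0.2) -> str:
    """Substitute a ``fraction`` of sites with a different random residue."""
    protein = list(protein)
    n_mut = int(round(fraction * len(protein)))
    sites = rng.choice(len(protein), size=n_mut, replace=False)
    for s in sites:
        choices = [a for a in AA20 if a != protein[s]]
        protein[s] = choices[rng.integers(len(choices))]
    return "".join(protein)


# ---------------------------------------------------------------------------
# α-factor pro-pheromone genes
# ---------------------------------------------------------------------------

_KEX = ("KR", "RR", "KK")
_STE13_X = "DEGNQST"   # first residue of an XA/XP dipeptide
_SPACER_AA = "DEGNQSTWYFHC"  # no K/R (no spurious KEX), no A/P (no spurious STE13)
_SIGNAL_AA = "LIVF"          # hydrophobic, no A/P


def sample_repeat(rng, min_len: int = 9, max_len: int = 14) -> str:
    """A random mature-repeat peptide compatible with the processing grammar.

    Constraints: no internal KEX dipeptide (it would be cleaved), second
    residue not A/P (the preceding STE13 run would re-anchor), and no
    K/R at the last position (it would extend the following KEX site).
    """
    length = int(rng.integers(min_len, max_len + 1))
    while True:
        res = [rng.choice(list(AA20)) for _ in range(length)]
        if res[1] in "AP" or res[-1] in "KR":
            continue
        seq = "".join(res)
        if any(seq[i : i + 2] in _KEX for i in range(length - 1)):
            continue
        return seq


def _ste13_run(rng) -> str:
    x1, x2 = rng.choice(list(_STE13_X)), rng.choice(list(_STE13_X))
    a1, a2 = rng.choice(["A", "P"]), rng.choice(["A", "P"])
    return f"{x1}{a1}{x2}{a2}"


def build_alpha_protein(repeat: str, n_repeats: int, rng) -> str:
    """Signal + [spacer, STE13 run, repeat, KEX] × n + short tail."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    parts = ["M" + random_protein(int(rng.integers(12, 17)), rng, _SIGNAL_AA)]
    for _ in range(n_repeats):
        parts.append(random_protein(int(rng.integers(2, 6)), rng, _SPACER_AA))
        parts.append(_ste13_run(rng))
        parts.append(repeat)
        parts.append(_KEX[rng.integers(3)])
    parts.append(random_protein(int(rng.integers(0, 4)), rng, "GNDE"))
    return "".join(parts)


def _insert_intron(cds: str, rng, length_range=(50, 80)) -> tuple[str, list[tuple[int, int]]]:
    """Insert one canonical GT..AG intron; return gene DNA and exon intervals."""
    ilen = int(rng.integers(length_range[0], length_range[1] + 1))
    intron = "GT" + random_dna(ilen - 4, rng) + "AG"
    pos = int(rng.integers(30, len(cds) - 30))
    gene = cds[:pos] + intron + cds[pos:]
    return gene, [(0, pos), (pos + ilen, len(gene))]


@dataclass
class PlantedGene:
    """One planted gene with its contig and truth payload."""

    contig: SequenceRecord
    gene: GeneModel
    protein: str
    truth: dict = field(default_factory=dict)


def gen_alpha_gene(
    repeat: str | None = None,
    n_repeats: int = 3,
    seed: int | np.random.Generator = 0,
    intron_probability: float = 0.5,
    contig_id: str = "alpha_contig",
    strand: str = "+",
) -> PlantedGene:
    """A grammar-valid α-factor pro-pheromone gene on a random contig."""
    rng = _rng(seed)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if repeat is None:
        repeat = sample_repeat(rng)
    if len(repeat) < 2:
        raise ValueError("repeat too short")
    protein = build_alpha_protein(repeat, n_repeats, rng)
    cds = reverse_translate(protein, rng)
    if rng.random() < intron_probability:
        gene_dna, exons = _insert_intron(cds, rng)
    else:
        gene_dna, exons = cds, [(0, len(cds))]
    flank5 = random_dna(int(rng.integers(120, 260)), rng)
    flank3 = random_dna(int(rng.integers(120, 260)), rng)
    off = len(flank5)
    dna = flank5 + gene_dna + flank3
    if strand == "-":
        n = len(dna)
        dna = revcomp(dna)
        exon_ivals = [(n - (off + b), n - (off + a)) for a, b in exons][::-1]
    else:
        exon_ivals = [(off + a, off + b) for a, b in exons]
    contig = SequenceRecord(contig_id, dna, "dna")
    gene = GeneModel("alpha1", contig_id, strand, exon_ivals, "alpha_pheromone")
    return PlantedGene(
        contig, gene, protein,
        {"kind": "alpha", "repeat": repeat, "n_repeats": n_repeats, "protein": protein},
    )


# ---------------------------------------------------------------------------
# a-factor genes and decoys
# ---------------------------------------------------------------------------

def build_afactor_protein(
    length_aa: int, box: str, st_rich: bool, gy: bool, rng
) -> str:
    """Short a-factor-like precursor: M + body + (GY near tail) + CAAX/CPAX box."""
    if box.upper() not in A_FACTOR_BOXES:
        raise ValueError(f"box {box!r} not one of {A_FACTOR_BOXES}")
    if length_aa < 20:
        raise ValueError("a-factor precursors are at least 20 aa")
    body_len = length_aa - 5  # M + body + 4-aa box
    body = []
    for i in range(body_len):
        if st_rich and i < 19:
            body.append(rng.choice(list("ST")) if rng.random() < 0.5 else rng.choice(list(AA20)))
        else:
            body.append(rng.choice(list(AA20)))
    body = list("".join(body))
    if gy:
        # GY start within the 15-residue window upstream of the box cysteine
        offset = int(rng.integers(3, 11))  # distance from GY start to box C
        pos = body_len - offset
        if pos < 0:
            pos = 0
        body[pos : pos + 2] = ["G", "Y"]
    else:
        txt = "".join(body)
        while "GY" in txt[-15:]:
            i = len(txt) - 15 + txt[-15:].rindex("GY")
            body[i] = rng.choice(list("ASTN"))
            txt = "".join(body)
    return "M" + "".join(body) + box.upper()


def gen_afactor_gene(
    length_aa: int = 55,
    box: str = "CTVM",
    st_rich: bool = True,
    gy: bool = True,
    seed: int | np.random.Generator = 0,
    contig_id: str = "afactor_contig",
    gene_id: str = "afactor1",
    protein: str | None = None,
) -> PlantedGene:
    """An a-factor-like gene (intron-free) on a random contig.

    Pass ``protein`` to plant a fixed precursor (e.g. the same gene across
    a cohort of relatives, with codon usage re-randomised per genome).
    """
    rng = _rng(seed)
    if protein is None:
        protein = build_afactor_protein(length_aa, box, st_rich, gy, rng)
    cds = reverse_translate(protein, rng)
    flank5 = random_dna(int(rng.integers(100, 200)), rng)
    flank3 = random_dna(int(rng.integers(100, 200)), rng)
    dna = flank5 + cds + flank3
    contig = SequenceRecord(contig_id, dna, "dna")
    gene = GeneModel(gene_id, contig_id, "+", [(len(flank5), len(flank5) + len(cds))], "a_pheromone")
    return PlantedGene(
        contig, gene, protein,
        {"kind": "a_factor", "box": protein[-4:], "st_rich": st_rich, "gy": gy, "protein": protein},
    )


def gen_decoy_caax_orf(
    seed: int | np.random.Generator,
    contig_id: str = "decoy_contig",
    gene_id: str = "decoy",
) -> PlantedGene:
    """A private decoy: short random protein ending in a CAAX/CPAX box."""
    rng = _rng(seed)
    length = int(rng.integers(25, 96))
    box = A_FACTOR_BOXES[rng.integers(len(A_FACTOR_BOXES))]
    protein = "M" + random_protein(length - 5, rng) + box
    cds = reverse_translate(protein, rng)
    flank5 = random_dna(int(rng.integers(80, 160)), rng)
    flank3 = random_dna(int(rng.integers(80, 160)), rng)
    contig = SequenceRecord(contig_id, flank5 + cds + flank3, "dna")
    gene = GeneModel(gene_id, contig_id, "+", [(len(flank5), len(flank5) + len(cds))], "other")
    return PlantedGene(contig, gene, protein, {"kind": "decoy_caax", "protein": protein})


# ---------------------------------------------------------------------------
# receptors
# ---------------------------------------------------------------------------

def build_receptor_protein(n_tm: int, rng) -> str:
    """n_tm hydrophobic 21-aa helices separated by 15-aa hydrophilic linkers."""
    hydrophilic = "STNQDEGKRHY"
    parts = ["M" + random_protein(29, rng, hydrophilic)]
    for i in range(n_tm):
        parts.append(random_protein(21, rng, "LIVF"))
        if i < n_tm - 1:
            parts.append(random_protein(15, rng, hydrophilic))
    parts.append(random_protein(25, rng, hydrophilic))
    return "".join(parts)


def gen_receptor_gene(
    receptor: str = "STE2",
    n_tm: int = 7,
    premature_stop: bool = False,
    seed: int | np.random.Generator = 0,
    contig_id: str = "receptor_contig",
    gene_id: str | None = None,
) -> PlantedGene:
    """A synthetic receptor gene with a controllable TM-helix count."""
    rng = _rng(seed)
    protein = build_receptor_protein(n_tm, rng)
    cds = reverse_translate(protein, rng)
    if premature_stop:
        mid = (len(cds) // 6) * 3  # in-frame, well inside the CDS
        cds = cds[:mid] + "TAA" + cds[mid + 3 :]
    flank5 = random_dna(int(rng.integers(100, 200)), rng)
    flank3 = random_dna(int(rng.integers(100, 200)), rng)
    contig = SequenceRecord(contig_id, flank5 + cds + flank3, "dna")
    gene = GeneModel(
        gene_id or receptor.lower(), contig_id, "+",
        [(len(flank5), len(flank5) + len(cds))], receptor.lower(),
    )
    return PlantedGene(
        contig, gene, protein,
        {"kind": "receptor", "receptor": receptor, "n_tm": n_tm, "premature_stop": premature_stop},
    )


# ---------------------------------------------------------------------------
# MAT-locus architectures
# ---------------------------------------------------------------------------

REFERENCE_LENGTHS = {
    "APN2": 420,
    "SLA2": 460,
    "MAT1-1-1": 360,
    "MAT1-1-3": 290,
    "MAT1-1-5": 210,
    "MAT1-1-13": 90,
    "MAT1-2-1": 330,
    "MAT1-2-10": 190,
}


def make_reference_proteins(seed: int = 971) -> dict[str, SequenceRecord]:
    """Synthetic stand-ins for the MAT/anchor reference protein set.

    These are random proteins of realistic lengths, generated once from a
    fixed seed; architecture genes are mutated copies of them, so the
    homology relationships of a real locus are reproduced without any
    deposited sequence data.
    """
    rng = _rng(seed)
    return {
        name: SequenceRecord(name, random_protein(length, rng), "protein")
        for name, length in REFERENCE_LENGTHS.items()
    }


def _gene_dna(ref: SequenceRecord, rng, divergence: float = 0.2,
              part: tuple[float, float] = (0.0, 1.0)) -> str:
    """DNA of a diverged (and possibly partial) copy of a reference protein."""
    protein = mutate_protein(ref.residues, rng, divergence)
    a = int(part[0] * len(protein))
    b = int(part[1] * len(protein))
    return reverse_translate(protein[a:b], rng, stop=(part[1] >= 1.0))


@dataclass
class MatArchitecture:
    name: str
    contigs: list[SequenceRecord]
    truth: dict


def gen_mat_architecture(
    name: str,
    seed: int | np.random.Generator = 0,
    references: dict[str, SequenceRecord] | None = None,
    divergence: float = 0.2,
) -> MatArchitecture:
    """Generate contig(s) reproducing one named MAT-locus architecture."""
    if name not in MAT_ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}; valid: {MAT_ARCHITECTURES}")
    rng = _rng(seed)
    refs = references or make_reference_proteins()
    repeat250 = random_dna(250, rng)

    def spacer() -> str:
        return random_dna(int(rng.integers(150, 300)), rng)

    def g(ref_name: str, part=(0.0, 1.0)) -> str:
        return _gene_dna(refs[ref_name], rng, divergence, part)

    layouts: dict[str, list[list[str]]] = {
        "het_MAT1_1": [["APN2", "MAT1-1-1", "MAT1-1-5", "frag:MAT1-2-1", "SLA2"]],
        "het_MAT1_2": [["APN2", "MAT1-2-1", "MAT1-2-10", "SLA2"]],
        "fused_homothallic": [["APN2", "MAT1-1-1", "MAT1-1-3", "MAT1-2-1", "SLA2"]],
        "inversion_switch": [[
            "APN2", "frag5:MAT1-1-1", "R+", "MAT1-2-1", "MAT1-2-10", "MAT1-1-5",
            "R-", "frag3:MAT1-1-1", "SLA2",
        ]],
        "deletion_switch": [[
            "APN2", "MAT1-1-1", "MAT1-1-5", "R+", "MAT1-2-1", "MAT1-2-10", "R+", "SLA2",
        ]],
        "lachnellula_MAT1_1": [["APN2", "MAT1-1-3", "SLA2"]],
        "lachnellula_MAT1_2": [["APN2", "MAT1-2-1", "SLA2"]],
        "split_mixed": [
            ["APN2", "MAT1-1-1", "MAT1-1-3", "SLA2"],
            ["MAT1-2-1"],
        ],
        "truncated_undetermined": [["APN2", "trunc5:MAT1-1-1", "MAT1-2-1", "SLA2"]],
        "sborealis_fragmented": [
            ["APN2", "trunc5:MAT1-2-10", "MAT1-2-1", "MAT1-1-5"],
            ["frag5:MAT1-1-1"],
            ["frag3:MAT1-1-1"],
            ["SLA2"],
        ],
    }

    contigs: list[SequenceRecord] = []
    placed: list[dict] = []
    for ci, layout in enumerate(layouts[name]):
        parts = [spacer()]
        for item in layout:
            if item == "R+":
                parts.append(repeat250)
                placed.append({"element": "repeat250", "contig": ci, "orientation": "+"})
            elif item == "R-":
                parts.append(revcomp(repeat250))
                placed.append({"element": "repeat250", "contig": ci, "orientation": "-"})
            else:
                kind, _, gname = item.rpartition(":")
                if kind == "frag" or kind == "frag5":
                    dna = g(gname, (0.0, 0.35))
                elif kind == "frag3":
                    dna = g(gname, (0.65, 1.0))
                elif kind == "trunc5":
                    dna = g(gname, (0.35, 1.0))  # 3' region present, 5' missing
                else:
                    dna = g(gname)
                parts.append(dna)
                placed.append({"element": gname, "contig": ci, "form": kind or "intact"})
            parts.append(spacer())
        contigs.append(SequenceRecord(f"{name}_ctg{ci}", "".join(parts), "dna"))
    return MatArchitecture(
        name, contigs,
        {
            "kind": "mat_architecture",
            "architecture": name,
            "expected_strategy": ARCHITECTURE_STRATEGY[name],
            "elements": placed,
        },
    )


def gen_mat11_13_gene(seed: int | np.random.Generator = 0) -> PlantedGene:
    """The short novel MAT1-1 gene construct: 330 bp, two exons, 57-bp intron.

    The spliced CDS is 273 nt including the stop, encoding a 90-aa protein.
    """
    rng = _rng(seed)
    protein = random_protein(90, rng)
    cds = reverse_translate(protein, rng)  # 273 nt with stop
    intron = "GT" + random_dna(53, rng) + "AG"
    pos = int(rng.integers(60, len(cds) - 60))
    gene_dna = cds[:pos] + intron + cds[pos:]
    flank5 = random_dna(150, rng)
    dna = flank5 + gene_dna + random_dna(150, rng)
    contig = SequenceRecord("mat1113_contig", dna, "dna")
    off = len(flank5)
    gene = GeneModel(
        "MAT1-1-13", "mat1113_contig", "+",
        [(off, off + pos), (off + pos + 57, off + len(gene_dna))], "MAT1-1-13",
    )
    return PlantedGene(contig, gene, protein, {"kind": "mat1113", "protein": protein})


# ---------------------------------------------------------------------------
# trees, states and cohorts
# ---------------------------------------------------------------------------

def gen_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0, death_rate: float = 0.2) -> str:
    """A birth–death species tree as Newick with branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    import random as _random

    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=_random.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:03d}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def assign_clustered_states(
    tree: PhyloTree,
    n_hom: int,
    n_unknown: int,
    seed: int = 0,
) -> dict[str, str]:
    """Tip states with homothallic taxa clustered in a few clades.

    Homothallic tips are chosen clade-by-clade (internal nodes of modest
    clade size, in a seeded random order) until ``n_hom`` is reached;
    unknown (?) tips are then scattered over the remaining heterothallic
    tips.  Everything else is heterothallic (state 1).
    """
    rng = _rng(seed)
    leaves = set(tree.leaves)
    # clade leaf sets of internal nodes
    below: dict[int, set[int]] = {}
    for i in tree.postorder:
        if not tree.children[i]:
            below[i] = {i}
        else:
            below[i] = set().union(*(below[c] for c in tree.children[i]))
    internal = [i for i in tree.postorder if tree.children[i] and i != tree.root]
    order = list(rng.permutation(len(internal)))
    hom: set[int] = set()
    for k in order:
        clade = below[internal[k]]
        if len(clade) <= max(2, n_hom // 2) and not clade & hom:
            take = set(list(clade)[: n_hom - len(hom)])
            hom |= take
        if len(hom) >= n_hom:
            break
    # top up with single tips if clades did not cover n_hom exactly
    for leaf in sorted(leaves - hom):
        if len(hom) >= n_hom:
            break
        hom.add(leaf)
    rest = sorted(leaves - hom)
    unknown = set(rng.choice(rest, size=n_unknown, replace=False)) if n_unknown else set()
    states = {}
    for i in leaves:
        label = tree.labels[i]
        if i in hom:
            states[label] = "0"
        elif i in unknown:
            states[label] = "?"
        else:
            states[label] = "1"
    return states


#: architectures cycled through per planted thallism state
_STATE_ARCHITECTURES = {
    "1": ["het_MAT1_1", "het_MAT1_2", "lachnellula_MAT1_1", "lachnellula_MAT1_2"],
    "0": ["fused_homothallic", "fused_homothallic", "inversion_switch", "deletion_switch"],
    "?": ["truncated_undetermined", "split_mixed", "sborealis_fragmented"],
}

#: how each strategy call maps back to a thallism state
STRATEGY_TO_STATE = {
    "heterothallic_MAT1_1": "1",
    "heterothallic_MAT1_2": "1",
    "lachnellula_HMG_only": "1",
    "primary_homothallic": "0",
    "switching_inversion": "0",
    "switching_deletion": "0",
    "undetermined": "?",
    "possible_mixed_culture": "?",
    "unknown": "?",
}


@dataclass
class SyntheticGenome:
    genome_id: str
    contigs: list[SequenceRecord]
    genes: list[GeneModel]
    truth: dict


@dataclass
class SyntheticCohort:
    """A cohort of synthetic genomes with tree, states and full truth."""

    genomes: list[SyntheticGenome]
    newick: str
    states: dict[str, str]
    truth: dict

    def genome(self, genome_id: str) -> SyntheticGenome:
        return next(g for g in self.genomes if g.genome_id == genome_id)


def gen_genome(
    genome_id: str,
    architecture: str,
    seed: int | np.random.Generator,
    references: dict[str, SequenceRecord] | None = None,
    shared_afactor: str | None = None,
    n_decoys: int = 3,
    alpha_repeat: str | None = None,
    with_receptors: bool = False,
) -> SyntheticGenome:
    """One genome: a MAT architecture plus planted pheromone genes and decoys."""
    rng = _rng(seed)
    arch = gen_mat_architecture(architecture, rng, references)
    contigs = list(arch.contigs)
    genes: list[GeneModel] = []
    truth: dict = {"architecture": arch.truth, "genes": {}}

    alpha = gen_alpha_gene(
        repeat=alpha_repeat, n_repeats=int(rng.integers(2, 6)), seed=rng,
        contig_id=f"{genome_id}_alpha",
    )
    contigs.append(alpha.contig)
    genes.append(alpha.gene)
    truth["genes"]["alpha1"] = alpha.truth

    af = gen_afactor_gene(
        seed=rng, contig_id=f"{genome_id}_af", gene_id="afactor1", protein=shared_afactor
    )
    contigs.append(af.contig)
    genes.append(af.gene)
    truth["genes"]["afactor1"] = af.truth

    for d in range(n_decoys):
        decoy = gen_decoy_caax_orf(rng, f"{genome_id}_d{d}", f"decoy{d}")
        contigs.append(decoy.contig)
        genes.append(decoy.gene)
        truth["genes"][f"decoy{d}"] = decoy.truth

    if with_receptors:
        for rec_name in ("STE2", "STE3"):
            rec = gen_receptor_gene(rec_name, seed=rng, contig_id=f"{genome_id}_{rec_name.lower()}")
            contigs.append(rec.contig)
            genes.append(rec.gene)
            truth["genes"][rec.gene.gene_id] = rec.truth

    return SyntheticGenome(genome_id, contigs, genes, truth)


def gen_cohort(
    n_genomes: int,
    seed: int = 0,
    states: dict[str, str] | None = None,
    state_split: tuple[int, int, int] | None = None,
    mk2_params: Mk2Params | None = None,
    n_decoys: int = 3,
    with_receptors: bool = False,
    shared_alpha_repeat: str = "WCGRPGQPC",
) -> SyntheticCohort:
    """A cohort of genomes on a birth–death tree with planted thallism states.

    States come from (in order of precedence) the explicit ``states`` map,
    a ``state_split`` (n_het, n_hom, n_unknown) with homothallics
    clustered in clades, or simulation under ``mk2_params``.  Every
    genome carries the architecture its state implies, one α-factor gene
    (sharing a cohort-wide mature repeat), one copy of a cohort-wide
    a-factor gene, and private decoy CAAX ORFs.
    """
    if n_genomes < 2:
        raise ValueError("a cohort needs at least 2 genomes")
    rng = np.random.default_rng(seed)
    newick = gen_tree(n_genomes, seed=seed)
    tree = PhyloTree.from_newick(newick)
    labels = sorted(tree.labels.values())
    if states is None:
        if state_split is not None:
            n_het, n_hom, n_unknown = state_split
            if n_het + n_hom + n_unknown != n_genomes:
                raise ValueError("state split must sum to n_genomes")
            states = assign_clustered_states(tree, n_hom, n_unknown, seed=seed + 1)
        else:
            tips, _ = simulate_mk2(tree, mk2_params or Mk2Params(0.5, 0.5), seed=rng)
            states = tips
    shared_afactor = build_afactor_protein(55, "CTVM", True, True, rng)
    counters = {"0": 0, "1": 0, "?": 0}
    genomes = []
    for label in labels:
        st = states[label]
        archs = _STATE_ARCHITECTURES[st]
        arch = archs[counters[st] % len(archs)]
        counters[st] += 1
        genomes.append(
            gen_genome(
                label, arch, rng, shared_afactor=shared_afactor,
                n_decoys=n_decoys, alpha_repeat=shared_alpha_repeat,
                with_receptors=with_receptors,
            )
        )
    truth = {
        "states": states,
        "shared_afactor": shared_afactor,
        "shared_alpha_repeat": shared_alpha_repeat,
        "architectures": {g.genome_id: g.truth["architecture"]["architecture"] for g in genomes},
    }
    return SyntheticCohort(genomes, newick, states, truth)


def states_tsv(states: dict[str, str]) -> str:
    lines = ["taxon\tstate"]
    for k in sorted(states):
        lines.append(f"{k}\t{states[k]}")
    return "\n".join(lines) + "\n"


def gen_count_table(seed: int = 0) -> "pd.DataFrame":
    """A small synthetic pheromone count table over pure and mixed samples."""
    import pandas as pd

    rng = _rng(seed)
    rows = []
    genes = {"alpha1": 300, "afactor1": 168}
    samples = [("s_mat11", "MAT1-1"), ("s_mat12", "MAT1-2"), ("s_mixed", "mixed")]
    for gene, length in genes.items():
        for sample, mtype in samples:
            lib = int(rng.integers(8, 12)) * 10**5
            rows.append(
                {
                    "gene_id": gene,
                    "gene_length_bp": length,
                    "sample_id": sample,
                    "mating_type": mtype,
                    "library_size": lib,
                    "count": int(rng.integers(0, 40)),
                }
            )
    return pd.DataFrame(rows)
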