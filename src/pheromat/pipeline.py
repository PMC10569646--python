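"""Cohort orchestration: run every stage over a set of genomes.

The stages are plain library calls; this module wires them together for
a cohort and produces the cross-genome summary tables: a thallism
summary, an α-factor table (per-species class and repeat sharing), an
a-factor candidate table, receptor tallies, and ancestral-state node
posteriors.  A file-based entry point (``run_all``) consumes a manifest
listing per-genome FASTA/GFF paths plus optional tree, states and count
files, so each stage is re-runnable from files alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import afactor, alpha, asr, expression, homology, mat_locus, receptor, seqio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds in one place (YAML-loadable)."""

    alpha: alpha.AlphaConfig = field(default_factory=alpha.AlphaConfig)
    afactor: afactor.AFactorConfig = field(default_factory=afactor.AFactorConfig)
    locus: mat_locus.LocusConfig = field(default_factory=mat_locus.LocusConfig)
    receptor: receptor.ReceptorConfig = field(default_factory=receptor.ReceptorConfig)
    search: homology.SearchParams = field(default_factory=homology.SearchParams)
    rpkm_threshold_on: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        sections = {
            "alpha": cfg.alpha, "afactor": cfg.afactor, "locus": cfg.locus,
            "receptor": cfg.receptor, "search": cfg.search,
        }
        for key, value in raw.items():
            if key in sections:
                for k, v in (value or {}).items():
                    if not hasattr(sections[key], k):
                        raise ValueError(f"unknown config key {key}.{k}")
                    setattr(sections[key], k, v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenomeReport:
    genome_id: str
    thallism: mat_locus.ThallismCall
    locus: mat_locus.MatLocusModel
    repeat_pairs: list[mat_locus.RepeatPair]
    alpha_annotations: dict[str, alpha.AlphaAnnotation]
    afactor_candidates: list[afactor.AFactorCandidate]
    receptor_calls: list[receptor.ReceptorCall]

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "strategy": self.thallism.strategy,
            "evidence": self.thallism.evidence,
            "locus_genes": [asdict(g) for g in self.locus.genes],
            "repeat_pairs": [asdict(p) for p in self.repeat_pairs],
            "alpha": {
                pid: {
                    "class": ann.klass,
                    "n_repeats": ann.n_repeats,
                    "repeats": ann.repeat_sequences,
                }
                for pid, ann in self.alpha_annotations.items()
            },
            "afactor": [afactor.evidence_report(c) for c in self.afactor_candidates],
            "receptors": [asdict(c) for c in self.receptor_calls],
        }


def analyze_genome(
    genome_id: str,
    contigs: list[seqio.SequenceRecord],
    gene_models: list[seqio.GeneModel],
    references: dict[str, seqio.SequenceRecord],
    config: PipelineConfig | None = None,
) -> GenomeReport:
    """Run MAT classification, pheromone screens and receptor QC on one genome."""
    config = config or PipelineConfig()
    genome_map = {c.id: c for c in contigs}

    locus = mat_locus.locate_mat_locus(contigs, references, config.search, config.locus)
    pairs: list[mat_locus.RepeatPair] = []
    if locus.window is not None:
        contig = genome_map[locus.window[0]]
        ws, we = locus.window[1]
        pairs = mat_locus.detect_repeat_pairs(
            contig.residues[ws:we],
            min_len=config.locus.repeat_len_min,
            identity_min=config.locus.repeat_identity_min,
        )
    call = mat_locus.classify_thallism(locus.genes, pairs, None)

    alpha_annotations: dict[str, alpha.AlphaAnnotation] = {}
    proteins: list[seqio.SequenceRecord] = []
    receptor_calls: list[receptor.ReceptorCall] = []
    for gene in gene_models:
        rec = seqio.extract_cds_and_translate(genome_map, gene)
        if gene.tag == "alpha_pheromone":
            alpha_annotations[gene.gene_id] = alpha.annotate_repeats(
                rec.residues, config.alpha, protein_id=gene.gene_id
            )
        elif gene.tag in ("ste2", "ste3"):
            receptor_calls.append(
                receptor.qc_receptor(gene, genome_map, gene.tag.upper(), config.receptor)
            )
        proteins.append(rec)
    candidates = afactor.filter_proteome(proteins, config=config.afactor)
    return GenomeReport(
        genome_id, call, locus, pairs, alpha_annotations, candidates, receptor_calls
    )


def thallism_summary(reports: list[GenomeReport]) -> pd.DataFrame:
    rows = [
        {"genome": r.genome_id, "strategy": r.thallism.strategy} for r in reports
    ]
    return pd.DataFrame(rows).sort_values("genome").reset_index(drop=True)


def alpha_summary(reports: list[GenomeReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for pid, ann in r.alpha_annotations.items():
            rows.append(
                {
                    "genome": r.genome_id,
                    "protein_id": pid,
                    "class": ann.klass,
                    "n_repeats": ann.n_repeats,
                    "repeats": ";".join(ann.repeat_sequences),
                }
            )
    return pd.DataFrame(rows)


def afactor_summary(reports: list[GenomeReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for c in r.afactor_candidates:
            rec = afactor.evidence_report(c)
            rec["genome"] = r.genome_id
            rows.append(rec)
    return pd.DataFrame(rows)


def receptor_summary(reports: list[GenomeReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for c in r.receptor_calls:
            rows.append(
                {
                    "genome": r.genome_id,
                    "receptor": c.receptor,
                    "tm_count": c.tm_count,
                    "verdict": c.verdict,
                }
            )
    return pd.DataFrame(rows)


def run_all(manifest_path: str | Path, outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    """File-based pipeline entry point.

    The YAML manifest lists genomes (``id``, ``fasta``, optional ``gff``),
    a ``references`` FASTA of MAT/anchor proteins, and optional ``tree``
    (Newick), ``states`` (TSV taxon/state) and ``counts`` (TSV) files.
    Writes per-genome JSON reports and cohort summary TSVs to ``outdir``
    and returns the summary tables.
    """
    manifest_path = Path(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or "genomes" not in manifest or not manifest["genomes"]:
        raise ValueError(f"{manifest_path}: manifest lists no genomes")

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else manifest_path.parent / q

    refs_path = manifest.get("references")
    if not refs_path:
        raise ValueError(f"{manifest_path}: 'references' protein FASTA is required")
    references = {r.id: r for r in seqio.read_fasta(_resolve(refs_path), alphabet="protein")}

    reports = []
    for entry in manifest["genomes"]:
        gid = entry["id"]
        fasta = _resolve(entry["fasta"])
        if not fasta.exists():
            raise FileNotFoundError(f"manifest genome {gid!r}: missing FASTA {fasta}")
        contigs = seqio.read_fasta(fasta, alphabet="dna")
        genes: list[seqio.GeneModel] = []
        if entry.get("gff"):
            gff = _resolve(entry["gff"])
            if not gff.exists():
                raise FileNotFoundError(f"manifest genome {gid!r}: missing GFF {gff}")
            genes = seqio.read_gff3(gff, {c.id: len(c) for c in contigs})
        report = analyze_genome(gid, contigs, genes, references, config)
        with open(outdir / f"{gid}.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
        reports.append(report)

    out: dict = {"reports": reports}
    thallism_summary(reports).to_csv(outdir / "thallism_summary.tsv", sep="\t", index=False)
    alpha_summary(reports).to_csv(outdir / "alpha_summary.tsv", sep="\t", index=False)
    afactor_summary(reports).to_csv(outdir / "afactor_summary.tsv", sep="\t", index=False)
    receptor_summary(reports).to_csv(outdir / "receptor_summary.tsv", sep="\t", index=False)

    if manifest.get("tree") and manifest.get("states"):
        tree = asr.PhyloTree.from_newick(Path(_resolve(manifest["tree"])).read_text())
        states_df = pd.read_csv(_resolve(manifest["states"]), sep="\t", dtype=str)
        states = dict(zip(states_df["taxon"], states_df["state"]))
        result = asr.mcmc_rates(tree, states, n_samples=400, seed=config.seed)
        (outdir / "asr_posteriors.tsv").write_text(
            asr.posteriors_tsv(tree, result.mean_posteriors)
        )
        out["asr"] = result

    if manifest.get("counts"):
        table = expression.CountTable.from_tsv(_resolve(manifest["counts"]))
        (outdir / "rpkm.tsv").write_text(expression.rpkm_table_tsv(table))
        verdicts = {
            gid: expression.mating_dependence(table, gid, config.rpkm_threshold_on)
            for gid in table.data["gene_id"].unique()
        }
        (outdir / "mating_dependence.tsv").write_text(
            "gene_id\tverdict\n" + "".join(f"{g}\t{v}\n" for g, v in sorted(verdicts.items()))
        )
        out["expression"] = verdicts
    return out
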