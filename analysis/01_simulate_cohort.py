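#!/usr/bin/env python
"""Simulate a small genome cohort with planted mating-gene ground truth.

Generates 12 synthetic genomes (8 heterothallic, 2 homothallic, 2 of
undetermined strategy) on a birth-death species tree.  Every genome
carries the MAT-locus architecture its thallism state implies, one
α-factor pro-pheromone gene sharing the cohort-wide mature repeat
WCGRPGQPC, one copy of a cohort-wide a-factor gene, private decoy CAAX
ORFs, and intact seven-helix STE2/STE3 receptor genes.  Inputs for the
downstream pipeline (FASTA, GFF3, Newick, states TSV, counts TSV and a
manifest) are written under scratch/cohort/.
"""

import sys
from collections import Counter
from pathlib import Path

import yaml

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from pheromat import seqio, synth  # noqa: E402

SEED = 2024
OUT = ROOT / "scratch" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = synth.gen_cohort(12, seed=SEED, state_split=(8, 2, 2), with_receptors=True)
    entries = []
    for g in cohort.genomes:
        seqio.write_fasta(g.contigs, OUT / f"{g.genome_id}.fna")
        seqio.write_gff3(g.genes, OUT / f"{g.genome_id}.gff")
        entries.append(
            {"id": g.genome_id, "fasta": f"{g.genome_id}.fna", "gff": f"{g.genome_id}.gff"}
        )
    seqio.write_fasta(synth.make_reference_proteins().values(), OUT / "references.faa")
    (OUT / "tree.nwk").write_text(cohort.newick)
    (OUT / "states.tsv").write_text(synth.states_tsv(cohort.states))
    synth.gen_count_table(SEED).to_csv(OUT / "counts.tsv", sep="\t", index=False)
    (OUT / "manifest.yaml").write_text(
        yaml.safe_dump(
            {
                "genomes": entries,
                "references": "references.faa",
                "tree": "tree.nwk",
                "states": "states.tsv",
                "counts": "counts.tsv",
            }
        )
    )
    counts = Counter(cohort.states.values())
    archs = Counter(cohort.truth["architectures"].values())
    print(f"wrote {len(entries)} genomes to {OUT}")
    print(f"planted states: {dict(counts)} (1=heterothallic, 0=homothallic, ?=unknown)")
    print(f"planted architectures: {dict(archs)}")
    print(f"shared mature repeat: {cohort.truth['shared_alpha_repeat']}")


if __name__ == "__main__":
    main()
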