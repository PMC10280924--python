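"""Reading a fixture/analysis bundle from disk.

A bundle directory holds the plain-text inputs every stage consumes:
``annotation.gff3``, ``circ_junctions.bed``, ``{mrna,mirna,circ}_counts.tsv``,
``design.tsv``, ``mirna.fasta``, ``targets.fasta`` and optionally
``terms.tsv``, ``truth.json`` and ``sample_sets.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotation import CircRNARecord, GenomeAnnotation, read_junctions_bed
from .expression import ExpressionMatrix
from .simulate import FixtureBundle, GroundTruth, SimulationConfig


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_bundle(bundle_dir: str) -> FixtureBundle:
    d = Path(bundle_dir)
    if (d / "config.json").exists():
        with open(d / "config.json") as fh:
            raw = json.load(fh)
        raw["groups"] = tuple(raw["groups"])
        raw["base_mean_log_range"] = tuple(raw["base_mean_log_range"])
        config = SimulationConfig(**raw)
    else:
        config = SimulationConfig()

    annotation = GenomeAnnotation.from_gff3(d / "annotation.gff3")
    circs = read_junctions_bed(d / "circ_junctions.bed")
    if (d / "sample_sets.json").exists():
        with open(d / "sample_sets.json") as fh:
            sets = json.load(fh)
        circs = [
            CircRNARecord(c.id, c.chrom, c.start, c.end, c.strand,
                          sample_ids=frozenset(sets.get(c.id, ())))
            for c in circs
        ]

    mats = {
        name: ExpressionMatrix.from_tsv(d / f"{name}_counts.tsv", d / "design.tsv")
        for name in ("mrna", "mirna", "circ")
    }
    mirna_seqs = read_fasta(d / "mirna.fasta")
    target_seqs = read_fasta(d / "targets.fasta")

    terms: list[tuple[str, str]] = []
    if (d / "terms.tsv").exists():
        tdf = pd.read_csv(d / "terms.tsv", sep="\t")
        terms = [tuple(r) for r in tdf[["feature", "term"]].itertuples(index=False)]

    if (d / "truth.json").exists():
        truth = GroundTruth.from_json(d / "truth.json")
    else:
        truth = GroundTruth([], {}, {}, {})

    return FixtureBundle(config, annotation, circs, truth,
                         mats["mrna"], mats["mirna"], mats["circ"],
                         mirna_seqs, target_seqs, terms)
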