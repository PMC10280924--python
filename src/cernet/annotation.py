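"""Genome annotation model, circRNA classification and summary statistics.

A circRNA is represented by its back-splice junction span on the genome
(BED-style 0-based half-open coordinates).  Classification against a gene
annotation assigns each record to exactly one of five genomic-origin
categories, evaluated in precedence order:

1. ``exonic`` — both junction ends coincide exactly with annotated exon
   boundaries of one same-strand transcript (the circle is a run of whole
   exons);
2. ``intronic`` — the span lies strictly inside a single intron of a
   same-strand transcript;
3. ``sense_overlapping`` — any other overlap with a same-strand gene;
4. ``antisense`` — overlap only with opposite-strand gene(s);
5. ``intergenic`` — no gene overlap at all.

The precedence resolves records that would otherwise satisfy several
definitions (e.g. a circle whose ends hit exon boundaries also overlaps its
host gene).  ``length`` throughout is the genomic span ``end - start``, not
the spliced length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

CATEGORIES = ("exonic", "intronic", "sense_overlapping", "antisense", "intergenic")


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # sorted, 0-based half-open

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


class GenomeAnnotation:
    """Gene/transcript/exon intervals indexed for strand-aware overlap queries."""

    def __init__(self, genes: Iterable[Gene], chrom_lengths: Mapping[str, int] | None = None):
        self.genes: dict[str, Gene] = {g.id: g for g in genes}
        self.chrom_lengths = dict(chrom_lengths or {})
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            self._trees.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g.id

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: (g.start, g.id))

    @classmethod
    def from_gff3(cls, path: str) -> "GenomeAnnotation":
        """Read a GFF3 file (gene / mRNA / exon features; 1-based closed coords)."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes: dict[str, Gene] = {}
        chrom_lengths: dict[str, int] = {}
        for line in open(path):
            if line.startswith("##sequence-region"):
                _, chrom, _one, length = line.split()
                chrom_lengths[chrom] = int(length)
        for gf in db.features_of_type("gene"):
            genes[gf.id] = Gene(gf.id, gf.seqid, gf.start - 1, gf.end, gf.strand)
        for tf in db.features_of_type("mRNA"):
            parent = db.parents(tf, featuretype="gene")
            gene = genes[next(parent).id]
            tr = Transcript(tf.id, gene.id, tf.seqid, tf.start - 1, tf.end, tf.strand)
            for ef in db.children(tf, featuretype="exon", order_by="start"):
                tr.exons.append((ef.start - 1, ef.end))
            gene.transcripts.append(tr)
        return cls(genes.values(), chrom_lengths)

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.chrom_lengths):
                fh.write(f"##sequence-region {chrom} 1 {self.chrom_lengths[chrom]}\n")
            for gid in sorted(self.genes):
                g = self.genes[gid]
                fh.write(
                    f"{g.chrom}\tcernet\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}\n"
                )
                for tr in g.transcripts:
                    fh.write(
                        f"{g.chrom}\tcernet\tmRNA\t{tr.start + 1}\t{tr.end}\t.\t{tr.strand}\t.\t"
                        f"ID={tr.id};Parent={g.id}\n"
                    )
                    for i, (es, ee) in enumerate(tr.exons, 1):
                        fh.write(
                            f"{g.chrom}\tcernet\texon\t{es + 1}\t{ee}\t.\t{tr.strand}\t.\t"
                            f"ID={tr.id}.exon{i};Parent={tr.id}\n"
                        )


@dataclass
class CircRNARecord:
    """One back-splice event: junction span, strand and (once classified) origin."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str
    category: str | None = None
    exon_count: int | None = None
    sample_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: invalid strand {self.strand!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"{self.id}: unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LengthStats:
    count: int
    total_length: int
    mean_length: float
    min_length: int
    max_length: int
    n50: int
    count_ge_200: int
    count_ge_500: int
    count_ge_1000: int


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_circrna(
    circ: CircRNARecord,
    annotation: GenomeAnnotation,
    boundary_slack: int = 0,
) -> tuple[str, int]:
    """Assign one of the five origin categories plus a same-strand exon count.

    ``exon_count`` is the number of exons of the best (largest-overlap)
    same-strand transcript that the span strictly overlaps; it is 0 for
    antisense and intergenic records.  Total function: unknown chromosomes
    classify as intergenic.
    """
    genes = annotation.overlapping_genes(circ.chrom, circ.start, circ.end)
    sense = [g for g in genes if g.strand == circ.strand]
    span = (circ.start, circ.end)

    def near(a: int, b: int) -> bool:
        return abs(a - b) <= boundary_slack

    exon_count = 0
    best_tr_overlap = -1
    for g in sense:
        for tr in g.transcripts:
            ov = _overlap_len(span, (tr.start, tr.end))
            if ov <= 0:
                continue
            n_ex = sum(1 for ex in tr.exons if _overlap_len(span, ex) > 0)
            if ov > best_tr_overlap:
                best_tr_overlap = ov
                exon_count = n_ex

    if sense:
        for g in sense:
            for tr in g.transcripts:
                starts = [ex[0] for ex in tr.exons]
                ends = [ex[1] for ex in tr.exons]
                if any(near(circ.start, s) for s in starts) and any(
                    near(circ.end, e) for e in ends
                ):
                    return "exonic", exon_count
        for g in sense:
            for tr in g.transcripts:
                for istart, iend in tr.introns:
                    if istart < circ.start and circ.end < iend:
                        return "intronic", 0
        return "sense_overlapping", exon_count
    if genes:
        return "antisense", 0
    return "intergenic", 0


def classify_all(
    circs: Sequence[CircRNARecord],
    annotation: GenomeAnnotation,
    boundary_slack: int = 0,
) -> list[CircRNARecord]:
    out = []
    for c in circs:
        cat, n_ex = classify_circrna(c, annotation, boundary_slack)
        out.append(
            CircRNARecord(c.id, c.chrom, c.start, c.end, c.strand, cat, n_ex, c.sample_ids)
        )
    return out


def category_proportions(circs: Sequence[CircRNARecord]) -> pd.DataFrame:
    """Per-category count and percentage (2 d.p.), count-descending."""
    for c in circs:
        if c.category is None:
            raise ValueError(f"unclassified record: {c.id}")
    counts = {cat: 0 for cat in CATEGORIES}
    for c in circs:
        counts[c.category] += 1
    return proportions_from_counts(counts)


def proportions_from_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    total = sum(counts.values())
    rows = [
        {"category": cat, "count": n, "percent": round(100.0 * n / total, 2)}
        for cat, n in counts.items()
        if n > 0
    ]
    rows.sort(key=lambda r: (-r["count"], r["category"]))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def summarize_lengths(circs: Sequence[CircRNARecord]) -> LengthStats:
    """Count / total / mean / min / max / N50 and >=200/500/1000 nt tallies.

    N50 by descending-length accumulation: the length of the record at which
    the running total first reaches half the summed length.
    """
    if not circs:
        raise ValueError("summarize_lengths: empty input")
    lengths = sorted((c.length for c in circs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for ln in lengths:
        acc += ln
        if 2 * acc >= total:
            n50 = ln
            break
    return LengthStats(
        count=len(lengths),
        total_length=total,
        mean_length=round(total / len(lengths), 2),
        min_length=lengths[-1],
        max_length=lengths[0],
        n50=n50,
        count_ge_200=sum(1 for x in lengths if x >= 200),
        count_ge_500=sum(1 for x in lengths if x >= 500),
        count_ge_1000=sum(1 for x in lengths if x >= 1000),
    )


def per_chromosome_counts(circs: Sequence[CircRNARecord]) -> list[tuple[str, int]]:
    """Chromosome -> record count, ordered count-descending then name."""
    counts: dict[str, int] = {}
    for c in circs:
        counts[c.chrom] = counts.get(c.chrom, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def unique_counts(
    per_sample_sets: Mapping[str, set[str] | frozenset[str]],
) -> dict[str, tuple[int, int]]:
    """Per sample: (number predicted, number predicted in that sample only)."""
    if not per_sample_sets:
        raise ValueError("unique_counts: no samples")
    seen_in: dict[str, int] = {}
    for ids in per_sample_sets.values():
        for i in ids:
            seen_in[i] = seen_in.get(i, 0) + 1
    return {
        s: (len(ids), sum(1 for i in ids if seen_in[i] == 1))
        for s, ids in per_sample_sets.items()
    }


def exon_count_histogram(circs: Sequence[CircRNARecord]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for c in circs:
        if c.exon_count is None:
            raise ValueError(f"unclassified record: {c.id}")
        hist[c.exon_count] = hist.get(c.exon_count, 0) + 1
    return dict(sorted(hist.items()))


def read_junctions_bed(path: str) -> list[CircRNARecord]:
    """Read back-splice junctions from BED6 (0-based half-open, strand col 6)."""
    recs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
            recs.append(CircRNARecord(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return recs


def write_junctions_bed(circs: Sequence[CircRNARecord], path: str) -> None:
    with open(path, "w") as fh:
        for c in circs:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t0\t{c.strand}\n")


def write_classified_tsv(circs: Sequence[CircRNARecord], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "id": c.id, "chrom": c.chrom, "start": c.start, "end": c.end,
                "strand": c.strand, "category": c.category,
                "exon_count": c.exon_count, "length": c.length,
            }
            for c in circs
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_stats_json(stats: LengthStats, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(stats.__dict__, fh, indent=1, sort_keys=True)
        fh.write("\n")
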