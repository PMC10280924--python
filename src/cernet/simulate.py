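"""Synthetic fixture bundles with planted ceRNA structure.

The generator emulates the data the pipeline is designed for: a two-breed
ovary study with three replicates per group, negative-binomial junction and
read counts, circRNAs of all five genomic-origin categories, and planted
sponge triplets (circRNA, miRNA, mRNA) in which

* the miRNA carries a differential-expression effect opposite in direction
  to both partners',
* per-sample miRNA activity ``a_s`` multiplies the mRNA mean by
  ``2^(-beta * a_s)`` (miRNA-mediated repression), and
* the circRNA attenuates that activity multiplicatively,
  ``a_s * 2^(-sponge_strength * c_s)`` with ``c_s`` the standardized
  circRNA level —

so that planted pairs show the correlation signs the screens look for
(miRNA-mRNA and miRNA-circRNA negative, circRNA-mRNA positive).  Sequences
carry seed-complement binding sites exactly at recorded positions, and are
rejection-sampled so no miRNA seed complement occurs anywhere else; this
makes plant-and-recover closure exact for the binding-site scanner.

Everything is driven by one root seed with fixed per-stage child streams,
so an identical config reproduces a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    CATEGORIES,
    CircRNARecord,
    Gene,
    GenomeAnnotation,
    Transcript,
    write_junctions_bed,
)
from .binding import reverse_complement
from .expression import ExpressionMatrix

_STREAMS = {"annotation": 1, "circrnas": 2, "expression": 3, "sequences": 4,
            "samples": 5, "terms": 6}

# Five-way genomic-origin mix observed in sheep ovary back-splice catalogs:
# sense-overlapping dominates when junction ends rarely coincide with
# annotated exon boundaries.
DEFAULT_CATEGORY_PROPORTIONS = {
    "sense_overlapping": 0.9081,
    "intergenic": 0.0360,
    "exonic": 0.0320,
    "antisense": 0.0153,
    "intronic": 0.0086,
}


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 60
    n_mirnas: int = 40
    n_circrnas: int = 80
    samples_per_group: int = 3
    groups: tuple[str, str] = ("X_LC", "D_LC")
    nb_dispersion: float = 0.05
    base_mean_log_range: tuple[float, float] = (6.0, 11.0)  # log2 of NB base mean
    repression_strength: float = 1.5   # beta: effect of miRNA activity on target mean
    sponge_strength: float = 0.5       # attenuation of miRNA activity by circRNA level
    n_planted_triplets: int = 20
    de_lfc: float = 3.0                # log2 group effect for planted DE features
    mirna_length: int = 22
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    n_decoy_de_per_class: int = 4      # DE features outside any planted triplet
    target_length: int = 600           # mean circRNA/mRNA sequence length, nt
    sites_per_pair: int = 2            # MREs planted per (miRNA, target) pair
    three_prime_frac: float = 0.5      # fraction of 3' extension positions paired
    chromosome_length: int | None = None  # fixed length; error if genes do not fit

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_genes", "n_mirnas", "n_circrnas",
                     "n_planted_triplets", "mirna_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.repression_strength < 0 or self.sponge_strength < 0:
            raise ValueError("effect strengths must be non-negative")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"category proportions sum to {total}, not 1")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if self.n_planted_triplets > min(self.n_mirnas, self.n_genes, self.n_circrnas):
            raise ValueError("n_planted_triplets exceeds available features")
        if self.mirna_length < 8:
            raise ValueError("mirna_length must be >= 8")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups for i in range(self.samples_per_group)]

    @property
    def design(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g in self.groups for i in range(self.samples_per_group)}


@dataclass
class GroundTruth:
    planted_triplets: list[tuple[str, str, str]]  # (circ, miRNA, mRNA)
    planted_categories: dict[str, str]
    planted_de: dict[str, str]  # feature -> up/down (group1 over group2)
    planted_sites: dict[tuple[str, str], list[int]]  # (miRNA, target) -> positions

    def to_json(self, path: str) -> None:
        obj = {
            "planted_triplets": [list(t) for t in self.planted_triplets],
            "planted_categories": self.planted_categories,
            "planted_de": self.planted_de,
            "planted_sites": {f"{m}|{t}": v for (m, t), v in self.planted_sites.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            planted_triplets=[tuple(t) for t in obj["planted_triplets"]],
            planted_categories=obj["planted_categories"],
            planted_de=obj["planted_de"],
            planted_sites={
                tuple(k.split("|", 1)): v for k, v in obj["planted_sites"].items()
            },
        )


@dataclass
class FixtureBundle:
    config: SimulationConfig
    annotation: GenomeAnnotation
    circrnas: list[CircRNARecord]
    truth: GroundTruth
    mrna_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    circ_counts: ExpressionMatrix
    mirna_seqs: dict[str, str]
    target_seqs: dict[str, str]
    term_mapping: list[tuple[str, str]]  # (feature, term)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


# ---------------------------------------------------------------- annotation

def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Non-overlapping genes, one transcript each, 1-18 sorted exons."""
    rng = _rng(config, "annotation")
    genes: list[Gene] = []
    chrom_lengths: dict[str, int] = {}
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    gidx = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 1000
        for _ in range(per_chrom[ci]):
            gidx += 1
            pos += int(rng.integers(500, 2001))  # inter-gene gap
            n_exons = int(rng.integers(1, 19))
            exon_lens = rng.integers(80, 301, n_exons)
            intron_lens = rng.integers(100, 1001, max(n_exons - 1, 0))
            exons = []
            cursor = pos
            for k in range(n_exons):
                exons.append((cursor, cursor + int(exon_lens[k])))
                cursor = exons[-1][1]
                if k < n_exons - 1:
                    cursor += int(intron_lens[k])
            # guarantee both strands appear once there are >= 2 genes
            if gidx == 1:
                strand = "+"
            elif gidx == 2:
                strand = "-"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{gidx:04d}"
            tr = Transcript(f"{gid}.t1", gid, chrom, pos, exons[-1][1], strand, exons)
            genes.append(Gene(gid, chrom, pos, exons[-1][1], strand, [tr]))
            pos = exons[-1][1]
        chrom_lengths[chrom] = pos + 2000
        if config.chromosome_length is not None:
            if pos + 2000 > config.chromosome_length:
                raise GenerationError(
                    f"{chrom}: {per_chrom[ci]} genes need {pos + 2000} nt, "
                    f"chromosome_length is {config.chromosome_length}"
                )
            chrom_lengths[chrom] = config.chromosome_length
    return GenomeAnnotation(genes, chrom_lengths)


# ----------------------------------------------------------------- circRNAs

def _category_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_circrnas over the proportions."""
    props = config.category_proportions
    raw = {c: props.get(c, 0.0) * config.n_circrnas for c in CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_circrnas - sum(counts.values())
    for c in sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    return counts


def generate_circrnas(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[CircRNARecord], dict[str, str]]:
    """Plant circRNAs constructed to satisfy their assigned category definition."""
    rng = rng if rng is not None else _rng(config, "circrnas")
    if not annotation.genes:
        raise GenerationError("empty annotation")
    genes = [annotation.genes[g] for g in sorted(annotation.genes)]
    transcripts = [tr for g in genes for tr in g.transcripts]
    multi_exon = [tr for tr in transcripts if len(tr.exons) >= 2]

    # intergenic room: gaps between consecutive genes per chromosome + margins
    gaps: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in sorted(by_chrom.items()):
        glist = sorted(glist, key=lambda g: g.start)
        if glist[0].start > 200:
            gaps.append((chrom, 100, glist[0].start - 50))
        for a, b in zip(glist, glist[1:]):
            if b.start - a.end > 150:
                gaps.append((chrom, a.end + 50, b.start - 50))
        clen = annotation.chrom_lengths.get(chrom, glist[-1].end + 2000)
        if clen - glist[-1].end > 200:
            gaps.append((chrom, glist[-1].end + 50, clen - 100))

    counts = _category_counts(config)
    categories = [c for c in CATEGORIES for _ in range(counts[c])]
    categories = [categories[i] for i in rng.permutation(len(categories))]

    records: list[CircRNARecord] = []
    truth: dict[str, str] = {}
    for idx, cat in enumerate(categories, 1):
        cid = f"circRNA_{idx:04d}"
        if cat == "exonic":
            tr = transcripts[int(rng.integers(len(transcripts)))]
            i = int(rng.integers(len(tr.exons)))
            j = int(rng.integers(i, len(tr.exons)))
            rec = CircRNARecord(cid, tr.chrom, tr.exons[i][0], tr.exons[j][1], tr.strand)
        elif cat == "intronic":
            if not multi_exon:
                raise GenerationError("intronic requested but no multi-exon transcript")
            tr = multi_exon[int(rng.integers(len(multi_exon)))]
            istart, iend = tr.introns[int(rng.integers(len(tr.introns)))]
            lo, hi = istart + 1, iend - 1  # strictly inside
            ln = int(rng.integers(30, max(31, min(hi - lo, 400) + 1)))
            start = lo + int(rng.integers(0, hi - lo - ln + 1))
            rec = CircRNARecord(cid, tr.chrom, start, start + ln, tr.strand)
        elif cat == "sense_overlapping":
            tr = transcripts[int(rng.integers(len(transcripts)))]
            ex0 = tr.exons[0]
            delta = int(rng.integers(1, ex0[1] - ex0[0]))  # inside exon 1, off-boundary
            rec = CircRNARecord(cid, tr.chrom, ex0[0] + delta, tr.end, tr.strand)
        elif cat == "antisense":
            g = genes[int(rng.integers(len(genes)))]
            ln = int(rng.integers(60, max(61, min(g.end - g.start, 1200) + 1)))
            start = g.start + int(rng.integers(0, g.end - g.start - ln + 1))
            rec = CircRNARecord(cid, g.chrom, start, start + ln,
                                "-" if g.strand == "+" else "+")
        elif cat == "intergenic":
            usable = [gp for gp in gaps if gp[2] - gp[1] >= 80]
            if not usable:
                raise GenerationError("intergenic requested but no inter-gene room")
            chrom, lo, hi = usable[int(rng.integers(len(usable)))]
            ln = int(rng.integers(60, min(hi - lo, 1500) + 1))
            start = lo + int(rng.integers(0, hi - lo - ln + 1))
            rec = CircRNARecord(cid, chrom, start, start + ln,
                                "+" if rng.random() < 0.5 else "-")
        else:  # pragma: no cover
            raise GenerationError(f"category unattainable: {cat}")
        records.append(rec)
        truth[cid] = cat

    # per-sample detection sets (for the unique/non-unique summary)
    srng = _rng(config, "samples")
    samples = config.sample_ids
    out = []
    for rec in records:
        present = [s for s in samples if srng.random() < 0.7]
        if not present:
            present = [samples[int(srng.integers(len(samples)))]]
        out.append(CircRNARecord(rec.id, rec.chrom, rec.start, rec.end, rec.strand,
                                 sample_ids=frozenset(present)))
    return out, truth


# --------------------------------------------------------------- expression

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial: var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def plant_truth(
    config: SimulationConfig,
    circ_ids: list[str],
    mrna_ids: list[str],
    truth_categories: dict[str, str],
) -> GroundTruth:
    """Choose planted triplets (distinct members per class), DE directions and
    binding-site positions. Positions are resolved later against drawn lengths;
    here only the triplet/DE structure is fixed."""
    rng = _rng(config, "expression")
    mirna_ids = [f"miR_{i + 1:03d}" for i in range(config.n_mirnas)]
    k = config.n_planted_triplets
    circ_sel = [circ_ids[i] for i in rng.choice(len(circ_ids), k, replace=False)]
    mir_sel = [mirna_ids[i] for i in rng.choice(len(mirna_ids), k, replace=False)]
    mrna_sel = [mrna_ids[i] for i in rng.choice(len(mrna_ids), k, replace=False)]
    triplets = list(zip(circ_sel, mir_sel, mrna_sel))

    planted_de: dict[str, str] = {}
    for c, m, g in triplets:
        mdir = "up" if rng.random() < 0.5 else "down"
        odir = "down" if mdir == "up" else "up"
        planted_de[m] = mdir
        planted_de[c] = odir
        planted_de[g] = odir
    # decoy DE features outside any triplet exercise the downstream screens
    for pool in (circ_ids, mirna_ids, mrna_ids):
        free = [f for f in pool if f not in planted_de]
        n = min(config.n_decoy_de_per_class, len(free))
        for i in rng.choice(len(free), n, replace=False):
            planted_de[free[i]] = "up" if rng.random() < 0.5 else "down"

    return GroundTruth(triplets, dict(truth_categories), planted_de, {})


def generate_expression(
    truth: GroundTruth,
    config: SimulationConfig,
    annotation_gene_ids: list[str],
    circ_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Negative-binomial count matrices (mRNA, miRNA, circRNA) with the
    planted sponge structure; library sizes vary by +/-20%."""
    rng = rng if rng is not None else np.random.default_rng(
        [config.seed, _STREAMS["expression"], 7]
    )
    samples = config.sample_ids
    design = config.design
    n_s = len(samples)
    group1 = config.groups[0]
    gvec = np.array([1.0 if design[s] == group1 else -1.0 for s in samples])
    mirna_ids = [f"miR_{i + 1:03d}" for i in range(config.n_mirnas)]

    def base_means(ids: list[str]) -> np.ndarray:
        lo, hi = config.base_mean_log_range
        return 2.0 ** rng.uniform(lo, hi, len(ids))

    # planted triplet mRNAs get their group effect through the repression
    # mechanism itself (miRNA DE -> activity shift -> target shift), so they
    # carry no direct shift — a direct one would compound to extreme fold
    # changes that drive counts to zero.
    mechanism_driven = {g for _, _, g in truth.planted_triplets}

    def group_shift(ids: list[str]) -> np.ndarray:
        shift = np.zeros((len(ids), n_s))
        for i, fid in enumerate(ids):
            if fid in mechanism_driven:
                continue
            d = truth.planted_de.get(fid)
            if d == "up":
                shift[i] = +0.5 * config.de_lfc * gvec
            elif d == "down":
                shift[i] = -0.5 * config.de_lfc * gvec
        return shift

    def libfactors() -> np.ndarray:
        return rng.uniform(0.8, 1.2, n_s)

    # miRNAs first.  Per-sample activity is the standardized *latent*
    # log-mean (the biological signal the counts are drawn around), so the
    # repression a planted target experiences is not double-counted with the
    # miRNA's own measurement noise; the observed miRNA counts track the
    # same latent signal, which is what makes the screened correlations
    # negative.
    mi_mu = base_means(mirna_ids)[:, None] * 2.0 ** group_shift(mirna_ids)
    mi_counts = _nb_draw(rng, mi_mu * libfactors()[None, :], config.nb_dispersion)
    activity = {m: _standardize(np.log2(mi_mu[i])) for i, m in enumerate(mirna_ids)}

    # circRNAs next: independent NB draws; standardized level feeds the sponge
    circ_mu = base_means(circ_ids)[:, None] * 2.0 ** group_shift(circ_ids)
    circ_counts = _nb_draw(rng, circ_mu * libfactors()[None, :], config.nb_dispersion)
    circ_level = {
        c: _standardize(np.log2(circ_counts[i] + 1.0)) for i, c in enumerate(circ_ids)
    }

    # mRNAs last: planted targets are repressed by sponge-attenuated activity
    sponge_of = {g: (c, m) for c, m, g in truth.planted_triplets}
    mrna_mu = base_means(annotation_gene_ids)[:, None] * 2.0 ** group_shift(annotation_gene_ids)
    for i, gid in enumerate(annotation_gene_ids):
        if gid in sponge_of:
            c, m = sponge_of[gid]
            eff = activity[m] * 2.0 ** (-config.sponge_strength * circ_level[c])
            mrna_mu[i] = mrna_mu[i] * 2.0 ** (-config.repression_strength * eff)
    mrna_counts = _nb_draw(rng, mrna_mu * libfactors()[None, :], config.nb_dispersion)

    def as_matrix(ids: list[str], counts: np.ndarray) -> ExpressionMatrix:
        df = pd.DataFrame(counts, index=ids, columns=samples, dtype=float)
        return ExpressionMatrix(df, dict(design))

    return (
        as_matrix(annotation_gene_ids, mrna_counts),
        as_matrix(mirna_ids, mi_counts),
        as_matrix(circ_ids, circ_counts),
    )


# ---------------------------------------------------------------- sequences

_BASES = np.array(list("ACGU"))
_PAIRS = {"A": {"U"}, "U": {"A", "G"}, "G": {"C", "U"}, "C": {"G"}}  # WC + wobble


def _draw_mirnas(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """miRNA sequences with mutually distinct seeds; no miRNA's seed occurs as a
    substring of another's 5' pairing region (positions 2..8+E), which keeps
    planted site content free of foreign seed complements."""
    E = round(config.three_prime_frac * (config.mirna_length - 8))
    region_end = 1 + 7 + E
    mirna_ids = [f"miR_{i + 1:03d}" for i in range(config.n_mirnas)]
    seqs: dict[str, str] = {}
    for mid in mirna_ids:
        for _ in range(1000):
            cand = "".join(rng.choice(_BASES, config.mirna_length))
            seed = cand[1:8]
            region = cand[1:region_end]
            # overlap-aware: the seed must occur in the pairing region exactly
            # once, at its canonical place (str.count misses overlapping hits)
            occ = [i for i in range(len(region) - 6) if region[i:i + 7] == seed]
            if occ != [0]:
                continue
            ok = True
            for other in seqs.values():
                if other[1:8] in region or seed in other[1:region_end]:
                    ok = False
                    break
            if ok:
                seqs[mid] = cand
                break
        else:
            raise GenerationError(f"could not draw a compatible sequence for {mid}")
    return seqs


def plant_binding_sites(
    truth: GroundTruth,
    config: SimulationConfig,
    circ_ids: list[str],
    mrna_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """miRNA and target FASTA content with MREs planted at recorded positions.

    Each planted (miRNA, target) pair receives ``sites_per_pair``
    non-overlapping sites: the seed complement plus a contiguous 3'
    complementary extension covering ``three_prime_frac`` of the remaining
    miRNA positions.  The base 5' of each site is forced to be non-pairing so
    the scanner's extension terminates exactly at the planted boundary, and
    everywhere outside planted sites every miRNA seed complement is rejected.
    Updates ``truth.planted_sites`` in place.
    """
    rng = rng if rng is not None else _rng(config, "sequences")
    mirna_seqs = _draw_mirnas(config, rng)
    E = round(config.three_prime_frac * (config.mirna_length - 8))
    site_len = 7 + E
    seed_rc = {reverse_complement(s[1:8]): mid for mid, s in mirna_seqs.items()}

    pair_plan: dict[str, list[str]] = {}  # target -> miRNAs to plant
    for c, m, g in truth.planted_triplets:
        pair_plan.setdefault(c, []).append(m)
        pair_plan.setdefault(g, []).append(m)

    target_seqs: dict[str, str] = {}
    truth.planted_sites = {}
    for tid in sorted(set(circ_ids) | set(mrna_ids)):
        tlen = int(rng.integers(round(0.8 * config.target_length),
                                round(1.2 * config.target_length) + 1))
        seq = rng.choice(_BASES, tlen)
        planted: list[tuple[int, str]] = []  # (position, miRNA)
        designated: set[int] = set()
        protected = np.zeros(tlen, dtype=bool)
        flank_ban: dict[int, str] = {}  # position -> miRNA base it must not pair
        for m in pair_plan.get(tid, []):
            n_sites = config.sites_per_pair
            block = tlen // n_sites
            if block < site_len + 2:
                raise GenerationError(
                    f"{tid}: target too short for {n_sites} sites of {site_len} nt"
                )
            mi = mirna_seqs[m]
            content = reverse_complement(mi[1:1 + site_len])
            for b in range(n_sites):
                # keep >= 1 nt of unprotected sequence between consecutive
                # sites so one site's extension can never run into another
                lo = b * block + 1
                hi = min((b + 1) * block, tlen) - site_len - 1
                p = int(rng.integers(lo, hi + 1))
                seq[p:p + site_len] = list(content)
                protected[p:p + site_len] = True
                if p > 0 and E < config.mirna_length - 8:
                    flank_ban[p - 1] = mi[8 + E]  # next unpaired miRNA base
                planted.append((p, m))
                designated.add(p + E)
            truth.planted_sites[(m, tid)] = sorted(
                p for p, mm in planted if mm == m
            )

        def redraw(pos: int) -> None:
            if protected[pos]:
                return
            if pos in flank_ban:
                allowed = [b for b in "ACGU" if b not in _PAIRS[flank_ban[pos]]]
                seq[pos] = allowed[int(rng.integers(len(allowed)))]
            else:
                seq[pos] = _BASES[int(rng.integers(4))]

        for pos in sorted(flank_ban):
            redraw(pos)

        # rejection pass: no seed complement outside the designated matches
        for _ in range(200):
            s = "".join(seq)
            bad = [
                q for q in range(tlen - 6)
                if s[q:q + 7] in seed_rc and q not in designated
            ]
            if not bad:
                break
            for q in bad:
                for pos in range(q, q + 7):
                    redraw(pos)
        else:
            raise GenerationError(f"{tid}: could not sanitize sequence")
        target_seqs[tid] = "".join(seq)
    return mirna_seqs, target_seqs


# --------------------------------------------------------------------- terms

def generate_terms(
    config: SimulationConfig, mrna_ids: list[str], n_terms: int = 16
) -> list[tuple[str, str]]:
    """Random (feature, term) annotation over the mRNAs for enrichment runs."""
    rng = _rng(config, "terms")
    mapping = []
    namespaces = ["BP", "CC", "MF", "pathway"]
    for t in range(n_terms):
        size = int(rng.integers(5, max(6, len(mrna_ids) // 3)))
        members = rng.choice(len(mrna_ids), min(size, len(mrna_ids)), replace=False)
        term = f"TERM:{namespaces[t % 4]}:{t + 1:04d}"
        for i in sorted(members):
            mapping.append((mrna_ids[int(i)], term))
    return mapping


# -------------------------------------------------------------------- bundle

def simulate_bundle(config: SimulationConfig) -> FixtureBundle:
    annotation = generate_annotation(config)
    circs, categories = generate_circrnas(annotation, config)
    circ_ids = [c.id for c in circs]
    mrna_ids = sorted(annotation.genes)
    truth = plant_truth(config, circ_ids, mrna_ids, categories)
    mrna_m, mirna_m, circ_m = generate_expression(truth, config, mrna_ids, circ_ids)
    mirna_seqs, target_seqs = plant_binding_sites(truth, config, circ_ids, mrna_ids)
    terms = generate_terms(config, mrna_ids)
    return FixtureBundle(config, annotation, circs, truth,
                         mrna_m, mirna_m, circ_m, mirna_seqs, target_seqs, terms)


def _write_fasta(seqs: dict[str, str], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seqs[k]), id=k, description="") for k in sorted(seqs)]
    SeqIO.write(records, path, "fasta")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(bundle: FixtureBundle, out_dir: str) -> dict[str, str]:
    """Emit the bundle files plus a checksum manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.annotation.to_gff3(out / "annotation.gff3")
    write_junctions_bed(bundle.circrnas, out / "circ_junctions.bed")
    bundle.mrna_counts.to_tsv(out / "mrna_counts.tsv")
    bundle.mirna_counts.to_tsv(out / "mirna_counts.tsv")
    bundle.circ_counts.to_tsv(out / "circ_counts.tsv")
    design = bundle.config.design
    pd.DataFrame(
        {"sample": list(design), "group": [design[s] for s in design]}
    ).to_csv(out / "design.tsv", sep="\t", index=False)
    _write_fasta(bundle.mirna_seqs, out / "mirna.fasta")
    _write_fasta(bundle.target_seqs, out / "targets.fasta")
    pd.DataFrame(bundle.term_mapping, columns=["feature", "term"]).to_csv(
        out / "terms.tsv", sep="\t", index=False
    )
    bundle.truth.to_json(out / "truth.json")
    with open(out / "sample_sets.json", "w") as fh:
        json.dump(
            {c.id: sorted(c.sample_ids) for c in bundle.circrnas},
            fh, indent=0, sort_keys=True,
        )
        fh.write("\n")
    with open(out / "config.json", "w") as fh:
        cfg = asdict(bundle.config)
        cfg["groups"] = list(cfg["groups"])
        cfg["base_mean_log_range"] = list(cfg["base_mean_log_range"])
        json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")

    names = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {n: _sha256(out / n) for n in names}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
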