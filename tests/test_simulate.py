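"""Synthetic-bundle generation: determinism, planted-structure closure and
the induced correlation signs."""

import numpy as np
import pytest

from cernet.annotation import classify_all, classify_circrna
from cernet.correlation import pearson_r
from cernet.expression import normalize
from cernet.simulate import (
    GenerationError,
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    generate_circrnas,
    generate_expression,
    plant_truth,
    simulate_bundle,
    write_fixture_bundle,
)


class TestConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(samples_per_group=1)
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(category_proportions={"exonic": 0.7})
        with pytest.raises(ValueError):
            SimulationConfig(n_planted_triplets=999)


class TestAnnotationGeneration:
    def test_degenerate_single_gene(self):
        cfg = SimulationConfig(seed=0, n_chromosomes=1, n_genes=1,
                               n_circrnas=1, n_mirnas=1, n_planted_triplets=1)
        ann = generate_annotation(cfg)
        (gene,) = ann.genes.values()
        tr = gene.transcripts[0]
        if len(tr.exons) == 1:
            assert (tr.start, tr.end) == tr.exons[0]
        assert tr.start == gene.start and tr.end == gene.end

    def test_genes_nonoverlapping_brute_force(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=2, n_genes=50)
        ann = generate_annotation(cfg)
        assert len(ann.genes) == 50
        by_chrom = {}
        for g in ann.genes.values():
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            for i, a in enumerate(spans):
                for b in spans[i + 1:]:
                    assert a[1] <= b[0] or b[1] <= a[0]

    def test_exons_sorted_within_gene_bounds(self):
        ann = generate_annotation(SimulationConfig(seed=6))
        strands = set()
        for g in ann.genes.values():
            strands.add(g.strand)
            tr = g.transcripts[0]
            assert 1 <= len(tr.exons) <= 18
            assert tr.exons == sorted(tr.exons)
            for (s1, e1), (s2, e2) in zip(tr.exons, tr.exons[1:]):
                assert e1 <= s2
            assert tr.exons[0][0] == g.start and tr.exons[-1][1] == g.end
        assert strands == {"+", "-"}

    def test_deterministic_gff3(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        a = tmp_path / "a.gff3"
        b = tmp_path / "b.gff3"
        generate_annotation(cfg).to_gff3(a)
        generate_annotation(cfg).to_gff3(b)
        assert a.read_bytes() == b.read_bytes()

    def test_packing_error(self):
        with pytest.raises(GenerationError, match="chromosome_length"):
            generate_annotation(SimulationConfig(seed=0, chromosome_length=5000))


class TestCircRNAGeneration:
    def test_all_intergenic_proportions(self):
        cfg = SimulationConfig(seed=2, category_proportions={"intergenic": 1.0})
        ann = generate_annotation(cfg)
        circs, truth = generate_circrnas(ann, cfg)
        assert set(truth.values()) == {"intergenic"}
        for c in circs:
            assert ann.overlapping_genes(c.chrom, c.start, c.end) == []

    def test_exonic_boundaries_coincide(self):
        cfg = SimulationConfig(seed=2, category_proportions={"exonic": 1.0})
        ann = generate_annotation(cfg)
        circs, _ = generate_circrnas(ann, cfg)
        for c in circs:
            cat, _ = classify_circrna(c, ann)
            assert cat == "exonic"

    def test_classifier_recovers_all_categories(self):
        cfg = SimulationConfig(seed=2)
        ann = generate_annotation(cfg)
        circs, truth = generate_circrnas(ann, cfg)
        classified = classify_all(circs, ann)
        assert all(c.category == truth[c.id] for c in classified)
        assert set(truth.values()) == {
            "exonic", "intronic", "sense_overlapping", "antisense", "intergenic"
        }

    def test_unattainable_category_named(self):
        # single-exon genes only: no introns to put an intronic circle in
        cfg = SimulationConfig(seed=2, category_proportions={"intronic": 1.0})
        ann = generate_annotation(cfg)
        multi = [g for g in ann.genes.values()
                 if len(g.transcripts[0].exons) >= 2]
        for g in multi:  # strip introns from the annotation
            tr = g.transcripts[0]
            tr.exons = [(tr.start, tr.end)]
        with pytest.raises(GenerationError, match="intronic"):
            generate_circrnas(ann, cfg)


def _small_expression(seed, **overrides):
    cfg = SimulationConfig(seed=seed, n_chromosomes=1, n_genes=12, n_mirnas=8,
                           n_circrnas=12, n_planted_triplets=5,
                           n_decoy_de_per_class=0, **overrides)
    ann = generate_annotation(cfg)
    circs, cats = generate_circrnas(ann, cfg)
    circ_ids = [c.id for c in circs]
    mrna_ids = sorted(ann.genes)
    truth = plant_truth(cfg, circ_ids, mrna_ids, cats)
    mats = generate_expression(truth, cfg, mrna_ids, circ_ids)
    return truth, mats


def _planted_r(truth, mats):
    mrna, mirna, _ = mats
    mrna_l = np.log2(normalize(mrna, "CPM").values + 1)
    mirna_l = np.log2(normalize(mirna, "CPM").values + 1)
    out = []
    for _, m, g in truth.planted_triplets:
        try:
            out.append(pearson_r(mirna_l.loc[m].values, mrna_l.loc[g].values))
        except ZeroDivisionError:
            pass
    return out


class TestExpressionGeneration:
    def test_null_effects_give_null_correlations(self):
        """With repression off, planted miRNA-mRNA pairs correlate no better
        than chance: at n = 6 the exact null expectation of |r| is 3/8
        (density proportional to 1 - r^2), so the Monte-Carlo mean over 200
        seeds must sit at 0.375, far below any screening threshold."""
        rs = []
        for seed in range(200):
            truth, mats = _small_expression(
                seed, repression_strength=0.0, sponge_strength=0.0, de_lfc=0.0
            )
            rs.extend(abs(r) for r in _planted_r(truth, mats))
        assert np.mean(rs) == pytest.approx(3 / 8, abs=0.05)

    def test_strong_repression_gives_strong_negative_r(self):
        """beta = 2, dispersion 0.05: > 90% of planted miRNA-mRNA pairs show
        r <= -0.8 at n = 6 (Monte Carlo over 50 seeds)."""
        rs = []
        for seed in range(50):
            truth, mats = _small_expression(
                seed, repression_strength=2.0, nb_dispersion=0.05
            )
            rs.extend(_planted_r(truth, mats))
        assert np.mean([r <= -0.8 for r in rs]) > 0.9

    def test_triplet_de_directions_opposed(self, default_bundle):
        t = default_bundle.truth
        for c, m, g in t.planted_triplets:
            assert t.planted_de[m] != t.planted_de[c]
            assert t.planted_de[c] == t.planted_de[g]

    def test_zero_count_row_roundtrips(self, tmp_path):
        import pandas as pd

        from cernet.expression import ExpressionMatrix

        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["z", "f"],
                          columns=["s1", "s2"])
        m = ExpressionMatrix(df, {"s1": "A", "s2": "B"})
        p = tmp_path / "c.tsv"
        m.to_tsv(p)
        back = pd.read_csv(p, sep="\t", index_col=0)
        assert (back.loc["z"] == 0).all()
        assert back.astype(float).equals(m.values)


class TestBundle:
    def test_bundle_files_and_checksums(self, tmp_path):
        b = simulate_bundle(SimulationConfig(seed=12))
        manifest = write_fixture_bundle(b, tmp_path / "out")
        expected = {
            "annotation.gff3", "circ_junctions.bed", "mrna_counts.tsv",
            "mirna_counts.tsv", "circ_counts.tsv", "design.tsv",
            "mirna.fasta", "targets.fasta", "truth.json", "terms.tsv",
            "sample_sets.json", "config.json",
        }
        assert set(manifest) == expected
        import hashlib
        for name, digest in manifest.items():
            data = (tmp_path / "out" / name).read_bytes()
            assert hashlib.sha256(data).hexdigest() == digest

    def test_same_seed_identical_bundles(self, tmp_path):
        cfg = SimulationConfig(seed=12)
        m1 = write_fixture_bundle(simulate_bundle(cfg), tmp_path / "a")
        m2 = write_fixture_bundle(simulate_bundle(cfg), tmp_path / "b")
        assert m1 == m2
        m3 = write_fixture_bundle(simulate_bundle(SimulationConfig(seed=13)),
                                  tmp_path / "c")
        assert m1 != m3

    def test_truth_json_roundtrip(self, tmp_path, default_bundle):
        p = tmp_path / "truth.json"
        default_bundle.truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back == default_bundle.truth

    def test_truth_ids_exist_in_bundle(self, default_bundle):
        b = default_bundle
        circ_ids = {c.id for c in b.circrnas}
        mrna_ids = set(b.mrna_counts.feature_ids)
        mirna_ids = set(b.mirna_counts.feature_ids)
        for c, m, g in b.truth.planted_triplets:
            assert c in circ_ids and m in mirna_ids and g in mrna_ids
        for (m, t) in b.truth.planted_sites:
            assert m in b.mirna_seqs and t in b.target_seqs
        assert set(b.truth.planted_categories) == circ_ids
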