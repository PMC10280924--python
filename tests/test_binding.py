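"""Seed-and-extend MRE scanner, per-pair aggregation and pair-table I/O."""

import numpy as np
import pytest

from cernet import reference_data_path
from cernet.binding import (
    BindingSite,
    ScanParams,
    aggregate_pair,
    read_pair_table,
    reverse_complement,
    scan_targets,
)
from cernet.simulate import SimulationConfig, simulate_bundle

MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt


class TestScanner:
    def test_no_seed_complement_no_sites(self):
        target = "A" * 50  # seed complement of MIRNA contains C/U
        assert scan_targets(MIRNA, target) == []

    def test_full_complement_site(self):
        """A target carrying the exact reverse complement of the whole 22-nt
        miRNA at offset 7: one site, position 7, 14 WC extension pairs."""
        target = "GCUAGCU" + reverse_complement(MIRNA) + "GCAU"
        sites = scan_targets(MIRNA, target)
        assert len(sites) == 1
        s = sites[0]
        assert s.position == 7
        assert s.score == pytest.approx(40 + 5 * 14)
        assert s.energy == pytest.approx(-(7.0 + 0.45 * 14))

    def test_seed_only_site(self):
        # seed complement with a non-pairing base 5' of it: no extension
        seed_rc = reverse_complement(MIRNA[1:8])
        nonpair = "C"  # miRNA position 9 is "U"; C neither WC- nor GU-pairs U
        target = "AAAA" + nonpair + seed_rc + "AAAA"
        sites = scan_targets(MIRNA, target)
        assert len(sites) == 1
        assert sites[0].position == 5
        assert sites[0].score == pytest.approx(40.0)
        assert sites[0].energy == pytest.approx(-7.0)

    def test_gu_wobble_scores_between(self):
        seed_rc = reverse_complement(MIRNA[1:8])
        # miRNA position 9 is U (index 8): G makes a G:U wobble, then stop
        target = "AAAC" + "G" + seed_rc + "AAAA"
        sites = scan_targets(MIRNA, target)
        assert len(sites) == 1
        assert sites[0].score == pytest.approx(42.0)
        assert sites[0].energy == pytest.approx(-7.2)

    def test_dna_input_accepted(self):
        target = ("GCTAGCT" + reverse_complement(MIRNA) + "GCAT").replace("U", "T")
        sites = scan_targets(MIRNA.replace("U", "T"), target)
        assert len(sites) == 1 and sites[0].position == 7

    def test_invalid_symbol_named(self):
        with pytest.raises(ValueError, match="'N'"):
            scan_targets(MIRNA, "ACGUN")

    def test_deterministic_ordered_nonoverlapping(self):
        """On random sequences the scanner is deterministic, reports sites in
        position order, and resolves overlaps (no two site regions intersect)."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGU"))
        seed_rc = reverse_complement(MIRNA[1:8])
        for _ in range(20):
            # seed the target with tandem/overlapping complements to stress
            # the greedy overlap resolution
            target = (
                "".join(rng.choice(bases, 60)) + seed_rc + seed_rc
                + "".join(rng.choice(bases, 40)) + seed_rc
                + "".join(rng.choice(bases, 30))
            )
            first = scan_targets(MIRNA, target)
            again = scan_targets(MIRNA, target)
            assert [(s.position, s.score) for s in first] == [
                (s.position, s.score) for s in again
            ]
            positions = [s.position for s in first]
            assert positions == sorted(positions)
            regions = [(s.position, s.seed_start + 7) for s in first]
            for (a1, b1), (a2, b2) in zip(regions, regions[1:]):
                assert b1 <= a2

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            scan_targets("ACGUACG", "ACGU" * 10)

    def test_planted_sites_recovered_exactly(self, default_bundle):
        """Every planted (miRNA, target) pair yields MREs at exactly the
        recorded positions — plant-and-recover closure."""
        b = default_bundle
        for (mid, tid), positions in b.truth.planted_sites.items():
            sites = scan_targets(b.mirna_seqs[mid], b.target_seqs[tid])
            assert [s.position for s in sites] == sorted(positions), (mid, tid)

    def test_unplanted_pairs_have_no_sites(self, default_bundle):
        """Sequence sanitization removes every off-target seed complement."""
        b = default_bundle
        planted = set(b.truth.planted_sites)
        checked = 0
        for mid in sorted(b.mirna_seqs)[:8]:
            for tid in sorted(b.target_seqs)[:20]:
                if (mid, tid) in planted:
                    continue
                assert scan_targets(b.mirna_seqs[mid], b.target_seqs[tid]) == []
                checked += 1
        assert checked > 100


class TestAggregate:
    def test_single_site(self):
        s = BindingSite("m", "t", 10, 55.0, -9.0)
        agg = aggregate_pair([s], 500)
        assert agg.total_score == agg.max_score == 55.0
        assert agg.total_energy == agg.max_energy == -9.0
        assert agg.mre_count == 1 and agg.positions == [10]

    def test_totals_and_maxima(self):
        sites = [BindingSite("m", "t", 10, 10.0, -2.0),
                 BindingSite("m", "t", 40, 20.0, -5.0)]
        agg = aggregate_pair(sites, 500)
        assert (agg.total_score, agg.max_score) == (30.0, 20.0)
        assert agg.total_energy == pytest.approx(-7.0)
        assert agg.max_energy == -5.0  # energy of the max-score site

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(1, 8))
            sites = [
                BindingSite("m", "t", int(p), float(s), float(-e))
                for p, s, e in zip(rng.integers(0, 400, n),
                                   rng.uniform(40, 160, n),
                                   rng.uniform(5, 30, n))
            ]
            agg = aggregate_pair(sites, 500)
            assert agg.total_score == pytest.approx(sum(s.score for s in sites))
            assert agg.total_energy == pytest.approx(sum(s.energy for s in sites))
            assert agg.max_score == max(s.score for s in sites)
            assert agg.total_score >= agg.max_score

    def test_mixed_pairs_rejected(self):
        sites = [BindingSite("m1", "t", 0, 50.0, -8.0),
                 BindingSite("m2", "t", 30, 50.0, -8.0)]
        with pytest.raises(ValueError, match="mixed"):
            aggregate_pair(sites, 100)


class TestPairTable:
    def test_reference_table_set_statistics(self):
        """The shipped 12-row published table parses into 12 summaries over
        9 distinct circRNAs and 8 distinct miRNAs."""
        rows = read_pair_table(reference_data_path("reference_pair_table.tsv"))
        assert len(rows) == 12
        assert len({r.target_id for r in rows}) == 9
        assert len({r.mirna_id for r in rows}) == 8

    def test_single_site_rows_have_total_equal_max(self):
        rows = read_pair_table(reference_data_path("reference_pair_table.tsv"))
        for r in rows:
            if r.mre_count == 1:
                assert r.total_score == r.max_score
                assert r.total_energy == r.max_energy

    def test_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(
            "mirna_id\ttarget_id\ttotal_score\ttotal_energy\tmax_score\t"
            "max_energy\ttarget_length\tpositions\tmre_count\n"
        )
        assert read_pair_table(p) == []

    def test_invariant_violation_skipped(self, tmp_path, caplog):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "mirna_id\ttarget_id\ttotal_score\ttotal_energy\tmax_score\t"
            "max_energy\ttarget_length\tpositions\tmre_count\n"
            "m\tt\t100\t-10\t100\t-10\t500\t5 10\t1\n"  # mre != |positions|
            "m\tt2\t100\t-10\t100\t-10\t500\t5\t1\n"
        )
        rows = read_pair_table(p)
        assert [r.target_id for r in rows] == ["t2"]

    def test_roundtrip_through_writer(self, tmp_path, default_bundle):
        from cernet.binding import scan_pairs, write_pair_table

        b = default_bundle
        pairs = sorted(b.truth.planted_sites)[:6]
        out = scan_pairs(b.mirna_seqs, b.target_seqs, pairs)
        path = tmp_path / "pairs.tsv"
        write_pair_table(out, path)
        back = read_pair_table(path)
        assert [(r.mirna_id, r.target_id, r.positions, r.mre_count) for r in back] \
            == [(r.mirna_id, r.target_id, r.positions, r.mre_count) for r in out]
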