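import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from panploid import pav, simulate
from panploid.containers import (
    ABSENT,
    MISSING,
    PRESENT,
    GeneModel,
    LineageDesign,
    PavTable,
)
from panploid.errors import ParameterError
from panploid.intervals import GenomicInterval


def make_table(rows, genotypes, samples):
    records = pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "svtype", "svlen"]
    )
    geno = pd.DataFrame(
        genotypes, columns=samples, index=pd.Index(records["id"], name="id"),
        dtype=np.int8,
    )
    return PavTable(records, geno)


class TestMergePavs:
    def test_identical_records_merge(self):
        t1 = make_table([("d1", "chr1", 100, 200, "DEL", 100)], [[PRESENT]], ["s1"])
        t2 = make_table([("d2", "chr1", 100, 200, "DEL", 100)], [[PRESENT]], ["s2"])
        merged = pav.merge_pavs([t1, t2])
        assert len(merged) == 1
        assert merged.records.iloc[0]["id"] == "d1"  # first-seen coordinates
        assert merged.genotypes.iloc[0].tolist() == [PRESENT, PRESENT]

    def test_distant_records_stay_separate(self):
        t1 = make_table([("d1", "chr1", 100, 200, "DEL", 100)], [[PRESENT]], ["s1"])
        t2 = make_table([("d2", "chr1", 2100, 2200, "DEL", 100)], [[PRESENT]], ["s2"])
        assert len(pav.merge_pavs([t1, t2], pos_tol_bp=1000)) == 2

    def test_size_ratio_blocks_merge(self):
        t1 = make_table([("d1", "chr1", 100, 200, "DEL", 100)], [[PRESENT]], ["s1"])
        t2 = make_table([("d2", "chr1", 100, 160, "DEL", 60)], [[PRESENT]], ["s2"])
        assert len(pav.merge_pavs([t1, t2], size_ratio=0.8)) == 2
        assert len(pav.merge_pavs([t1, t2], size_ratio=0.5)) == 1

    def test_svtype_must_match(self):
        t1 = make_table([("d1", "chr1", 100, 200, "DEL", 100)], [[PRESENT]], ["s1"])
        t2 = make_table([("i1", "chr1", 100, 101, "INS", 100)], [[PRESENT]], ["s2"])
        assert len(pav.merge_pavs([t1, t2])) == 2

    def test_genotype_dominance(self):
        # present dominates absent dominates missing in the union
        t1 = make_table([("d1", "chr1", 100, 200, "DEL", 100)],
                        [[ABSENT, MISSING]], ["s1", "s2"])
        t2 = make_table([("d2", "chr1", 100, 200, "DEL", 100)],
                        [[PRESENT, ABSENT]], ["s1", "s2"])
        merged = pav.merge_pavs([t1, t2])
        assert merged.genotypes.iloc[0].tolist() == [PRESENT, ABSENT]

    def test_idempotent(self):
        table, _ = simulate.make_pav_matrix(
            200, ["A1", "A2"], ["B1", "B2"], 0.3, 0.05, seed=1
        )
        once = pav.merge_pavs([table])
        twice = pav.merge_pavs([once])
        pd.testing.assert_frame_equal(once.records, twice.records)
        pd.testing.assert_frame_equal(once.genotypes, twice.genotypes)


class TestFilterPavs:
    def test_missingness_filter(self):
        t = make_table(
            [("p1", "chr1", 0, 100, "DEL", 100)],
            [[MISSING, MISSING, MISSING, PRESENT, ABSENT]],
            list("abcde"),
        )
        assert len(pav.filter_pavs(t, max_missing=0.5)) == 0
        assert len(pav.filter_pavs(t, max_missing=0.6)) == 1

    def test_monomorphic_dropped_with_minor_freq(self):
        t = make_table(
            [("p1", "chr1", 0, 100, "DEL", 100)],
            [[PRESENT, PRESENT, PRESENT]],
            list("abc"),
        )
        assert len(pav.filter_pavs(t, min_minor_freq=0.05)) == 0

    def test_permissive_filters_are_identity(self):
        table, _ = simulate.make_pav_matrix(
            100, ["A1", "A2"], ["B1", "B2"], 0.3, 0.1, seed=2
        )
        kept = pav.filter_pavs(table, max_missing=1.0, min_minor_freq=0.0)
        assert len(kept) == len(table)


class TestLineageDifferentiated:
    design = LineageDesign(("A1", "A2"), ("B1", "B2"))

    def make(self, genoA, genoB):
        return make_table(
            [("p1", "chr1", 0, 100, "DEL", 100)],
            [genoA + genoB],
            ["A1", "A2", "B1", "B2"],
        )

    def test_fixed_difference_reported(self):
        t = self.make([PRESENT, PRESENT], [ABSENT, ABSENT])
        assert len(pav.lineage_differentiated(t, self.design)) == 1

    def test_equal_frequencies_not_reported(self):
        t = self.make([PRESENT, ABSENT], [PRESENT, ABSENT])
        assert len(pav.lineage_differentiated(t, self.design)) == 0

    def test_threshold_boundary_inclusive(self):
        # freq_A=1, freq_B=0.2 with min_freq_diff=0.8 -> reported
        t = make_table(
            [("p1", "chr1", 0, 100, "DEL", 100)],
            [[PRESENT] * 5 + [PRESENT] + [ABSENT] * 4],
            [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        )
        design = LineageDesign(
            tuple(f"A{i}" for i in range(5)), tuple(f"B{i}" for i in range(5))
        )
        assert len(pav.lineage_differentiated(t, design, 0.8)) == 1
        assert len(pav.lineage_differentiated(t, design, 0.81)) == 0

    def test_all_missing_lineage_skipped(self, caplog):
        t = self.make([MISSING, MISSING], [ABSENT, ABSENT])
        with caplog.at_level("WARNING", logger="panploid"):
            hits = pav.lineage_differentiated(t, self.design)
        assert len(hits) == 0
        assert any("missing" in m for m in caplog.messages)

    def test_recovers_simulated_truth_exactly(self):
        table, truth = simulate.make_pav_matrix(
            3000, ["A1", "A2", "A3"], ["B1", "B2", "B3"], 0.259, 0.0, seed=4
        )
        design = LineageDesign(("A1", "A2", "A3"), ("B1", "B2", "B3"))
        hits = pav.lineage_differentiated(table, design, 1.0)
        assert set(hits.records["id"]) == truth.differentiated_pavs

    def test_null_simulation_reports_nothing(self):
        table, _ = simulate.make_pav_matrix(
            10_000,
            [f"A{i}" for i in range(5)],
            [f"B{i}" for i in range(5)],
            0.0, 0.0, seed=5,
        )
        design = LineageDesign(
            tuple(f"A{i}" for i in range(5)), tuple(f"B{i}" for i in range(5))
        )
        hits = pav.lineage_differentiated(table, design, 1.0)
        assert len(hits) / len(table) <= 0.01


class TestAnnotate:
    gene = GeneModel("g1", GenomicInterval("chr1", 5000, 8000, "+"))

    def pav_at(self, start, end):
        return make_table(
            [("p1", "chr1", start, end, "DEL", end - start)], [[PRESENT]], ["s1"]
        )

    @pytest.mark.parametrize(
        "start,end,hit",
        [(3500, 3580, True), (2500, 2580, False), (7990, 8100, True),
         (9990, 10_050, True), (10_000, 10_080, False)],
        ids=["upstream-in-flank", "upstream-outside", "spans-gene-end",
             "downstream-in-flank", "downstream-boundary-out"],
    )
    def test_two_kb_flank(self, start, end, hit):
        assoc = pav.annotate_pavs_to_genes(self.pav_at(start, end), [self.gene], 2000)
        assert len(assoc) == (1 if hit else 0)

    def test_negative_flank_rejected(self):
        with pytest.raises(ParameterError):
            pav.annotate_pavs_to_genes(self.pav_at(0, 100), [self.gene], -1)

    def test_association_listed_once(self):
        genes = [self.gene, GeneModel("g2", GenomicInterval("chr1", 6000, 7000))]
        assoc = pav.annotate_pavs_to_genes(self.pav_at(5500, 6500), genes, 2000)
        assert sorted(assoc["gene_id"]) == ["g1", "g2"]
        assert not assoc.duplicated(["gene_id", "pav_id"]).any()


class TestPermutationTest:
    universe = {f"g{i}" for i in range(6)}

    def test_deg_equals_universe_gives_p_one(self):
        obs, null_mean, p = pav.deg_overlap_permutation(
            {"g0", "g1", "g2"}, self.universe, self.universe, n_perm=99, seed=0
        )
        assert obs == 3
        assert null_mean == pytest.approx(3.0)
        assert p == 1.0

    def test_null_distribution_is_hypergeometric(self):
        # target=deg={g0,g1,g2} in a 6-gene universe: overlap of a uniform
        # draw of 3 is Hypergeom(6,3,3); brute-force expectation 1.5 and
        # P(overlap=3)=1/20
        obs, null_mean, p = pav.deg_overlap_permutation(
            {"g0", "g1", "g2"}, {"g0", "g1", "g2"}, self.universe,
            n_perm=4000, seed=1,
        )
        assert obs == 3
        assert null_mean == pytest.approx(hypergeom(6, 3, 3).mean(), abs=0.1)
        assert p == pytest.approx(1 / 20, abs=0.015)

    def test_p_always_in_valid_range(self):
        rng = np.random.default_rng(2)
        uni = sorted(self.universe)
        for _ in range(20):
            target = set(rng.choice(uni, 3, replace=False))
            deg = set(rng.choice(uni, 2, replace=False))
            _, _, p = pav.deg_overlap_permutation(
                target, deg, self.universe, n_perm=50, seed=int(rng.integers(1e6))
            )
            assert 1 / 51 <= p <= 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            pav.deg_overlap_permutation(set(), set(), set(), 10, 0)

    def test_enriched_overlap_detected(self):
        universe = {f"g{i}" for i in range(1000)}
        target = {f"g{i}" for i in range(100)}
        deg = {f"g{i}" for i in range(50, 200)}
        _, null_mean, p = pav.deg_overlap_permutation(
            target, deg, universe, n_perm=999, seed=3
        )
        assert p == pytest.approx(1 / 1000)
        assert null_mean < 20
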