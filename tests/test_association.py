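"""Gene-element association, variance-ratio tests, and hypergeometric ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import f_sf_numeric, hypergeom_sf_exact
from te_reguscan.association import (
    associate_genes,
    flag_elements,
    ora_hypergeometric,
    promoters_from_tss,
    significance_marker,
    stratified_responsiveness,
    variance_ratio_test,
)


def _elements(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df["te_derived"] = [r[3].startswith("te") for r in rows]
    df["te_age_category"] = "none"
    return df


class TestAssociateGenes:
    def test_promoter_and_element_endpoints_link(self):
        promoters = pd.DataFrame(
            [("g1", "chr1", 1000, 3000)], columns=["gene", "chrom", "start", "end"]
        )
        elements = _elements([("chr1", 50_000, 50_500, "te_peak")])
        links = pd.DataFrame(
            [("chr1", 1000, 3000, "chr1", 50_100, 50_200, "g1")],
            columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "gene"],
        )
        out = associate_genes(links, elements, promoters)
        assert len(out) == 1
        assert bool(out.iloc[0]["te_derived"])

    def test_swapped_endpoints_also_link(self):
        promoters = pd.DataFrame(
            [("g1", "chr1", 1000, 3000)], columns=["gene", "chrom", "start", "end"]
        )
        elements = _elements([("chr1", 50_000, 50_500, "te_peak")])
        links = pd.DataFrame(
            [("chr1", 50_100, 50_200, "chr1", 1500, 2500, "g1")],
            columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "gene"],
        )
        assert len(associate_genes(links, elements, promoters)) == 1

    def test_no_links_empty_map(self):
        promoters = pd.DataFrame(
            [("g1", "chr1", 0, 100)], columns=["gene", "chrom", "start", "end"]
        )
        links = pd.DataFrame(
            columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "gene"]
        )
        out = associate_genes(links, _elements([("chr1", 10, 20, "te_x")]), promoters)
        assert len(out) == 0

    def test_gene_without_promoter_skipped(self, caplog):
        promoters = pd.DataFrame(
            [("g1", "chr1", 0, 100)], columns=["gene", "chrom", "start", "end"]
        )
        links = pd.DataFrame(
            [("chr1", 0, 50, "chr1", 10, 20, "gX")],
            columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "gene"],
        )
        out = associate_genes(links, _elements([("chr1", 10, 20, "te_x")]), promoters)
        assert len(out) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        promoters = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "chrom": "chr1",
                "start": rng.integers(0, 9000, 10),
            }
        )
        promoters["end"] = promoters["start"] + 500
        el_starts = rng.integers(0, 9000, 15)
        elements = _elements(
            [("chr1", int(s), int(s) + 400, f"te_e{i}") for i, s in enumerate(el_starts)]
        )
        a_starts = rng.integers(0, 9000, 30)
        b_starts = rng.integers(0, 9000, 30)
        links = pd.DataFrame(
            {
                "chromA": "chr1", "startA": a_starts, "endA": a_starts + 300,
                "chromB": "chr1", "startB": b_starts, "endB": b_starts + 300,
                "gene": [f"g{rng.integers(0, 10)}" for _ in range(30)],
            }
        )
        got = associate_genes(links, elements, promoters)
        got_set = set(zip(got["gene"], got["element_index"]))

        def ov(s1, e1, s2, e2):
            return min(e1, e2) - max(s1, s2) >= 1

        expected = set()
        for _, ln in links.iterrows():
            p = promoters.set_index("gene").loc[ln["gene"]]
            for ei, el in elements.iterrows():
                for pe, de in (
                    ((ln["startA"], ln["endA"]), (ln["startB"], ln["endB"])),
                    ((ln["startB"], ln["endB"]), (ln["startA"], ln["endA"])),
                ):
                    if ov(*pe, p["start"], p["end"]) and ov(*de, el["start"], el["end"]):
                        expected.add((ln["gene"], ei))
        assert got_set == expected

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(77)
        promoters = pd.DataFrame(
            {"gene": ["g1", "g2"], "chrom": "chr1", "start": [100, 5000]}
        )
        promoters["end"] = promoters["start"] + 500
        elements = _elements([("chr1", 2000, 2400, "te_a"), ("chr1", 8000, 8300, "b")])
        links = pd.DataFrame(
            {
                "chromA": "chr1", "startA": [150, 5100], "endA": [250, 5200],
                "chromB": "chr1", "startB": [2100, 8100], "endB": [2200, 8200],
                "gene": ["g1", "g2"],
            }
        )
        a = associate_genes(links, elements, promoters)
        b = associate_genes(links.iloc[::-1].reset_index(drop=True), elements, promoters)
        pd.testing.assert_frame_equal(
            a.sort_values(["gene"]).reset_index(drop=True),
            b.sort_values(["gene"]).reset_index(drop=True),
        )


class TestFlags:
    def test_primate_wins_over_ancient(self):
        peaks = pd.DataFrame([("chr1", 0, 100, "p")], columns=["chrom", "start", "end", "name"])
        pairs = pd.DataFrame(
            {"peak_index": [0, 0], "peak_name": "p",
             "family": ["A", "B"], "te_class": "DNA",
             "age_class": ["Eutheria", "Primates"], "copy_id": ["c1", "c2"],
             "overlap_bp": [10, 10]},
        )
        out = flag_elements(peaks, pairs)
        assert out.loc[0, "te_age_category"] == "primate_specific"

    def test_promoters_from_tss_default_flank(self):
        tss = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "pos": [500]})
        out = promoters_from_tss(tss)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 1500)


class TestVarianceRatio:
    def test_worked_example_f_twenty(self):
        res = variance_ratio_test([-2, -1, 1, 2], [-0.5, 0, 0, 0.5])
        assert res.F == pytest.approx(20.0)
        assert res.df == (3, 3)

    def test_identity_gives_f_one_p_one(self):
        res = variance_ratio_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.F == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 2, 30), rng.normal(0, 1, 25)
        r1 = variance_ratio_test(a, b)
        r2 = variance_ratio_test(b, a)
        assert r1.F == pytest.approx(1 / r2.F)
        assert r1.p == pytest.approx(r2.p)

    def test_p_matches_f_distribution_integration(self):
        res = variance_ratio_test([-2, -1, 1, 2], [-0.5, 0, 0, 0.5])
        sf = f_sf_numeric(res.F, 3, 3)
        assert res.p == pytest.approx(2 * sf, abs=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            a, b = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
            if variance_ratio_test(a, b).p <= 0.05:
                rejections += 1
        assert abs(rejections / n_sims - 0.05) < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            variance_ratio_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            variance_ratio_test([1.0, 2.0], [3.0, 3.0])


class TestStratified:
    def test_identical_sets_give_f_one(self):
        de = pd.DataFrame({"gene": [f"g{i}" for i in range(8)],
                           "log2FC": [1, -1, 2, -2, 1, -1, 2, -2]})
        flags = pd.Series([True] * 4 + [False] * 4, index=de["gene"])
        strata = pd.Series(["s"] * 8, index=de["gene"])
        out = stratified_responsiveness(de, flags, strata)
        assert out.iloc[0]["F"] == pytest.approx(1.0)

    def test_planted_ratio_recovered(self):
        rng = np.random.default_rng(3)
        n = 200
        genes = [f"g{i}" for i in range(2 * n)]
        fc = np.concatenate([rng.normal(0, 2, n), rng.normal(0, 1, n)])
        de = pd.DataFrame({"gene": genes, "log2FC": fc})
        flags = pd.Series([True] * n + [False] * n, index=genes)
        strata = pd.Series(["s"] * 2 * n, index=genes)
        out = stratified_responsiveness(de, flags, strata)
        assert 3.2 <= out.iloc[0]["F"] <= 5.0

    def test_small_cells_reported_missing(self):
        de = pd.DataFrame({"gene": ["a", "b", "c"], "log2FC": [1.0, 2.0, 3.0]})
        flags = pd.Series([True, False, False], index=de["gene"])
        strata = pd.Series(["s"] * 3, index=de["gene"])
        out = stratified_responsiveness(de, flags, strata)
        assert np.isnan(out.iloc[0]["F"])

    def test_markers_at_study_thresholds(self):
        assert significance_marker(0.5) == ""
        assert significance_marker(0.005) == "*"
        assert significance_marker(5e-7) == "**"


class TestORA:
    def test_full_background_ratio_exactly_one(self):
        bg = {f"g{i}" for i in range(50)}
        out = ora_hypergeometric(bg, bg, {"pw": set(list(bg)[:10])})
        assert out.iloc[0]["ratio"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_exact_tail_example(self):
        bg = {f"g{i}" for i in range(100)}
        pw = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(5, 15)}  # overlap {g5..g9} = 5
        out = ora_hypergeometric(hits, bg, {"pw": pw})
        assert out.iloc[0]["k"] == 5
        assert out.iloc[0]["ratio"] == pytest.approx(5.0)
        assert out.iloc[0]["p"] == pytest.approx(
            hypergeom_sf_exact(5, 100, 10, 10), abs=1e-12
        )

    def test_null_hits_calibrated(self):
        rng = np.random.default_rng(4)
        bg = [f"g{i}" for i in range(400)]
        pathways = {
            f"pw{j}": set(rng.choice(bg, size=40, replace=False)) for j in range(60)
        }
        sig = 0
        n_sims = 50
        for _ in range(n_sims):
            hits = set(rng.choice(bg, size=40, replace=False))
            out = ora_hypergeometric(hits, set(bg), pathways)
            sig += (out["p"] <= 0.05).sum() / len(pathways)
        # hypergeometric tail at discrete k: rejection rate <= alpha
        assert sig / n_sims <= 0.07

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora_hypergeometric({"x"}, {"a"}, {})
        with pytest.raises(ValueError, match="background"):
            ora_hypergeometric(set(), set(), {})
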