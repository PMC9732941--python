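"""Synthetic-data generators: planted structure, invariants, determinism."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from te_reguscan.io import (
    read_bedpe,
    write_bedpe,
    write_te_bed,
)
from te_reguscan.annotation import merge_fragmented_copies, overlap_peaks_tes
from te_reguscan.phylo import parse_tree
from te_reguscan.sim import (
    DESpec,
    ExpressionSpec,
    PeakSpec,
    ReporterSpec,
    SimConfig,
    TEFamilySpec,
    gen_de_table,
    gen_expression_phylo,
    gen_peaks,
    gen_promoters,
    gen_reg_links,
    gen_reporter_plates,
    gen_te_annotation,
)


class TestTEAnnotation:
    def test_unfragmented_family_direct_construction(self):
        cfg = SimConfig(
            genome_chrom_sizes={"chr1": 10_000},
            te_family_specs=[TEFamilySpec("TOYDNA1", "DNA", "Eutheria", 10, 100, 0.0)],
            seed=1,
        )
        tes = gen_te_annotation(cfg)
        assert len(tes) == 10
        total = (tes["end"] - tes["start"]).sum()
        assert 700 <= total <= 1400  # ~10 x 100 bp with length jitter
        assert (tes["age_class"] == "Eutheria").all()

    def test_forced_fragmentation_split_records(self):
        cfg = SimConfig(
            genome_chrom_sizes={"chr1": 10_000},
            te_family_specs=[TEFamilySpec("F", "LTR", "Primates", 1, 200, 1.0)],
            seed=2,
        )
        tes = gen_te_annotation(cfg)
        assert len(tes) >= 2
        assert tes["copy_id"].nunique() == 1
        a, b = tes.sort_values("start").itertuples(index=False), None
        rows = tes.sort_values("start").to_numpy()
        assert rows[0][2] <= rows[1][1]  # disjoint, ordered
        gap = rows[1][1] - rows[0][2]
        assert 0 < gap <= cfg.max_fragment_gap

    def test_fragments_restored_by_merge(self):
        cfg = SimConfig(
            genome_chrom_sizes={"chr1": 50_000},
            te_family_specs=[TEFamilySpec("F", "LTR", "Primates", 30, 300, 1.0)],
            seed=3,
        )
        tes = gen_te_annotation(cfg)
        merged = merge_fragmented_copies(tes, max_gap=cfg.max_fragment_gap)
        assert len(merged) == 30

    def test_determinism_byte_identical(self):
        cfg = SimConfig(seed=7)
        out1, out2 = io.StringIO(), io.StringIO()
        write_te_bed(gen_te_annotation(cfg), out1)
        write_te_bed(gen_te_annotation(SimConfig(seed=7)), out2)
        assert out1.getvalue() == out2.getvalue()

    def test_capacity_error(self):
        cfg_kwargs = dict(
            genome_chrom_sizes={"chr1": 10_000},
            te_family_specs=[TEFamilySpec("F", "DNA", "Eutheria", 100, 95, 0.0)],
        )
        with pytest.raises(ValueError, match="90%"):
            gen_te_annotation(SimConfig(**cfg_kwargs))


class TestPeaks:
    def test_uniform_placement_ratio_calibrated(self):
        # with all multipliers 1, observed/expected overlap ratio ~ 1
        cfg = SimConfig(
            genome_chrom_sizes={"chr1": 200_000},
            te_family_specs=[TEFamilySpec("F", "DNA", "Eutheria", 50, 300, 0.0)],
            peak_spec=PeakSpec(n_peaks=300, mean_length=200),
            seed=5,
        )
        tes = gen_te_annotation(cfg)
        # Monte-Carlo oracle: expected TE-hitting count under uniform starts
        ts, te_ = tes["start"].to_numpy(), tes["end"].to_numpy()
        rng = np.random.default_rng(99)

        def mc_expected(lengths, reps=200):
            hits = 0
            for _ in range(reps):
                s = rng.integers(0, 200_000 - lengths + 1)
                e = s + lengths
                hits += ((s[:, None] < te_[None, :]) & (e[:, None] > ts[None, :])).any(1).sum()
            return hits / reps

        ratios = []
        for stream in range(40):
            peaks = gen_peaks(cfg, tes, stream=stream)
            obs = overlap_peaks_tes(peaks, tes).n_peaks_with_te
            exp = mc_expected((peaks["end"] - peaks["start"]).to_numpy(), reps=50)
            ratios.append(obs / exp)
        assert 0.95 <= np.mean(ratios) <= 1.05

    def test_planted_multiplier_three_on_ten_percent_family(self):
        cfg = SimConfig(
            genome_chrom_sizes={"chr1": 1_000_000},
            te_family_specs=[TEFamilySpec("F", "LTR", "Primates", 100, 1000, 0.0)],
            peak_spec=PeakSpec(n_peaks=400, mean_length=60,
                               per_family_enrichment_multiplier={"F": 3.0}),
            seed=6,
        )
        tes = gen_te_annotation(cfg)
        q = (tes["end"] - tes["start"]).sum() / 1_000_000  # ~0.1
        peaks = gen_peaks(cfg, tes)
        frac = overlap_peaks_tes(peaks, tes).n_peaks_with_te / 400
        target = min(1.0, 3.0 * ((tes["end"] - tes["start"]).sum() + len(tes) * 59)
                     / 1_000_000)
        lo, hi = stats.binom.interval(0.999, 400, target)
        assert lo / 400 <= frac <= hi / 400
        assert frac > 2 * q  # clearly above the uniform baseline

    def test_zero_peaks_empty_frame(self):
        cfg = SimConfig(peak_spec=PeakSpec(n_peaks=0))
        tes = gen_te_annotation(cfg)
        assert len(gen_peaks(cfg, tes)) == 0


class TestExpressionPhylo:
    def test_no_events_root_expressed_all_tips_expressed(self):
        cfg = SimConfig(
            expression_spec=ExpressionSpec(
                n_genes=300, gain_rate=0.0, loss_rate=0.0, root_expressed_prob=1.0
            ),
            seed=8,
        )
        tpm, events, states = gen_expression_phylo(cfg)
        assert len(events) == 0
        assert (states == 1).all().all()
        # binarization error rate = P(lognormal_expressed < 2)
        es = cfg.expression_spec
        p_err = stats.norm.cdf(
            (np.log(2) - es.expressed_TPM_logmean) / es.TPM_logsd
        )
        frac_below = (tpm.to_numpy() < 2).mean()
        n = tpm.size
        assert abs(frac_below - p_err) < 3 * np.sqrt(p_err * (1 - p_err) / n) + 1e-3

    def test_planted_gain_confined_to_clade(self):
        cfg = SimConfig(
            tree_newick="(((A:1,B:1):1,C:1):1,(O1:1,O2:1):1);",
            expression_spec=ExpressionSpec(
                n_genes=500, gain_rate=0.03, loss_rate=0.0, root_expressed_prob=0.0
            ),
            seed=9,
        )
        tree = parse_tree(cfg.tree_newick)
        tpm, events, states = gen_expression_phylo(cfg)
        idx = tree.label_index()
        for _, ev in events.iterrows():
            clade = tree.clade_tips(idx[ev["branch"]])
            g = ev["gene"]
            # expressed tips are exactly within the event clade (single gain)
            expressed = set(states.columns[states.loc[g] == 1])
            assert expressed <= tree.clade_tips(idx[ev["branch"]]) or len(
                events[events["gene"] == g]
            ) > 1

    def test_same_seed_identical_matrix(self):
        cfg = SimConfig(seed=10, expression_spec=ExpressionSpec(n_genes=50))
        a, _, _ = gen_expression_phylo(cfg)
        b, _, _ = gen_expression_phylo(SimConfig(seed=10, expression_spec=ExpressionSpec(n_genes=50)))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_tips_rejected(self):
        cfg_kwargs = dict(tree_newick="(A:1,B:1);")
        with pytest.raises(ValueError, match="tip"):
            gen_expression_phylo(SimConfig(**cfg_kwargs))


class TestLinksAndDE:
    def _setup(self, fraction, seed=12):
        from te_reguscan.sim import LinkSpec

        cfg = SimConfig(seed=seed)
        cfg.link_spec = LinkSpec(te_linked_fraction=fraction)
        tes = gen_te_annotation(cfg)
        peaks = gen_peaks(cfg, tes)
        ov = overlap_peaks_tes(peaks, tes)
        mask = np.zeros(len(peaks), dtype=bool)
        mask[ov.pairs["peak_index"].unique()] = True
        promoters = gen_promoters(cfg, [f"g{i}" for i in range(100)])
        links, truth = gen_reg_links(cfg, peaks, promoters, mask)
        return cfg, peaks, promoters, links, truth, mask

    def test_fraction_zero_no_te_links(self):
        *_, truth, _ = self._setup(0.0)
        assert not truth.any()

    def test_fraction_one_all_te_links(self):
        *_, truth, _ = self._setup(1.0)
        assert truth.all()

    def test_bedpe_round_trip(self, tmp_path):
        _, _, _, links, _, _ = self._setup(0.5)
        p = tmp_path / "links.bedpe"
        write_bedpe(links, p)
        back = read_bedpe(p)
        pd.testing.assert_frame_equal(links.reset_index(drop=True), back)

    def test_de_table_variance_ratio_planted(self):
        cfg = SimConfig(seed=13, de_spec=DESpec(variance_ratio_planted=4.0,
                                                n_genes_per_set=400))
        te = [f"t{i}" for i in range(400)]
        ot = [f"o{i}" for i in range(400)]
        de = gen_de_table(cfg, te, ot)
        v_te = de.set_index("gene").loc[te, "log2FC"].var()
        v_ot = de.set_index("gene").loc[ot, "log2FC"].var()
        assert 2.5 < v_te / v_ot < 6.0

    def test_de_rejects_overlapping_or_empty_sets(self):
        cfg = SimConfig(seed=14)
        with pytest.raises(ValueError, match="disjoint"):
            gen_de_table(cfg, ["a"], ["a", "b"])
        with pytest.raises(ValueError, match="nonempty"):
            gen_de_table(cfg, [], ["b"])

    def test_negative_variance_ratio_rejected(self):
        with pytest.raises(ValueError, match="variance_ratio"):
            SimConfig(de_spec=DESpec(variance_ratio_planted=-1))


class TestReporterPlates:
    def test_composition_and_controls_present(self):
        cfg = SimConfig(seed=15)
        wells, truth = gen_reporter_plates(cfg)
        assert {"Basic_minP", "TAP2_C"} <= set(wells["construct"])
        n = cfg.reporter_spec.n_constructs
        assert (truth["effect_class"] == "repressor").sum() == round(0.6 * n)
        per_group = wells.groupby(["construct", "cell_type", "treatment"]).size()
        assert (per_group == cfg.reporter_spec.n_replicates).all()

    def test_tsa_restores_derepressed_constructs(self):
        cfg = SimConfig(
            seed=16,
            reporter_spec=ReporterSpec(n_constructs=30, tsa_derepression_prob=1.0,
                                       noise_sd=0.0),
        )
        wells, truth = gen_reporter_plates(cfg)
        ratios = wells.assign(r=wells["firefly"] / wells["renilla"])
        for _, row in truth[truth["effect_class"] == "repressor"].iterrows():
            sub = ratios[(ratios["construct"] == row["construct"])
                         & (ratios["cell_type"] == "ESF")]
            r_none = sub[sub["treatment"] == "none"]["r"].mean()
            r_tsa = sub[sub["treatment"] == "TSA"]["r"].mean()
            assert r_none == pytest.approx(0.3 * cfg.reporter_spec.baseline_ratio)
            assert r_tsa == pytest.approx(cfg.reporter_spec.baseline_ratio)

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError, match="n_replicates"):
            SimConfig(reporter_spec=ReporterSpec(n_replicates=1))

    def test_same_seed_identical_csv(self):
        from te_reguscan.io import write_plates

        a, b = io.StringIO(), io.StringIO()
        write_plates(gen_reporter_plates(SimConfig(seed=17))[0], a)
        write_plates(gen_reporter_plates(SimConfig(seed=17))[0], b)
        assert a.getvalue() == b.getvalue()

    def test_effect_fraction_overflow_rejected(self):
        with pytest.raises(ValueError, match="frac_repressor"):
            SimConfig(reporter_spec=ReporterSpec(frac_repressor=0.7, frac_enhancer=0.5))
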