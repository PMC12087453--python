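import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylseed.diffmeth import moderated_ttest, probes_in_dmrs
from methylseed.preprocess import beta_to_m
from methylseed.simulate import (
    ISLAND_PROBS,
    SimulationConfig,
    generate_annotation,
    generate_cohort,
    generate_dmr_track,
    generate_expression,
    generate_external_cohort,
    generate_pathways,
)


class TestAnnotation:
    def test_schema_and_categories(self):
        ann = generate_annotation(10, 2, seed=1)
        assert ann.shape[0] == 10
        assert set(ann.columns) >= {"chrom", "pos", "gene", "region", "island"}
        allowed = {"TSS200", "TSS1500", "5'UTR", "Body", "3'UTR", "intergenic"}
        assert set(ann["region"]) <= allowed
        assert set(ann["island"]) <= set(ISLAND_PROBS)

    def test_seeded_determinism(self):
        a = generate_annotation(10, 2, seed=1)
        b = generate_annotation(10, 2, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_every_gene_has_promoter_probe(self):
        ann = generate_annotation(1000, 100, seed=7)
        prom = ann[ann["region"].isin(("TSS200", "TSS1500")) & (ann["gene"] != "")]
        covered = set(prom["gene"])
        assert covered == {f"GENE{i:05d}" for i in range(1, 101)}

    def test_positions_increasing_within_chromosome(self):
        ann = generate_annotation(500, 50, seed=3)
        for c, sub in ann.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert sub["pos"].is_unique

    def test_more_genes_than_probes_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(5, 6, seed=0)


class TestCohort:
    def test_null_config_nominal_false_positive_rate(self, null_cohort):
        m = beta_to_m(null_cohort.beta)
        groups = null_cohort.metadata.loc[m.columns, "group"]
        res = moderated_ttest(m, groups)
        frac = float((res["p_raw"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07
        assert null_cohort.truth_cpg == {}

    def test_planted_shift_mean_matches_nominal(self):
        cfg = SimulationConfig(n_cpg=2000, n_gene=200, seed=11)
        with pytest.warns(UserWarning, match="clipped"):
            c = generate_cohort(cfg)
        case = c.metadata.index[c.metadata["group"] == "case"]
        ctrl = c.metadata.index[c.metadata["group"] == "control"]
        truth = list(c.truth_cpg)
        diff = (
            c.beta.loc[truth, case].to_numpy().mean()
            - c.beta.loc[truth, ctrl].to_numpy().mean()
        )
        assert abs(diff - cfg.delta_beta) <= 0.03

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_cpg=500, n_gene=50, seed=5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_cohort(cfg)
            b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        assert a.truth_cpg == b.truth_cpg

    def test_beta_strictly_inside_unit_interval(self, small_cohort):
        vals = small_cohort.beta.to_numpy()
        assert vals.min() > 0 and vals.max() < 1

    def test_truth_probes_exist_in_annotation(self, small_cohort):
        assert set(small_cohort.truth_cpg) <= set(small_cohort.annotation.index)

    def test_metadata_aligned_with_beta(self, small_cohort):
        assert list(small_cohort.metadata.index) == list(small_cohort.beta.columns)

    def test_null_pvalues_uniform(self):
        """No planted effect, no confounders: raw p-values across 10,000
        CpGs are indistinguishable from uniform."""
        cfg = SimulationConfig(
            n_cpg=10_000,
            n_gene=500,
            delta_beta=0.0,
            confounder_spec=[],
            batch_spec=(1, 0.0, 1.0),
            seed=29,
        )
        c = generate_cohort(cfg)
        m = beta_to_m(c.beta)
        res = moderated_ttest(m, c.metadata.loc[m.columns, "group"])
        ks = stats.kstest(res["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_control", 0),
            ("frac_affected_cpg", 1.5),
            ("delta_beta", 1.0),
            ("expr_rho", 0.5),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = SimulationConfig(n_cpg=100, n_gene=10, **{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_tiny_affected_fraction_rejected(self):
        cfg = SimulationConfig(n_cpg=100, n_gene=10, frac_affected_cpg=0.001)
        with pytest.raises(ValueError, match="frac_affected_cpg"):
            cfg.validate()


class TestPathways:
    def test_sizes_within_range(self, small_cohort):
        sets, _ = generate_pathways(small_cohort.annotation, 10, (5, 20), seed=1)
        assert len(sets) == 10
        assert all(5 <= len(g) <= 20 for g in sets.values())

    def test_truth_pathways_contain_planted_genes(self, small_cohort):
        sets, truth_names = generate_pathways(
            small_cohort.annotation, 10, (10, 50), seed=2,
            truth_genes=small_cohort.truth_genes,
        )
        covered = set().union(*(set(sets[n]) for n in truth_names))
        truth = set(small_cohort.truth_genes)
        assert len(covered & truth) >= 0.8 * len(truth)

    def test_decoys_exclude_planted_genes(self, small_cohort):
        sets, truth_names = generate_pathways(
            small_cohort.annotation, 10, (10, 50), seed=2,
            truth_genes=small_cohort.truth_genes,
        )
        truth = set(small_cohort.truth_genes)
        for name, genes in sets.items():
            if name not in truth_names:
                assert not (set(genes) & truth)

    def test_seeded_rerun_identical(self, small_cohort, tmp_path):
        from methylseed.io import write_gmt

        a, _ = generate_pathways(small_cohort.annotation, 5, (5, 15), seed=9)
        b, _ = generate_pathways(small_cohort.annotation, 5, (5, 15), seed=9)
        write_gmt(a, tmp_path / "a.gmt")
        write_gmt(b, tmp_path / "b.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_infeasible_size_range_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="infeasible"):
            generate_pathways(small_cohort.annotation, 5, (5, 10_000), seed=0)


class TestDMRTrack:
    def test_empty_track(self, small_cohort):
        track, inside = generate_dmr_track(small_cohort.annotation, 0, seed=1)
        assert len(track.intervals) == 0 and inside == set()

    def test_each_interval_covers_a_probe(self, small_cohort):
        track, inside = generate_dmr_track(small_cohort.annotation, 5, seed=4)
        assert len(track.intervals) == 5
        for _, iv in track.intervals.iterrows():
            sub = small_cohort.annotation
            hits = probes_in_dmrs(
                sub, type(track)(pd.DataFrame([iv]))
            )
            assert len(hits) >= 1

    def test_recorded_probes_match_containment(self, small_cohort):
        track, inside = generate_dmr_track(small_cohort.annotation, 8, seed=6)
        assert inside == set(probes_in_dmrs(small_cohort.annotation, track))

    def test_seeded_rerun_identical(self, small_cohort):
        a, _ = generate_dmr_track(small_cohort.annotation, 5, seed=4)
        b, _ = generate_dmr_track(small_cohort.annotation, 5, seed=4)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)


class TestExpression:
    def test_perfect_negative_coupling(self, small_cohort):
        expr = generate_expression(small_cohort, rho=-1.0, seed=1)
        from methylseed.integration import promoter_gene_beta

        gene_beta, _ = promoter_gene_beta(small_cohort.beta, small_cohort.annotation)
        for gene in gene_beta.index[:20]:
            r = np.corrcoef(gene_beta.loc[gene], expr.loc[gene])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-9)

    def test_target_rho_mean_recovered(self, small_cohort):
        expr = generate_expression(small_cohort, rho=-0.5, seed=2)
        from methylseed.integration import promoter_gene_beta

        gene_beta, _ = promoter_gene_beta(small_cohort.beta, small_cohort.annotation)
        rs = [
            np.corrcoef(gene_beta.loc[g], expr.loc[g])[0, 1]
            for g in gene_beta.index
        ]
        assert abs(np.mean(rs) - (-0.5)) <= 0.1

    def test_zero_rho_independent(self, small_cohort):
        expr = generate_expression(small_cohort, rho=0.0, seed=3)
        from methylseed.integration import promoter_gene_beta

        gene_beta, _ = promoter_gene_beta(small_cohort.beta, small_cohort.annotation)
        rs = [
            np.corrcoef(gene_beta.loc[g], expr.loc[g])[0, 1]
            for g in gene_beta.index
        ]
        assert abs(np.mean(rs)) <= 0.05

    def test_nonnegative_values(self, small_cohort):
        expr = generate_expression(small_cohort, rho=-0.5, seed=4)
        assert (expr.to_numpy() >= 0).all()

    def test_positive_rho_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            generate_expression(small_cohort, rho=0.2, seed=0)


class TestExternalCohort:
    def test_marker_shift_recovered(self):
        markers = [f"mk{i}" for i in range(30)]
        beta, labels = generate_external_cohort(markers, 50, 50, shift=0.2, seed=8)
        pos = labels.index[labels == 1]
        neg = labels.index[labels == 0]
        diff = (
            beta.loc[markers, pos].to_numpy().mean()
            - beta.loc[markers, neg].to_numpy().mean()
        )
        assert abs(diff - 0.2) <= 0.05

    def test_zero_shift_classes_exchangeable(self):
        markers = [f"mk{i}" for i in range(30)]
        beta, labels = generate_external_cohort(markers, 40, 40, shift=0.0, seed=9)
        pos = labels.index[labels == 1]
        neg = labels.index[labels == 0]
        diff = (
            beta.loc[markers, pos].to_numpy().mean()
            - beta.loc[markers, neg].to_numpy().mean()
        )
        assert abs(diff) <= 0.02

    def test_background_probes_balanced(self):
        beta, labels = generate_external_cohort(["mk0"], 50, 50, shift=0.3, seed=10)
        bg = [p for p in beta.index if p.startswith("bg")]
        pos = labels.index[labels == 1]
        neg = labels.index[labels == 0]
        diff = beta.loc[bg, pos].to_numpy().mean() - beta.loc[bg, neg].to_numpy().mean()
        assert abs(diff) <= 0.02

    def test_seeded_rerun_identical(self):
        a, la = generate_external_cohort(["mk0", "mk1"], 10, 10, shift=0.2, seed=11)
        b, lb = generate_external_cohort(["mk0", "mk1"], 10, 10, shift=0.2, seed=11)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(la, lb)

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError):
            generate_external_cohort([], 10, 10, shift=0.2, seed=0)
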