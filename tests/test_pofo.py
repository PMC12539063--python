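import math

import numpy as np
import pandas as pd
import pytest

from asepofo import pofo
from asepofo.pofo import (
    DesignError,
    PofoResult,
    build_design,
    classify,
    fit_quasipoisson,
    fold_change,
    pofo_score,
    reduce_indicators,
    run_pofo,
    score_gene,
)
from conftest import phased_gene_frame
from oracles import poisson_mle, random_design, statsmodels_cluster_cov


class TestReduceIndicators:
    def test_single_snp_gives_constant_half_vector(self):
        u = np.ones((4, 1))
        v, q = reduce_indicators(u)
        assert q == 1
        np.testing.assert_allclose(np.abs(v[:, 0]), 0.5)

    def test_disjoint_indicator_singular_values(self):
        # rows per SNP (4, 2) -> singular values (2, sqrt 2), both above 1%
        u = np.zeros((6, 2))
        u[:4, 0] = 1
        u[4:, 1] = 1
        sv = np.linalg.svd(u, compute_uv=False)
        np.testing.assert_allclose(sorted(sv, reverse=True), [2.0, math.sqrt(2)])
        v, q = reduce_indicators(u)
        assert q == 2
        np.testing.assert_allclose(v.T @ v, np.eye(2), atol=1e-12)

    def test_tiny_snp_dropped_below_threshold(self):
        # rows per SNP (20000, 1): sigma = (141.42, 1); 1% of max = 1.414 > 1
        u = np.zeros((20001, 2))
        u[:20000, 0] = 1
        u[20000:, 1] = 1
        _, q = reduce_indicators(u)
        assert q == 1

    def test_threshold_is_inclusive(self):
        # sigma_2 exactly at 1% of sigma_1 is kept ("at least")
        u = np.zeros((10001, 2), dtype=float)
        u[:10000, 0] = 1.0
        u[10000, 1] = 1.0
        sv = np.linalg.svd(u, compute_uv=False)
        assert sv[1] == pytest.approx(0.01 * sv[0])
        _, q = reduce_indicators(u, rel_threshold=0.01)
        assert q == 2


class TestBuildDesign:
    def test_single_subject_single_snp(self):
        frame = phased_gene_frame([("A", 100, 8, 2, "ref")])
        d = build_design(frame)
        assert d.n_obs == 2 and d.m == 1
        np.testing.assert_allclose(d.y, [8, 2])
        np.testing.assert_allclose(d.x, [0.5, -0.5])
        np.testing.assert_allclose(d.z, [0.5, -0.5])

    def test_paternal_alt_flips_z_not_x(self):
        d = build_design(phased_gene_frame([("A", 100, 8, 2, "alt")]))
        np.testing.assert_allclose(d.x, [0.5, -0.5])
        np.testing.assert_allclose(d.z, [-0.5, 0.5])

    def test_strand_records_summed_before_rows(self):
        frame = phased_gene_frame(
            [("A", 100, 5, 1, "ref"), ("A", 100, 3, 1, "ref")]
        )
        frame.loc[1, "strand_label"] = "reverse"
        d = build_design(frame, combine_strands=True)
        assert d.n_obs == 2
        np.testing.assert_allclose(d.y, [8, 2])

    def test_u_column_sums_count_observations(self):
        entries = [(s, p, 4, 4, "ref") for s in "ABC" for p in (100, 200)]
        d = build_design(phased_gene_frame(entries))
        assert d.n_obs == 12
        np.testing.assert_allclose(d.u.sum(axis=0), [6, 6])
        assert (d.u.sum(axis=1) == 1).all()

    def test_paired_rows_balance_z_and_x(self):
        d = build_design(phased_gene_frame([("A", 100, 8, 2, "ref"), ("B", 200, 1, 9, "alt")]))
        for pair in (slice(0, 2), slice(2, 4)):
            assert d.z[pair].sum() == 0
            assert d.x[pair].sum() == 0

    def test_no_phased_rows_raises(self):
        frame = phased_gene_frame([("A", 100, 8, 2, "ref")])
        frame["paternal_allele"] = "unknown"
        with pytest.raises(DesignError):
            build_design(frame)


class TestFit:
    def test_symmetric_fixture_closed_form(self):
        """Mirror-image subjects force po = log(30/3) and beta1 = 0."""
        frame = phased_gene_frame([("A", 100, 30, 3, "ref"), ("B", 100, 3, 30, "alt")])
        fit = fit_quasipoisson(build_design(frame))
        assert fit.params["z"] == pytest.approx(math.log(10), abs=1e-8)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.converged

    def test_flat_counts_give_zero_po(self):
        frame = phased_gene_frame(
            [("A", 100, 7, 7, "ref"), ("B", 100, 7, 7, "alt"), ("C", 100, 7, 7, "ref")]
        )
        fit = fit_quasipoisson(build_design(frame))
        assert fit.params["z"] == pytest.approx(0.0, abs=1e-10)

    def test_intercept_collinearity_always_resolved(self, rng):
        """With every singular vector kept the V block spans the constant
        column, so a redundant column must be dropped whenever q == m."""
        for _ in range(5):
            d = random_design(rng, max_subjects=8, max_snps=4)
            if d.q == d.m:
                fit = fit_quasipoisson(d)
                assert fit.dropped_columns
                assert "z" in fit.names and "intercept" in fit.names

    def test_irls_matches_generic_optimizer(self, rng):
        for _ in range(5):
            d = random_design(rng, max_subjects=10, max_snps=5)
            fit = fit_quasipoisson(d)
            full, names = d.matrix()
            keep = [names.index(n) for n in fit.names]
            oracle = poisson_mle(full[:, keep], d.y)
            np.testing.assert_allclose(
                np.array([fit.params[n] for n in fit.names]), oracle, atol=1e-6
            )

    def test_sandwich_matches_statsmodels(self, rng):
        for _ in range(3):
            d = random_design(rng, max_subjects=10, max_snps=5)
            fit = fit_quasipoisson(d, small_sample_correction="none")
            full, names = d.matrix()
            keep = [names.index(n) for n in fit.names]
            ref = statsmodels_cluster_cov(full[:, keep], d.y, d.clusters)
            np.testing.assert_allclose(fit.cov, ref, atol=1e-6)

    def test_cr1_scales_covariance_by_g_over_g_minus_1(self, rng):
        d = random_design(rng, max_subjects=8, max_snps=3)
        plain = fit_quasipoisson(d, small_sample_correction="none")
        cr1 = fit_quasipoisson(d, small_sample_correction="cr1")
        g = d.n_subjects
        np.testing.assert_allclose(cr1.cov, plain.cov * g / (g - 1))

    def test_covariance_symmetric_psd(self, rng):
        d = random_design(rng)
        fit = fit_quasipoisson(d)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-10)


class TestEquivariance:
    def _flip_parent(self, frame):
        out = frame.copy()
        out["paternal_allele"] = out["paternal_allele"].map({"ref": "alt", "alt": "ref"})
        pc = out["paternal_count"].copy()
        out["paternal_count"], out["maternal_count"] = out["maternal_count"], pc
        return out

    def _flip_refalt(self, frame):
        out = frame.copy()
        rc = out["ref_count"].copy()
        out["ref_count"], out["alt_count"] = out["alt_count"], rc
        out["paternal_allele"] = out["paternal_allele"].map({"ref": "alt", "alt": "ref"})
        return out

    def test_parent_flip_negates_po(self, rng):
        for _ in range(3):
            cfg_seed = int(rng.integers(0, 2**31 - 1))
            from asepofo.simulate import SimConfig, simulate_gene_sites

            frame, _ = simulate_gene_sites(
                SimConfig(n_subjects=8, snps_per_gene=3, po_true=0.7, seed=cfg_seed),
                np.random.default_rng(cfg_seed),
            )
            a = score_gene(frame)
            b = score_gene(self._flip_parent(frame))
            assert b.po == pytest.approx(-a.po, abs=1e-8)
            assert b.po_z == pytest.approx(-a.po_z, abs=1e-6)

    def test_refalt_flip_leaves_po_unchanged(self, rng):
        from asepofo.simulate import SimConfig, simulate_gene_sites

        seed = int(rng.integers(0, 2**31 - 1))
        frame, _ = simulate_gene_sites(
            SimConfig(n_subjects=8, snps_per_gene=3, po_true=0.7, seed=seed),
            np.random.default_rng(seed),
        )
        a = score_gene(frame)
        b = score_gene(self._flip_refalt(frame))
        assert b.po == pytest.approx(a.po, abs=1e-8)


class TestScoringAndClassification:
    def _result(self, po, po_z, testable=True, reason="none"):
        return PofoResult("g", po, po / po_z if po_z else 1.0, po_z, 10, 2, 20,
                          testable, reason)

    def test_po_z_is_ratio(self, rng):
        d = random_design(rng, max_subjects=10, max_snps=3)
        res = pofo_score(fit_quasipoisson(d))
        assert res.po_z == pytest.approx(res.po / res.po_se)

    def test_too_few_subjects_untestable(self):
        frame = phased_gene_frame([("A", 100, 30, 3, "ref"), ("B", 100, 3, 30, "alt")])
        res = score_gene(frame, min_subjects=3)
        assert not res.testable
        assert res.untestable_reason == "too_few_subjects"

    @pytest.mark.parametrize(
        "po,po_z,expected",
        [
            (3.5, 6.0, "strong_paternal"),
            (-3.5, -6.0, "strong_maternal"),
            (-1.2, -4.0, "significant_maternal"),
            (1.2, 4.0, "significant_paternal"),
            (4.0, 2.0, "not_significant"),  # z gate first
            (0.1, 0.5, "not_significant"),
        ],
    )
    def test_classification_table(self, po, po_z, expected):
        assert classify(self._result(po, po_z)) == expected

    def test_untestable_class(self):
        assert classify(self._result(1, 5, testable=False, reason="no_phased_snps")) == "untestable"

    def test_direction_follows_sign(self):
        assert self._result(2.0, 5.0).direction == "paternal"
        assert self._result(-2.0, -5.0).direction == "maternal"

    @pytest.mark.parametrize("po,expected", [(0.0, 1.0), (3.0, 20.085536923187668),
                                             (math.log(10), 10.0), (-math.log(10), 10.0)])
    def test_fold_change(self, po, expected):
        assert fold_change(po) == pytest.approx(expected)


class TestRunPofo:
    def test_per_gene_table(self):
        frames = []
        for gid in ("g1", "g2"):
            f = phased_gene_frame(
                [("A", 100, 20, 10, "ref"), ("B", 100, 15, 15, "alt"),
                 ("C", 100, 18, 12, "ref")],
                gene_id=gid,
            )
            frames.append(f)
        out = run_pofo(pd.concat(frames, ignore_index=True))
        assert out["gene_id"].tolist() == ["g1", "g2"]
        assert out["testable"].all()
        assert set(out.columns) >= {"po", "po_se", "po_z", "classification"}
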