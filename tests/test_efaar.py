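import numpy as np
import pandas as pd
import pytest

from conftest import make_units
from permap.efaar import (
    PipelineConfig,
    aggregate_mean,
    align_center_scale,
    align_tvn,
    apply_filters,
    drop_columns,
    embed_pca,
    pipeline_preset,
    range_filter,
    relate_cosine,
    robust_gaussian_outlier,
    run_pipeline,
)
from permap.map_model import AggregatedMap, PermapError
from permap.efaar import _inv_sqrt


def _gaussian_units(n, d, seed=0, n_batches=1, n_controls=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    batches = [f"b{i % n_batches}" for i in range(n)]
    ctrl = [i < n_controls for i in range(n)]
    pert = ["ctrl" if c else f"g{i}" for i, c in enumerate(ctrl)]
    return make_units(X, pert, batches, ctrl)


# ---------------------------------------------------------------------------
# Embed
# ---------------------------------------------------------------------------

class TestEmbedPCA:
    def test_rank_deficient_third_component_explains_nothing(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 5))
        X = rng.standard_normal((20, 2)) @ basis  # rank 2
        units = make_units(X, [f"g{i}" for i in range(20)], ["b"] * 20,
                           [False] * 20)
        out = embed_pca(units, k=3, prescale_per_batch=False)
        evr = out.info["pca"]["explained_variance_ratio"]
        assert evr[2] < 1e-10

    def test_k_exceeding_rank_errors_with_attainable_rank(self):
        units = _gaussian_units(4, 6)
        with pytest.raises(PermapError, match="attainable rank 4"):
            embed_pca(units, k=5, prescale_per_batch=False)

    def test_projection_matches_eigendecomposition_oracle(self):
        # oracle: eigendecomposition of the sample covariance of a 10x5 matrix
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10, 5))
        k = 3
        mu = X.mean(axis=0)
        Xc = X - mu
        C = Xc.T @ Xc / (X.shape[0] - 1)
        w, V = np.linalg.eigh(C)
        V = V[:, np.argsort(w)[::-1]][:, :k].T  # components in rows
        flip = np.sign(V[np.arange(k), np.abs(V).argmax(axis=1)])
        V = V * flip[:, None]
        oracle_scores = Xc @ V.T
        oracle_recon = oracle_scores @ V + mu

        units = make_units(X, [f"g{i}" for i in range(10)], ["b"] * 10,
                           [False] * 10)
        out = embed_pca(units, k=k, prescale_per_batch=False)
        scores = out.values()
        assert np.allclose(scores, oracle_scores, atol=1e-10)
        comps = V  # same sign convention as the implementation
        assert np.allclose(scores @ comps + mu, oracle_recon, atol=1e-10)

    def test_retains_all_128_components_when_requested(self):
        units = _gaussian_units(200, 130)
        out = embed_pca(units, k=128, prescale_per_batch=False)
        assert out.n_dims == 128

    def test_sign_convention_is_deterministic(self):
        units = _gaussian_units(30, 4, seed=1)
        a = embed_pca(units, k=4, prescale_per_batch=False).values()
        b = embed_pca(units, k=4, prescale_per_batch=False).values()
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# Filter
# ---------------------------------------------------------------------------

class TestFilters:
    def test_range_filter_inclusive_boundaries(self):
        counts = [49, 50, 200, 350, 351]
        units = make_units(
            np.ones((5, 2)), [f"g{i}" for i in range(5)], ["b"] * 5,
            [False] * 5, qc={"Nuclei_Number_Object_Number": counts},
        )
        out = apply_filters(
            units, [range_filter("Nuclei_Number_Object_Number", 50, 350)]
        )
        kept = out.qc["Nuclei_Number_Object_Number"].tolist()
        assert kept == [50, 200, 350]

    def test_drop_columns_removes_exactly_the_prefix(self):
        feats = pd.DataFrame(
            np.ones((3, 4)),
            columns=["Image_a", "Image_b", "Cells_a", "Nuclei_a"],
            index=["u0", "u1", "u2"],
        )
        units = make_units(np.ones((3, 4)), ["g0", "g1", "g2"], ["b"] * 3,
                           [False] * 3)
        units = units.with_features(feats.set_axis(units.unit_ids))
        out = apply_filters(units, [drop_columns("Image_")])
        assert list(out.features.columns) == ["Cells_a", "Nuclei_a"]

    def test_robust_gaussian_outlier_removes_planted_outlier(self):
        # oracle: the planted 10-sigma point has by far the largest
        # Mahalanobis distance under the sample mean/covariance
        rng = np.random.default_rng(3)
        X = rng.standard_normal((1000, 3))
        X[123] = 10.0
        mu = X.mean(axis=0)
        P = np.linalg.inv(np.cov(X, rowvar=False))
        d2 = np.einsum("ij,jk,ik->i", X - mu, P, X - mu)
        assert np.argmax(d2) == 123

        units = make_units(X, [f"g{i}" for i in range(1000)], ["b"] * 1000,
                           [False] * 1000)
        out = apply_filters(
            units, [robust_gaussian_outlier("f", contamination=0.01, seed=0)]
        )
        removed = set(units.unit_ids) - set(out.unit_ids)
        assert "unit123" in removed
        assert 5 <= len(removed) <= 20  # ~1% of 1000

    def test_all_units_filtered_is_an_error(self):
        units = make_units(np.ones((2, 1)), ["g0", "g1"], ["b"] * 2,
                           [False] * 2, qc={"count": [400, 500]})
        with pytest.raises(PermapError, match="all units filtered"):
            apply_filters(units, [range_filter("count", 50, 350)])


# ---------------------------------------------------------------------------
# Align
# ---------------------------------------------------------------------------

class TestCenterScale:
    def test_controls_standardized_per_batch(self):
        units = _gaussian_units(200, 4, n_batches=2, n_controls=60, seed=2)
        out = align_center_scale(units, scope="per_batch",
                                 reference="controls")
        for b in out.batch.unique():
            m = ((out.batch == b) & out.is_control).to_numpy()
            Xc = out.values()[m]
            assert np.allclose(Xc.mean(axis=0), 0.0, atol=1e-9)
            assert np.allclose(Xc.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_global_equals_per_batch_for_single_batch(self):
        units = _gaussian_units(50, 3, n_controls=10)
        a = align_center_scale(units, scope="global").values()
        b = align_center_scale(units, scope="per_batch").values()
        assert np.array_equal(a, b)

    def test_non_controls_use_control_parameters_hand_arithmetic(self, toy_units):
        # batch b1: control features f0 = (1, 3) -> mean 2, sd sqrt(2)
        #           control features f1 = (2, 6) -> mean 4, sd 2*sqrt(2)
        # geneA unit (2, 1) -> ((2-2)/sqrt2, (1-4)/(2 sqrt2))
        out = align_center_scale(toy_units, scope="per_batch",
                                 reference="controls")
        got = out.values()[2]
        expected = [0.0, -3.0 / (2 * np.sqrt(2))]
        assert np.allclose(got, expected, atol=1e-12)

    def test_batch_with_too_few_controls_is_an_error(self):
        units = make_units(np.eye(3), ["ctrl", "g1", "g2"],
                           ["b1", "b1", "b2"], [True, False, False])
        with pytest.raises(PermapError, match="b1.*|batches"):
            align_center_scale(units, scope="per_batch")

    def test_zero_variance_feature_named_in_error(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        units = make_units(X, ["ctrl", "ctrl", "g"], ["b"] * 3,
                           [True, True, False])
        with pytest.raises(PermapError, match="f1"):
            align_center_scale(units, scope="per_batch")

    def test_alignment_is_affine_per_batch(self):
        # three collinear non-control points stay collinear
        rng = np.random.default_rng(0)
        base, step = rng.standard_normal(3), rng.standard_normal(3)
        pts = [base, base + step, base + 2 * step]
        ctrl = rng.standard_normal((4, 3))
        X = np.vstack([ctrl, pts])
        units = make_units(X, ["c"] * 4 + ["g1", "g2", "g3"], ["b"] * 7,
                           [True] * 4 + [False] * 3)
        for out in (align_center_scale(units), align_tvn(units)):
            Y = out.values()[4:]
            diffs = np.vstack([Y[1] - Y[0], Y[2] - Y[0]])
            s = np.linalg.svd(diffs, compute_uv=False)
            assert s[1] < 1e-8 * s[0]


class TestTVN:
    def test_single_batch_coral_step_is_identity(self):
        # one batch: batch controls == global controls, whose score
        # covariance is already the identity after the global scaling, so
        # the per-batch whitening must be a no-op
        units = _gaussian_units(120, 5, n_controls=40, seed=4)
        full = align_tvn(units).values()
        no_coral = align_center_scale(
            embed_pca(align_center_scale(units, scope="global"),
                      k=min(39, 5), fit_on="controls",
                      prescale_per_batch=False),
            scope="global",
        ).values()
        assert np.allclose(full, no_coral, atol=1e-6)

    def test_batch_control_covariance_becomes_identity(self):
        rng = np.random.default_rng(8)
        rows, pert, batch, ctrl = [], [], [], []
        for bi, (shift, scale) in enumerate([(0.0, 1.0), (3.0, 2.5)]):
            C = rng.standard_normal((500, 4)) * scale + shift
            G = rng.standard_normal((100, 4)) * scale + shift + 0.5
            rows.append(np.vstack([C, G]))
            pert += ["ctrl"] * 500 + [f"g{bi}_{i}" for i in range(100)]
            batch += [f"b{bi}"] * 600
            ctrl += [True] * 500 + [False] * 100
        units = make_units(np.vstack(rows), pert, batch, ctrl)
        out = align_tvn(units)
        for b in out.batch.unique():
            m = ((out.batch == b) & out.is_control).to_numpy()
            cov = np.cov(out.values()[m], rowvar=False)
            off = cov - np.diag(np.diag(cov))
            assert np.abs(off).max() < 0.05
            assert np.allclose(np.diag(cov), 1.0, atol=0.05)

    def test_inverse_sqrt_of_diagonal_covariance_closed_form(self):
        W = _inv_sqrt(np.diag([4.0, 1.0]), batch="b")
        assert np.allclose(W, np.diag([0.5, 1.0]), atol=1e-5)

    def test_tvn_requires_controls(self):
        units = _gaussian_units(10, 3)
        with pytest.raises(PermapError, match="control"):
            align_tvn(units)


# ---------------------------------------------------------------------------
# Aggregate, Relate
# ---------------------------------------------------------------------------

class TestAggregateRelate:
    def test_single_replicate_is_its_own_vector(self):
        units = make_units([[1.0, 2.0]], ["geneA"], ["b"], [False])
        amap = aggregate_mean(units)
        assert amap.genes == ["geneA"]
        assert np.array_equal(amap.values(), [[1.0, 2.0]])

    def test_two_replicate_mean(self):
        units = make_units([[0.0, 0.0], [2.0, 4.0]], ["g", "g"], ["b"] * 2,
                           [False] * 2)
        assert np.array_equal(aggregate_mean(units).values(), [[1.0, 2.0]])

    def test_grouped_means_match_loop_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 3))
        genes = [f"g{i % 4}" for i in range(12)]
        units = make_units(X, genes, ["b"] * 12, [False] * 12)
        amap = aggregate_mean(units)
        for g in sorted(set(genes)):
            rows = [X[i] for i in range(12) if genes[i] == g]
            oracle = np.mean(rows, axis=0)
            assert np.allclose(amap.vectors.loc[g].to_numpy(), oracle,
                               atol=1e-12)

    def test_controls_excluded_from_gene_universe(self, toy_units):
        amap = aggregate_mean(toy_units)
        assert amap.genes == ["geneA"]

    def test_cosine_closed_forms(self):
        vectors = pd.DataFrame(
            [[1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [2.0, 0.0]],
            index=["a", "ab", "b", "a2"],
        )
        sim = relate_cosine(AggregatedMap(vectors))
        assert sim.lookup("a", "a2") == pytest.approx(1.0, abs=1e-12)
        assert sim.lookup("a", "b") == pytest.approx(0.0, abs=1e-12)
        assert sim.lookup("a", "ab") == pytest.approx(1 / np.sqrt(2),
                                                      abs=1e-12)

    def test_zero_norm_vector_error_names_gene(self):
        vectors = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["ok", "bad"])
        with pytest.raises(PermapError, match="bad"):
            relate_cosine(AggregatedMap(vectors))

    def test_cosine_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(1)
        vectors = pd.DataFrame(rng.standard_normal((5, 4)),
                               index=list("abcde"))
        sim1 = relate_cosine(AggregatedMap(vectors))
        vectors2 = vectors.copy()
        vectors2.loc["c"] *= 7.5
        sim2 = relate_cosine(AggregatedMap(vectors2))
        assert np.allclose(sim1.values, sim2.values, atol=1e-12)


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

class TestRunPipeline:
    def test_passthrough_config_reproduces_manual_composition(self, toy_units):
        amap, sim = run_pipeline(toy_units, PipelineConfig(name="raw"))
        manual = relate_cosine(aggregate_mean(toy_units))
        assert np.array_equal(sim.values, manual.values)

    def test_pca_cs_equals_manual_stage_composition(self, mild_screen):
        units, _, _ = mild_screen
        amap, sim = run_pipeline(units, pipeline_preset("pca-cs", k=8))
        manual = relate_cosine(aggregate_mean(align_center_scale(
            embed_pca(units, k=8), scope="per_batch", reference="controls")))
        assert np.array_equal(sim.values, manual.values)

    def test_identical_config_is_bit_identical(self, mild_screen):
        units, _, _ = mild_screen
        _, sim1 = run_pipeline(units, pipeline_preset("pca-tvn", k=8, seed=3))
        _, sim2 = run_pipeline(units, pipeline_preset("pca-tvn", k=8, seed=3))
        assert np.array_equal(sim1.values, sim2.values)

    def test_unknown_stage_rejected(self):
        with pytest.raises(PermapError, match="embed"):
            PipelineConfig(embed="umap")

    def test_provenance_records_pipeline(self, mild_screen):
        units, _, _ = mild_screen
        amap, _ = run_pipeline(units, pipeline_preset("pca", k=4))
        assert amap.provenance["pipeline"]["embed"] == "pca"
        assert amap.provenance["pipeline"]["pca_k"] == 4
        assert "replicate_counts" in amap.provenance
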