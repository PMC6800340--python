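"""Searchlight engine: normalization, geometry, data RDMs, fit, inference."""

import numpy as np
import pytest

from semrsa import rdm as R
from semrsa import ssrsa as SS
from semrsa import synth as S
from tests.conftest import random_rdm


def make_epochs(rng, n=10, v=15, t=30, step=2.0, scale=25.0):
    coords = rng.uniform(0, scale, (v, 3))
    data = rng.standard_normal((n, v, t))
    return SS.SourceEpochs(data, coords, step * np.arange(t),
                           [f"s{i:04d}" for i in range(n)], "sub00")


class TestSourceEpochs:
    def test_nonuniform_time_axis_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="uniform"):
            SS.SourceEpochs(rng.standard_normal((2, 3, 4)),
                            rng.uniform(0, 1, (3, 3)),
                            np.array([0.0, 2.0, 4.0, 7.0]), ["a", "b"])

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng)
        ep.save(tmp_path / "ep.h5")
        back = SS.SourceEpochs.load(tmp_path / "ep.h5")
        np.testing.assert_allclose(back.data, ep.data, atol=1e-6)
        assert back.trial_ids == ep.trial_ids
        assert back.subject_id == "sub00"
        assert back.step_ms == 2.0


class TestMultivariateNormalize:
    def test_white_data_nearly_unchanged(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng, n=2000, v=12, t=5)
        out = SS.multivariate_normalize(ep, shrinkage="auto")
        rel = np.linalg.norm(out.data - ep.data) / np.linalg.norm(ep.data)
        assert rel < 0.05

    def test_full_shrinkage_is_per_vertex_scaling(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng, n=40, v=8, t=12)
        out = SS.multivariate_normalize(ep, shrinkage=1.0)
        resid = ep.data - ep.data.mean(axis=0, keepdims=True)
        pooled = resid.transpose(0, 2, 1).reshape(-1, 8)
        sd = np.sqrt((pooled ** 2).mean(axis=0))
        np.testing.assert_allclose(out.data, ep.data / sd[None, :, None],
                                   rtol=1e-8)

    def test_whitened_residual_covariance_near_identity(self):
        rng = np.random.default_rng(4)
        v = 10
        mixing = rng.standard_normal((v, v)) * 0.5 + np.eye(v)
        white = rng.standard_normal((500, v, 8))
        data = np.einsum("uv,nvt->nut", mixing, white)
        ep = SS.SourceEpochs(data, rng.uniform(0, 20, (v, 3)),
                             2.0 * np.arange(8),
                             [f"s{i}" for i in range(500)])
        out = SS.multivariate_normalize(ep, shrinkage=0.01)
        resid = out.data - out.data.mean(axis=0, keepdims=True)
        pooled = resid.transpose(0, 2, 1).reshape(-1, v)
        corr = np.corrcoef(pooled.T)
        off = corr[~np.eye(v, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_singular_covariance_advises_shrinkage(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((30, 1, 6))
        data = np.repeat(base, 4, axis=1)  # rank-1 spatial structure
        ep = SS.SourceEpochs(data, rng.uniform(0, 20, (4, 3)),
                             2.0 * np.arange(6),
                             [f"s{i}" for i in range(30)])
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            SS.multivariate_normalize(ep, shrinkage=0.0)


class TestSearchlightGeometry:
    def test_radius_zero_is_self_only(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 50, (20, 3))
        hoods = SS.searchlight_neighborhoods(
            coords, SS.SearchlightSpec(spatial_radius_mm=0.0))
        for i, h in enumerate(hoods):
            np.testing.assert_array_equal(h, [i])

    def test_huge_radius_includes_everyone(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 10, (15, 3))
        hoods = SS.searchlight_neighborhoods(
            coords, SS.SearchlightSpec(spatial_radius_mm=1e3))
        for h in hoods:
            assert h.size == 15

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 40, (50, 3))
        spec = SS.SearchlightSpec(spatial_radius_mm=12.0)
        hoods = SS.searchlight_neighborhoods(coords, spec)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        for i in range(50):
            np.testing.assert_array_equal(
                hoods[i], np.flatnonzero(d[i] <= 12.0))

    def test_spatial_adjacency_matches_brute_force(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 40, (30, 3))
        adj = SS.spatial_adjacency(coords, 15.0).toarray()
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        want = (d <= 15.0) & ~np.eye(30, dtype=bool)
        np.testing.assert_array_equal(adj, want)


class TestDataRdm:
    def test_identical_and_negated_trials(self):
        rng = np.random.default_rng(10)
        pattern = rng.standard_normal((1, 4, 9))
        data = np.concatenate([pattern, pattern, -pattern], axis=0)
        ep = SS.SourceEpochs(data, rng.uniform(0, 10, (4, 3)),
                             2.0 * np.arange(9), ["a", "b", "c"])
        rdm = SS.data_rdm(ep, np.arange(4), center_time_ms=8.0,
                          temporal_radius_ms=6.0)
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.values[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        ep = make_epochs(rng, n=5, v=6, t=20)
        verts = np.array([0, 2, 3])
        rdm = SS.data_rdm(ep, verts, 20.0, 8.0)
        feats = ep.data[:, verts, 6:15].reshape(5, -1)
        for i in range(5):
            for j in range(5):
                xi = feats[i] - feats[i].mean()
                xj = feats[j] - feats[j].mean()
                want = 0.0 if i == j else 1 - xi @ xj / (
                    np.linalg.norm(xi) * np.linalg.norm(xj))
                assert rdm.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_constant_trial_names_offender(self):
        rng = np.random.default_rng(12)
        ep = make_epochs(rng, n=4, v=5, t=10)
        ep.data[2] = 7.0
        with pytest.raises(R.UndefinedCorrelationError, match="s0002"):
            SS.data_rdm(ep, np.arange(5), 10.0, 4.0)

    def test_affine_gain_invariance(self):
        rng = np.random.default_rng(13)
        ep = make_epochs(rng, n=6, v=5, t=12)
        gains = rng.uniform(0.5, 3.0, 6)
        offsets = rng.standard_normal(6)
        scaled = ep.data * gains[:, None, None] + offsets[:, None, None]
        ep2 = SS.SourceEpochs(scaled, ep.vertex_coords, ep.times_ms,
                              ep.trial_ids)
        a = SS.data_rdm(ep, np.arange(5), 12.0, 6.0)
        b = SS.data_rdm(ep2, np.arange(5), 12.0, 6.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestModelFitMap:
    def test_matches_naive_searchlight(self):
        """The vectorized fit map equals per-searchlight data_rdm +
        partial_spearman to machine precision."""
        rng = np.random.default_rng(14)
        ep = make_epochs(rng, n=12, v=20, t=40)
        model = random_rdm(12, rng, item_order=ep.trial_ids)
        ctrl = random_rdm(12, rng, item_order=ep.trial_ids, label="noun_topic")
        spec = SS.SearchlightSpec(spatial_radius_mm=10.0,
                                  temporal_radius_ms=8.0, center_step=3)
        fm = SS.model_fit_map(ep, model, controls=[ctrl], spec=spec)
        hoods = SS.searchlight_neighborhoods(ep.vertex_coords, spec)
        y = R.vectorize_upper(model)
        cvec = R.vectorize_upper(ctrl)
        for vi in range(20):
            for ci, tms in enumerate(fm.center_times_ms):
                c = ep.time_index(tms)
                if c - 4 < 0 or c + 5 > 40:
                    assert np.isnan(fm.rho[vi, ci])
                    continue
                drdm = SS.data_rdm(ep, hoods[vi], tms, 8.0)
                want = R.partial_spearman(R.vectorize_upper(drdm), y, [cvec])
                assert fm.rho[vi, ci] == pytest.approx(want, abs=1e-10)

    def test_planted_geometry_noise_free_rho_one(self):
        """A patch whose dissimilarities realize the model RDM exactly gives
        Spearman rho = 1."""
        rng = np.random.default_rng(15)
        n = 24
        # tie-free cosine RDM from continuous topic-like vectors (its
        # similarity matrix is an exact Gram matrix, so the embedding and
        # hence the data distances reproduce it exactly)
        vecs = rng.dirichlet(np.full(6, 5.0), size=n)
        ids = [f"s{i:04d}" for i in range(n)]
        model = R.distance_rdm(list(vecs), ids, "verb_topic")
        # 6 vertices x 9 samples; the searchlight window covers the whole
        # patch, so the data RDM sees the embedded geometry exactly
        P = S.embed_rdm_patterns(model.values, 54, rng)
        data = P.reshape(n, 6, 9)
        ep = SS.SourceEpochs(data, rng.uniform(0, 5, (6, 3)),
                             2.0 * np.arange(9), ids)
        drdm = SS.data_rdm(ep, np.arange(6), 8.0, 8.0)
        rho = R.partial_spearman(R.vectorize_upper(drdm),
                                 R.vectorize_upper(model))
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_permuted_model_fits_nothing(self):
        """Against planted geometry, item-permuted model RDMs average to
        zero fit."""
        rng = np.random.default_rng(16)
        model = random_rdm(16, rng)
        P = S.embed_rdm_patterns(np.clip(model.values, 0, None) /
                                 model.values.max(), 50, rng)
        rhos = []
        y = R.vectorize_upper(model)
        d = R.vectorize_upper(R.RDM(
            1 - np.corrcoef(P), model.item_order, "data",
            "correlation_distance"))
        for _ in range(100):
            perm = rng.permutation(16)
            pm = model.values[np.ix_(perm, perm)]
            rhos.append(R.partial_spearman(
                d, R.vectorize_upper(R.RDM(pm, model.item_order, "x",
                                           "cosine")), []))
        assert abs(np.mean(rhos)) < 0.02

    def test_self_partialling_gives_zero(self):
        rng = np.random.default_rng(17)
        ep = make_epochs(rng, n=8, v=10, t=20)
        model = random_rdm(8, rng, item_order=ep.trial_ids)
        fm = SS.model_fit_map(ep, model, controls=[model],
                              spec=SS.SearchlightSpec(temporal_radius_ms=6.0))
        valid = np.isfinite(fm.rho)
        assert valid.any()
        assert np.abs(fm.rho[valid]).max() == 0.0

    def test_alignment_error_lists_unmatched(self):
        rng = np.random.default_rng(18)
        ep = make_epochs(rng, n=6, v=5, t=16)
        model = random_rdm(6, rng, item_order=["x"] * 0 + [f"t{i}" for i in
                                                           range(6)])
        with pytest.raises(ValueError, match="s0000"):
            SS.model_fit_map(ep, model)

    def test_missing_trials_are_dropped_from_model(self):
        rng = np.random.default_rng(19)
        ep = make_epochs(rng, n=8, v=8, t=20)
        model = random_rdm(10, rng,
                           item_order=[f"s{i:04d}" for i in range(10)])
        fm = SS.model_fit_map(ep, model,
                              spec=SS.SearchlightSpec(temporal_radius_ms=4.0))
        assert np.isfinite(fm.rho).any()


class TestGroupClusterInference:
    def test_all_zero_maps_give_no_clusters(self):
        rng = np.random.default_rng(20)
        coords = rng.uniform(0, 30, (10, 3))
        fms = [SS.FitMap(np.zeros((10, 8)), np.arange(10),
                         2.0 * np.arange(8), "m", f"s{i}") for i in range(6)]
        gr = SS.group_cluster_inference(
            fms, SS.spatial_adjacency(coords, 12.0), n_perm=100, seed=0)
        assert gr.clusters == []
        assert not gr.mask.any()

    def test_planted_block_recovered_at_minimum_p(self):
        """A strong 20-point block yields exactly one significant cluster
        at the attainable minimum p."""
        rng = np.random.default_rng(21)
        coords = rng.uniform(20, 60, (25, 3))
        coords[:4] = rng.uniform(0, 5, (4, 3))  # block vertices adjacent
        block_v, block_t = np.arange(4), np.arange(5)
        fms = []
        for i in range(12):
            rho = rng.normal(0.0, 0.05, (25, 10))
            rho[np.ix_(block_v, block_t)] = rng.normal(0.5, 0.05, (4, 5))
            fms.append(SS.FitMap(rho, np.arange(25), 2.0 * np.arange(10),
                                 "m", f"s{i}"))
        n_perm = 500
        gr = SS.group_cluster_inference(
            fms, SS.spatial_adjacency(coords, 15.0), n_perm=n_perm, seed=1)
        sig = [c for c in gr.clusters if c.p < 0.05]
        assert len(sig) == 1
        assert sig[0].p == pytest.approx(1.0 / (1 + n_perm))
        got = set(map(int, sig[0].points))
        want = {v * 10 + t for v in block_v for t in block_t}
        assert want <= got

    def test_single_subject_rejected(self):
        fm = SS.FitMap(np.zeros((3, 3)), np.arange(3), np.arange(3.0), "m")
        with pytest.raises(ValueError, match="2 subjects"):
            SS.group_cluster_inference(fm and [fm], SS.spatial_adjacency(
                np.zeros((3, 3)), 1.0), n_perm=100)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(22)
        coords = rng.uniform(0, 30, (8, 3))
        fms = [SS.FitMap(rng.normal(0.1, 0.2, (8, 6)), np.arange(8),
                         2.0 * np.arange(6), "m", f"s{i}") for i in range(5)]
        adj = SS.spatial_adjacency(coords, 12.0)
        a = SS.group_cluster_inference(fms, adj, n_perm=200, seed=9)
        b = SS.group_cluster_inference(fms, adj, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.t_map, b.t_map)
        assert [c.p for c in a.clusters] == [c.p for c in b.clusters]

    def test_group_result_save_load(self, tmp_path):
        rng = np.random.default_rng(23)
        coords = rng.uniform(0, 30, (8, 3))
        fms = [SS.FitMap(rng.normal(0.2, 0.1, (8, 6)), np.arange(8),
                         2.0 * np.arange(6), "m", f"s{i}") for i in range(5)]
        gr = SS.group_cluster_inference(fms, SS.spatial_adjacency(coords, 12.0),
                                        n_perm=150, seed=3)
        gr.save(tmp_path / "g.h5")
        back = SS.GroupResult.load(tmp_path / "g.h5")
        np.testing.assert_allclose(back.t_map, gr.t_map)
        np.testing.assert_array_equal(back.mask, gr.mask)
        assert len(back.clusters) == len(gr.clusters)
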