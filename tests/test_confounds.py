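"""Confound builders: motion expansions, tissue signals, aCompCor, spatial ICA
and the rule-based motion-component classifier."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from denoisebench.confounds import (
    AROMA_HYPERPLANE,
    ComponentFeatures,
    acompcor,
    aroma_features,
    classify_aroma,
    expand_motion,
    nonaggressive_remove,
    spatial_ica,
    tissue_signals,
)
from denoisebench.synthcohort import simulate_motion
from denoisebench.types import (
    CSF,
    GM,
    WM,
    AcquisitionGrid,
    BoldVolume,
    MotionTrace,
    TissueLabelMap,
)


def _random_trace(T=50, seed=0):
    return simulate_motion(T, "high", seed=seed)


class TestExpandMotion:
    @pytest.mark.parametrize("scheme,expected", [("mp6", 6), ("mp12", 12), ("mp24", 24)])
    def test_column_counts(self, scheme, expected):
        m = expand_motion(_random_trace(), scheme)
        assert m.values.shape[1] == expected
        assert m.tdof_cost == expected

    def test_derivatives_are_backward_differences(self):
        trace = _random_trace()
        m = expand_motion(trace, "mp12")
        d = m.values[:, 6:]
        assert np.allclose(d[0], 0.0)
        np.testing.assert_allclose(d[1:], np.diff(trace.params, axis=0))

    def test_constant_trace_drops_degenerate_columns_with_warning(self):
        trace = MotionTrace(params=np.ones((20, 6)))
        with pytest.warns(UserWarning, match="zero-variance"):
            m = expand_motion(trace, "mp24")
        # constant params and their squares are nonzero-variance? no: constant
        # columns have zero variance too, so everything degenerate is dropped
        assert m.values.shape[1] == 0 or m.values.std(axis=0).min() > 0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            expand_motion(_random_trace(), "mp36")


def _toy_tissue():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[:2] = GM
    labels[2] = WM
    labels[3] = CSF
    return TissueLabelMap(labels=labels)


def _toy_vol(data):
    grid = AcquisitionGrid(dims=data.shape[:3], n_volumes=data.shape[3])
    return BoldVolume(data=data, grid=grid, mask=np.ones(data.shape[:3], bool))


class TestTissueSignals:
    def test_constant_volume_gives_constant_gs(self):
        data = np.full((4, 4, 4, 5), 7.0)
        m = tissue_signals(_toy_vol(data), _toy_tissue(), which=("GS",))
        np.testing.assert_allclose(m.values[:, 0], 7.0)

    def test_wm_twice_csf(self):
        tissue = _toy_tissue()
        data = np.zeros((4, 4, 4, 6))
        data[tissue.csf] = np.arange(6.0)
        data[tissue.wm] = 2 * np.arange(6.0)
        m = tissue_signals(_toy_vol(data), tissue, which=("WM", "CSF"))
        np.testing.assert_allclose(m.values[:, 0], 2 * m.values[:, 1])

    def test_two_voxel_hand_mean(self):
        labels = np.zeros((2, 1, 1), dtype=int)
        labels[:] = GM
        tissue = TissueLabelMap(labels=labels)
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 0, 0] = [3, 2, 1]
        m = tissue_signals(_toy_vol(data), tissue, which=("GS",))
        np.testing.assert_allclose(m.values[:, 0], [2, 2, 2])

    def test_empty_class_names_the_tissue(self):
        labels = np.full((2, 2, 2), GM)
        with pytest.raises(ValueError, match="CSF"):
            tissue_signals(_toy_vol(np.ones((2, 2, 2, 4))), TissueLabelMap(labels=labels),
                           which=("CSF",))


class TestACompCor:
    def test_rank_one_field_recovers_latent(self, rng):
        tissue = _toy_tissue()
        T = 60
        latent = np.sin(np.linspace(0, 8 * np.pi, T))
        data = np.zeros((4, 4, 4, T))
        wmcsf = tissue.wm | tissue.csf
        weights = rng.standard_normal(wmcsf.sum())
        data[wmcsf] = np.outer(weights, latent) + 1e-6 * rng.standard_normal((wmcsf.sum(), T))
        m = acompcor(_toy_vol(data), tissue, n_components=3)
        r = np.corrcoef(m.values[:, 0], latent)[0, 1]
        assert abs(r) > 0.999

    def test_five_orthogonal_components(self, rng):
        tissue = _toy_tissue()
        data = rng.standard_normal((4, 4, 4, 40))
        m = acompcor(_toy_vol(data), tissue, n_components=5)
        assert m.values.shape[1] == 5
        gram = m.values.T @ m.values
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_voxel_order_invariance(self, rng):
        """Components do not depend on how WM/CSF voxels are laid out."""
        tissue = _toy_tissue()
        data = rng.standard_normal((4, 4, 4, 30))
        m1 = acompcor(_toy_vol(data), tissue, n_components=3)
        perm = np.transpose(data, (1, 0, 2, 3)).copy()  # swap x/y of a symmetric layout
        labels_t = np.transpose(tissue.labels, (1, 0, 2)).copy()
        m2 = acompcor(_toy_vol(perm), TissueLabelMap(labels=labels_t), n_components=3)
        np.testing.assert_allclose(np.abs(m1.values), np.abs(m2.values), atol=1e-8)

    def test_too_few_voxels_rejected(self):
        labels = np.zeros((2, 1, 1), dtype=int)
        labels[0] = WM
        tissue = TissueLabelMap(labels=labels)
        with pytest.raises(ValueError, match="voxels"):
            acompcor(_toy_vol(np.random.default_rng(0).normal(size=(2, 1, 1, 10))), tissue, 5)

    def test_csf_only_flag_uses_csf_mask(self, rng):
        tissue = _toy_tissue()
        data = rng.standard_normal((4, 4, 4, 30))
        # zero out WM: csf_only result must be unaffected, union result changes
        data2 = data.copy()
        data2[tissue.wm] = rng.standard_normal((tissue.wm.sum(), 30))
        a = acompcor(_toy_vol(data), tissue, 3, csf_only=True)
        b = acompcor(_toy_vol(data2), tissue, 3, csf_only=True)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


def _ica_testbed(rng, n_sources=3, dims=(8, 8, 8), T=80):
    grid = AcquisitionGrid(dims=dims, n_volumes=T)
    mask = np.ones(dims, bool)
    V = mask.sum()
    # independent super-Gaussian spatial sources, the classic ICA setting
    maps = rng.laplace(size=(n_sources, V))
    mixing = rng.standard_normal((T, n_sources))
    data = (mixing @ maps) + 0.01 * rng.standard_normal((T, V))
    vol = BoldVolume(
        data=data.T.reshape(*dims, T), grid=grid, mask=mask
    )
    return vol, maps


class TestSpatialICA:
    def test_recovers_planted_spatial_sources(self, rng):
        vol, maps = _ica_testbed(rng)
        comps = spatial_ica(vol, n_components=3, seed=0)
        for k in range(3):
            best = max(
                abs(np.corrcoef(maps[k], comps.maps[j])[0, 1]) for j in range(3)
            )
            assert best > 0.95

    def test_deterministic_given_seed(self, rng):
        vol, _ = _ica_testbed(rng)
        a = spatial_ica(vol, n_components=3, seed=7)
        b = spatial_ica(vol, n_components=3, seed=7)
        np.testing.assert_allclose(a.maps, b.maps, atol=1e-10)
        np.testing.assert_allclose(a.mixing, b.mixing, atol=1e-10)

    def test_model_order_precondition(self, rng):
        vol, _ = _ica_testbed(rng, T=20)
        with pytest.raises(ValueError, match="n_components"):
            spatial_ica(vol, n_components=20, seed=0)


def _feature_testbed(rng):
    dims = (8, 8, 8)
    labels = np.zeros(dims, dtype=int)
    labels[1:7, 1:7, 1:7] = GM
    labels[3:5, 3:5, 3:5] = CSF
    labels[0] = 4  # EDGE rim slab
    tissue = TissueLabelMap(labels=labels)
    grid = AcquisitionGrid(dims=dims, n_volumes=64)
    mask = labels > 0
    return tissue, grid, mask


class TestAromaFeatures:
    def test_map_inside_csf_has_unit_csf_fraction(self, rng):
        from denoisebench.confounds import IcaComponentSet

        tissue, grid, mask = _feature_testbed(rng)
        amap = np.zeros(mask.sum())
        csf_in_mask = tissue.csf[mask]
        amap[csf_in_mask] = 1.0
        mixing = rng.standard_normal((64, 1))
        comps = IcaComponentSet(maps=amap[None, :], mixing=mixing, mask=mask)
        motion = simulate_motion(64, "low", seed=0)
        f = aroma_features(comps, 0, tissue, motion, tr=2.5)
        assert f.csf_fraction == pytest.approx(1.0)
        assert f.edge_fraction == pytest.approx(0.0)

    def test_nyquist_tone_has_unit_hf_content(self, rng):
        from denoisebench.confounds import IcaComponentSet

        tissue, grid, mask = _feature_testbed(rng)
        amap = rng.uniform(0.5, 1.0, mask.sum())
        tone = np.cos(np.pi * np.arange(64))  # alternating = Nyquist
        comps = IcaComponentSet(maps=amap[None, :], mixing=tone[:, None], mask=mask)
        motion = simulate_motion(64, "low", seed=0)
        f = aroma_features(comps, 0, tissue, motion, tr=2.5)
        assert f.hf_content == pytest.approx(1.0)

    def test_mixing_equal_to_trans_x_has_unit_rp_correlation(self, rng):
        from denoisebench.confounds import IcaComponentSet

        tissue, grid, mask = _feature_testbed(rng)
        motion = simulate_motion(64, "high", seed=1)
        amap = rng.uniform(0.5, 1.0, mask.sum())
        comps = IcaComponentSet(
            maps=amap[None, :], mixing=motion.params[:, [0]].copy(), mask=mask
        )
        f = aroma_features(comps, 0, tissue, motion, tr=2.5)
        assert f.max_rp_correlation == pytest.approx(1.0, abs=1e-9)


class TestClassifyAroma:
    def test_csf_rule(self):
        f = ComponentFeatures(0.0, 0.2, 0.0, 0.0)
        assert classify_aroma(f) is True

    def test_hf_rule(self):
        f = ComponentFeatures(0.0, 0.0, 0.5, 0.0)
        assert classify_aroma(f) is True

    def test_all_zero_is_signal(self):
        f = ComponentFeatures(0.0, 0.0, 0.0, 0.0)
        assert classify_aroma(f) is False

    def test_hyperplane_rule(self):
        b0, b1, b2 = AROMA_HYPERPLANE
        # a point clearly on the noise side of the boundary
        f = ComponentFeatures(edge_fraction=0.9, csf_fraction=0.0, hf_content=0.0,
                              max_rp_correlation=0.9)
        assert b0 + b1 * 0.9 + b2 * 0.9 > 0
        assert classify_aroma(f) is True

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 0.5), st.floats(0, 0.5), st.floats(0, 0.5), st.floats(0, 0.5),
    )
    def test_monotone_in_every_feature(self, e, c, h, r, de, dc, dh, dr):
        """Increasing any feature never flips a noise call back to signal."""
        lo = ComponentFeatures(e, c, h, r)
        hi = ComponentFeatures(
            min(e + de, 1.0), min(c + dc, 1.0), min(h + dh, 1.0), min(r + dr, 1.0)
        )
        if classify_aroma(lo):
            assert classify_aroma(hi)


class TestNonaggressiveRemoval:
    def _vol_and_comps(self, rng, orthogonal=False):
        from denoisebench.confounds import IcaComponentSet

        dims, T, n = (6, 6, 6), 60, 3
        grid = AcquisitionGrid(dims=dims, n_volumes=T)
        mask = np.ones(dims, bool)
        if orthogonal:
            raw = rng.standard_normal((T, n))
            q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # zero-mean orthonormal
            mixing = q
        else:
            mixing = rng.standard_normal((T, n))
        maps = rng.standard_normal((n, mask.sum()))
        data = (mixing @ maps).T.reshape(*dims, T) + 0.1 * rng.standard_normal((*dims, T))
        vol = BoldVolume(data=data, grid=grid, mask=mask)
        return vol, IcaComponentSet(maps=maps, mixing=mixing, mask=mask)

    def test_empty_noise_set_is_identity(self, rng):
        vol, comps = self._vol_and_comps(rng)
        out = nonaggressive_remove(vol, comps, [])
        np.testing.assert_array_equal(out.data, vol.data)

    def test_all_flagged_equals_full_residual(self, rng):
        vol, comps = self._vol_and_comps(rng)
        out = nonaggressive_remove(vol, comps, [0, 1, 2])
        Y = vol.data[vol.mask].T
        X = np.column_stack([np.ones(Y.shape[0]), comps.mixing])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid_plus_intercept = Y - X[:, 1:] @ beta[1:]
        np.testing.assert_allclose(out.data[vol.mask].T, resid_plus_intercept, atol=1e-8)

    def test_orthogonal_mixing_matches_per_component_subtraction(self, rng):
        vol, comps = self._vol_and_comps(rng, orthogonal=True)
        out = nonaggressive_remove(vol, comps, [1])
        Y = vol.data[vol.mask].T
        Yc = Y - Y.mean(axis=0)
        m = comps.mixing[:, 1]
        mc = m - m.mean()
        proj = np.outer(mc, (mc @ Yc) / (mc @ mc))
        # nonaggressive with jointly (near-)orthogonal mixing ~ own projection
        np.testing.assert_allclose(out.data[vol.mask].T, Y - proj, atol=1e-6)

    def test_invalid_component_id_rejected(self, rng):
        vol, comps = self._vol_and_comps(rng)
        with pytest.raises(ValueError):
            nonaggressive_remove(vol, comps, [5])
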