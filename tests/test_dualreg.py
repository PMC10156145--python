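import numpy as np
import pytest

from dynecm.dualreg import (
    CollinearityError,
    NetworkTimecourses,
    TemplateSet,
    dual_regression_stage1,
    dual_regression_stage2,
    network_variability,
    template_mean_timecourses,
    temporal_variability,
)
from dynecm.dynamic import DynamicCentralitySeries, build_window_scheme
from tests.conftest import make_series


def _setup(rng, n_voxels=60, K=3, n_windows=8, orthogonal=True):
    """Mask + orthogonal zero-mean templates + a window scheme."""
    ser = make_series(rng, n_voxels=n_voxels, T=n_windows * 20)
    mask = ser.mask
    if orthogonal:
        maps = np.zeros((n_voxels, K))
        block = n_voxels // K
        for k in range(K):
            sl = slice(k * block, (k + 1) * block)
            maps[sl, k] = np.linspace(-1, 1, block)  # zero-mean, disjoint support
    else:
        maps = rng.standard_normal((n_voxels, K))
    templates = TemplateSet(mask=mask, maps=maps, names=tuple(f"n{k}" for k in range(K)))
    scheme = build_window_scheme(n_windows * 20, 20, n_windows)
    return mask, templates, scheme


class TestStage1:
    def test_exact_recovery_on_pure_template_columns(self, rng):
        mask, templates, scheme = _setup(rng)
        dyn_vals = np.tile(3.0 * templates.maps[:, 1:2], (1, scheme.n_windows))
        dyn = DynamicCentralitySeries(mask=mask, values=dyn_vals, scheme=scheme)
        tcs = dual_regression_stage1(dyn, templates)
        assert np.allclose(tcs.values[:, 1], 3.0, atol=1e-10)
        assert np.allclose(tcs.values[:, [0, 2]], 0.0, atol=1e-10)

    def test_duplicated_templates_rejected(self, rng):
        mask, templates, scheme = _setup(rng)
        dup = TemplateSet(
            mask=mask,
            maps=np.column_stack([templates.maps[:, 0], templates.maps[:, 0]]),
            names=("a", "b"),
        )
        dyn = DynamicCentralitySeries(
            mask=mask,
            values=np.abs(rng.standard_normal((mask.n_voxels, scheme.n_windows))),
            scheme=scheme,
        )
        with pytest.raises(CollinearityError, match="a.*b"):
            dual_regression_stage1(dyn, dup)

    def test_noisy_mixture_recovery(self, rng):
        mask, templates, scheme = _setup(rng, n_voxels=200, K=4, n_windows=30)
        truth = rng.standard_normal((scheme.n_windows, 4))
        clean = templates.maps @ truth.T
        noisy = clean + 0.3 * rng.standard_normal(clean.shape)
        dyn = DynamicCentralitySeries(mask=mask, values=noisy, scheme=scheme)
        tcs = dual_regression_stage1(dyn, templates)
        for k in range(4):
            r = np.corrcoef(tcs.values[:, k], truth[:, k])[0, 1]
            assert r > 0.95


class TestStage2:
    def test_noiseless_round_trip_recovers_templates(self, rng):
        mask, templates, scheme = _setup(rng, n_voxels=90, K=3, n_windows=12)
        truth = rng.standard_normal((scheme.n_windows, 3))
        dyn = DynamicCentralitySeries(
            mask=mask, values=templates.maps @ truth.T, scheme=scheme
        )
        tcs = dual_regression_stage1(dyn, templates)
        maps = dual_regression_stage2(dyn, tcs)
        for k in range(3):
            r = np.corrcoef(maps.maps[:, k], templates.maps[:, k])[0, 1]
            assert r > 0.999

    def test_constant_timecourses_rejected(self, rng):
        mask, templates, scheme = _setup(rng)
        tcs = NetworkTimecourses(
            subject_id="s",
            values=np.ones((scheme.n_windows, 3)),
            scheme=scheme,
            names=templates.names,
        )
        dyn = DynamicCentralitySeries(
            mask=mask,
            values=rng.standard_normal((mask.n_voxels, scheme.n_windows)),
            scheme=scheme,
        )
        with pytest.raises(CollinearityError, match="constant"):
            dual_regression_stage2(dyn, tcs)

    def test_noisy_recovery(self, rng):
        mask, templates, scheme = _setup(rng, n_voxels=300, K=3, n_windows=40)
        truth = rng.standard_normal((scheme.n_windows, 3))
        noisy = templates.maps @ truth.T + 0.2 * rng.standard_normal(
            (mask.n_voxels, scheme.n_windows)
        )
        dyn = DynamicCentralitySeries(mask=mask, values=noisy, scheme=scheme)
        maps = dual_regression_stage2(dyn, dual_regression_stage1(dyn, templates))
        for k in range(3):
            assert np.corrcoef(maps.maps[:, k], templates.maps[:, k])[0, 1] > 0.9


class TestVariability:
    def test_closed_form_values(self):
        assert temporal_variability(np.array([1.0, 3.0, 5.0])) == (2.0, 4.0)
        assert temporal_variability(np.array([4.0, 4.0, 4.0])) == (0.0, 0.0)

    def test_zero_iff_constant(self, rng):
        x = rng.standard_normal(10)
        sd, width = temporal_variability(x)
        assert sd > 0 and width > 0
        sd0, width0 = temporal_variability(np.full(10, x[0]))
        assert sd0 == 0.0 and width0 == 0.0

    def test_invariant_to_window_reordering(self, rng):
        mask, templates, scheme = _setup(rng)
        vals = rng.standard_normal((scheme.n_windows, 3))
        a = network_variability(
            NetworkTimecourses("s", vals, scheme, templates.names)
        )
        b = network_variability(
            NetworkTimecourses("s", vals[::-1].copy(), scheme, templates.names)
        )
        assert np.allclose(a[["sd", "range"]], b[["sd", "range"]])

    def test_needs_at_least_two_windows(self, rng):
        with pytest.raises(ValueError):
            temporal_variability(np.array([1.0]))


class TestTemplateSet:
    def test_all_zero_column_rejected(self, rng):
        mask, templates, _ = _setup(rng)
        maps = templates.maps.copy()
        maps[:, 1] = 0.0
        with pytest.raises(ValueError, match="n1"):
            TemplateSet(mask=mask, maps=maps, names=templates.names)

    def test_mask_mean_alternative_timecourses(self, rng):
        mask, templates, scheme = _setup(rng)
        maps = np.abs(templates.maps) + 0.01
        tset = TemplateSet(mask=mask, maps=maps, names=templates.names)
        dyn = DynamicCentralitySeries(
            mask=mask,
            values=np.abs(rng.standard_normal((mask.n_voxels, scheme.n_windows))),
            scheme=scheme,
        )
        tcs = template_mean_timecourses(dyn, tset)
        sel = maps[:, 0] >= 0.5 * maps[:, 0].max()
        assert np.allclose(tcs.values[:, 0], dyn.values[sel].mean(axis=0))
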