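"""PCA retention, varimax, scores, FWHM, and window construction."""

import numpy as np
import pytest

from aperislope.layout import default_layout
from aperislope.reduction import (
    ekc_retain,
    estimate_fwhm,
    fit_component_model,
    project_scores,
    run_spatial_pca,
    run_temporal_pca,
    segment_windows,
    varimax_criterion,
    varimax_rotate,
    window_scores,
)
from aperislope.slope import SlopeMaps
from aperislope.synth import CELLS


def two_factor_data(rng, n_cases=1000, loading=0.8):
    """6 standardized variables driven by two orthogonal factors."""
    f = rng.standard_normal((n_cases, 2))
    L = np.zeros((6, 2))
    L[:3, 0] = loading
    L[3:, 1] = loading
    unique_sd = np.sqrt(1 - loading**2)
    x = f @ L.T + unique_sd * rng.standard_normal((n_cases, 6))
    return x


class TestEkc:
    def test_single_variable(self):
        assert ekc_retain([1.0], n_cases=100, n_vars=1) == 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ekc_retain([1.0, 2.0], n_cases=100, n_vars=2)

    def test_two_factor_monte_carlo(self):
        """Two factors with loadings 0.8 on 6 variables: EKC retains 2 in
        >= 95% of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = two_factor_data(rng)
            x = (x - x.mean(0)) / x.std(0, ddof=1)
            lam = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
            hits += ekc_retain(lam, n_cases=1000, n_vars=6) == 2
        assert hits >= 95

    def test_pure_noise_retains_none(self):
        """Independent variables: no component passes in most seeds."""
        zeros = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((500, 8))
            lam = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
            zeros += ekc_retain(lam, n_cases=500, n_vars=8) == 0
        assert zeros > 20


def brute_force_varimax(A, sweeps=200):
    """Classic pairwise Jacobi-rotation oracle (Kaiser-normalized)."""
    A = np.asarray(A, dtype=float)
    h = np.sqrt((A**2).sum(axis=1))
    B = A / h[:, None]
    p, k = B.shape
    for _ in range(sweeps):
        changed = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = B[:, i], B[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                num = 2 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > 1e-12:
                    c, s = np.cos(phi), np.sin(phi)
                    B[:, i], B[:, j] = c * x + s * y, -s * x + c * y
                    changed = True
        if not changed:
            break
    return B * h[:, None]


class TestVarimax:
    def test_single_component_identity(self, rng):
        A = rng.standard_normal((8, 1))
        rotated, R = varimax_rotate(A)
        assert np.allclose(np.abs(rotated), np.abs(A))
        assert R.shape == (1, 1)

    def test_block_structure_preserved(self):
        A = np.zeros((6, 2))
        A[:3, 0] = 0.9
        A[3:, 1] = 0.7
        rotated, _ = varimax_rotate(A)
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(A), rel=1e-8
        )

    def test_matches_pairwise_jacobi_oracle(self, rng):
        A = rng.standard_normal((10, 3))
        rotated, R = varimax_rotate(A)
        oracle = brute_force_varimax(A)
        assert varimax_criterion(rotated) >= varimax_criterion(A) - 1e-12
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(oracle), rel=1e-6
        )
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-8)

    def test_communalities_conserved(self, rng):
        A = rng.standard_normal((12, 4))
        rotated, _ = varimax_rotate(A)
        assert np.allclose(
            (rotated**2).sum(axis=1), (A**2).sum(axis=1), atol=1e-8
        )

    def test_sign_convention(self, rng):
        A = rng.standard_normal((9, 3))
        rotated, _ = varimax_rotate(A)
        for j in range(3):
            peak = np.abs(rotated[:, j]).argmax()
            assert rotated[peak, j] > 0

    def test_rank_deficient_warns(self):
        A = np.ones((5, 2))
        with pytest.warns(UserWarning, match="rank"):
            rotated, _ = varimax_rotate(A)
        assert np.array_equal(rotated, A)


class TestScores:
    def test_loading_pattern_scores_unity(self, rng):
        x = two_factor_data(rng, n_cases=4000)
        model = fit_component_model(x, [f"v{i}" for i in range(6)])
        # a case lying exactly on one component's loading pattern
        load = model.loadings_rotated
        probe = model.mean + load[:, 0]
        s = project_scores(probe[None, :], model, components="rotated")
        assert s[0, 0] == pytest.approx(1.0, abs=0.15)
        assert abs(s[0, 1]) < 0.15

    def test_mean_data_scores_zero(self, rng):
        x = two_factor_data(rng)
        model = fit_component_model(x, list(range(6)))
        s = project_scores(model.mean[None, :], model)
        assert np.allclose(s, 0.0, atol=1e-10)

    def test_full_rank_reconstruction(self, rng):
        """With every component, loadings @ scores' reconstructs the data."""
        x = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
        model = fit_component_model(x, list(range(5)))
        s = project_scores(x, model, components="all")
        recon = model.mean + s @ model.loadings_unrotated.T
        assert np.allclose(recon, x, atol=1e-8)

    def test_variable_mismatch(self, rng):
        model = fit_component_model(rng.standard_normal((50, 4)), list(range(4)))
        with pytest.raises(ValueError):
            project_scores(rng.standard_normal((3, 5)), model)


def make_maps(values, times):
    P, C, ch, T = values.shape
    return SlopeMaps(
        values=values,
        participants=np.arange(1, P + 1),
        cells=list(CELLS),
        times=times,
        counts=np.full((P, len(CELLS)), 10),
        channel_labels=default_layout().labels,
    )


def three_source_maps(rng, n_participants=8, effect_scale=0.4, noise=0.12):
    """Condition slope maps driven by three regional sources with distinct
    temporal bursts, mimicking the generator's spatial structure."""
    layout = default_layout()
    times = -500.0 + np.arange(1024) * 1000.0 / 512.0
    w = np.stack([layout.gaussian_weights(g, 0.45)
                  for g in ("frontal", "central", "occipital")])
    centers = (250.0, 500.0, 750.0)
    base = np.exp(-0.5 * ((times[None, :] - np.array(centers)[:, None]) / 120.0) ** 2)
    P, C, ch, T = n_participants, 4, 56, times.size
    vals = np.full((P, C, ch, T), -1.5)
    for p in range(P):
        for c in range(C):
            amps = effect_scale * (1.0 + 0.5 * rng.standard_normal(3))
            act = (amps[:, None] * base)  # (3 sources, T)
            vals[p, c] -= w.T @ act
            vals[p, c] += noise * rng.standard_normal((ch, T))
    return make_maps(vals, times)


class TestSpatialTemporalPca:
    def test_three_sources_recovered_from_generator(self):
        """Slope maps from the three-source generator yield exactly the
        frontal/central/occipital retained components."""
        from aperislope.synth import SimConfig
        from conftest import generator_slope_maps

        maps = generator_slope_maps(
            SimConfig(n_participants=3, n_trials_per_cell=6, rng_seed=5)
        )
        model = run_spatial_pca(maps, layout=default_layout())
        names = [model.names[j] for j in np.flatnonzero(model.retained)]
        assert sorted(names) == ["central", "frontal", "occipital"]

    def test_three_constructed_sources_have_regional_peaks(self, rng):
        """Directly constructed 3-source maps: the rotated loadings peak in
        the three source regions (retention aside)."""
        layout = default_layout()
        maps = three_source_maps(rng)
        model = run_spatial_pca(maps, layout=layout)
        assert model.n_ekc >= 3
        assert sorted(model.names[:3]) == ["central", "frontal", "occipital"]

    def test_single_source(self, rng):
        layout = default_layout()
        times = -500.0 + np.arange(1024) * 1000.0 / 512.0
        w = layout.gaussian_weights("occipital", 0.45)
        burst = np.exp(-0.5 * ((times - 400.0) / 150.0) ** 2)
        vals = np.full((6, 4, 56, times.size), -1.5)
        for p in range(6):
            for c in range(4):
                amp = 0.5 + 0.2 * rng.standard_normal()
                vals[p, c] -= amp * np.outer(w, burst)
                vals[p, c] += 0.1 * rng.standard_normal((56, times.size))
        model = run_spatial_pca(make_maps(vals, times), layout=layout)
        retained_names = [model.names[j] for j in np.flatnonzero(model.retained)]
        assert retained_names == ["occipital"]

    def test_electrode_permutation_invariance(self, rng):
        maps = three_source_maps(rng)
        model = run_spatial_pca(maps)
        perm = rng.permutation(56)
        permuted = make_maps(maps.values[:, :, perm, :], maps.times)
        permuted.channel_labels = [maps.channel_labels[i] for i in perm]
        model_p = run_spatial_pca(permuted)
        assert model_p.n_ekc == model.n_ekc
        assert np.allclose(
            np.abs(model_p.loadings_rotated), np.abs(model.loadings_rotated[perm]),
            atol=1e-6,
        )

    def test_temporal_bursts_recovered(self, rng):
        """Two temporally disjoint bursts give two retained temporal
        components with non-overlapping FWHM intervals."""
        layout = default_layout()
        times = -500.0 + np.arange(1024) * 1000.0 / 512.0
        w = layout.gaussian_weights("central", 0.45)
        b1 = np.exp(-0.5 * ((times - 150.0) / 90.0) ** 2)
        b2 = np.exp(-0.5 * ((times - 900.0) / 90.0) ** 2)
        vals = np.full((8, 4, 56, times.size), -1.5)
        for p in range(8):
            for c in range(4):
                a1 = 0.5 + 0.25 * rng.standard_normal()
                a2 = 0.5 + 0.25 * rng.standard_normal()
                vals[p, c] -= np.outer(w, a1 * b1 + a2 * b2)
                vals[p, c] += 0.05 * rng.standard_normal((56, times.size))
        model, _ = run_temporal_pca(make_maps(vals, times))
        assert model.n_ekc >= 2
        # evaluate the two leading rotated loading curves directly
        t = np.asarray(model.variables)
        spans, peaks = [], []
        for j in range(2):
            fwhm, peak, _ = estimate_fwhm(t, model.loadings_rotated[:, j])
            spans.append((peak - fwhm / 2, peak + fwhm / 2))
            peaks.append(peak)
        spans = sorted(spans)
        assert spans[0][1] < spans[1][0]  # non-overlapping FWHM intervals
        peaks = sorted(peaks)
        assert abs(peaks[0] - 150.0) < 100.0
        assert abs(peaks[1] - 900.0) < 100.0


class TestFwhm:
    def test_gaussian_closed_form(self):
        t = np.linspace(-400.0, 400.0, 2001)
        sigma = 68.0
        curve = np.exp(-0.5 * (t / sigma) ** 2)
        fwhm, peak, truncated = estimate_fwhm(t, curve)
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, abs=0.5)
        assert peak == 0.0
        assert not truncated

    def test_triangle_exact(self):
        t = np.linspace(-200.0, 200.0, 401)
        curve = np.clip(1 - np.abs(t) / 100.0, 0, None)
        fwhm, _, _ = estimate_fwhm(t, curve)
        assert fwhm == pytest.approx(100.0, abs=1e-9)

    def test_noisy_gaussian_within_ten_percent(self):
        t = np.linspace(-500.0, 500.0, 1001)
        sigma = 68.0
        truth = 2 * np.sqrt(2 * np.log(2)) * sigma
        rng = np.random.default_rng(17)
        est = []
        for _ in range(30):
            curve = np.exp(-0.5 * (t / sigma) ** 2) + 0.1 * rng.standard_normal(
                t.size
            )
            # mild smoothing as a peak-finding stabilizer (SNR 10)
            curve = np.convolve(curve, np.ones(21) / 21, mode="same")
            fwhm, _, _ = estimate_fwhm(t, curve)
            est.append(fwhm)
        assert abs(np.median(est) - truth) / truth < 0.1

    def test_truncated_side_flagged(self):
        t = np.linspace(0.0, 300.0, 301)
        curve = np.exp(-0.5 * ((t - 20.0) / 100.0) ** 2)
        fwhm, _, truncated = estimate_fwhm(t, curve)
        assert truncated

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError):
            estimate_fwhm(np.arange(10.0), np.ones(10))


class TestWindows:
    def test_printed_window_list(self):
        ws = segment_windows(crop_ms=(-300.0, 1300.0), width_ms=160.0)
        assert ws.labels == [
            "[-160,0]", "(0,160]", "(160,320]", "(320,480]", "(480,640]",
            "(640,800]", "(800,960]", "(960,1120]", "(1120,1280]",
        ]
        assert ws.windows[-1].hi == 1280.0

    def test_symmetric_small_crop(self):
        ws = segment_windows(crop_ms=(-160.0, 160.0), width_ms=160.0)
        assert ws.labels == ["[-160,0]", "(0,160]"]

    def test_oversize_width_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(crop_ms=(-300.0, 1300.0), width_ms=1600.0)

    def test_boundary_membership(self):
        ws = segment_windows(crop_ms=(-300.0, 1300.0), width_ms=160.0)
        w_01, w_12 = ws.windows[1], ws.windows[2]
        assert w_01.contains(np.array([160.0]))[0]
        assert not w_12.contains(np.array([160.0]))[0]
        # t = 0 belongs to the (closed) pre-stimulus window, not to (0,160]
        assert ws.windows[0].contains(np.array([0.0]))[0]
        assert not w_01.contains(np.array([0.0]))[0]

    def test_window_means_match_masked_average(self, rng):
        ws = segment_windows()
        t = -300.0 + np.arange(820) * 1000.0 / 512.0
        x = rng.standard_normal((3, t.size))
        means = window_scores(x, t, ws)
        for k, w in enumerate(ws.windows):
            mask = w.contains(t)
            assert np.allclose(means[:, k], x[:, mask].mean(axis=1))

    def test_constant_series(self):
        ws = segment_windows()
        t = -300.0 + np.arange(820) * 1000.0 / 512.0
        means = window_scores(np.full((2, t.size), 3.14), t, ws)
        assert np.allclose(means, 3.14)


class TestComponentModelInvariants:
    def test_explained_variance_sums_to_one(self, rng):
        x = rng.standard_normal((300, 6)) @ rng.standard_normal((6, 6))
        model = fit_component_model(x, list(range(6)))
        total = model.eigenvalues / model.eigenvalues.sum()
        assert total.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(model.eigenvalues) <= 1e-10).all()

    def test_rotation_preserves_communalities(self, rng):
        x = two_factor_data(rng, n_cases=2000)
        model = fit_component_model(x, list(range(6)))
        assert np.allclose(
            model.communalities_rotated, model.communalities_unrotated, atol=1e-8
        )

    def test_retained_meet_one_over_x(self, rng):
        x = two_factor_data(rng)
        model = fit_component_model(x, list(range(6)))
        if model.n_ekc:
            thresh = 1.0 / model.n_ekc
            assert (
                model.explained_of_solution[model.retained] >= thresh - 1e-12
            ).all()
            assert model.explained_of_solution.sum() == pytest.approx(1.0)
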