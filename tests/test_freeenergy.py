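"""WHAM, block errors, tilting, force-extension, Debye screening."""

import numpy as np
import pandas as pd
import pytest

from chromoclutch.constants import KT_300K, PN_PER_KCAL_MOL_NM
from chromoclutch.freeenergy import (FreeEnergyProfile, UmbrellaWindow,
                                     block_errors, debye_cutoff, debye_length,
                                     harmonic_fit, marginalize, mean_extension,
                                     profile_from_samples, tilt, wham)
from chromoclutch.sampling import Bias


def gaussian_window(rng, k_true, x0, center, spring_k, n, cv="x",
                    temperature_K=300.0):
    """Exact sampler of a harmonic bias on a quadratic free energy.

    The biased density exp(-(0.5 k (x-x0)^2 + 0.5 kw (x-c)^2)/kBT) is a
    Gaussian with known mean and variance -- an analytic ground truth.
    """
    kT = KT_300K * temperature_K / 300.0
    prec = (k_true + spring_k) / kT
    mu = (k_true * x0 + spring_k * center) / (k_true + spring_k)
    x = rng.normal(mu, np.sqrt(1 / prec), n)
    b = Bias("umbrella", cv=cv, center=float(center), spring_k=spring_k)
    return UmbrellaWindow([b], pd.DataFrame({cv: x}))


def quadratic_profile(k=1.0, x0=5.0, lo=0.0, hi=10.0, nbins=200):
    x = np.linspace(lo, hi, nbins)
    return FreeEnergyProfile(cvs=("x",), axes=(x,), F=0.5 * k * (x - x0) ** 2)


class TestWham:
    def test_recovers_quadratic_truth(self, rng):
        k_true, x0 = 1.5, 5.0
        windows = [gaussian_window(rng, k_true, x0, c, 2.0, 20000)
                   for c in np.linspace(1, 9, 8)]
        prof = wham(windows, grid_spec={"x": (0.0, 10.0, 100)})
        xs = prof.axes[0]
        allx = np.concatenate([w.samples["x"] for w in windows])
        lo, hi = np.quantile(allx, [0.1, 0.9])
        m = (xs >= lo) & (xs <= hi) & np.isfinite(prof.F)
        F_true = 0.5 * k_true * (xs - x0) ** 2
        F_true -= F_true[m].min()
        rms = np.sqrt(np.mean((prof.F[m] - F_true[m]) ** 2))
        assert rms < 0.1

    def test_single_flat_window(self, rng):
        # spring -> 0 limit: uniform samples must give a flat profile
        x = rng.uniform(0, 10, 100000)
        b = Bias("umbrella", cv="x", center=5.0, spring_k=1e-12)
        prof = wham([UmbrellaWindow([b], pd.DataFrame({"x": x}))],
                    grid_spec={"x": (0.5, 9.5, 30)})
        spread = np.nanmax(prof.F) - np.nanmin(prof.F)
        assert spread < 3 * KT_300K * np.sqrt(30 / (len(x) / 30))

    def test_disjoint_windows_warn_and_flag(self, rng):
        w1 = gaussian_window(rng, 5.0, 0.0, 0.0, 50.0, 1000)
        w2 = gaussian_window(rng, 5.0, 40.0, 40.0, 50.0, 1000)
        with pytest.warns(UserWarning, match="shared occupied bin"):
            prof = wham([w1, w2], grid_spec={"x": (-5.0, 45.0, 100)})
        assert "poor_overlap" in prof.flags

    def test_invariant_under_constant_bias_shift(self, rng):
        # adding an arbitrary constant to each window's bias energy is
        # absorbed into the window free energies and cannot change F(x)
        windows = [gaussian_window(rng, 1.0, 5.0, c, 2.0, 5000)
                   for c in np.linspace(2, 8, 5)]
        import dataclasses
        shifted = [
            UmbrellaWindow(
                [dataclasses.replace(w.biases[0], offset=float(off))],
                w.samples)
            for w, off in zip(windows, rng.uniform(-30, 30, len(windows)))
        ]
        p1 = wham(windows, grid_spec={"x": (0.0, 10.0, 50)})
        p2 = wham(shifted, grid_spec={"x": (0.0, 10.0, 50)})
        assert np.allclose(p1.F, p2.F, equal_nan=True, atol=1e-6)

    def test_empty_grid_rejected(self, rng):
        w = gaussian_window(rng, 1.0, 5.0, 5.0, 2.0, 100)
        w.samples["x"] = 5.0
        with pytest.raises(ValueError, match="empty grid"):
            wham([w])

    def test_unvisited_bins_are_nan_not_zero(self, rng):
        w = gaussian_window(rng, 5.0, 5.0, 5.0, 10.0, 2000)
        prof = wham([w], grid_spec={"x": (0.0, 50.0, 100)})
        far = prof.axes[0] > 20
        assert np.all(np.isnan(prof.F[far]))

    def test_2d_marginal_matches_1d(self, rng):
        # independent quadratic wells in two CVs sampled jointly
        kx, ky = 1.0, 2.0
        windows = []
        for cx in np.linspace(2, 8, 4):
            for cy in np.linspace(2, 8, 4):
                bx = Bias("umbrella", cv="x", center=float(cx), spring_k=2.0)
                by = Bias("umbrella", cv="y", center=float(cy), spring_k=2.0)
                kT = KT_300K
                mx = (kx * 5 + 2 * cx) / (kx + 2)
                my = (ky * 5 + 2 * cy) / (ky + 2)
                n = 8000
                windows.append(UmbrellaWindow([bx, by], pd.DataFrame({
                    "x": rng.normal(mx, np.sqrt(kT / (kx + 2)), n),
                    "y": rng.normal(my, np.sqrt(kT / (ky + 2)), n),
                })))
        grid = {"x": (1.0, 9.0, 40), "y": (1.0, 9.0, 40)}
        p2d = wham(windows, grid_spec=grid)
        p1d = wham([UmbrellaWindow([w.biases[0]], w.samples[["x"]])
                    for w in windows], grid_spec={"x": grid["x"]})
        marg = marginalize(p2d, "x")
        both = np.isfinite(marg.F) & np.isfinite(p1d.F)
        mid = (marg.axes[0] > 2.5) & (marg.axes[0] < 7.5) & both
        diff = marg.F[mid] - p1d.F[mid]
        assert np.max(np.abs(diff - diff.mean())) < 0.2


class TestBlockErrors:
    def test_sd_of_three_blocks(self):
        # estimator returning per-block constants {1, 2, 3} -> err = sd = 1
        x = np.array([0.5, 1.5])
        calls = {"n": 0}

        # full estimate first, then blocks yielding {1, 2, 3} at bin 0
        # (bin 1 anchors the profile's zero reference)
        def estimator(windows):
            calls["n"] += 1
            val = {1: 2.0, 2: 1.0, 3: 2.0, 4: 3.0}[calls["n"]]
            return FreeEnergyProfile(cvs=("x",), axes=(x,),
                                     F=np.array([val, 0.0]))

        b = Bias("umbrella", cv="x", center=0.5, spring_k=1.0)
        w = UmbrellaWindow([b], pd.DataFrame({"x": np.linspace(0, 1, 9)}))
        prof = block_errors([w], estimator)
        assert prof.err[0] == pytest.approx(1.0)
        assert prof.err[1] == pytest.approx(0.0)

    def test_identical_blocks_zero_error(self, rng):
        b = Bias("umbrella", cv="x", center=5.0, spring_k=2.0)
        base = rng.normal(5, 0.5, 1000)
        w = UmbrellaWindow([b], pd.DataFrame({"x": np.tile(base, 3)}))
        prof = block_errors([w], lambda ws: wham(
            ws, grid_spec={"x": (3.0, 7.0, 20)}))
        assert np.nanmax(prof.err) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_noise_calibration(self, rng):
        # block estimates with iid N(0, sigma) noise: mean err ~ sigma
        sigma = 0.3
        errs = []
        x = np.array([0.0])
        for _ in range(1000):
            vals = rng.normal(0, sigma, 3)
            errs.append(np.std(vals, ddof=1))
        assert np.mean(errs) == pytest.approx(sigma * 0.886, rel=0.05)
        # 0.886 = E[sd]/sigma for n=3 Gaussian samples (c4 constant)


class TestTiltAndExtension:
    def test_zero_force_identity(self):
        prof = quadratic_profile()
        t = tilt(prof, 0.0)
        assert np.allclose(t.F, prof.F)

    def test_harmonic_minimum_shift(self):
        k = 0.8
        prof = quadratic_profile(k=k, x0=5.0, lo=-20, hi=30, nbins=2000)
        f = 2.0
        t = tilt(prof, f)
        expected = 5.0 + f / (PN_PER_KCAL_MOL_NM * k)
        assert t.min_location() == pytest.approx(expected, abs=0.05)

    def test_tilt_matches_pointwise_arithmetic(self, rng):
        x = np.linspace(0, 10, 50)
        F = rng.uniform(0, 5, 50)
        prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=F)
        t = tilt(prof, 3.0, n_scale=12)
        manual = prof.F - (3.0 / PN_PER_KCAL_MOL_NM) * 12 * x
        manual -= manual.min()
        assert np.allclose(t.F, manual)

    def test_gaussian_mean_linear_in_force(self):
        k = 0.5
        prof = quadratic_profile(k=k, x0=5.0, lo=-50, hi=60, nbins=4000)
        for f in (0.5, 1.0, 2.0, 3.0):
            got = mean_extension(prof, f) - mean_extension(prof, 0.0)
            assert got == pytest.approx(f / (PN_PER_KCAL_MOL_NM * k),
                                        rel=1e-3)

    def test_flat_profile_truncated_exponential(self):
        # flat F on [a, b] under force f: <x> of a truncated exponential
        a, b, f = 0.0, 10.0, 2.0
        nb = 20000
        x = np.linspace(a, b, nb)
        prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=np.zeros(nb))
        lam = f / PN_PER_KCAL_MOL_NM / KT_300K
        expected = (b - 1 / lam + a / (1 - np.exp(lam * (b - a)))
                    ) if False else (
            (np.exp(lam * b) * (lam * b - 1) - np.exp(lam * a) * (lam * a - 1))
            / (lam * (np.exp(lam * b) - np.exp(lam * a))))
        assert mean_extension(prof, f) == pytest.approx(expected, rel=1e-4)

    def test_monotone_in_force_for_random_profiles(self, rng):
        for _ in range(100):
            nb = 80
            x = np.sort(rng.uniform(0, 20, nb))
            F = rng.uniform(0, 8, nb)
            prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=F)
            ext = [mean_extension(prof, f) for f in np.linspace(0, 6, 7)]
            assert np.all(np.diff(ext) >= -1e-9)

    def test_all_bins_undefined_rejected(self):
        prof = FreeEnergyProfile(cvs=("x",), axes=(np.arange(5.0),),
                                 F=np.full(5, np.nan))
        with pytest.raises(ValueError, match="no defined bins"):
            mean_extension(prof, 1.0)


class TestHarmonicFit:
    def test_exact_quadratic_recovered(self):
        prof = quadratic_profile(k=1.3, x0=4.2, lo=0, hi=9, nbins=150)
        fit = harmonic_fit(prof)
        assert fit.k == pytest.approx(1.3, rel=1e-9)
        assert fit.x0 == pytest.approx(4.2, rel=1e-9)
        assert not fit.anharmonic

    def test_noisy_quadratic_within_tolerance(self, rng):
        x = np.linspace(0, 10, 120)
        F = 0.5 * 1.0 * (x - 5.0) ** 2 + rng.normal(0, 0.05, len(x))
        prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=F)
        fit = harmonic_fit(prof)
        assert fit.k == pytest.approx(1.0, rel=0.05)

    def test_flat_bottom_flagged_anharmonic(self):
        # flat over a wide central region, steep walls: poor quadratic fit
        x = np.linspace(0, 10, 200)
        F = np.where(np.abs(x - 5) < 3, 0.0, 10 * (np.abs(x - 5) - 3) ** 2)
        prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=F)
        assert harmonic_fit(prof).anharmonic


class TestDebye:
    def test_four_kappa_at_physiological_salt(self):
        assert debye_cutoff(0.15) == pytest.approx(3.14, abs=0.01)

    def test_square_root_scaling(self):
        assert debye_length(0.6) == pytest.approx(debye_length(0.15) / 2,
                                                  rel=1e-12)

    def test_high_salt_limit(self):
        vals = [debye_length(I) for I in (0.1, 1.0, 10.0, 100.0)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.05


class TestProfileFromSamples:
    def test_gaussian_samples_recover_quadratic(self, rng):
        sigma = 1.5
        x = rng.normal(0, sigma, 200000)
        prof = profile_from_samples(x, "x", bins=60, range_=(-4, 4))
        k_fit = harmonic_fit(prof, window_kcal=1.0).k
        assert k_fit == pytest.approx(KT_300K / sigma**2, rel=0.1)
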