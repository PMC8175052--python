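"""SFS weights, expected spectra, model fitting, LRT and bootstrap."""

import numpy as np
import pytest

from gbgc import likelihood as lk
from gbgc import simulate as sim


@pytest.fixture(scope="module")
def m1_spectra():
    """One dataset from M1 truth (lambda=3, B=0.5, ~1e5 sites, n=20)."""
    return sim.simulate_spectra(3.0, 0.5, n=20, gc=0.32, target_snps=1e5, seed=7)


@pytest.fixture(scope="module")
def m1_fits(m1_spectra):
    gc, n = 0.32, 20
    return {m: lk.fit_model(m1_spectra, lk.GBGCModelSpec(m, gc, n), n_starts=3)
            for m in lk.MODELS}


class TestSfsWeight:
    @pytest.mark.parametrize("n", [2, 10, 20])
    def test_neutral_limit(self, n):
        i = np.arange(1, n)
        assert np.allclose(lk.sfs_weight(i, n, 0.0), 1.0 / i, atol=1e-12)

    def test_n2_closed_form_across_B(self):
        for B in np.linspace(-10, 10, 81):
            if abs(B) < 2e-4:
                continue
            quad = lk.sfs_weight([1], 2, B)[0]
            assert quad == pytest.approx(lk.sfs_weight_n2_closed_form(B), abs=1e-8)

    def test_f1_of_one(self):
        assert lk.sfs_weight([1], 2, 1.0)[0] == pytest.approx(1.164, abs=5e-4)

    def test_high_frequency_excess_under_positive_B(self):
        """Favored (W->S) alleles are enriched above 1/i for i > n/2, and
        the normalized spectrum shifts mass from low to high classes."""
        for n in (10, 20):
            for B in (0.2, 0.8, 2.0):
                i = np.arange(1, n)
                F = lk.sfs_weight(i, n, B)
                high = i > n / 2
                assert (F[high] > 1.0 / i[high]).all()
                neutral = (1.0 / i) / (1.0 / i).sum()
                shape = F / F.sum()
                assert shape[0] < neutral[0]
                assert (shape[high] > neutral[high]).all()

    def test_series_continuous_at_switch(self):
        eps = 1e-4
        below = lk.sfs_weight(np.arange(1, 20), 20, eps * 0.99)
        above = lk.sfs_weight(np.arange(1, 20), 20, eps * 1.01)
        assert np.allclose(below, above, atol=1e-7)

    def test_nonfinite_B_raises(self):
        with pytest.raises(ValueError):
            lk.sfs_weight([1], 2, np.nan)


class TestExpectedSpectra:
    def _fit(self, lam=3.0, B=0.0, gc=0.32, n=20, **kw):
        return lk.GBGCFit(model="M1", n=n, gc=gc, lam=lam, B=B, theta_N=100.0,
                          theta_WS=100.0, r=np.ones(n - 1), **kw)

    def test_neutral_shape_identity(self):
        """At B=0 and no errors, E_WS/E_SW = (1-gc)/(lambda*gc) in every class."""
        mu = lk.expected_spectra(self._fit())
        ratio = mu["WS"] / mu["SW"]
        assert np.allclose(ratio, (1 - 0.32) / (3.0 * 0.32), rtol=1e-12)

    def test_mutational_equilibrium_flux_balance(self):
        gc = 1.0 / (1.0 + 3.0)
        mu = lk.expected_spectra(self._fit(gc=gc))
        assert mu["WS"].sum() == pytest.approx(mu["SW"].sum(), rel=1e-12)

    def test_misorientation_mixture(self):
        """e_N moves a fraction of singleton mass to the mirrored class."""
        clean = lk.expected_spectra(self._fit())
        mixed = lk.expected_spectra(self._fit(e_N=0.1))
        expect_top = 0.9 * clean["NN"][-1] + 0.1 * clean["NN"][0]
        assert mixed["NN"][-1] == pytest.approx(expect_top, rel=1e-12)
        assert mixed["NN"].sum() == pytest.approx(clean["NN"].sum(), rel=1e-12)

    def test_degenerate_gc_rejected(self):
        with pytest.raises(ValueError):
            lk.GBGCModelSpec("M1", 0.0, 20)


class TestFitModel:
    def test_m1_recovers_truth(self, m1_fits):
        fit = m1_fits["M1"]
        assert fit.converged
        assert fit.lam == pytest.approx(3.0, abs=0.15)
        assert fit.B == pytest.approx(0.5, abs=0.1)

    def test_m0_pins_B_at_zero(self, m1_fits):
        assert m1_fits["M0"].B == 0.0

    def test_loglik_nesting(self, m1_fits):
        """Adding parameters can only improve the maximized likelihood."""
        assert m1_fits["M1"].loglik >= m1_fits["M0"].loglik - 1e-6
        assert m1_fits["M1star"].loglik >= m1_fits["M1"].loglik - 1e-9
        assert m1_fits["M0star"].loglik >= m1_fits["M0"].loglik - 1e-9

    def test_strong_weak_label_symmetry(self, m1_spectra):
        """Swapping W<->S labels and gc -> 1-gc maps the MLE to
        (1/lambda, -B)."""
        import copy
        swapped = copy.deepcopy(m1_spectra)
        swapped.counts["WS"], swapped.counts["SW"] = (
            m1_spectra.counts["SW"].copy(), m1_spectra.counts["WS"].copy())
        swapped.counts["SS"], swapped.counts["WW"] = (
            m1_spectra.counts["WW"].copy(), m1_spectra.counts["SS"].copy())
        swapped.L_W, swapped.L_S = m1_spectra.L_S, m1_spectra.L_W
        f = lk.fit_model(m1_spectra, lk.GBGCModelSpec("M1", 0.32, 20), n_starts=3)
        g = lk.fit_model(swapped, lk.GBGCModelSpec("M1", 0.68, 20), n_starts=3)
        assert g.lam == pytest.approx(1.0 / f.lam, rel=1e-4)
        assert g.B == pytest.approx(-f.B, abs=1e-4)
        assert g.loglik == pytest.approx(f.loglik, abs=1e-6)

    def test_r_distortion_absorbed(self):
        """A bottleneck-like excess of intermediate classes is soaked up by
        r_i without biasing B."""
        r = np.ones(19)
        r[4:12] = 1.6
        s = sim.simulate_spectra(3.0, 0.3, 20, 0.32, 1e5, r=r, seed=42)
        fit = lk.fit_model(s, lk.GBGCModelSpec("M1", 0.32, 20), n_starts=3)
        assert fit.B == pytest.approx(0.3, abs=0.12)
        assert fit.r[7] == pytest.approx(1.6, rel=0.15)

    def test_empty_spectra_raises(self):
        empty = sim.simulate_spectra(3.0, 0.0, 20, 0.32, 0, seed=0)
        with pytest.raises(ValueError):
            lk.fit_model(empty, lk.GBGCModelSpec("M1", 0.32, 20))


class TestLikelihoodRatioTest:
    def _fit(self, model, ll, gc=0.32, n=20):
        return lk.GBGCFit(model=model, n=n, gc=gc, lam=3.0, B=0.0, theta_N=1,
                          theta_WS=1, r=np.ones(n - 1), loglik=ll)

    def test_critical_value_df1(self):
        res = lk.likelihood_ratio_test(self._fit("M0", 0.0),
                                       self._fit("M1", 3.841 / 2))
        assert res["df"] == 1
        assert res["p"] == pytest.approx(0.050, abs=5e-4)

    def test_identical_fits_give_p_one(self):
        res = lk.likelihood_ratio_test(self._fit("M0", -5.0), self._fit("M1", -5.0))
        assert res["p"] == 1.0

    def test_df_wiring(self):
        assert lk.likelihood_ratio_test(self._fit("M0", 0), self._fit("M1", 1))["df"] == 1
        assert lk.likelihood_ratio_test(self._fit("M1", 0), self._fit("M1star", 1))["df"] == 3
        assert lk.likelihood_ratio_test(self._fit("M0", 0), self._fit("M0star", 1))["df"] == 3

    def test_negative_statistic_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = lk.likelihood_ratio_test(self._fit("M0", 1.0), self._fit("M1", 0.5))
        assert res["statistic"] == 0.0
        assert res["p"] == 1.0


class TestBootstrap:
    def test_identity_resample_equals_point_fit(self, small_dataset):
        ds = small_dataset
        sites = ds.truth.rename(columns={"i": "derived_count"})
        spec = lk.GBGCModelSpec("M1", 0.32, 20)
        point = lk.fit_model(
            __import__("gbgc").spectra.build_spectra(sites, 20, 1e4, 5e3),
            spec, n_starts=3)
        res = lk.bootstrap_fit(sites, spec, n_reps=1, seed=1, L_W=1e4, L_S=5e3,
                               resample=False)
        assert res.fits["lambda"].iloc[0] == pytest.approx(point.lam, rel=1e-9)
        assert res.fits["B"].iloc[0] == pytest.approx(point.B, abs=1e-9)

    def test_bootstrap_mean_near_point_and_width_scaling(self):
        """Bootstrap mean of B tracks the point estimate, and the percentile
        interval shrinks roughly as 1/sqrt(sites) between 1e4 and 4e4."""
        spec = lk.GBGCModelSpec("M1", 0.32, 20)
        widths = {}
        for n_sites in (10_000, 40_000):
            s = sim.simulate_spectra(3.0, 0.4, 20, 0.32, n_sites, seed=9)
            rows = []
            for cat in ("SS", "WW", "SW", "WS"):
                for i in range(1, 20):
                    rows.extend([(cat, i)] * int(s.counts[cat][i - 1]))
            import pandas as pd
            sites = pd.DataFrame(rows, columns=["category", "derived_count"])
            point = lk.fit_model(s, spec, n_starts=3)
            res = lk.bootstrap_fit(sites, spec, n_reps=12, seed=5,
                                   L_W=s.L_W, L_S=s.L_S, n_starts=2)
            assert res.n_failed == 0
            se = res.fits["B"].std()
            assert res.summary["B"]["mean"] == pytest.approx(point.B, abs=3 * se)
            widths[n_sites] = (res.summary["B"]["q97.5"] - res.summary["B"]["q2.5"])
        ratio = widths[10_000] / widths[40_000]
        assert 1.2 < ratio < 3.5
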