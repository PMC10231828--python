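"""Continuous assignment: posteriors, binarization, summaries, validation."""

import math

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from otoscape import assignment as asg
from otoscape import isoscape as iso
from otoscape import synthetic as syn


def _toy_iso(mu_grid, mask=None, year=2000, contingent="southern"):
    mu = np.asarray(mu_grid, dtype=float)
    lat = np.arange(40.0, 40.0 + mu.shape[0])
    lon = np.arange(-70.0, -70.0 + mu.shape[1])
    coords = {"lat": lat, "lon": lon}
    if mask is None:
        mask = np.isfinite(mu)
    values = np.where(mask, mu, np.nan)
    return iso.Isoscape(
        year=year, contingent=contingent, months=[5, 6, 7],
        values=xr.DataArray(values, coords=coords, dims=("lat", "lon")),
        domain_mask=xr.DataArray(mask, coords=coords, dims=("lat", "lon")),
    )


class TestCombinedSigma:
    def test_default_components(self):
        vm = asg.VarianceModel(0.1, 0.29)
        assert asg.combined_sigma(vm) == pytest.approx(math.sqrt(0.0941))
        assert asg.combined_sigma(vm) == pytest.approx(0.3068, abs=5e-5)

    def test_single_component_limit(self):
        assert asg.combined_sigma(asg.VarianceModel(0.4, 0.0)) == 0.4

    def test_negative_component_rejected(self):
        with pytest.raises(asg.AssignmentError):
            asg.VarianceModel(-0.1, 0.2)

    def test_zero_sigma_rejected_by_likelihood(self):
        vm = asg.VarianceModel(0.0, 0.0)
        scape = _toy_iso(np.zeros((2, 2)))
        with pytest.raises(asg.AssignmentError):
            asg.posterior_surface(0.0, scape, vm)


class TestPosteriorSurface:
    def test_two_cell_density_ratio(self):
        """Posterior ratio between cells mu = y and mu = y + delta equals
        exp(delta^2 / (2 sigma^2))."""
        y, delta = -1.0, 0.4
        vm = asg.VarianceModel(0.1, 0.29)
        sigma = asg.combined_sigma(vm)
        scape = _toy_iso([[y, y + delta], [np.nan, np.nan]])
        ps = asg.posterior_surface(y, scape, vm)
        ratio = ps.posterior.values[0, 0] / ps.posterior.values[0, 1]
        assert ratio == pytest.approx(np.exp(delta**2 / (2 * sigma**2)))

    def test_flat_isoscape_gives_uniform_posterior(self):
        scape = _toy_iso(np.full((3, 4), -0.8))
        ps = asg.posterior_surface(-0.2, scape, asg.VarianceModel())
        assert np.allclose(ps.posterior.values, 1 / 12)

    def test_normalization_and_max_scaling(self, southern_iso,
                                           variance_model):
        ps = asg.posterior_surface(-0.6, southern_iso, variance_model)
        vals = ps.posterior.values[southern_iso.domain_mask.values]
        assert vals.sum() == pytest.approx(1.0, abs=1e-12)
        assert (vals >= 0).all()
        scaled = ps.scaled.values[southern_iso.domain_mask.values]
        assert scaled.max() == 1.0
        # scaled surface is a positive multiple of the posterior
        assert np.allclose(scaled * vals.max(), vals)

    def test_brute_force_density_oracle(self, southern_iso, variance_model):
        """Log-space posterior equals direct normal-density evaluation."""
        from scipy.stats import norm

        y = -0.45
        sigma = asg.combined_sigma(variance_model)
        mask = southern_iso.domain_mask.values
        mu = southern_iso.values.values[mask]
        dens = norm.pdf(y, loc=mu, scale=sigma)
        expected = dens / dens.sum()
        ps = asg.posterior_surface(y, southern_iso, variance_model)
        got = ps.posterior.values[mask]
        assert np.allclose(got, expected, rtol=1e-10)

    def test_far_off_range_fish_does_not_underflow(self, southern_iso,
                                                   variance_model):
        ps = asg.posterior_surface(25.0, southern_iso, variance_model)
        vals = ps.posterior.values[southern_iso.domain_mask.values]
        assert vals.sum() == pytest.approx(1.0, abs=1e-10)
        assert vals.max() > 0

    def test_prior_zero_cells_excluded(self):
        scape = _toy_iso(np.zeros((2, 2)))
        prior = xr.zeros_like(scape.values)
        prior.values[0, 0] = 1.0
        ps = asg.posterior_surface(0.0, scape, asg.VarianceModel(),
                                   prior=prior)
        assert ps.posterior.values[0, 0] == pytest.approx(1.0)
        assert np.isnan(ps.posterior.values[1, 1])

    def test_non_finite_observation_rejected(self):
        scape = _toy_iso(np.zeros((2, 2)))
        with pytest.raises(asg.AssignmentError):
            asg.posterior_surface(np.nan, scape, asg.VarianceModel())


class TestBinarize:
    def test_exact_count_distinct_values(self):
        mu = np.arange(8, dtype=float).reshape(2, 4)
        ps = asg.posterior_surface(7.0, _toy_iso(mu), asg.VarianceModel())
        bs = asg.binarize(ps, q=0.75)
        assert int(bs.likely.values.sum()) == math.ceil(0.25 * 8)
        # the two largest-posterior cells (mu closest to y = 7)
        assert bs.likely.values[1, 3] and bs.likely.values[1, 2]

    def test_ties_broken_deterministically(self):
        ps = asg.posterior_surface(0.0, _toy_iso(np.zeros((2, 4))),
                                   asg.VarianceModel())
        bs = asg.binarize(ps, q=0.75)
        assert int(bs.likely.values.sum()) == 2
        # lat index ascending, then lon index ascending
        assert bs.likely.values[0, 0] and bs.likely.values[0, 1]

    def test_half_quantile_count(self):
        mu = np.arange(10, dtype=float).reshape(2, 5)
        ps = asg.posterior_surface(0.0, _toy_iso(mu), asg.VarianceModel())
        bs = asg.binarize(ps, q=0.5)
        assert int(bs.likely.values.sum()) == 5

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.7])
    def test_quantile_domain_checked(self, q):
        ps = asg.posterior_surface(0.0, _toy_iso(np.zeros((2, 4))),
                                   asg.VarianceModel())
        with pytest.raises(asg.AssignmentError):
            asg.binarize(ps, q=q)

    def test_likely_sets_nested_in_q(self, southern_iso, variance_model):
        rng = np.random.default_rng(5)
        for y in rng.uniform(-2, 1, 5):
            ps = asg.posterior_surface(y, southern_iso, variance_model)
            prev = None
            for q in (0.25, 0.5, 0.75, 0.9):
                cur = asg.binarize(ps, q).likely.values
                if prev is not None:
                    assert (cur <= prev).all()   # subset of the looser set
                prev = cur


class TestSummarize:
    def test_identical_surfaces_reproduce_surface(self):
        ps = asg.posterior_surface(2.0, _toy_iso(np.arange(8.).reshape(2, 4)),
                                   asg.VarianceModel())
        b = asg.binarize(ps, 0.75)
        sm = asg.summarize([b, b, b], year_class=2000)
        assert np.array_equal(sm.values.values, b.likely.values.astype(float))
        assert sm.n_fish == 3

    def test_disjoint_surfaces_average_to_half(self):
        mu = np.arange(8.).reshape(2, 4)
        b1 = asg.binarize(asg.posterior_surface(0.0, _toy_iso(mu),
                                                asg.VarianceModel()), 0.75)
        b2 = asg.binarize(asg.posterior_surface(7.0, _toy_iso(mu),
                                                asg.VarianceModel()), 0.75)
        assert not (b1.likely.values & b2.likely.values).any()
        sm = asg.summarize([b1, b2], year_class=2000)
        marked = b1.likely.values | b2.likely.values
        assert np.allclose(sm.values.values[marked], 0.5)
        assert np.allclose(sm.values.values[~marked], 0.0)

    def test_fraction_of_fish(self):
        mu = np.arange(8.).reshape(2, 4)
        hit = asg.binarize(asg.posterior_surface(0.0, _toy_iso(mu),
                                                 asg.VarianceModel()), 0.75)
        miss = asg.binarize(asg.posterior_surface(7.0, _toy_iso(mu),
                                                  asg.VarianceModel()), 0.75)
        sm = asg.summarize([hit, hit, hit, miss], year_class=2000)
        assert sm.values.values[0, 0] == pytest.approx(0.75)

    def test_empty_list_rejected(self):
        with pytest.raises(asg.AssignmentError):
            asg.summarize([], year_class=2000)


class TestValidation:
    def _setup(self, southern_iso, masks):
        sub = {k: masks[k] for k in syn.SUBREGION_NAMES}
        return sub

    def test_whole_domain_subregion_always_correct(self, southern_iso,
                                                   variance_model):
        whole = xr.DataArray(
            southern_iso.domain_mask.values.copy(),
            coords=southern_iso.domain_mask.coords, dims=("lat", "lon"))
        fish = pd.DataFrame([{"fish_id": "f", "d18o": -0.4,
                              "year_class": 2013, "subregion": "ALL"}])
        acc = asg.validate(fish, {2013: southern_iso}, variance_model,
                           {"ALL": whole}, q=0.75)
        assert acc == 1.0

    def test_disjoint_subregion_is_error(self, southern_iso, variance_model):
        empty = xr.DataArray(
            np.zeros(southern_iso.domain_mask.shape, dtype=bool),
            coords=southern_iso.domain_mask.coords, dims=("lat", "lon"))
        fish = pd.DataFrame([{"fish_id": "f", "d18o": -0.4,
                              "year_class": 2013, "subregion": "NOWHERE"}])
        with pytest.raises(asg.AssignmentError, match="NOWHERE"):
            asg.validate(fish, {2013: southern_iso}, variance_model,
                         {"NOWHERE": empty}, q=0.75)

    def test_low_noise_fish_assigned_near_truth(self, scfg, southern_iso,
                                                masks):
        vm = asg.VarianceModel(0.02, 0.0)   # noise far below spatial gradient
        sub = self._setup(southern_iso, masks)
        cfg = syn.SyntheticConfig(seed=9, sigma_analytical=0.02,
                                  sigma_within_pop=0.0)
        fish = syn.gen_known_origin_fish(cfg, southern_iso, 40, sub)
        acc = asg.validate(fish, {2013: southern_iso}, vm, sub, q=0.75)
        assert acc >= 0.9

    def test_sweep_monotone_and_floor_semantics(self, scfg, southern_iso,
                                                masks, variance_model):
        sub = self._setup(southern_iso, masks)
        fish = syn.gen_known_origin_fish(scfg, southern_iso, 40, sub)
        grid = np.linspace(0.05, 0.95, 10)
        curve = asg.threshold_sweep(fish, {2013: southern_iso},
                                    variance_model, sub, q_grid=grid)
        # nested likely sets make accuracy non-increasing in q
        assert (np.diff(curve.accuracy) <= 1e-12).all()
        # floor 0 -> most precise (largest) threshold chosen
        loose = asg.threshold_sweep(fish, {2013: southern_iso},
                                    variance_model, sub, q_grid=grid,
                                    floor=0.0)
        assert loose.chosen == pytest.approx(grid[-1])
        # unattainable floor -> no threshold chosen
        strict = asg.threshold_sweep(fish, {2013: southern_iso},
                                     variance_model, sub, q_grid=grid,
                                     floor=1.01)
        assert strict.chosen is None


def test_assign_fish_skips_unassigned(southern_iso, variance_model):
    adults = pd.DataFrame([
        {"fish_id": "a", "d18o": -0.5, "year_class": 2013,
         "decision": "southern"},
        {"fish_id": "b", "d18o": -0.5, "year_class": 2013,
         "decision": "unassigned"},
    ])
    surfaces, binaries, summaries = asg.assign_fish(
        adults, {("southern", 2013): southern_iso},
        variance_model, q=0.75)
    assert [s.fish_id for s in surfaces] == ["a"]
    assert len(summaries) == 1 and summaries[0].n_fish == 1
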