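"""Hardy-Weinberg genotype drawing and the carrier phenotype model."""

import dataclasses

import numpy as np
import pytest

from gvkernel import (
    InputError,
    SimulationConfig,
    center_phenotype,
    power_experiment,
    simulate_genotypes,
    simulate_phenotype,
)


def cfg(**kw) -> SimulationConfig:
    base = dict(n=100, site_freqs=(0.1, 0.2), genotype_seed=1, phenotype_seed=2)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("freqs", [(0.0,), (1.0,), (-0.1,), (0.5, 1.2), ()])
    def test_frequencies_must_be_in_open_unit_interval(self, freqs):
        with pytest.raises(InputError):
            cfg(site_freqs=freqs)

    def test_noise_sd_must_be_positive(self):
        with pytest.raises(InputError):
            cfg(noise_sd=0.0)

    def test_policies_are_checked(self):
        with pytest.raises(InputError):
            cfg(monomorphic="ignore")
        with pytest.raises(InputError):
            cfg(effect_mode="recessive")


def test_genotype_marginals_match_hwe_proportions():
    n = 100_000
    config = cfg(n=n, site_freqs=(0.5,), genotype_seed=11)
    (site,) = simulate_genotypes(config)
    het_frac = site.b.sum() / n
    hom_alt_frac = site.c.sum() / n
    # three binomial standard deviations around 2p(1-p) and p^2
    assert abs(het_frac - 0.5) < 3 * np.sqrt(0.5 * 0.5 / n)
    assert abs(hom_alt_frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


def test_genotypes_are_deterministic_given_seed():
    a = simulate_genotypes(cfg())
    b = simulate_genotypes(cfg())
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.g, sb.g)
        assert sa.site_id == sb.site_id


def test_extremely_rare_site_with_drop_policy_may_vanish_silently():
    config = cfg(n=50, site_freqs=(1e-4,), genotype_seed=3)
    sites = simulate_genotypes(config)
    assert isinstance(sites, list)  # possibly empty; never an error


def test_redraw_policy_always_returns_polymorphic_sites():
    config = cfg(n=30, site_freqs=(0.01, 0.02), monomorphic="redraw", genotype_seed=4)
    sites = simulate_genotypes(config)
    assert len(sites) == 2
    for s in sites:
        assert 0 < s.g.sum() < 2 * s.n


def test_null_phenotype_is_pure_gaussian_noise():
    config = cfg(n=50_000, carrier_effect=0.0, phenotype_seed=8)
    sites = simulate_genotypes(config)
    y = simulate_phenotype(sites, config)
    assert abs(y.mean()) < 3 / np.sqrt(config.n)
    assert abs(y.std() - 1.0) < 0.02


def test_carrier_shift_recovers_the_effect_size():
    n = 100_000
    config = cfg(n=n, site_freqs=(0.3,), carrier_effect=-1.0, genotype_seed=5, phenotype_seed=6)
    sites = simulate_genotypes(config)
    y = simulate_phenotype(sites, config)
    carriers = sites[0].g > 0
    diff = y[carriers].mean() - y[~carriers].mean()
    se = np.sqrt(1 / carriers.sum() + 1 / (~carriers).sum())
    assert abs(diff - (-1.0)) < 3 * se


def test_noiseless_limit_splits_cohort_into_two_trait_values():
    config = cfg(n=500, site_freqs=(0.2,), noise_sd=1e-12, genotype_seed=7, phenotype_seed=8)
    sites = simulate_genotypes(config)
    y = np.round(simulate_phenotype(sites, config), 6)
    assert set(np.unique(y)) == {-1.0, 0.0}


def test_additive_mode_shifts_once_per_causal_site():
    config = cfg(
        n=2000,
        site_freqs=(0.3, 0.4),
        noise_sd=1e-12,
        effect_mode="additive",
        genotype_seed=9,
        phenotype_seed=10,
    )
    sites = simulate_genotypes(config)
    y = simulate_phenotype(sites, config)
    carried = sum((s.g > 0).astype(int) for s in sites)
    np.testing.assert_allclose(y, -1.0 * carried, atol=1e-9)


def test_phenotype_with_no_causal_sites_requires_zero_effect():
    config = cfg(carrier_effect=-1.0)
    with pytest.raises(InputError):
        simulate_phenotype([], config)
    null = dataclasses.replace(config, carrier_effect=0.0)
    y = simulate_phenotype([], null)
    assert y.shape == (config.n,)


class TestPowerExperiment:
    def test_deterministic_under_master_seed(self):
        config = cfg(n=200, site_freqs=(0.05, 0.1))
        a = power_experiment(config, replicates=4, B=99, alpha=0.5, master_seed=3)
        b = power_experiment(config, replicates=4, B=99, alpha=0.5, master_seed=3)
        assert a == b

    def test_degenerate_alpha_one_rejects_everything(self):
        config = cfg(n=100, site_freqs=(0.1,), carrier_effect=0.0)
        res = power_experiment(config, replicates=5, B=19, alpha=1.0, master_seed=1)
        assert res.rejections == res.replicates == 5

    def test_power_does_not_decrease_with_effect_size(self):
        config0 = cfg(n=400, site_freqs=(0.05, 0.1), carrier_effect=0.0)
        config1 = dataclasses.replace(config0, carrier_effect=-1.0)
        null = power_experiment(config0, replicates=20, B=199, alpha=0.05, master_seed=17)
        alt = power_experiment(config1, replicates=20, B=199, alpha=0.05, master_seed=17)
        assert alt.rejections >= null.rejections

    def test_replicate_count_validated(self):
        with pytest.raises(InputError):
            power_experiment(cfg(), replicates=0, B=9, alpha=0.5, master_seed=0)
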