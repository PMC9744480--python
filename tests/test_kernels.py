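"""Fast per-site statistics, weights and the aggregated set statistic."""

import numpy as np
import pytest

from gvkernel import (
    GRM,
    IBS,
    InputError,
    WeightScheme,
    build_genotype_site,
    center_phenotype,
    kernel_statistic,
    q_statistic,
    r_statistic,
    resolve_weights,
)
from gvkernel.oracle import grm_matrix, ibs_matrix, quadratic_form

from conftest import make_centered, make_random_site


@pytest.fixture
def y2():
    return center_phenotype([1.0, -1.0])


@pytest.mark.parametrize(
    "calls,q,r",
    [
        (["0/1", "0/0"], 1.0, 2.0),
        (["1/1", "0/0"], 4.0, 4.0),
    ],
)
def test_per_site_statistics_on_two_individual_examples(y2, calls, q, r):
    site = build_genotype_site(calls)
    assert q_statistic(y2, site) == pytest.approx(q, rel=1e-12)
    assert r_statistic(y2, site) == pytest.approx(r, rel=1e-12)


def test_zero_phenotype_annihilates_both_statistics(rng):
    y = center_phenotype(np.zeros(6))
    site = make_random_site(rng, 6)
    assert q_statistic(y, site) == 0.0
    assert r_statistic(y, site) == 0.0


def test_length_mismatch_is_an_input_error(y2):
    site = build_genotype_site(["0/0", "0/1", "1/1"])
    with pytest.raises(InputError):
        q_statistic(y2, site)
    with pytest.raises(InputError):
        r_statistic(y2, site)


class TestWeights:
    def test_uniform_resolves_to_ones(self):
        sites = [build_genotype_site(["0/1", "0/0"]) for _ in range(3)]
        np.testing.assert_array_equal(resolve_weights(WeightScheme.uniform(), sites), [1, 1, 1])

    def test_custom_is_passthrough(self):
        sites = [build_genotype_site(["0/1", "0/0"]) for _ in range(2)]
        np.testing.assert_array_equal(
            resolve_weights(WeightScheme.custom_weights([0.5, 2.0]), sites), [0.5, 2.0]
        )

    def test_beta_1_1_is_flat(self):
        sites = [
            build_genotype_site(["0/1", "0/0"]),
            build_genotype_site(["0/1", "0/1", "1/1", "0/0"]),
        ]
        np.testing.assert_allclose(
            resolve_weights(WeightScheme.beta(1.0, 1.0), sites), [1.0, 1.0]
        )

    def test_beta_upweights_rarer_sites(self):
        rare = build_genotype_site(["0/1"] + ["0/0"] * 49)
        common = build_genotype_site(["0/1"] * 25 + ["0/0"] * 25)
        w = resolve_weights(WeightScheme.beta(1.0, 25.0), [rare, common])
        assert w[0] > w[1]

    def test_negative_custom_weight_rejected(self):
        with pytest.raises(InputError):
            WeightScheme.custom_weights([1.0, -0.5])
        sites = [build_genotype_site(["0/1", "0/0"])]
        with pytest.raises(InputError):
            resolve_weights(WeightScheme(kind="custom", custom=(-1.0,)), sites)

    def test_custom_length_mismatch_rejected(self):
        sites = [build_genotype_site(["0/1", "0/0"])] * 3
        with pytest.raises(InputError):
            resolve_weights(WeightScheme.custom_weights([1.0, 2.0]), sites)


class TestAggregate:
    def test_single_site_equals_per_site_statistic(self, y2):
        site = build_genotype_site(["0/1", "0/0"])
        res = kernel_statistic(y2, [site], kernel=GRM)
        assert res.S == pytest.approx(q_statistic(y2, site), rel=1e-12)

    def test_two_identical_sites_double_the_statistic(self, y2):
        site = build_genotype_site(["0/1", "0/0"])
        res = kernel_statistic(y2, [site, site], kernel=GRM)
        assert res.S == pytest.approx(2 * q_statistic(y2, site), rel=1e-12)

    def test_worked_two_site_example_sums_to_five(self, y2):
        sites = [build_genotype_site(["0/1", "0/0"]), build_genotype_site(["1/1", "0/0"])]
        assert kernel_statistic(y2, sites, kernel=GRM).S == pytest.approx(5.0, rel=1e-12)

    def test_empty_site_list_rejected(self, y2):
        with pytest.raises(InputError):
            kernel_statistic(y2, [])

    def test_aggregate_matches_weighted_sum_of_per_site(self, rng):
        y = make_centered(rng, 30)
        sites = [make_random_site(rng, 30) for _ in range(10)]
        w = rng.random(10)
        for kernel in (GRM, IBS):
            res = kernel_statistic(y, sites, WeightScheme.custom_weights(w), kernel)
            parts = [st.Q if kernel == GRM else st.R for st in res.per_site]
            assert res.S == pytest.approx(float(np.dot(w, parts)), rel=1e-12)

    def test_kernel_name_is_case_insensitive(self, y2):
        site = build_genotype_site(["0/1", "0/0"])
        assert kernel_statistic(y2, [site], kernel="ibs").kernel == IBS
        with pytest.raises(InputError):
            kernel_statistic(y2, [site], kernel="linear")


class TestAlgebraicProperties:
    def test_fast_path_matches_matrix_oracle(self, rng):
        """Q and R agree with the explicit yᵀKy on random small instances."""
        for _ in range(150):
            n = int(rng.integers(2, 31))
            y = make_centered(rng, n)
            site = make_random_site(rng, n)
            q_ref = quadratic_form(y, grm_matrix(site))
            r_ref = quadratic_form(y, ibs_matrix(site))
            assert q_statistic(y, site) == pytest.approx(q_ref, rel=1e-9, abs=1e-9)
            assert r_statistic(y, site) == pytest.approx(r_ref, rel=1e-9, abs=1e-9)

    def test_statistics_scale_quadratically_in_the_phenotype(self, rng):
        y = make_centered(rng, 20)
        site = make_random_site(rng, 20)
        for lam in (-3.0, 0.5, 7.25):
            scaled = center_phenotype(lam * y.values)
            assert q_statistic(scaled, site) == pytest.approx(
                lam**2 * q_statistic(y, site), rel=1e-9
            )
            assert r_statistic(scaled, site) == pytest.approx(
                lam**2 * r_statistic(y, site), rel=1e-9
            )

    def test_rare_site_identity_r_equals_twice_q(self, rng):
        """Without hom-alt carriers, yᵀa = −yᵀb makes R exactly 2Q."""
        from gvkernel import GenotypeSite

        for _ in range(50):
            n = int(rng.integers(2, 40))
            site = GenotypeSite.from_genotype_values(rng.integers(0, 2, n))
            y = make_centered(rng, n)
            q = q_statistic(y, site)
            r = r_statistic(y, site)
            assert r == pytest.approx(2 * q, rel=1e-12, abs=1e-12)

    def test_joint_permutation_of_phenotype_and_genotypes_is_invariant(self, rng):
        from gvkernel import GenotypeSite, PhenotypeVector

        n = 25
        y = make_centered(rng, n)
        sites = [make_random_site(rng, n) for _ in range(4)]
        perm = rng.permutation(n)
        y_p = PhenotypeVector(y.values[perm])
        sites_p = [GenotypeSite.from_genotype_values(s.g[perm], s.site_id) for s in sites]
        for kernel in (GRM, IBS):
            before = kernel_statistic(y, sites, kernel=kernel).S
            after = kernel_statistic(y_p, sites_p, kernel=kernel).S
            assert after == pytest.approx(before, rel=1e-12)

    def test_monomorphic_site_contributes_exactly_zero(self, rng):
        y = make_centered(rng, 10)
        mono = build_genotype_site(["0/0"] * 10)
        assert q_statistic(y, mono) == 0.0
        assert r_statistic(y, mono) == pytest.approx(0.0, abs=1e-24)
        poly = build_genotype_site(["0/1"] * 3 + ["0/0"] * 7)
        with_mono = kernel_statistic(y, [poly, mono], kernel=GRM).S
        without = kernel_statistic(y, [poly], kernel=GRM).S
        assert with_mono == pytest.approx(without, rel=1e-12)
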