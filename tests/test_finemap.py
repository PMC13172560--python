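"""Wakefield log-ABF, PIP normalisation and credible-set construction."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from locusfine import LocusTable, PriorSpec, credible_set, finemap_locus, log_abf, pips
from locusfine.finemap import FinemapError, ZScaleWarning, finemap_zscores

from conftest import make_record


def abf_by_integration(z: float, se: float, W: float) -> float:
    """Independent oracle: the normal-normal marginal-likelihood ratio
    int N(bhat; b, V) N(b; 0, W) db / N(bhat; 0, V) by adaptive
    quadrature over posterior-centred finite limits."""
    V = se * se
    bhat = z * se
    mu = bhat * W / (V + W)
    sd = math.sqrt(V * W / (V + W))
    num = quad(
        lambda b: norm.pdf(bhat, b, math.sqrt(V)) * norm.pdf(b, 0, math.sqrt(W)),
        mu - 12 * sd, mu + 12 * sd, epsabs=0, epsrel=1e-12,
    )[0]
    return num / norm.pdf(bhat, 0, math.sqrt(V))


class TestLogABF:
    @pytest.mark.parametrize("z,se", [(0.0, 1.0), (5.0, 0.3), (-17.2, 0.01)])
    def test_zero_prior_variance_forces_unit_bf(self, z, se):
        assert log_abf(z, se, 0.0) == 0.0

    def test_null_z_closed_form(self):
        # 0.5 * ln(1 - 0.04/1.04)
        assert log_abf(0.0, 1.0, 0.04) == pytest.approx(-0.0196104, abs=1e-7)

    def test_strong_signal_closed_form(self):
        # 0.5 * (ln 0.2 + 0.8 * 100)
        assert log_abf(10.0, 0.1, 0.04) == pytest.approx(39.19528, abs=1e-5)

    def test_oracle_equivalence_random_grid(self, rng):
        for _ in range(100):
            z = rng.uniform(-8, 8)
            se = rng.uniform(0.01, 1.0)
            W = rng.uniform(0.001, 1.0)
            expected = abf_by_integration(z, se, W)
            assert math.exp(log_abf(z, se, W)) == pytest.approx(
                expected, rel=1e-6
            )

    def test_monotone_in_z_squared(self):
        vals = [log_abf(z, 0.05, 0.04) for z in (0.0, 1.0, 2.0, 5.0, 10.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("se,W", [(0.0, 0.04), (-1.0, 0.04), (0.1, -0.01)])
    def test_domain_errors(self, se, W):
        with pytest.raises(FinemapError):
            log_abf(1.0, se, W)


class TestPips:
    def test_single_variant(self):
        assert pips([3.7]).tolist() == [1.0]

    def test_symmetry(self):
        np.testing.assert_allclose(pips([2.0, 2.0]), [0.5, 0.5])

    def test_closed_form_normalisation(self):
        np.testing.assert_allclose(
            pips([0.0, math.log(3.0)]), [0.25, 0.75], atol=1e-12
        )

    def test_huge_labf_no_overflow(self):
        out = pips([9000.0, 10000.0, 0.0])
        assert np.isfinite(out).all()
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[1] == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        labf = rng.uniform(-5, 50, 30)
        np.testing.assert_allclose(
            pips(labf), pips(labf + 123.456), atol=1e-12
        )

    def test_prior_weights(self):
        out = pips([0.0, 0.0], prior=[3.0, 1.0])
        np.testing.assert_allclose(out, [0.75, 0.25])

    def test_empty_rejected(self):
        with pytest.raises(FinemapError):
            pips([])


class TestCredibleSet:
    @pytest.mark.parametrize(
        "pip,expected_size",
        [
            ([0.96, 0.03, 0.01], 1),
            ([0.94, 0.04, 0.02], 2),  # cumulative 0.94, 0.98
            ([0.5, 0.3, 0.2], 3),  # cumulative 0.8, then 1.0
        ],
    )
    def test_minimal_prefix(self, pip, expected_size):
        # brute-force oracle: shortest descending-pip prefix with mass > 0.95
        order = sorted(range(len(pip)), key=lambda i: -pip[i])
        brute = next(
            k for k in range(1, len(pip) + 1)
            if sum(pip[i] for i in order[:k]) > 0.95
        )
        assert brute == expected_size
        assert len(credible_set(pip, 0.95)) == expected_size

    def test_minimality_dropping_last_member(self, rng):
        for _ in range(50):
            raw = rng.dirichlet(np.ones(rng.integers(2, 20)))
            cs = credible_set(raw, 0.95)
            mass = raw[cs].sum()
            assert mass > 0.95
            if len(cs) > 1:
                assert mass - raw[cs[-1]] <= 0.95

    def test_tie_break_by_p_then_position(self):
        cs = credible_set(
            [0.4, 0.4, 0.2],
            level=0.5,
            p=[1e-5, 1e-9, 1e-3],
            pos=[10, 20, 30],
        )
        assert cs[0] == 1  # equal pip, smaller p wins

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.2])
    def test_level_domain(self, level):
        with pytest.raises(FinemapError):
            credible_set([1.0], level)


class TestFinemapLocus:
    def test_dominant_variant(self, toy_table):
        res = finemap_locus(toy_table)
        assert res.top_variant == "rsB"
        assert res.pip.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.pip[1] > 0.999
        assert res.credible_set == ("rsB",)
        assert res.credible_mass > 0.95

    def test_exchangeable_records_split_evenly(self):
        t = LocusTable(
            (make_record("rs1", 100, beta=0.05, se=0.005),
             make_record("rs2", 200, beta=0.05, se=0.005))
        )
        res = finemap_locus(t)
        np.testing.assert_allclose(res.pip, [0.5, 0.5])
        assert len(res.credible_set) == 2

    def test_records_without_beta_se_excluded_and_reported(self):
        t = LocusTable(
            (make_record("rs1", 100),
             make_record("rs2", 200, beta=None, se=None, p=1e-10))
        )
        res = finemap_locus(t)
        assert res.excluded == ("rs2",)
        assert res.rsids == ("rs1",)

    def test_all_excluded_raises(self):
        t = LocusTable((make_record("rs1", 100, beta=None, se=None, p=0.5),))
        with pytest.raises(FinemapError):
            finemap_locus(t)

    def test_w_zero_gives_uniform_pips(self, toy_table):
        res = finemap_locus(toy_table, PriorSpec(W=0.0))
        np.testing.assert_allclose(res.pip, np.full(3, 1 / 3), atol=1e-15)

    def test_zscale_path_warns(self):
        with pytest.warns(ZScaleWarning):
            res = finemap_zscores([1.0, 8.0], W=0.04)
        assert res.z_scale
        assert res.pip.sum() == pytest.approx(1.0, abs=1e-12)
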