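"""Disproportionality statistics against independent oracles.

ROR/PRR/chi-square are checked against direct hand arithmetic; the
closed-form information component against a posterior-sampling oracle
(the value for the (20, 80, 80, 9820) table was frozen from a 2×10^7-draw
run of the sampler, seed 12345, before being asserted here); MGPS against
digamma arithmetic, parameter-recovery simulations and shrinkage bounds.
"""

import math

import numpy as np
import pytest
from scipy import special

from pvsignal.contingency import ContingencyTable
from pvsignal.exceptions import UndefinedResultError, ValidationError
from pvsignal.stats import (
    BCPNNConfig,
    CANONICAL_PRIOR,
    MGPSPrior,
    bcpnn_ic,
    bcpnn_ic_montecarlo,
    chi_square,
    mgps_ebgm,
    mgps_fit_prior,
    prr,
    ror,
)

GRID = [
    (10, 10, 10, 10), (269, 1653, 87, 10501), (5, 5, 5, 45),
    (20, 80, 40, 60), (1, 9, 9, 81), (3, 17, 30, 950), (50, 50, 25, 875),
    (7, 3, 11, 979), (100, 900, 900, 8100), (2, 8, 5, 985),
]


def table_with(a, e, n=10000, r=100):
    """An integer table with the requested a and expected count E."""
    c_margin = int(round(e * n / r))
    t = ContingencyTable(a=a, b=r - a, c=c_margin - a,
                         d=n - r - c_margin + a)
    assert t.expected == pytest.approx(e, rel=1e-9)
    return t


class TestRorPrrChi2:
    @pytest.mark.parametrize("cells", GRID)
    def test_ror_matches_hand_arithmetic(self, cells):
        a, b, c, d = cells
        est = ror(ContingencyTable(a, b, c, d))
        assert est.value == pytest.approx((a * d) / (b * c), rel=1e-12)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert est.low == pytest.approx(est.value * math.exp(-1.96 * se),
                                        rel=1e-12)
        assert est.low < est.value < est.high

    @pytest.mark.parametrize("cells", GRID)
    def test_prr_matches_hand_arithmetic(self, cells):
        a, b, c, d = cells
        est = prr(ContingencyTable(a, b, c, d))
        assert est.value == pytest.approx((a / (a + b)) / (c / (c + d)),
                                          rel=1e-12)

    def test_reference_values(self):
        assert ror(ContingencyTable(10, 10, 10, 10)).value == 1.0
        assert ror(ContingencyTable(269, 1653, 87, 10501)).value == \
            pytest.approx(19.642, abs=5e-4)
        assert prr(ContingencyTable(5, 5, 5, 45)).value == pytest.approx(5.0)

    def test_ror_point_estimate_invariant_to_column_scaling(self):
        base = ror(ContingencyTable(12, 40, 30, 500)).value
        scaled = ror(ContingencyTable(12, 40 * 3, 30, 500 * 3)).value
        assert scaled == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("cells", GRID)
    def test_ror_farther_from_one_than_prr(self, cells):
        r = ror(ContingencyTable(*cells)).value
        p = prr(ContingencyTable(*cells)).value
        assert (r >= p >= 1) or (r <= p <= 1) or (r == p == 1)

    def test_zero_numerator_gives_raw_zero_with_corrected_interval(self):
        est = prr(ContingencyTable(0, 10, 10, 80))
        assert est.value == 0.0
        assert est.corrected
        est = ror(ContingencyTable(0, 10, 10, 80))
        assert est.value == 0.0 and est.corrected

    def test_zero_denominator_without_correction_is_an_error(self):
        with pytest.raises(UndefinedResultError):
            ror(ContingencyTable(5, 0, 10, 80), zero_cell="error")
        with pytest.raises(UndefinedResultError):
            prr(ContingencyTable(5, 10, 0, 80), zero_cell="error")

    def test_zero_denominator_with_correction_is_finite(self):
        est = ror(ContingencyTable(5, 0, 10, 80))
        assert est.corrected and np.isfinite(est.value) and est.value > 0

    @pytest.mark.parametrize("cells", GRID)
    def test_chi_square_matches_hand_pearson(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        stat, p = chi_square(ContingencyTable(a, b, c, d))
        hand = n * (a * d - b * c) ** 2 / \
            ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(hand, rel=1e-10)

    def test_chi_square_reference_value(self):
        stat, p = chi_square(ContingencyTable(20, 80, 40, 60))
        assert stat == pytest.approx(9.523809523809524, rel=1e-12)

    @pytest.mark.parametrize("cells", GRID)
    def test_yates_never_exceeds_uncorrected(self, cells):
        plain, _ = chi_square(ContingencyTable(*cells))
        yates, _ = chi_square(ContingencyTable(*cells), yates=True)
        assert yates <= plain + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square(ContingencyTable(0, 0, 10, 10))


class TestBCPNN:
    def test_independence_structured_table_gives_ic_near_zero(self):
        res = bcpnn_ic(ContingencyTable(100, 900, 900, 8100))
        assert abs(res.ic) < 0.02

    def test_frozen_sampling_oracle_value(self):
        """Closed form vs the 2×10^7-draw posterior-sampling run."""
        res = bcpnn_ic(ContingencyTable(20, 80, 80, 9820))
        assert res.ic == pytest.approx(3.35779, abs=1e-3)
        assert res.variance == pytest.approx(0.14247, abs=1e-3)
        assert res.ic025 == pytest.approx(2.61798, abs=2e-3)

    def test_ic_strictly_increasing_in_a(self):
        values = [bcpnn_ic(ContingencyTable(a, 100, 100, 5000)).ic
                  for a in (1, 5, 20, 50)]
        assert all(x < y for x, y in zip(values, values[1:]))

    @pytest.mark.parametrize("cells", [(20, 80, 80, 9820), (3, 97, 120, 9780),
                                       (100, 900, 900, 8100)])
    def test_closed_form_agrees_with_sampler(self, cells):
        table = ContingencyTable(*cells)
        closed = bcpnn_ic(table)
        mean, var, se = bcpnn_ic_montecarlo(table, n_draws=200_000, rng=99)
        assert abs(closed.ic - mean) < 3 * se
        assert closed.variance == pytest.approx(var, rel=0.05)

    def test_interval_contains_mean(self):
        res = bcpnn_ic(ContingencyTable(20, 80, 80, 9820))
        assert res.ic025 < res.ic

    def test_gamma_approximation_variant(self):
        t = ContingencyTable(20, 80, 80, 9820)
        res = bcpnn_ic(t, BCPNNConfig(method="gamma-approx"))
        assert res.ic == pytest.approx(math.log2((t.a + 0.5) /
                                                 (t.expected + 0.5)), rel=1e-12)
        assert res.ic025 < res.ic
        # Both routes agree where counts are large and the ratio is near 1.
        big = ContingencyTable(100, 900, 900, 8100)
        approx = bcpnn_ic(big, BCPNNConfig(method="gamma-approx"))
        assert approx.ic == pytest.approx(bcpnn_ic(big).ic, abs=0.05)


class TestMGPS:
    def test_degenerate_prior_ebgm_from_digamma(self):
        """p=1, Gamma(1,1) prior, a=0, E=1: posterior Gamma(1,2) and
        EBGM = exp(ψ(1) − ln 2)."""
        prior = MGPSPrior(1.0, 1.0, 1.0, 1.0, 1.0)
        ebgm, eb05 = mgps_ebgm(ContingencyTable(0, 2, 2, 0), prior)
        assert ebgm == pytest.approx(math.exp(special.digamma(1) - math.log(2)),
                                     rel=1e-10)
        # Gamma(1, rate 2) 5th percentile: -ln(0.95)/2
        assert eb05 == pytest.approx(-math.log(0.95) / 2, abs=1e-6)

    def test_eb05_below_ebgm_on_grid(self):
        for a in (0, 1, 3, 10, 50):
            for e in (0.5, 1.0, 2.0, 10.0):
                ebgm, eb05 = mgps_ebgm(table_with(a, e), CANONICAL_PRIOR)
                assert eb05 < ebgm

    def test_shrinkage_toward_prior_geometric_mean(self):
        """For small a, log EBGM sits between the prior geometric mean and
        the raw log ratio."""
        p = CANONICAL_PRIOR
        prior_gm = (p.p * (special.digamma(p.alpha1) - math.log(p.beta1))
                    + (1 - p.p) * (special.digamma(p.alpha2) - math.log(p.beta2)))
        for a in range(6):
            for e in (0.5, 1.0, 2.0):
                ebgm, _ = mgps_ebgm(table_with(a, e), p)
                raw = math.log((a + 0.01) / e)
                assert abs(math.log(ebgm) - prior_gm) <= abs(raw - prior_gm) \
                    + 1e-9

    def test_ebgm_approaches_raw_ratio_at_large_counts(self):
        t = ContingencyTable(10_000, 90_000, 40_000, 860_000)
        assert t.expected == pytest.approx(5000.0)
        ebgm, eb05 = mgps_ebgm(t, CANONICAL_PRIOR)
        assert ebgm == pytest.approx(t.a / t.expected, rel=0.01)
        assert eb05 < ebgm

    def test_prior_fit_recovers_single_gamma(self):
        """Counts from λ ~ Gamma(2, rate 2): fit with the mixture weight
        pinned at 1 recovers the shape and rate within 15%."""
        rng = np.random.default_rng(2024)
        n = 5000
        e = rng.lognormal(0.5, 1.0, size=n) + 0.2
        lam = rng.gamma(2.0, 1 / 2.0, size=n)
        a = rng.poisson(lam * e)
        fit = mgps_fit_prior(list(zip(a, e)), fix_p=1.0)
        assert fit.converged
        assert fit.prior.alpha1 == pytest.approx(2.0, rel=0.15)
        assert fit.prior.beta1 == pytest.approx(2.0, rel=0.15)

    def test_fit_improves_on_canonical_start_and_truth(self):
        """Two-component truth: the fitted likelihood is at least the
        likelihood at the true parameters, and the fitted prior mean is
        close to the true mean."""
        rng = np.random.default_rng(7)
        truth = CANONICAL_PRIOR
        n = 20_000
        e = rng.lognormal(0.0, 1.0, size=n) + 0.1
        comp = rng.random(n) < truth.p
        lam = np.where(comp,
                       rng.gamma(truth.alpha1, 1 / truth.beta1, size=n),
                       rng.gamma(truth.alpha2, 1 / truth.beta2, size=n))
        a = rng.poisson(lam * e)
        fit = mgps_fit_prior(list(zip(a, e)))
        ll_truth = float(truth.log_marginal(a, e).sum())
        assert fit.loglik >= ll_truth - 1e-6
        assert fit.prior.mean == pytest.approx(truth.mean, rel=0.15)

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValidationError, match="20"):
            mgps_fit_prior([(1, 1.0)] * 5)

    def test_zero_expected_count_rejected(self):
        with pytest.raises(UndefinedResultError):
            mgps_ebgm(ContingencyTable(0, 5, 0, 5), CANONICAL_PRIOR)


def test_point_estimates_consistent_under_independence():
    """500 multinomial tables at N=50,000 under row/column independence:
    median ROR/PRR/EBGM within 10% of 1, median IC within 0.15 of 0."""
    rng = np.random.default_rng(314)
    p_drug, p_soc = 0.3, 0.1
    probs = [p_drug * p_soc, p_drug * (1 - p_soc),
             (1 - p_drug) * p_soc, (1 - p_drug) * (1 - p_soc)]
    rors, prrs, ics, ebgms = [], [], [], []
    for _ in range(500):
        a, b, c, d = rng.multinomial(50_000, probs)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        rors.append(ror(t).value)
        prrs.append(prr(t).value)
        ics.append(bcpnn_ic(t).ic)
        ebgms.append(mgps_ebgm(t, CANONICAL_PRIOR)[0])
    assert 0.9 <= np.median(rors) <= 1.1
    assert 0.9 <= np.median(prrs) <= 1.1
    assert 0.9 <= np.median(ebgms) <= 1.1
    assert abs(np.median(ics)) <= 0.15
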