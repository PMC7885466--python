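"""Poisson quantification layer: lambda, duplex channels, fractions, cn."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonedrop import (
    DropletWell,
    allele_fraction,
    copy_number,
    duplex_quantify,
    poisson_lambda,
    pool_wells,
)
from clonedrop.errors import (
    EmptyWellError,
    NoReferenceError,
    SaturationError,
    UndefinedFractionError,
)


@pytest.mark.parametrize(
    "n_pos,n_total,expected",
    [
        (0, 10_000, 0.0),
        (6321, 10_000, -math.log(1 - 0.6321)),  # ~1 copy/droplet at 1 - e^-1
        (5000, 20_000, -math.log(0.75)),
        (1, 4, -math.log(0.75)),
    ],
)
def test_poisson_lambda_closed_form(n_pos, n_total, expected):
    est = poisson_lambda(n_pos, n_total)
    assert est.lambda_hat == pytest.approx(expected, abs=1e-12)
    assert est.ci95[0] <= est.lambda_hat <= est.ci95[1]


def test_poisson_lambda_units():
    est = poisson_lambda(5000, 20_000, droplet_volume_nl=0.85)
    # copies/uL = lambda per droplet / (0.85 nL) converted to uL
    assert est.copies_per_ul == pytest.approx(est.lambda_hat / 0.85e-3)


def test_blank_well_has_positive_upper_bound():
    est = poisson_lambda(0, 20_000)
    assert est.lambda_hat == 0.0
    assert est.ci95[1] > 0.0


def test_poisson_lambda_errors():
    with pytest.raises(SaturationError):
        poisson_lambda(100, 100)
    with pytest.raises(EmptyWellError):
        poisson_lambda(0, 0)


@given(
    n_total=st.integers(100, 50_000),
    frac=st.tuples(st.floats(0.0, 0.98), st.floats(0.001, 0.02)),
)
@settings(max_examples=100, deadline=None)
def test_lambda_monotone_in_positives(n_total, frac):
    """lambda increases strictly with the positive count at fixed total."""
    f, df = frac
    n1 = int(f * n_total)
    n2 = min(int((f + df) * n_total), n_total - 1)
    l1 = poisson_lambda(n1, n_total).lambda_hat
    l2 = poisson_lambda(n2, n_total).lambda_hat
    if n2 > n1:
        assert l2 > l1
    else:
        assert l2 == l1
    assert poisson_lambda(0, n_total).lambda_hat == 0.0


class TestDuplex:
    def test_mutant_negative_well(self):
        # the classic wild-type-only pattern: nothing on channel 1
        well = DropletWell("A01", 0, 0, 4000, 16_000)
        ch1, ch2 = duplex_quantify(well)
        assert ch1.lambda_hat == 0.0
        assert ch2.lambda_hat == pytest.approx(-math.log(0.8))

    def test_symmetric_channels(self):
        well = DropletWell("A02", 100, 900, 900, 18_100)
        ch1, ch2 = duplex_quantify(well)
        assert ch1.lambda_hat == ch2.lambda_hat == pytest.approx(-math.log(0.95))

    @given(
        d=st.integers(0, 500),
        a=st.integers(0, 2000),
        b=st.integers(0, 2000),
        n=st.integers(1000, 30_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_double_positives_count_on_both_channels(self, d, a, b, n):
        well = DropletWell("w", d, a, b, n)
        ch1, ch2 = duplex_quantify(well)
        assert ch1.lambda_hat == poisson_lambda(d + a, well.n_total).lambda_hat
        assert ch2.lambda_hat == poisson_lambda(d + b, well.n_total).lambda_hat

    def test_saturated_channel_propagates(self):
        well = DropletWell("w", 10, 90, 0, 0)
        with pytest.raises(SaturationError):
            duplex_quantify(well)


class TestAlleleFraction:
    def test_absent_mutant(self):
        mut = poisson_lambda(0, 20_000)
        wt = poisson_lambda(6594, 20_000)  # lambda ~ 0.4
        frac = allele_fraction(mut, wt)
        assert frac.fraction == 0.0
        assert frac.ci95[1] > 0.0

    def test_symmetry(self):
        a = poisson_lambda(5000, 20_000)
        frac = allele_fraction(a, a)
        assert frac.fraction == pytest.approx(0.5)

    def test_low_fraction_readout(self):
        # lambda ratio 0.184 : 0.816 -> fraction 0.184
        mut = poisson_lambda(int(20_000 * (1 - math.exp(-0.184))), 20_000)
        wt = poisson_lambda(int(20_000 * (1 - math.exp(-0.816))), 20_000)
        frac = allele_fraction(mut, wt)
        assert frac.fraction == pytest.approx(0.184, abs=1e-3)
        assert frac.ci95[0] < frac.fraction < frac.ci95[1]

    def test_both_zero_is_undefined(self):
        z = poisson_lambda(0, 20_000)
        with pytest.raises(UndefinedFractionError):
            allele_fraction(z, z)

    @given(scale=st.floats(0.1, 5.0), l1=st.floats(0.05, 1.5), l2=st.floats(0.05, 1.5))
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_common_rescaling(self, scale, l1, l2):
        """The fraction depends only on the lambda ratio, not input amount."""
        n = 100_000

        def est(lam):
            return poisson_lambda(int(n * (1 - math.exp(-lam))), n)

        base = allele_fraction(est(l1), est(l2)).fraction
        scaled = allele_fraction(est(scale * l1), est(scale * l2)).fraction
        assert scaled == pytest.approx(base, abs=5e-4)

    def test_bootstrap_ci_is_seeded_and_close_to_delta(self):
        a = poisson_lambda(8000, 20_000)
        b = poisson_lambda(5000, 20_000)
        f1 = allele_fraction(a, b, bootstrap=True, seed=1)
        f2 = allele_fraction(a, b, bootstrap=True, seed=1)
        assert f1.ci95 == f2.ci95
        fd = allele_fraction(a, b)
        assert f1.ci95[0] == pytest.approx(fd.ci95[0], abs=0.01)
        assert f1.ci95[1] == pytest.approx(fd.ci95[1], abs=0.01)


class TestCopyNumber:
    def test_identity_is_exact(self):
        x = poisson_lambda(7000, 20_000)
        assert copy_number(x, x).cn == 2.0
        assert copy_number(x, x, reference_copies=4).cn == 4.0

    @pytest.mark.parametrize("ratio,expected", [(0.665, 1.33), (1.34, 2.68)])
    def test_loss_and_gain_ratios(self, ratio, expected):
        n = 200_000
        ref_lam = 0.6
        t = poisson_lambda(int(n * (1 - math.exp(-ratio * ref_lam))), n)
        r = poisson_lambda(int(n * (1 - math.exp(-ref_lam))), n)
        est = copy_number(t, r)
        assert est.cn == pytest.approx(expected, abs=5e-3)
        assert est.ci95[0] < est.cn < est.ci95[1]

    def test_zero_reference(self):
        t = poisson_lambda(100, 20_000)
        r = poisson_lambda(0, 20_000)
        with pytest.raises(NoReferenceError):
            copy_number(t, r)


class TestPooling:
    def test_pooled_counts_are_summed(self):
        wells = [
            DropletWell("A", 10, 100, 200, 15_000),
            DropletWell("B", 20, 150, 180, 14_000),
        ]
        pooled = pool_wells(wells)
        assert pooled.n_double_pos == 30
        assert pooled.n_total == sum(w.n_total for w in wells)

    def test_pooling_beats_averaging(self):
        # ML treatment: correct counts first, then pool -- equivalent to
        # estimating lambda from the summed table, not the mean of lambdas
        w1 = DropletWell("A", 0, 1000, 0, 9_000)
        w2 = DropletWell("B", 0, 4000, 0, 6_000)
        pooled = pool_wells([w1, w2])
        lam = poisson_lambda(pooled.n_ch1_positive, pooled.n_total).lambda_hat
        mean_of_lams = (
            poisson_lambda(1000, 10_000).lambda_hat
            + poisson_lambda(4000, 10_000).lambda_hat
        ) / 2
        assert lam == pytest.approx(-math.log(1 - 0.25))
        assert lam != pytest.approx(mean_of_lams)

    def test_mixed_volumes_rejected(self):
        w1 = DropletWell("A", 0, 10, 10, 100, droplet_volume_nl=0.85)
        w2 = DropletWell("B", 0, 10, 10, 100, droplet_volume_nl=0.91)
        with pytest.raises(ValueError):
            pool_wells([w1, w2])


def test_well_invariants():
    with pytest.raises(ValueError):
        DropletWell("w", -1, 0, 0, 100)
    with pytest.raises(EmptyWellError):
        DropletWell("w", 0, 0, 0, 0)
    with pytest.raises(ValueError):
        DropletWell("w", 0, 0, 0, 100, droplet_volume_nl=0.0)
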