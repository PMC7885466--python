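"""Cell-fraction arithmetic, forward model, and event ordering."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonedrop import (
    AberrantFractionEstimate,
    AlleleFractionEstimate,
    CellFractionEstimate,
    CloneComposition,
    CloneModel,
    ClonePopulation,
    CopyNumberEstimate,
    Locus,
    aberrant_fraction_from_cn,
    aberrant_fraction_from_snp,
    forward_model,
    mutant_cell_fraction,
    order_events,
    poisson_lambda,
)
from clonedrop.errors import (
    DirectionMismatchError,
    InconsistentMeasurementsError,
    ModelMismatchError,
)


def cn_est(cn, half_width=0.02):
    return CopyNumberEstimate(cn, (cn - half_width, cn + half_width))


def maf_est(f, half_width=0.01):
    return AlleleFractionEstimate(f, (max(0, f - half_width), min(1, f + half_width)))


class TestAberrantFromCn:
    @pytest.mark.parametrize(
        "cn,alteration,expected",
        [
            (2.0, "single_copy_loss", 0.0),
            (1.33, "single_copy_loss", 0.67),
            (2.68, "single_copy_gain", 0.68),
        ],
    )
    def test_affine_mapping(self, cn, alteration, expected):
        est = aberrant_fraction_from_cn(cn_est(cn), alteration)
        assert est.fraction == pytest.approx(expected)
        assert est.ci95[0] <= est.fraction <= est.ci95[1]

    def test_ci_width_is_preserved(self):
        est = aberrant_fraction_from_cn(cn_est(1.5, 0.05), "single_copy_loss")
        assert est.ci95 == (pytest.approx(0.45), pytest.approx(0.55))

    def test_direction_mismatch(self):
        with pytest.raises(DirectionMismatchError):
            aberrant_fraction_from_cn(cn_est(2.5), "single_copy_loss")
        with pytest.raises(DirectionMismatchError):
            aberrant_fraction_from_cn(cn_est(1.4), "single_copy_gain")


class TestAberrantFromSnp:
    def _conc(self, lam, n=1_000_000):
        return poisson_lambda(int(n * (1 - math.exp(-lam))), n)

    def test_balanced_heterozygote(self):
        a = self._conc(0.5)
        est = aberrant_fraction_from_snp(a, a, "single_copy_loss")
        assert est.fraction == pytest.approx(0.0, abs=1e-9)

    def test_loss_of_affected_allele(self):
        est = aberrant_fraction_from_snp(
            self._conc(0.6), self._conc(0.6 * 0.33), "single_copy_loss"
        )
        assert est.fraction == pytest.approx(0.67, abs=1e-3)

    def test_gain_of_affected_allele(self):
        est = aberrant_fraction_from_snp(
            self._conc(0.5), self._conc(0.5 * 1.45), "single_copy_gain"
        )
        assert est.fraction == pytest.approx(0.45, abs=1e-3)

    def test_ratio_above_one_contradicts_loss(self):
        with pytest.raises(ModelMismatchError):
            aberrant_fraction_from_snp(
                self._conc(0.5), self._conc(0.7), "single_copy_loss"
            )


class TestMutantCellFraction:
    def test_diploid_doubles_maf(self, loh_model):
        est = mutant_cell_fraction(maf_est(0.18), loh_model)
        assert est.fraction == pytest.approx(0.36)

    def test_fully_mutant_heterozygous(self, loh_model):
        est = mutant_cell_fraction(maf_est(0.50), loh_model)
        assert est.fraction == pytest.approx(1.0)

    def test_wildtype_loss_correction(self, loh_model):
        L = AberrantFractionEstimate(0.67, (0.65, 0.69), "single_copy_loss", "CYSLTR2")
        est = mutant_cell_fraction(maf_est(0.55), loh_model, L)
        assert est.fraction == pytest.approx(0.55 * (2 - 0.67))

    def test_mutant_gain_correction(self, gain_model):
        G = AberrantFractionEstimate(0.68, (0.66, 0.70), "single_copy_gain", "CYSLTR2")
        est = mutant_cell_fraction(maf_est(0.57), gain_model, G)
        assert est.fraction == pytest.approx(0.57 * (2 + 0.68) - 0.68)

    @given(maf=st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_zero_cna_reduces_to_twice_maf(self, maf):
        model = CloneModel(
            loci=[Locus(locus_id="G", alleles={"mut": 0, "wt": 2})],
            populations=[
                ClonePopulation(population_id="healthy"),
                ClonePopulation(
                    population_id="cloneI", copies={"G": {"mut": 1, "wt": 1}}
                ),
            ],
        )
        zero_loss = AberrantFractionEstimate(
            0.0, (0.0, 0.0), "single_copy_loss", "G"
        )
        a = mutant_cell_fraction(maf_est(maf), model, None).fraction
        b = mutant_cell_fraction(maf_est(maf), model, zero_loss).fraction
        assert a == pytest.approx(2 * maf)
        assert b == pytest.approx(a)

    def test_inconsistent_measurements(self, loh_model):
        with pytest.raises(InconsistentMeasurementsError):
            mutant_cell_fraction(maf_est(0.9, half_width=0.005), loh_model)


class TestForwardModel:
    def test_pure_germline(self, loh_model):
        comp = CloneComposition(tuple(loh_model.population_ids), (1.0, 0.0, 0.0))
        pred = forward_model(loh_model, comp)["CYSLTR2"]
        assert pred.allele_fraction("mut") == 0.0
        assert pred.cn == 2.0

    def test_gain_scenario_allele_fraction(self, gain_model):
        comp = CloneComposition(tuple(gain_model.population_ids), (0.15, 0.17, 0.68))
        pred = forward_model(gain_model, comp)["CYSLTR2"]
        assert pred.allele_fraction("mut") == pytest.approx(
            (0.17 + 2 * 0.68) / (2 + 0.68)
        )
        assert pred.cn == pytest.approx(2.68)

    def test_loss_scenario_weighted_sums(self, loh_model):
        comp = CloneComposition(tuple(loh_model.population_ids), (0.26, 0.07, 0.67))
        pred = forward_model(loh_model, comp)["CYSLTR2"]
        assert pred.allele_fraction("mut") == pytest.approx(0.74 / 1.33)
        assert pred.cn == pytest.approx(1.33)

    def test_composition_mismatch(self, loh_model):
        with pytest.raises(ModelMismatchError):
            forward_model(
                loh_model, CloneComposition(("healthy", "other"), (0.5, 0.5))
            )


class TestCloneModelSchema:
    def test_genotypes_inherit_along_the_chain(self, loh_model):
        assert loh_model.genotype("healthy", "CYSLTR2") == {"mut": 0, "wt": 2}
        assert loh_model.genotype("cloneI", "CYSLTR2") == {"mut": 1, "wt": 1}
        assert loh_model.genotype("cloneII", "CYSLTR2") == {"mut": 1, "wt": 0}

    def test_healthy_must_be_germline(self):
        with pytest.raises(ValueError):
            CloneModel(
                loci=[Locus(locus_id="G", alleles={"mut": 0, "wt": 2})],
                populations=[
                    ClonePopulation(
                        population_id="healthy", copies={"G": {"mut": 1, "wt": 1}}
                    )
                ],
            )

    def test_composition_must_be_on_simplex(self):
        with pytest.raises(ValueError):
            CloneComposition(("a", "b"), (0.6, 0.6))
        with pytest.raises(ValueError):
            CloneComposition(("a", "b"), (1.2, -0.2))


class TestOrderEvents:
    def make(self, f, lo, hi, name):
        return CellFractionEstimate(f, (lo, hi), event=name)

    def test_equal_abundances_form_one_clonal_group(self):
        events = [
            self.make(0.74, 0.72, 0.76, n)
            for n in ("mutation", "gain8q", "loss1p", "loss16q")
        ]
        groups = order_events(events)
        assert len(groups) == 1
        assert groups[0].label == "clonal"
        assert set(groups[0].events) == {"mutation", "gain8q", "loss1p", "loss16q"}

    def test_significantly_smaller_fraction_is_subclonal(self):
        events = [
            self.make(0.74, 0.72, 0.76, "mutation"),
            self.make(0.67, 0.65, 0.69, "loss13q"),
        ]
        groups = order_events(events)
        assert [g.label for g in groups] == ["clonal", "subclonal"]
        assert groups[0].events == ("mutation",)
        assert groups[1].events == ("loss13q",)

    def test_single_event_is_trivially_clonal(self):
        groups = order_events([self.make(0.5, 0.4, 0.6, "only")])
        assert len(groups) == 1 and groups[0].label == "clonal"

    @given(perm=st.permutations(list(range(5))))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, perm):
        base = [
            self.make(0.74, 0.72, 0.76, "a"),
            self.make(0.73, 0.71, 0.75, "b"),
            self.make(0.67, 0.65, 0.69, "c"),
            self.make(0.66, 0.64, 0.68, "d"),
            self.make(0.30, 0.28, 0.32, "e"),
        ]
        ref = order_events(base)
        shuffled = order_events([base[i] for i in perm])
        assert [set(g.events) for g in shuffled] == [set(g.events) for g in ref]
        assert [g.label for g in shuffled] == [g.label for g in ref]
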