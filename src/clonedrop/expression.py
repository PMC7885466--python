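"""DNA-vs-RNA allelic balance testing.

A heterozygous variant (or SNP) should appear in RNA at the same fraction
as in DNA if both alleles are transcribed equally per copy ("proportional
expression").  Preferential expression of one allele shifts the RNA
fraction away from the DNA fraction.  This module estimates count-based
allele fractions with Wilson score intervals and tests the RNA fraction
against either the measured DNA fraction (two-proportion z-test) or a
fixed expected fraction (exact binomial test).
"""

from __future__ import annotations

from dataclasses import replace

from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .errors import PairingError, UndefinedFractionError
from .records import AlleleCountPair, AlleleFractionEstimate, BalanceComparison


def allele_fraction_from_counts(pair: AlleleCountPair) -> AlleleFractionEstimate:
    """Allele-1 fraction from molecule/read counts, Wilson 95% CI."""
    n = pair.total
    if n == 0:
        raise UndefinedFractionError(
            f"sample {pair.sample_id!r}: zero total count at {pair.level} level"
        )
    frac = pair.n_allele1 / n
    lo, hi = proportion_confint(pair.n_allele1, n, alpha=0.05, method="wilson")
    return AlleleFractionEstimate(
        fraction=frac,
        ci95=(min(float(lo), frac), max(float(hi), frac)),
        level=pair.level,
        allele_labels=pair.allele_labels,
        ci_method="wilson",
    )


def compare_dna_rna(
    dna: AlleleCountPair,
    rna: AlleleCountPair,
    expected_rna_fraction: float | None = None,
    alpha: float = 0.05,
) -> BalanceComparison:
    """Test whether RNA allelic balance matches DNA (or an expected value).

    With ``expected_rna_fraction`` given (the proportional-expression null
    under a known copy-number change), the RNA counts are tested against
    that fixed fraction by an exact two-sided binomial test.  Otherwise
    the null is RNA fraction = DNA fraction, tested by a two-proportion
    z-test on the raw counts.  The verdict is ``balanced`` iff p >= alpha;
    a significant result is labelled by the allele the RNA is skewed
    toward.
    """
    if dna.level != "DNA" or rna.level != "RNA":
        raise PairingError(
            f"expected one DNA and one RNA count pair, got {dna.level}/{rna.level}"
        )
    if dna.sample_id != rna.sample_id:
        raise PairingError(
            f"sample ids differ: {dna.sample_id!r} vs {rna.sample_id!r}"
        )
    if dna.allele_labels != rna.allele_labels:
        raise PairingError(
            f"allele labels differ: {dna.allele_labels} vs {rna.allele_labels}"
        )
    dna_frac = allele_fraction_from_counts(dna)
    rna_frac = allele_fraction_from_counts(rna)

    if expected_rna_fraction is not None:
        null = float(expected_rna_fraction)
        p = stats.binomtest(rna.n_allele1, rna.total, null).pvalue
        test = f"exact-binomial(null={null:.4g})"
        reference = null
    else:
        if (
            dna.n_allele1 == rna.n_allele1
            and dna.n_allele2 == rna.n_allele2
        ) or dna_frac.fraction == rna_frac.fraction:
            p = 1.0
        else:
            _, p = proportions_ztest(
                [rna.n_allele1, dna.n_allele1], [rna.total, dna.total]
            )
        test = "two-proportion-z"
        reference = dna_frac.fraction

    p = float(min(1.0, p))
    delta = rna_frac.fraction - dna_frac.fraction
    if p >= alpha:
        verdict = "balanced"
    elif rna_frac.fraction > reference:
        verdict = "skewed_to_allele1"
    else:
        verdict = "skewed_to_allele2"
    return BalanceComparison(
        sample_id=dna.sample_id,
        dna_fraction=dna_frac,
        rna_fraction=rna_frac,
        delta=delta,
        p_value=p,
        verdict=verdict,
        test=test,
        alpha=alpha,
    )


def adjust_balance_pvalues(
    comparisons: list[BalanceComparison], method: str = "fdr_bh"
) -> list[BalanceComparison]:
    """Optional multiple-testing correction across samples.

    By default samples are tested independently (per-tumour comparisons);
    this applies Benjamini-Hochberg (or any statsmodels method) to the
    p-values and re-derives each verdict at the stored alpha.
    """
    if not comparisons:
        return []
    _, p_adj, _, _ = multipletests([c.p_value for c in comparisons], method=method)
    out = []
    for c, p in zip(comparisons, p_adj):
        verdict = c.verdict
        if p >= c.alpha:
            verdict = "balanced"
        out.append(
            replace(c, p_value=float(p), verdict=verdict, test=f"{c.test}+{method}")
        )
    return out
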