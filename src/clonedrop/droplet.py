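"""Poisson quantification of droplet digital PCR wells.

A ddPCR reaction partitions the sample into ~20,000 nanolitre droplets.
Target molecules distribute across droplets approximately Poisson, so the
mean occupancy lambda follows from the fraction of positive droplets p as

    lambda = -ln(1 - p)

and the absolute concentration is lambda divided by the droplet volume.
This module converts classified droplet counts into concentration, allele
fraction, and copy-number estimates with asymptotic 95% confidence
intervals.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

from .errors import (
    EmptyWellError,
    NoReferenceError,
    SaturationError,
    UndefinedFractionError,
)
from .records import (
    AlleleFractionEstimate,
    ConcentrationEstimate,
    CopyNumberEstimate,
    DropletWell,
    DEFAULT_DROPLET_VOLUME_NL,
)

Z95 = 1.959963984540054


def poisson_lambda(
    n_positive: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> ConcentrationEstimate:
    """Estimate mean copies per droplet from positive-droplet counts.

    The 95% CI is a normal approximation on lambda with asymptotic variance
    (e^lambda - 1) / n_total.  When no droplet is positive that variance is
    zero, so the upper bound falls back to the rule-of-three limit
    -ln(1 - 3/n), giving a non-degenerate interval for blank wells.

    Raises
    ------
    SaturationError
        If every droplet is positive (lambda is unbounded).
    EmptyWellError
        If ``n_total`` is zero.
    """
    if n_total <= 0:
        raise EmptyWellError("cannot quantify a well with zero droplets")
    if not 0 <= n_positive <= n_total:
        raise ValueError(f"need 0 <= n_positive <= n_total, got {n_positive}/{n_total}")
    if n_positive == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: channel saturated, "
            "dilute the sample or merge with emptier wells"
        )

    p = n_positive / n_total
    lam = -math.log1p(-p)
    if n_positive == 0:
        lo, hi = 0.0, -math.log1p(-min(3.0 / n_total, 1.0 - 1e-12))
        method = "rule-of-three"
    else:
        se = math.sqrt((math.exp(lam) - 1.0) / n_total)
        lo = max(0.0, lam - Z95 * se)
        hi = lam + Z95 * se
        method = "normal-approx"
    return ConcentrationEstimate(
        lambda_hat=lam,
        copies_per_ul=lam / droplet_volume_nl * 1000.0,
        ci95=(lo, hi),
        n_droplets=n_total,
        ci_method=method,
    )


def duplex_quantify(
    well: DropletWell,
) -> tuple[ConcentrationEstimate, ConcentrationEstimate]:
    """Quantify both channels of a duplex well.

    Double-positive droplets contain both targets and are counted as
    positive on each channel (independent-target duplex).
    """
    ch1 = poisson_lambda(well.n_ch1_positive, well.n_total, well.droplet_volume_nl)
    ch2 = poisson_lambda(well.n_ch2_positive, well.n_total, well.droplet_volume_nl)
    return ch1, ch2


def pool_wells(wells: Sequence[DropletWell], well_id: str = "pooled") -> DropletWell:
    """Merge replicate wells by summing droplet counts.

    Pooling counts before Poisson correction is the maximum-likelihood
    treatment of replicates (averaging corrected lambdas is not).
    """
    if not wells:
        raise EmptyWellError("no wells to pool")
    volumes = {w.droplet_volume_nl for w in wells}
    if len(volumes) > 1:
        raise ValueError(f"cannot pool wells with different droplet volumes: {volumes}")
    return DropletWell(
        well_id=well_id,
        n_double_pos=sum(w.n_double_pos for w in wells),
        n_ch1_only=sum(w.n_ch1_only for w in wells),
        n_ch2_only=sum(w.n_ch2_only for w in wells),
        n_negative=sum(w.n_negative for w in wells),
        droplet_volume_nl=wells[0].droplet_volume_nl,
    )


def allele_fraction(
    num: ConcentrationEstimate,
    den_other: ConcentrationEstimate,
    level: str = "DNA",
    allele_labels: tuple[str, str] = ("allele1", "allele2"),
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AlleleFractionEstimate:
    """Allele fraction lambda_num / (lambda_num + lambda_other).

    The default CI propagates the two lambda CIs to first order (delta
    method).  ``bootstrap=True`` replaces it with a seeded parametric
    bootstrap: lambdas resampled from normal(lambda_hat, se), fraction
    percentiles at 2.5/97.5.
    """
    l1, l2 = num.lambda_hat, den_other.lambda_hat
    if l1 + l2 <= 0:
        raise UndefinedFractionError("both alleles have zero concentration")
    frac = l1 / (l1 + l2)

    if bootstrap:
        rng = np.random.default_rng(seed)
        s1 = np.clip(rng.normal(l1, num.se, n_boot), 0.0, None)
        s2 = np.clip(rng.normal(l2, den_other.se, n_boot), 0.0, None)
        with np.errstate(invalid="ignore"):
            fr = s1 / (s1 + s2)
        fr = fr[np.isfinite(fr)]
        lo, hi = np.percentile(fr, [2.5, 97.5])
        lo, hi = min(lo, frac), max(hi, frac)
        method = f"parametric-bootstrap(n={n_boot},seed={seed})"
    else:
        # d f / d l1 = l2 / (l1+l2)^2 ; d f / d l2 = -l1 / (l1+l2)^2
        tot2 = (l1 + l2) ** 2
        var = (l2 * num.se) ** 2 / tot2**2 + (l1 * den_other.se) ** 2 / tot2**2
        se = math.sqrt(var)
        lo, hi = frac - Z95 * se, frac + Z95 * se
        method = "delta"
    return AlleleFractionEstimate(
        fraction=frac,
        ci95=(max(0.0, min(lo, frac)), min(1.0, max(hi, frac))),
        level=level,  # type: ignore[arg-type]
        allele_labels=allele_labels,
        ci_method=method,
    )


def copy_number(
    target: ConcentrationEstimate,
    reference: ConcentrationEstimate,
    reference_copies: int = 2,
    target_assay: str = "",
    reference_assay: str = "",
) -> CopyNumberEstimate:
    """Germline-normalised copy number: reference_copies * lambda_t / lambda_r.

    The reference assay must target a region that is germline-diploid (or
    ``reference_copies``-ploid) and unaltered in the tumour.  CI by the
    delta method on the ratio.
    """
    if reference.lambda_hat <= 0:
        raise NoReferenceError("reference assay concentration is zero")
    ratio = target.lambda_hat / reference.lambda_hat
    cn = reference_copies * ratio
    # var(r)/r^2 = var(t)/t^2 + var(ref)/ref^2 (first order, independent wells)
    if target.lambda_hat > 0:
        rel_var = (target.se / target.lambda_hat) ** 2 + (
            reference.se / reference.lambda_hat
        ) ** 2
        se = cn * math.sqrt(rel_var)
    else:
        se = reference_copies * target.se / reference.lambda_hat
    lo = max(0.0, cn - Z95 * se)
    hi = cn + Z95 * se
    return CopyNumberEstimate(
        cn=cn,
        ci95=(lo, hi),
        target_assay=target_assay,
        reference_assay=reference_assay,
        ci_method="delta",
    )
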