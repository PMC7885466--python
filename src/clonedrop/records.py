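"""Measurement records shared across the package.

These are plain frozen dataclasses: a droplet well's 2x2 classification
table, and the estimate records (concentration, allele fraction, copy
number, aberrant cell fraction) that carry a point estimate together with
a 95% confidence interval and the name of the method that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

from .errors import EmptyWellError

#: Default droplet partition volume in nanolitres (Bio-Rad QX200).
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DropletWell:
    """One ddPCR well's droplet classification counts.

    Channel 1 positives are ``n_double_pos + n_ch1_only``; double-positive
    droplets contain both targets and count toward both channels.
    """

    well_id: str
    n_double_pos: int
    n_ch1_only: int
    n_ch2_only: int
    n_negative: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        counts = (self.n_double_pos, self.n_ch1_only, self.n_ch2_only, self.n_negative)
        if any(c < 0 for c in counts):
            raise ValueError(f"well {self.well_id!r}: negative droplet count {counts}")
        if sum(counts) == 0:
            raise EmptyWellError(f"well {self.well_id!r} contains no droplets")
        if self.droplet_volume_nl <= 0:
            raise ValueError(
                f"well {self.well_id!r}: droplet volume must be positive, "
                f"got {self.droplet_volume_nl}"
            )

    @property
    def n_total(self) -> int:
        return self.n_double_pos + self.n_ch1_only + self.n_ch2_only + self.n_negative

    @property
    def n_ch1_positive(self) -> int:
        return self.n_double_pos + self.n_ch1_only

    @property
    def n_ch2_positive(self) -> int:
        return self.n_double_pos + self.n_ch2_only


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Mean copies per droplet (lambda) of one target, with 95% CI.

    ``copies_per_ul`` converts lambda through the droplet partition volume:
    copies/uL = lambda / volume_nL * 1000.
    """

    lambda_hat: float
    copies_per_ul: float
    ci95: tuple[float, float]
    n_droplets: int
    ci_method: str = "normal-approx"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if self.lambda_hat < 0:
            raise ValueError(f"lambda_hat must be >= 0, got {self.lambda_hat}")
        if not (lo <= self.lambda_hat <= hi):
            raise ValueError(f"CI {self.ci95} does not contain lambda {self.lambda_hat}")

    @property
    def se(self) -> float:
        """Standard error implied by the stored 95% CI."""
        lo, hi = self.ci95
        return (hi - lo) / (2 * 1.959963984540054)


@dataclass(frozen=True)
class AlleleFractionEstimate:
    """Fraction of one allele among a pair, at DNA or RNA level."""

    fraction: float
    ci95: tuple[float, float]
    level: Literal["DNA", "RNA"] = "DNA"
    allele_labels: tuple[str, str] = ("allele1", "allele2")
    ci_method: str = "delta"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.fraction <= hi <= 1.0):
            raise ValueError(
                f"allele fraction {self.fraction} with CI {self.ci95} violates "
                "0 <= low <= fraction <= high <= 1"
            )

    @property
    def se(self) -> float:
        lo, hi = self.ci95
        return (hi - lo) / (2 * 1.959963984540054)


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Average copies per cell of a locus, germline-normalised (diploid = 2.0)."""

    cn: float
    ci95: tuple[float, float]
    target_assay: str = ""
    reference_assay: str = ""
    ci_method: str = "delta"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")
        if not (lo <= self.cn <= hi):
            raise ValueError(f"CI {self.ci95} does not contain cn {self.cn}")

    @property
    def se(self) -> float:
        lo, hi = self.ci95
        return (hi - lo) / (2 * 1.959963984540054)


@dataclass(frozen=True)
class AberrantFractionEstimate:
    """Fraction of cells carrying a single-copy gain or loss at a locus."""

    fraction: float
    ci95: tuple[float, float]
    alteration: Literal["single_copy_loss", "single_copy_gain"]
    locus_id: str = ""
    ci_method: str = "delta"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"aberrant fraction must be in [0,1], got {self.fraction}")
        if lo > hi:
            raise ValueError(f"CI {self.ci95} is not ordered")

    @property
    def se(self) -> float:
        lo, hi = self.ci95
        return (hi - lo) / (2 * 1.959963984540054)


@dataclass(frozen=True)
class CellFractionEstimate:
    """Fraction of all cells (tumour + healthy) carrying an event."""

    fraction: float
    ci95: tuple[float, float]
    event: str = ""
    ci_method: str = "delta"

    @property
    def se(self) -> float:
        lo, hi = self.ci95
        return (hi - lo) / (2 * 1.959963984540054)


@dataclass(frozen=True)
class AlleleCountPair:
    """Molecule or read counts for two alleles in one sample at one level."""

    sample_id: str
    level: Literal["DNA", "RNA"]
    n_allele1: int
    n_allele2: int
    source: Literal["ddPCR", "sequencing"] = "ddPCR"
    allele_labels: tuple[str, str] = ("allele1", "allele2")

    def __post_init__(self) -> None:
        if self.n_allele1 < 0 or self.n_allele2 < 0:
            raise ValueError("allele counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_allele1 + self.n_allele2


@dataclass(frozen=True)
class BalanceComparison:
    """DNA-vs-RNA allelic balance test result for one sample."""

    sample_id: str
    dna_fraction: AlleleFractionEstimate
    rna_fraction: AlleleFractionEstimate
    delta: float
    p_value: float
    verdict: Literal["balanced", "skewed_to_allele1", "skewed_to_allele2"]
    test: str = "two-proportion-z"
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)
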