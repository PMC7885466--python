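"""Clone models, cell-fraction arithmetic, and subclonal deconvolution.

The biological picture is a bulk tumour sample that is a mixture of
healthy (germline) cells and a chain of nested clones: each clone descends
from the previous one and carries all of its alterations plus new ones
(germline -> clone I -> clone II).  Every population has an integer allele
copy number at every locus; bulk measurements (mutant allele fraction,
copy number, aberrant-cell fraction) are composition-weighted averages of
those copy numbers.  This module provides:

* the forward model mapping a composition to predicted measurements,
* its inverse (``deconvolve``): constrained weighted least squares on the
  simplex with seeded parametric-bootstrap CIs,
* copy-number-corrected mutant cell fractions,
* aberrant-cell fractions from copy number or SNP allelic imbalance,
* clonal/subclonal ordering of events by pairwise two-proportion z-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.optimize import nnls

from .errors import (
    DirectionMismatchError,
    InconsistentMeasurementsError,
    ModelMismatchError,
    UnidentifiableModelError,
)
from .records import (
    AberrantFractionEstimate,
    AlleleFractionEstimate,
    CellFractionEstimate,
    ConcentrationEstimate,
    CopyNumberEstimate,
)

Z95 = 1.959963984540054

Alteration = Literal["single_copy_loss", "single_copy_gain"]


# ---------------------------------------------------------------------------
# model schema


class Locus(BaseModel):
    """A measured locus with its germline allele copy numbers.

    ``alleles`` maps allele label -> copies per germline cell, e.g.
    ``{"mut": 0, "wt": 2}`` for a somatic point mutation on an autosome or
    ``{"A": 1, "B": 1}`` for a heterozygous germline SNP.
    """

    locus_id: str
    alleles: dict[str, int]

    @model_validator(mode="after")
    def _check(self) -> "Locus":
        if not self.alleles:
            raise ValueError(f"locus {self.locus_id!r} has no alleles")
        if any(c < 0 for c in self.alleles.values()):
            raise ValueError(f"locus {self.locus_id!r}: negative germline copies")
        if self.germline_copies < 1:
            raise ValueError(f"locus {self.locus_id!r}: germline copies must be >= 1")
        return self

    @property
    def germline_copies(self) -> int:
        return sum(self.alleles.values())

    @property
    def somatic_alleles(self) -> list[str]:
        """Alleles absent from the germline (i.e. somatic mutations)."""
        return [a for a, c in self.alleles.items() if c == 0]


class ClonePopulation(BaseModel):
    """One cell population; ``copies`` lists only the loci that differ
    from the parent (inheritance fills in the rest)."""

    population_id: str
    parent: Optional[str] = None
    copies: dict[str, dict[str, int]] = Field(default_factory=dict)


class CloneModel(BaseModel):
    """Populations with per-locus allele copy numbers.

    The first population is the healthy one and always carries the
    germline genotype; each subsequent clone descends from the previous
    population by default (linear chain), or from an explicit ``parent``.
    """

    loci: list[Locus]
    populations: list[ClonePopulation]

    @model_validator(mode="after")
    def _validate(self) -> "CloneModel":
        if len(self.populations) < 1:
            raise ValueError("clone model needs at least the healthy population")
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate population ids: {ids}")
        locus_ids = {l.locus_id for l in self.loci}
        healthy = self.populations[0]
        for lid, geno in healthy.copies.items():
            locus = self.locus(lid)
            if geno != locus.alleles:
                raise ValueError(
                    f"healthy population must carry the germline genotype at "
                    f"{lid!r}: {geno} != {locus.alleles}"
                )
        for i, pop in enumerate(self.populations):
            if pop.parent is not None and pop.parent not in ids[:i]:
                raise ValueError(
                    f"population {pop.population_id!r}: parent {pop.parent!r} "
                    "must precede it in the list"
                )
            for lid, geno in pop.copies.items():
                if lid not in locus_ids:
                    raise ValueError(
                        f"population {pop.population_id!r} references unknown "
                        f"locus {lid!r}"
                    )
                locus = self.locus(lid)
                if set(geno) - set(locus.alleles):
                    raise ValueError(
                        f"population {pop.population_id!r}, locus {lid!r}: "
                        f"unknown alleles {set(geno) - set(locus.alleles)}"
                    )
                if any(c < 0 for c in geno.values()):
                    raise ValueError(
                        f"population {pop.population_id!r}: negative copy number"
                    )
        return self

    # -- resolved genotypes -------------------------------------------------

    def locus(self, locus_id: str) -> Locus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(f"unknown locus {locus_id!r}")

    @property
    def population_ids(self) -> list[str]:
        return [p.population_id for p in self.populations]

    def genotype(self, population_id: str, locus_id: str) -> dict[str, int]:
        """Allele copy numbers of one population at one locus, resolving
        inheritance along the parent chain (germline at the root)."""
        locus = self.locus(locus_id)
        idx = {p.population_id: i for i, p in enumerate(self.populations)}
        i = idx[population_id]
        chain: list[ClonePopulation] = []
        while True:
            pop = self.populations[i]
            chain.append(pop)
            if i == 0:
                break
            i = idx[pop.parent] if pop.parent is not None else i - 1
        geno = dict(locus.alleles)
        for pop in reversed(chain):
            if locus_id in pop.copies:
                geno.update(pop.copies[locus_id])
        return geno

    def copy_matrix(self, locus_id: str) -> dict[str, dict[str, int]]:
        """population_id -> {allele: copies} at a locus."""
        return {pid: self.genotype(pid, locus_id) for pid in self.population_ids}

    def mutation_locus(self) -> Locus:
        """The (single) locus carrying a somatic allele, if any."""
        cands = [l for l in self.loci if l.somatic_alleles]
        if len(cands) != 1:
            raise ModelMismatchError(
                f"expected exactly one mutation locus, found {len(cands)}"
            )
        return cands[0]


@dataclass(frozen=True)
class CloneComposition:
    """Mixing proportions on the simplex, ordered like the model's populations."""

    population_ids: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.population_ids) != len(self.proportions):
            raise ValueError("one proportion per population required")
        if any(p < -1e-12 or p > 1 + 1e-12 for p in self.proportions):
            raise ValueError(f"proportions must be in [0,1]: {self.proportions}")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1: {sum(self.proportions)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)

    def __getitem__(self, population_id: str) -> float:
        return self.proportions[self.population_ids.index(population_id)]


# ---------------------------------------------------------------------------
# forward model


@dataclass(frozen=True)
class LocusPrediction:
    """Composition-weighted averages at one locus."""

    locus_id: str
    allele_avg: dict[str, float]  # average copies per cell of each allele
    total_avg: float  # average total copies per cell
    cn: float  # germline-normalised (diploid reference = 2.0)

    def allele_fraction(self, allele: str) -> float:
        if self.total_avg <= 0:
            raise ZeroDivisionError(f"locus {self.locus_id}: zero total copies")
        return self.allele_avg[allele] / self.total_avg


def forward_model(
    model: CloneModel, composition: CloneComposition
) -> dict[str, LocusPrediction]:
    """Predict bulk measurements for a known composition.

    Per locus: average copies of each allele = composition-weighted sum of
    population copy numbers; allele fraction = allele average / total
    average; copy number = 2 x total / germline copies.  Deterministic.
    """
    if tuple(model.population_ids) != composition.population_ids:
        raise ModelMismatchError(
            f"composition populations {composition.population_ids} do not match "
            f"model populations {model.population_ids}"
        )
    w = composition.as_array()
    out: dict[str, LocusPrediction] = {}
    for locus in model.loci:
        cmat = model.copy_matrix(locus.locus_id)
        avg = {
            a: float(sum(w[i] * cmat[pid][a] for i, pid in enumerate(model.population_ids)))
            for a in locus.alleles
        }
        total = sum(avg.values())
        out[locus.locus_id] = LocusPrediction(
            locus_id=locus.locus_id,
            allele_avg=avg,
            total_avg=total,
            cn=2.0 * total / locus.germline_copies,
        )
    return out


# ---------------------------------------------------------------------------
# measurement -> cell-fraction operations


def aberrant_fraction_from_cn(
    cn: CopyNumberEstimate, alteration: Alteration, locus_id: str = ""
) -> AberrantFractionEstimate:
    """Fraction of cells carrying a single-copy gain or loss, from copy number.

    A single-copy loss in a fraction f of cells shifts the average copy
    number to 2 - f, so f = 2 - cn; a gain gives f = cn - 2.  The CI is the
    cn CI mapped through the same affine transform, clipped to [0, 1].
    """
    lo, hi = cn.ci95
    if alteration == "single_copy_loss":
        if lo > 2.0:
            raise DirectionMismatchError(
                f"cn CI {cn.ci95} excludes values <= 2; not consistent with a loss"
            )
        f, f_lo, f_hi = 2.0 - cn.cn, 2.0 - hi, 2.0 - lo
    elif alteration == "single_copy_gain":
        if hi < 2.0:
            raise DirectionMismatchError(
                f"cn CI {cn.ci95} excludes values >= 2; not consistent with a gain"
            )
        f, f_lo, f_hi = cn.cn - 2.0, lo - 2.0, hi - 2.0
    else:
        raise ValueError(f"unknown alteration {alteration!r}")
    clip = lambda x: min(1.0, max(0.0, x))
    return AberrantFractionEstimate(
        fraction=clip(f),
        ci95=(clip(f_lo), clip(f_hi)),
        alteration=alteration,
        locus_id=locus_id or cn.target_assay,
        ci_method=cn.ci_method,
    )


def aberrant_fraction_from_snp(
    retained_allele: ConcentrationEstimate,
    affected_allele: ConcentrationEstimate,
    alteration: Alteration,
    locus_id: str = "",
) -> AberrantFractionEstimate:
    """Aberrant-cell fraction from allelic imbalance at a heterozygous SNP.

    With one copy of each allele per germline cell, losing the affected
    allele in a fraction f of cells gives lambda_affected/lambda_retained =
    1 - f; gaining it gives 1 + f.  CI by the delta method on the ratio.
    """
    if retained_allele.lambda_hat <= 0:
        raise ModelMismatchError("retained allele has zero concentration")
    r = affected_allele.lambda_hat / retained_allele.lambda_hat
    rel = 0.0
    if affected_allele.lambda_hat > 0:
        rel += (affected_allele.se / affected_allele.lambda_hat) ** 2
    rel += (retained_allele.se / retained_allele.lambda_hat) ** 2
    se_r = (
        r * math.sqrt(rel)
        if affected_allele.lambda_hat > 0
        else affected_allele.se / retained_allele.lambda_hat
    )
    if alteration == "single_copy_loss":
        if r - Z95 * se_r > 1.0:
            raise ModelMismatchError(
                f"allele ratio {r:.3f} > 1 beyond CI: inconsistent with loss of "
                "the affected allele"
            )
        f, f_lo, f_hi = 1.0 - r, 1.0 - (r + Z95 * se_r), 1.0 - (r - Z95 * se_r)
    elif alteration == "single_copy_gain":
        if r + Z95 * se_r < 1.0:
            raise ModelMismatchError(
                f"allele ratio {r:.3f} < 1 beyond CI: inconsistent with gain of "
                "the affected allele"
            )
        f, f_lo, f_hi = r - 1.0, (r - Z95 * se_r) - 1.0, (r + Z95 * se_r) - 1.0
    else:
        raise ValueError(f"unknown alteration {alteration!r}")
    clip = lambda x: min(1.0, max(0.0, x))
    return AberrantFractionEstimate(
        fraction=clip(f),
        ci95=(clip(f_lo), clip(f_hi)),
        alteration=alteration,
        locus_id=locus_id,
        ci_method="delta",
    )


def mutant_cell_fraction(
    maf: AlleleFractionEstimate,
    model: CloneModel,
    cna_fraction: AberrantFractionEstimate | None = None,
) -> CellFractionEstimate:
    """Copy-number-corrected fraction of cells carrying the mutation.

    * no CNA, diploid heterozygous:            MCF = 2 * MAF
    * single-copy loss of wild-type in L:      MCF = MAF * (2 - L)
    * single-copy gain of the mutant in G:     MCF = MAF * (2 + G) - G

    The loss/gain formulas follow from the chain model in which the CNA
    clone is nested inside the mutant clone.  CI by first-order
    propagation of the MAF and CNA-fraction uncertainties.
    """
    m, vm = maf.fraction, maf.se**2
    if cna_fraction is None:
        mcf = 2.0 * m
        var = 4.0 * vm
    elif cna_fraction.alteration == "single_copy_loss":
        L, vL = cna_fraction.fraction, cna_fraction.se**2
        mcf = m * (2.0 - L)
        var = (2.0 - L) ** 2 * vm + m**2 * vL
    else:  # single_copy_gain
        G, vG = cna_fraction.fraction, cna_fraction.se**2
        mcf = m * (2.0 + G) - G
        var = (2.0 + G) ** 2 * vm + (m - 1.0) ** 2 * vG
    se = math.sqrt(var)
    if mcf > 1.0 + Z95 * se or mcf < -Z95 * se:
        raise InconsistentMeasurementsError(
            f"derived mutant cell fraction {mcf:.3f} lies outside [0,1] beyond "
            "its CI; MAF and CNA measurements are mutually inconsistent"
        )
    mut_locus = model.mutation_locus()
    clip = lambda x: min(1.0, max(0.0, x))
    return CellFractionEstimate(
        fraction=clip(mcf),
        ci95=(clip(mcf - Z95 * se), clip(mcf + Z95 * se)),
        event=f"{mut_locus.locus_id}:{mut_locus.somatic_alleles[0]}",
        ci_method="delta",
    )


# ---------------------------------------------------------------------------
# deconvolution


@dataclass(frozen=True)
class Observation:
    """One bulk measurement used to constrain the composition.

    statistic:
        ``maf``  mutant allele fraction at ``locus_id`` (needs ``allele``);
        ``cn``   germline-normalised copy number at ``locus_id``;
        ``aberrant_fraction`` fraction of cells with a gain/loss at
        ``locus_id`` (needs ``alteration``);
        ``cell_fraction``     fraction of cells carrying >= 1 copy of
        ``allele`` at ``locus_id`` (e.g. the mutation-positive fraction).
    """

    statistic: Literal["maf", "cn", "aberrant_fraction", "cell_fraction"]
    locus_id: str
    value: float
    ci95: tuple[float, float] | None = None
    allele: str | None = None
    alteration: Alteration | None = None

    @property
    def se(self) -> float:
        if self.ci95 is None:
            return 0.0
        lo, hi = self.ci95
        return (hi - lo) / (2 * Z95)

    @staticmethod
    def from_estimate(
        est: Union[
            AlleleFractionEstimate,
            CopyNumberEstimate,
            AberrantFractionEstimate,
            CellFractionEstimate,
        ],
        locus_id: str,
        allele: str | None = None,
    ) -> "Observation":
        if isinstance(est, AlleleFractionEstimate):
            return Observation("maf", locus_id, est.fraction, est.ci95, allele=allele)
        if isinstance(est, CopyNumberEstimate):
            return Observation("cn", locus_id, est.cn, est.ci95)
        if isinstance(est, AberrantFractionEstimate):
            return Observation(
                "aberrant_fraction", locus_id, est.fraction, est.ci95,
                alteration=est.alteration,
            )
        if isinstance(est, CellFractionEstimate):
            return Observation(
                "cell_fraction", locus_id, est.fraction, est.ci95, allele=allele
            )
        raise TypeError(f"cannot build an observation from {type(est).__name__}")


@dataclass(frozen=True)
class DeconvolutionResult:
    population_ids: tuple[str, ...]
    proportions: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...]
    n_boot: int
    seed: int | None
    method: str = "simplex-constrained WLS, parametric bootstrap"

    @property
    def composition(self) -> CloneComposition:
        return CloneComposition(self.population_ids, self.proportions)

    def __getitem__(self, population_id: str) -> float:
        return self.proportions[self.population_ids.index(population_id)]


def _design_row(model: CloneModel, obs: Observation) -> tuple[np.ndarray, float]:
    """Linear row a such that a . w = b for composition w."""
    pids = model.population_ids
    locus = model.locus(obs.locus_id)
    cmat = model.copy_matrix(obs.locus_id)
    totals = np.array([sum(cmat[p].values()) for p in pids], dtype=float)
    if obs.statistic == "cn":
        return 2.0 * totals / locus.germline_copies, obs.value
    if obs.statistic == "aberrant_fraction":
        if obs.alteration is None:
            raise ValueError("aberrant_fraction observation needs an alteration")
        sign = -1.0 if obs.alteration == "single_copy_loss" else 1.0
        row = np.maximum(sign * (totals - locus.germline_copies), 0.0)
        return row, obs.value
    if obs.statistic == "cell_fraction":
        allele = obs.allele or locus.somatic_alleles[0]
        row = np.array([1.0 if cmat[p][allele] >= 1 else 0.0 for p in pids])
        return row, obs.value
    if obs.statistic == "maf":
        allele = obs.allele or locus.somatic_alleles[0]
        copies = np.array([cmat[p][allele] for p in pids], dtype=float)
        # maf = (c.w)/(t.w)  ->  (c - maf*t).w = 0
        return copies - obs.value * totals, 0.0
    raise ValueError(f"unknown statistic {obs.statistic!r}")


def _solve_simplex_wls(
    A: np.ndarray, b: np.ndarray, w: np.ndarray, strict: bool, neg_tol: float
) -> np.ndarray:
    """Minimise ||diag(sqrt(w)) (A x - b)|| subject to sum(x)=1, x>=0.

    The equality-constrained solution is computed first by eliminating the
    sum-to-one constraint (minimal-norm least squares, which also breaks
    ties in rank-deficient directions); non-negativity is enforced by NNLS
    with a heavily weighted sum-to-one row only when needed, so consistent
    determined systems are solved exactly.
    """
    k = A.shape[1]
    sw = np.sqrt(w)[:, None]
    # parameterise x = x0 + N u with sum(x0) = 1, columns of N summing to 0
    x0 = np.full(k, 1.0 / k)
    ones = np.ones((k, 1))
    N = np.eye(k) - ones @ ones.T / k
    # orthonormal basis of the sum-zero subspace
    Nq, _ = np.linalg.qr(N)
    Nq = Nq[:, : k - 1]
    u, *_ = np.linalg.lstsq(sw * (A @ Nq), (sw[:, 0]) * (b - A @ x0), rcond=None)
    x = x0 + Nq @ u
    if x.min() >= -1e-9:
        x = np.clip(x, 0.0, None)
        return x / x.sum()
    if strict and x.min() < -neg_tol:
        raise ModelMismatchError(
            f"least-squares composition has a negative proportion "
            f"({x.min():.3f} < -{neg_tol}); the observations are inconsistent "
            "with this clone model"
        )
    mu = 1e4 * max(np.sqrt(w).max(), 1.0)
    A_aug = np.vstack([np.sqrt(w)[:, None] * A, mu * np.ones((1, k))])
    b_aug = np.concatenate([np.sqrt(w) * b, [mu]])
    x, _ = nnls(A_aug, b_aug)
    s = x.sum()
    if s <= 0:
        raise ModelMismatchError("degenerate non-negative solution (all zero)")
    return x / s


def deconvolve(
    model: CloneModel,
    observations: Sequence[Observation],
    n_boot: int = 200,
    seed: int | None = 0,
    neg_tol: float = 0.05,
) -> DeconvolutionResult:
    """Infer the clone composition from bulk measurements.

    Solves the linear forward model for the mixing proportions by weighted
    least squares on the simplex (weights = inverse CI-derived variances;
    observations without a CI get unit weight on a common scale).  When the
    system is determined and consistent the exact solution is returned.
    Per-population CIs come from a seeded parametric bootstrap that
    resamples each observation from a normal with its CI-derived SE.

    Raises
    ------
    UnidentifiableModelError
        If the design matrix (with the sum-to-one constraint) is rank
        deficient; the error names the confounded populations.
    ModelMismatchError
        If the unconstrained-on-the-simplex solution is negative beyond
        ``neg_tol``.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("deconvolve needs at least one observation")
    pids = tuple(model.population_ids)
    k = len(pids)

    def build(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows, bs = [], []
        for o, v in zip(obs, values):
            o2 = Observation(o.statistic, o.locus_id, float(v), o.ci95, o.allele, o.alteration)
            a, b = _design_row(model, o2)
            rows.append(a)
            bs.append(b)
        return np.array(rows), np.array(bs)

    values0 = np.array([o.value for o in obs])
    A, b = build(values0)

    M = np.vstack([A, np.ones(k)])
    if np.linalg.matrix_rank(M, tol=1e-10) < k:
        _, _, vt = np.linalg.svd(M)
        null = vt[-1]
        confounded = [pids[i] for i in np.nonzero(np.abs(null) > 1e-8)[0]]
        raise UnidentifiableModelError(
            "observations do not identify the composition; confounded "
            f"populations: {confounded}",
            confounded=confounded,
        )

    ses = np.array([o.se for o in obs])
    floor = max(ses[ses > 0].min() if (ses > 0).any() else 1.0, 1e-6)
    weights = 1.0 / np.maximum(ses, 0.1 * floor) ** 2

    x = _solve_simplex_wls(A, b, weights, strict=True, neg_tol=neg_tol)

    if n_boot > 0 and (ses > 0).any():
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, k))
        for i in range(n_boot):
            v = rng.normal(values0, ses)
            Ab, bb = build(v)
            boots[i] = _solve_simplex_wls(Ab, bb, weights, strict=False, neg_tol=neg_tol)
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)
        ci = tuple(
            (float(min(l, xi)), float(max(h, xi))) for l, h, xi in zip(lo, hi, x)
        )
    else:
        ci = tuple((float(xi), float(xi)) for xi in x)

    return DeconvolutionResult(
        population_ids=pids,
        proportions=tuple(float(v) for v in x),
        ci95=ci,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# event ordering


@dataclass(frozen=True)
class EventGroup:
    """Events statistically indistinguishable in cell fraction."""

    label: Literal["clonal", "subclonal"]
    events: tuple[str, ...]
    fractions: tuple[float, ...]

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions))


def order_events(
    fractions: Sequence[AberrantFractionEstimate | CellFractionEstimate],
    alpha: float = 0.05,
) -> list[EventGroup]:
    """Group events by cell fraction and label them clonal or subclonal.

    Events whose pairwise two-proportion z-tests (on CI-derived standard
    errors) are non-significant at ``alpha`` are merged transitively into
    one group (connected components, hence permutation invariant).  Groups
    are sorted by descending mean fraction; the top group is labelled
    clonal, all others subclonal.
    """
    n = len(fractions)
    names = [
        getattr(f, "event", "") or getattr(f, "locus_id", "") or f"event{i}"
        for i, f in enumerate(fractions)
    ]
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            fi, fj = fractions[i], fractions[j]
            se = math.sqrt(fi.se**2 + fj.se**2)
            if se == 0:
                p = 1.0 if fi.fraction == fj.fraction else 0.0
            else:
                z = (fi.fraction - fj.fraction) / se
                p = 2.0 * stats.norm.sf(abs(z))
            if p >= alpha:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = sorted(
        comps.values(), key=lambda ix: -float(np.mean([fractions[i].fraction for i in ix]))
    )
    out = []
    for gi, ix in enumerate(groups):
        ix = sorted(ix, key=lambda i: (-fractions[i].fraction, names[i]))
        out.append(
            EventGroup(
                label="clonal" if gi == 0 else "subclonal",
                events=tuple(names[i] for i in ix),
                fractions=tuple(fractions[i].fraction for i in ix),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ready-made chain models for the two study scenarios


def loh_chain_model(locus_id: str = "CYSLTR2") -> CloneModel:
    """Germline -> heterozygous mutant clone -> clone with a single-copy
    loss of the wild-type allele."""
    return CloneModel(
        loci=[Locus(locus_id=locus_id, alleles={"mut": 0, "wt": 2})],
        populations=[
            ClonePopulation(population_id="healthy"),
            ClonePopulation(
                population_id="cloneI",
                parent="healthy",
                copies={locus_id: {"mut": 1, "wt": 1}},
            ),
            ClonePopulation(
                population_id="cloneII",
                parent="cloneI",
                copies={locus_id: {"mut": 1, "wt": 0}},
            ),
        ],
    )


def gain_chain_model(locus_id: str = "CYSLTR2") -> CloneModel:
    """Germline -> heterozygous mutant clone -> clone with an extra copy of
    the mutant allele."""
    return CloneModel(
        loci=[Locus(locus_id=locus_id, alleles={"mut": 0, "wt": 2})],
        populations=[
            ClonePopulation(population_id="healthy"),
            ClonePopulation(
                population_id="cloneI",
                parent="healthy",
                copies={locus_id: {"mut": 1, "wt": 1}},
            ),
            ClonePopulation(
                population_id="cloneII",
                parent="cloneI",
                copies={locus_id: {"mut": 2, "wt": 1}},
            ),
        ],
    )
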