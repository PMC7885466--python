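"""Synthetic ddPCR wells, clone-mixture tumours, and allele counts.

Droplet generation follows the physics of partitioning: each target's
molecules load into droplets independently Poisson(lambda), so a droplet
is positive for target i with probability 1 - e^{-lambda_i}, independently
across targets (no competition between amplicons).  Tumour simulations mix
healthy cells with nested clones, translate composition-weighted allele
copy numbers into per-channel loading rates, and emit one classified well
per assay together with a ground-truth record.  Everything is driven by a
``numpy`` Generator seeded explicitly, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .clones import CloneComposition, CloneModel, forward_model
from .records import (
    AlleleCountPair,
    DropletWell,
    DEFAULT_DROPLET_VOLUME_NL,
)


class SimulationConfig(BaseModel):
    """Study-condition parameters for the tumour simulator.

    ``input_copies_per_assay`` is the expected number of copies of a
    germline-diploid locus loaded per well; ~15,000 copies in ~20,000
    droplets gives per-channel occupancies in the assay's sweet spot
    (lambda ~ 0.3-0.8).  ``rna_skew`` is the per-copy transcription weight
    of allele 1: 0.5 means both alleles are expressed equally per copy.
    ``pipetting_cv`` optionally adds a multiplicative lognormal factor to
    the loading of each well (default off).
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    seed: int
    clone_model: CloneModel
    composition: list[float]
    n_droplets: int = 20_000
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    input_copies_per_assay: float = 15_000.0
    rna_skew: float = 0.5
    rna_depth: int = 5_000
    pipetting_cv: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if len(self.composition) != len(self.clone_model.populations):
            raise ValueError("one proportion per population required")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if not 0.0 <= self.rna_skew <= 1.0:
            raise ValueError("rna_skew must be in [0,1]")
        if self.n_droplets <= 0 or self.rna_depth <= 0 or self.input_copies_per_assay <= 0:
            raise ValueError("counts must be positive")
        return self

    def clone_composition(self) -> CloneComposition:
        return CloneComposition(
            tuple(self.clone_model.population_ids), tuple(self.composition)
        )


def simulate_well(
    true_lambda_ch1: float,
    true_lambda_ch2: float,
    n_droplets: int = 20_000,
    seed: int | np.random.Generator | None = None,
    well_id: str = "sim",
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> DropletWell:
    """Simulate one duplex well with independent Poisson occupancy.

    Droplet categories follow a multinomial with cell probabilities
    p1*p2, p1*(1-p2), (1-p1)*p2, (1-p1)*(1-p2) where
    p_i = 1 - e^{-lambda_i}.
    """
    if true_lambda_ch1 < 0 or true_lambda_ch2 < 0:
        raise ValueError("loading rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p1 = -np.expm1(-true_lambda_ch1)
    p2 = -np.expm1(-true_lambda_ch2)
    probs = [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)]
    dp, c1, c2, neg = rng.multinomial(n_droplets, probs)
    return DropletWell(
        well_id=well_id,
        n_double_pos=int(dp),
        n_ch1_only=int(c1),
        n_ch2_only=int(c2),
        n_negative=int(neg),
        droplet_volume_nl=droplet_volume_nl,
    )


@dataclass(frozen=True)
class TumorTruth:
    """Ground truth behind a simulated tumour sample."""

    composition: CloneComposition
    maf: dict[str, float]  # locus -> mutant/first-allele fraction
    cn: dict[str, float]  # locus -> germline-normalised copy number
    lambdas: dict[str, tuple[float, float]]  # assay -> (ch1, ch2) loading rates


def _locus_assays(model: CloneModel) -> list[tuple[str, str, Literal["duplex", "cn"]]]:
    """Default panel: one duplex per two-allele locus (mutation or SNP),
    one copy-number multiplex (target vs diploid reference) per locus."""
    assays: list[tuple[str, str, Literal["duplex", "cn"]]] = []
    for locus in model.loci:
        if len(locus.alleles) == 2:
            assays.append((f"{locus.locus_id}_duplex", locus.locus_id, "duplex"))
        assays.append((f"{locus.locus_id}_cn", locus.locus_id, "cn"))
    return assays


def simulate_tumor(
    config: SimulationConfig,
) -> tuple[dict[str, DropletWell], TumorTruth]:
    """Simulate one well per assay for a clone-mixture tumour.

    Per-assay loading rates are the forward-model allele averages scaled
    so that a diploid locus receives ``input_copies_per_assay`` copies per
    well: lambda(target) = input * (avg copies per cell / 2) / n_droplets.
    Duplex assays put the locus's two alleles on channels 1 and 2;
    copy-number assays put the locus total on channel 1 and a diploid
    reference on channel 2.
    """
    rng = np.random.default_rng(config.seed)
    comp = config.clone_composition()
    pred = forward_model(config.clone_model, comp)
    per_copy = config.input_copies_per_assay / (2.0 * config.n_droplets)

    wells: dict[str, DropletWell] = {}
    lambdas: dict[str, tuple[float, float]] = {}
    for assay_id, locus_id, kind in _locus_assays(config.clone_model):
        lp = pred[locus_id]
        if kind == "duplex":
            a1, a2 = list(config.clone_model.locus(locus_id).alleles)
            lam1 = per_copy * lp.allele_avg[a1]
            lam2 = per_copy * lp.allele_avg[a2]
        else:
            lam1 = per_copy * lp.total_avg
            lam2 = per_copy * 2.0  # germline-diploid reference target
        if config.pipetting_cv > 0:
            sigma = np.sqrt(np.log1p(config.pipetting_cv**2))
            factor = rng.lognormal(-(sigma**2) / 2.0, sigma)
            lam1, lam2 = lam1 * factor, lam2 * factor
        lambdas[assay_id] = (lam1, lam2)
        wells[assay_id] = simulate_well(
            lam1,
            lam2,
            n_droplets=config.n_droplets,
            seed=rng,
            well_id=assay_id,
            droplet_volume_nl=config.droplet_volume_nl,
        )

    maf = {}
    for locus in config.clone_model.loci:
        lp = pred[locus.locus_id]
        if len(locus.alleles) == 2 and lp.total_avg > 0:
            first = next(iter(locus.alleles))
            maf[locus.locus_id] = lp.allele_fraction(first)
    truth = TumorTruth(
        composition=comp,
        maf=maf,
        cn={l.locus_id: pred[l.locus_id].cn for l in config.clone_model.loci},
        lambdas=lambdas,
    )
    return wells, truth


@dataclass(frozen=True)
class ExpressionTruth:
    dna_fraction: float
    rna_fraction: float
    rna_skew: float


def simulate_expression(
    config: SimulationConfig,
    locus_id: str | None = None,
    sample_id: str = "sim",
) -> tuple[AlleleCountPair, AlleleCountPair, ExpressionTruth]:
    """Simulate paired DNA and RNA allele counts for one two-allele locus.

    DNA counts are binomial on the composition-averaged allele copy
    fractions; RNA counts are binomial at ``rna_depth`` with the per-copy
    expression weight ``rna_skew`` applied to allele 1:

        p_rna = s*c1 / (s*c1 + (1-s)*c2)

    so s = 0.5 reproduces the DNA fraction (proportional expression) and
    s = 1 gives monoallelic expression of allele 1.
    """
    rng = np.random.default_rng(config.seed)
    model = config.clone_model
    if locus_id is None:
        two = [l for l in model.loci if len(l.alleles) == 2]
        if not two:
            raise ValueError("no two-allele locus in the clone model")
        locus_id = two[0].locus_id
    locus = model.locus(locus_id)
    labels = tuple(locus.alleles)
    pred = forward_model(model, config.clone_composition())[locus_id]
    c1, c2 = (pred.allele_avg[a] for a in labels)
    if c1 + c2 <= 0:
        raise ValueError(f"locus {locus_id!r} has zero average copies")
    p_dna = c1 / (c1 + c2)
    s = config.rna_skew
    denom = s * c1 + (1.0 - s) * c2
    p_rna = (s * c1 / denom) if denom > 0 else 0.0

    n_dna = int(round(config.input_copies_per_assay))
    k_dna = int(rng.binomial(n_dna, p_dna))
    k_rna = int(rng.binomial(config.rna_depth, p_rna))
    dna = AlleleCountPair(
        sample_id=sample_id, level="DNA", n_allele1=k_dna, n_allele2=n_dna - k_dna,
        source="ddPCR", allele_labels=labels,
    )
    rna = AlleleCountPair(
        sample_id=sample_id, level="RNA", n_allele1=k_rna,
        n_allele2=config.rna_depth - k_rna, source="ddPCR", allele_labels=labels,
    )
    return dna, rna, ExpressionTruth(p_dna, p_rna, s)


def random_chain_model(
    rng: np.random.Generator,
    n_clones: int | None = None,
    p_gain: float = 0.5,
) -> "CloneModel":
    """Random linear-chain clone model for property testing.

    One mutation locus (somatic allele acquired by clone I) plus one
    private single-copy CNA locus per clone, so that a mutant allele
    fraction plus one copy number per CNA locus always identifies the
    composition.
    """
    from .clones import ClonePopulation, Locus

    if n_clones is None:
        n_clones = int(rng.integers(1, 4))
    loci = [Locus(locus_id="MUT", alleles={"mut": 0, "wt": 2})]
    pops = [ClonePopulation(population_id="healthy")]
    for j in range(1, n_clones + 1):
        lid = f"CNA{j}"
        loci.append(Locus(locus_id=lid, alleles={"a": 1, "b": 1}))
        copies: dict[str, dict[str, int]] = {lid: (
            {"a": 2, "b": 1} if rng.random() < p_gain else {"a": 0, "b": 1}
        )}
        if j == 1:
            copies["MUT"] = {"mut": 1, "wt": 1}
        pops.append(
            ClonePopulation(population_id=f"clone{j}", parent=pops[-1].population_id,
                            copies=copies)
        )
    return CloneModel(loci=loci, populations=pops)


def random_composition(
    rng: np.random.Generator, n_populations: int, min_fraction: float = 0.05
) -> CloneComposition:
    """Interior point of the simplex with every component >= min_fraction."""
    w = rng.dirichlet(np.ones(n_populations))
    w = min_fraction + (1.0 - n_populations * min_fraction) * w
    w = w / w.sum()
    pids = tuple(["healthy"] + [f"clone{j}" for j in range(1, n_populations)])
    return CloneComposition(pids, tuple(float(x) for x in w))
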