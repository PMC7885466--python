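"""End-to-end analysis of one sample: quantify -> copy number -> cell
fractions -> deconvolution -> event ordering -> report.

The report is a plain JSON-able dict holding every estimate at full
precision; :func:`render_report` renders the human-readable summary from
that same dict (percentages rounded to whole numbers for display), so
every displayed number is traceable to a JSON record.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

from . import droplet
from .clones import (
    CloneModel,
    Observation,
    aberrant_fraction_from_cn,
    aberrant_fraction_from_snp,
    deconvolve,
    mutant_cell_fraction,
    order_events,
)
from .errors import CloneDropError, InputValidationError, UnidentifiableModelError
from .io import AssayPanel
from .records import (
    AberrantFractionEstimate,
    AlleleFractionEstimate,
    CellFractionEstimate,
    ConcentrationEstimate,
    CopyNumberEstimate,
    DropletWell,
)


@dataclass(frozen=True)
class PipelineOptions:
    seed: int = 0
    alpha: float = 0.05
    n_boot: int = 200


@contextmanager
def _stage(name: str):
    try:
        yield
    except CloneDropError as exc:
        exc.args = (f"[stage {name}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
        raise


def _conc_dict(c: ConcentrationEstimate) -> dict:
    return {
        "lambda": c.lambda_hat,
        "copies_per_ul": c.copies_per_ul,
        "ci95": list(c.ci95),
        "n_droplets": c.n_droplets,
        "ci_method": c.ci_method,
    }


def _frac_dict(f) -> dict:
    return {"fraction": f.fraction, "ci95": list(f.ci95), "ci_method": f.ci_method}


def run_pipeline(
    panel: AssayPanel,
    clone_model: CloneModel,
    well_counts: list[tuple[str, DropletWell]],
    options: PipelineOptions = PipelineOptions(),
    sample_id: str = "sample",
) -> dict:
    """Run the full analysis for one sample and return the report dict.

    Replicate wells of the same assay are pooled (counts summed) before
    Poisson correction.  Loci whose copy-number CI contains 2 (and SNP
    ratio CI contains 1) are treated as unaltered; if no somatic event is
    detected at all, the report says so and the composition is 100%
    healthy.
    """
    panel.validate_against_model(clone_model)
    by_assay: dict[str, list[DropletWell]] = {}
    for assay_id, well in well_counts:
        by_assay.setdefault(assay_id, []).append(well)
    absent = [a.assay_id for a in panel.assays if a.assay_id not in by_assay]
    if absent:
        raise InputValidationError(
            f"panel assays without wells in the count table: {absent}"
        )

    report: dict = {
        "sample_id": sample_id,
        "seed": options.seed,
        "alpha": options.alpha,
        "concentrations": {},
        "maf": None,
        "copy_number": {},
        "snp_imbalance": {},
        "aberrant_fractions": [],
        "mutant_cell_fraction": None,
        "composition": None,
        "event_ordering": [],
        "notes": [],
    }

    mut_locus = clone_model.mutation_locus()
    maf_est: AlleleFractionEstimate | None = None
    cn_by_locus: dict[str, CopyNumberEstimate] = {}
    snp_conc: dict[str, tuple[str, ConcentrationEstimate, ConcentrationEstimate]] = {}

    with _stage("quantify"):
        quant: dict[str, tuple[ConcentrationEstimate, ConcentrationEstimate]] = {}
        for assay in panel.assays:
            pooled = droplet.pool_wells(by_assay[assay.assay_id], well_id=assay.assay_id)
            ch1, ch2 = droplet.duplex_quantify(pooled)
            quant[assay.assay_id] = (ch1, ch2)
            report["concentrations"][assay.assay_id] = {
                "ch1": _conc_dict(ch1),
                "ch2": _conc_dict(ch2),
                "n_wells_pooled": len(by_assay[assay.assay_id]),
            }

    with _stage("allele-fractions"):
        for assay in panel.assays:
            ch1, ch2 = quant[assay.assay_id]
            if assay.kind == "mutation_duplex":
                maf_est = droplet.allele_fraction(
                    ch1, ch2,
                    allele_labels=(assay.ch1_allele or "mut", assay.ch2_allele or "wt"),
                )
                report["maf"] = _frac_dict(maf_est)
            elif assay.kind == "snp_duplex":
                snp_conc[assay.locus_id] = (assay.assay_id, ch1, ch2)

    with _stage("copy-number"):
        for assay in panel.assays:
            if assay.kind != "cn_multiplex":
                continue
            ch1, ch2 = quant[assay.assay_id]
            if assay.reference_assay_id is not None:
                ref_ch1, _ = quant[assay.reference_assay_id]
                ref = ref_ch1
            else:
                ref = ch2
            cn = droplet.copy_number(
                ch1, ref, target_assay=assay.assay_id,
                reference_assay=assay.reference_assay_id or f"{assay.assay_id}/ch2",
            )
            cn_by_locus[assay.locus_id] = cn
            report["copy_number"][assay.locus_id] = {
                "cn": cn.cn, "ci95": list(cn.ci95), "ci_method": cn.ci_method,
            }

    aberrant: list[AberrantFractionEstimate] = []
    with _stage("aberrant-fractions"):
        for locus_id, cn in cn_by_locus.items():
            lo, hi = cn.ci95
            if lo <= 2.0 <= hi:
                continue  # no alteration detectable at this locus
            direction = "single_copy_loss" if cn.cn < 2.0 else "single_copy_gain"
            aberrant.append(aberrant_fraction_from_cn(cn, direction, locus_id=locus_id))
        for locus_id, (assay_id, ch1, ch2) in snp_conc.items():
            if locus_id in cn_by_locus:
                continue  # the multiplex already covers this locus
            retained, affected = (ch1, ch2) if ch1.lambda_hat >= ch2.lambda_hat else (ch2, ch1)
            ratio_est = droplet.copy_number(affected, retained, reference_copies=1)
            rlo, rhi = ratio_est.ci95
            if rlo <= 1.0 <= rhi:
                continue
            direction = "single_copy_loss" if ratio_est.cn < 1.0 else "single_copy_gain"
            est = aberrant_fraction_from_snp(retained, affected, direction, locus_id=locus_id)
            aberrant.append(est)
            report["snp_imbalance"][locus_id] = {
                "assay_id": assay_id,
                "fraction": est.fraction,
                "ci95": list(est.ci95),
                "alteration": est.alteration,
            }
        report["aberrant_fractions"] = [
            {
                "locus_id": a.locus_id,
                "alteration": a.alteration,
                "fraction": a.fraction,
                "ci95": list(a.ci95),
            }
            for a in aberrant
        ]

    mcf: CellFractionEstimate | None = None
    with _stage("mutant-cell-fraction"):
        if maf_est is not None:
            cna_at_mut = next(
                (a for a in aberrant if a.locus_id == mut_locus.locus_id), None
            )
            lo, hi = maf_est.ci95
            if maf_est.fraction > 0 or hi > 0:
                mcf = mutant_cell_fraction(maf_est, clone_model, cna_at_mut)
                report["mutant_cell_fraction"] = {
                    "fraction": mcf.fraction,
                    "ci95": list(mcf.ci95),
                    "corrected_for": None if cna_at_mut is None else cna_at_mut.alteration,
                }

    somatic = bool(aberrant) or (
        maf_est is not None and maf_est.ci95[0] > 0 and maf_est.fraction > 0.005
    )
    if not somatic:
        report["notes"].append("no somatic events detected")
        report["composition"] = {
            "populations": clone_model.population_ids,
            "proportions": [1.0] + [0.0] * (len(clone_model.populations) - 1),
            "ci95": None,
        }
        return report

    with _stage("deconvolution"):
        observations: list[Observation] = []
        if mcf is not None:
            observations.append(
                Observation(
                    "cell_fraction", mut_locus.locus_id, mcf.fraction, mcf.ci95,
                    allele=mut_locus.somatic_alleles[0],
                )
            )
        for a in aberrant:
            observations.append(Observation.from_estimate(a, a.locus_id))
        try:
            result = deconvolve(
                clone_model, observations, n_boot=options.n_boot, seed=options.seed
            )
            report["composition"] = {
                "populations": list(result.population_ids),
                "proportions": list(result.proportions),
                "ci95": [list(c) for c in result.ci95],
                "n_boot": result.n_boot,
                "seed": result.seed,
                "method": result.method,
            }
        except UnidentifiableModelError as exc:
            report["notes"].append(f"deconvolution skipped: {exc}")

    with _stage("event-ordering"):
        events = ([mcf] if mcf is not None else []) + aberrant
        groups = order_events(events, alpha=options.alpha)
        report["event_ordering"] = [
            {
                "label": g.label,
                "events": list(g.events),
                "fractions": list(g.fractions),
                "mean_fraction": g.mean_fraction,
            }
            for g in groups
        ]
        if groups:
            narrative = []
            for g in groups:
                narrative.append(
                    {"step": len(narrative) + 1, "label": g.label, "events": list(g.events)}
                )
            report["evolution_narrative"] = narrative

    return report


def render_report(report: dict) -> str:
    """Human-readable summary; percentages rounded to whole numbers."""
    pct = lambda x: f"{round(100 * x):d}%"
    lines = [f"Sample {report['sample_id']}", "=" * (7 + len(str(report["sample_id"])))]
    if report.get("maf") is not None:
        m = report["maf"]
        lines.append(
            f"Mutant allele fraction: {pct(m['fraction'])} "
            f"(95% CI {pct(m['ci95'][0])}-{pct(m['ci95'][1])})"
        )
    for locus, c in report.get("copy_number", {}).items():
        lines.append(f"Copy number {locus}: {c['cn']:.2f} "
                     f"(95% CI {c['ci95'][0]:.2f}-{c['ci95'][1]:.2f})")
    for a in report.get("aberrant_fractions", []):
        kind = "loss" if a["alteration"] == "single_copy_loss" else "gain"
        lines.append(f"Single-copy {kind} at {a['locus_id']}: {pct(a['fraction'])} of cells")
    if report.get("mutant_cell_fraction") is not None:
        m = report["mutant_cell_fraction"]
        lines.append(f"Mutant cell fraction: {pct(m['fraction'])} "
                     f"(95% CI {pct(m['ci95'][0])}-{pct(m['ci95'][1])})")
    comp = report.get("composition")
    if comp is not None:
        parts = ", ".join(
            f"{p} {pct(w)}" for p, w in zip(comp["populations"], comp["proportions"])
        )
        lines.append(f"Clonal composition: {parts}")
    for g in report.get("event_ordering", []):
        lines.append(f"{g['label'].capitalize()} events: {', '.join(g['events'])} "
                     f"(~{pct(g['mean_fraction'])} of cells)")
    for note in report.get("notes", []):
        lines.append(f"Note: {note}")
    return "\n".join(lines) + "\n"
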