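"""File formats: well-count CSV, panel/clone-model JSON, observation and
allele-count TSV, and report writers.

All tabular IO goes through pandas; configuration files are JSON or YAML
validated by the pydantic schemas.  Readers report malformed rows with
their line numbers (1-based, header included) so plate-layout mistakes are
easy to trace.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .clones import CloneModel, Observation
from .errors import InputValidationError
from .records import (
    AlleleCountPair,
    DropletWell,
    DEFAULT_DROPLET_VOLUME_NL,
)

WELL_COLUMNS = ["well_id", "assay_id", "n_double_pos", "n_ch1_only", "n_ch2_only", "n_negative"]


class Assay(BaseModel):
    """One ddPCR assay: what each fluorescence channel measures.

    kinds: ``mutation_duplex`` (ch1 = somatic allele, ch2 = wild-type),
    ``snp_duplex`` (ch1/ch2 = the two germline SNP alleles), and
    ``cn_multiplex`` (ch1 = locus total, ch2 = a germline-diploid
    reference, either in-well or via ``reference_assay_id``).
    """

    assay_id: str
    kind: Literal["mutation_duplex", "snp_duplex", "cn_multiplex"]
    locus_id: str
    ch1_allele: Optional[str] = None
    ch2_allele: Optional[str] = None
    reference_assay_id: Optional[str] = None


class AssayPanel(BaseModel):
    assays: list[Assay]

    @model_validator(mode="after")
    def _check(self) -> "AssayPanel":
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate assay ids: {ids}")
        for a in self.assays:
            if a.reference_assay_id is not None and a.reference_assay_id not in ids:
                raise ValueError(
                    f"assay {a.assay_id!r}: unknown reference assay "
                    f"{a.reference_assay_id!r}"
                )
        return self

    def validate_against_model(self, model: CloneModel) -> None:
        locus_ids = {l.locus_id for l in model.loci}
        for a in self.assays:
            if a.locus_id not in locus_ids:
                raise InputValidationError(
                    f"assay {a.assay_id!r} targets unknown locus {a.locus_id!r}"
                )
            if a.kind in ("mutation_duplex", "snp_duplex"):
                alleles = set(model.locus(a.locus_id).alleles)
                for ch in (a.ch1_allele, a.ch2_allele):
                    if ch is not None and ch not in alleles:
                        raise InputValidationError(
                            f"assay {a.assay_id!r}: allele {ch!r} not defined at "
                            f"locus {a.locus_id!r} (known: {sorted(alleles)})"
                        )

    def __getitem__(self, assay_id: str) -> Assay:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)


def read_panel(path: str | Path) -> AssayPanel:
    return AssayPanel.model_validate(_load_config(path))


def read_clone_model(path: str | Path) -> CloneModel:
    return CloneModel.model_validate(_load_config(path))


def _load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def read_well_counts(path: str | Path) -> list[tuple[str, DropletWell]]:
    """Read the well-count CSV (one row per well per assay).

    Required columns: well_id, assay_id, n_double_pos, n_ch1_only,
    n_ch2_only, n_negative; optional droplet_volume_nl.  Malformed rows
    raise :class:`InputValidationError` naming the file line.
    """
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    errors: list[str] = []
    out: list[tuple[str, DropletWell]] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        key = (str(row["well_id"]), str(row["assay_id"]))
        if key in seen:
            errors.append(f"line {line}: duplicate well/assay pair {key}")
            continue
        seen.add(key)
        counts = {}
        bad = False
        for c in WELL_COLUMNS[2:]:
            v = row[c]
            if pd.isna(v) or int(v) != v or int(v) < 0:
                errors.append(f"line {line}: column {c!r} must be a count, got {v!r}")
                bad = True
            else:
                counts[c] = int(v)
        if bad:
            continue
        vol = row.get("droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)
        if pd.isna(vol):
            vol = DEFAULT_DROPLET_VOLUME_NL
        try:
            well = DropletWell(
                well_id=str(row["well_id"]), droplet_volume_nl=float(vol), **counts
            )
        except Exception as exc:  # zero-droplet wells etc.
            errors.append(f"line {line}: {exc}")
            continue
        out.append((str(row["assay_id"]), well))
    if errors:
        raise InputValidationError(f"{path}: " + "; ".join(errors))
    return out


def write_well_counts(path: str | Path, wells: dict[str, DropletWell]) -> None:
    rows = [
        {
            "well_id": w.well_id,
            "assay_id": assay_id,
            "n_double_pos": w.n_double_pos,
            "n_ch1_only": w.n_ch1_only,
            "n_ch2_only": w.n_ch2_only,
            "n_negative": w.n_negative,
            "droplet_volume_nl": w.droplet_volume_nl,
        }
        for assay_id, w in wells.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations(path: str | Path) -> dict[str, list[Observation]]:
    """Observation TSV -> sample_id -> observations.

    Columns: sample_id, locus_id, statistic, value, ci_low, ci_high and
    optional allele / alteration.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "locus_id", "statistic", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    out: dict[str, list[Observation]] = {}
    for idx, row in df.iterrows():
        ci = None
        if "ci_low" in df.columns and not pd.isna(row.get("ci_low")):
            ci = (float(row["ci_low"]), float(row["ci_high"]))
        allele = row.get("allele")
        alteration = row.get("alteration")
        try:
            obs = Observation(
                statistic=str(row["statistic"]),  # type: ignore[arg-type]
                locus_id=str(row["locus_id"]),
                value=float(row["value"]),
                ci95=ci,
                allele=None if pd.isna(allele) else str(allele),
                alteration=None if pd.isna(alteration) else str(alteration),  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise InputValidationError(f"{path}: line {idx + 2}: {exc}") from exc
        out.setdefault(str(row["sample_id"]), []).append(obs)
    return out


def write_observations(
    path: str | Path, observations: dict[str, list[Observation]]
) -> None:
    rows = [
        {
            "sample_id": sid,
            "locus_id": o.locus_id,
            "statistic": o.statistic,
            "value": o.value,
            "ci_low": None if o.ci95 is None else o.ci95[0],
            "ci_high": None if o.ci95 is None else o.ci95[1],
            "allele": o.allele,
            "alteration": o.alteration,
        }
        for sid, obs in observations.items()
        for o in obs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path) -> list[AlleleCountPair]:
    """Count TSV: sample_id, level, allele1_label, allele2_label,
    n_allele1, n_allele2, source."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "level", "n_allele1", "n_allele2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    pairs = []
    for idx, row in df.iterrows():
        try:
            pairs.append(
                AlleleCountPair(
                    sample_id=str(row["sample_id"]),
                    level=str(row["level"]),  # type: ignore[arg-type]
                    n_allele1=int(row["n_allele1"]),
                    n_allele2=int(row["n_allele2"]),
                    source=str(row.get("source", "ddPCR")),  # type: ignore[arg-type]
                    allele_labels=(
                        str(row.get("allele1_label", "allele1")),
                        str(row.get("allele2_label", "allele2")),
                    ),
                )
            )
        except Exception as exc:
            raise InputValidationError(f"{path}: line {idx + 2}: {exc}") from exc
    return pairs


def write_allele_counts(path: str | Path, pairs: list[AlleleCountPair]) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "level": p.level,
            "allele1_label": p.allele_labels[0],
            "allele2_label": p.allele_labels[1],
            "n_allele1": p.n_allele1,
            "n_allele2": p.n_allele2,
            "source": p.source,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
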