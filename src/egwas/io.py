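"""Tab-separated file interfaces, configuration, and run manifests.

All tables are UTF-8, tab-delimited, with a header row.  Dosage matrices
follow the PLINK RAW convention (one row per subject, one 0/1/2 column per
SNP); association, replication, variance and catalog tables reuse the
column vocabulary of the printed result tables (P, P_Bonf, Q, Beta,
R2technical, ...) so outputs can be compared side by side.  A minimal VCF
dialect (biallelic, GT only) is supported for genotype ingestion.
Round-trip identity read(write(x)) == x holds for every schema at the
written precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    ExpressionMatrix,
    GenotypeMatrix,
    SchemaError,
    validate_annotation,
    validate_covariates,
)
from .simulate import SimulationConfig

__all__ = [
    "read_genotypes", "write_genotypes", "read_expression", "write_expression",
    "read_annotation", "write_annotation", "read_covariates", "write_covariates",
    "read_catalog", "write_catalog", "read_table", "write_table",
    "read_vcf", "load_config", "RunManifest", "write_manifest",
]

FLOAT_FORMAT = "%.6g"


def _fmt(full_precision: bool) -> str | None:
    return None if full_precision else FLOAT_FORMAT


def write_table(df: pd.DataFrame, path, full_precision: bool = False) -> None:
    """Write any result table as TSV (6 significant digits by default)."""
    df.to_csv(path, sep="\t", index=False, float_format=_fmt(full_precision))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- genotypes -------------------------------------------------------------

def write_genotypes(
    geno: GenotypeMatrix, dosage_path, map_path, full_precision: bool = False
) -> None:
    dos = geno.dosages.copy()
    dos.insert(0, "subject", dos.index)
    dos.to_csv(dosage_path, sep="\t", index=False, float_format=_fmt(full_precision))
    m = geno.snp_map.copy()
    m.insert(0, "snp", m.index)
    m.to_csv(map_path, sep="\t", index=False, float_format=_fmt(full_precision))


def read_genotypes(dosage_path, map_path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t")
    if "subject" not in dos.columns:
        raise SchemaError(f"{dosage_path}: missing 'subject' column")
    dos = dos.set_index("subject")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    if "snp" not in snp_map.columns:
        raise SchemaError(f"{map_path}: missing 'snp' column")
    snp_map = snp_map.set_index("snp")
    return GenotypeMatrix(dosages=dos, snp_map=snp_map)


def read_vcf(path, max_missing: float = 1.0) -> GenotypeMatrix:
    """Minor-allele dosage from a biallelic, GT-only VCF.

    Multiallelic sites are skipped with a warning.  The minor allele is
    determined from the sample genotypes, so dosages always count the rarer
    allele.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    subjects = list(vcf.samples)
    rows, ids, chroms, poss, a1s, a2s = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic site {var.CHROM}:{var.POS} ({var.ID})"
            )
            continue
        alt_dose = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else np.nan
             for gt in var.genotypes],
            dtype=float,
        )
        alt_freq = np.nanmean(alt_dose) / 2.0
        if alt_freq <= 0.5:
            dose, minor, major = alt_dose, var.ALT[0], var.REF
        else:
            dose, minor, major = 2.0 - alt_dose, var.REF, var.ALT[0]
        if np.isnan(dose).mean() > max_missing:
            continue
        rows.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        a1s.append(minor)
        a2s.append(major)
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(subjects), 0)),
        index=pd.Index(subjects, name="subject"),
        columns=ids,
    )
    maf = np.array([np.nanmean(r) / 2.0 for r in rows]) if rows else np.array([])
    snp_map = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s, "maf": maf},
        index=pd.Index(ids, name="snp"),
    )
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map)


# --- expression ------------------------------------------------------------

def write_expression(
    expr: ExpressionMatrix, values_path, detection_path=None,
    full_precision: bool = False,
) -> None:
    vals = expr.values.copy()
    vals.insert(0, "probe", vals.index)
    vals.to_csv(values_path, sep="\t", index=False, float_format=_fmt(full_precision))
    if detection_path is not None:
        det = expr.detected.astype(int).copy()
        det.insert(0, "probe", det.index)
        det.to_csv(detection_path, sep="\t", index=False)


def read_expression(values_path, detection_path=None, tissue: str = "") -> ExpressionMatrix:
    vals = pd.read_csv(values_path, sep="\t")
    if "probe" not in vals.columns:
        raise SchemaError(f"{values_path}: missing 'probe' column")
    vals = vals.set_index("probe")
    detected = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t").set_index("probe")
        detected = det.astype(bool)
    return ExpressionMatrix(values=vals, detected=detected, tissue=tissue)


# --- annotation / covariates / catalog -------------------------------------

def write_annotation(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_annotation(ann)


def write_covariates(covariates: pd.DataFrame, path, full_precision: bool = False) -> None:
    validate_covariates(covariates).to_csv(
        path, sep="\t", index=False, float_format=_fmt(full_precision)
    )


def read_covariates(path) -> pd.DataFrame:
    return validate_covariates(pd.read_csv(path, sep="\t"))


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- association tables ----------------------------------------------------

#: Internal -> printed column names (the vocabulary of the result tables).
ASSOCIATION_COLUMNS = {
    "chrom": "CHR", "snp": "SNP", "probe": "PROBE", "symbol": "SYMBOL",
    "n": "N", "beta": "Beta", "se": "SE", "p": "P", "p_gc": "P_GC",
    "q": "Q", "p_bonf": "P_Bonf", "cohort": "COHORT", "tissue": "TISSUE",
    "testable": "TESTABLE",
}
_ASSOCIATION_INVERSE = {v: k for k, v in ASSOCIATION_COLUMNS.items()}


def format_association_table(
    results: pd.DataFrame,
    snp_map: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rename an association frame to the printed column vocabulary,
    joining in chromosome and gene symbol when maps are provided."""
    out = results.copy()
    if snp_map is not None:
        out["chrom"] = snp_map.loc[out["snp"], "chrom"].to_numpy()
    if annotation is not None:
        sym = annotation.set_index("probe")["symbol"]
        out["symbol"] = sym.loc[out["probe"]].to_numpy()
    cols = [c for c in ASSOCIATION_COLUMNS if c in out.columns]
    return out[cols].rename(columns=ASSOCIATION_COLUMNS)


def write_association(
    results: pd.DataFrame, path, snp_map=None, annotation=None,
    full_precision: bool = False,
) -> None:
    write_table(
        format_association_table(results, snp_map, annotation), path, full_precision
    )


def read_association(path) -> pd.DataFrame:
    """Read an association TSV back into internal (lowercase) columns."""
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns=_ASSOCIATION_INVERSE)


# --- configuration ---------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML run configuration; the ``simulation`` block becomes a
    :class:`SimulationConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.get("simulation", {})
    if "effect_table" in sim and sim["effect_table"] is not None:
        sim["effect_table"] = [tuple(row) for row in sim["effect_table"]]
    for key in ("maf_range", "tissues"):
        if key in sim and sim[key] is not None:
            sim[key] = tuple(sim[key])
    raw["simulation"] = SimulationConfig(**sim)
    return raw


# --- manifest --------------------------------------------------------------

@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run: configuration echo, seeds,
    input checksums, per-stage counts and inflation factors."""

    config: dict
    seeds: dict
    input_checksums: dict
    stage_counts: dict
    lambda_gc: dict
    software_version: str


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(dataclasses.asdict(manifest)), fh, indent=2, sort_keys=True)
        fh.write("\n")
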