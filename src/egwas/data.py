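"""Core in-memory containers shared across the pipeline.

The pipeline is matrix-shaped: a genotype dosage matrix (subjects x SNPs,
counts of the minor allele), an expression matrix (probes x samples, with a
parallel detection indicator), a probe annotation table mapping probes to
gene coordinates, and a per-sample covariate table.  Containers are thin
dataclasses over pandas objects with schema validation; all downstream
modules accept and return these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of a SNP map table (indexed by SNP id).
SNP_MAP_COLUMNS = ["chrom", "pos", "a1", "a2", "maf"]

#: Required columns of a probe annotation table.
ANNOTATION_COLUMNS = ["probe", "symbol", "chrom", "start", "end"]

#: Required columns of the per-sample covariate table.  ``subject`` links
#: replicate measurements of the same individual; ``replicate`` is 0 for the
#: primary measurement.  Optional ``ev1..evK`` columns hold ancestry
#: eigenvectors.
COVARIATE_COLUMNS = [
    "sample", "subject", "apoe4_dose", "age_at_death", "sex",
    "diagnosis", "plate", "rin", "replicate",
]


class SchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {', '.join(missing)}")


def _require_unique(values, name: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"duplicated {name}: {dups}")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix plus its SNP map.

    Parameters
    ----------
    dosages
        subjects x SNPs frame of values in {0, 1, 2} (NaN allowed for
        failed genotypes), indexed by subject id.
    snp_map
        One row per SNP (indexed by SNP id) with columns
        ``chrom, pos, a1, a2, maf``; ``maf`` is the minor allele frequency.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.snp_map, SNP_MAP_COLUMNS, "snp_map")
        _require_unique(self.snp_map.index, "SNP ids in snp_map")
        _require_unique(self.dosages.index, "subject ids")
        _require_unique(self.dosages.columns, "SNP ids in dosage matrix")
        if list(self.dosages.columns) != list(self.snp_map.index):
            if set(self.dosages.columns) != set(self.snp_map.index):
                raise SchemaError("dosage columns and snp_map index disagree")
            self.snp_map = self.snp_map.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"dosage value {vals[i, j]!r} for subject "
                f"{self.dosages.index[i]!r} / SNP {self.dosages.columns[j]!r} "
                "is not in {0, 1, 2}"
            )

    @property
    def subjects(self) -> pd.Index:
        return self.dosages.index

    @property
    def snps(self) -> pd.Index:
        return self.dosages.columns

    def empirical_maf(self) -> pd.Series:
        """Minor-allele frequency observed in the dosage matrix."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_subjects(self, subjects) -> "GenotypeMatrix":
        return replace(self, dosages=self.dosages.loc[subjects])


@dataclass
class ExpressionMatrix:
    """Probe-level expression values with a per-measurement detection call.

    ``values`` is probes x samples; ``detected`` is a same-shaped boolean
    frame (True where the probe gave detectable signal in that sample).
    """

    values: pd.DataFrame
    detected: pd.DataFrame | None = None
    tissue: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        _require_unique(self.values.index, "probe ids")
        _require_unique(self.values.columns, "sample ids")
        if self.detected is None:
            self.detected = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if self.detected.shape != self.values.shape:
            raise SchemaError(
                f"detection matrix shape {self.detected.shape} does not match "
                f"expression shape {self.values.shape}"
            )
        if not (
            self.detected.index.equals(self.values.index)
            and self.detected.columns.equals(self.values.columns)
        ):
            raise SchemaError("detection matrix ids do not match expression ids")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def detection_rate(self) -> pd.Series:
        """Fraction of samples in which each probe is detected."""
        return self.detected.mean(axis=1)

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return replace(
            self, values=self.values.loc[probes], detected=self.detected.loc[probes]
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.loc[:, samples],
            detected=self.detected.loc[:, samples],
        )


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe annotation table (1-based inclusive coordinates)."""
    _require_columns(annotation, ANNOTATION_COLUMNS, "annotation")
    _require_unique(annotation["probe"], "probe ids in annotation")
    if (annotation["start"] > annotation["end"]).any():
        bad = annotation.loc[annotation["start"] > annotation["end"], "probe"]
        raise SchemaError(f"gene_start > gene_end for probe(s): {list(bad[:5])}")
    if annotation["chrom"].astype(str).str.len().eq(0).any():
        raise SchemaError("empty chromosome name in annotation")
    return annotation


def validate_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample covariate table."""
    _require_columns(covariates, COVARIATE_COLUMNS, "covariates")
    _require_unique(covariates["sample"], "sample ids in covariates")
    used = [c for c in COVARIATE_COLUMNS if c not in ("sample", "subject", "plate")]
    na = covariates[used].isna().any()
    if na.any():
        raise SchemaError(
            f"missing values in covariate column(s): {list(na[na].index)}"
        )
    if covariates["plate"].nunique() < 1:
        raise SchemaError("plate must have at least one level")
    return covariates


def primary_samples(covariates: pd.DataFrame) -> pd.DataFrame:
    """One covariate row per subject (the first-plate measurement).

    Replicate measurements are reserved for the intraclass-correlation
    analysis; each subject enters the association regressions once.
    """
    return covariates.loc[covariates["replicate"] == 0]
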