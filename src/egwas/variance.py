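"""Variance decomposition of probe expression.

Two complementary views of how much of expression variance is genetic:

* replicate-based intraclass correlation (ICC): one-way random-effects
  variance components estimated by the ANOVA method of moments on subjects
  measured repeatedly across PCR plates -- between-subject variance as a
  fraction of the total;
* a hierarchical (sequential) R-squared ladder per probe: technical terms
  first (plate, RIN, centered RIN squared), then biological covariates
  (APOE e4 dose, age, sex), then the best cisSNP's dosage.  Each increment
  is also reported adjusted for the technical fraction,
  ``adj = add / (1 - R2_technical)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import build_design, _drop_aliased, select_best_cissnp
from .data import ExpressionMatrix, GenotypeMatrix, primary_samples

__all__ = [
    "ICCResult",
    "VarianceDecomposition",
    "icc",
    "adjusted_r2",
    "variance_decompose",
    "summarize_variance",
]


@dataclass
class ICCResult:
    probe: str
    sigma2_between: float
    sigma2_within: float
    icc: float
    n_subjects: int
    n_measurements: int
    degenerate: bool = False


def icc(expr: ExpressionMatrix, covariates: pd.DataFrame) -> pd.DataFrame:
    """Intraclass correlation per probe from replicated subjects.

    One-way random-effects ANOVA method of moments: with subjects as the
    grouping factor, ``sigma2_within = MSW`` and
    ``sigma2_between = (MSB - MSW) / n0`` (``n0`` the effective replicate
    count for unbalanced designs), truncated at zero so the ICC
    ``sigma2_b / (sigma2_b + sigma2_w)`` stays in [0, 1].  Only subjects
    with at least two measurements contribute.
    """
    cov = covariates.set_index("sample").loc[expr.samples]
    counts = cov.groupby("subject").size()
    keep_subjects = counts.index[counts >= 2]
    if len(keep_subjects) < 2:
        raise ValueError("ICC requires >= 2 subjects with >= 2 replicates each")
    mask = cov["subject"].isin(keep_subjects)
    vals = expr.values.loc[:, mask.to_numpy()].to_numpy(dtype=float)
    groups = pd.Categorical(cov.loc[mask, "subject"]).codes
    a = groups.max() + 1
    n_i = np.bincount(groups).astype(float)
    n_total = n_i.sum()

    sums = np.zeros((vals.shape[0], a))
    np.add.at(sums.T, groups, vals.T)
    means_i = sums / n_i
    grand = vals.mean(axis=1, keepdims=True)

    ssb = ((means_i - grand) ** 2 * n_i).sum(axis=1)
    ssw = ((vals - means_i[:, groups]) ** 2).sum(axis=1)
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    n0 = (n_total - (n_i ** 2).sum() / n_total) / (a - 1)

    sigma2_w = msw
    sigma2_b = np.maximum((msb - msw) / n0, 0.0)
    total = sigma2_b + sigma2_w
    degenerate = total <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        icc_val = np.where(degenerate, 0.0, sigma2_b / np.where(total > 0, total, 1.0))

    return pd.DataFrame(
        {
            "probe": expr.probes,
            "sigma2_between": sigma2_b,
            "sigma2_within": sigma2_w,
            "icc": icc_val,
            "n_subjects": int(a),
            "n_measurements": int(n_total),
            "degenerate": degenerate,
        }
    ).set_index("probe")


def adjusted_r2(add_r2: float, r2_technical: float) -> float:
    """Adjust a sequential R-squared increment for the technical fraction:
    ``adj = add / (1 - R2_technical)`` -- the increment as a share of the
    variance left after technical effects."""
    if not 0.0 <= r2_technical < 1.0:
        raise ValueError("r2_technical must lie in [0, 1)")
    return add_r2 / (1.0 - r2_technical)


@dataclass
class VarianceDecomposition:
    probe: str
    raw_variance: float
    r2_technical: float
    add_r2_covariates: float
    adj_r2_covariates: float
    add_r2_best_snp: float
    adj_r2_best_snp: float
    best_snp: str


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Unadjusted coefficient of determination of an OLS fit."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(1.0 - (resid ** 2).sum() / tss)


def variance_decompose(
    probe: str,
    expr: ExpressionMatrix,
    covariates: pd.DataFrame,
    best_snp: str,
    geno: GenotypeMatrix,
) -> VarianceDecomposition:
    """Sequential R-squared ladder for one probe.

    Fits three nested OLS models -- technical only, plus biological
    covariates, plus the best cisSNP dosage -- and reports each increment
    raw and adjusted for the technical fraction.  Increments are
    non-negative by construction of nested least squares.
    """
    cov = primary_samples(covariates).set_index("sample")
    samples = expr.samples.intersection(cov.index)
    cov = cov.loc[samples]
    y = expr.values.loc[probe, samples].to_numpy(dtype=float)
    g = geno.dosages.loc[cov["subject"], best_snp].to_numpy(dtype=float)

    tech = build_design(cov, technical=True, biological=False)
    full_cov = build_design(cov, technical=True, biological=True)

    X_t, _ = _drop_aliased(tech.to_numpy(dtype=float), list(tech.columns))
    X_c, _ = _drop_aliased(full_cov.to_numpy(dtype=float), list(full_cov.columns))
    X_s, _ = _drop_aliased(
        np.column_stack([X_c, g]), [*full_cov.columns, "dosage"]
    )

    r2_t = _r2(y, X_t)
    r2_tc = _r2(y, X_c)
    r2_tcs = _r2(y, X_s)
    add_cov = max(r2_tc - r2_t, 0.0)
    add_snp = max(r2_tcs - r2_tc, 0.0)

    return VarianceDecomposition(
        probe=probe,
        raw_variance=float(np.var(y, ddof=1)),
        r2_technical=r2_t,
        add_r2_covariates=add_cov,
        adj_r2_covariates=adjusted_r2(add_cov, r2_t),
        add_r2_best_snp=add_snp,
        adj_r2_best_snp=adjusted_r2(add_snp, r2_t),
        best_snp=best_snp,
    )


def decompose_with_best_snps(
    results: pd.DataFrame,
    expr: ExpressionMatrix,
    covariates: pd.DataFrame,
    geno: GenotypeMatrix,
) -> pd.DataFrame:
    """Best-SNP selection plus decomposition for every probe in an
    association table."""
    rows = []
    for probe, grp in results.groupby("probe", sort=True):
        best = select_best_cissnp(grp)
        if best is None:
            continue
        rows.append(
            vars(variance_decompose(str(probe), expr, covariates, best["snp"], geno))
        )
    return pd.DataFrame(rows).set_index("probe")


def summarize_variance(
    decompositions: pd.DataFrame, top_probes=None
) -> pd.DataFrame:
    """Median and range of each variance column, overall and for a
    designated 'top' probe subset."""
    if decompositions.empty:
        raise ValueError("no decompositions to summarize")
    cols = [
        "raw_variance", "r2_technical", "add_r2_covariates", "adj_r2_covariates",
        "add_r2_best_snp", "adj_r2_best_snp",
    ]
    def _stats(df: pd.DataFrame, label: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": df[cols].median(), "min": df[cols].min(), "max": df[cols].max()}
        ).assign(subset=label)
    out = [_stats(decompositions, "all")]
    if top_probes is not None:
        top = decompositions.loc[decompositions.index.isin(pd.Index(top_probes))]
        if not top.empty:
            out.append(_stats(top, "top"))
    return pd.concat(out)
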