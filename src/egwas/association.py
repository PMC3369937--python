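"""Cis association engine.

For every (SNP, probe) pair with the SNP inside a +/-``window_bp`` flank of
the probe's gene, fits ordinary least squares of normalized expression on
minor-allele dosage (0, 1, 2) plus covariates: APOE e4 dose, age at death,
sex, PCR plate (indicator contrasts), RIN and centered RIN squared, and --
in combined-cohort runs only -- diagnosis.  Per analysis the raw p-values
are corrected for genomic inflation (median chi-square / 0.4549; lambda < 1
never deflates), converted to Storey q-values, and Bonferroni-corrected
over the analysis' pair count.

Two fitting routes exist: :func:`fit_cis_association` (statsmodels OLS, one
pair at a time, the reference) and the vectorized Frisch-Waugh
residualization path used by :func:`run_egwas`; the two agree to numerical
precision and are cross-checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .data import ExpressionMatrix, GenotypeMatrix, primary_samples, validate_annotation

__all__ = [
    "CHI2_MEDIAN",
    "AssociationResult",
    "CisPairs",
    "EgwasOptions",
    "EgwasResult",
    "enumerate_cis_pairs",
    "build_design",
    "fit_cis_association",
    "genomic_control",
    "storey_qvalues",
    "estimate_pi0",
    "select_best_cissnp",
    "hwe_pvalues",
    "run_egwas",
]

#: Median of a 1-df chi-square distribution, the genomic-control reference.
CHI2_MEDIAN = st.chi2.ppf(0.5, df=1)  # 0.454936...


class CisPairs(NamedTuple):
    """Result of cis-pair enumeration."""

    pairs: pd.DataFrame  # columns: snp, probe
    probes_without_snps: list[str]
    unknown_chroms: list[str]


def enumerate_cis_pairs(
    snp_map: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 100_000
) -> CisPairs:
    """All (SNP, probe) pairs with the SNP within ``window_bp`` of the gene.

    Coordinates are 1-based; the window test is inclusive at both ends:
    ``gene_start - window <= pos <= gene_end + window`` on the same
    chromosome.  SNPs on chromosomes absent from the annotation are listed
    and skipped; probes with zero cis SNPs are reported.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    validate_annotation(annotation)
    ann_chroms = set(annotation["chrom"].astype(str))
    snp_chroms = snp_map["chrom"].astype(str)
    unknown = sorted(set(snp_chroms) - ann_chroms)

    frames = []
    for chrom, genes in annotation.groupby(annotation["chrom"].astype(str)):
        snps = snp_map.loc[snp_chroms == chrom]
        if snps.empty:
            continue
        pos = snps["pos"].to_numpy()
        lo = (genes["start"] - window_bp).to_numpy()
        hi = (genes["end"] + window_bp).to_numpy()
        hit = (pos[:, None] >= lo[None, :]) & (pos[:, None] <= hi[None, :])
        si, gi = np.nonzero(hit)
        frames.append(
            pd.DataFrame(
                {"snp": snps.index.to_numpy()[si], "probe": genes["probe"].to_numpy()[gi]}
            )
        )
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["snp", "probe"])
    )
    with_snps = set(pairs["probe"])
    orphans = [p for p in annotation["probe"] if p not in with_snps]
    return CisPairs(pairs=pairs, probes_without_snps=orphans, unknown_chroms=unknown)


def build_design(
    covariates: pd.DataFrame,
    include_diagnosis: bool = False,
    technical: bool = True,
    biological: bool = True,
    include_eigenvectors: bool = True,
) -> pd.DataFrame:
    """Covariate design matrix (with intercept) for the association model.

    Technical terms: plate indicator contrasts, RIN and (RIN - mean RIN)^2,
    with the RIN mean recomputed on the analysis set.  Biological terms:
    APOE e4 dose, age at death, sex.  ``diagnosis`` enters only in
    combined-cohort analyses.  Eigenvector columns (``ev*``) are used when
    present unless disabled.
    """
    parts = {"const": pd.Series(1.0, index=covariates.index)}
    if technical:
        plates = pd.get_dummies(covariates["plate"], prefix="plate", drop_first=True)
        for c in plates.columns:
            parts[c] = plates[c].astype(float)
        rin = covariates["rin"].astype(float)
        parts["rin"] = rin
        parts["rin_c2"] = (rin - rin.mean()) ** 2
    if biological:
        parts["apoe4_dose"] = covariates["apoe4_dose"].astype(float)
        parts["age_at_death"] = covariates["age_at_death"].astype(float)
        parts["sex"] = covariates["sex"].astype(float)
    if include_diagnosis:
        parts["diagnosis"] = covariates["diagnosis"].astype(float)
    if include_eigenvectors:
        for c in covariates.columns:
            if c.startswith("ev"):
                parts[c] = covariates[c].astype(float)
    return pd.DataFrame(parts, index=covariates.index)


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns (QR with column pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [names[j] for j in sorted(piv[rank:])]
        warnings.warn(f"design is rank deficient; dropping aliased column(s): {dropped}")
        keep = sorted(piv[:rank])
        return X[:, keep], [names[j] for j in keep]
    return X, names


@dataclass
class AssociationResult:
    """One fitted cisSNP/transcript association."""

    snp: str
    probe: str
    n: int
    beta: float  # change in normalized expression per minor allele
    se: float
    p: float
    p_gc: float | None = None
    q: float | None = None
    p_bonf: float | None = None
    cohort: str = ""
    tissue: str = ""
    testable: bool = True


def fit_cis_association(
    snp: str,
    probe: str,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    include_diagnosis: bool = False,
) -> AssociationResult:
    """Reference single-pair fit via statsmodels OLS.

    Subjects missing the genotype or the expression value are dropped
    (complete-case per pair).  A constant genotype yields an untestable
    result rather than an error.
    """
    cov = primary_samples(covariates).set_index("sample")
    samples = expr.samples.intersection(cov.index)
    cov = cov.loc[samples]
    y = expr.values.loc[probe, samples].astype(float)
    g = geno.dosages.loc[cov["subject"], snp].astype(float)
    g.index = samples
    ok = y.notna() & g.notna()
    y, g, cov = y[ok], g[ok], cov.loc[ok]

    X = build_design(cov, include_diagnosis=include_diagnosis)
    n, p_cols = len(y), X.shape[1] + 1
    if n < p_cols + 1:
        raise ValueError(
            f"pair ({snp}, {probe}): only {n} complete observations for "
            f"{p_cols} parameters"
        )
    if np.ptp(g.to_numpy()) == 0:
        return AssociationResult(
            snp=snp, probe=probe, n=n, beta=np.nan, se=np.nan, p=np.nan, testable=False
        )
    design = pd.concat([pd.Series(g, name="dosage"), X], axis=1)
    mat, names = _drop_aliased(design.to_numpy(dtype=float), list(design.columns))
    fit = sm.OLS(y.to_numpy(dtype=float), mat).fit()
    j = names.index("dosage")
    return AssociationResult(
        snp=snp, probe=probe, n=n,
        beta=float(fit.params[j]), se=float(fit.bse[j]), p=float(fit.pvalues[j]),
    )


def genomic_control(p_values) -> tuple[float, np.ndarray]:
    """Genomic-control correction of a vector of p-values.

    lambda = median(qchisq(1 - p, 1)) / 0.4549.  When lambda > 1 every
    chi-square statistic is divided by lambda and converted back to a
    p-value; lambda <= 1 leaves the p-values unchanged (no deflation).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("genomic control requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = st.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_MEDIAN)
    if lam <= 1.0:
        return lam, p.copy()
    return lam, st.chi2.sf(chi2 / lam, df=1)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
    0.05, 0.10, ..., 0.95 is smoothed with a cubic fit and read off at the
    right end of the grid, then clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    if m < 2:
        return 1.0
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """FDR q-values.

    q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank(p_j); with
    ``pi0=1`` this is exactly Benjamini-Hochberg.  By default pi0 is
    estimated with the smoother method (:func:`estimate_pi0`).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p) if m >= 2 else 1.0
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_best_cissnp(results: pd.DataFrame) -> pd.Series | None:
    """The "best" cisSNP row for one probe's results.

    Minimal genomic-control-adjusted p; ties broken by larger \\|beta\\|,
    then lexicographically smaller SNP id.  Returns None when every result
    is untestable.
    """
    testable = results.loc[results["testable"]] if "testable" in results else results
    if testable.empty:
        return None
    key = testable.assign(_absbeta=-testable["beta"].abs())
    key = key.sort_values(["p_gc", "_absbeta", "snp"], kind="stable")
    return testable.loc[key.index[0]]


def hwe_pvalues(geno: GenotypeMatrix) -> pd.Series:
    """Chi-square (1 df) Hardy-Weinberg test per SNP from dosage counts."""
    d = geno.dosages.to_numpy(dtype=float)
    n0 = (d == 0).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    n = n0 + n1 + n2
    p_hat = (n1 + 2 * n2) / (2 * n)
    exp = np.stack([n * (1 - p_hat) ** 2, 2 * n * p_hat * (1 - p_hat), n * p_hat ** 2])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(
            np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0
        )
    pvals = st.chi2.sf(chi2, df=1)
    # Monomorphic SNPs carry no HWE information.
    pvals[(p_hat == 0) | (p_hat == 1)] = 1.0
    return pd.Series(pvals, index=geno.snps)


@dataclass
class EgwasOptions:
    """Tuning knobs of a full eGWAS run."""

    window_bp: int = 100_000
    maf_min: float = 0.01
    hwe_min_p: float = 1e-7
    pi0: float | None = None  # None -> smoother estimate
    include_eigenvectors: bool = True
    chunk_size: int = 50_000


@dataclass
class EgwasResult:
    """Full-analysis output: per-pair table plus inflation diagnostics."""

    results: pd.DataFrame
    lambda_gc: float
    qq: pd.DataFrame  # columns: expected, observed (-log10 p)
    n_pairs_tested: int
    n_pairs_untestable: int
    n_snps_failed_qc: int
    probes_without_snps: list[str] = field(default_factory=list)
    cohort: str = ""
    tissue: str = ""


def _bulk_pair_stats(
    Y: np.ndarray, G: np.ndarray, X: np.ndarray, probe_idx: np.ndarray,
    snp_idx: np.ndarray, chunk_size: int = 50_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Exact per-pair OLS via Frisch-Waugh residualization.

    ``Y`` is samples x probes, ``G`` samples x SNPs, ``X`` the covariate
    design (with intercept).  Residualizing both the phenotype and the
    dosage on X reduces each pair's multivariable fit to a simple
    regression with ``n - rank(X) - 1`` residual degrees of freedom; the
    betas, SEs and p-values are identical to the full OLS fit.
    """
    n = Y.shape[0]
    Q, _ = np.linalg.qr(X)
    r = X.shape[1]
    Yr = Y - Q @ (Q.T @ Y)
    Gr = G - Q @ (Q.T @ G)
    df = n - r - 1
    m = len(probe_idx)
    beta = np.empty(m)
    se = np.empty(m)
    pval = np.empty(m)
    for start in range(0, m, chunk_size):
        sl = slice(start, min(start + chunk_size, m))
        y = Yr[:, probe_idx[sl]]
        g = Gr[:, snp_idx[sl]]
        gg = np.einsum("ij,ij->j", g, g)
        gy = np.einsum("ij,ij->j", g, y)
        yy = np.einsum("ij,ij->j", y, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = gy / gg
            rss = np.maximum(yy - b * gy, 0.0)
            s = np.sqrt(rss / df / gg)
            t = b / s
        p = 2.0 * st.t.sf(np.abs(t), df)
        beta[sl], se[sl], pval[sl] = b, s, p
    return beta, se, pval, df


def run_egwas(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    covariates: pd.DataFrame,
    cohort: str = "all",
    options: EgwasOptions | None = None,
) -> EgwasResult:
    """One complete analysis: pairing, per-pair fits, genomic control,
    q-values, Bonferroni.

    ``cohort`` is ``"AD"``, ``"nonAD"`` or ``"all"``; the combined analysis
    adds diagnosis as a covariate, matching the three analysis columns of
    the discovery design.  SNPs failing the QC gates (MAF and Hardy-Weinberg
    on the analysis subjects) are removed before pairing.  Replicated
    subjects enter once, via their first-plate measurement.
    """
    options = options or EgwasOptions()
    cov = primary_samples(covariates)
    if cohort == "AD":
        cov = cov.loc[cov["diagnosis"] == 1]
    elif cohort == "nonAD":
        cov = cov.loc[cov["diagnosis"] == 0]
    elif cohort != "all":
        raise ValueError(f"unknown cohort {cohort!r} (expected 'AD', 'nonAD' or 'all')")
    cov = cov.loc[cov["sample"].isin(expr.samples) & cov["subject"].isin(geno.subjects)]
    if cov.empty:
        raise ValueError("no analysis samples after cohort selection")
    cov = cov.set_index("sample")
    samples = cov.index
    subjects = cov["subject"]

    sub_geno = geno.subset_subjects(subjects)
    # SNP QC on the analysis subjects
    maf = sub_geno.empirical_maf()
    hwe = hwe_pvalues(sub_geno)
    qc_ok = (maf >= options.maf_min) & (hwe > options.hwe_min_p)
    n_failed_qc = int((~qc_ok).sum())
    snp_map = geno.snp_map.loc[qc_ok[qc_ok].index]

    cis = enumerate_cis_pairs(snp_map, annotation, options.window_bp)
    pairs = cis.pairs.loc[cis.pairs["probe"].isin(expr.probes)].reset_index(drop=True)

    X = build_design(
        cov,
        include_diagnosis=(cohort == "all"),
        include_eigenvectors=options.include_eigenvectors,
    )
    Xmat, _ = _drop_aliased(X.to_numpy(dtype=float), list(X.columns))

    probe_ids, probe_codes = pd.factorize(pairs["probe"])
    snp_ids, snp_codes = pd.factorize(pairs["snp"])
    Y = expr.values.loc[probe_codes, samples].to_numpy(dtype=float).T
    G = sub_geno.dosages.loc[:, snp_codes].to_numpy(dtype=float)

    if np.isnan(Y).any() or np.isnan(G).any():
        # Complete-case per pair: fall back to the reference per-pair route.
        rows = [
            fit_cis_association(
                s, pr, expr, geno, covariates.loc[covariates["sample"].isin(samples)],
                include_diagnosis=(cohort == "all"),
            )
            for s, pr in zip(pairs["snp"], pairs["probe"])
        ]
        res = pd.DataFrame([vars(x) for x in rows])
        res["testable"] = res.pop("testable").astype(bool)
    else:
        beta, se, pval, df = _bulk_pair_stats(
            Y, G, Xmat, probe_ids, snp_ids, options.chunk_size
        )
        const = np.ptp(G[:, snp_ids], axis=0) == 0
        testable = ~const & np.isfinite(pval)
        res = pd.DataFrame(
            {
                "snp": pairs["snp"],
                "probe": pairs["probe"],
                "n": len(samples),
                "beta": np.where(testable, beta, np.nan),
                "se": np.where(testable, se, np.nan),
                "p": np.where(testable, np.clip(pval, np.nextafter(0, 1), 1.0), np.nan),
                "testable": testable,
            }
        )

    tested = res.loc[res["testable"]].copy()
    n_untestable = int((~res["testable"]).sum())
    if tested.empty:
        raise ValueError("no testable cis pairs in this analysis")
    m = len(tested)
    lam, p_gc = genomic_control(tested["p"].to_numpy())
    tested["p_gc"] = np.clip(p_gc, np.nextafter(0, 1), 1.0)
    tested["q"] = storey_qvalues(tested["p_gc"].to_numpy(), pi0=options.pi0)
    tested["p_bonf"] = np.minimum(1.0, m * tested["p_gc"])
    tested["cohort"] = cohort
    tested["tissue"] = expr.tissue

    obs = -np.log10(np.sort(tested["p_gc"].to_numpy()))[::-1]
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    qq = pd.DataFrame({"expected": exp[::-1], "observed": obs[::-1]})

    return EgwasResult(
        results=tested.reset_index(drop=True),
        lambda_gc=lam,
        qq=qq,
        n_pairs_tested=m,
        n_pairs_untestable=n_untestable,
        n_snps_failed_qc=n_failed_qc,
        probes_without_snps=cis.probes_without_snps,
        cohort=cohort,
        tissue=expr.tissue,
    )
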