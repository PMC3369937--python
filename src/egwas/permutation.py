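"""Westfall-Young stepdown permutation for family-wise error control.

Probes are correlated, so a Bonferroni penalty over all pairs is
conservative.  The resampling-style stepdown (max-T) approach permutes
whole phenotype vectors -- here the covariate-residualized expression rows,
jointly across probes, so the inter-probe correlation structure is
preserved -- and compares each observed statistic against the successive
maxima of the permuted statistics.  Covariate structure is maintained by
residualizing expression (and dosage) on the covariate design once before
permuting, a Freedman-Lane-style approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import build_design, _drop_aliased
from .data import ExpressionMatrix, GenotypeMatrix, primary_samples

__all__ = ["PermutationResult", "westfall_young"]


@dataclass
class PermutationResult:
    """Raw (marginal) and stepdown-adjusted permutation p-values per pair."""

    table: pd.DataFrame  # snp, probe, statistic, p_raw, p_adjusted
    n_permutations: int
    seed: int
    min_attainable_p: float


def _pair_abs_t(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """|correlation t| for column-matched residual pairs (constant columns
    give 0)."""
    gg = np.einsum("ij,ij->j", G, G)
    yy = np.einsum("ij,ij->j", Y, Y)
    gy = np.einsum("ij,ij->j", G, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = gy ** 2 / (gg * yy)
        stat = np.sqrt(np.where(np.isfinite(r2), r2, 0.0))
    return stat


def westfall_young(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    include_diagnosis: bool = False,
    alpha: float = 0.05,
) -> PermutationResult:
    """Stepdown max-T adjusted p-values for the given (snp, probe) pairs.

    Empirical p-values use +1 smoothing: ``(exceedances + 1) / (B + 1)``,
    so the smallest attainable value is ``1 / (B + 1)``.  The per-pair
    statistic is the absolute correlation between covariate-residualized
    expression and dosage (a monotone transform of the OLS |t|).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    min_p = 1.0 / (n_perm + 1)
    if min_p > alpha:
        warnings.warn(
            f"{n_perm} permutations cannot resolve p < {alpha}: "
            f"minimum attainable p is {min_p:.3g}"
        )

    cov = primary_samples(covariates).set_index("sample")
    samples = expr.samples.intersection(cov.index)
    cov = cov.loc[samples]
    X = build_design(cov, include_diagnosis=include_diagnosis)
    Xmat, _ = _drop_aliased(X.to_numpy(dtype=float), list(X.columns))
    Q, _ = np.linalg.qr(Xmat)

    probe_ids, probe_codes = pd.factorize(pairs["probe"])
    snp_ids, snp_codes = pd.factorize(pairs["snp"])
    Y = expr.values.loc[probe_codes, samples].to_numpy(dtype=float).T
    G = geno.dosages.loc[cov["subject"], snp_codes].to_numpy(dtype=float)
    Yr = Y - Q @ (Q.T @ Y)
    Gr = G - Q @ (Q.T @ G)

    Yp = Yr[:, probe_ids]  # samples x pairs, one column per hypothesis
    Gp = Gr[:, snp_ids]
    observed = _pair_abs_t(Yp, Gp)

    # Stepdown ordering: most significant hypothesis first.
    order = np.argsort(-observed, kind="stable")
    obs_sorted = observed[order]
    m = len(order)

    rng = np.random.default_rng(seed)
    exceed_adj = np.zeros(m, dtype=np.int64)
    exceed_raw = np.zeros(m, dtype=np.int64)
    n = Yr.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # Freedman-Lane: re-residualize the permuted rows on the covariate
        # design so permuted and observed statistics live in the same
        # (n - rank X)-dimensional space
        Yperm = Yp[perm]
        Yperm = Yperm - Q @ (Q.T @ Yperm)
        stat = _pair_abs_t(Yperm, Gp)
        exceed_raw += stat >= observed
        # successive maxima over the ordered hypotheses, from the bottom up
        u = np.maximum.accumulate(stat[order][::-1])[::-1]
        exceed_adj += u >= obs_sorted

    p_raw = (exceed_raw + 1.0) / (n_perm + 1.0)
    p_adj_sorted = (exceed_adj + 1.0) / (n_perm + 1.0)
    # enforce stepdown monotonicity along decreasing significance
    p_adj_sorted = np.maximum.accumulate(p_adj_sorted)
    p_adj = np.empty(m)
    p_adj[order] = p_adj_sorted
    p_adj = np.maximum(p_adj, p_raw)

    table = pd.DataFrame(
        {
            "snp": pairs["snp"].to_numpy(),
            "probe": pairs["probe"].to_numpy(),
            "statistic": observed,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        }
    )
    return PermutationResult(
        table=table, n_permutations=n_perm, seed=seed, min_attainable_p=min_p
    )
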