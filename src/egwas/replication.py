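"""Two-stage evidence rules.

Discovery: a cisSNP/transcript pair must reach q < 0.05 in *both* the AD and
non-AD cohorts of the discovery tissue.  Validation: the surviving pairs are
looked up in the validation tissue's combined analysis and must pass a
study-wide Bonferroni threshold whose denominator is the number of discovery
pairs that are testable in the validation tissue.  Effect-size concordance
(Pearson r of betas, sign agreement) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = ["DualCohortResult", "ReplicationReport", "dual_cohort_intersect",
           "validate_in_tissue"]


@dataclass
class DualCohortResult:
    """Pairs significant in both cohorts of the discovery tissue."""

    pairs: pd.DataFrame  # snp, probe, q_A, q_B, beta_A, beta_B
    beta_correlation: float | None  # Pearson r; None when undefined
    n_pairs: int
    n_unique_snps: int
    n_unique_probes: int


def dual_cohort_intersect(
    results_a: pd.DataFrame, results_b: pd.DataFrame, q_thresh: float = 0.05
) -> DualCohortResult:
    """Intersection of pairs with q < ``q_thresh`` in both cohorts.

    Both inputs are per-pair association tables (same tissue) carrying
    ``snp``, ``probe``, ``q`` and ``beta`` columns.
    """
    for name, res in (("results_a", results_a), ("results_b", results_b)):
        missing = {"snp", "probe", "q", "beta"} - set(res.columns)
        if missing:
            raise ValueError(f"{name} lacks column(s): {sorted(missing)}")
    sig_a = results_a.loc[results_a["q"] < q_thresh, ["snp", "probe", "q", "beta"]]
    sig_b = results_b.loc[results_b["q"] < q_thresh, ["snp", "probe", "q", "beta"]]
    merged = sig_a.merge(sig_b, on=["snp", "probe"], suffixes=("_a", "_b"))
    if len(merged) >= 2 and merged["beta_a"].nunique() > 1 and merged["beta_b"].nunique() > 1:
        r = float(st.pearsonr(merged["beta_a"], merged["beta_b"])[0])
    else:
        r = None
    return DualCohortResult(
        pairs=merged.reset_index(drop=True),
        beta_correlation=r,
        n_pairs=len(merged),
        n_unique_snps=merged["snp"].nunique(),
        n_unique_probes=merged["probe"].nunique(),
    )


@dataclass
class ReplicationReport:
    """Outcome of validating discovery pairs in a second tissue."""

    validated: pd.DataFrame
    failed: pd.DataFrame
    untestable: pd.DataFrame
    k_study_wide: int  # the study-wide Bonferroni denominator
    n_discovery: int
    n_validated: int
    n_failed: int
    n_untestable: int
    beta_correlation: float | None
    sign_concordance: float | None  # fraction of validated pairs with matching beta sign
    unique_counts: dict = field(default_factory=dict)


def validate_in_tissue(
    discovery_pairs: pd.DataFrame,
    validation_results: pd.DataFrame,
    alpha: float = 0.05,
) -> ReplicationReport:
    """Study-wide Bonferroni validation in the second tissue.

    A discovery pair is *testable* when it appears (and is testable) in the
    validation results; it is *validated* iff ``p_validation * K < alpha``
    with ``K`` the number of testable discovery pairs (the study-wide
    denominator).  The counting identity
    ``n_discovery = n_validated + n_failed + n_untestable`` always holds.
    """
    disc = discovery_pairs.drop_duplicates(subset=["snp", "probe"]).copy()
    val = validation_results
    if "testable" in val.columns:
        val = val.loc[val["testable"]]
    val = val.drop_duplicates(subset=["snp", "probe"])
    merged = disc.merge(
        val[["snp", "probe", "p", "beta"]].rename(
            columns={"p": "p_validation", "beta": "beta_validation"}
        ),
        on=["snp", "probe"],
        how="left",
    )
    testable = merged["p_validation"].notna()
    k = int(testable.sum())
    untestable = merged.loc[~testable]
    candidates = merged.loc[testable].copy()
    candidates["p_bonf_study"] = np.minimum(1.0, candidates["p_validation"] * k)
    ok = candidates["p_bonf_study"] < alpha
    validated = candidates.loc[ok]
    failed = candidates.loc[~ok]

    beta_disc_col = next(
        (c for c in ("beta", "beta_a", "beta_discovery") if c in validated.columns), None
    )
    r = None
    sign_conc = None
    if beta_disc_col is not None and len(validated) >= 2:
        if (
            validated[beta_disc_col].nunique() > 1
            and validated["beta_validation"].nunique() > 1
        ):
            r = float(
                st.pearsonr(validated[beta_disc_col], validated["beta_validation"])[0]
            )
        sign_conc = float(
            (
                np.sign(validated[beta_disc_col])
                == np.sign(validated["beta_validation"])
            ).mean()
        )

    return ReplicationReport(
        validated=validated.reset_index(drop=True),
        failed=failed.reset_index(drop=True),
        untestable=untestable.reset_index(drop=True),
        k_study_wide=k,
        n_discovery=len(merged),
        n_validated=len(validated),
        n_failed=len(failed),
        n_untestable=len(untestable),
        beta_correlation=r,
        sign_concordance=sign_conc,
        unique_counts={
            "snps_discovery": merged["snp"].nunique(),
            "probes_discovery": merged["probe"].nunique(),
            "snps_validated": validated["snp"].nunique(),
            "probes_validated": validated["probe"].nunique(),
        },
    )
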