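"""Synthetic study generator.

Emulates the statistical structure of a two-cohort, two-brain-region
expression GWAS so every downstream stage can be exercised without access to
the original subject-level data: Hardy-Weinberg genotypes across a
configurable minor-allele-frequency spectrum, probe expression with planted
additive cis effects inside +/-100 kb windows, PCR-plate and RIN technical
structure, a between-subject random effect carried by replicate
measurements, AD / non-AD diagnostic cohorts, and a disease/trait catalog
with a planted enrichment factor.

All randomness flows through a single ``numpy.random.Generator`` derived
from ``SimulationConfig.seed``; a fixed seed fully determines every output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    GenotypeMatrix,
    validate_annotation,
    validate_covariates,
)

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_map_and_annotation",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_catalog",
    "plant_effects",
    "simulate_study",
]


def _default_covariate_effects() -> dict[str, float]:
    # Modest, plausible magnitudes: technical (rin) and biological terms all
    # small relative to sigma_noise so planted cis effects dominate power.
    return {
        "age_at_death": 0.005,
        "sex": 0.10,
        "apoe4_dose": 0.05,
        "diagnosis": 0.10,
        "rin": 0.20,
    }


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_study`.

    Defaults mirror the structure of the autopsy cohort the pipeline is
    designed for: 374 subjects (197 AD, 177 non-AD), two brain regions,
    15 subjects re-measured on 5 different PCR plates, RIN ~ N(8, 0.5^2)
    truncated to [5, 10], and a +/-100 kb cis window.  Matrix sizes
    (``n_snps``, ``n_probes``) default to desk scale.
    """

    n_subjects: int = 374
    n_snps: int = 2000
    n_probes: int = 200
    maf_range: tuple[float, float] = (0.01, 0.5)
    window_bp: int = 100_000
    effect_table: list[tuple[str, str, float]] | None = None
    n_planted_effects: int = 0  # auto-plant when effect_table is None
    planted_beta: float = 1.0
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    sigma_subject: float = 1.0
    sigma_noise: float = 1.0
    sigma_plate: float = 0.3
    n_replicate_subjects: int = 15
    n_replicates: int = 5
    n_plates: int = 6
    frac_cases: float = 197 / 374
    tissues: tuple[str, ...] = ("cerebellum", "temporal_cortex")
    shared_tissue_effects: bool = True
    shared_cohort_effects: bool = True
    detect_rate_high: float = 0.995
    detect_rate_low: float = 0.5
    frac_low_detection: float = 0.1
    n_catalog: int = 0
    catalog_enrichment: float = 1.0
    gene_length: int = 10_000
    gene_spacing: int = 250_000
    n_chroms: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if not 0.0 <= self.frac_cases <= 1.0:
            raise ValueError("frac_cases must be a fraction in [0, 1]")
        if self.n_replicates > self.n_plates:
            raise ValueError("n_replicates cannot exceed n_plates (one plate per replicate)")


@dataclass
class SyntheticStudy:
    """Bundle of all generated components plus the planted truth."""

    genotypes: GenotypeMatrix
    expression: dict[str, ExpressionMatrix]
    annotation: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame  # columns: probe, snp, beta_true
    catalog: pd.DataFrame | None
    config: SimulationConfig


def simulate_map_and_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes and SNPs so every SNP is cis to exactly one gene.

    Genes are spaced ``gene_spacing`` apart (wider than gene length plus
    twice the cis window, so windows of neighbouring genes do not overlap)
    across ``n_chroms`` chromosomes; SNPs are assigned round-robin to genes
    and placed uniformly within each gene's cis window.  MAFs are drawn
    uniformly on ``maf_range`` so all ten enrichment bins are populated.
    """
    n_probes, n_snps = config.n_probes, config.n_snps
    gene_idx = np.arange(n_probes)
    chroms = (gene_idx % config.n_chroms + 1).astype(str)
    rank_on_chrom = gene_idx // config.n_chroms
    start = 1_000_000 + rank_on_chrom * config.gene_spacing
    end = start + config.gene_length - 1
    annotation = pd.DataFrame(
        {
            "probe": [f"PR{i:05d}" for i in gene_idx],
            "symbol": [f"GENE{i:05d}" for i in gene_idx],
            "chrom": chroms,
            "start": start,
            "end": end,
        }
    )

    snp_gene = np.arange(n_snps) % n_probes
    lo = np.maximum(1, start[snp_gene] - config.window_bp)
    hi = end[snp_gene] + config.window_bp
    pos = rng.integers(lo, hi + 1)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    alleles = np.array(["A", "C", "G", "T"])
    a1 = alleles[rng.integers(0, 4, size=n_snps)]
    a2 = alleles[(rng.integers(1, 4, size=n_snps) + np.searchsorted(alleles, a1)) % 4]
    snp_map = pd.DataFrame(
        {
            "chrom": chroms[snp_gene],
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "maf": maf,
        },
        index=pd.Index([f"rs{i + 1000000}" for i in range(n_snps)], name="snp"),
    )
    return snp_map, validate_annotation(annotation)


def simulate_genotypes(
    n_subjects: int,
    snp_map: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes: dosage ~ Binomial(2, MAF) per subject."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    maf = np.asarray(snp_map["maf"], dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        bad = snp_map.index[(maf <= 0) | (maf > 0.5)][:5].tolist()
        raise ValueError(f"MAF outside (0, 0.5] for SNP(s): {bad}")
    dosages = rng.binomial(2, maf, size=(n_subjects, len(maf))).astype(float)
    subjects = pd.Index([f"S{i:04d}" for i in range(n_subjects)], name="subject")
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=subjects, columns=snp_map.index),
        snp_map=snp_map,
    )


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample covariates: one primary measurement per subject plus
    ``n_replicates`` total measurements (on distinct plates) for the first
    ``n_replicate_subjects`` subjects."""
    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(n)]
    n_cases = int(round(config.frac_cases * n))
    diagnosis = np.zeros(n, dtype=int)
    diagnosis[rng.permutation(n)[:n_cases]] = 1
    age = np.clip(rng.normal(80.0, 8.0, size=n), 60.0, 100.0)
    sex = rng.integers(0, 2, size=n)
    # APOE e4 enriched in the AD cohort, as in real autopsy series.
    apoe_p = np.where(diagnosis == 1, 0.35, 0.15)
    apoe4 = rng.binomial(2, apoe_p)
    rin = np.clip(rng.normal(8.0, 0.5, size=n), 5.0, 10.0)

    rows = []
    for i, subj in enumerate(subjects):
        n_meas = config.n_replicates if i < config.n_replicate_subjects else 1
        base_plate = i % config.n_plates
        for k in range(n_meas):
            rows.append(
                {
                    "sample": subj if k == 0 else f"{subj}.r{k}",
                    "subject": subj,
                    "apoe4_dose": apoe4[i],
                    "age_at_death": age[i],
                    "sex": sex[i],
                    "diagnosis": diagnosis[i],
                    "plate": f"P{(base_plate + k) % config.n_plates + 1}",
                    "rin": rin[i],
                    "replicate": k,
                }
            )
    return validate_covariates(pd.DataFrame(rows))


def _check_cis(
    effect_table: list[tuple[str, str, float]],
    annotation: pd.DataFrame,
    snp_map: pd.DataFrame,
    window_bp: int,
) -> None:
    ann = annotation.set_index("probe")
    for probe, snp, beta in effect_table:
        if probe not in ann.index:
            raise ValueError(f"planted pair ({probe}, {snp}): unknown probe")
        if snp not in snp_map.index:
            raise ValueError(f"planted pair ({probe}, {snp}): unknown SNP")
        g = ann.loc[probe]
        s = snp_map.loc[snp]
        if not (
            str(s["chrom"]) == str(g["chrom"])
            and g["start"] - window_bp <= s["pos"] <= g["end"] + window_bp
        ):
            raise ValueError(
                f"planted pair ({probe}, {snp}) lies outside the cis window: "
                f"SNP at {s['chrom']}:{s['pos']}, gene at "
                f"{g['chrom']}:{g['start']}-{g['end']} +/- {window_bp}"
            )


def plant_effects(
    annotation: pd.DataFrame,
    snp_map: pd.DataFrame,
    n_effects: int,
    beta: float,
    rng: np.random.Generator,
    window_bp: int = 100_000,
) -> list[tuple[str, str, float]]:
    """Pick ``n_effects`` distinct probes and one random cis SNP for each."""
    ann = annotation.set_index("probe")
    probes = rng.choice(annotation["probe"].to_numpy(), size=n_effects, replace=False)
    table = []
    for probe in probes:
        g = ann.loc[probe]
        in_cis = (
            (snp_map["chrom"].astype(str) == str(g["chrom"]))
            & (snp_map["pos"] >= g["start"] - window_bp)
            & (snp_map["pos"] <= g["end"] + window_bp)
        )
        candidates = snp_map.index[in_cis]
        if len(candidates) == 0:
            raise ValueError(f"probe {probe} has no cis SNP to plant an effect on")
        table.append((str(probe), str(rng.choice(candidates)), float(beta)))
    return table


def simulate_expression(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
    tissue: str = "cerebellum",
    effect_table: list[tuple[str, str, float]] | None = None,
    apply_effects: bool = True,
) -> ExpressionMatrix:
    """Generate expression for one tissue.

    Per measurement: ``y = mu_probe + beta * dosage + plate + gamma * covariates
    + subject effect + noise`` where the plate term is probe-by-plate
    (N(0, sigma_plate^2)), the subject effect is probe-by-subject
    (N(0, sigma_subject^2)) and shared across replicate measurements of the
    same subject, and the noise is independent N(0, sigma_noise^2) per
    measurement.  The detection indicator is Bernoulli per measurement with a
    probe-level rate.
    """
    effect_table = effect_table if effect_table is not None else (config.effect_table or [])
    if effect_table:
        _check_cis(effect_table, annotation, genotypes.snp_map, config.window_bp)

    probes = annotation["probe"].to_numpy()
    n_probes = len(probes)
    samples = covariates["sample"].to_numpy()
    n_samples = len(samples)
    subj_codes, subj_uniques = pd.factorize(covariates["subject"])
    plate_codes, plate_uniques = pd.factorize(covariates["plate"])

    mu = rng.normal(7.0, 1.0, size=n_probes)
    plate_eff = rng.normal(0.0, config.sigma_plate, size=(n_probes, len(plate_uniques)))
    subj_eff = rng.normal(0.0, config.sigma_subject, size=(n_probes, len(subj_uniques)))

    ce = config.covariate_effects
    cov_term = np.zeros(n_samples)
    for col, coef in ce.items():
        cov_term += coef * covariates[col].to_numpy(dtype=float)

    values = (
        mu[:, None]
        + plate_eff[:, plate_codes]
        + subj_eff[:, subj_codes]
        + cov_term[None, :]
        + rng.normal(0.0, config.sigma_noise, size=(n_probes, n_samples))
    )

    if apply_effects and effect_table:
        probe_pos = {p: i for i, p in enumerate(probes)}
        dose = genotypes.dosages
        subj_of_sample = covariates["subject"].to_numpy()
        cohort_mask = np.ones(n_samples, dtype=bool)
        if not config.shared_cohort_effects:
            cohort_mask = covariates["diagnosis"].to_numpy() == 1
        tissue_ok = config.shared_tissue_effects or tissue == config.tissues[0]
        if tissue_ok:
            for probe, snp, beta in effect_table:
                g = dose.loc[subj_of_sample, snp].to_numpy(dtype=float)
                values[probe_pos[probe], cohort_mask] += beta * g[cohort_mask]

    n_low = int(round(config.frac_low_detection * n_probes))
    rate = np.full(n_probes, config.detect_rate_high)
    rate[rng.permutation(n_probes)[:n_low]] = config.detect_rate_low
    detected = rng.random(size=(n_probes, n_samples)) < rate[:, None]

    idx = pd.Index(probes, name="probe")
    cols = pd.Index(samples, name="sample")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        detected=pd.DataFrame(detected, index=idx, columns=cols),
        tissue=tissue,
    )


# --- disease/trait catalog -------------------------------------------------

MAF_BIN_EDGES = np.linspace(0.0, 0.5, 11)


def maf_bin_index(maf: np.ndarray) -> np.ndarray:
    """Ten half-open bins of width 0.05 on [0, 0.5); the last bin is closed
    at 0.5."""
    return np.minimum((np.asarray(maf, dtype=float) // 0.05).astype(int), 9)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        raise ValueError("cannot allocate over empty weights")
    exact = total * weights / weights.sum()
    alloc = np.floor(exact).astype(int)
    short = total - alloc.sum()
    order = np.argsort(-(exact - alloc))
    alloc[order[:short]] += 1
    return alloc


def simulate_catalog(
    snp_map: pd.DataFrame,
    sig_snps,
    enrichment_factor: float = 1.0,
    n_catalog: int = 100,
    seed: int | np.random.Generator = 0,
    n_multi_decoys: int = 5,
    n_nonrs_decoys: int = 5,
    n_weak_decoys: int = 5,
) -> pd.DataFrame:
    """Disease/trait catalog with a planted overlap against ``sig_snps``.

    ``n_catalog`` single-rs rows are drawn from the universe in ``snp_map``,
    MAF-bin-balanced, such that the expected fraction landing in ``sig_snps``
    is ``enrichment_factor * |sig| / |universe|`` within every bin
    (fractional expected counts are resolved by a Bernoulli coin, keeping
    the expectation exact).  Decoy rows without a single rs number, plus
    rows above the usual reported-p gate, are appended to exercise catalog
    filtering.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    sig = pd.Index(sig_snps)
    if not sig.isin(snp_map.index).all():
        raise ValueError("sig_snps must be a subset of the SNP universe")
    if n_catalog == 0:
        return pd.DataFrame(
            columns=["SNPs", "Disease/Trait", "p-Value", "Reported Gene(s)",
                     "Strongest SNP-Risk Allele"]
        )

    bins = maf_bin_index(snp_map["maf"].to_numpy())
    sig_mask = snp_map.index.isin(sig)
    chosen: list[str] = []
    occupied = np.flatnonzero(np.bincount(bins, minlength=10) > 0)
    alloc = np.zeros(10, dtype=int)
    alloc[occupied] = _largest_remainder(
        n_catalog, np.bincount(bins, minlength=10)[occupied].astype(float)
    )
    for b in range(10):
        k_b = alloc[b]
        if k_b == 0:
            continue
        in_bin = bins == b
        n_b = int(in_bin.sum())
        sig_b = snp_map.index[in_bin & sig_mask]
        non_b = snp_map.index[in_bin & ~sig_mask]
        expected = enrichment_factor * k_b * len(sig_b) / n_b
        k_sig = int(np.floor(expected)) + int(rng.random() < expected % 1)
        if k_sig > min(k_b, len(sig_b)) or k_b - k_sig > len(non_b):
            raise ValueError(
                f"requested enrichment unattainable in MAF bin "
                f"[{b * 0.05:.2f}, {(b + 1) * 0.05:.2f}): need {k_sig} of "
                f"{len(sig_b)} significant and {k_b - k_sig} of {len(non_b)} "
                "other SNPs"
            )
        chosen.extend(rng.choice(sig_b, size=k_sig, replace=False))
        chosen.extend(rng.choice(non_b, size=k_b - k_sig, replace=False))

    n_traits = max(1, n_catalog // 5)
    traits = [f"Trait_{i:03d}" for i in range(n_traits)]
    rows = []
    for i, snp in enumerate(chosen):
        rows.append(
            {
                "SNPs": snp,
                "Disease/Trait": traits[i % n_traits],
                "p-Value": 10.0 ** -float(rng.uniform(6, 20)),
                "Reported Gene(s)": f"GENE_{snp}",
                "Strongest SNP-Risk Allele": f"{snp}-?",
            }
        )
    # Decoys: multi-SNP entries, non-rs identifiers, and weak associations
    # above the reported-p gate -- all must be removed by catalog filtering.
    others = snp_map.index.to_numpy()
    for i in range(n_multi_decoys):
        a, b = rng.choice(others, size=2, replace=False)
        rows.append({"SNPs": f"{a}; {b}", "Disease/Trait": f"MultiTrait_{i}",
                     "p-Value": 1e-8, "Reported Gene(s)": "NR",
                     "Strongest SNP-Risk Allele": f"{a}-?"})
    for i in range(n_nonrs_decoys):
        rows.append({"SNPs": f"chr{i + 1}:{int(rng.integers(1, 10 ** 8))}",
                     "Disease/Trait": f"NonRsTrait_{i}", "p-Value": 1e-7,
                     "Reported Gene(s)": "NR", "Strongest SNP-Risk Allele": "NR"})
    for i in range(n_weak_decoys):
        snp = str(rng.choice(others))
        rows.append({"SNPs": snp, "Disease/Trait": f"WeakTrait_{i}",
                     "p-Value": 1e-3, "Reported Gene(s)": "NR",
                     "Strongest SNP-Risk Allele": f"{snp}-?"})
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full study bundle from one configuration."""
    rng = np.random.default_rng(config.seed)
    snp_map, annotation = simulate_map_and_annotation(config, rng)
    genotypes = simulate_genotypes(config.n_subjects, snp_map, rng)
    covariates = simulate_covariates(config, rng)
    effect_table = config.effect_table
    if effect_table is None and config.n_planted_effects > 0:
        effect_table = plant_effects(
            annotation, snp_map, config.n_planted_effects, config.planted_beta,
            rng, config.window_bp,
        )
    effect_table = effect_table or []
    expression = {
        tissue: simulate_expression(
            genotypes, annotation, config, covariates, rng,
            tissue=tissue, effect_table=effect_table,
        )
        for tissue in config.tissues
    }
    truth = pd.DataFrame(effect_table, columns=["probe", "snp", "beta_true"])
    catalog = None
    if config.n_catalog > 0:
        catalog = simulate_catalog(
            snp_map,
            truth["snp"].unique() if len(truth) else [],
            enrichment_factor=config.catalog_enrichment,
            n_catalog=config.n_catalog,
            seed=rng,
        )
    return SyntheticStudy(
        genotypes=genotypes,
        expression=expression,
        annotation=annotation,
        covariates=covariates,
        truth=truth,
        catalog=catalog,
        config=config,
    )
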