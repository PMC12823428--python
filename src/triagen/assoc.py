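"""Per-variant association scans with QC, conditional models and inflation.

Covers disease GWAS (logistic, covariate-adjusted, optionally conditional on
extra columns such as a risk-haplotype count) and protein pQTL scans (linear
per-SD slopes), plus the variant QC filters, the Hardy-Weinberg exact test,
the genomic-control inflation factor and delta-method odds-ratio intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, norm

from ._glm import linear_fit, logistic_fit

#: median of the chi-square(1) distribution
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))

ASSOC_COLUMNS = [
    "chrom", "pos", "id", "ea", "oa", "eaf",
    "beta", "se", "z", "p", "n", "n_cases", "flag",
]


@dataclass(frozen=True)
class QcThresholds:
    """Variant/sample QC thresholds.

    Defaults follow the disease-GWAS preset: minor allele count strictly
    greater than 5 in each of the case and control arms, variant missingness
    below 3% and Hardy-Weinberg exact p no smaller than 1e-6.  The pQTL
    preset tightens missingness to 1%, relaxes HWE to 1e-15 and adds a 1%
    minor-allele-frequency floor.
    """

    min_mac_per_arm: int = 5  # strict: keep if MAC > this in both arms
    max_missing: float = 0.03
    hwe_p_floor: float = 1e-6
    min_maf: float = 0.0
    max_sample_missing: float = 0.05

    @classmethod
    def gwas(cls) -> "QcThresholds":
        return cls()

    @classmethod
    def pqtl(cls) -> "QcThresholds":
        return cls(min_mac_per_arm=0, max_missing=0.01, hwe_p_floor=1e-15, min_maf=0.01)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value by full enumeration.

    Sums the probabilities of all heterozygote counts whose conditional
    probability (given the allele counts) does not exceed that of the
    observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (either allele works: symmetric)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # possible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_Aa = h | allele counts) up to a common constant
    logp = (
        -gammaln((rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - rare - hets) / 2 + 1)
        + hets * np.log(2)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_Aa)[0][0]]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def qc_variants(
    genotypes: pd.DataFrame,
    phenotype: pd.Series | np.ndarray,
    thresholds: QcThresholds = QcThresholds.gwas(),
) -> pd.DataFrame:
    """Partition variants into kept/dropped with one primary reason each.

    Reasons are checked in order: ``monomorphic``, ``missing``, ``maf``,
    ``mac_case`` / ``mac_control`` (binary phenotypes only), ``hwe``.
    Returns a frame indexed by variant id with columns ``kept`` and ``reason``.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != genotypes.shape[0]:
        raise ValueError(
            f"phenotype length {len(y)} does not match "
            f"{genotypes.shape[0]} genotyped samples"
        )
    binary = set(np.unique(y[~np.isnan(y)])) <= {0.0, 1.0}
    geno = genotypes.to_numpy(dtype=float)
    n = geno.shape[0]
    rows = []
    for j, vid in enumerate(genotypes.columns):
        g = geno[:, j]
        obs = ~np.isnan(g)
        reason = ""
        miss = 1.0 - obs.mean()
        ac = np.nansum(g)
        n_obs = obs.sum()
        if n_obs == 0 or ac == 0 or ac == 2 * n_obs:
            reason = "monomorphic"
        elif miss >= thresholds.max_missing:
            reason = "missing"
        else:
            eaf = ac / (2 * n_obs)
            maf = min(eaf, 1 - eaf)
            if maf <= thresholds.min_maf:
                reason = "maf"
            elif binary and thresholds.min_mac_per_arm > 0:
                for arm, label in ((1.0, "mac_case"), (0.0, "mac_control")):
                    sel = obs & (y == arm)
                    ga = g[sel]
                    mac = min(np.sum(ga), 2 * ga.size - np.sum(ga))
                    if mac <= thresholds.min_mac_per_arm:
                        reason = label
                        break
        if not reason:
            gi = g[obs].astype(int)
            p_hwe = hwe_exact_p(
                int(np.sum(gi == 0)), int(np.sum(gi == 1)), int(np.sum(gi == 2))
            )
            if p_hwe < thresholds.hwe_p_floor:
                reason = "hwe"
        rows.append({"id": vid, "kept": reason == "", "reason": reason or "pass"})
    return pd.DataFrame(rows).set_index("id")


def scan(
    genotypes: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    family: str = "binary",
    condition_on: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant regression scan; one association record per variant.

    Binary traits: maximum-likelihood logistic regression with Wald standard
    errors; quantitative traits: OLS per-SD slopes (the trait is used as
    given).  Missing dosages are handled by per-variant complete-case
    analysis.  Perfect separation or non-convergence flags the record and
    leaves p missing.
    """
    if family not in ("binary", "quantitative"):
        raise ValueError(f"unknown family {family!r}")
    y_all = np.asarray(trait, dtype=float)
    n_all = genotypes.shape[0]
    if len(y_all) != n_all:
        raise ValueError("trait length does not match genotype samples")

    cov_parts = []
    if covariates is not None:
        cov_parts.append(np.asarray(covariates, dtype=float))
    if condition_on is not None:
        cov_parts.append(
            np.asarray(condition_on, dtype=float).reshape(n_all, -1)
        )
    C = (
        np.column_stack([np.ones(n_all)] + cov_parts)
        if cov_parts
        else np.ones((n_all, 1))
    )

    vinfo = None
    if variants is not None:
        vinfo = variants.set_index("id")

    geno = genotypes.to_numpy(dtype=float)
    records = []
    for j, vid in enumerate(genotypes.columns):
        g = geno[:, j]
        obs = ~(np.isnan(g) | np.isnan(y_all) | np.isnan(C).any(axis=1))
        gv, yv, Cv = g[obs], y_all[obs], C[obs]
        n = int(obs.sum())
        eaf = float(np.mean(gv) / 2.0) if n else np.nan
        X = np.column_stack([gv, Cv])
        beta = se = z = p = np.nan
        flag = ""
        n_cases = int(np.sum(yv == 1)) if family == "binary" else None
        if n == 0 or np.nanstd(gv) == 0:
            flag = "degenerate"
        elif family == "binary":
            fit = logistic_fit(X, yv)
            if fit.separated:
                flag = "separated"
            elif not fit.converged:
                flag = "nonconverged"
            else:
                beta, se = float(fit.beta[0]), float(fit.se[0])
        else:
            fit = linear_fit(X, yv)
            beta, se = float(fit.beta[0]), float(fit.se[0])
        if not flag and se > 0:
            z = beta / se
            p = float(2.0 * norm.sf(abs(z)))
            p = max(p, 5e-324)
        rec = {
            "chrom": "", "pos": 0, "ea": "A", "oa": "G",
            "id": vid, "eaf": eaf, "beta": beta, "se": se, "z": z, "p": p,
            "n": n, "n_cases": n_cases, "flag": flag,
        }
        if vinfo is not None and vid in vinfo.index:
            vr = vinfo.loc[vid]
            rec.update(
                chrom=str(vr["chrom"]), pos=int(vr["pos"]),
                ea=str(vr["ea"]), oa=str(vr["oa"]),
            )
        records.append(rec)
    return pd.DataFrame(records)[ASSOC_COLUMNS]


def genomic_lambda(p_values=None, z_values=None) -> float:
    """Genomic-control inflation: median association chi-square / 0.4549."""
    if z_values is not None:
        stats = np.asarray(z_values, dtype=float) ** 2
    elif p_values is not None:
        p = np.asarray(p_values, dtype=float)
        stats = chi2.isf(p, 1)
    else:
        raise ValueError("provide p_values or z_values")
    stats = stats[np.isfinite(stats)]
    if stats.size < 10:
        raise ValueError("need at least 10 test statistics")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with delta-method confidence bounds OR -/+ z*se*OR."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    zq = float(norm.isf((1 - level) / 2))
    orr = float(np.exp(beta))
    half = zq * se * orr
    return orr, orr - half, orr + half
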