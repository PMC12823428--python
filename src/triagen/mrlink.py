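"""cis-pQTL instruments and the two-sample Mendelian randomization battery.

Instrument construction: LD clumping of per-protein association scans
(r^2 < 0.2 within ±250 kb of each index variant), then three filters — cis
location (±1 Mb of the protein's gene), instrument strength F = beta^2/se^2
>= 10, and association with fewer than five proteins (pleiotropy guard).

Estimators: Wald ratio (single instrument), inverse-variance weighted with
multiplicative over-dispersion when Cochran's Q exceeds its degrees of
freedom, weighted median with parametric-bootstrap se, bivariate-normal
maximum likelihood, and MR-Egger with its intercept (directional pleiotropy)
test.  Panel-level inference applies Benjamini-Hochberg FDR across proteins
and re-tests significant proteins on sensitivity and replication outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .pwas import bh_adjust


@dataclass
class Instrument:
    """One genetic instrument with exposure and outcome associations."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    cis: bool = True
    n_proteins_associated: int = 1

    @property
    def f_stat(self) -> float:
        return (self.beta_exp / self.se_exp) ** 2

    @property
    def ratio(self) -> float:
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> float:
        # first-order delta method (exposure se ignored; F >= 10 screened)
        return abs(self.se_out / self.beta_exp)


# ---------------------------------------------------------------------------
# clumping and instrument filters


def ld_matrix(genotypes: pd.DataFrame, variant_ids: list[str]) -> pd.DataFrame:
    """Pairwise r^2 between variants from a genotype reference panel."""
    sub = genotypes[variant_ids].to_numpy(dtype=float)
    sub = sub - np.nanmean(sub, axis=0)
    sub = np.where(np.isnan(sub), 0.0, sub)
    denom = np.sqrt((sub**2).sum(axis=0))
    denom[denom == 0] = np.nan
    corr = (sub.T @ sub) / np.outer(denom, denom)
    return pd.DataFrame(corr**2, index=variant_ids, columns=variant_ids)


def clump(
    assoc: pd.DataFrame,
    genotypes: pd.DataFrame,
    r2_max: float = 0.2,
    window_bp: int = 250_000,
    alpha: float = 5e-8,
) -> pd.DataFrame:
    """Greedy LD clumping of significant associations.

    Repeatedly promote the smallest-p significant variant to index status and
    drop significant variants within ±window_bp whose r^2 with any retained
    index reaches ``r2_max``.  Variants absent from the LD reference are
    dropped with a reason.
    """
    sig = assoc[(assoc["p"] < alpha) & assoc["p"].notna()].copy()
    missing = [v for v in sig["id"] if v not in genotypes.columns]
    sig = sig[~sig["id"].isin(missing)]
    if sig.empty:
        out = pd.DataFrame(columns=list(assoc.columns) + ["clump_reason"])
        out.attrs["dropped_no_ld"] = missing
        return out
    r2 = ld_matrix(genotypes, sig["id"].tolist())
    sig = sig.sort_values(["p", "id"]).reset_index(drop=True)
    kept: list[pd.Series] = []
    excluded: set[str] = set()
    for _, row in sig.iterrows():
        vid = row["id"]
        if vid in excluded:
            continue
        conflict = False
        for k in kept:
            same_window = k["chrom"] == row["chrom"] and abs(
                int(k["pos"]) - int(row["pos"])
            ) <= window_bp
            if same_window and r2.loc[vid, k["id"]] >= r2_max:
                conflict = True
                break
        if conflict:
            excluded.add(vid)
            continue
        kept.append(row)
    out = pd.DataFrame(kept).reset_index(drop=True)
    out.attrs["dropped_no_ld"] = missing
    return out


def build_instruments(
    clumped: pd.DataFrame,
    gene: tuple[str, int, int],
    outcome_stats: pd.DataFrame,
    proteins_per_variant: dict[str, int] | None = None,
    f_min: float = 10.0,
    max_proteins: int = 5,
    cis_bp: int = 1_000_000,
) -> tuple[list[Instrument], pd.DataFrame]:
    """Apply the cis / strength / pleiotropy filters and join outcome stats.

    ``gene`` is (chrom, start, end); the cis window is inclusive on both
    ends.  Returns surviving instruments plus an exclusion log.
    """
    chrom, start, end = gene
    out = outcome_stats.set_index("id")
    instruments, log = [], []
    for _, row in clumped.iterrows():
        vid = row["id"]
        reason = ""
        cis = str(row["chrom"]) == str(chrom) and (
            start - cis_bp <= int(row["pos"]) <= end + cis_bp
        )
        n_assoc = (proteins_per_variant or {}).get(vid, 1)
        f = (row["beta"] / row["se"]) ** 2
        if not cis:
            reason = "not_cis"
        elif f < f_min:
            reason = "weak_instrument"
        elif n_assoc >= max_proteins:
            reason = "pleiotropic"
        elif vid not in out.index:
            reason = "no_outcome_stats"
        if reason:
            log.append({"id": vid, "excluded": True, "reason": reason})
            continue
        o = out.loc[vid]
        instruments.append(
            Instrument(
                variant_id=vid,
                beta_exp=float(row["beta"]),
                se_exp=float(row["se"]),
                beta_out=float(o["beta"]),
                se_out=float(o["se"]),
                cis=True,
                n_proteins_associated=n_assoc,
            )
        )
        log.append({"id": vid, "excluded": False, "reason": "pass"})
    return instruments, pd.DataFrame(log, columns=["id", "excluded", "reason"])


# ---------------------------------------------------------------------------
# estimators


@dataclass
class MrResult:
    """Causal estimates for one protein across the estimator battery."""

    n_instruments: int
    estimates: dict[str, tuple[float, float, float]]  # method -> (beta, se, p)
    egger_intercept: tuple[float, float, float] | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    instruments: list[str] = field(default_factory=list)

    @property
    def primary(self) -> tuple[float, float, float]:
        return self.estimates["wald" if self.n_instruments == 1 else "ivw"]


def _wald_p(beta: float, se: float) -> float:
    return float(2 * norm.sf(abs(beta / se))) if se > 0 else np.nan


def mr_battery(
    instruments: list[Instrument],
    wm_boot: int = 500,
    seed: int = 0,
    overdispersion: bool = True,
) -> MrResult:
    """Run the full estimator battery on one protein's instruments.

    Instruments with a zero exposure effect are dropped.  With a single
    instrument only the Wald ratio is populated; with several, IVW is primary
    and weighted median, maximum likelihood and MR-Egger (with intercept
    test) plus Cochran's Q are added.
    """
    instruments = [iv for iv in instruments if iv.beta_exp != 0]
    if not instruments:
        raise ValueError("no usable instruments (all exposure effects zero)")
    k = len(instruments)
    res = MrResult(
        n_instruments=k,
        estimates={},
        instruments=[iv.variant_id for iv in instruments],
    )
    ratios = np.array([iv.ratio for iv in instruments])
    r_se = np.array([iv.ratio_se for iv in instruments])

    if k == 1:
        b, s = float(ratios[0]), float(r_se[0])
        res.estimates["wald"] = (b, s, _wald_p(b, s))
        return res

    w = 1.0 / r_se**2
    b_ivw = float(np.sum(w * ratios) / np.sum(w))
    se_ivw = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - b_ivw) ** 2))
    df = k - 1
    res.q_stat, res.q_df, res.q_p = q, df, float(chi2.sf(q, df))
    if overdispersion and q / df > 1:
        se_ivw *= np.sqrt(q / df)
    res.estimates["ivw"] = (b_ivw, se_ivw, _wald_p(b_ivw, se_ivw))

    b_wm = _weighted_median(ratios, w)
    se_wm = _wm_bootstrap_se(ratios, r_se, w, wm_boot, seed)
    res.estimates["wm"] = (b_wm, se_wm, _wald_p(b_wm, se_wm))

    b_ml, se_ml = _max_likelihood(instruments)
    res.estimates["ml"] = (b_ml, se_ml, _wald_p(b_ml, se_ml))

    bx = np.array([iv.beta_exp for iv in instruments])
    by = np.array([iv.beta_out for iv in instruments])
    sy = np.array([iv.se_out for iv in instruments])
    # orient so all exposure effects are positive (standard Egger convention)
    sign = np.sign(bx)
    bx, by = bx * sign, by * sign
    we = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    XtWX = (X * we[:, None]).T @ X
    cov = np.linalg.inv(XtWX)
    coef = cov @ (X * we[:, None]).T @ by
    resid = by - X @ coef
    sigma2 = max(float(np.sum(we * resid**2) / (k - 2)), 1.0) if k > 2 else 1.0
    se_coef = np.sqrt(np.diag(cov) * sigma2)
    res.estimates["egger"] = (
        float(coef[1]),
        float(se_coef[1]),
        _wald_p(float(coef[1]), float(se_coef[1])),
    )
    res.egger_intercept = (
        float(coef[0]),
        float(se_coef[0]),
        _wald_p(float(coef[0]), float(se_coef[0])),
    )
    return res


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return float(np.interp(0.5, cw, v))


def _wm_bootstrap_se(ratios, r_se, w, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, r_se, size=(n_boot, ratios.size))
    est = np.array([_weighted_median(d, w) for d in draws])
    return float(est.std(ddof=1))


def _max_likelihood(instruments: list[Instrument]) -> tuple[float, float]:
    """Bivariate-normal ML: gamma_j true exposure effects, beta causal slope."""
    bx = np.array([iv.beta_exp for iv in instruments])
    by = np.array([iv.beta_out for iv in instruments])
    sx = np.array([iv.se_exp for iv in instruments])
    sy = np.array([iv.se_out for iv in instruments])
    k = len(bx)

    def nll(theta):
        gamma, beta = theta[:k], theta[k]
        return 0.5 * np.sum(((bx - gamma) / sx) ** 2 + ((by - beta * gamma) / sy) ** 2)

    w0 = 1.0 / (sy / np.abs(bx)) ** 2
    beta0 = float(np.sum(w0 * by / bx) / np.sum(w0))
    x0 = np.concatenate([bx, [beta0]])
    opt = minimize(nll, x0, method="BFGS", options={"maxiter": 2000, "gtol": 1e-8})
    gamma, beta = opt.x[:k], float(opt.x[k])
    # observed-information se for the causal slope
    info_bb = np.sum(gamma**2 / sy**2)
    I = np.zeros((k + 1, k + 1))
    I[np.arange(k), np.arange(k)] = 1 / sx**2 + beta**2 / sy**2
    I[np.arange(k), k] = I[k, np.arange(k)] = (
        2 * beta * gamma - by
    ) / sy**2
    I[k, k] = info_bb
    try:
        se = float(np.sqrt(np.linalg.inv(I)[k, k]))
    except np.linalg.LinAlgError:
        se = np.nan
    return beta, se


# ---------------------------------------------------------------------------
# cohort-level orchestration


def pqtl_scan_all(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-protein quantitative association scans (one GWAS per protein)."""
    from .assoc import scan

    return {
        prot: scan(
            genotypes,
            proteins[prot],
            covariates,
            family="quantitative",
            variants=variants,
        )
        for prot in proteins.columns
    }


def mr_from_cohort(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    proteins: pd.DataFrame,
    genes: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 5e-8,
    r2_max: float = 0.2,
    clump_window_bp: int = 250_000,
    seed: int = 0,
) -> dict[str, MrResult]:
    """Full instrument pipeline from one proteomic cohort.

    Runs the per-protein pQTL scans, clumps each (r^2 < ``r2_max`` within
    ±``clump_window_bp``), counts how many proteins each pQTL is significant
    for (the pleiotropy filter input), applies the cis/strength/pleiotropy
    filters against the protein's gene, and runs the estimator battery
    against ``outcome_stats`` (a disease summary-stat set from a separate
    cohort, for a valid two-sample design).  Proteins without surviving
    instruments are omitted (untestable, not an error).
    """
    scans = pqtl_scan_all(genotypes, variants, proteins, covariates)
    counts: dict[str, int] = {}
    for res in scans.values():
        for vid in res.loc[(res["p"] < alpha) & res["p"].notna(), "id"]:
            counts[vid] = counts.get(vid, 0) + 1
    gene_map = genes.set_index("protein")
    out: dict[str, MrResult] = {}
    for prot, res in scans.items():
        if prot not in gene_map.index:
            continue
        clumped = clump(res, genotypes, r2_max, clump_window_bp, alpha)
        if clumped.empty:
            continue
        g = gene_map.loc[prot]
        ivs, _ = build_instruments(
            clumped,
            (str(g["chrom"]), int(g["start"]), int(g["end"])),
            outcome_stats,
            proteins_per_variant=counts,
        )
        ivs = [iv for iv in ivs if iv.beta_exp != 0]
        if not ivs:
            continue
        out[prot] = mr_battery(ivs, seed=seed)
    return out


# ---------------------------------------------------------------------------
# panel orchestration


def mr_panel(
    per_protein: dict[str, MrResult],
    sensitivity: dict[str, MrResult] | None = None,
    replication: dict[str, MrResult] | None = None,
    q_max: float = 0.05,
    rep_alpha: float = 0.05,
) -> pd.DataFrame:
    """FDR control across the protein panel plus sensitivity/replication flags.

    BH q-values are computed over the primary (IVW or Wald ratio) p-values of
    testable proteins only; q-significant proteins are re-examined on the
    sensitivity outcome (q < ``q_max`` within the re-tested set) and on the
    replication outcome (p < ``rep_alpha`` with concordant direction).
    """
    rows = []
    for prot, res in per_protein.items():
        b, s, p = res.primary
        rows.append(
            {
                "protein": prot,
                "beta": b,
                "se": s,
                "p": p,
                "n_instruments": res.n_instruments,
                "method": "wald" if res.n_instruments == 1 else "ivw",
                "q_het_p": res.q_p,
                "egger_intercept_p": (
                    res.egger_intercept[2] if res.egger_intercept else np.nan
                ),
            }
        )
    panel = pd.DataFrame(rows)
    if panel.empty:
        return panel
    panel["q"] = bh_adjust(panel["p"])
    panel["significant"] = panel["q"] < q_max

    def _lookup(source: dict[str, MrResult] | None, prot: str, direction: float):
        if source is None or prot not in source:
            return np.nan, False
        b, _, p = source[prot].primary
        return p, bool(np.sign(b) == direction)

    sens_p = np.full(len(panel), np.nan)
    sens_same = np.zeros(len(panel), dtype=bool)
    rep_p = np.full(len(panel), np.nan)
    rep_sig = np.zeros(len(panel), dtype=bool)
    for i, row in panel.iterrows():
        if not row["significant"]:
            continue
        direction = np.sign(row["beta"])
        sens_p[i], sens_same[i] = _lookup(sensitivity, row["protein"], direction)
        p, same = _lookup(replication, row["protein"], direction)
        rep_p[i] = p
        rep_sig[i] = bool(np.isfinite(p) and p < rep_alpha and same)
    # sensitivity outcome re-tested at FDR q < q_max within the re-tested set
    sens_q = np.full(len(panel), np.nan)
    tested = np.isfinite(sens_p)
    if tested.any():
        sens_q[tested] = bh_adjust(sens_p[tested])
    panel["sensitivity_p"] = sens_p
    panel["sensitivity_q"] = sens_q
    panel["sensitivity_pass"] = (
        np.isfinite(sens_q) & (sens_q < q_max) & sens_same
    )
    panel["replication_p"] = rep_p
    panel["replicated"] = rep_sig
    return panel
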