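"""ABF colocalization and the druggability triangulation report.

Colocalization follows the single-causal-variant approximate-Bayes-factor
scheme: per-variant Wakefield log-ABFs for each trait are combined into the
five hypothesis posteriors (H0 no association, H1/H2 one trait only, H3 two
distinct causal variants, H4 one shared causal variant) under per-variant
priors p1 = p2 = 1e-4 and p12 = 1e-5, in log-sum-exp arithmetic.

The triangulation report joins proteome-wide association, Mendelian
randomization, colocalization and druggability-tier evidence into one row
per protein, gated on dual PWAS/MR support with a consistent effect
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
#: prior effect sd: log-OR scale for binary traits, per-SD for protein traits
PRIOR_SD = {"binary": 0.2, "quantitative": 0.15}


def abf(beta: float, se: float, prior_sd: float = 0.2) -> float:
    """Wakefield log approximate Bayes factor for one variant.

    log ABF = 0.5*log(se^2/(se^2+W^2)) + z^2 W^2 / (2 (se^2 + W^2)),
    evaluated stably for large |z|.
    """
    if se <= 0 or prior_sd < 0:
        raise ValueError("se must be positive and prior_sd non-negative")
    if prior_sd == 0:
        return 0.0
    v, w2 = se**2, prior_sd**2
    z2 = (beta / se) ** 2
    return float(0.5 * np.log(v / (v + w2)) + z2 * w2 / (2 * (v + w2)))


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one region."""

    region: tuple[str, int, int]
    n_variants: int
    pp: dict[str, float]  # PP.H0 .. PP.H4
    priors: tuple[float, float, float]
    category: str
    labf1: pd.Series | None = None
    labf2: pd.Series | None = None

    @property
    def pp_h4(self) -> float:
        return self.pp["PP.H4"]


def categorize(pp_h4: float, strong: float = 0.8, suggestive: float = 0.5) -> str:
    if pp_h4 > strong:
        return "colocalized"
    if pp_h4 > suggestive:
        return "suggestive"
    return "none"


def coloc_region(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    region: tuple[str, int, int] | None = None,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float = PRIOR_SD["quantitative"],
    prior_sd2: float = PRIOR_SD["binary"],
    strong: float = 0.8,
    suggestive: float = 0.5,
) -> ColocResult:
    """Single-causal-variant colocalization of two summary-stat sets.

    Traits are intersected on variant id (restricted to ``region`` if given,
    inclusive bounds).  Priors are per-variant probabilities of causality for
    trait 1 only, trait 2 only, and both.
    """
    t1, t2 = trait1.copy(), trait2.copy()
    if region is not None:
        chrom, start, end = region
        for t in (t1, t2):
            if "chrom" in t.columns:
                sel = (t["chrom"].astype(str) == str(chrom)) & t["pos"].between(
                    start, end
                )
                t.drop(t.index[~sel], inplace=True)
    merged = t1.merge(t2, on="id", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no common variants between traits in the region")

    l1 = np.array(
        [abf(b, s, prior_sd1) for b, s in zip(merged["beta_1"], merged["se_1"])]
    )
    l2 = np.array(
        [abf(b, s, prior_sd2) for b, s in zip(merged["beta_2"], merged["se_2"])]
    )
    p1, p2, p12 = priors
    lsum1, lsum2 = logsumexp(l1), logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)  # shared causal variant
    # all ordered pairs minus the diagonal = two distinct causal variants
    lH3_pairs = _log_diff(lsum1 + lsum2, lsum12)

    lh = np.array(
        [
            0.0,  # H0
            np.log(p1) + lsum1,
            np.log(p2) + lsum2,
            np.log(p1) + np.log(p2) + lH3_pairs,
            np.log(p12) + lsum12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp_dict = {f"PP.H{i}": float(pp[i]) for i in range(5)}
    if region is None:
        chroms = merged.get("chrom_1", merged.get("chrom", pd.Series(["?"])))
        pos = merged.get("pos_1", merged.get("pos", pd.Series([0])))
        region = (str(chroms.iloc[0]), int(np.min(pos)), int(np.max(pos)))
    return ColocResult(
        region=region,
        n_variants=len(merged),
        pp=pp_dict,
        priors=priors,
        category=categorize(pp_dict["PP.H4"], strong, suggestive),
        labf1=pd.Series(l1, index=merged["id"]),
        labf2=pd.Series(l2, index=merged["id"]),
    )


def _log_diff(log_a: float, log_b: float) -> float:
    """log(exp(log_a) - exp(log_b)), requiring a > b."""
    if log_b >= log_a:
        return -np.inf
    return log_a + np.log1p(-np.exp(log_b - log_a))


# ---------------------------------------------------------------------------
# triangulation report


PWAS_TIERS = ("bonferroni", "fdr", "nominal", "none")


def pwas_tier(p: float, q: float, bonf_threshold: float, alpha: float = 0.05) -> str:
    if not np.isfinite(p):
        return "none"
    if p < bonf_threshold:
        return "bonferroni"
    if np.isfinite(q) and q < alpha:
        return "fdr"
    if p < alpha:
        return "nominal"
    return "none"


def triangulate(
    pwas_results: pd.DataFrame,
    mr_panel: pd.DataFrame,
    coloc_results: dict[str, ColocResult] | None = None,
    tiers: pd.DataFrame | None = None,
    alpha: float = 0.05,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-protein evidence table.

    Gate: PWAS p < ``alpha`` AND MR q < ``q_max`` AND concordant effect
    direction.  Proteins with an undefined direction (zero effect) are
    excluded with a reason; proteins missing from the druggability tier
    table are labelled "Not classified".
    """
    pw = pwas_results.set_index("protein")
    tier_map = (
        tiers.set_index("protein")["tier"].to_dict() if tiers is not None else {}
    )
    rows, excluded = [], []
    for _, mr in mr_panel.iterrows():
        prot = mr["protein"]
        if prot not in pw.index:
            continue
        pr = pw.loc[prot]
        if not (pr["p"] < alpha and mr["q"] < q_max):
            continue
        if pr["beta"] == 0 or mr["beta"] == 0:
            excluded.append({"protein": prot, "reason": "zero_effect"})
            continue
        if np.sign(pr["beta"]) != np.sign(mr["beta"]):
            excluded.append({"protein": prot, "reason": "direction_mismatch"})
            continue
        coloc = (coloc_results or {}).get(prot)
        rows.append(
            {
                "protein": prot,
                "direction": "+" if mr["beta"] > 0 else "-",
                "pwas_tier": pwas_tier(
                    pr["p"], pr.get("q", np.nan), pr.get("bonf_threshold", 0.0), alpha
                ),
                "mr_primary_q": float(mr["q"]),
                "mr_sensitivity_pass": bool(mr.get("sensitivity_pass", False)),
                "mr_egger_intercept_ok": bool(
                    np.isfinite(mr.get("egger_intercept_p", np.nan))
                    and mr["egger_intercept_p"] > alpha
                ),
                "mr_q_test_ok": bool(
                    np.isfinite(mr.get("q_het_p", np.nan)) and mr["q_het_p"] > alpha
                ),
                "replicated": bool(mr.get("replicated", False)),
                "coloc_category": coloc.category if coloc else "none",
                "pp_h4": coloc.pp_h4 if coloc else np.nan,
                "druggability_tier": tier_map.get(prot, "Not classified"),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["excluded"] = excluded
    return report


def read_tier_table(path) -> pd.DataFrame:
    tiers = pd.read_csv(path, sep="\t")
    if not {"protein", "tier"} <= set(tiers.columns):
        raise ValueError("tier table needs columns: protein, tier")
    return tiers
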