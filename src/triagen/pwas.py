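"""Proteome-wide association: preprocessing, per-protein scans, enrichment.

Preprocessing follows the fixed order: drop proteins with more than the
allowed missing fraction, mean-impute the remainder, rank-based inverse
normal transform, then standardize to mean 0 / sd 1.  The scan fits one
covariate-adjusted logistic model per protein against incident disease
status, with optional risk-haplotype adjustment and interaction.  Pathway
enrichment uses one-sided Fisher exact tests with Benjamini-Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata
from statsmodels.stats.multitest import multipletests

from ._glm import logistic_fit


@dataclass
class ProteinMatrix:
    """Samples x proteins matrix with processing-state bookkeeping."""

    values: pd.DataFrame
    state: str = "raw"
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean()


def int_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom (3/8) offset.

    Ties receive average ranks, so tied inputs map to identical outputs.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("impute missing values before the INT step")
    n = v.size
    if n < 2:
        raise ValueError("need at least two values")
    r = rankdata(v, method="average")
    return norm.ppf((r - 0.375) / (n + 0.25))


def preprocess(raw: ProteinMatrix, max_missing: float = 0.20) -> ProteinMatrix:
    """Filter by missingness, mean-impute, inverse-normal transform, standardize.

    Proteins are dropped only when their missing fraction strictly exceeds
    ``max_missing``; constant columns are dropped (``zero_variance``) since
    standardization is undefined for them.
    """
    if raw.state != "raw":
        raise ValueError(f"expected a raw matrix, got state {raw.state!r}")
    df = raw.values.copy()
    dropped = dict(raw.dropped)

    miss = df.isna().mean()
    for prot in df.columns[miss > max_missing]:
        dropped[prot] = "missingness"
    df = df.loc[:, miss <= max_missing]

    nunique = df.nunique(dropna=True)
    for prot in df.columns[nunique <= 1]:
        dropped[prot] = "zero_variance"
    df = df.loc[:, nunique > 1]
    if df.shape[1] == 0:
        raise ValueError("all proteins were dropped during preprocessing")

    df = df.fillna(df.mean())
    out = pd.DataFrame(
        {c: int_transform(df[c].to_numpy()) for c in df.columns}, index=df.index
    )
    out = (out - out.mean()) / out.std(ddof=0)
    return ProteinMatrix(out, state="standardized", dropped=dropped)


def pwas_scan(
    proteins: ProteinMatrix,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    e4_count: pd.Series | np.ndarray | None = None,
    e4_adjust: bool = False,
    e4_interaction: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One logistic model per protein: outcome ~ protein + covariates.

    Optional risk-haplotype (e4-like) count adjustment and protein x count
    interaction.  Returns per-protein beta/se/p with odds ratios, a
    Bonferroni flag at alpha / m and BH q-values over the m tested proteins.
    """
    if proteins.state != "standardized":
        raise ValueError("run preprocess() before the scan")
    y = np.asarray(outcome, dtype=float)
    C = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    e4 = None
    if e4_adjust or e4_interaction:
        if e4_count is None:
            raise ValueError("e4_count required for adjustment/interaction")
        e4 = np.asarray(e4_count, dtype=float)

    rows = []
    for prot in proteins.values.columns:
        x = proteins.values[prot].to_numpy()
        cols = [x]
        if e4 is not None:
            cols.append(e4)
        if e4_interaction:
            cols.append(x * e4)
        X = np.column_stack(cols + [C])
        fit = logistic_fit(X, y)
        flagged = fit.separated or not fit.converged
        beta = float(fit.beta[0]) if not flagged else np.nan
        se = float(fit.se[0]) if not flagged else np.nan
        z = beta / se if se and np.isfinite(se) else np.nan
        p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
        row = {
            "protein": prot,
            "beta": beta,
            "se": se,
            "or": float(np.exp(beta)) if np.isfinite(beta) else np.nan,
            "p": p,
            "flag": "unstable" if flagged else "",
        }
        if np.isfinite(beta):
            zq = norm.isf(0.025)
            row["ci_l"] = row["or"] - zq * se * row["or"]
            row["ci_u"] = row["or"] + zq * se * row["or"]
        if e4_interaction and not flagged:
            row["beta_int"] = float(fit.beta[2])
            row["se_int"] = float(fit.se[2])
            zi = row["beta_int"] / row["se_int"]
            row["p_int"] = float(2 * norm.sf(abs(zi)))
        rows.append(row)
    res = pd.DataFrame(rows)
    m = len(res)
    bonf = alpha / m
    res["bonf_threshold"] = bonf
    res["bonf_sig"] = (res["p"] < bonf) & (res["flag"] == "")
    ok = res["p"].notna() & (res["flag"] == "")
    q = np.full(m, np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res["q"] = q
    return res


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    if m < 1:
        raise ValueError("need at least one test")
    return alpha / m


# ---------------------------------------------------------------------------
# pathway enrichment


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member, member, ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def fisher_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided (enrichment) Fisher exact p: >= k hits of n draws from a pool
    of N containing K pathway members."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    hits: set[str],
    background: set[str],
    pathways: dict[str, set[str]],
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-pathway overlap test of ``hits`` against ``background``.

    Pathways are intersected with the background; the default test is the
    one-sided hypergeometric enrichment p, with BH q-values over pathways.
    """
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    N = len(background)
    n = len(hits)
    rows = []
    for name, members in pathways.items():
        mem = members & background
        K = len(mem)
        k = len(hits & mem)
        if n == 0:
            p = 1.0
        elif two_sided:
            from scipy.stats import fisher_exact

            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
        else:
            p = fisher_enrichment_p(k, K, n, N)
        denom = (n * K) / N if N else np.nan
        rows.append(
            {
                "pathway": name,
                "n_hits_in_pathway": k,
                "n_pathway": K,
                "odds_ratio": _overlap_or(k, K, n, N),
                "expected": denom,
                "p": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


def _overlap_or(k: int, K: int, n: int, N: int) -> float:
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    if b == 0 or c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
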