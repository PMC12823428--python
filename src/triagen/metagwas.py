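"""Fixed-effects inverse-variance meta-analysis with genomic control.

Also provides allele harmonization across studies, greedy lead-variant
extraction, a Bonferroni replication rule, stable normal-tail p/z conversion
and the observed-to-liability heritability conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import genomic_lambda

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
#: palindromic variants are resolved by allele frequency only when the
#: frequency is informative (far enough from 0.5)
PALINDROME_EAF_MARGIN = 0.08


@dataclass(frozen=True)
class LiabilityParams:
    """Inputs and output of the observed-to-liability scale conversion."""

    K: float  # population prevalence
    P: float  # sample prevalence
    h2_obs: float
    z_density: float  # standard-normal density at the K-quantile
    h2_liab: float


def harmonize(
    reference: pd.DataFrame, other: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align ``other`` to the reference study's effect alleles.

    Matching (ea, oa) passes through; swapped alleles flip the sign of beta
    and the frequency.  Palindromic (A/T, C/G) variants are resolved by
    frequency when both studies are informative (|eaf - 0.5| > margin) and
    dropped otherwise; other mismatches are dropped.  Returns the harmonized
    copy of ``other`` and a frame of dropped ids with reasons.
    """
    ref = reference.set_index("id")
    out_rows, dropped = [], []
    for _, row in other.iterrows():
        vid = row["id"]
        if vid not in ref.index:
            out_rows.append(row)
            continue
        r = ref.loc[vid]
        ea, oa = str(row["ea"]), str(row["oa"])
        rea, roa = str(r["ea"]), str(r["oa"])
        palindromic = (ea, oa) in _PALINDROMIC
        if (ea, oa) == (rea, roa):
            if palindromic:
                same = _palindrome_same_strand(row["eaf"], r["eaf"])
                if same is None:
                    dropped.append({"id": vid, "reason": "palindromic_ambiguous"})
                    continue
                if not same:
                    row = _flip(row)
            out_rows.append(row)
        elif (oa, ea) == (rea, roa):
            out_rows.append(_flip(row))
        else:
            dropped.append({"id": vid, "reason": "allele_mismatch"})
    harmonized = pd.DataFrame(out_rows).reset_index(drop=True)
    return harmonized, pd.DataFrame(dropped, columns=["id", "reason"])


def _flip(row: pd.Series) -> pd.Series:
    row = row.copy()
    row["ea"], row["oa"] = row["oa"], row["ea"]
    row["beta"] = -row["beta"]
    if "z" in row:
        row["z"] = -row["z"] if np.isfinite(row["z"]) else row["z"]
    if "eaf" in row and np.isfinite(row["eaf"]):
        row["eaf"] = 1.0 - row["eaf"]
    return row


def _palindrome_same_strand(eaf_a: float, eaf_b: float) -> bool | None:
    if not (np.isfinite(eaf_a) and np.isfinite(eaf_b)):
        return None
    if (
        abs(eaf_a - 0.5) <= PALINDROME_EAF_MARGIN
        or abs(eaf_b - 0.5) <= PALINDROME_EAF_MARGIN
    ):
        return None
    return (eaf_a > 0.5) == (eaf_b > 0.5)


def meta_fixed(
    studies: list[pd.DataFrame],
    gc: bool = True,
    allow_single_study: bool = False,
    meta_gc: bool = False,
) -> pd.DataFrame:
    """Fixed-effects inverse-variance pooling across harmonized studies.

    With genomic control on, each study's standard errors are inflated by
    sqrt(max(lambda, 1)) before pooling (single-stage GC); ``meta_gc``
    optionally applies a second correction to the pooled statistics.
    Variants present in fewer than two studies are excluded unless
    ``allow_single_study`` flags them through.
    """
    if not studies:
        raise ValueError("no studies supplied")
    ref = studies[0]
    harmonized = [ref]
    for s in studies[1:]:
        h, _ = harmonize(ref, s)
        harmonized.append(h)

    lambdas = []
    for s in harmonized:
        z = s["beta"] / s["se"]
        lam = genomic_lambda(z_values=z) if gc and len(s) >= 10 else 1.0
        lambdas.append(max(lam, 1.0) if gc else 1.0)

    by_variant: dict[str, list[tuple[int, pd.Series]]] = {}
    for si, s in enumerate(harmonized):
        for _, row in s.iterrows():
            if row["se"] <= 0 or not np.isfinite(row["se"]):
                continue
            by_variant.setdefault(row["id"], []).append((si, row))

    records = []
    for vid, entries in by_variant.items():
        if len(entries) < 2 and not allow_single_study:
            continue
        betas = np.array([e[1]["beta"] for e in entries], dtype=float)
        ses = np.array(
            [e[1]["se"] * np.sqrt(lambdas[e[0]]) for e in entries], dtype=float
        )
        w = 1.0 / ses**2
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        z = beta / se
        first = entries[0][1]
        q = float(np.sum(w * (betas - beta) ** 2))
        records.append(
            {
                "id": vid,
                "chrom": str(first.get("chrom", "")),
                "pos": int(first.get("pos", 0)),
                "ea": first.get("ea", "A"),
                "oa": first.get("oa", "G"),
                "beta": beta,
                "se": se,
                "z": z,
                "p": max(float(2 * norm.sf(abs(z))), 5e-324),
                "n_studies": len(entries),
                "het_q": q,
                "single_study": len(entries) < 2,
            }
        )
    meta = pd.DataFrame(records)
    if meta_gc and len(meta) >= 10:
        lam = max(genomic_lambda(z_values=meta["z"]), 1.0)
        meta["se"] = meta["se"] * np.sqrt(lam)
        meta["z"] = meta["beta"] / meta["se"]
        meta["p"] = np.maximum(2 * norm.sf(np.abs(meta["z"])), 5e-324)
    meta.attrs["lambdas"] = lambdas
    return meta


def lead_variants(
    meta: pd.DataFrame, window_bp: int = 500_000, alpha: float = 5e-8
) -> pd.DataFrame:
    """Greedy lead extraction: smallest p first, masking ±window_bp around it."""
    sig = meta[(meta["p"] < alpha) & np.isfinite(meta["p"])].copy()
    sig = sig.sort_values(["p", "chrom", "pos", "id"]).reset_index(drop=True)
    leads = []
    taken = np.zeros(len(sig), dtype=bool)
    for i in range(len(sig)):
        if taken[i]:
            continue
        row = sig.iloc[i]
        leads.append(row)
        same = (sig["chrom"] == row["chrom"]) & (
            (sig["pos"] - row["pos"]).abs() <= window_bp
        )
        taken |= same.to_numpy()
    return pd.DataFrame(leads).reset_index(drop=True)


def replicate(leads: pd.DataFrame, replication: pd.DataFrame) -> pd.DataFrame:
    """Bonferroni replication: p < 0.05/n_leads with concordant direction."""
    n_leads = len(leads)
    rep = replication.set_index("id")
    rows = []
    for _, lead in leads.iterrows():
        vid = lead["id"]
        if vid not in rep.index:
            rows.append({"id": vid, "replicated": False, "reason": "absent"})
            continue
        r = rep.loc[vid]
        threshold = 0.05 / n_leads
        same_sign = np.sign(lead["beta"]) == np.sign(r["beta"])
        ok = bool(r["p"] < threshold and same_sign)
        rows.append(
            {
                "id": vid,
                "replicated": ok,
                "reason": "pass" if ok else (
                    "direction" if r["p"] < threshold else "p_value"
                ),
                "p_rep": float(r["p"]),
                "beta_rep": float(r["beta"]),
            }
        )
    return pd.DataFrame(rows)


def h2_liability(h2_obs: float, K: float, P: float) -> LiabilityParams:
    """Observed-scale to liability-scale heritability conversion.

    h2_liab = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))] with z the standard
    normal density at the K-quantile.
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("prevalences must lie in (0, 1)")
    z = float(norm.pdf(norm.ppf(K)))
    h2_liab = h2_obs * (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    return LiabilityParams(K=K, P=P, h2_obs=h2_obs, z_density=z, h2_liab=h2_liab)


def z_from_p(p: float) -> float:
    """Two-sided p to |z|: z = Phi^{-1}(1 - p/2), stable to p ~ 1e-300."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    return float(norm.isf(p / 2.0))


def p_from_z(z: float) -> float:
    """Two-sided tail probability of |z|."""
    return float(2.0 * norm.sf(abs(z)))
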