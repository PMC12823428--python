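"""Weighting-based natural-effects mediation for a 3-level exposure.

Decomposes the total effect of a 0/1/2 exposure (risk-haplotype count) on a
binary outcome into natural direct and natural indirect (mediator-
transmitted) effects, on the log-odds scale, using the ratio-of-mediator-
probability weighting estimator: each subject is expanded over hypothetical
exposure levels, weighted by the relative likelihood of their observed
mediator value under the hypothetical versus observed exposure, and a
logistic natural-effects model is fit on the expanded data.  Inference is by
subject-level bootstrap; sensitivity to unmeasured confounding is summarized
by E-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._glm import logistic_fit

EXPOSURE_LEVELS = (0, 1, 2)


@dataclass
class MediationResult:
    """Natural direct/indirect/total effects per contrast (0 vs 1, 0 vs 2)."""

    contrasts: tuple[str, ...]
    nde: dict[str, float]
    nie: dict[str, float]
    te: dict[str, float] = field(default_factory=dict)
    nde_se: dict[str, float] = field(default_factory=dict)
    nie_se: dict[str, float] = field(default_factory=dict)
    nde_p: dict[str, float] = field(default_factory=dict)
    nie_p: dict[str, float] = field(default_factory=dict)
    proportion_direct: dict[str, float] = field(default_factory=dict)
    evalue_nde: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    boot_estimates: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.contrasts:
            for eff, est, se, p in (
                ("NDE", self.nde[c], self.nde_se.get(c), self.nde_p.get(c)),
                ("NIE", self.nie[c], self.nie_se.get(c), self.nie_p.get(c)),
                ("TE", self.te[c], None, None),
            ):
                rows.append(
                    {
                        "contrast": c,
                        "effect": eff,
                        "log_or": est,
                        "or": float(np.exp(est)),
                        "se": se,
                        "p": p,
                        "evalue": self.evalue_nde.get(c) if eff == "NDE" else None,
                        "proportion_direct": (
                            self.proportion_direct.get(c) if eff == "NDE" else None
                        ),
                    }
                )
        return pd.DataFrame(rows)


def evalue(or_value: float) -> float:
    """E-value: minimum unmeasured-confounder strength (risk-ratio scale, on
    both arms) required to fully explain away an observed odds ratio.

    E = RR + sqrt(RR * (RR - 1)) with RR approximated by the OR; ORs below 1
    are inverted first.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    rr = or_value if or_value >= 1.0 else 1.0 / or_value
    return float(rr + np.sqrt(rr * (rr - 1.0)))


def proportion_direct(nde_logor: float, nie_logor: float) -> float:
    """Share of the total effect that is direct, on the log-odds scale."""
    total = nde_logor + nie_logor
    if total == 0:
        raise ValueError("total effect is zero; proportion undefined")
    return nde_logor / total


def natural_effects(
    data: pd.DataFrame,
    exposure: str = "hap_count",
    mediator: str = "dementia",
    outcome: str = "delirium",
    covariates: tuple[str, ...] = ("age", "sex"),
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Estimate natural direct and indirect effects of a 0/1/2 exposure.

    Algorithm: (1) logistic mediator model M ~ exposure + covariates;
    (2) expand each row over hypothetical exposure levels x'; (3) weight by
    P(M = m_obs | x', C) / P(M = m_obs | x_obs, C); (4) fit the logistic
    natural-effects model  outcome ~ x (direct) + x' (indirect) + covariates
    on the expanded weighted rows.  Exposure enters both models as a factor.
    Bootstrap resamples subjects.
    """
    cols = [exposure, mediator, outcome, *covariates]
    df = data[cols].copy()
    if df[[exposure, mediator, outcome]].isna().any().any():
        raise ValueError("exposure, mediator and outcome must be fully observed")
    present = sorted(int(v) for v in df[exposure].unique())
    levels = [lv for lv in EXPOSURE_LEVELS if lv in present]
    if 0 not in levels or len(levels) < 2:
        raise ValueError("need the reference exposure level 0 plus >= 1 other")
    contrasts = tuple(f"0vs{lv}" for lv in levels if lv != 0)

    x = df[exposure].to_numpy(dtype=int)
    m = df[mediator].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    C = df[list(covariates)].to_numpy(dtype=float)

    point = _fit_once(x, m, y, C, levels)

    rng = np.random.default_rng(seed)
    n = len(df)
    boot_rows = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            est = _fit_once(x[idx], m[idx], y[idx], C[idx], levels)
        except (ValueError, np.linalg.LinAlgError):
            continue
        boot_rows.append(est)
    boot = pd.DataFrame(boot_rows)

    res = MediationResult(
        contrasts=contrasts,
        nde={c: point[f"nde_{c}"] for c in contrasts},
        nie={c: point[f"nie_{c}"] for c in contrasts},
        n_boot=len(boot),
        boot_estimates=boot if len(boot) else None,
    )
    for c in contrasts:
        res.te[c] = res.nde[c] + res.nie[c]
        if len(boot):
            nde_se = float(boot[f"nde_{c}"].std(ddof=1))
            nie_se = float(boot[f"nie_{c}"].std(ddof=1))
            res.nde_se[c], res.nie_se[c] = nde_se, nie_se
            res.nde_p[c] = _wald_p(res.nde[c], nde_se)
            res.nie_p[c] = _wald_p(res.nie[c], nie_se)
        if res.te[c] != 0:
            res.proportion_direct[c] = proportion_direct(res.nde[c], res.nie[c])
        res.evalue_nde[c] = evalue(float(np.exp(res.nde[c])))
    return res


def _fit_once(x, m, y, C, levels) -> dict[str, float]:
    n = len(x)
    ones = np.ones(n)
    Xm = np.column_stack([ones, _dummies(x, levels), C])
    med_fit = logistic_fit(Xm, m)
    if not med_fit.converged or med_fit.separated:
        raise ValueError("mediator model did not converge")

    # probability of the observed mediator value under exposure level lv
    def p_m_obs(lv: int) -> np.ndarray:
        Xl = np.column_stack([ones, _dummies(np.full(n, lv), levels), C])
        eta = Xl @ med_fit.beta
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.where(m == 1, p1, 1.0 - p1)

    p_obs = np.empty(n)
    p_by_level = {lv: p_m_obs(lv) for lv in levels}
    for lv in levels:
        p_obs[x == lv] = p_by_level[lv][x == lv]

    # expanded data: x1 = observed exposure (direct path, determines Y and M),
    # x0 = hypothetical level steering the mediator distribution
    X_parts, y_parts, w_parts = [], [], []
    for lv in levels:
        w = p_by_level[lv] / p_obs
        X_parts.append(
            np.column_stack(
                [ones, _dummies(x, levels), _dummies(np.full(n, lv), levels), C]
            )
        )
        y_parts.append(y)
        w_parts.append(w)
    Xe = np.vstack(X_parts)
    ye = np.concatenate(y_parts)
    we = np.concatenate(w_parts)
    ne_fit = logistic_fit(Xe, ye, weights=we)
    if not ne_fit.converged or ne_fit.separated:
        raise ValueError("natural-effects model did not converge")

    k = len(levels) - 1
    out = {}
    for i, lv in enumerate(lv for lv in levels if lv != 0):
        out[f"nde_0vs{lv}"] = float(ne_fit.beta[1 + i])
        out[f"nie_0vs{lv}"] = float(ne_fit.beta[1 + k + i])
    return out


def _dummies(x: np.ndarray, levels) -> np.ndarray:
    non_ref = [lv for lv in levels if lv != 0]
    return np.column_stack([(x == lv).astype(float) for lv in non_ref])


def _wald_p(est: float, se: float) -> float:
    if not se or not np.isfinite(se):
        return np.nan
    return float(2.0 * norm.sf(abs(est / se)))
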