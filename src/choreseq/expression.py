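"""Differential-expression ranking for a two-condition replicate matrix.

Per gene: log2 fold change (condition 2 minus condition 1), an empirical-Bayes
moderated t statistic with variance shrinkage

    s_tilde^2 = (nu0 * s0^2 + d * s^2) / (nu0 + d),   d = n1 + n2 - 2,

a two-sided p-value from the t distribution with nu0 + d degrees of freedom,
and a posterior probability of differential expression (PPDE) obtained from a
beta-uniform mixture f(p) = lambda + (1 - lambda) * a * p^(a-1) fitted to all
p-values by EM.  With nu0 = 0 the moderated t reduces exactly to the ordinary
two-sample pooled t.  When the prior (nu0, s0^2) is not supplied it is
estimated from the sample variances by moment matching on log s^2 (the
standard empirical-Bayes recipe), so null p-values stay calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_P_FLOOR = 1e-300

# The beta shape is kept at or below this bound: at a = 1 the beta component
# coincides with the uniform and lambda becomes unidentifiable (EM stalls at
# its initial value on null data).
_BUM_A_MAX = 0.8


def _condition_masks(
    conditions: Sequence[str], order: tuple[str, str] | None = None
) -> tuple[np.ndarray, np.ndarray, str, str]:
    labels = list(dict.fromkeys(conditions))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {labels}")
    if order is not None:
        if set(order) != set(labels):
            raise ValueError(f"order {order} does not match labels {labels}")
        labels = list(order)
    cond = np.asarray(conditions)
    return cond == labels[0], cond == labels[1], labels[0], labels[1]


def compute_fold_changes(
    matrix: pd.DataFrame,
    conditions: Sequence[str],
    order: tuple[str, str] | None = None,
) -> pd.Series:
    """Per-gene log2 fold change: mean(condition 2) - mean(condition 1).

    ``order`` fixes which label is condition 1 and which condition 2 (default:
    order of first appearance), so exchanging the two labels flips every sign.
    Genes with all-missing values in either condition are excluded with a
    warning.
    """
    m1, m2, l1, l2 = _condition_masks(conditions, order)
    mean1 = matrix.loc[:, m1].mean(axis=1)
    mean2 = matrix.loc[:, m2].mean(axis=1)
    fc = mean2 - mean1
    bad = fc.isna()
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} gene(s) with missing condition means"
        )
        fc = fc[~bad]
    fc.name = f"log2fc_{l2}_vs_{l1}"
    return fc


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-matching estimate of the scaled-inverse-chi-square variance prior.

    Matches the mean and variance of log s^2 (Smyth-style): the excess spread
    of log sample variances over the chi-square sampling noise identifies the
    prior degrees of freedom nu0; the location identifies s0^2.  Returns
    ``(nu0, s0^2)``; nu0 = inf means complete shrinkage to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if excess <= 0:
        nu0 = np.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        # solve trigamma(nu0/2) = excess
        f = lambda x: float(special.polygamma(1, x / 2)) - excess
        lo, hi = 1e-3, 1e3
        while f(hi) > 0:
            hi *= 10
            if hi > 1e12:
                return np.inf, float(np.exp(e.mean()))
        nu0 = float(optimize.brentq(f, lo, hi))
        s0_2 = float(
            np.exp(e.mean() + special.digamma(nu0 / 2) - np.log(nu0 / 2))
        )
    return nu0, s0_2


@dataclass
class BumFit:
    """Beta-uniform mixture fit: f(p) = lambda + (1-lambda) * a * p^(a-1)."""

    lambda_: float
    a: float
    log_likelihood: float
    n_iter: int
    converged: bool

    def ppde(self, p: np.ndarray) -> np.ndarray:
        """Posterior non-null probability at each p-value (monotone
        non-increasing in p for a < 1)."""
        p = np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0)
        alt = (1.0 - self.lambda_) * self.a * p ** (self.a - 1.0)
        return alt / (self.lambda_ + alt)


def fit_bum(
    pvalues: np.ndarray,
    init_lambda: float = 0.5,
    init_a: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BumFit:
    """Fit the beta-uniform mixture to p-values by EM.

    The beta shape is constrained to (0, 0.8] for identifiability (see module
    notes); the uniform weight lambda is the null fraction.  After EM the
    fitted mixture is compared with the pure-null model (lambda = 1, log-
    likelihood 0) by BIC; if the mixture does not earn its two extra
    parameters the pure-null fit is returned, so lambda-hat does not absorb
    sampling noise on all-null data.
    """
    p = np.clip(np.asarray(pvalues, dtype=float), _P_FLOOR, 1.0)
    lam, a = init_lambda, init_a
    logp = np.log(p)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alt = (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        f = lam + alt
        ll = float(np.log(f).sum())
        w = alt / f  # posterior non-null
        sw = float(w.sum())
        lam = float(np.clip(1.0 - sw / p.size, 1e-6, 1.0 - 1e-6))
        denom = float((w * logp).sum())  # <= 0 since log p <= 0
        if sw > 0 and denom < 0:
            a = float(np.clip(-sw / denom, 1e-3, _BUM_A_MAX))
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    bic_margin = np.log(p.size)  # (k=2 params) * log(n) / 2
    if prev_ll <= bic_margin:
        return BumFit(1.0, a, 0.0, it, converged)
    return BumFit(lam, a, prev_ll, it, converged)


class DifferentialExpressionResults:
    """Results container: per-gene estimates plus the fitted mixture.

    ``frame`` columns: log2fc, t, p, ppde, rank (rank 1 = strongest evidence
    of differential expression).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        bum: BumFit,
        nu0: float,
        s0_2: float,
        conditions: tuple[str, str],
    ):
        self.frame = frame
        self.bum = bum
        self.nu0 = nu0
        self.s0_2 = s0_2
        self.conditions = conditions

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Differential expression (moderated t + beta-uniform mixture)",
            f"  conditions: {self.conditions[1]} vs {self.conditions[0]}",
            f"  genes: {len(f)}",
            f"  variance prior: nu0 = {self.nu0:.4g}, s0^2 = {self.s0_2:.4g}",
            f"  mixture: lambda = {self.bum.lambda_:.4f}, a = {self.bum.a:.4f}"
            f" (converged: {self.bum.converged})",
            f"  genes with PPDE >= 0.95: {int((f['ppde'] >= 0.95).sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


def moderated_t_ppde(
    matrix: pd.DataFrame,
    conditions: Sequence[str],
    prior_df: float | None = None,
    prior_var: float | None = None,
    seed: int | None = None,
) -> DifferentialExpressionResults:
    """Moderated two-sample t statistics and PPDE for every gene.

    ``prior_df``/``prior_var`` default to empirical estimates from the sample
    variances; ``prior_df = 0`` gives the ordinary pooled two-sample t.
    ``seed`` is accepted for interface uniformity; the fit is deterministic.

    Genes are dropped (with a warning) if any condition has fewer than 2
    observed replicates.
    """
    m1, m2, l1, l2 = _condition_masks(conditions)
    x1 = matrix.loc[:, m1]
    x2 = matrix.loc[:, m2]
    n1_obs = x1.notna().sum(axis=1)
    n2_obs = x2.notna().sum(axis=1)
    keep = (n1_obs >= 2) & (n2_obs >= 2)
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} gene(s) with <2 observed "
            "replicates in a condition"
        )
    x1, x2 = x1[keep], x2[keep]
    n1 = x1.notna().sum(axis=1).to_numpy(dtype=float)
    n2 = x2.notna().sum(axis=1).to_numpy(dtype=float)
    mean1 = x1.mean(axis=1).to_numpy()
    mean2 = x2.mean(axis=1).to_numpy()
    fc = mean2 - mean1
    ss = (
        ((x1.sub(x1.mean(axis=1), axis=0)) ** 2).sum(axis=1)
        + ((x2.sub(x2.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    ).to_numpy()
    d = n1 + n2 - 2.0
    s2 = ss / d
    d_scalar = int(round(float(np.median(d))))
    if prior_df is None:
        nu0, s0_2_est = estimate_variance_prior(s2, d_scalar)
        s0_2 = s0_2_est if prior_var is None else prior_var
    else:
        nu0 = float(prior_df)
        s0_2 = float(prior_var) if prior_var is not None else float(np.mean(s2))
    if nu0 == 0 and not (s2 > 0).all():
        raise ValueError(
            "zero sample variance with nu0 = 0; use a nonzero variance prior"
        )
    if np.isinf(nu0):
        s_tilde2 = np.full_like(s2, s0_2)
        dof = np.inf
    else:
        s_tilde2 = (nu0 * s0_2 + d * s2) / (nu0 + d)
        dof = nu0 + d
    t = fc / np.sqrt(s_tilde2 * (1.0 / n1 + 1.0 / n2))
    if np.isinf(nu0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    bum = fit_bum(p)
    ppde = bum.ppde(p)
    frame = pd.DataFrame(
        {"log2fc": fc, "t": t, "p": p, "ppde": ppde}, index=x1.index
    )
    order = _rank_order(frame, "ppde")
    frame["rank"] = pd.Series(
        np.arange(1, len(frame) + 1), index=order
    ).reindex(frame.index)
    return DifferentialExpressionResults(frame, bum, nu0, s0_2, (l1, l2))


def _rank_order(frame: pd.DataFrame, key: str) -> pd.Index:
    """Deterministic descending order: key, then |log2fc|, then gene id."""
    if key == "ppde":
        primary = frame["ppde"]
    elif key == "fold_change":
        primary = frame["log2fc"]
    elif key in ("|t|", "abs_t"):
        primary = frame["t"].abs()
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    tmp = pd.DataFrame(
        {
            "primary": -primary.to_numpy(dtype=float),
            "secondary": -frame["log2fc"].abs().to_numpy(dtype=float),
            "gene": frame.index.astype(str),
        },
        index=frame.index,
    )
    return tmp.sort_values(["primary", "secondary", "gene"], kind="mergesort").index


def rank_genes(
    results: DifferentialExpressionResults, key: str = "ppde"
) -> list[str]:
    """Gene ids in descending order of the chosen key.

    Ties break by |log2 fold change|, then lexicographic gene id, so the
    order is fully deterministic and invariant to input row order.
    """
    return list(_rank_order(results.frame, key).astype(str))


def de_gene_list(
    results: DifferentialExpressionResults,
    ppde_cutoff: float | None = 0.95,
    p_cutoff: float | None = None,
) -> tuple[set[str], set[str]]:
    """Split genes passing the cutoff into up- and down-regulated sets."""
    f = results.frame
    if p_cutoff is not None:
        if not 0 < p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        sig = f["p"] <= p_cutoff
    else:
        if not 0 <= ppde_cutoff <= 1:
            raise ValueError("ppde_cutoff must be in [0, 1]")
        sig = f["ppde"] >= ppde_cutoff
    up = set(f.index[sig & (f["log2fc"] > 0)].astype(str))
    down = set(f.index[sig & (f["log2fc"] < 0)].astype(str))
    return up, down
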