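"""Minimal sum-of-single-effects regression on summary statistics.

Operates on the RSS parameterization z ~ MVN(R lambda, R): iterative
Bayesian stepwise selection over at most L single effects, each a Wakefield
single-SNP Bayes-factor model on residualized z-scores.  Produces one lbf
row per retained signal plus coverage/purity-filtered credible sets,
enabling the multiple-causal-variant mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from pleioscan.bayes_factors import BFDecomposition, wakefield_labf
from pleioscan.errors import ValidationError
from pleioscan.io import LDMatrix

#: grid of candidate per-effect prior variances on the z-score scale;
#: 0 switches an effect off entirely
DEFAULT_VARIANCE_GRID = (0.0, 1.0, 4.0, 16.0, 64.0, 256.0, 1024.0)


@dataclass
class SusieConfig:
    L_max: int = 10
    max_iter: int = 100
    tol: float = 1e-3
    coverage: float = 0.95
    min_purity: float = 0.5
    #: fixed per-effect prior variance (z scale); None = maximize the
    #: single-effect likelihood over ``variance_grid``
    prior_variance: float | None = None
    variance_grid: tuple = DEFAULT_VARIANCE_GRID

    def __post_init__(self) -> None:
        if self.L_max < 1:
            raise ValidationError("L_max must be >= 1")
        if not (0.0 < self.coverage < 1.0):
            raise ValidationError("coverage must be in (0, 1)")
        if not (0.0 <= self.min_purity <= 1.0):
            raise ValidationError("min_purity must be in [0, 1]")
        if self.prior_variance is not None and self.prior_variance <= 0:
            raise ValidationError("fixed prior_variance must be > 0")


def _single_effect_loglik(resid_z: np.ndarray, v: float) -> float:
    """Log marginal likelihood (up to a constant) of one single effect with
    prior variance v, averaging the per-SNP BFs under a uniform prior."""
    if v <= 0.0:
        return 0.0
    lbf = wakefield_labf(resid_z, 1.0, v)
    return float(logsumexp(lbf) - np.log(resid_z.size))


def _optimize_prior_variance(resid_z: np.ndarray, grid) -> float:
    return max(grid, key=lambda v: _single_effect_loglik(resid_z, v))


def credible_set(alpha: np.ndarray, coverage: float) -> list[int]:
    """Smallest set of SNPs (by descending inclusion probability) whose
    cumulative posterior mass reaches ``coverage``."""
    order = np.argsort(-alpha, kind="stable")
    cum = np.cumsum(alpha[order])
    k = int(np.searchsorted(cum, coverage) + 1)
    k = min(k, alpha.size)
    return sorted(int(i) for i in order[:k])


def set_purity(cs: list[int], r: np.ndarray) -> float:
    """Minimum absolute pairwise LD among set members; singletons have
    purity 1."""
    if len(cs) <= 1:
        return 1.0
    sub = np.abs(r[np.ix_(cs, cs)])
    return float(sub.min())


def susie_rss(z, ld: LDMatrix, config: SusieConfig | None = None,
              fallback_abf: bool = True) -> BFDecomposition:
    """Fit the sum-of-single-effects model to z-scores and an LD matrix.

    Returns a :class:`BFDecomposition` with one lbf row per signal whose
    credible set passes the coverage/purity filter.  When no set is
    retained and ``fallback_abf`` is true, a single unresidualized row
    (the single-causal-variant equivalent) is returned instead so the
    region stays scorable; ``credible_sets`` is then empty.
    """
    config = config or SusieConfig()
    z = np.asarray(z, dtype=float)
    Q = z.size
    if ld.Q != Q:
        raise ValidationError(
            f"z has {Q} entries but LD matrix is {ld.Q}x{ld.Q}")
    R = ld.regularize().r
    L = min(config.L_max, Q)

    alpha = np.full((L, Q), 1.0 / Q)
    mu = np.zeros((L, Q))
    lbf_rows = np.zeros((L, Q))
    v_used = np.zeros(L)
    Rb = R @ (alpha * mu).sum(axis=0)

    converged = False
    for _ in range(config.max_iter):
        alpha_prev = alpha.copy()
        for l in range(L):
            Rb = Rb - R @ (alpha[l] * mu[l])
            resid = z - Rb
            v = (config.prior_variance if config.prior_variance is not None
                 else _optimize_prior_variance(resid, config.variance_grid))
            if v <= 0.0:
                alpha[l] = 1.0 / Q
                mu[l] = 0.0
                lbf_rows[l] = 0.0
                v_used[l] = 0.0
            else:
                lbf = wakefield_labf(resid, 1.0, v)
                w = np.exp(lbf - logsumexp(lbf))
                alpha[l] = w / w.sum()
                mu[l] = (v / (1.0 + v)) * resid
                lbf_rows[l] = lbf
                v_used[l] = v
            Rb = Rb + R @ (alpha[l] * mu[l])
        if np.max(np.abs(alpha - alpha_prev)) < config.tol:
            converged = True
            break

    kept_rows: list[np.ndarray] = []
    kept_sets: list[list[int]] = []
    for l in range(L):
        if v_used[l] <= 0.0:
            continue
        cs = credible_set(alpha[l], config.coverage)
        if set_purity(cs, R) < config.min_purity:
            continue
        if cs in kept_sets:  # duplicate signal converged onto the same set
            continue
        kept_rows.append(lbf_rows[l])
        kept_sets.append(cs)

    if kept_rows:
        lbf_out = np.vstack(kept_rows)
    elif fallback_abf:
        v = (config.prior_variance if config.prior_variance is not None
             else _optimize_prior_variance(z, config.variance_grid))
        lbf_out = (wakefield_labf(z, 1.0, v) if v > 0.0
                   else np.zeros(Q))[None, :]
    else:
        lbf_out = np.zeros((1, Q))
    return BFDecomposition(lbf=lbf_out, method="SuSiE",
                           snp_ids=list(ld.snp_ids),
                           credible_sets=kept_sets, converged=converged)


# ---------------------------------------------------------------------------
# tabular exchange format: L rows x Q columns, header of snp ids, so a
# reference fine-mapper's per-signal lbf matrix can be substituted


def write_lbf_table(bf: BFDecomposition, path: str) -> None:
    if bf.snp_ids is None:
        raise ValidationError("BFDecomposition carries no snp ids")
    pd.DataFrame(bf.lbf, columns=bf.snp_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_lbf_table(path: str, method: str = "SuSiE") -> BFDecomposition:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return BFDecomposition(lbf=df.to_numpy(dtype=float), method=method,
                           snp_ids=[str(c) for c in df.columns])
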