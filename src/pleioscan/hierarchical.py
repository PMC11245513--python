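"""Hierarchical (empirical-Bayes) estimation of the scan priors by MCMC.

Instead of fixing (pn, pa, pc), the scan pools all (query variant, query
trait) regions and learns three parameters by random-walk Metropolis:

* ``alpha`` — log-scale propensity of any non-query SNP being causal,
* ``beta``  — log enrichment of the query variant over other SNPs,
* ``gamma`` — effect of a per-trait covariate (e.g. genetic correlation
  with the primary trait) on the query-causal propensity.

Priors per region follow a softmax over the Q+1 configurations with the
null as reference::

    Dx = 1 + (Q-1) e^alpha + e^(alpha+beta+gamma*x)
    pn = 1/Dx,   pa = e^alpha / Dx,   pc = e^(alpha+beta+gamma*x) / Dx

so pc/pa = e^(beta+gamma*x) and the constraint pn+(Q-1)pa+pc=1 holds by
construction.  Averaged priors and posteriors over the post-burn-in chain
are the scan's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleioscan.bayes_factors import BFDecomposition
from pleioscan.errors import ValidationError
from pleioscan.posteriors import PriorSet

_GAMMA_UNUSED = 0.0


@dataclass
class HierParams:
    alpha: float
    beta: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.alpha, self.beta, self.gamma])):
            raise ValidationError("hierarchical parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


@dataclass
class McmcConfig:
    n_iter: int = 30_000
    thin: int = 30
    #: fraction of the retained (thinned) chain discarded as burn-in
    burn_fraction: float = 0.5
    proposal_sd: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0
    prior_mean: tuple[float, float, float] = (-10.0, 0.0, 0.0)
    prior_sd: tuple[float, float, float] = (5.0, 5.0, 2.0)
    #: adapt proposal scales toward ~0.3 acceptance during the first
    #: adapt_fraction of iterations, then freeze (preserves detailed
    #: balance over the retained phase)
    adapt: bool = True
    adapt_fraction: float = 0.25
    adapt_interval: int = 200

    def __post_init__(self) -> None:
        if not (self.n_iter >= self.thin >= 1):
            raise ValidationError("need n_iter >= thin >= 1")
        if not (0.0 <= self.burn_fraction < 1.0):
            raise ValidationError("burn_fraction must be in [0, 1)")


class SignalData:
    """Flattened per-(region, signal) sufficient statistics.

    The hierarchical likelihood only needs, per signal, the log-sum of
    Bayes factors over non-query SNPs (``sa``), the log Bayes factor at the
    query variant (``sc``), the region size Q, and the covariate value x.
    """

    def __init__(self, trait_ids, sa, sc, q, x=None, signal_index=None):
        self.trait_ids = list(trait_ids)
        self.sa = np.asarray(sa, dtype=float)
        self.sc = np.asarray(sc, dtype=float)
        self.q = np.asarray(q, dtype=float)
        m = len(self.trait_ids)
        if not (len(self.sa) == len(self.sc) == len(self.q) == m):
            raise ValidationError("SignalData arrays have unequal lengths")
        if np.any(self.q < 2):
            raise ValidationError("regions need Q >= 2")
        self.x = (np.zeros(m) if x is None
                  else np.asarray(x, dtype=float))
        if len(self.x) != m:
            raise ValidationError("covariate vector has wrong length")
        self.signal_index = (np.zeros(m, dtype=int) if signal_index is None
                             else np.asarray(signal_index, dtype=int))
        self.log_qm1 = np.log(self.q - 1.0)

    def __len__(self) -> int:
        return len(self.trait_ids)

    @classmethod
    def from_regions(cls, items) -> "SignalData":
        """Build from an iterable of
        ``(trait_id, BFDecomposition, query_index[, x])`` tuples.

        Each signal row of every decomposition becomes one likelihood term.
        """
        trait_ids, sa, sc, q, x, sig = [], [], [], [], [], []
        from scipy.special import logsumexp
        for item in items:
            trait_id, bf, query_index = item[0], item[1], item[2]
            xi = float(item[3]) if len(item) > 3 else 0.0
            if not isinstance(bf, BFDecomposition):
                raise ValidationError("expected a BFDecomposition")
            mask = np.ones(bf.Q, dtype=bool)
            mask[query_index] = False
            for l in range(bf.L):
                trait_ids.append(trait_id)
                sa.append(float(logsumexp(bf.lbf[l][mask])))
                sc.append(float(bf.lbf[l][query_index]))
                q.append(bf.Q)
                x.append(xi)
                sig.append(l)
        if not trait_ids:
            raise ValidationError("empty dataset")
        return cls(trait_ids, sa, sc, q, x, sig)


def _log_masses(alpha: float, beta: float, gamma: float,
                data: SignalData) -> tuple[np.ndarray, ...]:
    """Per-signal (logD, log m_n, log m_a, log m_c); masses unnormalized."""
    la = alpha
    lc = alpha + beta + gamma * data.x
    log_d = np.logaddexp(0.0, np.logaddexp(data.log_qm1 + la, lc))
    return log_d, -log_d, la - log_d + data.sa, lc - log_d + data.sc


def priors_from_params(params: HierParams, x: float, Q: int) -> PriorSet:
    """Region-level PriorSet implied by hierarchical parameters and a
    covariate value; the constraint holds by construction."""
    if Q < 2:
        raise ValidationError("Q must be >= 2")
    la = params.alpha
    lc = params.alpha + params.beta + params.gamma * x
    terms = np.array([0.0, np.log(Q - 1.0) + la, lc])
    m = terms.max()
    un = np.exp(terms - m)
    total = un.sum()
    pn = un[0] / total
    pa = un[1] / total / (Q - 1.0)
    pc = un[2] / total
    return PriorSet(pn=pn, pa=pa, pc=pc, Q=Q)


def dataset_loglik(params: HierParams, data: SignalData) -> float:
    """Marginal log-likelihood of all signals:
    sum of ln(pn + pa * sum_{j != q} BF_j + pc * BF_q)."""
    _, mn, ma, mc = _log_masses(params.alpha, params.beta, params.gamma, data)
    return float(np.logaddexp(mn, np.logaddexp(ma, mc)).sum())


@dataclass
class ChainSummary:
    """Retained MCMC samples plus per-signal averaged priors/posteriors."""

    samples: np.ndarray           # (n_retained, 3) columns alpha, beta, gamma
    loglik: np.ndarray
    accepted: np.ndarray          # per retained sample
    acceptance_rate: float
    n_burn: int
    trait_ids: list[str]
    signal_index: np.ndarray
    avg_priors: pd.DataFrame      # per signal: pn, pa, pc
    avg_posteriors: pd.DataFrame  # per signal: ppHn, ppHa, ppHc
    use_covariate: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def post_burn(self) -> np.ndarray:
        return self.samples[self.n_burn:]

    def params_mean(self) -> HierParams:
        a, b, g = self.post_burn.mean(axis=0)
        return HierParams(alpha=float(a), beta=float(b), gamma=float(g))

    def enrichment_interval(self, level: float = 0.95):
        """Central credible interval for log(pc/pa) = beta + gamma*x at
        x=0, from the post-burn-in chain."""
        lo = (1.0 - level) / 2.0
        vals = self.post_burn[:, 1]
        return (float(np.quantile(vals, lo)),
                float(np.quantile(vals, 1.0 - lo)))

    def results_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"trait_id": self.trait_ids,
                           "signal": self.signal_index})
        return pd.concat([df, self.avg_priors, self.avg_posteriors], axis=1)

    def write_chain(self, path: str) -> None:
        df = pd.DataFrame(self.samples, columns=["alpha", "beta", "gamma"])
        df.insert(0, "iteration", np.arange(1, len(df) + 1))
        df["loglik"] = self.loglik
        df["accepted"] = self.accepted.astype(int)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _signal_posteriors(theta: np.ndarray, data: SignalData):
    log_d, mn, ma, mc = _log_masses(theta[0], theta[1], theta[2], data)
    tot = np.logaddexp(mn, np.logaddexp(ma, mc))
    post = np.exp(np.stack([mn, ma, mc]) - tot)
    lc = theta[0] + theta[1] + theta[2] * data.x
    priors = np.stack([np.exp(-log_d),
                       np.exp(theta[0] - log_d),
                       np.exp(lc - log_d)])
    return priors, post


def mcmc_run(data: SignalData, config: McmcConfig | None = None,
             use_covariate: bool = False) -> ChainSummary:
    """Random-walk Metropolis over (alpha, beta, gamma) with Gaussian
    proposals and Gaussian hyper-priors.

    The chain is thinned to ``n_iter // thin`` retained samples; the first
    ``burn_fraction`` of those is discarded before averaging priors and
    posteriors per signal.  Without a covariate, gamma is held at 0 but the
    proposal stream still consumes the same random draws, so fixing
    gamma = 0 in a covariate run reproduces this chain bit for bit.
    """
    config = config or McmcConfig()
    if len(data) == 0:
        raise ValidationError("empty dataset")
    rng = np.random.default_rng(config.seed)

    sd = np.array(config.proposal_sd, dtype=float).copy()
    if not use_covariate:
        sd[2] = 0.0
    mu0 = np.array(config.prior_mean, dtype=float)
    sd0 = np.array(config.prior_sd, dtype=float)

    def log_post(theta: np.ndarray) -> tuple[float, float]:
        ll = dataset_loglik(HierParams(*theta), data)
        lp = float(-0.5 * np.sum(((theta - mu0) / sd0) ** 2))
        return ll + lp, ll

    theta = mu0.copy()
    theta[2] = 0.0 if not use_covariate else theta[2]
    lp, ll = log_post(theta)

    n_ret = config.n_iter // config.thin
    samples = np.empty((n_ret, 3))
    logliks = np.empty(n_ret)
    accflags = np.empty(n_ret, dtype=bool)
    n_acc = 0
    adapt_until = int(config.adapt_fraction * config.n_iter)
    window_acc = 0

    k = 0
    for it in range(1, config.n_iter + 1):
        eps = rng.standard_normal(3)
        u = rng.random()
        prop = theta + sd * eps
        lp_new, ll_new = log_post(prop)
        accepted = np.log(u) < lp_new - lp
        if accepted:
            theta, lp, ll = prop, lp_new, ll_new
            n_acc += 1
            window_acc += 1
        if (config.adapt and it <= adapt_until
                and it % config.adapt_interval == 0):
            rate = window_acc / config.adapt_interval
            scale = np.exp(np.clip(rate - 0.3, -0.5, 0.5))
            sd = sd * scale
            window_acc = 0
        if it % config.thin == 0:
            samples[k] = theta
            logliks[k] = ll
            accflags[k] = accepted
            k += 1

    rate = n_acc / config.n_iter
    warnings = []
    if not (0.05 <= rate <= 0.8):
        warnings.append(
            f"acceptance rate {rate:.3f} outside [0.05, 0.8]; "
            "check mixing diagnostics")

    n_burn = int(config.burn_fraction * n_ret)
    post_samples = samples[n_burn:]
    prior_sum = np.zeros((3, len(data)))
    post_sum = np.zeros((3, len(data)))
    for theta_s in post_samples:
        pri, post = _signal_posteriors(theta_s, data)
        prior_sum += pri
        post_sum += post
    m = len(post_samples)
    avg_priors = pd.DataFrame(
        {"pn": prior_sum[0] / m, "pa": prior_sum[1] / m,
         "pc": prior_sum[2] / m})
    avg_posteriors = pd.DataFrame(
        {"ppHn": post_sum[0] / m, "ppHa": post_sum[1] / m,
         "ppHc": post_sum[2] / m})

    return ChainSummary(
        samples=samples, loglik=logliks, accepted=accflags,
        acceptance_rate=rate, n_burn=n_burn,
        trait_ids=list(data.trait_ids),
        signal_index=data.signal_index.copy(),
        avg_priors=avg_priors, avg_posteriors=avg_posteriors,
        use_covariate=use_covariate, warnings=warnings)


def score_signals_fixed(data: SignalData, pa: float, pc: float
                        ) -> pd.DataFrame:
    """Posteriors for every signal under fixed per-region priors built from
    (pa, pc) and each region's Q (pn from the constraint).

    Useful both as the fixed-prior scan mode and for reusing point
    estimates exported from a hierarchical fit on a larger dataset.
    """
    pn = 1.0 - (data.q - 1.0) * pa - pc
    if np.any(pn <= 0):
        raise ValidationError("fixed (pa, pc) leave no mass for pn")
    mn = np.log(pn)
    ma = np.log(pa) + data.sa
    mc = np.log(pc) + data.sc
    tot = np.logaddexp(mn, np.logaddexp(ma, mc))
    return pd.DataFrame({
        "trait_id": data.trait_ids,
        "signal": data.signal_index,
        "ppHn": np.exp(mn - tot),
        "ppHa": np.exp(ma - tot),
        "ppHc": np.exp(mc - tot),
    })
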