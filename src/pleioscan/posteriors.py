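"""Posterior probabilities of the three hypotheses and trait-level calls.

For a region with Q SNPs under a single causal variant per signal there are
Q+1 configurations: the null (Hn), the query variant causal (Hc), and each
of the Q-1 remaining SNPs causal (Ha).  Per-signal posteriors combine the
prior mass of each hypothesis with its summed Bayes factors by log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from pleioscan.bayes_factors import BFDecomposition
from pleioscan.errors import ValidationError

#: default calling thresholds
T_HC = 0.6
T_HN = 0.2


@dataclass
class PriorSet:
    """Configuration priors (pn, pa, pc) for a region of Q SNPs.

    ``pa`` is per non-query SNP, so the constraint is
    ``pn + (Q-1) pa + pc = 1``.
    """

    pn: float
    pa: float
    pc: float
    Q: int

    def __post_init__(self) -> None:
        for name in ("pn", "pa", "pc"):
            v = getattr(self, name)
            # upper bound closed: pn rounds to exactly 1.0 in degenerate
            # hierarchical limits where pa, pc underflow toward 0
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if self.Q < 2:
            raise ValidationError("Q must be >= 2")
        total = self.pn + (self.Q - 1) * self.pa + self.pc
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(
                f"prior constraint violated: pn+(Q-1)pa+pc = {total!r}")

    @classmethod
    def from_pa_pc(cls, pa: float, pc: float, Q: int) -> "PriorSet":
        """Fill in pn from the constraint."""
        return cls(pn=1.0 - (Q - 1) * pa - pc, pa=pa, pc=pc, Q=Q)


@dataclass
class PosteriorResult:
    """Per-signal posterior probabilities of the three hypotheses."""

    ppHn: float
    ppHa: float
    ppHc: float
    signal_index: int = 0
    trait_id: str = ""
    query_snp: str = ""

    def __post_init__(self) -> None:
        probs = (self.ppHn, self.ppHa, self.ppHc)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValidationError(f"posterior outside [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValidationError(f"posteriors do not sum to 1: {probs}")


@dataclass
class TraitCall:
    """Trait-level hypothesis call aggregated over signals."""

    call: str  # "Hn" | "Ha" | "Hc"
    signal_index: int
    t_hc: float = T_HC
    t_hn: float = T_HN


def region_posteriors(bf: BFDecomposition, priors: PriorSet,
                      query_index: int) -> list[PosteriorResult]:
    """Posteriors per signal row of ``bf``.

    Unnormalized masses per signal l::

        m_n = pn
        m_a = pa * sum_{j != q} exp(lbf[l, j])
        m_c = pc * exp(lbf[l, q])

    computed on the log scale and normalized.
    """
    if priors.Q != bf.Q:
        raise ValidationError(
            f"PriorSet Q={priors.Q} does not match BF Q={bf.Q}")
    if not (0 <= query_index < bf.Q):
        raise ValidationError("query_index out of range")
    out = []
    mask = np.ones(bf.Q, dtype=bool)
    mask[query_index] = False
    for l in range(bf.L):
        row = bf.lbf[l]
        log_m = np.array([
            np.log(priors.pn),
            np.log(priors.pa) + logsumexp(row[mask]),
            np.log(priors.pc) + row[query_index],
        ])
        post = np.exp(log_m - logsumexp(log_m))
        post = post / post.sum()
        out.append(PosteriorResult(ppHn=float(post[0]), ppHa=float(post[1]),
                                   ppHc=float(post[2]), signal_index=l))
    return out


def label_signal(result: PosteriorResult, t_hc: float = T_HC,
                 t_hn: float = T_HN) -> str:
    """Threshold rule for one signal: Hc if ppHc > t_hc, else Hn if
    ppHn > t_hn, else Ha."""
    if result.ppHc > t_hc:
        return "Hc"
    if result.ppHn > t_hn:
        return "Hn"
    return "Ha"


def call_trait(results: list[PosteriorResult], t_hc: float = T_HC,
               t_hn: float = T_HN) -> TraitCall:
    """Aggregate per-signal labels into one trait-level call.

    Ranking Hc > Hn > Ha: any Hc signal makes the trait Hc (ties broken by
    maximal ppHc); otherwise any Hn signal makes it Hn; otherwise the trait
    is Ha, reported through the signal with minimum ppHa.
    """
    if not results:
        raise ValidationError("call_trait needs at least one signal")
    labels = [label_signal(r, t_hc, t_hn) for r in results]
    if "Hc" in labels:
        idx = max((i for i, lab in enumerate(labels) if lab == "Hc"),
                  key=lambda i: results[i].ppHc)
        return TraitCall("Hc", results[idx].signal_index, t_hc, t_hn)
    if "Hn" in labels:
        idx = max((i for i, lab in enumerate(labels) if lab == "Hn"),
                  key=lambda i: results[i].ppHn)
        return TraitCall("Hn", results[idx].signal_index, t_hc, t_hn)
    idx = min(range(len(results)), key=lambda i: results[i].ppHa)
    return TraitCall("Ha", results[idx].signal_index, t_hc, t_hn)


def estimate_fdr(pphc_values, t: float = T_HC) -> float:
    """Internal FDR estimate ``1 - mean(ppHc | ppHc > t)``.

    Returns NaN when no value exceeds the threshold.
    """
    v = np.asarray(pphc_values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValidationError("ppHc values must lie in [0, 1]")
    sel = v[v > t]
    if sel.size == 0:
        return float("nan")
    return float(1.0 - sel.mean())
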