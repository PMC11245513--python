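"""Wakefield approximate Bayes factors for the single-causal-variant mode.

All Bayes-factor arithmetic is kept on the natural-log scale; downstream
sums use log-sum-exp so that |z| well beyond 40 stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pleioscan.errors import ValidationError
from pleioscan.io import RegionSummary


@dataclass
class EffectPrior:
    """Prior standard deviation of the causal effect.

    ``sd_cc`` applies to log odds ratios (case-control traits),
    ``sd_quant`` to standardized effects (quantitative traits).
    Conventional coloc-family defaults; configurable.
    """

    sd_cc: float = 0.2
    sd_quant: float = 0.15

    def __post_init__(self) -> None:
        if self.sd_cc <= 0 or self.sd_quant <= 0:
            raise ValidationError("effect prior sds must be > 0")

    def variance(self, trait_type: str) -> float:
        return (self.sd_cc if trait_type == "cc" else self.sd_quant) ** 2


@dataclass
class BFDecomposition:
    """Per-signal x per-SNP natural-log Bayes factors versus the null.

    One row for the ABF mode; one row per retained signal in SuSiE mode.
    """

    lbf: np.ndarray
    method: str  # "ABF" | "SuSiE"
    snp_ids: list[str] | None = None
    credible_sets: list[list[int]] | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        self.lbf = np.atleast_2d(np.asarray(self.lbf, dtype=float))
        if self.method not in ("ABF", "SuSiE"):
            raise ValidationError(f"unknown BF method {self.method!r}")
        if self.method == "ABF" and self.lbf.shape[0] != 1:
            raise ValidationError("ABF mode carries exactly one signal row")
        if not np.all(np.isfinite(self.lbf)):
            raise ValidationError("non-finite log Bayes factor")

    @property
    def L(self) -> int:
        return self.lbf.shape[0]

    @property
    def Q(self) -> int:
        return self.lbf.shape[1]


def wakefield_labf(z, V, W) -> np.ndarray | float:
    """Natural-log approximate Bayes factor of association versus null.

    With effect estimate variance ``V`` and prior effect variance ``W``::

        labf = 0.5 * [ ln(V / (V+W)) + z^2 * W / (V+W) ]

    which is the log ratio of the marginal likelihoods
    ``N(beta_hat; 0, V+W) / N(beta_hat; 0, V)``.  Broadcasts over arrays.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(V <= 0):
        raise ValidationError("V must be > 0")
    if np.any(W < 0):
        raise ValidationError("W must be >= 0")
    if not np.all(np.isfinite(z)):
        raise ValidationError("z must be finite")
    shrink = W / (V + W)
    out = 0.5 * (np.log1p(-shrink) + z * z * shrink)
    return out if out.ndim else float(out)


def effect_variance(region: RegionSummary) -> np.ndarray:
    """Per-SNP variance V of the effect estimate.

    Uses ``se**2`` when standard errors are present, otherwise the standard
    design-based approximation ``1/(2 maf (1-maf) n s (1-s))`` for
    case-control traits and ``1/(2 maf (1-maf) n)`` for quantitative ones.
    """
    if region.se is not None:
        return region.se ** 2
    denom = 2.0 * region.maf * (1.0 - region.maf) * region.n
    if region.trait_type == "cc":
        if region.s is None:
            raise ValidationError(
                "case fraction s required for the case-control V fallback")
        denom = denom * region.s * (1.0 - region.s)
    return 1.0 / denom


def region_abf(region: RegionSummary,
               prior: EffectPrior | None = None) -> BFDecomposition:
    """Single-signal log ABFs for every SNP of an (aligned) region."""
    prior = prior or EffectPrior()
    V = effect_variance(region)
    W = prior.variance(region.trait_type)
    lbf = wakefield_labf(region.z, V, W)
    return BFDecomposition(lbf=lbf[None, :], method="ABF",
                           snp_ids=list(region.snp_ids))
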