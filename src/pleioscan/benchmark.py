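"""Conventional PheWAS comparator and benchmark evaluation metrics.

The comparator tests each trait's query-variant p-value against a
multiple-testing threshold (Benjamini-Hochberg step-up or Bonferroni);
:func:`evaluate` tallies calls against simulated truth to yield per-class
sensitivity and the true-label FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleioscan.bayes_factors import EffectPrior, region_abf
from pleioscan.errors import ValidationError
from pleioscan.hierarchical import SignalData
from pleioscan.posteriors import PosteriorResult, T_HC, T_HN, call_trait
from pleioscan.susie import SusieConfig, susie_rss

#: truth classes counted as false positives when called Hc/associated
NON_CAUSAL_TRUTHS = ("Hn", "Ha", "Ha2")
CAUSAL_TRUTHS = ("Hc", "Hc2")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p-value threshold ``alpha / m`` controlling FWER at alpha."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / m


def bh_threshold(pvals: np.ndarray, alpha: float) -> float:
    """Realized Benjamini-Hochberg cutoff: the largest p_(k) with
    p_(k) <= k * alpha / m, or 0.0 when nothing is rejected."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    crit = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(p <= crit)[0]
    if passing.size == 0:
        return 0.0
    return float(p[passing[-1]])


def conventional_phewas(pvals, method: str = "BH",
                        alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Associated / not-associated calls for the query variant p-values.

    Returns a boolean rejection vector and the realized p-value cutoff.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if method == "Bonferroni":
        cutoff = bonferroni_threshold(alpha, p.size)
        return p <= cutoff, cutoff
    if method == "BH":
        cutoff = bh_threshold(p, alpha)
        return p <= cutoff if cutoff > 0 else np.zeros(p.size, bool), cutoff
    raise ValidationError(f"unknown method {method!r}")


@dataclass
class EvalReport:
    """Confusion counts and summary rates for one method's calls."""

    confusion: pd.DataFrame        # rows: truth class, cols: call
    sensitivity: dict[str, float]  # per truth class
    true_fdr: float                # fraction of Hc calls with non-causal truth
    n_called: int
    n_total: int
    internal_fdr: float | None = None
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": {t: {c: int(v) for c, v in row.items()}
                          for t, row in self.confusion.iterrows()},
            "sensitivity": self.sensitivity,
            "true_fdr": self.true_fdr,
            "n_called": self.n_called,
            "n_total": self.n_total,
            "internal_fdr": self.internal_fdr,
            "thresholds": self.thresholds,
        }


def evaluate(calls: pd.DataFrame, truth: pd.DataFrame,
             positive_call: str = "Hc",
             internal_fdr: float | None = None,
             thresholds: dict[str, float] | None = None) -> EvalReport:
    """Tally per-trait calls against truth.

    ``calls`` needs columns (trait_id, call); ``truth`` needs
    (trait_id, truth).  A call equal to ``positive_call`` (``"Hc"`` for the
    Bayesian scan, ``"associated"`` for the conventional comparator) counts
    toward sensitivity and the true-label FDR.
    """
    for df, cols, name in ((calls, {"trait_id", "call"}, "calls"),
                           (truth, {"trait_id", "truth"}, "truth")):
        if not cols <= set(df.columns):
            raise ValidationError(f"{name} table needs columns {sorted(cols)}")
    merged = calls.merge(truth, on="trait_id", how="inner")
    if len(merged) != len(calls) or len(merged) != len(truth):
        raise ValidationError(
            f"trait id mismatch: {len(calls)} calls, {len(truth)} truth, "
            f"{len(merged)} shared")

    confusion = (merged.groupby(["truth", "call"]).size()
                 .unstack(fill_value=0))
    sensitivity = {}
    for cls_name, grp in merged.groupby("truth"):
        sensitivity[str(cls_name)] = float((grp["call"] ==
                                            positive_call).mean())
    causal = merged["truth"].isin(CAUSAL_TRUTHS)
    if causal.any():
        sensitivity["causal"] = float(
            (merged.loc[causal, "call"] == positive_call).mean())

    called = merged["call"] == positive_call
    n_called = int(called.sum())
    if n_called:
        true_fdr = float(merged.loc[called, "truth"]
                         .isin(NON_CAUSAL_TRUTHS).mean())
    else:
        true_fdr = float("nan")
    return EvalReport(confusion=confusion, sensitivity=sensitivity,
                      true_fdr=true_fdr, n_called=n_called,
                      n_total=len(merged), internal_fdr=internal_fdr,
                      thresholds=thresholds or {})


# ---------------------------------------------------------------------------
# pipeline glue: dataset -> Bayes factors -> flattened likelihood terms


def signal_data_from_dataset(dataset, method: str = "abf",
                             effect_prior: EffectPrior | None = None,
                             susie_config: SusieConfig | None = None,
                             use_rg: bool = False) -> SignalData:
    """Compute per-region Bayes factors for a simulated (or loaded)
    benchmark dataset and flatten them into :class:`SignalData`.

    ``method`` selects the single-causal-variant ABF mode or the SuSiE
    multi-signal mode; with ``use_rg`` the dataset's covariate table feeds
    the hierarchical model's x values.
    """
    if method not in ("abf", "susie"):
        raise ValidationError(f"unknown BF method {method!r}")
    items = []
    cov = dataset.covariates if use_rg else None
    for region in dataset.regions:
        if method == "abf":
            bf = region_abf(region, effect_prior)
        else:
            bf = susie_rss(region.z, dataset.ld, susie_config)
        x = cov.lookup(region.trait_id) if cov is not None else 0.0
        items.append((region.trait_id, bf, region.query_index, x))
    return SignalData.from_regions(items)


def calls_from_posteriors(posteriors: pd.DataFrame, t_hc: float = T_HC,
                          t_hn: float = T_HN) -> pd.DataFrame:
    """Aggregate a per-signal posterior table (columns trait_id, signal,
    ppHn, ppHa, ppHc) into one call per trait."""
    need = {"trait_id", "ppHn", "ppHa", "ppHc"}
    if not need <= set(posteriors.columns):
        raise ValidationError(f"posterior table needs columns {sorted(need)}")
    rows = []
    for trait_id, grp in posteriors.groupby("trait_id", sort=False):
        results = [
            PosteriorResult(ppHn=r.ppHn, ppHa=r.ppHa, ppHc=r.ppHc,
                            signal_index=int(getattr(r, "signal", 0)),
                            trait_id=str(trait_id))
            for r in grp.itertuples()
        ]
        tc = call_trait(results, t_hc=t_hc, t_hn=t_hn)
        best = max(results, key=lambda p: p.ppHc)
        rows.append({"trait_id": trait_id, "call": tc.call,
                     "signal": tc.signal_index, "ppHc": best.ppHc})
    return pd.DataFrame(rows)
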