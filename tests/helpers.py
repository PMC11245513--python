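"""Independent oracles shared across test modules.

Each function here recomputes a quantity by brute force (enumeration,
direct density evaluation, naive loops) so the package's vectorized /
log-space implementations can be checked against an independent path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def density_ratio_labf(z: float, V: float, W: float) -> float:
    """Log Bayes factor as a direct ratio of two normal densities
    N(beta_hat; 0, V+W) / N(beta_hat; 0, V) with beta_hat = z * sqrt(V)."""
    beta_hat = z * np.sqrt(V)
    return (stats.norm.logpdf(beta_hat, 0.0, np.sqrt(V + W))
            - stats.norm.logpdf(beta_hat, 0.0, np.sqrt(V)))


def enumerate_posteriors(lbf_row: np.ndarray, pn: float, pa: float,
                         pc: float, query_index: int) -> tuple[float, ...]:
    """Exhaustive scan over the Q+1 single-causal configurations.

    Configuration 0 is the null with mass pn * 1; configuration j places
    the causal variant at SNP j with mass pa * BF_j (pc * BF_j at the
    query).  Returns (ppHn, ppHa, ppHc).
    """
    lbf_row = np.asarray(lbf_row, dtype=float)
    masses = [pn * 1.0]
    hyps = ["Hn"]
    for j, lbf in enumerate(lbf_row):
        if j == query_index:
            masses.append(pc * np.exp(lbf))
            hyps.append("Hc")
        else:
            masses.append(pa * np.exp(lbf))
            hyps.append("Ha")
    masses = np.array(masses)
    masses /= masses.sum()
    return (float(masses[np.array(hyps) == "Hn"].sum()),
            float(masses[np.array(hyps) == "Ha"].sum()),
            float(masses[np.array(hyps) == "Hc"].sum()))


def bh_reject_oracle(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Step-up procedure by exhaustive k scan."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def naive_fdr(values, t: float) -> float:
    """Filter-and-average loop for the internal FDR estimator."""
    kept = [v for v in values if v > t]
    if not kept:
        return float("nan")
    return 1.0 - sum(kept) / len(kept)


def correlated_genotypes(n: int, f: float, r: float,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Two genotype vectors with allele frequency f and LD correlation r,
    built from explicit two-locus haplotype frequencies."""
    p11 = f * f + r * f * (1.0 - f)
    p10 = f - p11
    p01 = f - p11
    p00 = 1.0 - p11 - p10 - p01
    haps = rng.choice(4, size=(n, 2), p=[p00, p01, p10, p11])
    a = (haps >= 2).sum(axis=1)  # first locus allele in haplotypes 2,3
    b = (haps % 2).sum(axis=1)   # second locus allele in haplotypes 1,3
    return a.astype(float), b.astype(float)


def two_causal_ml_pair(z: np.ndarray, r: np.ndarray,
                       lams: tuple[float, float]) -> tuple[int, int]:
    """Maximum-likelihood causal pair by exhaustive configuration scan.

    For every ordered pair (i, j), evaluates the MVN(R lambda_ij, R)
    log-likelihood of z with the known non-centralities placed at i and j,
    and returns the best pair (unordered, sorted).
    """
    q = z.size
    r_reg = r + 1e-6 * np.eye(q)
    rinv = np.linalg.inv(r_reg)
    best, best_ll = None, -np.inf
    for i in range(q):
        for j in range(q):
            if i == j:
                continue
            lam = np.zeros(q)
            lam[i], lam[j] = lams
            resid = z - r_reg @ lam
            ll = -0.5 * resid @ rinv @ resid
            if ll > best_ll:
                best_ll, best = ll, (i, j)
    return tuple(sorted(best))
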