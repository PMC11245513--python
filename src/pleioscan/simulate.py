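"""Simulation of regional GWAS summary statistics with known truth.

Summary z-scores are drawn from the standard multivariate-normal summary
model: with LD matrix R and sparse causal signal vector lambda (non-centrality
per causal SNP), the expected z is R @ lambda and z ~ MVN(R lambda, R).
Five trait classes are generated: Hn (no causal variant), Ha/Ha2 (one/two
causal non-query variants), Hc (the query variant causal), Hc2 (the query
variant plus one other causal variant).  Parametric LD (AR1 or blockwise)
replaces reference haplotypes so benchmarks need no external downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from pleioscan.errors import ValidationError
from pleioscan.io import CovariateTable, LDMatrix, RegionSummary, \
    read_gwas_table, read_ld_matrix, write_gwas_table, write_ld_matrix

TRUTH_CLASSES = ("Hn", "Ha", "Ha2", "Hc", "Hc2")
_N_CAUSAL = {"Hn": 0, "Ha": 1, "Ha2": 2, "Hc": 1, "Hc2": 2}

#: class counts of the full-scale benchmark
FULL_CLASS_COUNTS = {"Hn": 88048, "Ha": 4700, "Ha2": 4700,
                     "Hc": 6276, "Hc2": 6276}
#: 1/10-scale counts used for desk runs
DESK_CLASS_COUNTS = {"Hn": 8805, "Ha": 470, "Ha2": 470,
                     "Hc": 628, "Hc2": 628}


@dataclass
class LDModel:
    """Parametric LD structure: ``ar1`` (r[i,j] = rho^|i-j|) or
    ``blockwise`` (independent AR1 blocks with per-block decay drawn from
    ``rho_range``)."""

    kind: str = "ar1"
    rho: float = 0.9
    block_size: int = 50
    rho_range: tuple[float, float] = (0.3, 0.95)
    maf_range: tuple[float, float] = (0.01, 0.5)

    def __post_init__(self) -> None:
        if self.kind not in ("ar1", "blockwise"):
            raise ValidationError(f"unknown LD model kind {self.kind!r}")
        if not (0.0 <= abs(self.rho) < 1.0):
            raise ValidationError("|rho| must be < 1")


@dataclass
class SimScenario:
    """One simulated trait: truth class plus causal configuration."""

    truth: str
    Q: int
    query_index: int
    causal_indices: tuple[int, ...]
    causal_log_ors: tuple[float, ...]
    n_cases: int = 10_000
    n_controls: int = 10_000
    trait_id: str = "sim_trait"

    def __post_init__(self) -> None:
        if self.truth not in TRUTH_CLASSES:
            raise ValidationError(f"unknown truth class {self.truth!r}")
        self.causal_indices = tuple(int(i) for i in self.causal_indices)
        self.causal_log_ors = tuple(float(g) for g in self.causal_log_ors)
        if len(self.causal_indices) != _N_CAUSAL[self.truth]:
            raise ValidationError(
                f"{self.truth} needs {_N_CAUSAL[self.truth]} causal "
                f"variants, got {len(self.causal_indices)}")
        if len(self.causal_log_ors) != len(self.causal_indices):
            raise ValidationError("one log-OR per causal variant required")
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ValidationError("causal indices must be distinct")
        if any(not (0 <= i < self.Q) for i in self.causal_indices):
            raise ValidationError("causal index out of range")
        if not (0 <= self.query_index < self.Q):
            raise ValidationError("query index out of range")
        is_query_causal = self.query_index in self.causal_indices
        if self.truth in ("Hc", "Hc2") and not is_query_causal:
            raise ValidationError(f"{self.truth} must include the query "
                                  "variant among causal indices")
        if self.truth in ("Hn", "Ha", "Ha2") and is_query_causal:
            raise ValidationError(f"{self.truth} must not include the query "
                                  "variant among causal indices")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def s(self) -> float:
        return self.n_cases / self.n


def default_snp_ids(Q: int, chrom: str = "1", start: int = 1_000_000,
                    step: int = 1_000) -> list[str]:
    return [f"{chrom}_{start + step * i}_A_G" for i in range(Q)]


def simulate_ld(Q: int, model: LDModel | None = None,
                seed: int | np.random.Generator = 0
                ) -> tuple[LDMatrix, np.ndarray]:
    """Draw an LD matrix and MAF vector from a parametric model.

    MAFs are uniform on the model's ``maf_range`` with the conventional
    floor at 0.01 (exclusive).
    """
    model = model or LDModel()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if Q < 2:
        raise ValidationError("Q must be >= 2")
    if model.kind == "ar1":
        r = toeplitz(model.rho ** np.arange(Q))
    else:
        r = np.eye(Q)
        start = 0
        while start < Q:
            stop = min(start + model.block_size, Q)
            rho = rng.uniform(*model.rho_range)
            b = stop - start
            r[start:stop, start:stop] = toeplitz(rho ** np.arange(b))
            start = stop
    lo, hi = model.maf_range
    lo = max(lo, 0.01)
    maf = lo + (hi - lo) * rng.random(Q)
    maf = np.nextafter(maf, 1.0)  # keep the 0.01 floor exclusive
    return LDMatrix(default_snp_ids(Q), r), maf


def noncentrality(scenario: SimScenario, maf: np.ndarray) -> np.ndarray:
    """Sparse signal vector lambda: per causal SNP m,
    ``gamma_m * sqrt(2 maf_m (1-maf_m) n s (1-s))``."""
    lam = np.zeros(scenario.Q)
    scale = np.sqrt(2.0 * maf * (1.0 - maf)
                    * scenario.n * scenario.s * (1.0 - scenario.s))
    for idx, gor in zip(scenario.causal_indices, scenario.causal_log_ors):
        lam[idx] = gor * scale[idx]
    return lam


def simulate_region(scenario: SimScenario, ld: LDMatrix, maf: np.ndarray,
                    rng: int | np.random.Generator = 0,
                    chol: np.ndarray | None = None,
                    se: np.ndarray | None = None) -> RegionSummary:
    """Draw one region's summary statistics under a scenario.

    ``chol`` (Cholesky factor of the regularized LD matrix) and ``se`` (the
    design-based standard errors) can be precomputed and shared across
    traits simulated on the same LD template.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    if ld.Q != scenario.Q or len(maf) != scenario.Q:
        raise ValidationError("LD/MAF dimensions do not match the scenario")
    lam = noncentrality(scenario, maf)
    ez = ld.r @ lam if scenario.causal_indices else np.zeros(scenario.Q)
    if chol is None:
        chol = np.linalg.cholesky(ld.regularize().r)
    z = ez + chol @ rng.standard_normal(scenario.Q)
    if se is None:
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * scenario.n
                           * scenario.s * (1.0 - scenario.s))
    positions = np.array([int(sid.split("_")[1]) for sid in ld.snp_ids])
    return RegionSummary(
        snp_ids=ld.snp_ids,
        positions=positions,
        maf=maf,
        n=float(scenario.n),
        query_index=scenario.query_index,
        trait_id=scenario.trait_id,
        trait_type="cc",
        beta=z * se,
        se=se,
        s=scenario.s,
    )


@dataclass
class BenchmarkDataset:
    """Simulated benchmark: regions, shared LD template, and truth table."""

    regions: list[RegionSummary]
    ld: LDMatrix
    maf: np.ndarray
    truth: pd.DataFrame  # trait_id, truth, query_index, causal_indices
    covariates: CovariateTable | None = None

    def __len__(self) -> int:
        return len(self.regions)


def _draw_causals(truth: str, query_index: int, Q: int, r: np.ndarray,
                  rng: np.random.Generator,
                  max_pair_r: float = 0.95) -> tuple[int, ...]:
    others = [i for i in range(Q) if i != query_index]
    if truth == "Hn":
        return ()
    if truth == "Hc":
        return (query_index,)
    if truth == "Ha":
        return (int(rng.choice(others)),)
    first = query_index if truth == "Hc2" else int(rng.choice(others))
    # keep the two causal variants distinguishable in LD
    for _ in range(1000):
        second = int(rng.choice(others))
        if second != first and abs(r[first, second]) < max_pair_r:
            return (first, second)
    raise ValidationError("could not place two causal variants with "
                          f"|r| < {max_pair_r}")


def build_benchmark_dataset(class_counts: dict[str, int], Q: int = 200,
                            effect_range: tuple[float, float] = (0.08, 0.25),
                            ld_model: LDModel | None = None, seed: int = 0,
                            n_cases: int = 10_000, n_controls: int = 10_000,
                            max_pair_r: float = 0.95,
                            with_rg: bool = True) -> BenchmarkDataset:
    """Simulate one region per trait with truth labels.

    Query variants are sampled uniformly at random per trait; causal
    log-OR magnitudes are uniform on ``effect_range`` with random sign.
    All traits share one LD template so the Cholesky factor is computed
    once.
    """
    for cls_name, cnt in class_counts.items():
        if cls_name not in TRUTH_CLASSES:
            raise ValidationError(f"unknown truth class {cls_name!r}")
        if cnt < 0:
            raise ValidationError("class counts must be >= 0")
    rng = np.random.default_rng(seed)
    ld, maf = simulate_ld(Q, ld_model, rng)
    chol = np.linalg.cholesky(ld.regularize().r)
    n = n_cases + n_controls
    s = n_cases / n
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * s * (1.0 - s))

    regions: list[RegionSummary] = []
    rows = []
    i = 0
    for truth in TRUTH_CLASSES:
        for _ in range(class_counts.get(truth, 0)):
            trait_id = f"trait{i:06d}"
            query_index = int(rng.integers(Q))
            causal = _draw_causals(truth, query_index, Q, ld.r, rng,
                                   max_pair_r)
            signs = rng.choice((-1.0, 1.0), size=len(causal))
            mags = rng.uniform(*effect_range, size=len(causal))
            scenario = SimScenario(
                truth=truth, Q=Q, query_index=query_index,
                causal_indices=causal,
                causal_log_ors=tuple(signs * mags),
                n_cases=n_cases, n_controls=n_controls, trait_id=trait_id)
            regions.append(simulate_region(scenario, ld, maf, rng,
                                           chol=chol, se=se))
            rows.append({
                "trait_id": trait_id,
                "truth": truth,
                "query_index": query_index,
                "query_snp": ld.snp_ids[query_index],
                "causal_indices": ",".join(map(str, causal)),
            })
            i += 1
    truth_df = pd.DataFrame(
        rows, columns=["trait_id", "truth", "query_index", "query_snp",
                       "causal_indices"])
    cov = None
    if with_rg and rows:
        cov = simulate_rg(truth_df["truth"].tolist(), rng,
                          trait_ids=truth_df["trait_id"].tolist())
        truth_df["rg"] = cov.rg
    return BenchmarkDataset(regions=regions, ld=ld, maf=maf,
                            truth=truth_df, covariates=cov)


def simulate_rg(truths, seed: int | np.random.Generator = 0,
                trait_ids: list[str] | None = None,
                hc_loc: float = 0.45, hc_scale: float = 0.25,
                null_scale: float = 0.25) -> CovariateTable:
    """Simulate genetic-correlation covariates.

    Traits whose truth is Hc/Hc2 draw from a distribution shifted toward
    high rg; all other classes draw symmetrically about zero.  Values are
    clipped to [-1, 1].
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    truths = list(truths)
    for t in truths:
        if t not in TRUTH_CLASSES:
            raise ValidationError(f"unknown truth class {t!r}")
    is_hc = np.array([t in ("Hc", "Hc2") for t in truths])
    rg = rng.normal(0.0, null_scale, size=len(truths))
    rg[is_hc] = rng.normal(hc_loc, hc_scale, size=int(is_hc.sum()))
    rg = np.clip(rg, -1.0, 1.0)
    if trait_ids is None:
        trait_ids = [f"trait{i:06d}" for i in range(len(truths))]
    return CovariateTable(trait_ids, rg)


def write_benchmark(dataset: BenchmarkDataset, outdir: str) -> None:
    """Materialize a dataset as plain-text files: one summary table per
    trait, the LD template with its id sidecar, and the truth table."""
    os.makedirs(outdir, exist_ok=True)
    trait_dir = os.path.join(outdir, "traits")
    os.makedirs(trait_dir, exist_ok=True)
    for region in dataset.regions:
        write_gwas_table(region,
                         os.path.join(trait_dir, f"{region.trait_id}.tsv"))
    write_ld_matrix(dataset.ld, os.path.join(outdir, "ld.txt"))
    dataset.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t",
                         index=False)
    if dataset.covariates is not None:
        dataset.covariates.write(os.path.join(outdir, "rg.tsv"))


def read_benchmark(outdir: str) -> BenchmarkDataset:
    """Load a dataset written by :func:`write_benchmark`."""
    truth = pd.read_csv(os.path.join(outdir, "truth.tsv"), sep="\t",
                        dtype={"causal_indices": str},
                        keep_default_na=False)
    ld = read_ld_matrix(os.path.join(outdir, "ld.txt"))
    regions = []
    for row in truth.itertuples():
        path = os.path.join(outdir, "traits", f"{row.trait_id}.tsv")
        regions.append(read_gwas_table(path, query_snp=row.query_snp,
                                       trait_id=row.trait_id))
    rg_path = os.path.join(outdir, "rg.tsv")
    cov = CovariateTable.read(rg_path) if os.path.exists(rg_path) else None
    maf = regions[0].maf if regions else np.empty(0)
    return BenchmarkDataset(regions=regions, ld=ld, maf=maf, truth=truth,
                            covariates=cov)
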