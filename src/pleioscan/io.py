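"""Reading, writing, harmonization and QC of regional summary statistics.

Variant identifiers follow the ``chrom_pos_ref_alt`` convention with the
alternate allele as the effect allele; allele harmonization against an LD
panel flips z/beta signs when a variant is encoded with swapped alleles.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pleioscan.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names of the tab-delimited summary dialect
STANDARD_COLUMNS = ("snp", "chr", "pos", "ref", "alt", "beta", "se", "z",
                    "p", "maf", "n", "s", "type")

TRAIT_TYPES = ("cc", "quant")
_TRAIT_TYPE_SYNONYMS = {
    "cc": "cc", "case-control": "cc", "case_control": "cc", "binary": "cc",
    "quant": "quant", "quantitative": "quant", "continuous": "quant",
}

#: default regularization weight applied before any factorization
LD_EPSILON = 1e-4


def parse_variant_id(snp_id: str) -> tuple[str, int, str, str]:
    """Split a ``chrom_pos_ref_alt`` identifier into its four parts."""
    parts = snp_id.split("_")
    if len(parts) < 4:
        raise ValidationError(
            f"variant id {snp_id!r} does not follow chrom_pos_ref_alt")
    chrom, pos, ref, alt = parts[0], parts[1], parts[-2], parts[-1]
    try:
        pos_i = int(pos)
    except ValueError as exc:
        raise ValidationError(f"non-integer position in id {snp_id!r}") from exc
    return chrom, pos_i, ref, alt


@dataclass
class RegionSummary:
    """One query trait's summary statistics over a genomic region.

    Per-SNP vectors (``positions``, ``beta``, ``se``, ``pval``, ``maf``,
    ``n``) all have length ``Q``; ``query_index`` locates the query variant
    within ``snp_ids``.  ``beta``/``se`` may be absent when only z-scores
    are available, in which case ``zscore`` was supplied directly.
    """

    snp_ids: list[str]
    positions: np.ndarray
    maf: np.ndarray
    n: np.ndarray
    query_index: int
    trait_id: str
    trait_type: str = "cc"
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    zscore: np.ndarray | None = None
    pval: np.ndarray | None = None
    s: float | None = None
    chrom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        self.n = np.broadcast_to(np.asarray(self.n, dtype=float),
                                 (len(self.snp_ids),)).copy()
        for name in ("beta", "se", "zscore", "pval"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.chrom is None and self.snp_ids:
            self.chrom = np.array(
                [parse_variant_id(sid)[0] for sid in self.snp_ids])
        elif self.chrom is not None:
            self.chrom = np.asarray(self.chrom).astype(str)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        q = len(self.snp_ids)
        if q == 0:  # degenerate sentinel produced by filters only
            return
        if q < 2:
            raise ValidationError(f"region needs Q >= 2 SNPs, got {q}")
        if len(set(self.snp_ids)) != q:
            seen, dupes = set(), []
            for sid in self.snp_ids:
                if sid in seen:
                    dupes.append(sid)
                seen.add(sid)
            raise ValidationError(f"duplicate snp ids: {sorted(set(dupes))}")
        for name in ("positions", "maf", "n"):
            if len(getattr(self, name)) != q:
                raise ValidationError(f"{name} has wrong length")
        for name in ("beta", "se", "zscore", "pval", "chrom"):
            v = getattr(self, name)
            if v is not None and len(v) != q:
                raise ValidationError(f"{name} has wrong length")
        if not (0 <= self.query_index < q):
            raise ValidationError(
                f"query_index {self.query_index} outside [0, {q})")
        if self.trait_type not in TRAIT_TYPES:
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "cc" and self.s is not None:
            if not (0.0 < self.s < 1.0):
                raise ValidationError(f"case fraction s={self.s} not in (0,1)")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValidationError("maf outside (0, 0.5]")
        if self.beta is not None:
            if self.se is None or np.any(self.se <= 0):
                raise ValidationError("se must be > 0 wherever beta is present")
            if not np.all(np.isfinite(self.beta / self.se)):
                raise ValidationError("z = beta/se not finite")
        elif self.zscore is None:
            raise ValidationError("either (beta, se) or zscore is required")
        if self.zscore is not None and not np.all(np.isfinite(self.zscore)):
            raise ValidationError("z not finite")
        if self.pval is not None and (np.any(self.pval <= 0)
                                      or np.any(self.pval > 1)):
            raise ValidationError("p-values outside (0, 1]")

    @property
    def Q(self) -> int:
        return len(self.snp_ids)

    @property
    def query_snp(self) -> str:
        return self.snp_ids[self.query_index]

    @property
    def z(self) -> np.ndarray:
        if self.beta is not None:
            return self.beta / self.se
        return self.zscore

    def pvalues(self) -> np.ndarray:
        """P-values, reconstructed from z via the two-sided normal tail
        when the table did not carry them."""
        if self.pval is not None:
            return self.pval
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def subset(self, indices: np.ndarray) -> "RegionSummary":
        """Restrict to ``indices`` (order preserved as given).

        The query variant must be among the retained indices.
        """
        indices = np.asarray(indices, dtype=int)
        keep = {int(i) for i in indices}
        if self.query_index not in keep:
            raise ValidationError(
                f"query variant {self.query_snp} lost in subset")
        new_query = int(np.where(indices == self.query_index)[0][0])
        pick = lambda v: None if v is None else v[indices]
        return RegionSummary(
            snp_ids=[self.snp_ids[i] for i in indices],
            positions=self.positions[indices],
            maf=self.maf[indices],
            n=self.n[indices],
            query_index=new_query,
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            beta=pick(self.beta),
            se=pick(self.se),
            zscore=pick(self.zscore),
            pval=pick(self.pval),
            s=self.s,
            chrom=pick(self.chrom),
        )


@dataclass
class LDMatrix:
    """SNP x SNP correlation matrix aligned to a :class:`RegionSummary`."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r = np.asarray(self.r, dtype=float)
        q = len(self.snp_ids)
        if self.r.shape != (q, q):
            raise ValidationError(
                f"LD matrix shape {self.r.shape} does not match {q} ids")
        if q and not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("LD matrix not symmetric")
        if q and not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValidationError("LD matrix diagonal not 1")
        if q and np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValidationError("LD entries outside [-1, 1]")

    @property
    def Q(self) -> int:
        return len(self.snp_ids)

    def regularize(self, epsilon: float = LD_EPSILON) -> "LDMatrix":
        """Shrink toward the identity: ``r <- (1-eps) r + eps I``.

        Guards PSD violations from finite reference panels before any
        factorization.
        """
        r = (1.0 - epsilon) * self.r + epsilon * np.eye(self.Q)
        out = LDMatrix.__new__(LDMatrix)
        out.snp_ids = list(self.snp_ids)
        out.r = r
        return out

    def subset(self, indices: np.ndarray) -> "LDMatrix":
        indices = np.asarray(indices, dtype=int)
        return LDMatrix([self.snp_ids[i] for i in indices],
                        self.r[np.ix_(indices, indices)])


@dataclass
class CovariateTable:
    """Per-query-trait covariate (genetic correlation with the primary
    trait), consumed by the hierarchical prior model."""

    trait_ids: list[str]
    rg: np.ndarray

    def __post_init__(self) -> None:
        self.trait_ids = list(self.trait_ids)
        self.rg = np.asarray(self.rg, dtype=float)
        if len(self.trait_ids) != len(self.rg):
            raise ValidationError("trait_ids and rg lengths differ")
        if np.any(np.abs(self.rg) > 1.0):
            raise ValidationError("rg outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trait_id": self.trait_ids, "rg": self.rg})

    @classmethod
    def read(cls, path: str) -> "CovariateTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if not {"trait_id", "rg"} <= set(df.columns):
            raise FormatError("covariate table needs columns trait_id, rg")
        return cls(df["trait_id"].astype(str).tolist(),
                   df["rg"].to_numpy(dtype=float))

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.17g")

    def lookup(self, trait_id: str, default: float = 0.0) -> float:
        try:
            return float(self.rg[self.trait_ids.index(trait_id)])
        except ValueError:
            return default


# ---------------------------------------------------------------------------
# summary tables


def _sniff_sep(path: str) -> str:
    opener = __import__("gzip").open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_gwas_table(path: str, dialect: dict[str, str] | None = None,
                    query_snp: str | None = None,
                    trait_id: str | None = None) -> RegionSummary:
    """Read one region's summary statistics into a :class:`RegionSummary`.

    Parameters
    ----------
    path:
        Tab- or comma-delimited file with a header; gzip is handled
        transparently.
    dialect:
        Maps standard column names (see :data:`STANDARD_COLUMNS`) to the
        file's column names, e.g. ``{"snp": "rsid", "p": "pvalue"}``.
    query_snp:
        Identifier of the query variant; defaults to the first row.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path),
                     float_precision="round_trip")
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    cols = set(df.columns)
    if "snp" not in cols:
        raise FormatError(f"{path}: missing required column 'snp'")
    has_beta = {"beta", "se"} <= cols
    if not has_beta and "z" not in cols:
        raise FormatError(
            f"{path}: need either columns (beta, se) or column z")
    for req in ("maf", "n"):
        if req not in cols:
            raise FormatError(f"{path}: missing required column {req!r}")

    required = ["snp", "maf", "n"] + (["beta", "se"] if has_beta else ["z"])
    n_before = len(df)
    df = df.dropna(subset=required)
    if len(df) < n_before:
        logger.info("%s: dropped %d rows with missing required fields",
                    path, n_before - len(df))

    snp_ids = df["snp"].astype(str).tolist()
    if len(set(snp_ids)) != len(snp_ids):
        dupes = sorted({s for s in snp_ids if snp_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate snp ids {dupes}")

    if "pos" in cols:
        positions = df["pos"].to_numpy(dtype=np.int64)
    else:
        positions = np.array([parse_variant_id(s)[1] for s in snp_ids])
    chrom = (df["chr"].astype(str).to_numpy() if "chr" in cols else None)

    qidx = 0
    if query_snp is not None:
        if query_snp not in snp_ids:
            raise ValidationError(
                f"query variant {query_snp!r} absent from {path}")
        qidx = snp_ids.index(query_snp)

    ttype = "cc"
    if "type" in cols and len(df):
        raw = str(df["type"].iloc[0]).lower()
        if raw not in _TRAIT_TYPE_SYNONYMS:
            raise FormatError(f"{path}: unknown trait type {raw!r}")
        ttype = _TRAIT_TYPE_SYNONYMS[raw]
    s = float(df["s"].iloc[0]) if ("s" in cols and len(df)) else None
    if ttype == "quant":
        s = None

    return RegionSummary(
        snp_ids=snp_ids,
        positions=positions,
        maf=df["maf"].to_numpy(dtype=float),
        n=df["n"].to_numpy(dtype=float),
        query_index=qidx,
        trait_id=trait_id if trait_id is not None
                 else os.path.splitext(os.path.basename(str(path)))[0],
        trait_type=ttype,
        beta=df["beta"].to_numpy(dtype=float) if has_beta else None,
        se=df["se"].to_numpy(dtype=float) if has_beta else None,
        zscore=df["z"].to_numpy(dtype=float) if "z" in cols else None,
        pval=df["p"].to_numpy(dtype=float) if "p" in cols else None,
        s=s,
        chrom=chrom,
    )


def write_gwas_table(region: RegionSummary, path: str) -> None:
    """Write a region back to the standard tab-delimited dialect at full
    precision (round-trips through :func:`read_gwas_table`)."""
    data: dict[str, object] = {"snp": region.snp_ids}
    if region.chrom is not None:
        data["chr"] = region.chrom
    data["pos"] = region.positions
    if region.beta is not None:
        data["beta"] = region.beta
        data["se"] = region.se
    if region.zscore is not None:
        data["z"] = region.zscore
    if region.pval is not None:
        data["p"] = region.pval
    data["maf"] = region.maf
    data["n"] = region.n
    if region.s is not None:
        data["s"] = np.full(region.Q, region.s)
    data["type"] = ["case-control" if region.trait_type == "cc"
                    else "quantitative"] * region.Q
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


# ---------------------------------------------------------------------------
# LD matrices


def read_ld_matrix(path: str, ids_path: str | None = None) -> LDMatrix:
    """Read an LD matrix.

    ``*.npz`` files are treated as the binary dialect (arrays ``r`` and
    ``snp_ids``); anything else as a whitespace-delimited square matrix
    with a sidecar id list at ``ids_path`` (default ``<path>.ids``).
    """
    if str(path).endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            return LDMatrix([str(s) for s in z["snp_ids"]], z["r"])
    r = np.loadtxt(path)
    if r.ndim == 0:
        raise FormatError(f"{path}: not a matrix")
    ids_path = ids_path or f"{path}.ids"
    with open(ids_path) as fh:
        snp_ids = [line.strip() for line in fh if line.strip()]
    return LDMatrix(snp_ids, r)


def write_ld_matrix(ld: LDMatrix, path: str,
                    ids_path: str | None = None) -> None:
    if str(path).endswith(".npz"):
        np.savez(path, r=ld.r, snp_ids=np.array(ld.snp_ids))
        return
    np.savetxt(path, ld.r, fmt="%.17g")
    with open(ids_path or f"{path}.ids", "w") as fh:
        fh.write("\n".join(ld.snp_ids) + "\n")


# ---------------------------------------------------------------------------
# harmonization and QC


def _canonical_key(snp_id: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = parse_variant_id(snp_id)
    a, b = sorted((ref, alt))
    return chrom, pos, a, b


def align_to_ld(region: RegionSummary,
                ld: LDMatrix) -> tuple[RegionSummary, LDMatrix]:
    """Restrict region and LD panel to their shared variants, in region
    order, flipping z/beta signs where the effect allele is encoded the
    other way round.

    The query variant must survive the intersection; ids in the returned
    objects follow the LD panel's encoding.  Idempotent.
    """
    if region.snp_ids == ld.snp_ids:
        return region, ld

    panel = {_canonical_key(sid): (j, sid) for j, sid in enumerate(ld.snp_ids)}
    keep_region: list[int] = []
    keep_panel: list[int] = []
    flips: list[bool] = []
    panel_ids: list[str] = []
    for i, sid in enumerate(region.snp_ids):
        key = _canonical_key(sid)
        hit = panel.get(key)
        if hit is None:
            continue
        j, panel_sid = hit
        _, _, ref_r, alt_r = parse_variant_id(sid)
        _, _, ref_p, alt_p = parse_variant_id(panel_sid)
        keep_region.append(i)
        keep_panel.append(j)
        flips.append((ref_r, alt_r) == (alt_p, ref_p))
        panel_ids.append(panel_sid)
    if not keep_region:
        raise ValidationError("no shared variants between region and panel")

    sub = region.subset(np.array(keep_region))
    flip = np.array(flips)
    if flip.any():
        sign = np.where(flip, -1.0, 1.0)
        if sub.beta is not None:
            sub.beta = sub.beta * sign
        if sub.zscore is not None:
            sub.zscore = sub.zscore * sign
        # MAF refers to the minor allele and is unchanged by recoding
    sub.snp_ids = panel_ids
    sub_ld = ld.subset(np.array(keep_panel))
    return sub, sub_ld


def window_region(region: RegionSummary,
                  half_width: float = 500_000) -> RegionSummary:
    """Restrict a region to SNPs within ``half_width`` bp of the query
    variant (fixed-width substitute for recombination-map windows)."""
    center = region.positions[region.query_index]
    same_chrom = (region.chrom == region.chrom[region.query_index])
    keep = same_chrom & (np.abs(region.positions - center) <= half_width)
    if keep.all():
        return region
    return region.subset(np.where(keep)[0])


@dataclass
class QCResult:
    """Outcome of :func:`qc_filter`: the filtered region plus flags."""

    region: RegionSummary | None
    testable: bool
    n_removed: int
    reason: str | None = None


def case_allele_count(region: RegionSummary) -> float:
    """Approximate allele count of the query variant among cases,
    ``2 * n * s * maf`` (summary dialects rarely carry the true AC)."""
    if region.trait_type != "cc" or region.s is None:
        return float("inf")
    q = region.query_index
    return float(2.0 * region.n[q] * region.s * region.maf[q])


def qc_filter(region: RegionSummary | None, min_case_ac: float = 25,
              hla_interval: tuple[float, float] = (20e6, 40e6),
              hla_chrom: str = "6") -> QCResult:
    """Apply the two scan-level QC rules.

    Variants inside the HLA interval on chromosome 6 are removed; a region
    whose query variant has case allele count <= ``min_case_ac`` (or falls
    inside the HLA interval) is flagged non-testable.
    """
    if region is None or region.Q == 0:
        return QCResult(region=region, testable=False, n_removed=0,
                        reason="empty region")
    lo, hi = hla_interval
    in_hla = ((region.chrom == hla_chrom)
              & (region.positions >= lo) & (region.positions <= hi))
    n_removed = int(in_hla.sum())
    if in_hla[region.query_index]:
        return QCResult(region=None, testable=False, n_removed=n_removed,
                        reason="query variant inside HLA interval")
    if n_removed:
        region = region.subset(np.where(~in_hla)[0])
    ac = case_allele_count(region)
    if ac <= min_case_ac:
        return QCResult(region=region, testable=False, n_removed=n_removed,
                        reason=f"query case allele count {ac:.1f} <= "
                               f"{min_case_ac}")
    return QCResult(region=region, testable=True, n_removed=n_removed)
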