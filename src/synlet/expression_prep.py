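"""Expression-matrix ingestion, normalisation, standardisation and gene-set I/O.

The scan statistic downstream works on per-gene z-scores, which are
invariant to any per-gene monotone affine transform, so the normalisation
here only has to put samples on a comparable scale: counts are converted
to log2 counts-per-million with an optional TMM scale-factor correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("counts", "log_expression", "standardized")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with a processing-stage tag."""

    values: pd.DataFrame
    stage: str = "counts"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_counts(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV of non-negative counts.

    First column is the gene id, remaining columns are samples.
    Duplicate gene rows are collapsed by summation (with a warning);
    negative or non-numeric cells are an error naming the offending cell.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            gene = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric count for gene {gene!r} in sample {col!r} of {path}"
            )
    if (raw.to_numpy() < 0).any():
        r, c = np.argwhere(raw.to_numpy() < 0)[0]
        raise ValueError(
            f"negative count for gene {raw.index[r]!r} in sample {raw.columns[c]!r}"
        )
    if raw.index.has_duplicates:
        n_dup = int(raw.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by sum", n_dup)
        raw = raw.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(raw.astype(float), stage="counts")


def _tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors (doubly trimmed, weighted).

    Reference sample: the one whose upper-quartile CPM is closest to the
    mean upper quartile. Factors are normalised to geometric mean 1.
    """
    cpm = counts / lib_sizes * 1e6
    uq = np.array([np.quantile(cpm[:, j][cpm[:, j] > 0], 0.75) for j in range(cpm.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if ok.sum() < 10:
            continue
        pj = counts[ok, j] / lib_sizes[j]
        pr = counts[ok, ref] / lib_sizes[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (lib_sizes[j] - counts[ok, j]) / (lib_sizes[j] * counts[ok, j]) + (
            lib_sizes[ref] - counts[ok, ref]
        ) / (lib_sizes[ref] * counts[ok, ref])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.any():
            factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def normalize_counts(
    m: ExpressionMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 1,
    use_tmm: bool = False,
    keep_samples: list[str] | None = None,
    prior: float = 0.5,
) -> ExpressionMatrix:
    """Filter lowly expressed genes and convert counts to log2-CPM.

    A gene is kept when its CPM is >= ``min_cpm`` (boundary inclusive) in
    at least ``min_samples`` samples; kept genes become
    ``log2(CPM + prior)``. Already-log input passes through unchanged.
    ``keep_samples`` subsets columns first (e.g. to drop normal tissue).
    """
    if m.stage == "log_expression":
        return m
    if m.stage != "counts":
        raise ValueError(f"expected counts, got stage {m.stage!r}")
    df = m.values if keep_samples is None else m.values.loc[:, list(keep_samples)]
    lib = df.to_numpy().sum(axis=0)
    if (lib <= 0).any():
        bad = df.columns[np.argmax(lib <= 0)]
        raise ValueError(f"sample {bad!r} has zero library size")
    if use_tmm:
        lib = lib * _tmm_factors(df.to_numpy(), lib)
    cpm = df.to_numpy() / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("all genes removed by the expression filter")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("expression filter removed %d of %d genes", n_drop, len(keep))
    out = pd.DataFrame(np.log2(cpm[keep] + prior), index=df.index[keep], columns=df.columns)
    return ExpressionMatrix(out, stage="log_expression")


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row to mean 0, sd 1 (population sd, denominator n).

    Constant rows cannot be standardised and are dropped with a warning.
    Idempotent on its own output up to floating-point error.
    """
    if m.stage not in ("log_expression", "standardized"):
        raise ValueError(f"expected log_expression, got stage {m.stage!r}")
    x = m.values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d constant gene rows before standardisation", n_drop)
    z = (x[keep] - mu[keep]) / sd[keep]
    out = pd.DataFrame(z, index=m.values.index[keep], columns=m.values.columns)
    return ExpressionMatrix(out, stage="standardized")


@dataclass
class GeneSetCollection:
    """Named gene sets (ordered, unique members) with a provenance note."""

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, self.provenance)


def read_gene_sets(
    path: str | Path,
    min_size: int = 5,
    universe=None,
) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes per tab-separated line).

    Members are de-duplicated preserving order and, when a ``universe`` of
    gene ids is given, intersected with it; sets smaller than ``min_size``
    after intersection are excluded (logged with their size).
    """
    universe_set = None if universe is None else set(universe)
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (<3 fields)")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if universe_set is not None:
                members = [g for g in members if g in universe_set]
            if len(members) < min_size:
                logger.info(
                    "excluding gene set %s (size %d < %d after universe intersection)",
                    name, len(members), min_size,
                )
                continue
            sets[name] = tuple(members)
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, collection.provenance or "na", *members]) + "\n")


@dataclass
class AnchorProfile:
    """Ranked anchor-gene expression curve across samples.

    ``curve`` holds samples sorted by ascending anchor expression with both
    log2 and linear values; ``ratio_at_rank(q)`` is the linear-scale
    expression at ascending rank ceil(q*n) divided by the linear median —
    e.g. q=0.10 asks how far below the cohort median the bottom decile sits.
    """

    anchor: str
    curve: pd.DataFrame
    median_linear: float

    def ratio_at_rank(self, q: float) -> float:
        n = len(self.curve)
        if not 0 < q <= 1:
            raise ValueError("q must be in (0, 1]")
        idx = math.ceil(q * n) - 1
        return float(self.curve["linear"].iloc[idx] / self.median_linear)


def anchor_profile(m: ExpressionMatrix, anchor: str) -> AnchorProfile:
    """Rank samples by anchor-gene log-expression (ascending)."""
    if m.stage != "log_expression":
        raise ValueError(f"anchor profile needs log_expression, got {m.stage!r}")
    if anchor not in m.values.index:
        raise ValueError(f"anchor gene {anchor!r} not present in the matrix")
    logvals = m.values.loc[anchor]
    order = np.argsort(logvals.to_numpy(), kind="stable")
    curve = pd.DataFrame(
        {
            "sample_id": logvals.index[order],
            "log2_expression": logvals.to_numpy()[order],
        }
    )
    curve["linear"] = 2.0 ** curve["log2_expression"]
    curve["rank"] = np.arange(1, len(curve) + 1)
    return AnchorProfile(anchor, curve, float(np.median(curve["linear"])))
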