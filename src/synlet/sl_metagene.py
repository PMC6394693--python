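"""Pathway-metagene association scan against an anchor gene.

For every gene set (pathway) with at least ``min_pathway_size`` members in
the cohort, the standardized member-gene submatrix is summarised by its
first right-singular vector — one metagene score per sample. Metagene and
anchor-gene expression are each binned into tertiles and their 3x3
contingency table scored with a Pearson chi-squared statistic. Because
cohort-wide inter-gene correlation inflates that statistic far beyond its
nominal df=4 distribution, significance comes from a size-matched
resampling null: random gene sets of the same size k, drawn from the whole
matrix (anchor excluded), pushed through the identical metagene -> tertile
-> chi-squared path. Empirical exceedance p-values are then adjusted with
the Benjamini-Hochberg step-up and called significant below an FDR
threshold (0.2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from ._util import substream
from .expression_prep import ExpressionMatrix, GeneSetCollection, standardize_genes

logger = logging.getLogger(__name__)

TERTILE_LABELS = np.array(["low", "mid", "high"])


# --------------------------------------------------------------------------
# Metagene
# --------------------------------------------------------------------------


@dataclass
class Metagene:
    """First-singular-vector summary of a pathway's standardized expression.

    ``scores`` is the unit-norm first right-singular vector (one value per
    sample); its sign is fixed so that it correlates non-negatively with
    the mean standardized expression of the member genes.
    ``explained_variance`` is sigma_1^2 over the sum of all squared
    singular values.
    """

    pathway: str
    scores: np.ndarray
    explained_variance: float
    k: int


def _leading_right_singular(a: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector and explained-variance fraction of ``a``.

    Uses the k x k Gram matrix eigendecomposition (k = rows << samples),
    which is exact and much cheaper than a full SVD in the resampling loop.
    """
    gram = a @ a.T
    w, u = np.linalg.eigh(gram)
    w = np.clip(w, 0.0, None)
    lam = w[-1]
    if lam <= 0:
        raise ValueError("matrix has no signal (all singular values zero)")
    v = a.T @ u[:, -1]
    v /= np.linalg.norm(v)
    return v, float(lam / w.sum())


def compute_metagene(submatrix, pathway: str = "") -> Metagene:
    """Metagene of a standardized genes x samples submatrix.

    Accepts an :class:`ExpressionMatrix` (stage ``standardized``), a
    DataFrame or a plain array. Requires at least 2 non-constant rows and
    at least 9 samples (so the downstream tertiles are non-degenerate).
    """
    if isinstance(submatrix, ExpressionMatrix):
        if submatrix.stage != "standardized":
            raise ValueError(f"metagene needs standardized input, got {submatrix.stage!r}")
        a = submatrix.values.to_numpy(dtype=float)
    elif isinstance(submatrix, pd.DataFrame):
        a = submatrix.to_numpy(dtype=float)
    else:
        a = np.asarray(submatrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("submatrix must be 2-dimensional (genes x samples)")
    if a.shape[1] < 9:
        raise ValueError("need at least 9 samples")
    if (a.std(axis=1) > 0).sum() < 2:
        raise ValueError("need at least 2 non-constant gene rows")
    v, ev = _leading_right_singular(a)
    if v @ a.mean(axis=0) < 0:
        v = -v
    return Metagene(pathway=pathway, scores=v, explained_variance=ev, k=a.shape[0])


# --------------------------------------------------------------------------
# Tertiles and chi-squared
# --------------------------------------------------------------------------


def _tertile_codes(values: np.ndarray) -> np.ndarray:
    """Integer tertile codes 0/1/2 (low/mid/high) by stable ascending sort.

    The first floor(n/3) samples are low, the last floor(n/3) high, the
    remainder mid; ties are broken by input order (stable sort), so the
    assignment is deterministic even for degenerate input.
    """
    values = np.asarray(values)
    n = values.size
    if n < 9:
        raise ValueError("need at least 9 samples for tertile binning")
    if np.unique(values).size == 1:
        logger.warning("tertile_bin: all values equal; assigning by input order")
    order = np.argsort(values, kind="stable")
    third = n // 3
    codes = np.ones(n, dtype=np.int64)
    codes[order[:third]] = 0
    codes[order[n - third :]] = 2
    return codes


def tertile_bin(values) -> np.ndarray:
    """Bin samples into labelled tertiles {'low', 'mid', 'high'}."""
    return TERTILE_LABELS[_tertile_codes(np.asarray(values))]


@dataclass
class ContingencyResult:
    table: np.ndarray  # 3x3 observed counts
    chi2: float
    df: int
    expected: np.ndarray


def _chi2_from_codes(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Pearson chi-squared of the 3x3 table of two coded label vectors.

    Hand-coded (no continuity correction) because this sits inside the
    resampling loop; cross-checked against scipy in the test suite.
    """
    table = np.bincount(codes_a * 3 + codes_b, minlength=9).reshape(3, 3).astype(float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    expected = np.outer(rows, cols) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if np.issubdtype(labels.dtype, np.integer):
        codes = labels.astype(np.int64)
        cats = np.unique(codes)
    else:
        cats, codes = np.unique(labels, return_inverse=True)
    if len(cats) != 3:
        raise ValueError(f"expected 3 categories, found {len(cats)} (degenerate margin)")
    return codes


def contingency_chi2(labels_a, labels_b) -> ContingencyResult:
    """3x3 contingency chi-squared between two tertile label vectors.

    Expected counts come from the row/column margins; df = 4. No p-value
    is attached — significance in the scan comes from resampling, never
    from the asymptotic chi-squared distribution.
    """
    a = _as_codes(labels_a)
    b = _as_codes(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    table = np.bincount(a * 3 + b, minlength=9).reshape(3, 3).astype(float)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row/column margin: degenerate binning")
    expected = np.outer(rows, cols) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return ContingencyResult(table=table.astype(int), chi2=chi2, df=4, expected=expected)


# --------------------------------------------------------------------------
# Resampling null and empirical p-values
# --------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Sorted chi-squared statistics from size-k random gene sets."""

    k: int
    n_iter: int
    stats: np.ndarray  # sorted ascending
    seed: int


def build_null(
    k: int,
    m: ExpressionMatrix,
    anchor_labels,
    n_iter: int = 500_000,
    seed: int = 0,
    exclude: tuple[str, ...] = (),
) -> NullDistribution:
    """Resampling null for pathway size k.

    Each iteration draws k genes without replacement from the standardized
    matrix (minus ``exclude``, normally the anchor gene), computes the
    metagene, tertile-bins it and scores the 3x3 chi-squared against the
    fixed anchor tertiles. Pathways sharing a size k can share one null.
    """
    if m.stage != "standardized":
        raise ValueError(f"null construction needs standardized input, got {m.stage!r}")
    values = m.values
    if exclude:
        values = values.drop(index=[g for g in exclude if g in values.index])
    x = np.ascontiguousarray(values.to_numpy(dtype=float))
    n_genes = x.shape[0]
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the {n_genes}-gene sampling universe")
    anchor_codes = _as_codes(anchor_labels)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(k),)))
    stats = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(n_genes, size=k, replace=False)
        v, _ = _leading_right_singular(x[idx])
        stats[i] = _chi2_from_codes(anchor_codes, _tertile_codes(v))
    stats.sort()
    return NullDistribution(k=k, n_iter=n_iter, stats=stats, seed=seed)


def empirical_p(chi2_observed: float, null: NullDistribution, correction: str = "add_one") -> float:
    """Exceedance p-value of an observed statistic within a resampling null.

    ``add_one`` (default): (1 + #{null > obs}) / (1 + n_iter), which is
    never zero and keeps the FDR step-up well behaved. ``raw``:
    #{null > obs} / n_iter, the literal counting rule, which can return 0.
    Exceedance is strict; ties do not count.
    """
    if null.stats.size == 0:
        raise ValueError("empty null distribution")
    n_greater = null.stats.size - int(np.searchsorted(null.stats, chi2_observed, side="right"))
    if correction == "add_one":
        return (1 + n_greater) / (1 + null.n_iter)
    if correction == "raw":
        return n_greater / null.n_iter
    raise ValueError(f"unknown correction {correction!r}")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, rank-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# The scan
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanConfig:
    n_iter: int = 500_000
    seed: int = 0
    fdr_threshold: float = 0.2
    correction: str = "add_one"
    share_nulls: bool = True
    min_pathway_size: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.min_pathway_size < 2:
            raise ValueError("min_pathway_size must be >= 2")


@dataclass
class ScanResult:
    """Per-pathway calls plus the resampling nulls that produced them."""

    calls: pd.DataFrame
    nulls: dict = field(default_factory=dict)
    anchor: str = ""

    @property
    def significant(self) -> pd.DataFrame:
        return self.calls[self.calls["significant"]]


def run_sl_scan(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    anchor: str,
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Full scan: metagene -> tertiles -> chi-squared -> resampling p -> BH.

    ``m`` is log-expression; it is standardized internally and the anchor's
    tertiles are taken from its log-expression row. The anchor gene is
    removed from any pathway containing it before the SVD (leakage guard)
    and excluded from the null sampling universe. Pathways that fall below
    ``min_pathway_size`` members within the matrix are skipped (logged).
    Deterministic for a fixed config and seed.
    """
    if m.stage != "log_expression":
        raise ValueError(f"scan needs log_expression input, got stage {m.stage!r}")
    if anchor not in m.values.index:
        raise ValueError(f"anchor gene {anchor!r} not present in the matrix")

    anchor_codes = _tertile_codes(m.values.loc[anchor].to_numpy(dtype=float))
    std = standardize_genes(m)
    universe = set(std.values.index)

    tested: list[tuple[str, tuple[str, ...]]] = []
    for name, members in sets.items():
        kept = tuple(g for g in members if g in universe and g != anchor)
        if anchor in members:
            logger.info("pathway %s: anchor %s removed from members before SVD", name, anchor)
        if len(kept) < config.min_pathway_size:
            logger.info(
                "pathway %s skipped: %d members in matrix < %d",
                name, len(kept), config.min_pathway_size,
            )
            continue
        tested.append((name, kept))
    if not tested:
        raise ValueError("no pathway passed the size filter")
    logger.info("testing %d of %d pathways against anchor %s", len(tested), len(sets), anchor)

    x = std.values
    observed: dict[str, tuple[int, float]] = {}
    for name, members in tested:
        try:
            mg = compute_metagene(x.loc[list(members)], pathway=name)
            chi2 = _chi2_from_codes(anchor_codes, _tertile_codes(mg.scores))
        except ValueError as exc:
            raise ValueError(f"pathway {name}: {exc}") from exc
        observed[name] = (len(members), chi2)

    nulls: dict = {}
    p_emp = {}
    if config.share_nulls:
        for k in sorted({k for k, _ in observed.values()}):
            nulls[k] = build_null(
                k, std, anchor_codes, n_iter=config.n_iter, seed=config.seed, exclude=(anchor,)
            )
        for name, (k, chi2) in observed.items():
            p_emp[name] = empirical_p(chi2, nulls[k], config.correction)
    else:
        for j, (name, (k, chi2)) in enumerate(observed.items()):
            null = build_null(
                k, std, anchor_codes, n_iter=config.n_iter,
                seed=int(substream(config.seed, 4, j).integers(2**31)), exclude=(anchor,),
            )
            nulls[name] = null
            p_emp[name] = empirical_p(chi2, null, config.correction)

    names = [name for name, _ in tested]
    p_vec = np.array([p_emp[n] for n in names])
    p_adj = adjust_fdr(p_vec)
    calls = pd.DataFrame(
        {
            "pathway": names,
            "k": [observed[n][0] for n in names],
            "chi2": [observed[n][1] for n in names],
            "p_empirical": p_vec,
            "p_adjusted": p_adj,
            "significant": p_adj < config.fdr_threshold,
        }
    ).sort_values(["p_adjusted", "p_empirical", "pathway"], kind="stable", ignore_index=True)
    logger.info(
        "%d of %d pathways significant at FDR %.2g",
        int(calls["significant"].sum()), len(calls), config.fdr_threshold,
    )
    return ScanResult(calls=calls, nulls=nulls, anchor=anchor)


# --------------------------------------------------------------------------
# Candidate-pathway descriptors
# --------------------------------------------------------------------------


def pathway_overlap(sets: GeneSetCollection) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise shared-gene counts and Jaccard indices between gene sets.

    The count diagonal holds the set sizes; the Jaccard diagonal is 1.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets for an overlap matrix")
    names = list(sets)
    members = {n: set(sets[n]) for n in names}
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    jaccard = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            inter = len(members[a] & members[b])
            union = len(members[a] | members[b])
            counts.loc[a, b] = counts.loc[b, a] = inter
            jaccard.loc[a, b] = jaccard.loc[b, a] = inter / union
    return counts, jaccard


@dataclass
class HeatmapLayout:
    gene_order: list[str]
    sample_order: list[str]
    clusters: pd.Series  # gene -> flat cluster id
    cut_height: float


def heatmap_layout(
    m: ExpressionMatrix,
    pathway_genes,
    anchor: str,
    method: str = "average",
    metric: str = "euclidean",
    cut_height: float | None = None,
) -> HeatmapLayout:
    """Row-clustered, anchor-ordered layout for a pathway expression heatmap.

    Gene rows are ordered by deterministic agglomerative clustering
    (``average`` linkage; euclidean or correlation distance) of the
    standardized submatrix; columns are *not* clustered — samples are fixed
    in ascending order of anchor expression. Flat clusters are cut at
    ``cut_height`` (default 0.7 x the maximum merge height).
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported distance {metric!r}")
    if anchor not in m.values.index:
        raise ValueError(f"anchor gene {anchor!r} not present in the matrix")
    genes = [g for g in pathway_genes if g in m.values.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 pathway genes present in the matrix")
    std = m if m.stage == "standardized" else standardize_genes(m)
    sub = std.values.loc[[g for g in genes if g in std.values.index]]
    z = linkage(sub.to_numpy(), method=method, metric=metric)
    order = leaves_list(z)
    cut = 0.7 * z[:, 2].max() if cut_height is None else float(cut_height)
    flat = fcluster(z, t=cut, criterion="distance")
    anchor_vals = m.values.loc[anchor].to_numpy(dtype=float)
    sample_order = list(m.values.columns[np.argsort(anchor_vals, kind="stable")])
    return HeatmapLayout(
        gene_order=[sub.index[i] for i in order],
        sample_order=sample_order,
        clusters=pd.Series(flat, index=sub.index, name="cluster"),
        cut_height=cut,
    )
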