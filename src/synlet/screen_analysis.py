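"""Viability-ratio analytics for an isogenic knockout/wild-type RNAi screen.

Each gene's knockdown effect is summarised as the ratio of post-knockdown
viability in the knockout line over the wild-type line (KO/WT). Ratios
below 1 mark candidate synthetic-lethal (SL) genes — knockdown hurts the
knockout line more — and ratios at or above a threshold (1.3 by default)
mark reverse-synthetic-lethal (RSL) genes. Gene classes are compared to
the genome-wide background with kernel-density summaries, peak locations
and two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Smallest p-value reported by the statistical environment used for the
#: original analyses; smaller values are floored to this in reports.
P_FLOOR = 2.2e-16


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a screen TSV with columns gene_id, wt_viability, ko_viability."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "wt_viability", "ko_viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table {path} lacks columns: {sorted(missing)}")
    return df


def compute_ratios(screen: pd.DataFrame) -> pd.DataFrame:
    """Attach the KO/WT viability ratio; the ratio is always recomputed.

    Raises for duplicate gene ids and for missing or non-positive
    viabilities, naming the first offending gene.
    """
    df = screen.copy()
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene id {df.loc[dup, 'gene_id'].iloc[0]!r}")
    for col in ("wt_viability", "ko_viability"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            gene = df.loc[bad, "gene_id"].iloc[0]
            raise ValueError(f"non-positive or missing {col} for gene {gene!r}")
        df[col] = vals.astype(float)
    df["ratio"] = df["ko_viability"] / df["wt_viability"]
    return df


def classify_sl_rsl(
    table: pd.DataFrame,
    rsl_threshold: float = 1.3,
    sl_threshold: float = 1.0,
) -> pd.DataFrame:
    """Label each gene RSL (ratio >= rsl_threshold, boundary inclusive),
    SL (ratio < sl_threshold) or neutral. Every gene gets exactly one label.
    """
    if not 0 <= sl_threshold <= rsl_threshold:
        raise ValueError(
            f"thresholds must satisfy 0 <= sl ({sl_threshold}) <= rsl ({rsl_threshold})"
        )
    df = table.copy()
    ratio = df["ratio"].to_numpy()
    label = np.where(ratio >= rsl_threshold, "RSL", np.where(ratio < sl_threshold, "SL", "neutral"))
    df["label"] = label
    return df


@dataclass
class DensitySummary:
    """Gaussian-kernel density on a fixed grid with located peaks."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peaks: list[tuple[float, float]] = field(default_factory=list)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth h = 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    The sd uses denominator n-1; when the IQR collapses to zero the sd
    alone is used. Identical values have no usable spread and raise.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("all values identical: bandwidth would be zero")
    return 0.9 * spread * n ** (-0.2)


def estimate_density(
    values,
    bandwidth: float | None = None,
    grid_size: int = 512,
    min_rel_height: float = 0.25,
) -> DensitySummary:
    """Gaussian KDE on a ``grid_size``-point grid spanning [min-3h, max+3h]."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if np.unique(values).size < 2:
        raise ValueError("all values identical: bandwidth would be zero")
    h = float(bandwidth) if bandwidth is not None else silverman_bandwidth(values)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(values, bw_method=h / values.std(ddof=1))
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    density = kde(grid)
    summary = DensitySummary(grid=grid, density=density, bandwidth=h)
    summary.peaks = find_peaks(summary, min_rel_height=min_rel_height)
    return summary


def find_peaks(
    summary: DensitySummary, min_rel_height: float = 0.25
) -> list[tuple[float, float]]:
    """Local density maxima at least ``min_rel_height`` of the global maximum.

    Interior grid points that exceed both neighbours qualify; results are
    sorted by location. A unimodal density yields its single global peak.
    """
    d = summary.density
    g = summary.grid
    floor = min_rel_height * d.max()
    idx = [
        i
        for i in range(1, len(d) - 1)
        if d[i] > d[i - 1] and d[i] > d[i + 1] and d[i] >= floor
    ]
    if not idx:  # monotone density within the grid: fall back to the global max
        idx = [int(np.argmax(d))]
    return sorted(((float(g[i]), float(d[i])) for i in idx), key=lambda p: p[0])


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_set: int
    n_ref: int

    @property
    def p_reported(self) -> float:
        """p-value floored at 2.2e-16, the convention used in reports."""
        return max(self.p_value, P_FLOOR)


def ks_two_sample(set_values, reference_values) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p).

    The reference is the full background *including* the set's own members,
    mirroring a set-versus-all-genes comparison.
    """
    a = np.asarray(set_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_set=a.size,
        n_ref=b.size,
    )


def read_gene_classes(directory: str | Path) -> dict[str, list[str]]:
    """Load gene-class lists (one id per line, UTF-8); class name = file stem."""
    classes: dict[str, list[str]] = {}
    for path in sorted(Path(directory).glob("*.txt")):
        genes = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
        classes[path.stem] = [g for g in genes if g]
    return classes


def group_summary(
    table: pd.DataFrame,
    classes: dict[str, list[str]],
    min_rel_height: float = 0.25,
) -> pd.DataFrame:
    """Per-class distribution summary against the genome-wide background.

    For each class: matched gene count, median and quartiles of the ratio,
    density peak locations, KS statistic and (floored) p-value versus all
    screened genes, and a direction call (SL if median < 1, RSL if > 1).
    Classes with fewer than 2 matched genes are flagged and not tested.
    """
    if "ratio" not in table.columns:
        raise ValueError("table lacks a 'ratio' column; run compute_ratios first")
    background = table["ratio"].to_numpy()
    by_gene = table.set_index("gene_id")["ratio"]
    rows = []
    for name, genes in classes.items():
        present = [g for g in genes if g in by_gene.index]
        missing = len(genes) - len(present)
        if missing:
            logger.warning("class %s: %d of %d genes absent from the screen", name, missing, len(genes))
        if len(present) < 2:
            logger.warning("class %s has <2 matched genes; flagged, not tested", name)
            rows.append(
                dict(class_name=name, n_present=len(present), n_missing=missing,
                     tested=False, median_ratio=np.nan, q1=np.nan, q3=np.nan,
                     peaks="", ks_D=np.nan, ks_p=np.nan, direction="untested")
            )
            continue
        vals = by_gene.loc[present].to_numpy()
        ks = ks_two_sample(vals, background)
        try:
            dens = estimate_density(vals, min_rel_height=min_rel_height)
            peaks = ";".join(f"{loc:.4f}" for loc, _ in dens.peaks)
        except ValueError:
            peaks = ""
        median = float(np.median(vals))
        direction = "SL" if median < 1 else ("RSL" if median > 1 else "neutral")
        rows.append(
            dict(
                class_name=name,
                n_present=len(present),
                n_missing=missing,
                tested=True,
                median_ratio=median,
                q1=float(np.percentile(vals, 25)),
                q3=float(np.percentile(vals, 75)),
                peaks=peaks,
                ks_D=ks.statistic,
                ks_p=ks.p_reported,
                direction=direction,
            )
        )
    return pd.DataFrame(rows)
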