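"""Seeded generators for the two inputs the pipeline consumes.

``simulate_screen`` emulates a genome-wide isogenic RNAi viability screen:
a large background of genes with log-ratio noise around 0 (ratio 1) plus
named gene classes whose log viability ratios are drawn from planted
Gaussian mixtures — single shifted peaks or bimodal SL/RSL classes.

``simulate_cohort`` emulates a tumour expression cohort of the shape used
for the metagene scan: an anchor gene (CDH1 by default) with a distinct
low-expression tail sitting at a fixed fraction of the cohort median, and
gene-set "pathways" whose shared latent factor is coupled to the anchor's
expression ranks through a Gaussian copula. The copula plants exactly the
kind of tertile-level association the chi-squared scan measures while
making no further distributional assumptions.

All draws come from per-component substreams of one master seed, so the
output is bit-reproducible and adding a pathway never perturbs the draws
of components that already existed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._util import substream
from .expression_prep import ExpressionMatrix, GeneSetCollection
from .screen_analysis import compute_ratios

# --------------------------------------------------------------------------
# RNAi screen
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian component of a group's log-ratio mixture."""

    weight: float
    mean_log_ratio: float
    sd_log_ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError("component weight must be in (0, 1]")
        if self.sd_log_ratio < 0:
            raise ValueError("component sd must be non-negative")


@dataclass(frozen=True)
class ScreenGroup:
    name: str
    n_genes: int
    components: tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"group {self.name!r} needs at least one gene")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group {self.name!r}: component weights sum to {total}, not 1")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for a simulated genome-wide screen."""

    n_background_genes: int
    groups: tuple[ScreenGroup, ...] = ()
    background_sd: float = 0.25
    viability_noise_sd: float = 0.05
    wt_log_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.n_background_genes + sum(g.n_genes for g in self.groups) < 1:
            raise ValueError("simulated screen must contain at least one gene")
        if self.background_sd < 0 or self.viability_noise_sd < 0 or self.wt_log_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


def default_screen_config(seed: int = 0) -> ScreenSimConfig:
    """An 18,120-gene screen with the protein-class effects the analysis targets.

    Planted classes mirror the qualitative picture seen in real isogenic
    CDH1 screens: phosphatases RSL (peak ~1.34), kinases mildly SL (~0.95),
    voltage-gated ion channels RSL (~1.14), and non-sensory GPCRs bimodal
    with SL and RSL peaks near 0.82 and 1.37.
    """
    groups = (
        ScreenGroup("PHOSPHATASE", 224, (MixtureComponent(1.0, np.log(1.34), 0.12),)),
        ScreenGroup("KINASE", 496, (MixtureComponent(1.0, np.log(0.95), 0.12),)),
        ScreenGroup(
            "GPCR_NON_SENSORY",
            245,
            (
                MixtureComponent(0.5, np.log(0.82), 0.08),
                MixtureComponent(0.5, np.log(1.37), 0.08),
            ),
        ),
        ScreenGroup("ION_CHANNEL_VG", 161, (MixtureComponent(1.0, np.log(1.14), 0.12),)),
    )
    n_grouped = sum(g.n_genes for g in groups)
    return ScreenSimConfig(n_background_genes=18_120 - n_grouped, groups=groups, seed=seed)


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate per-gene WT/KO viabilities; returns (screen table, group labels).

    Background log-ratios ~ N(0, background_sd); each group's log-ratio is
    drawn from its mixture. WT viability is log-normal around 1 and
    KO = WT * exp(log_ratio) * multiplicative noise, so with zero noise the
    recomputed KO/WT ratio equals exp(log_ratio) exactly.
    """
    gene_ids: list[str] = []
    labels: list[str] = []
    log_ratios: list[np.ndarray] = []

    rng_bg = substream(config.seed, 0)
    if config.n_background_genes:
        gene_ids += [f"BG{i:05d}" for i in range(config.n_background_genes)]
        labels += ["background"] * config.n_background_genes
        log_ratios.append(rng_bg.normal(0.0, config.background_sd, config.n_background_genes))

    for gi, group in enumerate(config.groups):
        rng = substream(config.seed, 1, gi)
        weights = np.array([c.weight for c in group.components])
        comp = rng.choice(len(group.components), size=group.n_genes, p=weights / weights.sum())
        means = np.array([c.mean_log_ratio for c in group.components])[comp]
        sds = np.array([c.sd_log_ratio for c in group.components])[comp]
        log_ratios.append(means + sds * rng.standard_normal(group.n_genes))
        gene_ids += [f"{group.name}_{j:04d}" for j in range(group.n_genes)]
        labels += [group.name] * group.n_genes

    lr = np.concatenate(log_ratios)
    n = lr.size
    rng_v = substream(config.seed, 2)
    wt = np.exp(rng_v.normal(0.0, config.wt_log_sd, n))
    noise = np.exp(substream(config.seed, 3).normal(0.0, config.viability_noise_sd, n))
    ko = wt * np.exp(lr) * noise
    table = compute_ratios(
        pd.DataFrame({"gene_id": gene_ids, "wt_viability": wt, "ko_viability": ko})
    )
    return table, pd.Series(labels, index=gene_ids, name="group")


# --------------------------------------------------------------------------
# Tumour expression cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwaySpec:
    """One simulated pathway: k member genes sharing a latent factor.

    ``rho`` couples the factor to the anchor gene's expression ranks
    (Gaussian copula); rho = 0 gives a null pathway. ``mode`` selects the
    coupling: "copula" plants a smooth monotone association, while
    "low_low_depletion" plants the synthetic-lethality signature directly —
    samples in the anchor's bottom tertile avoid the factor's bottom
    tertile, with |rho| as the depletion probability.

    The default ``loading_mean`` of 0.5 (against unit gene noise) puts
    ~20% of each member gene's variance on the shared factor — the
    coherence level of typical tumour co-expression modules. It matters
    for the scan's resampling null: a full k-gene pathway then still has
    a leading eigenvalue far above the Marchenko-Pastur noise edge (so
    its metagene recovers the factor), while the 2-5 gene fragments of
    any one module that land in a random resampled set stay below that
    edge and cannot dominate a random draw's leading component.
    """

    name: str
    k: int
    rho: float
    loading_mean: float = 0.5
    loading_sd: float = 0.25
    noise_sd: float = 1.0
    mode: str = "copula"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"pathway {self.name!r}: k must be >= 1")
        if not -1 <= self.rho <= 1:
            raise ValueError(f"pathway {self.name!r}: |rho| must be <= 1")
        if self.loading_sd < 0 or self.noise_sd < 0:
            raise ValueError(f"pathway {self.name!r}: sds must be non-negative")
        if self.mode not in ("copula", "low_low_depletion"):
            raise ValueError(f"pathway {self.name!r}: unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for a simulated tumour expression cohort.

    Defaults mirror a gastric-cancer cohort: 415 tumours, an anchor gene
    with a ~10% low-expression tail whose top sits at 36% of the cohort
    median on the linear scale, and log2 expression values centred near
    typical RNA-seq log-CPM levels.
    """

    n_samples: int = 415
    n_genes: int = 20_502
    anchor_name: str = "CDH1"
    anchor_low_fraction: float = 0.10
    anchor_low_scale: float = 0.36
    anchor_median_log2: float = 5.0
    anchor_main_sd: float = 0.5
    anchor_low_sd: float = 0.4
    pathways: tuple[PathwaySpec, ...] = ()
    n_null_pathways: int = 0
    null_pathway_size: int = 20
    global_factor_sd: float = 0.0
    background_module_size: int = 25
    background_loading_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 9:
            raise ValueError("n_samples must be >= 9 for non-degenerate tertiles")
        if not 0 <= self.anchor_low_fraction < 0.5:
            raise ValueError("anchor_low_fraction must be in [0, 0.5)")
        if not 0 < self.anchor_low_scale < 1:
            raise ValueError("anchor_low_scale must be in (0, 1)")
        if self.global_factor_sd < 0:
            raise ValueError("global_factor_sd must be non-negative")
        if self.background_module_size < 0:
            raise ValueError("background_module_size must be non-negative")
        names = [p.name for p in self.all_pathways()]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        n_pathway_genes = sum(p.k for p in self.all_pathways())
        if n_pathway_genes + 1 > self.n_genes:
            raise ValueError(
                f"pathway genes ({n_pathway_genes}) plus anchor exceed n_genes ({self.n_genes})"
            )

    def all_pathways(self) -> tuple[PathwaySpec, ...]:
        nulls = tuple(
            PathwaySpec(f"NULL{i:03d}", self.null_pathway_size, 0.0)
            for i in range(self.n_null_pathways)
        )
        return self.pathways + nulls


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    planted_pathways: set[str]
    factors: pd.DataFrame  # pathways x samples latent factors
    anchor_expression: pd.Series  # log2 scale


def _simulate_anchor(config: CohortSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-component anchor model on the log2 scale.

    A fraction ``anchor_low_fraction`` of samples forms a low tail whose
    *top* sits at ``anchor_low_scale`` times the cohort median on the
    linear scale — producing the sharp inflexion at the low-tail boundary
    that motivates rank-based thresholds. The tail is a downward
    half-normal below that boundary; the remaining samples are Gaussian
    around the median level (the boundary offset corrects for the small
    median shift the tail itself induces).
    """
    n = config.n_samples
    n_low = int(round(config.anchor_low_fraction * n))
    m = config.anchor_median_log2
    # mixture median solves (1-f)*Phi((x-m)/s) = 0.5 - f
    f = n_low / n
    med_shift = config.anchor_main_sd * norm.ppf((0.5 - f) / (1 - f)) if f > 0 else 0.0
    boundary = m + med_shift + np.log2(config.anchor_low_scale)
    main = m + config.anchor_main_sd * rng.standard_normal(n - n_low)
    low = boundary - np.abs(rng.normal(0.0, config.anchor_low_sd, n_low))
    values = np.concatenate([main, low])
    rng.shuffle(values)
    return values


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection, SimTruth]:
    """Simulate a log-expression cohort with planted anchor-coupled pathways.

    Each planted pathway's latent factor f satisfies
    ``f = rho * g + sqrt(1 - rho^2) * eps`` where g is the Gaussian-copula
    transform (normal scores) of the anchor's expression ranks; member-gene
    expression is ``baseline + loading * f + N(0, noise_sd)`` with loadings
    ~ N(loading_mean, loading_sd). Null pathways use independent factors;
    remaining genes carry independent background-module factors (plus an
    optional cohort-wide global factor) and unit noise.
    """
    n = config.n_samples
    sample_ids = [f"T{j:04d}" for j in range(n)]

    anchor = _simulate_anchor(config, substream(config.seed, 0))
    # Gaussian copula transform of the anchor: normal scores of its ranks.
    g = norm.ppf((rankdata(anchor) - 0.5) / n)

    global_factor = substream(config.seed, 1).standard_normal(n)

    gene_ids: list[str] = [config.anchor_name]
    rows: list[np.ndarray] = [anchor]
    sets: dict[str, tuple[str, ...]] = {}
    factor_rows: dict[str, np.ndarray] = {}

    anchor_ranks = rankdata(anchor)
    for pi, spec in enumerate(config.all_pathways()):
        rng = substream(config.seed, 2, pi)
        eps = rng.standard_normal(n)
        if spec.mode == "low_low_depletion":
            # Independent factor, then push anchor-low samples out of the
            # factor's bottom tertile with probability |rho|: a planted
            # deficit of low-anchor / low-pathway tumours.
            factor = eps.copy()
            q33 = norm.ppf(1.0 / 3.0)
            anchor_low = anchor_ranks <= n / 3.0
            move = anchor_low & (factor < q33) & (rng.random(n) < abs(spec.rho))
            if move.any():  # truncated normal above the tertile boundary
                u = rng.uniform(norm.cdf(q33), 1.0, int(move.sum()))
                factor[move] = norm.ppf(u)
        else:
            factor = spec.rho * g + np.sqrt(1.0 - spec.rho**2) * eps
        loadings = rng.normal(spec.loading_mean, spec.loading_sd, spec.k)
        noise = rng.normal(0.0, spec.noise_sd, (spec.k, n))
        baselines = rng.normal(config.baseline_mean, config.baseline_sd, spec.k)
        members = tuple(f"{spec.name}_G{j:03d}" for j in range(spec.k))
        rows.append(baselines[:, None] + loadings[:, None] * factor[None, :] + noise)
        gene_ids += list(members)
        sets[spec.name] = members
        factor_rows[spec.name] = factor

    n_background = config.n_genes - len(gene_ids)
    if n_background:
        rng = substream(config.seed, 3)
        baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_background)
        expr = (
            baselines[:, None]
            + config.global_factor_sd * global_factor[None, :]
            + rng.standard_normal((n_background, n))
        )
        if config.background_module_size > 0:
            # Background co-expression: genes fall into independent modules
            # (anchor-unrelated latent factors), emulating the pervasive
            # modular correlation structure of real tumour transcriptomes.
            size = config.background_module_size
            n_modules = int(np.ceil(n_background / size))
            module_factors = rng.standard_normal((n_modules, n))
            module_of = np.repeat(np.arange(n_modules), size)[:n_background]
            loadings = rng.normal(0.5, config.background_loading_sd, n_background)
            expr += loadings[:, None] * module_factors[module_of]
        rows.append(expr)
        gene_ids += [f"BGG{i:05d}" for i in range(n_background)]

    values = np.vstack([np.atleast_2d(r) for r in rows])
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), stage="log_expression"
    )
    truth = SimTruth(
        planted_pathways={p.name for p in config.all_pathways() if p.rho != 0},
        factors=pd.DataFrame(factor_rows, index=sample_ids).T,
        anchor_expression=pd.Series(anchor, index=sample_ids, name=config.anchor_name),
    )
    return matrix, GeneSetCollection(sets, provenance="simulate_cohort"), truth


# --------------------------------------------------------------------------
# Config loaders (YAML/dict -> dataclasses)
# --------------------------------------------------------------------------


def screen_config_from_dict(d: dict) -> ScreenSimConfig:
    groups = tuple(
        ScreenGroup(
            name=g["name"],
            n_genes=int(g["n_genes"]),
            components=tuple(
                MixtureComponent(float(c[0]), float(c[1]), float(c[2]))
                for c in g["components"]
            ),
        )
        for g in d.get("groups", [])
    )
    kwargs = {k: v for k, v in d.items() if k != "groups"}
    return ScreenSimConfig(groups=groups, **kwargs)


def cohort_config_from_dict(d: dict) -> CohortSimConfig:
    pathways = tuple(PathwaySpec(**p) for p in d.get("pathways", []))
    kwargs = {k: v for k, v in d.items() if k != "pathways"}
    return CohortSimConfig(pathways=pathways, **kwargs)
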