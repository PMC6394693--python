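"""End-to-end orchestration: simulate / load -> prep -> scan -> screen analytics.

Every run writes a JSON manifest (parameters, seed, library versions,
filter counts per stage) and stamps each TSV output with the manifest hash
so any table can be traced back to the exact run that produced it.
On a stage failure nothing but the manifest (recording the failing stage)
is left behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from ._util import stable_hash
from . import expression_prep as ep
from . import screen_analysis as sa
from . import sl_metagene as mg
from . import synthetic_data as sd

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML- and CLI-mappable)."""

    out_dir: str
    seed: int = 0
    anchor: str = "CDH1"
    n_iter: int = 500_000
    fdr_threshold: float = 0.2
    rsl_threshold: float = 1.3
    sl_threshold: float = 1.0
    min_pathway_size: int = 5
    correction: str = "add_one"
    share_nulls: bool = True
    # inputs: either paths or simulation configs
    matrix_path: str | None = None
    matrix_is_counts: bool = False
    sets_path: str | None = None
    screen_path: str | None = None
    classes_dir: str | None = None
    cohort_sim: sd.CohortSimConfig | None = None
    screen_sim: sd.ScreenSimConfig | None = None
    write_nulls: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not 0 <= self.sl_threshold <= self.rsl_threshold:
            raise ValueError("need 0 <= sl_threshold <= rsl_threshold")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _manifest_skeleton(config: RunConfig) -> dict:
    params = asdict(config)
    for key in ("cohort_sim", "screen_sim"):
        if params[key] is not None:
            params[key] = {k: str(v) for k, v in params[key].items()}
    manifest = {
        "tool": "synlet",
        "versions": {
            "synlet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": params,
        "stages": {},
        "status": "running",
    }
    # the hash identifies the scientific configuration, not the destination
    hashed = {k: v for k, v in params.items() if k != "out_dir"}
    manifest["hash"] = stable_hash({"parameters": hashed, "seed": config.seed})
    return manifest


def write_tsv(df: pd.DataFrame, path: Path, run_hash: str, index: bool = False) -> None:
    """Write a TSV stamped with the run-manifest hash in a comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# synlet run={run_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    Stages (each skipped when its inputs are absent): cohort simulation,
    screen simulation, expression prep, metagene scan, screen analytics.
    Any stage error is recorded in the manifest and re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_skeleton(config)
    run_hash = manifest["hash"]
    stage = "setup"
    try:
        matrix = None
        sets = None
        screen_table = None

        if config.cohort_sim is not None:
            stage = "simulate_cohort"
            matrix, sets, truth = sd.simulate_cohort(config.cohort_sim)
            manifest["stages"][stage] = {
                "n_genes": matrix.n_genes,
                "n_samples": matrix.n_samples,
                "n_pathways": len(sets),
                "n_planted": len(truth.planted_pathways),
            }
        if config.screen_sim is not None:
            stage = "simulate_screen"
            screen_table, labels = sd.simulate_screen(config.screen_sim)
            manifest["stages"][stage] = {
                "n_genes": len(screen_table),
                "groups": sorted(labels.unique()),
            }

        if matrix is None and config.matrix_path:
            stage = "load_matrix"
            if config.matrix_is_counts:
                counts = ep.read_counts(config.matrix_path)
                matrix = ep.normalize_counts(counts)
                manifest["stages"]["normalize"] = {
                    "genes_in": counts.n_genes,
                    "genes_kept": matrix.n_genes,
                }
            else:
                df = pd.read_csv(config.matrix_path, sep="\t", index_col=0, comment="#")
                matrix = ep.ExpressionMatrix(df, stage="log_expression")
        if sets is None and config.sets_path:
            stage = "load_sets"
            universe = None if matrix is None else matrix.gene_ids
            sets = ep.read_gene_sets(
                config.sets_path, min_size=config.min_pathway_size, universe=universe
            )
        if screen_table is None and config.screen_path:
            stage = "load_screen"
            screen_table = sa.compute_ratios(sa.read_screen_table(config.screen_path))

        if matrix is not None and sets is not None:
            stage = "scan"
            scan_cfg = mg.ScanConfig(
                n_iter=config.n_iter,
                seed=config.seed,
                fdr_threshold=config.fdr_threshold,
                correction=config.correction,
                share_nulls=config.share_nulls,
                min_pathway_size=config.min_pathway_size,
            )
            result = mg.run_sl_scan(matrix, sets, config.anchor, scan_cfg)
            write_tsv(result.calls, out / "pathway_calls.tsv", run_hash)
            manifest["stages"]["scan"] = {
                "pathways_in": len(sets),
                "pathways_tested": len(result.calls),
                "significant": int(result.calls["significant"].sum()),
                "n_iter": config.n_iter,
            }
            sig = list(result.significant["pathway"])
            if len(sig) >= 2:
                counts_m, jaccard = mg.pathway_overlap(sets.subset(sig))
                write_tsv(counts_m, out / "overlap_counts.tsv", run_hash, index=True)
                write_tsv(jaccard, out / "overlap_jaccard.tsv", run_hash, index=True)
            profile = ep.anchor_profile(matrix, config.anchor)
            write_tsv(profile.curve, out / "anchor_profile.tsv", run_hash)
            manifest["stages"]["anchor_profile"] = {
                "ratio_at_rank_0.10": profile.ratio_at_rank(0.10)
            }
            if config.write_nulls and config.share_nulls:
                null_df = pd.DataFrame(
                    {f"k={k}": pd.Series(nd.stats) for k, nd in result.nulls.items()}
                )
                write_tsv(null_df, out / "null_distributions.tsv", run_hash)

        if screen_table is not None:
            stage = "screen_analytics"
            labelled = sa.classify_sl_rsl(
                screen_table, config.rsl_threshold, config.sl_threshold
            )
            write_tsv(labelled, out / "screen_labelled.tsv", run_hash)
            counts = labelled["label"].value_counts().to_dict()
            manifest["stages"]["screen_analytics"] = {
                "n_genes": len(labelled),
                "labels": {k: int(v) for k, v in counts.items()},
            }
            classes = None
            if config.classes_dir:
                classes = sa.read_gene_classes(config.classes_dir)
            elif config.screen_sim is not None:
                classes = {
                    g.name: [f"{g.name}_{j:04d}" for j in range(g.n_genes)]
                    for g in config.screen_sim.groups
                }
            if classes:
                summary = sa.group_summary(labelled, classes)
                write_tsv(summary, out / "class_summary.tsv", run_hash)
                manifest["stages"]["screen_analytics"]["classes_tested"] = int(
                    summary["tested"].sum()
                )

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
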