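"""Run manifests and tabular report assembly for the sweep pipeline."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .robustness import (
    ResampleConfig,
    SweepResult,
    category_mean_table,
    effect_size_trend,
    trend_analysis,
)


def write_manifest(out_dir: Path, config: dict, seed: int, extra: dict | None = None):
    """Record everything needed to regenerate a run's outputs byte-identically."""
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "scrrobust": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(out_dir: Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


def write_sweep_reports(sweep: SweepResult, out_dir: Path) -> dict[str, Path]:
    """Write the three report families for one sweep.

    * per-size pairwise tau-b tables (one CSV per size, supplementary-table
      layout: strategy_a, strategy_b, mean_taub, ci_low, ci_high),
    * a trend CSV (pair, r, p, fdr flag) per family,
    * a category effect-size-by-size CSV,
    plus a degenerate-count log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if not sweep.pairwise.empty:
        for size, chunk in sweep.pairwise.groupby("size"):
            p = out_dir / f"pairwise_taub_N{size}.csv"
            chunk.to_csv(p, index=False)
            written[f"pairwise_N{size}"] = p
        p = out_dir / "strategy_mean_taub.csv"
        sweep.strategy_means.to_csv(p, index=False)
        written["strategy_means"] = p
        if sweep.pairwise["size"].nunique() >= 3:
            p = out_dir / "taub_trends.csv"
            trend_analysis(sweep.pairwise).to_csv(p, index=False)
            written["trends"] = p

    p = out_dir / "category_effect_sizes.csv"
    category_mean_table(sweep).to_csv(p, index=False)
    written["category_effect_sizes"] = p
    if len(sweep.config.sizes) >= 3:
        p = out_dir / "effect_size_trends.csv"
        effect_size_trend(sweep).to_csv(p, index=False)
        written["effect_size_trends"] = p

    degenerate = pd.DataFrame(
        [
            {"size": size, "strategy": sid, "degenerate_count": cnt}
            for size, mat in sweep.matrices.items()
            for sid, cnt in mat.degenerate_counts.items()
        ]
    )
    p = out_dir / "degenerate_counts.csv"
    degenerate.to_csv(p, index=False)
    written["degenerate_counts"] = p
    return written


def run_sweep_to_dir(source, config: ResampleConfig, out_dir: Path) -> SweepResult:
    """Execute a sweep and write reports plus a manifest."""
    from .robustness import size_sweep

    sweep = size_sweep(source, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_sweep_reports(sweep, out_dir)
    write_manifest(out_dir, {"resample": config.to_dict()}, config.seed)
    return sweep
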