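"""Bootstrap robustness experiment: resample, allocate, inject, evaluate, rank.

The pipeline at one sample size N is:

1. draw a bootstrap dataset of N rows from the source population
   (phase-wise by default: each phase x stimulus block is resampled
   independently across participants, creating chimeric rows),
2. allocate three equal-but-random groups,
3. optionally inject one of the simulated group-level effect schedules into
   group 3's CS+ (offsets scaled by the bootstrapped sample's own per-trial
   CS+ SDs),
4. evaluate all 15 analytic strategies, keeping each one's group-interaction
   partial eta squared.

Repeating this ``n_resamples`` times yields an effect matrix (resamples x 15
strategies); robustness between two strategies of the same family is the
Kendall tau-b rank correlation of their columns, with a percentile bootstrap
CI from resampling the paired observations.  Trend tests relate robustness
(and mean effect size) to sample size via Pearson correlations with
Benjamini-Hochberg FDR control within each family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import Dataset, ValidationError
from .effects import builtin_schedule, compute_sd_reference, inject
from .strategies import CATEGORIES, builtin_strategies, evaluate_all

DEFAULT_SIZES = (
    30, 60, 120, 180, 240, 360, 480, 600, 720, 840,
    960, 1080, 1200, 1500, 1750, 2000,
)
FDR_Q = 0.1

STRATEGY_IDS = [s.id for s in builtin_strategies()]
CATEGORY_OF = {s.id: s.category for s in builtin_strategies()}


@dataclass
class ResampleConfig:
    """Parameters of one robustness sweep."""

    sizes: tuple[int, ...] = DEFAULT_SIZES
    n_resamples: int = 100
    n_ci_boot: int = 1000
    mode: str = "phase_wise"  # phase_wise | phase_only | full_row
    effect: str = "none"  # none | base | a | b
    n_groups: int = 3
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < self.n_groups for s in self.sizes):
            raise ValidationError("every size must be >= n_groups")
        if self.n_resamples < 2 or self.n_ci_boot < 1:
            raise ValidationError("n_resamples >= 2 and n_ci_boot >= 1 required")
        if self.mode not in ("phase_wise", "phase_only", "full_row"):
            raise ValidationError(f"unknown resampling mode {self.mode!r}")
        if self.effect.lower() not in ("none", "base", "a", "b"):
            raise ValidationError(f"unknown effect variant {self.effect!r}")
        self.effect = self.effect.lower()

    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "n_resamples": self.n_resamples,
            "n_ci_boot": self.n_ci_boot,
            "mode": self.mode,
            "effect": self.effect,
            "n_groups": self.n_groups,
            "ci_level": self.ci_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResampleConfig":
        return cls(
            sizes=tuple(int(s) for s in d["sizes"]),
            n_resamples=int(d["n_resamples"]),
            n_ci_boot=int(d["n_ci_boot"]),
            mode=str(d["mode"]),
            effect=str(d["effect"]),
            n_groups=int(d.get("n_groups", 3)),
            ci_level=float(d.get("ci_level", 0.95)),
            seed=int(d["seed"]),
        )


@dataclass
class EffectMatrix:
    """Per-size matrix of strategy effect sizes over bootstrap resamples."""

    size: int
    values: np.ndarray  # (n_resamples, 15), NaN where degenerate
    degenerate_counts: dict[str, int] = field(default_factory=dict)

    def column(self, strategy_id: str) -> np.ndarray:
        return self.values[:, STRATEGY_IDS.index(strategy_id)]


def bootstrap_dataset(
    source: Dataset, n_rows: int, mode: str, rng: np.random.Generator
) -> Dataset:
    """Resample ``n_rows`` rows with replacement from the source population.

    ``full_row`` keeps whole participants; ``phase_wise`` draws each of the
    six phase x stimulus blocks independently (chimeric rows); ``phase_only``
    keeps CS+ and CS- of a phase together but draws phases independently.
    """
    if source.n == 0:
        raise ValidationError("cannot bootstrap from an empty dataset")
    ids = [f"B{i + 1:05d}" for i in range(n_rows)]
    r = source.responses
    if mode == "full_row":
        pick = rng.integers(0, source.n, n_rows)
        return Dataset(ids, r[pick].copy())
    out = np.empty((n_rows,) + r.shape[1:])
    if mode == "phase_only":
        for p in range(r.shape[1]):
            pick = rng.integers(0, source.n, n_rows)
            out[:, p] = r[pick, p]
    elif mode == "phase_wise":
        for p in range(r.shape[1]):
            for s in range(r.shape[3]):
                pick = rng.integers(0, source.n, n_rows)
                out[:, p, :, s] = r[pick, p, :, s]
    else:
        raise ValidationError(f"unknown resampling mode {mode!r}")
    return Dataset(ids, out)


def allocate_groups(
    n: int, k: int = 3, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Equal-but-random allocation to groups 1..k (sizes differ by <= 1)."""
    if n < k:
        raise ValidationError(f"cannot allocate {n} rows to {k} groups")
    rng = np.random.default_rng() if rng is None else rng
    counts = np.full(k, n // k)
    counts[rng.choice(k, n % k, replace=False)] += 1
    labels = np.repeat(np.arange(1, k + 1), counts)
    rng.shuffle(labels)
    return labels


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b with tie corrections; error on an all-tied vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("tau-b needs two equal-length vectors, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("tau-b undefined for an all-tied vector")
    return float(stats.kendalltau(x, y).statistic)


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail empirical percentile interval with linear interpolation."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValidationError("percentile CI needs >= 2 samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _resample_rng(seed: int, size_index: int, resample_index: int):
    # independent substream per (size, resample) so partial sweeps agree
    return np.random.default_rng([seed, size_index, resample_index])


def strategy_effect_matrix(
    source: Dataset,
    size: int,
    config: ResampleConfig,
    size_index: int = 0,
) -> EffectMatrix:
    """Run the bootstrap-allocate-inject-evaluate pipeline ``n_resamples`` times."""
    schedule = (
        None if config.effect == "none" else builtin_schedule(config.effect)
    )
    values = np.full((config.n_resamples, len(STRATEGY_IDS)), np.nan)
    degenerate = dict.fromkeys(STRATEGY_IDS, 0)
    for rep in range(config.n_resamples):
        rng = _resample_rng(config.seed, size_index, rep)
        boot = bootstrap_dataset(source, size, config.mode, rng)
        boot = boot.with_groups(allocate_groups(size, config.n_groups, rng))
        if schedule is not None:
            sd_ref = compute_sd_reference(boot)  # pre-injection, whole sample
            boot = inject(boot, schedule, sd_ref, target_group=3)
        for j, res in enumerate(evaluate_all(boot)):
            if res.degenerate:
                degenerate[res.strategy] += 1
            else:
                values[rep, j] = res.eta_p2
    return EffectMatrix(size, values, degenerate)


def category_pairs() -> list[tuple[str, str, str]]:
    """(category, strategy_a, strategy_b) for all within-family pairs."""
    out = []
    for cat in CATEGORIES:
        ids = [s for s in STRATEGY_IDS if CATEGORY_OF[s] == cat]
        for a, b in itertools.combinations(ids, 2):
            out.append((cat, a, b))
    return out


def pairwise_robustness(
    matrix: EffectMatrix, config: ResampleConfig
) -> pd.DataFrame:
    """Mean tau-b and bootstrap CI for every within-family strategy pair.

    The CI bootstrap resamples the paired effect-size observations (the
    resample index set) ``n_ci_boot`` times, recomputing tau-b each time.
    Degenerate resamples are pairwise-deleted.
    """
    rng = np.random.default_rng([config.seed, 10_000 + matrix.size])
    rows = []
    for cat, a, b in category_pairs():
        xa = matrix.column(a)
        xb = matrix.column(b)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        xa, xb = xa[ok], xb[ok]
        if len(xa) < 2:
            raise ValidationError(
                f"pair ({a}, {b}) has fewer than 2 usable resamples"
            )
        tau = kendall_tau_b(xa, xb)
        boots = np.empty(config.n_ci_boot)
        n = len(xa)
        for i in range(config.n_ci_boot):
            idx = rng.integers(0, n, n)
            ra, rb = xa[idx], xb[idx]
            if np.all(ra == ra[0]) or np.all(rb == rb[0]):
                boots[i] = np.nan
            else:
                boots[i] = stats.kendalltau(ra, rb).statistic
        usable = boots[~np.isnan(boots)]
        mean_tau = float(np.mean(usable)) if usable.size else tau
        lo, hi = percentile_ci(usable if usable.size >= 2 else np.array([tau, tau]))
        rows.append(
            {
                "size": matrix.size,
                "category": cat,
                "strategy_a": a,
                "strategy_b": b,
                "taub": tau,
                "mean_taub": mean_tau,
                "ci_low": lo,
                "ci_high": hi,
                "n_used": n,
            }
        )
    return pd.DataFrame(rows)


def per_strategy_means(pairwise: pd.DataFrame) -> pd.DataFrame:
    """Mean tau-b of each strategy against the others in its family."""
    rows = []
    for (size, cat), chunk in pairwise.groupby(["size", "category"]):
        ids = sorted(set(chunk["strategy_a"]) | set(chunk["strategy_b"]))
        for sid in ids:
            mask = (chunk["strategy_a"] == sid) | (chunk["strategy_b"] == sid)
            rows.append(
                {
                    "size": size,
                    "category": cat,
                    "strategy": sid,
                    "mean_taub_vs_others": float(chunk.loc[mask, "mean_taub"].mean()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Everything a size sweep produces."""

    config: ResampleConfig
    matrices: dict[int, EffectMatrix]
    pairwise: pd.DataFrame  # per size x pair: mean tau-b + CI
    strategy_means: pd.DataFrame

    def effect_sizes_long(self) -> pd.DataFrame:
        """One row per (size, resample, strategy) with its eta_p2."""
        rows = []
        for size, mat in self.matrices.items():
            for j, sid in enumerate(STRATEGY_IDS):
                col = mat.values[:, j]
                for rep, v in enumerate(col):
                    rows.append(
                        {
                            "size": size,
                            "resample": rep,
                            "strategy": sid,
                            "category": CATEGORY_OF[sid],
                            "eta_p2": v,
                        }
                    )
        return pd.DataFrame(rows)

    def category_means_per_resample(self) -> pd.DataFrame:
        """Category-average eta_p2 per (size, resample)."""
        long = self.effect_sizes_long()
        return (
            long.groupby(["size", "resample", "category"])["eta_p2"]
            .mean()
            .reset_index()
        )


def size_sweep(
    source: Dataset, config: ResampleConfig, compute_pairwise: bool = True
) -> SweepResult:
    """Full experiment: effect matrices and pairwise robustness per size."""
    matrices = {}
    pair_frames = []
    for i, size in enumerate(config.sizes):
        mat = strategy_effect_matrix(source, size, config, size_index=i)
        matrices[size] = mat
        if compute_pairwise:
            pair_frames.append(pairwise_robustness(mat, config))
    pairwise = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame()
    )
    strategy_means = (
        per_strategy_means(pairwise) if compute_pairwise else pd.DataFrame()
    )
    return SweepResult(config, matrices, pairwise, strategy_means)


def trend_analysis(pairwise: pd.DataFrame, q: float = FDR_Q) -> pd.DataFrame:
    """Pearson trend of mean tau-b vs sample size per pair, BH-FDR per family.

    Pairs with a constant tau-b profile have no defined correlation and are
    reported with missing r/p, excluded from the FDR family.
    """
    if pairwise["size"].nunique() < 3:
        raise ValidationError("trend analysis needs >= 3 sample sizes")
    rows = []
    for (cat, a, b), chunk in pairwise.groupby(
        ["category", "strategy_a", "strategy_b"]
    ):
        chunk = chunk.sort_values("size")
        sizes = chunk["size"].to_numpy(dtype=float)
        taus = chunk["mean_taub"].to_numpy(dtype=float)
        if np.all(taus == taus[0]):
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(sizes, taus)
        rows.append(
            {
                "category": cat,
                "strategy_a": a,
                "strategy_b": b,
                "r": r,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_significant"] = False
    for cat in out["category"].unique():
        mask = (out["category"] == cat) & out["p"].notna()
        if mask.any():
            flags = multipletests(out.loc[mask, "p"], alpha=q, method="fdr_bh")[0]
            out.loc[mask, "fdr_significant"] = flags
    return out


def effect_size_trend(
    sweep: SweepResult, aggregate: str = "resample"
) -> pd.DataFrame:
    """Pearson trend of category-average effect size vs sample size.

    ``aggregate='resample'`` (default) correlates one category-average eta_p2
    per bootstrapped dataset against its sample size — each resampled dataset
    is one observation, mirroring how the per-size spreads are produced.
    ``aggregate='size_mean'`` first averages over resamples, leaving one point
    per size.
    """
    if len(sweep.config.sizes) < 3:
        raise ValidationError("trend analysis needs >= 3 sample sizes")
    per_resample = sweep.category_means_per_resample()
    rows = []
    for cat, chunk in per_resample.groupby("category"):
        chunk = chunk.dropna(subset=["eta_p2"])
        if aggregate == "size_mean":
            chunk = chunk.groupby("size")["eta_p2"].mean().reset_index()
        x = chunk["size"].to_numpy(dtype=float)
        y = chunk["eta_p2"].to_numpy(dtype=float)
        if np.all(y == y[0]):
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"category": cat, "r": r, "p": p, "n_points": len(x)})
    return pd.DataFrame(rows)


def category_mean_table(sweep: SweepResult) -> pd.DataFrame:
    """Per-size category mean eta_p2 with a 95% CI over resamples."""
    per_resample = sweep.category_means_per_resample()
    rows = []
    for (size, cat), chunk in per_resample.groupby(["size", "category"]):
        vals = chunk["eta_p2"].dropna().to_numpy()
        lo, hi = percentile_ci(vals) if vals.size >= 2 else (np.nan, np.nan)
        rows.append(
            {
                "size": size,
                "category": cat,
                "mean_eta_p2": float(vals.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "n_resamples": vals.size,
            }
        )
    return pd.DataFrame(rows)
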