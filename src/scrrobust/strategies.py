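"""The catalogue of 15 published analytic strategies for extinction SCR data.

Each strategy is a declarative recipe — which trials to keep, how to
aggregate them, whether to analyse CS+/CS- separately or their difference —
ending in a mixed ANOVA whose highest-order Group interaction is summarised
as partial eta squared.  Strategies fall into three families:

* ``ACQ_EXT`` (4) — change from acquisition to extinction,
* ``EXT``     (7) — a static index of extinction,
* ``EXT_EXT`` (4) — change across the extinction phase (early vs late).

Trial windows quoted as fractions of a phase ("last half", "first quarter")
are resolved on this protocol's 5 acquisition + 10 extinction trials with
half-up rounding; the constants live at module level so the rounding policy
is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import (
    AnovaTable,
    DegenerateVarianceError,
    DesignSpec,
    group_contrast_eta,
    mixed_anova_cells,
    one_way_eta,
)
from .data import Dataset, ValidationError

N_ACQ_TRIALS = 5
N_EXT_TRIALS = 10  # early + late concatenated in order

# fraction-of-phase windows resolve by round-half-up on this layout
ACQ_LAST_HALF = (3, 4, 5)  # ceil(5/2) = 3 trials
EXT_FIRST_HALF = (1, 2, 3, 4, 5)
EXT_LAST_HALF = (6, 7, 8, 9, 10)
EXT_LAST_THREE_QUARTERS = (3, 4, 5, 6, 7, 8, 9, 10)  # round(7.5) -> 8 trials
EXT_FIRST_QUARTER = (1, 2, 3)  # round(2.5) -> 3 trials
EXT_LAST_QUARTER = (8, 9, 10)

CATEGORIES = ("ACQ_EXT", "EXT", "EXT_EXT")


@dataclass(frozen=True)
class TrialSelection:
    """A trial window within one phase: named rule plus resolved trials."""

    rule: str  # ALL, LAST_K, FIRST_K, LAST_FRACTION, FIRST_FRACTION,
    #            MAX_RESPONSE, SINGLE_LAST
    trials: tuple[int, ...]  # resolved 1-based trial numbers in the phase

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValidationError("empty trial selection")


@dataclass(frozen=True)
class StrategySpec:
    """One analytic strategy: selection, aggregation, stimuli, model term."""

    category: str
    index: int
    aggregation: str  # MEAN, TRIAL_BY_TRIAL, RUNNING_AVERAGE, SINGLE_TRIAL
    stimulus_handling: str  # DIFFERENTIAL, BOTH, CSP_ONLY
    model_term: str  # highest-order Group term reported as eta_p2
    description: str
    acq_selection: TrialSelection | None = None
    ext_selection: TrialSelection | None = None
    ext_selection_late: TrialSelection | None = None  # second window (EXT_EXT)

    @property
    def id(self) -> str:
        return f"{self.category}.{self.index}"


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    eta_p2: float | None
    n_subjects: int
    degenerate: bool = False


def _sel(rule: str, trials) -> TrialSelection:
    return TrialSelection(rule, tuple(trials))


def builtin_strategies() -> list[StrategySpec]:
    """The 15 catalogued strategies, in family order."""
    acq_all = _sel("ALL", range(1, 6))
    specs = [
        StrategySpec(
            "ACQ_EXT", 1, "MEAN", "DIFFERENTIAL", "Phase×Group",
            "mean differential, all ACQ vs last 2 EXT trials",
            acq_selection=acq_all, ext_selection=_sel("LAST_K", (9, 10)),
        ),
        StrategySpec(
            "ACQ_EXT", 2, "MEAN", "DIFFERENTIAL", "Phase×Group",
            "max differential ACQ response vs mean of last 2 EXT trials",
            acq_selection=_sel("MAX_RESPONSE", range(1, 6)),
            ext_selection=_sel("LAST_K", (9, 10)),
        ),
        StrategySpec(
            "ACQ_EXT", 3, "MEAN", "DIFFERENTIAL", "Phase×Group",
            "mean differential, all ACQ vs last 3 EXT trials",
            acq_selection=acq_all, ext_selection=_sel("LAST_K", (8, 9, 10)),
        ),
        StrategySpec(
            "ACQ_EXT", 4, "MEAN", "DIFFERENTIAL", "Group",
            "paired contrast: last half of ACQ vs first half of EXT, "
            "Group one-way on the contrast scores",
            acq_selection=_sel("LAST_FRACTION", ACQ_LAST_HALF),
            ext_selection=_sel("FIRST_FRACTION", EXT_FIRST_HALF),
        ),
        StrategySpec(
            "EXT", 1, "MEAN", "BOTH", "Group×Stim",
            "mean CS+/CS- over last three-quarters of EXT",
            ext_selection=_sel("LAST_FRACTION", EXT_LAST_THREE_QUARTERS),
        ),
        StrategySpec(
            "EXT", 2, "TRIAL_BY_TRIAL", "BOTH", "Trial×Group×Stim",
            "first 5 EXT trials, trial-by-trial, CS+/CS-",
            ext_selection=_sel("FIRST_K", range(1, 6)),
        ),
        StrategySpec(
            "EXT", 3, "MEAN", "BOTH", "Group×Stim",
            "mean CS+/CS- over last half of EXT",
            ext_selection=_sel("LAST_FRACTION", EXT_LAST_HALF),
        ),
        StrategySpec(
            "EXT", 4, "SINGLE_TRIAL", "DIFFERENTIAL", "Group",
            "differential response on the last EXT trial",
            ext_selection=_sel("SINGLE_LAST", (10,)),
        ),
        StrategySpec(
            "EXT", 5, "MEAN", "BOTH", "Group×Stim",
            "mean CS+/CS- over last 2 EXT trials",
            ext_selection=_sel("LAST_K", (9, 10)),
        ),
        StrategySpec(
            "EXT", 6, "RUNNING_AVERAGE", "DIFFERENTIAL", "Trial×Group",
            "running average of first 5 EXT differential trials "
            "(4 pseudo-trials)",
            ext_selection=_sel("FIRST_K", range(1, 6)),
        ),
        StrategySpec(
            "EXT", 7, "TRIAL_BY_TRIAL", "DIFFERENTIAL", "Trial×Group",
            "first 2 EXT trials, trial-by-trial differential",
            ext_selection=_sel("FIRST_K", (1, 2)),
        ),
        StrategySpec(
            "EXT_EXT", 1, "MEAN", "BOTH", "Phase×Group×Stim",
            "mean CS+/CS- per extinction half",
            ext_selection=_sel("FIRST_FRACTION", EXT_FIRST_HALF),
            ext_selection_late=_sel("LAST_FRACTION", EXT_LAST_HALF),
        ),
        StrategySpec(
            "EXT_EXT", 2, "MEAN", "DIFFERENTIAL", "Phase×Group",
            "mean differential per extinction half",
            ext_selection=_sel("FIRST_FRACTION", EXT_FIRST_HALF),
            ext_selection_late=_sel("LAST_FRACTION", EXT_LAST_HALF),
        ),
        StrategySpec(
            "EXT_EXT", 3, "MEAN", "CSP_ONLY", "Phase×Group",
            "mean CS+ over first vs last quarter of EXT",
            ext_selection=_sel("FIRST_FRACTION", EXT_FIRST_QUARTER),
            ext_selection_late=_sel("LAST_FRACTION", EXT_LAST_QUARTER),
        ),
        StrategySpec(
            "EXT_EXT", 4, "MEAN", "CSP_ONLY", "Phase×Group",
            "mean CS+ per extinction half",
            ext_selection=_sel("FIRST_FRACTION", EXT_FIRST_HALF),
            ext_selection_late=_sel("LAST_FRACTION", EXT_LAST_HALF),
        ),
    ]
    assert [s.category for s in specs].count("ACQ_EXT") == 4
    assert [s.category for s in specs].count("EXT") == 7
    assert [s.category for s in specs].count("EXT_EXT") == 4
    return specs


def catalogue_frame() -> pd.DataFrame:
    """Catalogue dump (id, category, selection, aggregation, stimuli, term)."""
    rows = []
    for s in builtin_strategies():
        rows.append(
            {
                "id": s.id,
                "category": s.category,
                "acq_trials": s.acq_selection.trials if s.acq_selection else None,
                "ext_trials": s.ext_selection.trials if s.ext_selection else None,
                "ext_trials_late": (
                    s.ext_selection_late.trials if s.ext_selection_late else None
                ),
                "aggregation": s.aggregation,
                "stimulus_handling": s.stimulus_handling,
                "model_term": s.model_term,
                "description": s.description,
            }
        )
    return pd.DataFrame(rows)


def _ext_responses(dataset: Dataset) -> np.ndarray:
    """(n, 10, 2) extinction responses, early then late in trial order."""
    r = dataset.responses
    return np.concatenate([r[:, 1], r[:, 2]], axis=1)


def _check_ext_trials(trials) -> np.ndarray:
    idx = np.asarray(trials, dtype=int)
    if idx.min() < 1 or idx.max() > N_EXT_TRIALS:
        raise ValidationError(f"extinction trials {trials} outside 1..10")
    return idx - 1


def _design_matrix(dataset: Dataset, spec: StrategySpec):
    """Per-subject value matrix and design for one strategy.

    Returns (y, design, columns) where ``y`` is (n_subjects, n_cells),
    ``design`` the within-factor structure, and ``columns`` a list of dicts
    naming each cell's within levels (for the long-table view).
    """
    ext = _ext_responses(dataset)  # (n, 10, 2)
    ext_diff = ext[:, :, 0] - ext[:, :, 1]
    acq = dataset.responses[:, 0]  # (n, 5, 2)
    acq_diff = acq[:, :, 0] - acq[:, :, 1]

    cat = spec.category
    if cat == "ACQ_EXT":
        e = _check_ext_trials(spec.ext_selection.trials)
        ext_val = ext_diff[:, e].mean(axis=1)
        a = np.asarray(spec.acq_selection.trials, dtype=int) - 1
        if spec.acq_selection.rule == "MAX_RESPONSE":
            acq_val = acq_diff[:, a].max(axis=1)
        else:
            acq_val = acq_diff[:, a].mean(axis=1)
        y = np.column_stack([acq_val, ext_val])
        design = DesignSpec(within=(("Phase", 2),))
        columns = [{"Phase": "ACQ"}, {"Phase": "EXT"}]
        return y, design, columns

    if cat == "EXT":
        e = _check_ext_trials(spec.ext_selection.trials)
        if spec.aggregation == "MEAN" and spec.stimulus_handling == "BOTH":
            y = ext[:, e].mean(axis=1)  # (n, 2)
            design = DesignSpec(within=(("Stim", 2),))
            columns = [{"Stim": "CSP"}, {"Stim": "CSM"}]
        elif spec.aggregation == "TRIAL_BY_TRIAL" and spec.stimulus_handling == "BOTH":
            y = ext[:, e].reshape(len(ext), -1)  # trial-major, stim fastest
            design = DesignSpec(within=(("Trial", len(e)), ("Stim", 2)))
            columns = [
                {"Trial": int(t), "Stim": s}
                for t in spec.ext_selection.trials
                for s in ("CSP", "CSM")
            ]
        elif spec.aggregation == "SINGLE_TRIAL":
            y = ext_diff[:, e].reshape(len(ext), 1)
            design = DesignSpec(within=())
            columns = [{}]
        elif spec.aggregation == "RUNNING_AVERAGE":
            d = ext_diff[:, e]
            y = (d[:, :-1] + d[:, 1:]) / 2.0  # (n, len(e)-1) pseudo-trials
            design = DesignSpec(within=(("Trial", y.shape[1]),))
            columns = [{"Trial": k + 1} for k in range(y.shape[1])]
        elif spec.aggregation == "TRIAL_BY_TRIAL":
            y = ext_diff[:, e]
            design = DesignSpec(within=(("Trial", len(e)),))
            columns = [{"Trial": int(t)} for t in spec.ext_selection.trials]
        else:
            raise ValidationError(f"unsupported EXT spec {spec.id}")
        return y, design, columns

    if cat == "EXT_EXT":
        e1 = _check_ext_trials(spec.ext_selection.trials)
        e2 = _check_ext_trials(spec.ext_selection_late.trials)
        if spec.stimulus_handling == "BOTH":
            y = np.column_stack(
                [
                    ext[:, e1, 0].mean(axis=1),
                    ext[:, e1, 1].mean(axis=1),
                    ext[:, e2, 0].mean(axis=1),
                    ext[:, e2, 1].mean(axis=1),
                ]
            )
            design = DesignSpec(within=(("Phase", 2), ("Stim", 2)))
            columns = [
                {"Phase": p, "Stim": s}
                for p in ("EARLY", "LATE")
                for s in ("CSP", "CSM")
            ]
        elif spec.stimulus_handling == "DIFFERENTIAL":
            y = np.column_stack(
                [ext_diff[:, e1].mean(axis=1), ext_diff[:, e2].mean(axis=1)]
            )
            design = DesignSpec(within=(("Phase", 2),))
            columns = [{"Phase": "EARLY"}, {"Phase": "LATE"}]
        else:  # CSP_ONLY
            y = np.column_stack(
                [ext[:, e1, 0].mean(axis=1), ext[:, e2, 0].mean(axis=1)]
            )
            design = DesignSpec(within=(("Phase", 2),))
            columns = [{"Phase": "EARLY"}, {"Phase": "LATE"}]
        return y, design, columns

    raise ValidationError(f"unknown strategy category {cat!r}")


def select_trials(dataset: Dataset, spec: StrategySpec) -> pd.DataFrame:
    """Long analysis table for one strategy: subject, group, within levels, value."""
    y, _, columns = _design_matrix(dataset, spec)
    rows = []
    groups = dataset.groups
    for i, sid in enumerate(dataset.ids):
        for c, meta in enumerate(columns):
            rec = {"subject": sid}
            if groups is not None:
                rec["group"] = int(groups[i])
            rec.update(meta)
            rec["value"] = y[i, c]
            rows.append(rec)
    return pd.DataFrame(rows)


def evaluate_strategy(dataset: Dataset, spec: StrategySpec) -> StrategyResult:
    """Partial eta squared of the strategy's highest-order Group term."""
    if dataset.groups is None:
        raise ValidationError("strategy evaluation requires group labels")
    y, design, _ = _design_matrix(dataset, spec)
    try:
        if spec.category == "ACQ_EXT" and spec.index == 4:
            eta = group_contrast_eta(y[:, 0] - y[:, 1], dataset.groups)
        elif not design.within:
            eta = one_way_eta(y[:, 0], dataset.groups)
        else:
            table = mixed_anova_cells(y, dataset.groups, design)
            eta = table.eta_p2(spec.model_term)
    except DegenerateVarianceError:
        return StrategyResult(spec.id, None, dataset.n, degenerate=True)
    return StrategyResult(spec.id, float(eta), dataset.n)


def evaluate_all(dataset: Dataset) -> list[StrategyResult]:
    """All 15 strategies on one labelled dataset, in catalogue order."""
    return [evaluate_strategy(dataset, s) for s in builtin_strategies()]
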