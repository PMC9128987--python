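"""Trial-level skin-conductance-response (SCR) containers and long-format CSV I/O.

The unit of analysis is one participant's complete response grid from a
differential fear-conditioning protocol: 5 acquisition trials followed by
10 extinction trials (split into early and late blocks of 5), with a CS+
(reinforced) and CS- (safety) response on every trial.  Responses are phasic
SCR amplitudes in micro-Siemens and are non-negative by construction.

The interchange format is a long CSV with one row per (participant, phase,
trial, stimulus) cell; see :func:`read_long_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES: tuple[str, ...] = ("ACQ", "EXT_EARLY", "EXT_LATE")
STIMULI: tuple[str, ...] = ("CSP", "CSM")
N_TRIALS = 5
N_CELLS = len(PHASES) * N_TRIALS * len(STIMULI)  # 30

PHASE_INDEX = {p: i for i, p in enumerate(PHASES)}
STIM_INDEX = {s: i for i, s in enumerate(STIMULI)}

CSV_COLUMNS = ["participant", "group", "phase", "trial", "stimulus", "response"]


class ValidationError(ValueError):
    """Structured validation failure naming the offending cell or row."""


@dataclass(frozen=True)
class TrialGrid:
    """One participant's 3-phase x 5-trial x 2-stimulus response grid (uS)."""

    responses: np.ndarray  # shape (3, 5, 2), float

    def __post_init__(self) -> None:
        arr = np.asarray(self.responses, dtype=float)
        if arr.shape != (len(PHASES), N_TRIALS, len(STIMULI)):
            raise ValidationError(
                f"TrialGrid needs shape (3, 5, 2), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("TrialGrid contains non-finite responses")
        if np.any(arr < 0):
            raise ValidationError("TrialGrid contains negative responses")
        object.__setattr__(self, "responses", arr)

    def value(self, phase: str, trial: int, stimulus: str) -> float:
        return float(self.responses[PHASE_INDEX[phase], trial - 1, STIM_INDEX[stimulus]])


@dataclass(frozen=True)
class DifferentialGrid:
    """Per-(phase, trial) CS+ minus CS- differences (uS); may be negative."""

    diffs: np.ndarray  # shape (3, 5)

    def value(self, phase: str, trial: int) -> float:
        return float(self.diffs[PHASE_INDEX[phase], trial - 1])


def differential(grid: TrialGrid) -> DifferentialGrid:
    """CS+ minus CS- for each of the 15 (phase, trial) cells."""
    return DifferentialGrid(grid.responses[:, :, 0] - grid.responses[:, :, 1])


@dataclass
class Dataset:
    """An ordered collection of participant grids with optional group labels.

    Internally the grids are stacked into one ``(n, 3, 5, 2)`` array so that
    resampling and strategy evaluation are plain numpy operations.  ``groups``
    is either ``None`` (unlabelled) or an integer array with labels drawn from
    ``{1, 2, 3}``.
    """

    ids: list[str]
    responses: np.ndarray  # (n, 3, 5, 2)
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        n = len(self.ids)
        if self.responses.shape != (n, len(PHASES), N_TRIALS, len(STIMULI)):
            raise ValidationError(
                f"responses shape {self.responses.shape} does not match "
                f"{n} participants"
            )
        if len(set(self.ids)) != n:
            raise ValidationError("participant ids are not unique")
        if not np.all(np.isfinite(self.responses)):
            raise ValidationError("dataset contains non-finite responses")
        if np.any(self.responses < 0):
            bad = int(np.argwhere(np.min(self.responses, axis=(1, 2, 3)) < 0)[0][0])
            raise ValidationError(
                f"negative response for participant {self.ids[bad]!r}"
            )
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=int)
            if self.groups.shape != (n,):
                raise ValidationError("group labels do not cover every participant")
            allowed = set(np.unique(self.groups).tolist())
            if not allowed <= {1, 2, 3}:
                raise ValidationError(f"group labels {sorted(allowed)} not in {{1,2,3}}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def grid(self, i: int) -> TrialGrid:
        return TrialGrid(self.responses[i])

    def with_groups(self, groups: np.ndarray) -> "Dataset":
        return Dataset(list(self.ids), self.responses.copy(), np.asarray(groups))

    def differentials(self) -> np.ndarray:
        """(n, 3, 5) array of CS+ minus CS- per participant and cell."""
        return self.responses[:, :, :, 0] - self.responses[:, :, :, 1]

    def equals(self, other: "Dataset") -> bool:
        if self.ids != other.ids:
            return False
        if not np.array_equal(self.responses, other.responses):
            return False
        if (self.groups is None) != (other.groups is None):
            return False
        if self.groups is not None and not np.array_equal(self.groups, other.groups):
            return False
        return True


def from_frame(df: pd.DataFrame) -> Dataset:
    """Build a validated Dataset from a long-format DataFrame.

    Expects columns participant, phase, trial, stimulus, response and an
    optional group column; one row per cell, 30 cells per participant.
    """
    required = {"participant", "phase", "trial", "stimulus", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")

    bad_phase = set(df["phase"].unique()) - set(PHASES)
    if bad_phase:
        raise ValidationError(f"unknown phase labels: {sorted(bad_phase)}")
    bad_stim = set(df["stimulus"].unique()) - set(STIMULI)
    if bad_stim:
        raise ValidationError(f"unknown stimulus labels: {sorted(bad_stim)}")
    trials = df["trial"].astype(int)
    if ((trials < 1) | (trials > N_TRIALS)).any():
        raise ValidationError("trial numbers must be in 1..5 within each phase")

    dup = df.duplicated(subset=["participant", "phase", "trial", "stimulus"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate cell for participant "
            f"{row['participant']!r} ({row['phase']}, trial {row['trial']}, "
            f"{row['stimulus']})"
        )

    ids = list(dict.fromkeys(df["participant"].astype(str)))
    n = len(ids)
    idx = {p: i for i, p in enumerate(ids)}

    responses = np.full((n, len(PHASES), N_TRIALS, len(STIMULI)), np.nan)
    pi = df["phase"].map(PHASE_INDEX).to_numpy()
    si = df["stimulus"].map(STIM_INDEX).to_numpy()
    ri = df["participant"].astype(str).map(idx).to_numpy()
    responses[ri, pi, trials.to_numpy() - 1, si] = df["response"].to_numpy(dtype=float)

    if np.isnan(responses).any():
        i, p, t, s = (int(x[0]) for x in np.nonzero(np.isnan(responses)))
        raise ValidationError(
            f"participant {ids[i]!r} is missing cell "
            f"({PHASES[p]}, trial {t + 1}, {STIMULI[s]})"
        )
    if (responses < 0).any():
        i = int(np.argwhere(np.min(responses, axis=(1, 2, 3)) < 0)[0][0])
        raise ValidationError(f"negative response for participant {ids[i]!r}")

    groups = None
    if "group" in df.columns and df["group"].notna().all():
        g = np.full(n, -1, dtype=int)
        g[ri] = df["group"].astype(int).to_numpy()
        # reject inconsistent per-participant labels
        per = df.groupby("participant")["group"].nunique()
        if (per > 1).any():
            raise ValidationError(
                f"participant {per[per > 1].index[0]!r} has conflicting group labels"
            )
        groups = g
    return Dataset(ids, responses, groups)


def to_frame(dataset: Dataset) -> pd.DataFrame:
    """Long-format DataFrame, one row per cell, participant order preserved."""
    n = dataset.n
    recs = {
        "participant": np.repeat(dataset.ids, N_CELLS),
        "phase": np.tile(np.repeat(PHASES, N_TRIALS * len(STIMULI)), n),
        "trial": np.tile(np.repeat(np.arange(1, N_TRIALS + 1), len(STIMULI)),
                         n * len(PHASES)),
        "stimulus": np.tile(STIMULI, n * len(PHASES) * N_TRIALS),
        "response": dataset.responses.reshape(-1),
    }
    df = pd.DataFrame(recs)
    if dataset.groups is not None:
        df.insert(1, "group", np.repeat(dataset.groups, N_CELLS))
    return df


def read_long_csv(path) -> Dataset:
    """Read and validate a long-format SCR CSV into a Dataset."""
    df = pd.read_csv(path, float_precision="round_trip")
    return from_frame(df)


def write_long_csv(dataset: Dataset, path) -> None:
    """Write a Dataset as a long CSV readable by :func:`read_long_csv`."""
    # %.17g round-trips IEEE doubles exactly, keeping read(write(d)) == d
    to_frame(dataset).to_csv(path, index=False, float_format="%.17g")
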