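"""Simulated group-level effects: trial-wise SD-unit offsets on one group's CS+.

Three built-in schedules describe distinct conditioning/extinction phenotypes
for the target group (canonically group 3):

* ``BASE`` — high differential acquisition with rapid extinction,
* ``A``    — moderate differential acquisition with rapid extinction,
* ``B``    — differential responding that does not extinguish early.

An offset of ``o`` at (phase, trial) adds ``o * sd(phase, trial)`` to every
target-group participant's CS+ response in that cell, where ``sd`` is the
per-trial SD of CS+ responses across the (pre-injection) dataset.  CS- and
the other groups are never touched, so injections create pure group x
stimulus x trial structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, N_TRIALS, PHASES, ValidationError

_SCHEDULES = {
    "BASE": np.array(
        [
            [1.0, 0.8, 0.6, 0.4, 0.0],  # acquisition
            [2.0, 1.5, 1.0, 0.8, 0.5],  # early extinction
            [1.0, 0.8, 0.5, 0.2, 0.0],  # late extinction
        ]
    ),
    "A": np.array(
        [
            [0.0, 0.3, 0.3, 0.3, 0.3],
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [1.5, 1.0, 0.5, 0.1, 0.0],
        ]
    ),
    "B": np.array(
        [
            [0.0, 0.0, 0.3, 0.3, 0.3],
            [2.0, 1.5, 1.0, 0.5, 0.3],
            [1.5, 1.0, 0.5, 0.1, 0.0],
        ]
    ),
}


@dataclass(frozen=True)
class EffectSchedule:
    """Per-(phase, trial) CS+ offsets in SD units for the target group."""

    variant: str
    offsets: np.ndarray  # (3, 5)

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets, dtype=float)
        if arr.shape != (len(PHASES), N_TRIALS):
            raise ValidationError("offsets must have shape (3, 5)")
        object.__setattr__(self, "offsets", arr)

    def to_dict(self) -> dict:
        return {"variant": self.variant, "offsets": self.offsets.tolist()}


@dataclass(frozen=True)
class SdReference:
    """Per-(phase, trial) SD of CS+ responses used to scale offsets (uS)."""

    sd: np.ndarray  # (3, 5)

    def __post_init__(self) -> None:
        arr = np.asarray(self.sd, dtype=float)
        if arr.shape != (len(PHASES), N_TRIALS):
            raise ValidationError("sd must have shape (3, 5)")
        if np.any(arr < 0):
            raise ValidationError("sd values must be >= 0")
        object.__setattr__(self, "sd", arr)


def builtin_schedule(variant: str, stacked: bool = False) -> EffectSchedule:
    """One of the three built-in effect schedules.

    ``stacked=True`` returns the variant's offsets added on top of the BASE
    schedule, for reading the phenotypes as increments over the first rather
    than standalone profiles (the standalone reading is the default).
    """
    key = variant.upper()
    if key not in _SCHEDULES:
        raise ValidationError(f"unknown effect variant {variant!r}")
    offsets = _SCHEDULES[key]
    if stacked and key != "BASE":
        offsets = offsets + _SCHEDULES["BASE"]
    return EffectSchedule(key, offsets.copy())


def compute_sd_reference(dataset: Dataset, group: int | None = None) -> SdReference:
    """Per-(phase, trial) SD (n-1) of CS+ responses across participants.

    By default the SD is taken over all rows of the (pre-injection) dataset;
    pass ``group`` to restrict the reference population to one group.
    """
    csp = dataset.responses[:, :, :, 0]
    if group is not None:
        if dataset.groups is None:
            raise ValidationError("dataset has no group labels")
        csp = csp[dataset.groups == group]
    if csp.shape[0] < 2:
        raise ValidationError("SD reference requires at least 2 participants")
    return SdReference(csp.std(axis=0, ddof=1))


def inject(
    dataset: Dataset,
    schedule: EffectSchedule,
    sd_ref: SdReference,
    target_group: int = 3,
) -> Dataset:
    """Add ``offsets * sd`` to the target group's CS+ responses, cell-wise.

    Returns a new Dataset; row order, ids, CS- responses and non-target
    groups are preserved exactly.
    """
    if dataset.groups is None:
        raise ValidationError("injection requires a group-labelled dataset")
    mask = dataset.groups == target_group
    if not mask.any():
        raise ValidationError(f"target group {target_group} absent from dataset")
    responses = dataset.responses.copy()
    # purely additive; no re-flooring at zero (built-in offsets are >= 0 and
    # act on CS+ only, so non-negativity is preserved automatically)
    responses[mask, :, :, 0] += schedule.offsets * sd_ref.sd
    return Dataset(list(dataset.ids), responses, dataset.groups.copy())
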