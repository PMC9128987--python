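"""Synthetic null populations of fear-conditioning SCR data.

The generator emulates the statistical structure of a pooled differential
fear-conditioning sample: differential acquisition (CS+ above CS-), CS+
responding decaying back to the CS- level across the ten extinction trials,
a participant-level random intercept inducing within-subject correlation,
cell-level noise, and a floor at zero reproducing the zero-inflation of
scored SCRs.  No group structure is generated here: group labels are
allocated downstream and group-level effects are injected by
:mod:`scrrobust.effects`.

Model per participant i and cell (phase p, trial t, stimulus s):

    response = max(0, a_i + mu(p, t, s) + e_{i,p,t,s})

with a_i ~ N(0, sigma_subject^2) and e ~ N(0, sigma_noise^2) i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, N_TRIALS, PHASES, STIMULI, ValidationError

DEFAULT_N_PARTICIPANTS = 379  # size of the pooled sample the generator stands in for
DEFAULT_SIGMA_SUBJECT = 0.2  # uS, SD of the participant random intercept
DEFAULT_SIGMA_NOISE = 0.25  # uS, SD of cell-level noise
CSM_LEVEL = 0.3  # uS, flat CS- orienting-response level


def default_mu_profile() -> np.ndarray:
    """Default mean-response surface, shape (3 phases, 5 trials, 2 stimuli), uS.

    CS- is flat at ``CSM_LEVEL``.  CS+ rises to ~0.8 uS over acquisition
    (differential conditioning on every trial) and decays monotonically across
    the ten extinction trials back to the CS- level.
    """
    mu = np.empty((len(PHASES), N_TRIALS, len(STIMULI)))
    mu[:, :, 1] = CSM_LEVEL
    mu[0, :, 0] = [0.55, 0.65, 0.75, 0.80, 0.80]  # acquisition CS+
    mu[1, :, 0] = [0.80, 0.70, 0.60, 0.50, 0.45]  # early extinction CS+
    mu[2, :, 0] = [0.42, 0.39, 0.36, 0.33, 0.30]  # late extinction CS+
    return mu


@dataclass
class GeneratorConfig:
    """Parameters of the null SCR population generator."""

    n_participants: int = DEFAULT_N_PARTICIPANTS
    mu: np.ndarray = field(default_factory=default_mu_profile)
    sigma_subject: float = DEFAULT_SIGMA_SUBJECT
    sigma_noise: float = DEFAULT_SIGMA_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.sigma_subject < 0 or self.sigma_noise < 0:
            raise ValidationError("sigma values must be >= 0")
        if self.mu.shape != (len(PHASES), N_TRIALS, len(STIMULI)):
            raise ValidationError("mu must have shape (3, 5, 2)")
        if np.any(self.mu < 0) or not np.all(np.isfinite(self.mu)):
            raise ValidationError("mu values must be finite and >= 0")

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "mu": self.mu.tolist(),
            "sigma_subject": self.sigma_subject,
            "sigma_noise": self.sigma_noise,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_participants=int(d["n_participants"]),
            mu=np.asarray(d["mu"], dtype=float),
            sigma_subject=float(d["sigma_subject"]),
            sigma_noise=float(d["sigma_noise"]),
            seed=int(d["seed"]),
        )


def generate_null_population(config: GeneratorConfig) -> Dataset:
    """Draw a null (no group effect) population of participant grids.

    Each participant gets an independent random substream derived from
    ``(config.seed, participant index)``, so increasing ``n_participants``
    extends the population without reshuffling earlier participants.
    """
    n = config.n_participants
    shape = (len(PHASES), N_TRIALS, len(STIMULI))
    responses = np.empty((n,) + shape)
    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        a_i = rng.normal(0.0, config.sigma_subject)
        noise = rng.normal(0.0, config.sigma_noise, size=shape)
        responses[i] = np.maximum(0.0, a_i + config.mu + noise)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    return Dataset(ids, responses)


def summarize_population(dataset: Dataset) -> pd.DataFrame:
    """Per-(phase, trial, stimulus) mean and SD (n-1 denominator) table."""
    if dataset.n < 2:
        raise ValidationError("summary requires at least 2 participants")
    mean = dataset.responses.mean(axis=0)
    sd = dataset.responses.std(axis=0, ddof=1)
    recs = []
    for p, phase in enumerate(PHASES):
        for t in range(N_TRIALS):
            for s, stim in enumerate(STIMULI):
                recs.append(
                    {
                        "phase": phase,
                        "trial": t + 1,
                        "stimulus": stim,
                        "mean": mean[p, t, s],
                        "sd": sd[p, t, s],
                    }
                )
    return pd.DataFrame(recs)
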