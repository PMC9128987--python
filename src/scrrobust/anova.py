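"""Balanced mixed-design ANOVA with per-term partial eta squared.

One between-subjects factor (Group, k levels) crossed with up to three
within-subject factors (any of Phase, Trial, Stimulus).  The decomposition is
the classical univariate repeated-measures one: each subject's cell vector is
projected onto an orthonormal contrast basis per within-effect, and each
stratum is then an ordinary one-way (multi-column) Group decomposition,

* between stratum        — subject means; Group tested against
                           subjects-within-groups,
* within stratum for S   — the within effect S and its Group interaction,
                           tested against S x subjects-within-groups.

Partial eta squared is SS_effect / (SS_effect + SS_error_stratum), computed
from raw sums of squares (no sphericity correction enters SS).  Group sizes
may differ by the allocation remainder (+/-1); strata then use the standard
weighted one-way decomposition, which coincides with the balanced formulas
whenever groups are equal.

Zero error variance in a stratum raises :class:`DegenerateVarianceError`
rather than returning NaN, so resampling loops can count and skip degenerate
draws explicitly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateVarianceError(ValueError):
    """An error stratum has (numerically) zero variance."""


@dataclass(frozen=True)
class DesignSpec:
    """Mixed design: Group between-subjects, listed within factors crossed."""

    within: tuple[tuple[str, int], ...]  # ordered (name, levels)
    between: str = "Group"

    @property
    def n_cells(self) -> int:
        out = 1
        for _, lv in self.within:
            out *= lv
        return out


@dataclass(frozen=True)
class AnovaTerm:
    name: str
    ss: float
    df: int
    error_ss: float
    error_df: int

    @property
    def f(self) -> float:
        if self.error_ss == 0:
            return float("inf")
        return (self.ss / self.df) / (self.error_ss / self.error_df)

    @property
    def eta_p2(self) -> float:
        return partial_eta_squared(self.ss, self.error_ss)


def _term_key(name: str) -> frozenset[str]:
    return frozenset(part.strip().lower() for part in name.split("×"))


@dataclass
class AnovaTable:
    """Per-term SS, df, error SS/df, F and partial eta squared."""

    terms: list[AnovaTerm]

    def term(self, name: str) -> AnovaTerm:
        key = _term_key(name)
        for t in self.terms:
            if _term_key(t.name) == key:
                return t
        raise KeyError(f"no term {name!r} in table")

    def eta_p2(self, name: str) -> float:
        return self.term(name).eta_p2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "SS": t.ss,
                    "df": t.df,
                    "error_SS": t.error_ss,
                    "error_df": t.error_df,
                    "F": t.f,
                    "eta_p2": t.eta_p2,
                }
                for t in self.terms
            ]
        )


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error), defined when the sum is positive."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    total = ss_effect + ss_error
    if total <= 0:
        raise DegenerateVarianceError("effect and error SS are both zero")
    return ss_effect / total


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels, levels-1) orthonormal basis of the subspace orthogonal to 1."""
    # normalized Helmert contrasts
    h = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _group_decomposition(z: np.ndarray, groups: np.ndarray):
    """Weighted one-way decomposition of an (n, d) score matrix.

    Returns (ss_between, ss_within) summed over the d columns.
    """
    grand = z.mean(axis=0)
    ss_b = 0.0
    ss_w = 0.0
    for g in np.unique(groups):
        zg = z[groups == g]
        m = zg.mean(axis=0)
        ss_b += len(zg) * float(np.sum((m - grand) ** 2))
        ss_w += float(np.sum((zg - m) ** 2))
    return ss_b, ss_w


def _check_stratum(label: str, stratum_ss: float, total_ss: float) -> None:
    # a stratum is degenerate when it carries no variance at all (e.g. all
    # responses identical, or a differential analysis of CSP == CSM data);
    # zero *error* SS alone is legitimate and yields eta_p2 = 1
    if stratum_ss <= 1e-12 * max(total_ss, 1e-30):
        raise DegenerateVarianceError(f"no variance in the {label} stratum")


def mixed_anova_cells(
    y: np.ndarray, groups: np.ndarray, design: DesignSpec
) -> AnovaTable:
    """ANOVA from a subjects x within-cells value matrix.

    ``y`` has one row per subject and one column per within cell, columns in
    C order of ``design.within`` (last factor fastest).  ``groups`` holds one
    label per subject.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, m = y.shape if y.ndim == 2 else (y.shape[0], 1)
    y = y.reshape(n, m)
    if m != design.n_cells:
        raise ValueError(f"expected {design.n_cells} cells per subject, got {m}")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    total_ss = float(np.sum((y - y.mean()) ** 2))

    names = [nm for nm, _ in design.within]
    levels = [lv for _, lv in design.within]
    contrasts = [_orthonormal_contrasts(lv) for lv in levels]
    unit = [np.full((lv, 1), 1.0 / np.sqrt(lv)) for lv in levels]

    terms: list[AnovaTerm] = []

    # between-subjects stratum: scaled subject means
    scale_vec = np.ones((m, 1)) / np.sqrt(m)
    z0 = y @ scale_vec
    ss_g, ss_subj = _group_decomposition(z0, groups)
    _check_stratum("between-subjects", ss_g + ss_subj, total_ss)
    terms.append(
        AnovaTerm("Group", ss_g, len(labels) - 1, ss_subj, n - len(labels))
    )

    # one stratum per non-empty subset of within factors
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(range(len(names)), r):
            basis = np.ones((1, 1))
            for j in range(len(names)):
                block = contrasts[j] if j in subset else unit[j]
                basis = np.kron(basis, block)
            z = y @ basis  # (n, d)
            d = z.shape[1]
            zbar = z.mean(axis=0)
            ss_main = n * float(np.sum(zbar**2))
            ss_bg, ss_err = _group_decomposition(z, groups)
            label = "×".join(names[j] for j in subset)
            # the stratum's corrected variance excludes its grand-mean part
            _check_stratum(label, ss_bg + ss_err, total_ss)
            err_df = d * (n - len(labels))
            terms.append(AnovaTerm(label, ss_main, d, ss_err, err_df))
            terms.append(
                AnovaTerm(
                    label + "×Group",
                    ss_bg,
                    d * (len(labels) - 1),
                    ss_err,
                    err_df,
                )
            )
    return AnovaTable(terms)


def mixed_anova(
    data: pd.DataFrame, design: DesignSpec, value: str = "value",
    subject: str = "subject", group: str = "group"
) -> AnovaTable:
    """ANOVA from a long table with one row per subject x within cell.

    The table must be complete and balanced: every subject contributes exactly
    one value per within cell.  Within-factor columns are named as in
    ``design.within``; their levels are taken in sorted order.
    """
    cols = [nm for nm, _ in design.within]
    for nm, lv in design.within:
        observed = data[nm].nunique()
        if observed != lv:
            raise ValueError(f"factor {nm} has {observed} levels, expected {lv}")
    counts = data.pivot_table(
        index=subject, columns=cols or None, values=value,
        aggfunc="count", dropna=False, fill_value=0,
    ).to_numpy(dtype=float)
    if counts.shape[1] != design.n_cells or (counts != 1).any():
        raise ValueError("design is incomplete or has duplicate cells")
    wide = data.pivot_table(index=subject, columns=cols or None, values=value)
    if cols:
        wide = wide.sort_index(axis=1)
    group_of = data.drop_duplicates(subject).set_index(subject)[group]
    if data.groupby(subject)[group].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")
    y = wide.to_numpy(dtype=float)
    groups = group_of.loc[wide.index].to_numpy()
    return mixed_anova_cells(y, groups, design)


def one_way_eta(values: np.ndarray, groups: np.ndarray) -> float:
    """Partial eta squared of Group from a one-way ANOVA on per-subject scores."""
    table = mixed_anova_cells(
        np.asarray(values, dtype=float).reshape(-1, 1),
        groups,
        DesignSpec(within=()),
    )
    return table.eta_p2("Group")


def group_contrast_eta(contrast_scores: np.ndarray, groups: np.ndarray) -> float:
    """Group effect size on per-subject contrast (phase-difference) scores.

    The between-groups analogue of a paired-contrast analysis: each subject is
    reduced to one contrast score and the Group effect is a one-way ANOVA on
    those scores.
    """
    return one_way_eta(contrast_scores, groups)
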