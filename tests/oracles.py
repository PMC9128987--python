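"""Independent brute-force oracles used only by the tests.

These deliberately take different computational routes from the package:
the ANOVA oracle works on the long-format design matrix with incremental
QR projections, tau-b is an explicit all-pairs enumeration, and the
generator-mean oracle is the closed-form rectified-normal expectation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def _indicator_columns(levels: np.ndarray) -> np.ndarray:
    """One 0/1 column per distinct level of a long-format factor column."""
    uniq = np.unique(levels)
    return np.column_stack([(levels == u).astype(float) for u in uniq])


def _interaction_columns(cols: list[np.ndarray]) -> np.ndarray:
    out = cols[0]
    for c in cols[1:]:
        out = np.einsum("ni,nj->nij", out, c).reshape(len(out), -1)
    return out


def anova_ss_oracle(y: np.ndarray, groups: np.ndarray, within_levels: list[int]):
    """Sums of squares for every term of the mixed design, by QR projection.

    ``y`` is (n_subjects, n_cells) with cells in C order of ``within_levels``.
    Returns a dict mapping term keys to SS, where keys are frozensets over
    {'G', 'W0', 'W1', ...} for model terms and the same with 'S' added for
    error strata (subject-within-group interactions).
    """
    n, m = y.shape
    assert m == int(np.prod(within_levels)) if within_levels else m == 1

    # long format: one row per subject x cell
    yy = y.reshape(-1)
    subj = np.repeat(np.arange(n), m)
    grp = np.repeat(np.asarray(groups), m)
    cell_levels = (
        np.array(list(itertools.product(*[range(lv) for lv in within_levels])))
        if within_levels
        else np.zeros((1, 0), dtype=int)
    )
    wcols = [np.tile(cell_levels[:, j], n) for j in range(len(within_levels))]

    factor_cols = {"G": _indicator_columns(grp), "S": _indicator_columns(subj)}
    for j in range(len(within_levels)):
        factor_cols[f"W{j}"] = _indicator_columns(wcols[j])

    wnames = [f"W{j}" for j in range(len(within_levels))]
    # hierarchical processing order: grand mean, factorial terms by order,
    # then subject, then within x subject error strata by order
    terms: list[frozenset] = []
    model_factors = ["G"] + wnames
    for r in range(1, len(model_factors) + 1):
        for comb in itertools.combinations(model_factors, r):
            terms.append(frozenset(comb))
    terms.append(frozenset({"S"}))
    for r in range(1, len(wnames) + 1):
        for comb in itertools.combinations(wnames, r):
            terms.append(frozenset(set(comb) | {"S"}))

    nrows = len(yy)
    basis = np.ones((nrows, 1)) / math.sqrt(nrows)
    ss: dict[frozenset, float] = {}
    for term in terms:
        x = _interaction_columns([factor_cols[f] for f in sorted(term)])
        resid = x - basis @ (basis.T @ x)
        u, sv, _ = np.linalg.svd(resid, full_matrices=False)
        keep = u[:, sv > 1e-9 * max(1.0, sv.max(initial=0.0))]
        proj = keep.T @ yy
        ss[term] = float(proj @ proj)
        basis = np.hstack([basis, keep])
    return ss


def oracle_eta_p2(ss: dict, term: frozenset, n_within_factors: int) -> float:
    """Partial eta squared of a model term from the oracle's SS dict."""
    within_part = {f for f in term if f.startswith("W")}
    error_key = frozenset(within_part | {"S"})
    return ss[term] / (ss[term] + ss[error_key])


def taub_brute(x, y) -> float:
    """Kendall tau-b by enumerating all pairs with explicit tie counts."""
    x = list(x)
    y = list(y)
    c = d = tx = ty = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif (dx > 0) == (dy > 0):
                c += 1
            else:
                d += 1
    return (c - d) / math.sqrt((c + d + tx) * (c + d + ty))


def rectified_normal_mean(mu: float, sigma: float) -> float:
    """E[max(0, X)] for X ~ N(mu, sigma^2), closed form."""
    if sigma == 0:
        return max(0.0, mu)
    z = mu / sigma
    return mu * norm.cdf(z) + sigma * norm.pdf(z)


def bh_stepup(pvalues, q):
    """Benjamini-Hochberg step-up flags, straight from the definition."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    n = len(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / n:
            k = rank
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return flags
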