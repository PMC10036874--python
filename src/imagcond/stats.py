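"""Paired t-tests, JZS Bayes factors, and within-subject ANOVA.

The inferential layer for condition means (self-report and SCR): paired t
with Cohen's d = t/√n, the default two-sided Jeffreys–Zellner–Siow Bayes
factor with a Cauchy(0, r) prior on the standardized effect (r = 0.707 by
default), and a classical repeated-measures ANOVA for fully-crossed
within-subject designs reporting F, p, and classical η² (SS_effect divided
by the total sum of squares over all effect and error strata).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "PairedTResult",
    "BayesFactorResult",
    "paired_t",
    "jzs_bf10",
    "bf_sensitivity",
    "rm_anova",
    "rm_anova_2x2x2",
    "InfiniteTError",
    "IncompleteDesignError",
    "BayesFactorNumericalError",
    "DEFAULT_PRIOR_SCALE",
    "DEFAULT_PRIOR_GRID",
]

DEFAULT_PRIOR_SCALE = 0.707
DEFAULT_PRIOR_GRID = (0.5, 0.707, 1.0, 1.41)


class InfiniteTError(ZeroDivisionError):
    """Zero variance of paired differences with a nonzero mean."""


class IncompleteDesignError(ValueError):
    pass


class BayesFactorNumericalError(ArithmeticError):
    pass


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d = t / sqrt(n)

    @property
    def n(self) -> int:
        return self.df + 1


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    prior_scale: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test with Cohen's d for the paired design."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, d=0.0)
        raise InfiniteTError("all paired differences identical and nonzero")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), d=float(t / math.sqrt(n)))


def jzs_bf10(
    t: float, n: int, r: float = DEFAULT_PRIOR_SCALE, rel_tol: float = 1e-4
) -> BayesFactorResult:
    """Two-sided JZS Bayes factor for a one-sample (paired) t statistic.

    Marginal likelihood of ``t`` under a Cauchy(0, r) prior on the
    standardized effect δ, divided by the point-null likelihood.  The prior
    integral uses the substitution δ = r·tan(θ), which maps the heavy Cauchy
    tails onto a finite interval:

        m1 = (1/π) ∫_{-π/2}^{π/2} f_nct(t; ν, √n·r·tanθ) dθ

    with ν = n − 1 and f_nct the noncentral-t density.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if r <= 0:
        raise ValueError("prior scale must be positive")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(theta: float) -> float:
        delta = r * math.tan(theta)
        return sps.nct.pdf(t, nu, sqrt_n * delta)

    m1, err = integrate.quad(
        integrand, -math.pi / 2, math.pi / 2, limit=400, epsabs=0.0, epsrel=1e-9
    )
    m1 /= math.pi
    err /= math.pi
    if not np.isfinite(m1) or m1 <= 0 or err > max(rel_tol * m1, 1e-300):
        raise BayesFactorNumericalError(
            f"prior integral did not converge (m1={m1!r}, abserr={err!r})"
        )
    m0 = sps.t.pdf(t, nu)
    return BayesFactorResult(bf10=float(m1 / m0), prior_scale=float(r))


def bf_sensitivity(
    t: float, n: int, r_grid=DEFAULT_PRIOR_GRID
) -> pd.DataFrame:
    """BF10 across a grid of Cauchy prior widths (robustness check)."""
    rows = [
        {"prior_scale": r, "bf10": jzs_bf10(t, n, r).bf10, "bf01": jzs_bf10(t, n, r).bf01}
        for r in r_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def _effect_ss(cells: np.ndarray, subset: tuple[int, ...]) -> float:
    """Sum of squares of the pure interaction term for the given axes.

    Inclusion–exclusion over marginal means of a balanced factorial array
    (axis 0 = subject); the term is broadcast back to the full shape so each
    observation contributes once.
    """
    full_axes = tuple(range(cells.ndim))
    term = np.zeros_like(cells, dtype=float)
    for sub in itertools.chain.from_iterable(
        itertools.combinations(subset, k) for k in range(len(subset) + 1)
    ):
        drop = tuple(ax for ax in full_axes if ax not in sub)
        marginal = cells.mean(axis=drop, keepdims=True)
        sign = (-1.0) ** (len(subset) - len(sub))
        term = term + sign * np.broadcast_to(marginal, cells.shape)
    return float(np.sum(term**2))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | tuple[str, ...],
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Classical fully-within-subject ANOVA on a complete balanced design.

    One observation per subject × cell.  For each effect (every non-empty
    subset of the within factors), F = MS_effect / MS_(effect × subject),
    p from F(df_effect, df_error), and classical η² = SS_effect / SS_total
    where SS_total = Σ(y − grand mean)² over all observations.
    """
    within = list(within)
    levels = {f: sorted(data[f].unique()) for f in within}
    subjects = sorted(data[subject].unique())
    n = len(subjects)
    if n < 2:
        raise IncompleteDesignError("need at least two subjects")
    shape = [n] + [len(levels[f]) for f in within]
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean", dropna=False)
    expected_cols = int(np.prod(shape[1:]))
    if pivot.shape[1] != expected_cols or pivot.isna().any().any():
        raise IncompleteDesignError("design is incomplete: every subject needs every cell")
    # order columns lexicographically by factor levels for a clean reshape
    if len(within) == 1:
        pivot = pivot.reindex(columns=levels[within[0]])
    else:
        pivot = pivot.reindex(columns=pd.MultiIndex.from_product([levels[f] for f in within]))
    cells = pivot.to_numpy(dtype=float).reshape(shape)

    ss_total = float(np.sum((cells - cells.mean()) ** 2))
    rows = []
    factor_axis = {f: i + 1 for i, f in enumerate(within)}
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            axes = tuple(factor_axis[f] for f in combo)
            ss_eff = _effect_ss(cells, axes)
            ss_err = _effect_ss(cells, (0,) + axes)  # effect × subject stratum
            df_eff = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_err = df_eff * (n - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            f_val = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else math.inf)
            p = float(sps.f.sf(f_val, df_eff, df_err)) if np.isfinite(f_val) else 0.0
            rows.append(
                {
                    "effect": " × ".join(combo),
                    "F": float(f_val),
                    "df_effect": df_eff,
                    "df_error": df_err,
                    "p": p,
                    "eta_squared": ss_eff / ss_total if ss_total > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def rm_anova_2x2x2(
    data: pd.DataFrame,
    dv: str,
    factors: tuple[str, str, str] = ("cs_type", "modality", "phase"),
    subject: str = "participant_id",
) -> pd.DataFrame:
    """The 2×2×2 within-subject ANOVA (CS type × modality × phase).

    Requires each factor to have exactly two levels; all seven effects have
    df_effect = 1 and df_error = n − 1.
    """
    for f in factors:
        if data[f].nunique() != 2:
            raise IncompleteDesignError(f"factor {f!r} must have exactly 2 levels")
    return rm_anova(data, dv=dv, within=list(factors), subject=subject)


def condition_contrast(
    means: pd.DataFrame,
    value: str,
    phase: str,
    modality: str,
    subject: str = "participant_id",
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (CS+, CS−) vectors for one phase × modality cell, subject-aligned."""
    sel = means[(means["phase"] == phase) & (means["modality"] == modality)]
    wide = sel.pivot_table(index=subject, columns="cs_type", values=value)
    if "CSplus" not in wide or "CSminus" not in wide or wide.isna().any().any():
        raise IncompleteDesignError(f"incomplete CS+/CS− data for {phase}/{modality}")
    return wide["CSplus"].to_numpy(), wide["CSminus"].to_numpy()
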