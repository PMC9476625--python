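"""Repeated-measures ANOVA, post-hoc tests, SP-index, tract-FA rules, regression.

The factorial analyses operate on per-subject condition means (cell means),
as is standard for this paradigm.  All within-subject factors have two
levels, so every effect has one numerator degree of freedom, sphericity is
moot, and each effect's F test is equivalent to a one-sample t test on a
per-subject contrast score.  The sums-of-squares decomposition is
implemented from first principles:

    SS_effect = n * m * Lbar^2         L_s = mean_c sign(c) * y_{s,c}
    SS_error  = m * sum_s (L_s - Lbar)^2

with n subjects, m cells and sign(c) the product of +/-1 codes of the
factors in the effect.  F(1, n-1) = SS_effect / (SS_error / (n-1)), and the
partial eta squared is SS_effect / (SS_effect + SS_error).

The SP-index (structural-priming index) is the per-subject double difference
SP = (RT_irregular,long - RT_regular,long) - (RT_irregular,short -
RT_regular,short); its subject mean equals the STRUCTURE x CONTEXT
interaction contrast of the same table.  The movement cost is the mean RT of
the motor blocks minus the baseline blocks.  Tract-FA summarization averages
FA over voxels with FA > 0 that belong to exactly one tract and are reliably
part of it in at least 50% of participants.  Multiple regression (ordinary
least squares on z-scored variables) reports standardized betas, t and p per
coefficient, and the adjusted R^2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RepeatedMeasuresAnova",
    "AnovaResults",
    "rm_anova_2x2",
    "rm_anova_2x2x2",
    "paired_t_bonferroni",
    "sp_index",
    "movement_cost",
    "tract_mean_fa",
    "TractFA",
    "multiple_regression",
    "RegressionResult",
]


@dataclass(frozen=True)
class AnovaResults:
    """Fitted repeated-measures ANOVA: one row per effect."""

    table: pd.DataFrame  # index: effect; columns F, df_num, df_den, p, partial_eta_sq, ss_effect, ss_error
    factors: tuple[str, ...]
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        if name not in self.table.index:
            raise KeyError(
                f"unknown effect {name!r}; available: {list(self.table.index)}"
            )
        return self.table.loc[name]

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA ({' x '.join(self.factors)}), "
            f"n = {self.n_subjects} subjects",
            "-" * 72,
            f"{'effect':<28}{'F':>10}{'df':>9}{'p':>10}{'np2':>8}",
        ]
        for name, row in self.table.iterrows():
            lines.append(
                f"{name:<28}{row['F']:>10.3f}"
                f"{f'({row.df_num:.0f},{row.df_den:.0f})':>9}"
                f"{row['p']:>10.4f}{row['partial_eta_sq']:>8.3f}"
            )
        return "\n".join(lines)


class RepeatedMeasuresAnova:
    """Fully within-subjects factorial ANOVA on per-subject cell means.

    Parameters
    ----------
    data
        Long-format table with one row per subject x cell.
    dv, subject
        Column names of the dependent variable and the subject identifier.
    within
        Names of the within-subject factor columns; every factor must have
        exactly two levels and every subject must have a complete set of
        cells (incomplete tables are rejected listing the missing cells).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        subject: str,
        within: Sequence[str],
    ):
        within = list(within)
        if not within:
            raise ValueError("at least one within-subject factor is required")
        for col in [dv, subject, *within]:
            if col not in data.columns:
                raise KeyError(f"column {col!r} not found in data")
        levels = {}
        for f in within:
            lv = sorted(data[f].dropna().unique())
            if len(lv) != 2:
                raise ValueError(
                    f"factor {f!r} must have exactly 2 levels, found {lv}"
                )
            levels[f] = lv

        wide = data.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="mean"
        )
        expected = list(itertools.product(*(levels[f] for f in within)))
        expected_cols = [c if len(within) > 1 else c[0] for c in expected]
        missing_cols = [c for c in expected_cols if c not in wide.columns]
        cells_with_nan = wide.reindex(columns=expected_cols)
        missing = cells_with_nan.isna()
        if missing_cols or missing.to_numpy().any():
            bad = [
                f"subject {s}, cell {c}"
                for s in cells_with_nan.index
                for c in cells_with_nan.columns
                if pd.isna(cells_with_nan.loc[s, c])
            ]
            raise ValueError("incomplete cell-means table: missing " + "; ".join(bad))
        if len(wide) < 2:
            raise ValueError("at least 2 subjects are required")
        self._wide = cells_with_nan
        self._cells = expected
        self.levels = levels
        self.within = within
        self.dv = dv
        self.subject = subject

    def fit(self) -> AnovaResults:
        y = self._wide.to_numpy(dtype=float)
        n, m = y.shape
        rows = {}
        for r in range(1, len(self.within) + 1):
            for combo in itertools.combinations(self.within, r):
                signs = np.array(
                    [
                        np.prod(
                            [
                                1.0
                                if cell[self.within.index(f)] == self.levels[f][0]
                                else -1.0
                                for f in combo
                            ]
                        )
                        for cell in self._cells
                    ]
                )
                L = (y * signs).mean(axis=1)
                Lbar = L.mean()
                ss_eff = n * m * Lbar**2
                ss_err = m * ((L - Lbar) ** 2).sum()
                df_num, df_den = 1, n - 1
                if ss_err == 0.0:
                    F = 0.0 if ss_eff == 0.0 else np.inf
                else:
                    F = (ss_eff / df_num) / (ss_err / df_den)
                p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
                denom = ss_eff + ss_err
                pes = float(ss_eff / denom) if denom > 0 else 0.0
                # signed contrast estimate: for a 2x2 interaction this is the
                # difference of differences (first-sorted levels coded +1)
                rows[" x ".join(combo)] = {
                    "estimate": float(m * Lbar),
                    "F": float(F),
                    "df_num": df_num,
                    "df_den": df_den,
                    "p": p,
                    "partial_eta_sq": pes,
                    "ss_effect": float(ss_eff),
                    "ss_error": float(ss_err),
                }
        table = pd.DataFrame(rows).T
        return AnovaResults(
            table=table, factors=tuple(self.within), n_subjects=n
        )


def rm_anova_2x2(
    cell_means: pd.DataFrame,
    dv: str = "rt_ms",
    subject: str = "subject_id",
    factors: Sequence[str] = ("structure", "context"),
) -> AnovaResults:
    """Two-way repeated-measures ANOVA on a long-format cell-means table."""
    if len(factors) != 2:
        raise ValueError("rm_anova_2x2 expects exactly two factors")
    return RepeatedMeasuresAnova(cell_means, dv=dv, subject=subject, within=factors).fit()


def rm_anova_2x2x2(
    cell_means: pd.DataFrame,
    dv: str = "n_errors",
    subject: str = "subject_id",
    factors: Sequence[str] = ("structure", "movement", "error_type"),
) -> AnovaResults:
    """Three-way repeated-measures ANOVA (e.g. with an ERROR TYPE factor)."""
    if len(factors) != 3:
        raise ValueError("rm_anova_2x2x2 expects exactly three factors")
    return RepeatedMeasuresAnova(cell_means, dv=dv, subject=subject, within=factors).fit()


def paired_t_bonferroni(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    n_comparisons: int | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Paired t tests with Bonferroni correction (adjusted p = min(1, p*m))."""
    m = n_comparisons if n_comparisons is not None else len(pairs)
    if m < 1:
        raise ValueError("n_comparisons must be at least 1")
    rows = []
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a, b, alternative=alternative)
        rows.append(
            {
                "t": float(t),
                "df": len(a) - 1,
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


# -- behavioral indices ------------------------------------------------------

_SP_CELLS = (
    "baseline-irregular", "baseline-regular",
    "structure-irregular", "structure-regular",
)
_MOTOR_BLOCKS = ("motor-regular", "motor-irregular")
_BASELINE_BLOCKS = ("baseline-regular", "baseline-irregular")


def sp_index(rt_means: pd.DataFrame) -> pd.Series:
    """Structural-priming index per subject (ms).

    SP = (RT_irregular,long - RT_regular,long)
       - (RT_irregular,short - RT_regular,short),
    from the four baseline/structure-block condition means.  Larger SP means
    stronger context-based structural planning.
    """
    for c in _SP_CELLS:
        if c not in rt_means.columns:
            raise KeyError(f"condition {c!r} missing from the RT table")
    sp = (rt_means["baseline-irregular"] - rt_means["baseline-regular"]) - (
        rt_means["structure-irregular"] - rt_means["structure-regular"]
    )
    sp.name = "sp_ms"
    if not np.isfinite(sp.to_numpy()).all():
        raise ValueError("SP-index undefined for subjects with missing cells")
    return sp


def movement_cost(rt_means: pd.DataFrame) -> pd.Series:
    """Overall RT slowing under nonstandard fingering per subject (ms):
    mean RT of the motor blocks minus mean RT of the baseline blocks."""
    for c in _MOTOR_BLOCKS + _BASELINE_BLOCKS:
        if c not in rt_means.columns:
            raise KeyError(f"condition {c!r} missing from the RT table")
    cost = rt_means[list(_MOTOR_BLOCKS)].mean(axis=1) - rt_means[
        list(_BASELINE_BLOCKS)
    ].mean(axis=1)
    cost.name = "cost_ms"
    if not np.isfinite(cost.to_numpy()).all():
        raise ValueError("movement cost undefined for subjects with missing cells")
    return cost


# -- tract FA ----------------------------------------------------------------


@dataclass(frozen=True)
class TractFA:
    tract_id: str
    mean_fa: float
    n_voxels: int


def tract_mean_fa(
    fa_map: Mapping,
    tract_masks: Mapping[str, Iterable],
    membership_freq: Mapping,
) -> list[TractFA]:
    """Mean FA per tract under the voxel-inclusion rules.

    A voxel contributes iff its FA exceeds 0, it belongs to exactly one
    tract, and it was reliably part of that tract in at least 50% of
    participants.  A tract with no surviving voxels is flagged (NaN mean),
    never silently zero.
    """
    masks = {t: set(v) for t, v in tract_masks.items()}
    counts: dict = {}
    for voxels in masks.values():
        for v in voxels:
            counts[v] = counts.get(v, 0) + 1
    out = []
    for tract, voxels in masks.items():
        vals = []
        for v in voxels:
            fa = fa_map.get(v)
            if fa is None:
                continue
            if not (0.0 <= fa <= 1.0):
                raise ValueError(f"FA value {fa} of voxel {v} outside [0, 1]")
            if fa > 0 and counts[v] == 1 and membership_freq.get(v, 0.0) >= 0.5:
                vals.append(fa)
        out.append(
            TractFA(
                tract_id=tract,
                mean_fa=float(np.mean(vals)) if vals else float("nan"),
                n_voxels=len(vals),
            )
        )
    return out


# -- multiple regression -----------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    predictors: tuple[str, ...]
    standardized_betas: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    f_pvalue: float

    def summary(self) -> str:
        lines = [
            "OLS regression (standardized variables)",
            f"  adj. R^2 = {self.adjusted_r_squared:.3f}  "
            f"F = {self.f_statistic:.2f} (p = {self.f_pvalue:.4f})",
            f"  {'predictor':<16}{'beta':>8}{'t':>8}{'p':>10}",
        ]
        for name, b, t, p in zip(
            self.predictors, self.standardized_betas, self.t_values, self.p_values
        ):
            lines.append(f"  {name:<16}{b:>8.3f}{t:>8.3f}{p:>10.4f}")
        return "\n".join(lines)


def multiple_regression(
    y: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
) -> RegressionResult:
    """OLS with standardized coefficients and adjusted R^2.

    y and all predictors are z-scored on the analyzed sample; the intercept
    of the standardized model is exactly zero, and coefficient t tests use
    n - p - 1 error degrees of freedom (an intercept is estimated).
    Rank-deficient designs are rejected.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns) if names is None else list(names)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = (
            [f"x{i+1}" for i in range(X.shape[1])] if names is None else list(names)
        )
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and predictors must have matching length")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValueError("rank-deficient design matrix")

    zy = (y - y.mean()) / y.std(ddof=1)
    zX = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    fit = sm.OLS(zy, sm.add_constant(zX)).fit()
    return RegressionResult(
        predictors=tuple(names),
        standardized_betas=fit.params[1:],
        t_values=fit.tvalues[1:],
        p_values=fit.pvalues[1:],
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
    )
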