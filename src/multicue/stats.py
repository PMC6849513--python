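"""Within-subject analyses: one-way repeated-measures ANOVA and Bonferroni post hocs.

The ANOVA is computed directly from the sums-of-squares decomposition of a
fully crossed subjects x conditions table:

    SS_effect  = n * sum_j (mean_j - grand)^2
    SS_subject = k * sum_i (mean_i - grand)^2
    SS_error   = SS_total - SS_effect - SS_subject

with F = (SS_effect/df_effect) / (SS_error/df_error), df = (k-1, (k-1)(n-1)),
and partial eta squared = SS_effect / (SS_effect + SS_error). Post hoc tests
are paired t-tests with p-values multiplied by the number of pairs and
capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "OutcomeTable",
    "RmAnovaResult",
    "PairwiseResult",
    "rm_anova",
    "bonferroni_pairwise",
]


@dataclass(frozen=True)
class OutcomeTable:
    """Fully crossed within-subject outcome matrix: rows = replicates, columns = conditions."""

    values: np.ndarray
    condition_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D subjects x conditions matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must have no missing cells")
        if len(self.condition_names) != v.shape[1]:
            raise ValueError("one name per condition column required")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "condition_names", tuple(self.condition_names))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_subject: float
    ss_error: float
    degenerate: bool = False  # zero error variance: F/p not numeric


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    degenerate: bool = False  # zero within-pair variance


_EPS = 1e-300


def rm_anova(table: OutcomeTable) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with partial eta squared."""
    v = table.values
    n, k = v.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = v.mean()
    ss_effect = n * float(((v.mean(axis=0) - grand) ** 2).sum())
    ss_subject = k * float(((v.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((v - grand) ** 2).sum())
    ss_error = max(ss_total - ss_effect - ss_subject, 0.0)
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    denom = ss_effect + ss_error
    eta = ss_effect / denom if denom > _EPS else 0.0
    if ss_error <= _EPS * max(1.0, ss_total):
        return RmAnovaResult(
            F=float("nan"),
            df_effect=df_effect,
            df_error=df_error,
            p=float("nan"),
            partial_eta_sq=eta,
            ss_effect=ss_effect,
            ss_subject=ss_subject,
            ss_error=ss_error,
            degenerate=True,
        )
    F = (ss_effect / df_effect) / (ss_error / df_error)
    p = float(sps.f.sf(F, df_effect, df_error))
    return RmAnovaResult(
        F=float(F),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        partial_eta_sq=eta,
        ss_effect=ss_effect,
        ss_subject=ss_subject,
        ss_error=ss_error,
    )


def bonferroni_pairwise(table: OutcomeTable) -> list[PairwiseResult]:
    """Paired t-test per condition pair, Bonferroni-adjusted (capped at 1)."""
    v = table.values
    names = table.condition_names
    k = v.shape[1]
    if k < 2:
        raise ValueError("need at least 2 conditions")
    pairs = list(itertools.combinations(range(k), 2))
    n_pairs = len(pairs)
    results = []
    for i, j in pairs:
        diff = v[:, i] - v[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            results.append(
                PairwiseResult(
                    pair=(names[i], names[j]),
                    t=float("nan"),
                    df=v.shape[0] - 1,
                    p_raw=float("nan"),
                    p_adjusted=float("nan"),
                    degenerate=True,
                )
            )
            continue
        t, p = sps.ttest_rel(v[:, i], v[:, j])
        results.append(
            PairwiseResult(
                pair=(names[i], names[j]),
                t=float(t),
                df=v.shape[0] - 1,
                p_raw=float(p),
                p_adjusted=float(min(1.0, p * n_pairs)),
            )
        )
    return results
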