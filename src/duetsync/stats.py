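"""Inference layer: fully-within repeated-measures ANOVA for 2-level
factorial designs, paired t with Cohen's d, Pearson correlation, and the
Fisher r-to-z comparison of two independent correlations.

With only 2 levels per within factor every effect is a single-df paired
contrast, so F = t^2 exactly, sphericity is trivially satisfied, and partial
eta squared is F / (F + df_error).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.F) and self.F < 0:
            raise ValueError("F must be >= 0")


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d for the paired contrast, d = t / sqrt(n)
    note: str = ""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    r_squared: float


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p_two_tailed: float
    p_one_tailed: float
    note: str = ""


def _contrast_signs(n_factors: int, effect: tuple[int, ...]) -> np.ndarray:
    """Per-cell +/-1 codes for an effect; cells in lexicographic level order."""
    signs = np.ones(2**n_factors)
    for j in range(2**n_factors):
        for f in effect:
            level = (j >> (n_factors - 1 - f)) & 1
            signs[j] *= 1.0 if level else -1.0
    return signs


def rm_anova_cells(scores: np.ndarray, factors: list[str]) -> list[AnovaResult]:
    """Repeated-measures ANOVA on a (subjects x cells) score matrix.

    Cells must be ordered lexicographically by factor levels (last factor
    fastest).  Every main effect and interaction is a paired contrast tested
    as F(1, n-1) = t^2; degenerate contrasts (zero variance across subjects)
    are reported as infinite F (nonzero mean) or NaN with a diagnostic note.
    """
    scores = np.asarray(scores, dtype=float)
    k = len(factors)
    if k not in (2, 3):
        raise ValueError(f"rm_anova supports 2 or 3 two-level factors, got {k}")
    if scores.ndim != 2 or scores.shape[1] != 2**k:
        raise ValueError(f"expected (n_subjects, {2**k}) score matrix, got {scores.shape}")
    complete = np.isfinite(scores).all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} participant(s) with missing cells (listwise)", stacklevel=2)
        scores = scores[complete]
    n = scores.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 complete participants, have {n}")
    df2 = n - 1
    results = []
    for size in range(1, k + 1):
        for effect in itertools.combinations(range(k), size):
            name = " x ".join(factors[f] for f in effect)
            w = _contrast_signs(k, effect) / 2 ** (k - 1)
            c = scores @ w  # per-subject contrast score
            sd = c.std(ddof=1)
            if sd == 0:
                note = "zero contrast variance across participants"
                F = np.inf if c.mean() != 0 else np.nan
                p = 0.0 if np.isfinite(c.mean()) and c.mean() != 0 else np.nan
                results.append(AnovaResult(name, F, 1, df2, p, np.nan, note))
                continue
            t = c.mean() / (sd / np.sqrt(n))
            F = t**2
            p = float(sps.f.sf(F, 1, df2))
            results.append(AnovaResult(name, float(F), 1, df2, p, eta_p2_from_f(F, df2)))
    return results


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> list[AnovaResult]:
    """Long-format front end: one row per subject x cell.

    Each factor in ``within`` must have exactly 2 levels; levels are ordered
    by sorted label so contrast signs are reproducible.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    levels = [sorted(data[f].dropna().unique()) for f in within]
    for f, lv in zip(within, levels):
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, has {len(lv)}: {lv}")
    cols = list(itertools.product(*levels))
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols, names=within) if len(within) > 1 else [c[0] for c in cols])
    return rm_anova_cells(wide.to_numpy(), list(within))


def eta_p2_from_f(F: float, df2: int) -> float:
    """Partial eta squared of a 1-df effect: F / (F + df_error)."""
    return float(F / (F + df2))


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-contrast Cohen's d_z = t / sqrt(n)."""
    return float(t / np.sqrt(n))


def paired_t(x, y) -> PairedTestResult:
    """Two-tailed paired t test with Cohen's d_z = t / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long (paired)")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    n = len(diff)
    if diff.std(ddof=1) == 0:
        return PairedTestResult(np.nan, n - 1, np.nan, np.nan, "zero-variance differences")
    res = sps.ttest_rel(x, y)
    return PairedTestResult(float(res.statistic), n - 1, float(res.pvalue), cohens_d_from_t(res.statistic, n))


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with two-tailed p and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be 1-D, equally long, length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(np.nan, len(x), np.nan, np.nan)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, len(x), float(res.pvalue), r * r)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Fisher Z-test comparing two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); both one- and
    two-tailed normal p values are reported.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 per sample")
    note = ""
    clip = 1.0 - 1e-12
    if abs(r1) >= 1 or abs(r2) >= 1:
        warnings.warn("|r| >= 1 clipped before the r-to-z transform", stacklevel=2)
        note = "|r| clipped to < 1"
        r1 = float(np.clip(r1, -clip, clip))
        r2 = float(np.clip(r2, -clip, clip))
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_one = float(sps.norm.sf(abs(z)))
    return FisherZResult(float(z), 2 * p_one, p_one, note)


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Tabular view mirroring the F(1, df) / P / partial-eta-squared layout."""
    return pd.DataFrame(
        [
            {"effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p, "eta_p2": r.eta_p2, "note": r.note}
            for r in results
        ]
    )
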