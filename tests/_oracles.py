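"""Independent brute-force oracles used only by the tests.

Each oracle is written from the defining formula, deliberately avoiding the
package's code paths (double loops instead of vectorization, full
sum-of-squares decomposition instead of paired contrasts).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def brute_pearson(x, y) -> float:
    """Sample Pearson r via explicit double-loop sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def brute_lag_pairs(iki_melody, iki_bass, lag: int):
    """Pairings for the lagged cross-correlation, spelled out index by index."""
    pairs = []
    for n in range(6):
        m = n + lag  # bass index paired with melody index n
        if 0 <= m < 6:
            pairs.append((iki_melody[n], iki_bass[m]))
    return pairs


def brute_lag_crosscorr(iki_melody, iki_bass, lag: int) -> float:
    pairs = brute_lag_pairs(iki_melody, iki_bass, lag)
    return brute_pearson([p[0] for p in pairs], [p[1] for p in pairs])


def ss_rm_anova(data: np.ndarray, factor_names: list[str]):
    """Full sum-of-squares repeated-measures ANOVA decomposition.

    ``data`` has axes (subject, factor1, factor2, ...), each factor axis of
    size 2.  For each effect E the error term is the E x subject
    interaction: F = (SS_E / df_E) / (SS_ExS / df_ExS).  Returns a dict
    effect-name -> (F, df1, df2, p).
    """
    data = np.asarray(data, dtype=float)
    n_axes = data.ndim
    sizes = data.shape
    total = data.size

    def effect_ss(axes: tuple[int, ...]) -> float:
        """SS of the pure effect on the given axes via inclusion-exclusion.

        The effect term is constant within its cells, so summing its square
        over the full broadcast array weights each cell by its count.
        """
        term = np.zeros(sizes)
        for sub_len in range(len(axes) + 1):
            for sub in itertools.combinations(axes, sub_len):
                other = tuple(a for a in range(n_axes) if a not in sub)
                marg = data.mean(axis=other, keepdims=True)
                term = term + (-1) ** (len(axes) - len(sub)) * marg
        return float((term**2).sum())

    results = {}
    subject_axis = 0
    factor_axes = list(range(1, n_axes))
    for k in range(1, len(factor_axes) + 1):
        for axes in itertools.combinations(factor_axes, k):
            name = " x ".join(factor_names[a - 1] for a in axes)
            ss_e = effect_ss(axes)
            ss_es = effect_ss((subject_axis, *axes))
            df1 = int(np.prod([sizes[a] - 1 for a in axes]))
            df2 = (sizes[subject_axis] - 1) * df1
            F = (ss_e / df1) / (ss_es / df2)
            results[name] = (F, df1, df2, float(sps.f.sf(F, df1, df2)))
    return results


def drift_recursion(
    alpha_melody: float,
    alpha_bass: float,
    kappa: float,
    iki_target_melody: float,
    iki_target_bass: float,
    tau: float = 500.0,
    start: float = 3000.0,
    n_notes: int = 7,
):
    """Noiseless coupled-timekeeper recursion, step by step.

    Returns (melody onsets, bass onsets) as plain lists.
    """
    t_m, t_b = [start], [start]
    for n in range(1, n_notes):
        T_m = tau + kappa * (iki_target_melody - tau) * n / n_notes
        T_b = tau + kappa * (iki_target_bass - tau) * n / n_notes
        asyn = t_m[-1] - t_b[-1]
        t_m.append(t_m[-1] + T_m - alpha_melody * asyn)
        t_b.append(t_b[-1] + T_b - alpha_bass * (-asyn))
    return t_m, t_b
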