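"""Phenotyping statistics: root metrics, one-way ANOVA, Duncan's multiple
range test with compact letter display, and Pearson correlation matrices.

Duncan's multiple range test is a stepwise post-hoc procedure on the ordered
group means.  A span of p consecutive ordered means is compared against a
critical range built from the studentized range distribution at the
span-dependent protection level 1 − (1 − α)^(p−1), with the ANOVA mean square
error and error degrees of freedom.  A span can only be declared significant
if every span enclosing it is significant (containment), which makes the
non-significant pair relation hereditary on intervals of the ordered means and
allows an exact compact letter display: groups sharing a letter are not
significantly different, groups sharing none are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "lateral_root_density",
    "AnovaResult",
    "anova_oneway",
    "DuncanMRT",
    "DuncanResults",
    "duncan_mrt",
    "pearson_matrix",
]


def lateral_root_density(count, length_mm):
    """Lateral root density in roots·cm⁻¹: visible lateral roots per primary
    root length (length given in mm, converted to cm internally)."""
    count = np.asarray(count, dtype=float)
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(length_mm <= 0):
        raise ValueError("primary root length must be positive")
    if np.any(count < 0):
        raise ValueError("lateral root count must be nonnegative")
    out = count / (length_mm / 10.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# One-way ANOVA

@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    mse: float
    df_between: int
    df_within: int
    group_means: dict
    group_sizes: dict
    flags: tuple[str, ...] = ()


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects decomposition.

    Degenerate inputs (zero within-group variance everywhere) yield an
    undefined F, reported as NaN with a flag rather than raising, so that a
    downstream Duncan test can still rank the means.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {k!r} contains non-finite values")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    flags: tuple[str, ...] = ()
    if mse == 0.0:
        f = np.nan if ms_between == 0.0 else np.inf
        p = np.nan if ms_between == 0.0 else 0.0
        flags = ("degenerate_zero_mse",)
    else:
        f = ms_between / mse
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        mse=float(mse),
        df_between=df_between,
        df_within=df_within,
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        group_sizes={k: int(a.size) for k, a in arrays.items()},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test

@lru_cache(maxsize=4096)
def duncan_quantile(p: int, df: int, alpha: float = 0.05) -> float:
    """Critical studentized-range value for a span of p ordered means.

    Uses the protection level 1 − (1 − α)^(p−1): the quantile
    q_{1−(1−α)^(p−1)}(p, df) of the studentized range distribution.  For
    p = 2 this is the ordinary α-level studentized range (a t-type
    comparison), so adjacent-mean comparisons are never more conservative
    than an unprotected pairwise test.
    """
    if p < 2:
        raise ValueError("span must cover at least two means")
    protection = (1.0 - alpha) ** (p - 1)
    return float(sps.studentized_range.ppf(protection, p, df))


@dataclass(frozen=True)
class DuncanResults:
    """Outcome of Duncan's multiple range test.

    ``significant[a][b]`` is True when groups a and b differ at level alpha
    after the stepwise containment rule; ``letters`` is the compact letter
    display (groups sharing any letter are not significantly different).
    """

    group_means: dict
    group_sizes: dict
    letters: dict
    significant: pd.DataFrame
    critical_ranges: dict
    anova: AnovaResult
    alpha: float
    flags: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        """Per-group table: mean, n, compact letters, sorted by mean."""
        order = sorted(self.group_means, key=lambda g: (self.group_means[g], str(g)))
        return pd.DataFrame(
            {
                "group": order,
                "mean": [self.group_means[g] for g in order],
                "n": [self.group_sizes[g] for g in order],
                "letters": [self.letters[g] for g in order],
            }
        )


class DuncanMRT:
    """Model object for Duncan's multiple range test on ≥ 2 samples.

    Parameters
    ----------
    groups : mapping of group label -> 1-D sample
    alpha : float
        Per-comparison protection base level (0.05 in the phenotyping
        convention).
    """

    def __init__(self, groups: Mapping[str, Sequence[float]], alpha: float = 0.05):
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
        self.alpha = alpha

    def fit(self) -> DuncanResults:
        anova = anova_oneway(self.groups)
        labels = list(self.groups)
        k = len(labels)
        means = anova.group_means
        sizes = anova.group_sizes
        flags = anova.flags

        # harmonic-mean sample size for unbalanced designs
        ns = np.array([sizes[g] for g in labels], dtype=float)
        if np.all(ns == ns[0]):
            n_eff = float(ns[0])
        else:
            n_eff = k / np.sum(1.0 / ns)
            flags = flags + ("unbalanced_harmonic_mean",)

        order = sorted(labels, key=lambda g: (means[g], str(g)))
        m = np.array([means[g] for g in order])
        df_err = anova.df_within
        se = np.sqrt(anova.mse / n_eff)

        crit = {
            p: duncan_quantile(p, df_err, self.alpha) * se for p in range(2, k + 1)
        }

        # stepwise from the widest span down; containment: a span is
        # non-significant if its range is below the critical value or either
        # immediate enclosing span is non-significant
        sig = np.zeros((k, k), dtype=bool)
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                raw = (m[j] - m[i]) > crit[span]
                enclosed_ok = True
                if i > 0 and not sig[i - 1, j]:
                    enclosed_ok = False
                if j < k - 1 and not sig[i, j + 1]:
                    enclosed_ok = False
                if span == k:
                    enclosed_ok = True
                sig[i, j] = sig[j, i] = raw and enclosed_ok

        letters = _compact_letter_display(order, sig)
        sig_df = pd.DataFrame(sig, index=order, columns=order).loc[labels, labels]
        return DuncanResults(
            group_means=means,
            group_sizes=sizes,
            letters=letters,
            significant=sig_df,
            critical_ranges=crit,
            anova=anova,
            alpha=self.alpha,
            flags=flags,
        )


def _compact_letter_display(order: list, sig: np.ndarray) -> dict:
    """Insert-and-absorb letters over the sorted means.

    Containment makes non-significance hereditary on intervals, so the
    maximal non-significant intervals of the ordered means cover all
    non-significant pairs; each maximal interval gets one letter and
    intervals contained in another are absorbed.
    """
    k = len(order)
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # absorb intervals contained in an earlier (necessarily wider) one
    maximal: list[tuple[int, int]] = []
    for iv in intervals:
        if not any(a <= iv[0] and iv[1] <= b for a, b in maximal):
            maximal.append(iv)

    def letter(idx: int) -> str:
        # a, b, ..., z, aa, ab, ... for arbitrarily many letter classes
        s = ""
        idx += 1
        while idx:
            idx, r = divmod(idx - 1, 26)
            s = chr(ord("a") + r) + s
        return s

    letters = {g: "" for g in order}
    for li, (a, b) in enumerate(maximal):
        for pos in range(a, b + 1):
            letters[order[pos]] += letter(li)
    return letters


def duncan_mrt(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> DuncanResults:
    """Functional wrapper: ``DuncanMRT(groups, alpha).fit()``."""
    return DuncanMRT(groups, alpha=alpha).fit()


# ---------------------------------------------------------------------------
# Pearson correlation matrices

def pearson_matrix(
    table: pd.DataFrame,
    traits: Sequence[str],
    grouping: str = "overall",
    group_col: str = "genotype",
    min_n: int = 3,
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlation matrices across traits.

    ``grouping='overall'`` pools every row into one matrix; ``'per-genotype'``
    (or any value other than 'overall') returns one matrix per level of
    ``group_col``, pooling treatments within that level.  Cells with fewer
    than ``min_n`` complete pairs or zero variance are NaN (undefined), never
    silently 0.
    """
    traits = list(traits)
    missing = set(traits) - set(table.columns)
    if missing:
        raise ValueError(f"traits not in table: {sorted(missing)}")

    def corr(df: pd.DataFrame) -> pd.DataFrame:
        sub = df[traits].astype(float)
        r = sub.corr(method="pearson", min_periods=min_n)
        # pandas leaves the diagonal at 1 even for constant columns; a
        # zero-variance or under-sampled trait has no defined correlation
        for t in traits:
            col = sub[t].dropna()
            defined = col.size >= min_n and float(np.var(col)) > 0.0
            if not defined:
                r.loc[t, :] = np.nan
                r.loc[:, t] = np.nan
            else:
                r.at[t, t] = 1.0
        return r

    if grouping == "overall":
        return {"overall": corr(table)}
    return {
        str(level): corr(sub)
        for level, sub in table.groupby(group_col, sort=True)
    }
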