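"""Colony-level statistics: patriline rarefaction, Chao1 richness, and the
patriline caste-bias ANOVA with its detectable-effect-size simulation.

These summarize how thoroughly a colony's paternity has been sampled (how
many fathers, i.e. matings, the genotyped workers reveal) and whether a
continuous caste proxy such as centroid size or back-leg length differs
among patrilines.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RichnessEstimate",
    "AccumulationCurve",
    "patriline_accumulation",
    "chao1",
    "caste_anova",
    "AnovaResult",
    "anova_detectable_effect",
]


@dataclass
class RichnessEstimate:
    """Chao1 mating-frequency (patriline richness) estimate."""

    s_obs: int     # observed patrilines
    f1: int        # singletons (patrilines seen once)
    f2: int        # doubletons (patrilines seen twice)
    chao1: float   # estimated richness, >= s_obs


def _as_counts(labels_or_counts) -> np.ndarray:
    arr = list(labels_or_counts)
    if len(arr) == 0:
        raise ValueError("empty input: no observations")
    if all(isinstance(x, (int, np.integer)) for x in arr) and min(arr) >= 1:
        # already per-class abundances
        return np.asarray(arr, dtype=int)
    return np.asarray(list(Counter(map(str, arr)).values()), dtype=int)


def chao1(labels_or_counts) -> RichnessEstimate:
    """Chao1 richness: S_obs + F1^2 / (2 F2), falling back to the
    bias-corrected S_obs + F1 (F1 - 1) / 2 when no doubletons exist.

    Accepts either one patriline label per individual or per-patriline
    abundances (a sequence of positive integers).
    """
    counts = _as_counts(labels_or_counts)
    s_obs = int(len(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        est = s_obs + f1**2 / (2.0 * f2)
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0
    return RichnessEstimate(s_obs=s_obs, f1=f1, f2=f2, chao1=float(est))


@dataclass
class AccumulationCurve:
    """Bootstrap patriline accumulation (individual-based rarefaction)."""

    sample_sizes: np.ndarray      # m = 1..n
    mean_richness: np.ndarray     # mean distinct patrilines at each m
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_size": self.sample_sizes,
            "mean_patrilines": self.mean_richness,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def patriline_accumulation(labels: Sequence, n_boot: int = 1000,
                           seed: int = 0, ci: float = 0.95) -> AccumulationCurve:
    """Mean number of distinct patrilines among m individuals drawn without
    replacement, for m = 1..n, over ``n_boot`` bootstrap subsamples, with a
    percentile confidence band."""
    labels = np.asarray([str(x) for x in labels])
    n = labels.size
    if n < 1 or n_boot < 1:
        raise ValueError("need at least one label and one bootstrap draw")
    _, codes = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    richness = np.empty((n_boot, n), dtype=int)
    for b in range(n_boot):
        perm = rng.permutation(codes)
        # distinct classes among the first m of a random permutation == a
        # without-replacement subsample of size m
        first_seen = np.zeros(n, dtype=bool)
        seen = set()
        for i, c in enumerate(perm):
            if c not in seen:
                seen.add(c)
                first_seen[i] = True
        richness[b] = np.cumsum(first_seen)
    q = (1.0 - ci) / 2.0
    return AccumulationCurve(
        sample_sizes=np.arange(1, n + 1),
        mean_richness=richness.mean(axis=0),
        ci_low=np.quantile(richness, q, axis=0),
        ci_high=np.quantile(richness, 1.0 - q, axis=0),
        n_boot=n_boot, seed=int(seed),
    )


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA of a caste proxy among patrilines."""

    f_stat: float
    pvalue: float
    effect_size: float  # ML (population) SD of fitted patriline means
    df_between: int
    df_within: int
    group_means: dict

    def summary(self) -> str:
        return (
            f"One-way ANOVA among patrilines: F({self.df_between}, "
            f"{self.df_within}) = {self.f_stat:.3f}, p = {self.pvalue:.3g}; "
            f"effect size (SD of patriline means) = {self.effect_size:.4g}"
        )


def caste_anova(trait: Sequence[float], patrilines: Sequence) -> AnovaResult:
    """One-way ANOVA of a continuous caste proxy among patrilines.

    The effect summary is the ML estimate of the spread of patriline means:
    the size-weighted population SD of the fitted group means.
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray([str(x) for x in patrilines])
    if y.size != g.size:
        raise ValueError("trait and patriline vectors differ in length")
    groups = [y[g == lvl] for lvl in np.unique(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 patrilines")
    if any(len(gr) == 0 for gr in groups):
        raise ValueError("empty patriline group after filtering")
    if y.size - len(groups) < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    ssw = sum(float(((gr - gr.mean()) ** 2).sum()) for gr in groups)
    if ssw == 0.0:
        raise ValueError("zero residual variance: ANOVA undefined")
    f_stat, pvalue = stats.f_oneway(*groups)
    means = {lvl: float(y[g == lvl].mean()) for lvl in np.unique(g)}
    grand = float(y.mean())
    weights = np.array([np.sum(g == lvl) for lvl in np.unique(g)], float)
    mvec = np.array(list(means.values()))
    effect = float(np.sqrt(np.sum(weights * (mvec - grand) ** 2) / y.size))
    return AnovaResult(
        f_stat=float(f_stat), pvalue=float(pvalue), effect_size=effect,
        df_between=len(groups) - 1, df_within=int(y.size - len(groups)),
        group_means=means,
    )


def _standardized_pattern(n_groups: int) -> np.ndarray:
    """A fixed, centered group-mean pattern with unit population SD: the
    injected effect is then exactly the requested SD of patriline means."""
    c = np.arange(n_groups, dtype=float)
    c -= c.mean()
    return c / np.sqrt(np.mean(c**2))


def anova_detectable_effect(
    n: int,
    n_groups: int,
    residual_sd: float,
    effect_grid: Sequence[float],
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple:
    """Smallest simulated patriline-mean spread detectable by the ANOVA.

    For each candidate effect (the SD of injected patriline means), simulate
    ``n_reps`` balanced datasets of ``n`` individuals in ``n_groups``
    patrilines with Gaussian residual noise, run :func:`caste_anova` at level
    ``alpha``, and return ``(smallest_detectable_effect_or_None,
    detection_fractions)`` where detection requires a fraction > 0.5.
    """
    grid = np.asarray(list(effect_grid), dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("effect_grid must be non-empty and increasing")
    base, rem = divmod(n, n_groups)
    sizes = np.array([base + (1 if i < rem else 0) for i in range(n_groups)])
    labels = np.repeat(np.arange(n_groups), sizes)
    pattern = _standardized_pattern(n_groups)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    fractions = np.empty(grid.size)
    for j, eff in enumerate(grid):
        shifts = (eff * pattern)[labels]
        hits = 0
        for _ in range(n_reps):
            yobs = shifts + rng.normal(0.0, residual_sd, size=n)
            res = caste_anova(yobs, labels)
            hits += res.pvalue < alpha
        fractions[j] = hits / n_reps
    detectable = np.nonzero(fractions > 0.5)[0]
    smallest = float(grid[detectable[0]]) if detectable.size else None
    return smallest, fractions
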