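"""Dose-dependent protein displacement testing.

In a competition pulldown, proteins bound by an immobilized bait are
challenged with increasing concentrations of free compound; a true binder
is displaced, so its abundance falls monotonically with concentration.
The test combines three ingredients:

* an empirical-Bayes *moderated* one-way fit: each protein's residual
  variance ``s^2`` (with ``d`` residual degrees of freedom) is shrunk
  toward a prior ``s0^2`` with ``d0`` prior degrees of freedom estimated
  across all proteins by matching the moments of ``log s^2`` to a scaled
  F distribution (Smyth-style), giving the posterior variance
  ``s_post^2 = (d0*s0^2 + d*s^2) / (d0 + d)``;
* *monotonic contrasts*: for every cut point between consecutive
  concentration levels, a two-group t-statistic compares the samples at or
  below the cut with those above it, using the moderated variance; positive
  values mean displacement.  The per-protein statistic is the maximum of
  this t series;
* a Westfall-Young *step-down minP* permutation test, one-sided: the
  concentration labels are permuted (default 1000 times), the full pipeline
  including variance moderation is recomputed per permutation, per-protein
  raw p-values are taken from each protein's own permutation null with
  add-one smoothing ``p = (1 + #{perm >= obs}) / (B + 1)``, and the
  step-down minima of permutation p-values give family-wise adjusted
  p-values (single-pass variant sharing one permutation set, exceedance
  counts compared as integers).  Proteins with adjusted p below 5% are
  called specific binders.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

DEFAULT_LEVELS = (0.0, 0.5, 1.0, 5.0, 10.0)
ALPHA = 0.05


@dataclass(frozen=True)
class DoseDesign:
    """Sample-to-concentration mapping of a dose-response pulldown."""

    samples: tuple[str, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.concentrations):
            raise ValueError("samples and concentrations differ in length")
        if len(self.levels) < 2:
            raise ValueError("need at least two distinct concentration levels")

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted(set(self.concentrations)))

    @property
    def level_index(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.levels)}
        return np.array([lookup[c] for c in self.concentrations], dtype=int)

    @classmethod
    def from_table(cls, design: pd.DataFrame) -> "DoseDesign":
        return cls(
            samples=tuple(design["sample_id"].astype(str)),
            concentrations=tuple(design["concentration_uM"].astype(float)),
        )


@dataclass(frozen=True)
class ModeratedFit:
    """Per-protein group means and moderated variances."""

    protein_ids: tuple[str, ...]
    levels: tuple[float, ...]
    group_means: np.ndarray  # P x K
    group_counts: np.ndarray  # P x K
    s2: np.ndarray  # P
    df: np.ndarray  # P
    d0: float
    s0_sq: float
    s_post_sq: np.ndarray  # P

    @property
    def df_total(self) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(self.df, np.inf, dtype=float)
        return self.df + self.d0


# ---------------------------------------------------------------------------
# Variance moderation (empirical Bayes on log residual variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s0^2) and return posterior variances.

    Moment matching on ``e = log s^2 - digamma(d/2) + log(d/2)``: under the
    scaled-F model, ``E[e] = log s0^2 + digamma(d0/2) - log(d0/2)`` and
    ``Var[e] = trigamma(d/2) + trigamma(d0/2)``.  Sums are taken over sorted
    values so the estimate is exactly invariant to protein order.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    informative = np.isfinite(s2) & (df > 0)
    if informative.sum() < 2:
        raise ValueError("variance moderation needs >=2 proteins with residual df")
    use = informative & (s2 > 0)
    if use.sum() == 0:
        raise ValueError("all residual variances are zero; nothing to moderate")
    if use.sum() == 1:
        # spread not estimable from a single positive variance
        d0, s0_sq = math.inf, float(s2[use][0])
        return d0, s0_sq, posterior_variances(s2, df, d0, s0_sq)
    z = np.log(s2[use])
    if np.ptp(z) == 0.0 and use.sum() == informative.sum():
        # exactly degenerate: every variance identical -> point-mass prior
        d0, s0_sq = math.inf, float(s2[use][0])
        return d0, s0_sq, posterior_variances(s2, df, d0, s0_sq)
    e = z - special.digamma(df[use] / 2.0) + np.log(df[use] / 2.0)
    n = e.size
    e_sorted = np.sort(e)
    emean = float(e_sorted.sum()) / n
    dev = np.sort((e - emean) ** 2)
    evar = float(dev.sum()) / (n - 1) - float(
        np.sort(special.polygamma(1, df[use] / 2.0)).sum()
    ) / n
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    s_post = posterior_variances(s2, df, d0, s0_sq)
    return d0, s0_sq, s_post


def posterior_variances(
    s2: np.ndarray, df: np.ndarray, d0: float, s0_sq: float
) -> np.ndarray:
    s2c = np.where(np.isfinite(s2) & (df > 0), s2, 0.0)
    dfc = np.where(df > 0, df, 0.0)
    if math.isinf(d0):
        return np.full(s2c.shape, s0_sq)
    return (d0 * s0_sq + dfc * s2c) / (d0 + dfc)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray, level_idx: np.ndarray, n_levels: int):
    """Group sums/counts and residual variance of a one-way layout.

    ``values`` is P x N with NaN for missing; returns per-protein per-level
    counts and sums, residual variance s^2 and residual df.
    """
    present = ~np.isnan(values)
    vals = np.where(present, values, 0.0)
    ind = np.zeros((values.shape[1], n_levels))
    ind[np.arange(values.shape[1]), level_idx] = 1.0
    counts = present @ ind  # P x K
    sums = vals @ ind
    sqs = (vals ** 2) @ ind
    means0 = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    ss_within = (sqs - counts * means0 ** 2).sum(axis=1)
    n_obs = present.sum(axis=1)
    k_obs = (counts > 0).sum(axis=1)
    df = (n_obs - k_obs).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df > 0, ss_within / np.maximum(df, 1), np.nan)
    # guard tiny negative round-off
    s2 = np.where(np.isfinite(s2) & (s2 < 0), 0.0, s2)
    return counts, sums, s2, df


def _cut_t_stats(
    counts: np.ndarray, sums: np.ndarray, s_post: np.ndarray
) -> np.ndarray:
    """Monotonic-contrast t per cut: mean(levels <= cut) - mean(levels > cut),
    scaled by the moderated standard error.  P x (K-1); NaN where a side is
    empty."""
    ccum = counts.cumsum(axis=1)
    scum = sums.cumsum(axis=1)
    n_tot = ccum[:, -1:]
    s_tot = scum[:, -1:]
    n_low = ccum[:, :-1]
    n_high = n_tot - n_low
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_low = scum[:, :-1] / n_low
        mean_high = (s_tot - scum[:, :-1]) / n_high
        se = np.sqrt(s_post[:, None] * (1.0 / n_low + 1.0 / n_high))
        t = (mean_low - mean_high) / se
    t = np.where((n_low > 0) & (n_high > 0) & (se > 0), t, np.nan)
    return t


def _pipeline_max_t(
    values: np.ndarray,
    level_idx: np.ndarray,
    n_levels: int,
    frozen: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """max-t per protein for one labelling; re-estimates moderation unless
    (d0, s0_sq) is frozen.  Returns (max_t, t_matrix, (d0, s0_sq))."""
    counts, sums, s2, df = _group_stats(values, level_idx, n_levels)
    if frozen is None:
        d0, s0_sq, s_post = squeeze_variances(s2, df)
    else:
        d0, s0_sq = frozen
        s_post = posterior_variances(s2, df, d0, s0_sq)
    t = _cut_t_stats(counts, sums, s_post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_t = np.nanmax(t, axis=1)
    return max_t, t, (d0, s0_sq)


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def _check_matrix(matrix: pd.DataFrame, design: DoseDesign) -> np.ndarray:
    missing = [s for s in design.samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks design samples: {missing}")
    return matrix[list(design.samples)].to_numpy(dtype=float)


def fit_moderated(matrix: pd.DataFrame, design: DoseDesign) -> ModeratedFit:
    """Moderated one-way group-mean fit of a protein x sample log-abundance
    matrix against the concentration design."""
    values = _check_matrix(matrix, design)
    level_idx = design.level_index
    n_levels = len(design.levels)
    counts, sums, s2, df = _group_stats(values, level_idx, n_levels)
    d0, s0_sq, s_post = squeeze_variances(s2, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ModeratedFit(
        protein_ids=tuple(str(i) for i in matrix.index),
        levels=design.levels,
        group_means=means,
        group_counts=counts,
        s2=s2,
        df=df,
        d0=d0,
        s0_sq=s0_sq,
        s_post_sq=s_post,
    )


def monotonic_contrast_ts(fit: ModeratedFit) -> pd.DataFrame:
    """t statistic per cut point (one column per below/above split)."""
    sums = np.where(fit.group_counts > 0, fit.group_means * fit.group_counts, 0.0)
    t = _cut_t_stats(fit.group_counts, sums, fit.s_post_sq)
    cols = [f"t_le_{lvl:g}" for lvl in fit.levels[:-1]]
    return pd.DataFrame(t, index=list(fit.protein_ids), columns=cols)


def max_t(t_series: Sequence[float] | np.ndarray) -> float:
    """Maximum of a t series; NaN cuts ignored, empty series -> NaN."""
    arr = np.asarray(t_series, dtype=float)
    valid = arr[np.isfinite(arr)]
    return float(valid.max()) if valid.size else math.nan


# ---------------------------------------------------------------------------
# Step-down minP permutation test
# ---------------------------------------------------------------------------

def _distinct_assignments(level_idx: np.ndarray) -> list[np.ndarray]:
    return [np.array(p, dtype=int) for p in multiset_permutations(level_idx.tolist())]


def permute_and_minp(
    matrix: pd.DataFrame,
    design: DoseDesign,
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    remoderate: bool = True,
    alpha: float = ALPHA,
    bh_after_minp: bool = False,
) -> pd.DataFrame:
    """Displacement test with Westfall-Young step-down minP adjustment.

    Concentration labels are permuted across all samples; the full pipeline
    (moderation included, unless ``remoderate=False`` freezes the observed
    prior) is recomputed per permutation.  With ``exhaustive=True`` all
    distinct label assignments are enumerated instead of sampling and the
    resulting p-values are exact.  ``bh_after_minp`` applies an additional
    Benjamini-Hochberg pass over the step-down p-values into ``p_adj``.

    A protein is tested only if every concentration level retains at least
    one observation; untested proteins get missing statistics and are never
    called binders.  Binder = adjusted p < ``alpha``.
    """
    if not exhaustive and n_permutations < 1:
        raise ValueError("need at least one permutation")
    values = _check_matrix(matrix, design)
    level_idx = design.level_index
    n_levels = len(design.levels)
    frozen = None
    obs_max, obs_t, obs_prior = _pipeline_max_t(values, level_idx, n_levels)
    if not remoderate:
        frozen = obs_prior
    tested = np.all(_group_stats(values, level_idx, n_levels)[0] > 0, axis=1) & np.isfinite(
        obs_max
    )
    n_proteins = values.shape[0]

    if exhaustive:
        labellings = _distinct_assignments(level_idx)
        null_cols = [
            _pipeline_max_t(values, lab, n_levels, frozen)[0] for lab in labellings
        ]
        denom = len(labellings)
        add_one = 0
    else:
        rng = np.random.default_rng(seed)
        null_cols = []
        for _ in range(n_permutations):
            perm = rng.permutation(level_idx.size)
            null_cols.append(
                _pipeline_max_t(values, level_idx[perm], n_levels, frozen)[0]
            )
        denom = n_permutations + 1
        add_one = 1
    null_stats = np.column_stack(null_cols)  # P x B
    # a labelling that empties a level for some protein yields no statistic;
    # such columns never exceed the observation
    null_stats = np.where(np.isnan(null_stats), -np.inf, null_stats)
    if not exhaustive and 1.0 / denom > alpha:
        warnings.warn(
            f"minimum attainable raw p-value {1.0 / denom:.3g} exceeds "
            f"alpha={alpha}; increase n_permutations"
        )

    # integer exceedance counts; comparisons stay exact
    raw_counts = add_one + (null_stats >= obs_max[:, None]).sum(axis=1).astype(int)
    # per-column counts within each protein's own null (self-inclusive)
    col_counts = np.zeros_like(null_stats, dtype=int)
    for j in range(n_proteins):
        if not tested[j]:
            continue
        row = null_stats[j]
        order = np.argsort(-row, kind="mergesort")
        sorted_vals = row[order]
        # number of entries >= each value (ties share the larger count)
        ge = np.searchsorted(-sorted_vals, -sorted_vals, side="right")
        col_counts[j, order] = add_one + ge
    p_raw = np.where(tested, raw_counts / denom, np.nan)

    # step-down over tested proteins ordered by raw count (ties: larger stat first)
    idx = np.flatnonzero(tested)
    order = idx[np.lexsort((idx, -obs_max[idx], raw_counts[idx]))]
    m = order.size
    p_adj = np.full(n_proteins, np.nan)
    if m:
        cc = col_counts[order]  # m x B
        q = np.minimum.accumulate(cc[::-1], axis=0)[::-1]
        hits = (q <= raw_counts[order][:, None]).sum(axis=1)
        adj = (add_one + hits) / denom
        adj = np.minimum(np.maximum.accumulate(adj), 1.0)
        p_adj[order] = adj
    if bh_after_minp and m:
        p_adj[order] = multipletests(p_adj[order], method="fdr_bh")[1]

    binder = np.zeros(n_proteins, dtype=bool)
    binder[tested] = p_adj[tested] < alpha
    out = pd.DataFrame(
        obs_t,
        index=[str(i) for i in matrix.index],
        columns=[f"t_le_{lvl:g}" for lvl in design.levels[:-1]],
    )
    out.insert(0, "tested", tested)
    out["max_t"] = np.where(tested, obs_max, np.nan)
    out["p_minp"] = p_raw
    out["p_adj"] = p_adj
    out["binder"] = binder
    out.index.name = "protein_id"
    return out
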