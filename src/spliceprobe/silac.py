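"""SILAC affinity-enrichment statistics for chemical proteomics.

Heavy/light pulldown ratios (active vs. inactive bait) are harmonized —
label-swapped samples are inverted back, all ratios log2-transformed — and
protein rows pass a filter chain: at least two quantified peptides, a
search-engine score above 31, quantified in at least 7 of 10 samples, and
only the gel band where a protein was found with the highest abundance is
kept.  A one-sided one-sample t-test against a mean log-ratio of zero,
Benjamini-Hochberg adjusted across proteins, calls a protein enriched when
the adjusted p-value is at most 5% and the fold change between groups
exceeds 1.5.  Category enrichment of the hit list against the background is
assessed with one-sided Fisher exact tests (cutoff 0.001), optionally after
removing a protein set (e.g. ribosomal proteins) from both lists.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RATIO_PREFIX = "ratio_"

MIN_PEPTIDES = 2
MIN_SCORE = 31.0
MIN_SAMPLES = 7
ALPHA = 0.05
FOLD = 1.5
FISHER_CUTOFF = 1e-3


def ratio_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(RATIO_PREFIX)]


def harmonize_ratios(
    table: pd.DataFrame, swapped_samples: Iterable[str] = ()
) -> pd.DataFrame:
    """Log2 ratio matrix with label-swapped samples inverted back.

    ``table`` holds linear H:L ratios in ``ratio_<sample>`` columns;
    ``swapped_samples`` names the samples whose labels were reversed, so
    their ratios are inverted (r -> 1/r) before the log2 transform.
    Non-positive ratios are set missing with a warning.
    """
    cols = ratio_columns(table)
    swapped = set(swapped_samples)
    unknown = swapped - {c[len(RATIO_PREFIX):] for c in cols}
    if unknown:
        raise ValueError(f"swapped samples not in table: {sorted(unknown)}")
    mat = table[cols].astype(float).copy()
    bad = (mat <= 0).to_numpy()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-positive ratios set to missing")
        mat = mat.mask(mat <= 0)
    for col in cols:
        if col[len(RATIO_PREFIX):] in swapped:
            mat[col] = 1.0 / mat[col]
    return np.log2(mat)


def filter_protein_table(
    table: pd.DataFrame,
    min_peptides: int = MIN_PEPTIDES,
    min_score: float = MIN_SCORE,
    min_samples: int = MIN_SAMPLES,
) -> pd.DataFrame:
    """Apply the protein-level filter chain; idempotent.

    Retains rows with ``n_quant_peptides >= min_peptides``, ``score`` strictly
    above ``min_score`` and a non-missing ratio in at least ``min_samples``
    samples; of multiple gel-band rows per protein, only the one with the
    highest abundance (an ``intensity`` column when present, otherwise the
    quantified-peptide count) survives.
    """
    cols = ratio_columns(table)
    detected = table[cols].notna().sum(axis=1)
    keep = (
        (table["n_quant_peptides"] >= min_peptides)
        & (table["score"] > min_score)
        & (detected >= min_samples)
    )
    out = table.loc[keep]
    abundance = (
        out["intensity"] if "intensity" in out.columns else out["n_quant_peptides"]
    )
    # stable best-band pick: highest abundance, ties by band_id then position
    order = out.assign(_abundance=abundance)
    order = order.sort_values(
        ["protein_id", "_abundance", "band_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    best = order.drop_duplicates("protein_id", keep="first").drop(columns="_abundance")
    return best.sort_index()


def test_enrichment(
    log2_matrix: pd.DataFrame,
    protein_ids: Sequence[str] | None = None,
    alpha: float = ALPHA,
    fold: float = FOLD,
    fold_scale: str = "linear",
) -> pd.DataFrame:
    """One-sided one-sample t-tests (mean log2 ratio > 0) with BH adjustment.

    ``fold_scale='linear'`` calls a protein enriched when the adjusted
    p-value is <= ``alpha`` and the mean linear ratio exceeds ``fold``
    (mean log2 > log2(fold)); ``fold_scale='log2'`` instead requires the mean
    log2 ratio itself to exceed ``fold``.  Proteins with fewer than two
    quantified ratios get a missing p-value and are never called enriched.
    """
    if fold_scale not in ("linear", "log2"):
        raise ValueError("fold_scale must be 'linear' or 'log2'")
    vals = log2_matrix.to_numpy(dtype=float)
    n = np.sum(~np.isnan(vals), axis=1)
    total = np.nansum(vals, axis=1)
    mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    ok = n >= 2
    sd = np.full(len(vals), np.nan)
    if ok.any():
        sq = np.nansum((vals - mean[:, None]) ** 2, axis=1)
        sd[ok] = np.sqrt(sq[ok] / (n[ok] - 1))
    t = np.full(len(vals), np.nan)
    for i in range(len(vals)):
        if not ok[i]:
            continue
        if sd[i] == 0:
            t[i] = 0.0 if mean[i] == 0 else math.copysign(math.inf, mean[i])
        else:
            t[i] = mean[i] / (sd[i] / math.sqrt(n[i]))
    p = np.full(len(vals), np.nan)
    p[ok] = stats.t.sf(t[ok], df=n[ok] - 1)
    p_adj = np.full(len(vals), np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    threshold = math.log2(fold) if fold_scale == "linear" else fold
    enriched = ok & (p_adj <= alpha) & (mean > threshold)
    index = (
        list(protein_ids) if protein_ids is not None else list(log2_matrix.index)
    )
    return pd.DataFrame(
        {
            "protein_id": index,
            "n": n,
            "mean_log2_ratio": mean,
            "t_statistic": t,
            "p_value": p,
            "p_adj": p_adj,
            "enriched": enriched,
        }
    ).set_index("protein_id")


def silac_enrich(
    table: pd.DataFrame,
    swapped_samples: Iterable[str] = (),
    min_peptides: int = MIN_PEPTIDES,
    min_score: float = MIN_SCORE,
    min_samples: int = MIN_SAMPLES,
    alpha: float = ALPHA,
    fold: float = FOLD,
    fold_scale: str = "linear",
) -> pd.DataFrame:
    """Full pipeline: filter chain, ratio harmonization, enrichment tests."""
    filtered = filter_protein_table(table, min_peptides, min_score, min_samples)
    log2 = harmonize_ratios(filtered, swapped_samples)
    return test_enrichment(
        log2,
        protein_ids=filtered["protein_id"].tolist(),
        alpha=alpha,
        fold=fold,
        fold_scale=fold_scale,
    )


def fisher_category_enrichment(
    hits: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    p_cutoff: float = FISHER_CUTOFF,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """One-sided Fisher exact category enrichment of hits vs. background.

    ``annotation`` maps protein id -> iterable of category ids.  When
    ``exclude`` is non-empty (e.g. ribosomal proteins), both hit and
    background lists are re-derived without those ids before testing.
    Returns one row per category present in the background with hit count,
    background count, p-value, -log10 p and the ``enriched`` call at
    ``p_cutoff``.
    """
    excl = set(exclude)
    bg = sorted(set(background) - excl)
    hit = sorted(set(hits) - excl)
    if not bg:
        raise ValueError("background set is empty")
    if not set(hit) <= set(bg):
        raise ValueError("hits must be a subset of the background")
    cats: dict[str, set[str]] = {}
    for pid in bg:
        for cat in annotation.get(pid, ()):
            cats.setdefault(cat, set()).add(pid)
    rows = []
    n_bg = len(bg)
    n_hit = len(hit)
    hit_set = set(hit)
    for cat in sorted(cats):
        members = cats[cat]
        a = len(members & hit_set)  # hits in category
        b = n_hit - a
        c = len(members) - a  # non-hit background in category
        d = (n_bg - n_hit) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "category_id": cat,
                "hit_count": a,
                "background_count": len(members),
                "p_value": p,
                "neg_log10_p": -math.log10(p) if p > 0 else math.inf,
                "enriched": p <= p_cutoff,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category_id",
            "hit_count",
            "background_count",
            "p_value",
            "neg_log10_p",
            "enriched",
        ],
    )
    return out.sort_values(["p_value", "category_id"], kind="mergesort").reset_index(
        drop=True
    )
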