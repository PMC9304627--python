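"""Differential abundance of taxa between strata.

Taxa are screened by mean relative abundance (>= 1% in at least one
group/timepoint stratum by default), then compared with rank tests: Mann-
Whitney U for the two unpaired contrasts (CTRL vs ERA-T0 and CTRL vs ERA-T1)
and the subject-matched Wilcoxon signed-rank test for ERA T0 vs T1.
Benjamini-Hochberg FDR correction is applied independently within each
contrast family; both raw p and q are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import strata
from .stats import bh_fdr, mann_whitney_u, wilcoxon_signed_rank

__all__ = ["select_abundant_taxa", "compare_taxa", "CONTRASTS"]

CONTRASTS = ("CTRL_vs_ERA-T0", "CTRL_vs_ERA-T1", "ERA-T0_vs_ERA-T1")


def select_abundant_taxa(
    rel: pd.DataFrame, meta: pd.DataFrame, threshold: float = 0.01
) -> list[str]:
    """Taxa whose mean relative abundance reaches ``threshold`` in >= 1 stratum."""
    keep: list[str] = []
    group_means = {
        label: rel.loc[rel.index.intersection(idx)].mean(axis=0)
        for label, idx in strata(meta).items()
    }
    for taxon in rel.columns:
        if any(means[taxon] >= threshold for means in group_means.values()):
            keep.append(taxon)
    return keep


def _paired_diffs(rel: pd.DataFrame, meta: pd.DataFrame, taxon: str) -> np.ndarray:
    era = meta[meta["group"] == "ERA"]
    diffs = []
    for subject, block in era.groupby("subject_id"):
        t0 = block.index[block["timepoint"] == "T0"]
        t1 = block.index[block["timepoint"] == "T1"]
        if len(t0) != 1 or len(t1) != 1 or t0[0] not in rel.index or t1[0] not in rel.index:
            warnings.warn(f"subject {subject!r} lacks a paired sample; dropped", stacklevel=3)
            continue
        diffs.append(rel.at[t1[0], taxon] - rel.at[t0[0], taxon])
    return np.asarray(diffs, dtype=float)


def compare_taxa(
    rel: pd.DataFrame, meta: pd.DataFrame, taxa, rank: str | None = None
) -> pd.DataFrame:
    """Rank-test each taxon across the three design contrasts.

    Parameters
    ----------
    rel : DataFrame
        Relative abundances, samples x taxa (rows sum to 1).
    meta : DataFrame
        Validated metadata (group/timepoint/subject_id).
    taxa : sequence of str
        Taxa to test (typically from :func:`select_abundant_taxa`).
    rank : str, optional
        Annotation only (e.g. "genus" or "species").

    Returns
    -------
    DataFrame with one row per (taxon, contrast): per-stratum mean relative
    abundances, test name, statistic, raw p and BH-FDR q (corrected within
    each contrast family).
    """
    taxa = list(taxa)
    missing = [t for t in taxa if t not in rel.columns]
    if missing:
        raise KeyError(f"taxa not in table: {missing[:5]}")
    groups = strata(meta)
    means = {
        label: rel.loc[rel.index.intersection(idx), taxa].mean(axis=0)
        for label, idx in groups.items()
    }
    records = []
    for contrast in CONTRASTS:
        left, right = contrast.split("_vs_")
        paired = contrast == "ERA-T0_vs_ERA-T1"
        pvals, stats_, names = [], [], []
        for taxon in taxa:
            if paired:
                diffs = _paired_diffs(rel, meta, taxon)
                try:
                    stat, p = wilcoxon_signed_rank(diffs)
                except ValueError:  # all differences zero -> no evidence
                    stat, p = 0.0, 1.0
                names.append("wilcoxon_signed_rank")
            else:
                x = rel.loc[rel.index.intersection(groups[left]), taxon]
                y = rel.loc[rel.index.intersection(groups[right]), taxon]
                stat, p = mann_whitney_u(x, y)
                names.append("mann_whitney_u")
            stats_.append(stat)
            pvals.append(p)
        qvals = bh_fdr(pvals)
        for taxon, name, stat, p, q in zip(taxa, names, stats_, pvals, qvals):
            rec = {
                "taxon": taxon,
                "rank": rank,
                "contrast": contrast,
                "test": name,
                "statistic": stat,
                "p": p,
                "q": q,
            }
            for label in groups:
                rec[f"mean_{label}"] = float(means[label][taxon])
            records.append(rec)
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["contrast", "q", "p"], kind="mergesort").reset_index(drop=True)
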