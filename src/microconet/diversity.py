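"""Alpha/beta diversity, ordination and distance-based group comparisons.

Alpha diversity is computed per sample on (rarefied) counts:

* Shannon index ``H = -sum p_i ln p_i`` (natural log by default; base-2
  available via ``base``),
* Simpson index reported on the probability scale as ``1 - sum p_i**2``
  (the probability that two random reads belong to different taxa),
* observed richness (number of taxa with count > 0).

Beta diversity offers the Bray-Curtis dissimilarity on counts and the
presence/absence (unweighted) UniFrac distance on a phylogeny; both live in
[0, 1]. Ordination is classical scaling (PCoA) and the between-group test is
a permutational ANOVA (PERMANOVA) on the distance matrix with a
seed-reproducible permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix, TreeNode

from .io import CountTable, strata
from .stats import wilcoxon_signed_rank

__all__ = [
    "alpha_diversity",
    "rarefaction_curves",
    "bray_curtis",
    "unweighted_unifrac",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
    "pc1_paired_test",
]


def alpha_diversity(table: CountTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon, Simpson (1-D) and observed richness.

    Parameters
    ----------
    table : CountTable
    base : float, optional
        Logarithm base for Shannon; natural log when None.

    Returns
    -------
    pandas.DataFrame indexed by sample with columns
    ``shannon``, ``simpson``, ``observed_otus``.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -(p * logs).sum(axis=1)
    if base is not None:
        shannon = shannon / np.log(base)
    simpson = 1.0 - (p**2).sum(axis=1)
    observed = (counts > 0).sum(axis=1)
    return pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "observed_otus": observed},
        index=table.data.index,
    )


def rarefaction_curves(
    table: CountTable,
    meta: pd.DataFrame,
    depths,
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Group-averaged rarefaction curves with t-based 95% CIs.

    For each depth, each sample with total >= depth is subsampled ``reps``
    times without replacement; the sample's value at that depth is the mean
    over replicates, and the group summary is the mean with a t-based 95%
    confidence interval across samples. Strata with no surviving sample at a
    depth are omitted with a warning.
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly ascending")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    groups = strata(meta)
    records = []
    for depth in depths:
        # per-sample replicate-averaged indices at this depth
        values: dict[str, pd.Series] = {}
        for s in table.data.index:
            if totals[s] < depth:
                continue
            row = table.data.loc[s].to_numpy()
            reps_idx = np.empty((reps, 3))
            for r in range(reps):
                sub = rng.multivariate_hypergeometric(row, depth)
                p = sub / depth
                nz = p[p > 0]
                reps_idx[r] = (
                    -(nz * np.log(nz)).sum(),
                    1.0 - (nz**2).sum(),
                    (sub > 0).sum(),
                )
            values[s] = pd.Series(
                reps_idx.mean(axis=0), index=["shannon", "simpson", "observed_otus"]
            )
        for label, idx in groups.items():
            present = [s for s in idx if s in values]
            if not present:
                warnings.warn(
                    f"stratum {label} has no sample at depth {depth}", stacklevel=2
                )
                continue
            block = pd.DataFrame([values[s] for s in present])
            n = len(present)
            mean = block.mean(axis=0)
            if n > 1:
                half = (
                    sps.t.ppf(0.975, n - 1) * block.std(axis=0, ddof=1) / np.sqrt(n)
                )
            else:
                half = pd.Series(np.nan, index=mean.index)
            for index_name in block.columns:
                records.append(
                    {
                        "stratum": label,
                        "depth": depth,
                        "index": index_name,
                        "mean": mean[index_name],
                        "ci_low": mean[index_name] - half[index_name],
                        "ci_high": mean[index_name] + half[index_name],
                        "n": n,
                    }
                )
    return pd.DataFrame.from_records(records)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on counts:

    ``d(a, b) = 1 - 2 sum_i min(a_i, b_i) / (sum a + sum b)``.
    """
    x = table.counts.astype(float)
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / (totals[i] + totals[i + 1 :])
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac distance.

    ``d(a, b)`` is the branch length of the tree leading only to taxa present
    in exactly one of the two samples, divided by the branch length leading
    to taxa present in either.
    """
    tips = {t.name for t in tree.tips()}
    present_any = [
        t for t, c in zip(table.taxon_ids, (table.counts > 0).any(axis=0)) if c
    ]
    missing = [t for t in present_any if t not in tips]
    if missing:
        raise KeyError(f"taxon {missing[0]!r} absent from the tree")
    presence = pd.DataFrame(
        table.counts > 0, index=table.data.index, columns=table.taxon_ids
    )
    col = {t: j for j, t in enumerate(table.taxon_ids)}
    n = presence.shape[0]
    rows_l: list[float] = []
    rows_p: list[np.ndarray] = []
    # postorder pass: each internal branch subtends the union of its children
    node_presence: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in col:
                vec = presence.iloc[:, col[node.name]].to_numpy()
            else:
                vec = np.zeros(n, dtype=bool)
        else:
            vec = np.zeros(n, dtype=bool)
            for child in node.children:
                vec = vec | node_presence[id(child)]
        node_presence[id(node)] = vec
        if node.is_root():
            continue
        length = node.length or 0.0
        if length > 0:
            rows_l.append(length)
            rows_p.append(vec)
    if not rows_p:
        raise ValueError("tree has no branches with positive length")
    P = np.asarray(rows_p, dtype=float)  # branches x samples
    L = np.asarray(rows_l)
    shared = (P * L[:, None]).T @ P
    total = (P * L[:, None]).sum(axis=0)
    union = total[:, None] + total[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, 1.0 - shared / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a distance matrix.

    Attributes
    ----------
    coordinates : DataFrame, samples x axes (PC1, PC2, ...).
    eigenvalues : all eigenvalues, sorted descending (negatives included).
    proportion_explained : percent of variance per retained axis, computed
        from the positive eigenvalues only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by double-centred eigendecomposition.

    Axes with positive eigenvalue are retained; negative eigenvalues are
    reported but excluded from the percent-variance denominator. The sign of
    each axis is fixed so that the sample with the largest absolute
    coordinate is positive.
    """
    d = dm.data
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite values")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals[0])) if n else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    pct = 100.0 * eigvals[pos] / eigvals[pos].sum()
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=pct,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def permanova(
    dm: DistanceMatrix, labels, n_perm: int = 1000, seed: int | None = None
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic partitions the total sum of squared distances into
    among- and within-group components; significance comes from ``n_perm``
    random relabelings, with ``p = (1 + #{F* >= F}) / (n_perm + 1)``.
    """
    labels = np.asarray(pd.Series(labels, index=list(dm.ids)).loc[list(dm.ids)])
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    n = len(labels)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    d2 = dm.data**2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(perm_inv: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            idx = np.flatnonzero(perm_inv == g)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        ss_among = ss_total - ss_within
        return (ss_among / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            count_ge += 1
    p = (1.0 + count_ge) / (n_perm + 1.0)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p), n_permutations=n_perm)


def pc1_paired_test(ordination: OrdinationResult, meta: pd.DataFrame) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on PC1 between timepoints.

    For each ERA subject with both T0 and T1 samples in the ordination, the
    difference PC1(T1) - PC1(T0) enters a two-sided Wilcoxon signed-rank
    test. Subjects missing a timepoint are dropped with a warning.
    """
    coords = ordination.coordinates["PC1"]
    era = meta[meta["group"] == "ERA"]
    diffs = []
    for subject, block in era.groupby("subject_id"):
        t0 = block.index[block["timepoint"] == "T0"]
        t1 = block.index[block["timepoint"] == "T1"]
        if len(t0) != 1 or len(t1) != 1 or t0[0] not in coords.index or t1[0] not in coords.index:
            warnings.warn(f"subject {subject!r} lacks a paired sample; dropped", stacklevel=2)
            continue
        diffs.append(coords[t1[0]] - coords[t0[0]])
    if not diffs:
        raise ValueError("no paired subjects available")
    return wilcoxon_signed_rank(np.asarray(diffs))
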