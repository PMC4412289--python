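"""Parental-strain analysis: normalization, QC, stress-induction calling,
strain effects on induction, and the fold-change correlation network.

Counts are normalized between samples with trimmed-mean-of-M-values (TMM)
factors.  Induction is called per strain by an exact two-group negative
binomial test on library-equalized pooled counts with a common
method-of-moments dispersion; a gene counts as ER-stress induced when its
point estimate is at least 1.5-fold up and the within-strain BH q-value is
at or below 1%.  Strain effects on the TM response are tested by one-way
ANOVA on per-replicate log2 fold changes versus the median control.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneCountMatrix
from .stats import bh_fdr, nb_exact_test, one_way_anova, spearman_correlation

__all__ = [
    "QCError",
    "tmm_factors",
    "qc_condition_outliers",
    "estimate_common_dispersion",
    "test_induction",
    "induced_gene_sets",
    "fold_change_table",
    "strain_effect",
    "correlation_network",
    "INDUCTION_FOLD",
    "INDUCTION_FDR",
]

#: linear-scale fold-change threshold for the induced-gene definition
INDUCTION_FOLD = 1.5
#: FDR threshold for the induced-gene definition
INDUCTION_FDR = 0.01


class QCError(RuntimeError):
    """Outlier removal would leave too few replicates."""


def tmm_factors(
    matrix: GeneCountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For every other sample, M (log2
    ratio of count fractions) and A (average log2 abundance) values over
    genes expressed in both are doubly trimmed (``trim_m`` per M tail,
    ``trim_a`` per A tail) and averaged with delta-method precision
    weights.  Factors are rescaled to geometric mean 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    frac = counts / lib
    uq = np.array([np.quantile(frac[:, j][counts[:, j] > 0], 0.75) if (counts[:, j] > 0).any() else 0 for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if ok.sum() < 10:
            continue
        x, r = counts[ok, j], counts[ok, ref]
        m = np.log2((x / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((x / lib[j]) * (r / lib[ref]))
        w = 1.0 / ((lib[j] - x) / (lib[j] * x) + (lib[ref] - r) / (lib[ref] * r))
        keep = (
            (m >= np.quantile(m, trim_m))
            & (m <= np.quantile(m, 1 - trim_m))
            & (a >= np.quantile(a, trim_a))
            & (a <= np.quantile(a, 1 - trim_a))
        )
        if keep.sum() == 0:
            continue
        log_factors[j] = (w[keep] * m[keep]).sum() / w[keep].sum()
    log_factors -= log_factors.mean()
    return pd.Series(2.0 ** log_factors, index=matrix.counts.columns, name="tmm_factor")


def _two_means(points: np.ndarray) -> np.ndarray:
    """Deterministic 2-means on a small point cloud (Lloyd iterations,
    centers initialized at the two most distant points)."""
    d = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    centers = points[[i, j]].copy()
    labels = np.zeros(len(points), dtype=int)
    for _ in range(50):
        dist = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_labels = dist.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for k in (0, 1):
            if (labels == k).any():
                centers[k] = points[labels == k].mean(axis=0)
    return labels


def qc_condition_outliers(matrix: GeneCountMatrix, strain: str) -> list[str]:
    """Identify samples not clustering with their own condition.

    Projects log-normalized counts of one strain's samples onto the first
    two principal components, partitions them by 2-means, and flags samples
    whose cluster's majority condition differs from their own.  Removal is
    attempted only when the two clusters are well separated and carry
    different majority conditions; overlapping condition clouds yield an
    empty list.  Raises :class:`QCError` if removal would leave fewer than
    two replicates in any condition.
    """
    ids = matrix.strain_samples(strain)
    if not ids:
        raise ValueError(f"no samples for strain {strain!r}")
    sub = matrix.counts[ids].to_numpy(dtype=float)
    lib = sub.sum(axis=0)
    logcpm = np.log2(sub / lib * 1e6 + 1.0)
    centered = logcpm - logcpm.mean(axis=1, keepdims=True)
    # PCA on samples via SVD of the gene x sample matrix
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    proj = vt[:2].T * sv[:2]
    labels = _two_means(proj)
    conditions = matrix.samples.loc[ids, "condition"].to_numpy()
    majorities = []
    for k in (0, 1):
        members = conditions[labels == k]
        conds, counts_k = np.unique(members, return_counts=True)
        # a cluster "is" a condition only when at least two thirds of its
        # members agree; anything weaker means the conditions overlap
        if len(conds) and counts_k.max() >= 2 / 3 * len(members):
            majorities.append(conds[np.argmax(counts_k)])
        else:
            majorities.append(None)
    if None in majorities or majorities[0] == majorities[1]:
        return []
    centers = np.array([proj[labels == k].mean(axis=0) for k in (0, 1)])
    between = np.linalg.norm(centers[0] - centers[1])
    within = np.sqrt(
        np.mean(
            [
                ((proj[labels == k] - centers[k]) ** 2).sum(axis=1).mean()
                for k in (0, 1)
                if (labels == k).any()
            ]
        )
    )
    if within > 0 and between < 2.0 * within:
        return []  # conditions not separable; nothing to remove
    removed = [
        sid
        for sid, lab, cond in zip(ids, labels, conditions)
        if majorities[lab] != cond
    ]
    if removed:
        remaining = matrix.samples.loc[[s for s in ids if s not in removed]]
        for condition, group in remaining.groupby("condition"):
            if len(group) < 2:
                raise QCError(
                    f"removing outliers would leave {len(group)} replicate(s) "
                    f"for strain {strain!r}, condition {condition!r}"
                )
    return removed


def _pseudo_counts(
    matrix: GeneCountMatrix, ids: list[str], ref: float | None = None
) -> np.ndarray:
    """Counts scaled to a common effective library size.

    ``ref`` must be shared by every group entering one comparison;
    defaults to the geometric mean of the selected samples' effective
    library sizes.
    """
    counts = matrix.counts[ids].to_numpy(dtype=float)
    eff = matrix.effective_lib_sizes.loc[ids].to_numpy()
    if ref is None:
        ref = float(np.exp(np.mean(np.log(eff))))
    return counts * (ref / eff)


def estimate_common_dispersion(matrix: GeneCountMatrix, ids_by_group: list[list[str]]) -> float:
    """Method-of-moments common NB dispersion across genes.

    Per gene and replicate group, phi_g = (s^2 - m) / m^2 from the moment
    identity E[s^2] = m + phi m^2; the common value is the plain mean of
    the per-gene estimates over adequately expressed genes (m >= 20).
    The per-gene estimates are scale-free, so no single highly expressed
    gene dominates; negative estimates average out and the result is
    clipped at zero.
    """
    estimates = []
    for ids in ids_by_group:
        if len(ids) < 2:
            continue
        pseudo = _pseudo_counts(matrix, ids)
        m = pseudo.mean(axis=1)
        s2 = pseudo.var(axis=1, ddof=1)
        ok = m >= 20.0
        if ok.any():
            estimates.append((s2[ok] - m[ok]) / m[ok] ** 2)
    if not estimates:
        return 0.0
    return max(0.0, float(np.concatenate(estimates).mean()))


def test_induction(
    matrix: GeneCountMatrix,
    strain: str,
    dispersion: float | None = None,
    fold_threshold: float = INDUCTION_FOLD,
    fdr: float = INDUCTION_FDR,
) -> pd.DataFrame:
    """Per-gene exact NB test of TM vs control for one strain.

    Returns a frame with columns ``gene, log2fc, p, q, induced, tested``.
    Genes with zero counts in every sample of the strain are excluded from
    testing (``tested=False``).  ``induced`` requires an estimated fold
    change of at least ``fold_threshold`` (upregulation only) and
    ``q <= fdr``.
    """
    ids_c = matrix.strain_samples(strain, "control")
    ids_t = matrix.strain_samples(strain, "TM")
    if len(ids_c) < 2 or len(ids_t) < 2:
        raise ValueError(f"strain {strain!r} needs >= 2 replicates per condition")
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, [ids_c, ids_t])
    eff = matrix.effective_lib_sizes.loc[ids_c + ids_t]
    ref = float(np.exp(np.mean(np.log(eff))))
    pseudo_c = _pseudo_counts(matrix, ids_c, ref=ref)
    pseudo_t = _pseudo_counts(matrix, ids_t, ref=ref)
    s_c = np.rint(pseudo_c.sum(axis=1)).astype(np.int64)
    s_t = np.rint(pseudo_t.sum(axis=1)).astype(np.int64)
    mean_c = pseudo_c.mean(axis=1)
    mean_t = pseudo_t.mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
    genes = matrix.counts.index
    tested = (s_c + s_t) > 0
    p = np.full(len(genes), np.nan)
    for i in np.flatnonzero(tested):
        p[i] = nb_exact_test(int(s_c[i]), int(s_t[i]), len(ids_c), len(ids_t), dispersion)
    q = np.full(len(genes), np.nan)
    q[tested] = bh_fdr(p[tested])
    induced = tested & (log2fc >= np.log2(fold_threshold)) & (q <= fdr)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "induced": induced,
            "tested": tested,
        }
    ).reset_index(drop=True)


def induced_gene_sets(results_by_strain: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sharing spectrum over the union of induced genes.

    For every gene induced in at least one strain, counts the inducing
    strains and partitions the union into ``unique`` (exactly one),
    ``shared`` (two to K-1) and ``common`` (all K strains).
    """
    n_strains = len(results_by_strain)
    tallies: dict[str, int] = {}
    for res in results_by_strain.values():
        for gene in res.loc[res["induced"], "gene"]:
            tallies[gene] = tallies.get(gene, 0) + 1
    rows = []
    for gene in sorted(tallies):
        k = tallies[gene]
        if k == n_strains:
            label = "common"
        elif k == 1:
            label = "unique"
        else:
            label = "shared"
        rows.append((gene, k, label))
    return pd.DataFrame(rows, columns=["gene", "n_strains_induced", "sharing"])


def fold_change_table(matrix: GeneCountMatrix) -> pd.DataFrame:
    """Per-replicate TM log2 fold changes against the median control.

    For each strain, computes the median TMM-normalized control expression
    (counts per million) per gene and, for every TM replicate, the log2
    ratio of that replicate's CPM to the control median, with a 0.5 CPM
    offset on both for stability.  Genes whose median control CPM is zero
    in a strain are dropped for that strain.
    """
    eff = matrix.effective_lib_sizes
    cpm = matrix.counts / eff * 1e6
    rows = []
    for strain in matrix.samples["strain"].unique():
        ids_c = matrix.strain_samples(strain, "control")
        ids_t = matrix.strain_samples(strain, "TM")
        if len(ids_c) < 2 or len(ids_t) < 2:
            continue
        med_c = cpm[ids_c].median(axis=1)
        keep = med_c > 0
        for sid in ids_t:
            rep = matrix.samples.loc[sid, "replicate"]
            fc = np.log2((cpm.loc[keep, sid] + 0.5) / (med_c[keep] + 0.5))
            rows.append(
                pd.DataFrame(
                    {
                        "gene": fc.index,
                        "strain": strain,
                        "replicate": rep,
                        "log2fc": fc.to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def strain_effect(fc: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """One-way ANOVA of TM log2 fold change across strains, per gene.

    Strains contribute only when they have >= 2 replicate fold changes for
    the gene; genes with fewer than two such strains are skipped
    (``tested=False``).  BH correction across tested genes; significant
    means ``q <= fdr``.
    """
    rows = []
    for gene, sub in fc.groupby("gene", sort=True):
        groups = [
            g["log2fc"].to_numpy()
            for _, g in sub.groupby("strain")
            if len(g) >= 2
        ]
        if len(groups) < 2:
            rows.append((gene, np.nan, np.nan, False))
            continue
        f, p = one_way_anova(groups)
        rows.append((gene, f, p, True))
    out = pd.DataFrame(rows, columns=["gene", "F", "p", "tested"])
    q = np.full(len(out), np.nan)
    tested = out["tested"].to_numpy()
    q[tested] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = tested & (out["q"] <= fdr)
    return out


def correlation_network(
    fc: pd.DataFrame, gene_subset: list[str] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman co-response network among genes.

    Each gene's observation vector is its (strain, replicate) fold-change
    profile; all pairwise rank correlations within the subset are computed
    and edges with ``p < alpha`` retained, weighted by rho.  Constant gene
    vectors are dropped with a warning.
    """
    wide = fc.pivot_table(
        index=["strain", "replicate"], columns="gene", values="log2fc"
    )
    if gene_subset is not None:
        wide = wide[[g for g in gene_subset if g in wide.columns]]
    wide = wide.dropna(axis=0)
    keep = []
    for gene in wide.columns:
        if np.ptp(wide[gene].to_numpy()) == 0:
            warnings.warn(f"gene {gene!r} has a constant fold-change vector; dropped")
        else:
            keep.append(gene)
    wide = wide[keep]
    rows = []
    for g1, g2 in itertools.combinations(wide.columns, 2):
        rho, p = spearman_correlation(wide[g1].to_numpy(), wide[g2].to_numpy())
        if p < alpha:
            rows.append((g1, g2, rho, p))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p"])


@dataclass
class NormalizedPanel:
    """A QC'd, renormalized parental panel plus what was removed."""

    matrix: GeneCountMatrix
    removed: dict[str, list[str]]
    dispersion: float


def normalize_and_qc(matrix: GeneCountMatrix) -> NormalizedPanel:
    """TMM-normalize, remove condition outliers per strain, renormalize."""
    matrix.norm_factors = tmm_factors(matrix)
    removed: dict[str, list[str]] = {}
    for strain in matrix.samples["strain"].unique():
        out = qc_condition_outliers(matrix, strain)
        if out:
            removed[strain] = out
    drop = [s for outs in removed.values() for s in outs]
    if drop:
        keep = [s for s in matrix.counts.columns if s not in drop]
        matrix = matrix.subset_samples(keep)
        matrix.norm_factors = tmm_factors(matrix)
    groups = [
        matrix.strain_samples(strain, condition)
        for strain in matrix.samples["strain"].unique()
        for condition in ("control", "TM")
    ]
    dispersion = estimate_common_dispersion(matrix, groups)
    return NormalizedPanel(matrix=matrix, removed=removed, dispersion=dispersion)
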