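"""Donor-PDX transcriptome concordance: pair correlations, clustering, passage.

Three complementary views of how faithful a xenograft transcriptome is to
its donor tumor, before and after excluding a gene set (typically the
donor-PDX differential genes):

* per-pair Pearson correlation of log2(CPM + 0.5) expression;
* average-linkage hierarchical clustering on correlation distance, scoring a
  pair "aligned" when donor and PDX are dendrogram siblings;
* per-gene Spearman association of PDX expression with PDX passage number.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


def log_cpm(counts, prior: float = 0.5, library_sizes=None) -> pd.DataFrame:
    """log2(CPM + prior) expression frame (genes x samples)."""
    cpm = counts.cpm(library_sizes)
    return pd.DataFrame(
        np.log2(cpm + prior), index=counts.genes, columns=counts.samples
    )


def donor_pdx_pairs(meta: pd.DataFrame) -> list[tuple[str, str]]:
    """(donor_sample, pdx_sample) per patient, from sample metadata."""
    pairs = []
    for pid, grp in meta.groupby("patient_id", sort=True):
        donors = grp.index[grp["tissue"] == "donor"].tolist()
        pdxs = grp.index[grp["tissue"] == "pdx"].tolist()
        if len(donors) == 1 and len(pdxs) == 1:
            pairs.append((donors[0], pdxs[0]))
    return pairs


def _apply_exclusion(log_expr: pd.DataFrame, exclude) -> pd.DataFrame:
    if not exclude:
        return log_expr
    exclude = set(exclude)
    return log_expr.loc[[g for g in log_expr.index if g not in exclude]]


def pair_correlations(
    log_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    exclude=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-pair correlation of donor vs PDX expression on non-excluded genes.

    Returns a frame with one row per pair plus the across-pair mean in
    ``.attrs['mean_r']``.
    """
    expr = _apply_exclusion(log_expr, exclude)
    rows = []
    for donor, pdx in pairs:
        x = expr[donor].to_numpy(dtype=float)
        y = expr[pdx].to_numpy(dtype=float)
        if method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(x, y).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append({"donor": donor, "pdx": pdx, "r": r})
    out = pd.DataFrame(rows)
    out.attrs["mean_r"] = float(out["r"].mean()) if len(out) else float("nan")
    out.attrs["n_genes"] = expr.shape[0]
    return out


def correlation_before_after(
    log_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    exclude_before=None,
    exclude_after=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Before/after exclusion table of per-pair correlations."""
    before = pair_correlations(log_expr, pairs, exclude_before, method)
    after = pair_correlations(log_expr, pairs, exclude_after, method)
    out = before.rename(columns={"r": "r_before"})
    out["r_after"] = after["r"]
    out.attrs["mean_r_before"] = before.attrs["mean_r"]
    out.attrs["mean_r_after"] = after.attrs["mean_r"]
    return out


# --------------------------------------------------------------------------
# Hierarchical clustering alignment
# --------------------------------------------------------------------------


@dataclass
class ClusterAlignment:
    aligned: int
    total: int
    aligned_pairs: list[tuple[str, str]]
    linkage: np.ndarray
    samples: list[str]
    newick: str


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = max(node.dist - node.get_left().dist, 0.0)
    dr = max(node.dist - node.get_right().dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_alignment(
    log_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    exclude=None,
) -> ClusterAlignment:
    """Average-linkage clustering on 1 - Pearson r; count sibling pairs.

    A donor/PDX pair is "aligned" when its two samples are merged with each
    other before either merges with any other sample.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    expr = _apply_exclusion(log_expr, exclude)
    samples = list(expr.columns)
    mat = expr.to_numpy(dtype=float).T  # samples x genes
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        bad = [samples[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression column for sample(s): {bad}")
    z = hierarchy.linkage(mat, method="average", metric="correlation")
    idx = {s: i for i, s in enumerate(samples)}
    sibling_merges = {
        frozenset((int(row[0]), int(row[1]))) for row in z if row[0] < len(samples) and row[1] < len(samples)
    }
    aligned_pairs = [
        (d, p)
        for d, p in pairs
        if frozenset((idx[d], idx[p])) in sibling_merges
    ]
    tree = hierarchy.to_tree(z)
    newick = _to_newick(tree, samples) + ";"
    return ClusterAlignment(
        aligned=len(aligned_pairs),
        total=len(pairs),
        aligned_pairs=aligned_pairs,
        linkage=z,
        samples=samples,
        newick=newick,
    )


# --------------------------------------------------------------------------
# Passage association
# --------------------------------------------------------------------------


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def passage_association(
    pdx_expr: pd.DataFrame,
    passages,
    max_exact_n: int = 9,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of PDX expression with passage number.

    For n <= ``max_exact_n`` samples the two-sided p-value is exact, from
    full enumeration of passage-order permutations (valid under ties); for
    larger n the t-approximation is used.  Genes with constant expression
    have undefined rho and are excluded from the BH adjustment.  The
    returned frame carries ``rho``, ``pvalue`` and BH ``qvalue``.
    """
    from .paired_de import benjamini_hochberg

    passages = np.asarray(passages, dtype=float)
    n = passages.shape[0]
    if pdx_expr.shape[1] != n:
        raise ValueError("one passage value per PDX sample required")
    if np.unique(passages).size < 4:
        raise ValueError("need at least 4 distinct passage values")
    expr = pdx_expr.to_numpy(dtype=float)
    constant = expr.std(axis=1) == 0
    ranks = _rank_rows(expr)
    pranks = stats.rankdata(passages)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    pc = pranks - pranks.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc * pc).sum(axis=1) / denom
    rho[constant] = np.nan

    pvals = np.full(expr.shape[0], np.nan)
    valid = ~constant
    if n <= max_exact_n:
        perms = np.array(list(itertools.permutations(pc)))
        obs = np.abs(rho[valid])
        exceed = np.zeros(valid.sum(), dtype=np.int64)
        chunk = max(1, int(2e7 // perms.shape[0]))
        rcv = rc[valid]
        dv = denom[valid]
        for s in range(0, rcv.shape[0], chunk):
            block = rcv[s : s + chunk] @ perms.T / dv[s : s + chunk, None]
            exceed[s : s + chunk] = (
                np.abs(block) >= obs[s : s + chunk, None] - 1e-12
            ).sum(axis=1)
        pvals[valid] = exceed / perms.shape[0]
    else:
        r = rho[valid]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        pvals[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pvals[valid] = np.minimum(pvals[valid], 1.0)
    out = pd.DataFrame(
        {
            "gene_id": list(pdx_expr.index),
            "rho": rho,
            "pvalue": pvals,
            "qvalue": benjamini_hochberg(pvals),
        }
    ).set_index("gene_id", drop=False)
    out.index.name = None
    return out
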