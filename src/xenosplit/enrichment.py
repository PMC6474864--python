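"""Gene-list overlap enrichment and signature correlation.

Overlap of two gene lists drawn from an explicit finite universe is tested
with the upper-tail hypergeometric probability; enrichment of a differential
gene set in user-supplied gene families with the two-sided Fisher exact test
(point-probability method); and similarity of differential log fold changes
with published signature scores with Spearman correlation on the
intersection genes.

The universe must always be given explicitly: overlap odds ratios are
meaningless without it, and the pipeline's convention is the set of genes
surviving the expression filter in both compared analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .paired_de import benjamini_hochberg


@dataclass
class OverlapResult:
    k_overlap: int
    n_a: int
    n_b: int
    n_universe: int
    pvalue: float
    odds_ratio: float
    haldane_corrected: bool


def hypergeom_overlap(list_a, list_b, universe) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene lists.

    With ``N = |universe|``, ``K = |a|``, ``n = |b|`` and ``k = |a & b|``,
    the p-value is ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  The
    sample odds ratio is the 2x2 cross-product, with a Haldane +0.5
    correction applied (and flagged) when a cell is zero.
    """
    universe = set(universe)
    a, b = set(list_a), set(list_b)
    outside = (a | b) - universe
    if outside:
        raise ValueError(
            f"elements outside the universe: {sorted(outside)[:10]}"
        )
    big_n, big_k, n = len(universe), len(a), len(b)
    k = len(a & b)
    pvalue = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    cells = np.array(
        [
            [k, big_k - k],
            [n - k, big_n - big_k - n + k],
        ],
        dtype=float,
    )
    haldane = bool((cells == 0).any())
    if haldane:
        cells = cells + 0.5
    odds = float(cells[0, 0] * cells[1, 1] / (cells[0, 1] * cells[1, 0]))
    return OverlapResult(
        k_overlap=k,
        n_a=big_k,
        n_b=n,
        n_universe=big_n,
        pvalue=min(pvalue, 1.0),
        odds_ratio=odds,
        haldane_corrected=haldane,
    )


def fisher_family_enrichment(
    deg_set, family_sets: dict, universe
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of a DEG set in each gene family.

    ``family_sets`` maps family name to a gene collection; each family is
    intersected with the universe, and a family with no member in the
    universe is an error.  BH adjustment runs across families.
    """
    universe = set(universe)
    degs = set(deg_set) & universe
    rows = []
    for name, fam in family_sets.items():
        fam = set(fam)
        if not fam & universe:
            raise ValueError(f"family {name!r} is disjoint from the universe")
        fam &= universe
        k = len(degs & fam)
        table = [
            [k, len(degs) - k],
            [len(fam) - k, len(universe) - len(degs) - len(fam) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"family": name, "n_family": len(fam), "k_overlap": k,
             "odds_ratio": odds, "pvalue": p}
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def signature_correlation(
    xdg_log2fc: pd.Series, signature_scores: pd.Series
) -> tuple[float, float, int]:
    """Spearman correlation of fold changes with signature scores.

    Only genes present in both series are used; at least five overlapping
    genes are required.  Returns ``(rho, two-sided p, n_overlap)``.
    """
    common = xdg_log2fc.index.intersection(signature_scores.index)
    if len(common) < 5:
        raise ValueError(
            f"only {len(common)} overlapping genes; need at least 5"
        )
    res = stats.spearmanr(
        xdg_log2fc.loc[common].to_numpy(dtype=float),
        signature_scores.loc[common].to_numpy(dtype=float),
    )
    return float(res.statistic), float(res.pvalue), int(len(common))


def read_gene_list(path) -> list[str]:
    """Single-column TSV of gene ids (header optional if 'gene_id')."""
    df = pd.read_csv(path, sep="\t", header=None)
    first = str(df.iloc[0, 0])
    values = df.iloc[:, 0].astype(str).tolist()
    return values[1:] if first == "gene_id" else values


def read_family_sets(path) -> dict:
    """Two-column TSV (family, gene_id) into {family: set of genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["family", "gene_id"])
    if str(df.iloc[0, 0]) == "family":
        df = df.iloc[1:]
    return {f: set(g["gene_id"].astype(str)) for f, g in df.groupby("family")}
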