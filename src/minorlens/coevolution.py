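"""Phylogenetic-profile co-occurrence screening and term enrichment.

Genes that function together tend to be lost together across species;
their binary presence/absence profiles correlate. Co-occurrence with a
query gene is scored with the Pearson correlation of the two binary
vectors, which on 0/1 data equals the 2x2 phi coefficient. Genes whose
correlation exceeds a cutoff (default 0.5, strict) form the
co-occurring set, which is then tested for annotation-term enrichment
with the one-sided Fisher's exact (hypergeometric upper-tail) test and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential_ir import adjust_bh

DEFAULT_R_MIN = 0.5


def read_profile_matrix(path: str) -> pd.DataFrame:
    """Read a genes x species 0/1 TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in profile matrix")
    if df.shape[1] < 2:
        raise ValueError("profile matrix needs at least two species")
    if not df.isin([0, 1]).all().all():
        raise ValueError("profile matrix entries must be 0/1")
    return df.astype(np.int8)


def profile_correlation(query, matrix: pd.DataFrame) -> pd.DataFrame:
    """Correlate every gene's profile with the query profile.

    ``query`` is a binary vector over the matrix's species columns (or
    a gene id present in the matrix). Returns a frame (gene, r) sorted
    by descending r, ties broken by gene id; genes with constant
    profiles get undefined r (NaN) and rank last. A constant query
    makes every r undefined.
    """
    if isinstance(query, str):
        if query not in matrix.index:
            raise KeyError(f"query gene {query!r} not in matrix")
        q = matrix.loc[query].to_numpy(dtype=float)
    else:
        q = np.asarray(query, dtype=float)
    if q.size != matrix.shape[1]:
        raise ValueError(
            f"query length {q.size} != number of species {matrix.shape[1]}"
        )
    X = matrix.to_numpy(dtype=float)
    qc = q - q.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    q_ss = float(qc @ qc)
    x_ss = (Xc * Xc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ qc) / np.sqrt(x_ss * q_ss)
    r[(x_ss == 0) | (q_ss == 0)] = np.nan
    out = pd.DataFrame({"gene": matrix.index.to_numpy(), "r": r})
    out["_nan"] = out["r"].isna()
    out = out.sort_values(
        by=["_nan", "r", "gene"], ascending=[True, False, True]
    ).drop(columns="_nan").reset_index(drop=True)
    return out


def select_cooccurring(
    results: pd.DataFrame, r_min: float = DEFAULT_R_MIN,
    query_gene: str | None = None,
) -> set[str]:
    """Genes with r strictly greater than ``r_min``, excluding the query."""
    hits = results[results["r"] > r_min]["gene"]
    selected = set(hits)
    if query_gene is not None:
        selected.discard(query_gene)
    return selected


def enrich_terms(
    selected: set[str], background: set[str], term_map: pd.DataFrame
) -> pd.DataFrame:
    """Term over-representation among selected genes.

    ``term_map`` has columns ``gene, term``. Per term with K background
    members, k of them among the n selected genes (background size N):
    p = P(X >= k) under Hypergeometric(N, K, n); BH across terms;
    fold enrichment (k/n) / (K/N).
    """
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    tm = term_map[term_map["gene"].isin(background)]
    N = len(background)
    n = len(selected)
    rows = []
    for term, sub in tm.groupby("term", sort=True):
        genes = set(sub["gene"])
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "p": min(p, 1.0), "fold_enrichment": fold}
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "fold_enrichment"])
    if not df.empty:
        df["p_adj"] = adjust_bh(df["p"].to_numpy())
    else:
        df["p_adj"] = []
    return df[["term", "k", "K", "n", "N", "p", "p_adj", "fold_enrichment"]]
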