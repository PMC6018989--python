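"""Functional enrichment: categorical (COG/GO) and spatial (map-based).

Categorical enrichment uses a two-tailed hypergeometric test per term
with step-up false-discovery-rate control — Benjamini–Hochberg for
largely independent vocabularies (COG) and Benjamini–Yekutieli when
dependencies between tests matter (GO, and all spatial tests).

Spatial ("SAFE-style") enrichment treats a 2D embedding as a
similarity map: around every strain a disc of radius equal to a low
percentile of the pairwise-distance distribution defines a local
neighborhood, and each annotation term is tested for local
over-representation against the hypergeometric null given the
neighborhood size and the term's global frequency.  Permutation
replicates (attributes shuffled across strains) provide an empirical
background score reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "two_tailed_hypergeom_p",
    "term_enrichment",
    "fdr_adjust",
    "safe_enrichment",
]


@dataclass
class AnnotationMap:
    """Gene/strain -> annotation terms, with optional term labels."""

    gene_terms: dict[str, set[str]]
    term_labels: dict[str, str] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_terms.get(gene, set())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationMap":
        """Build from a long table with columns (id, term[, namespace])."""
        gt: dict[str, set[str]] = {}
        ns: dict[str, str] = {}
        for row in df.itertuples(index=False):
            gt.setdefault(str(row[0]), set()).add(str(row[1]))
            if len(row) > 2:
                ns[str(row[1])] = str(row[2])
        return cls(gene_terms=gt, namespace=ns)

    @classmethod
    def read_tsv(cls, path) -> "AnnotationMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def two_tailed_hypergeom_p(k: int, N: int, K: int, n: int) -> float:
    """Two-tailed hypergeometric p by the doubling rule, capped at 1."""
    lower = hypergeom.cdf(k, N, K, n)
    upper = hypergeom.sf(k - 1, N, K, n)
    return float(min(1.0, 2.0 * min(lower, upper)))


def fdr_adjust(pvals, method: str = "bh") -> np.ndarray:
    """Step-up FDR adjustment; method 'bh' or 'by'."""
    method = method.lower()
    if method not in {"bh", "by"}:
        raise ValueError("method must be 'bh' or 'by'")
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method=f"fdr_{method}")[1]


def term_enrichment(
    member_set,
    universe,
    ann: AnnotationMap,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Two-tailed hypergeometric enrichment of annotation terms in a set."""
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    members = list(dict.fromkeys(member_set))
    offenders = [m for m in members if m not in uni]
    if offenders:
        raise ValueError(f"members not in universe: {offenders}")

    N, n = len(universe), len(members)
    term_universe: dict[str, int] = {}
    for g in universe:
        for t in ann.terms_of(g):
            term_universe[t] = term_universe.get(t, 0) + 1
    term_members: dict[str, int] = {t: 0 for t in term_universe}
    for g in members:
        for t in ann.terms_of(g):
            term_members[t] += 1

    rows = []
    for t, K in sorted(term_universe.items()):
        if K == 0:
            continue
        k = term_members[t]
        p = two_tailed_hypergeom_p(k, N, K, n)
        expected = n * K / N
        rows.append(
            {
                "term": t,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "direction": "enriched" if k >= expected else "depleted",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy(), adjust)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


@dataclass
class SafeResult:
    table: pd.DataFrame  # node x term rows
    radius: float
    n_perm: int

    def significant_nodes(self, term: str) -> list:
        sub = self.table[(self.table["term"] == term) & self.table["significant"]]
        return list(sub["node"])


def safe_enrichment(
    embedding: np.ndarray,
    attributes: pd.DataFrame,
    radius_percentile: float = 1.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SafeResult:
    """Local annotation enrichment on a 2D embedding.

    ``attributes`` is a binary strains x terms matrix aligned with the
    embedding rows.  Hypergeometric p-values drive the BY threshold at
    ``alpha``; the permutation background (empirical p and mean permuted
    neighborhood count) is reported alongside.
    """
    pts = np.asarray(embedding, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("embedding must be an (n, 2) array")
    n = len(pts)
    if n < 20:
        raise ValueError("need at least 20 points")
    if len(attributes) != n:
        raise ValueError("attributes must align with the embedding rows")

    radius = float(np.percentile(pdist(pts), radius_percentile))
    tree = cKDTree(pts)
    neigh = tree.query_ball_point(pts, r=radius)  # includes the point itself

    A = attributes.to_numpy(dtype=float)
    terms = list(attributes.columns)
    keep = []
    for j, t in enumerate(terms):
        if A[:, j].sum() == 0:
            warnings.warn(f"attribute '{t}' is all-zero; skipped")
        else:
            keep.append(j)

    M = np.zeros((n, n), dtype=float)
    for i, nb in enumerate(neigh):
        M[i, nb] = 1.0
    local_sizes = M.sum(axis=1).astype(int)
    local_counts = M @ A  # node x term annotated neighbor counts

    rng = np.random.default_rng(seed)
    perm_ge = np.zeros_like(local_counts)
    perm_sum = np.zeros_like(local_counts)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pc = M @ A[perm]
        perm_ge += pc >= local_counts
        perm_sum += pc

    rows = []
    index = list(attributes.index)
    for j in keep:
        K = int(A[:, j].sum())
        for i in range(n):
            k = int(local_counts[i, j])
            p_hyper = float(hypergeom.sf(k - 1, n, K, int(local_sizes[i])))
            rows.append(
                {
                    "node": index[i],
                    "term": terms[j],
                    "k_local": k,
                    "n_local": int(local_sizes[i]),
                    "K_global": K,
                    "p_hyper": p_hyper,
                    "p_perm": float((1.0 + perm_ge[i, j]) / (n_perm + 1.0)),
                    "background_mean": float(perm_sum[i, j] / max(n_perm, 1)),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = fdr_adjust(table["p_hyper"].to_numpy(), "by")
        table["significant"] = table["q"] < alpha
    return SafeResult(table=table, radius=radius, n_perm=n_perm)
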