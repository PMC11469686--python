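"""Map exploration: complex identification, neighbors and enrichment.

* ``identify_complexes`` asks, for every cataloged gene cluster with at
  least ``min_genes`` members present in the map, whether within-cluster
  cosine similarities are distributed differently from in/out similarities
  (one member, one non-member).  A two-sample Kolmogorov-Smirnov test gives
  the statistic and p-value; a cluster is *identified* at p < .01.

* ``top_neighbors`` returns the k genes most cosine-similar to a query
  (default 25, self excluded, ties broken lexicographically), and
  ``overlap_neighbors`` intersects neighbor lists from different maps —
  the workhorse for proposing roles for uncharacterized genes.

* ``enrich`` runs an upper-tail hypergeometric test of a query gene set
  against a gene-set collection (e.g. GO via GMT), with the map's gene
  universe as background, evaluating only terms with >= 10 genes in the
  map and Bonferroni-correcting over the evaluated terms.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .annotations import ComplexCatalog
from .map_model import PermapError, SimilarityMatrix

import numpy as np
import pandas as pd

__all__ = [
    "ComplexResult",
    "EnrichmentResult",
    "identify_complexes",
    "top_neighbors",
    "overlap_neighbors",
    "enrich",
    "complex_results_to_frame",
    "enrichment_results_to_frame",
]


@dataclass(frozen=True)
class ComplexResult:
    name: str
    n_in_map: int
    ks_statistic: float
    p_value: float
    identified: bool


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    term_size_in_map: int
    overlap: int
    raw_p: float
    corrected_p: float
    significant: bool


def identify_complexes(sim: SimilarityMatrix, catalog: ComplexCatalog,
                       min_genes: int = 10, alpha: float = 0.01,
                       ks_method: str = "asymp") -> list[ComplexResult]:
    """KS comparison of within-cluster vs in/out cosine similarities.

    Clusters with fewer than ``min_genes`` members in the map are skipped.
    Each unordered pair enters its distribution once; self-links are
    excluded.  ``ks_method`` is passed to the two-sample KS test
    ("asymp" by default; "exact" available for small clusters).
    """
    if len(catalog) == 0:
        raise PermapError("complex catalog is empty")
    gene_pos = {g: i for i, g in enumerate(sim.genes)}
    n = sim.n_genes
    results = []
    for name, members in catalog.items():
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos))
        if len(idx) < min_genes:
            continue
        if len(idx) >= n:
            raise PermapError(
                f"complex {name!r} covers the whole map; no outside genes"
            )
        inside = np.zeros(n, dtype=bool)
        inside[idx] = True
        sub = sim.values[np.ix_(idx, idx)]
        within = sub[np.triu_indices(len(idx), k=1)]
        cross = sim.values[np.ix_(idx, ~inside)].ravel()
        ks = stats.ks_2samp(within, cross, alternative="two-sided",
                            method=ks_method)
        results.append(ComplexResult(
            name=name, n_in_map=len(idx),
            ks_statistic=float(ks.statistic), p_value=float(ks.pvalue),
            identified=bool(ks.pvalue < alpha),
        ))
    return results


def top_neighbors(sim: SimilarityMatrix, gene: str, k: int = 25) -> list[str]:
    """The k genes with the highest cosine to ``gene``, descending.

    The query itself is never returned; ties are broken lexicographically.
    """
    i = sim.index_of(gene)
    if k >= sim.n_genes:
        raise PermapError(
            f"k={k} must be smaller than the map size {sim.n_genes}"
        )
    order = sorted(
        (g for g in sim.genes if g != gene),
        key=lambda g: (-sim.values[i, sim.index_of(g)], g),
    )
    return order[:k]


def overlap_neighbors(list_a: list[str], list_b: list[str]) -> set[str]:
    """Genes shared by two neighbor lists (order-independent)."""
    return set(list_a) & set(list_b)


def enrich(query_genes: set[str], collection: dict[str, list[str]],
           universe: set[str], min_term_size: int = 10,
           alpha: float = 0.01) -> list[EnrichmentResult]:
    """Hypergeometric gene-set enrichment with Bonferroni correction.

    ``universe`` is the map's gene universe; the query must be a subset of
    it.  Only terms with >= ``min_term_size`` genes in the universe are
    evaluated, and the Bonferroni factor is the number of evaluated terms.
    """
    query = set(query_genes)
    if not query:
        raise PermapError("empty query gene set")
    if not query <= set(universe):
        missing = sorted(query - set(universe))[:5]
        raise PermapError(f"query genes not in the universe: {missing}")
    universe = set(universe)
    M, N = len(universe), len(query)
    evaluated = []
    for term, members in collection.items():
        in_map = set(members) & universe
        if len(in_map) >= min_term_size:
            evaluated.append((term, in_map))
    n_tests = len(evaluated)
    results = []
    for term, in_map in evaluated:
        k_obs = len(in_map & query)
        raw = float(stats.hypergeom.sf(k_obs - 1, M, len(in_map), N))
        corrected = min(1.0, raw * n_tests)
        results.append(EnrichmentResult(
            term=term, term_size_in_map=len(in_map), overlap=k_obs,
            raw_p=raw, corrected_p=corrected,
            significant=bool(corrected < alpha),
        ))
    results.sort(key=lambda r: (r.corrected_p, r.term))
    return results


def complex_results_to_frame(results: list[ComplexResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["name", "n_in_map", "ks_statistic",
                                 "p_value", "identified"])


def enrichment_results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["term", "term_size_in_map", "overlap",
                                 "raw_p", "corrected_p", "significant"])
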