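"""Perturbation-signal benchmarks.

Two statistics quantify whether a perturbation leaves a detectable trace in
a map, both computed on aligned unit-level embeddings:

* **Consistency** (``avgsim``): the mean cosine similarity across all
  unordered pairs of a perturbation's replicate units.  It is 1 when the
  replicates share one orientation and 0 when they are mutually orthogonal
  (self-pairs are excluded by default so this holds; a flag restores the
  literal all-pairs form, which equals ``(n-1)/n * avgsim + 1/n``).

* **Magnitude**: the energy distance between a perturbation's units and the
  negative-control units,

  .. math::

     E(X, Y) = \\frac{2}{n_1 n_2}\\sum_{i,j}\\lVert x_i-y_j\\rVert
             - \\frac{1}{n_1^2}\\sum_{i,j}\\lVert x_i-x_j\\rVert
             - \\frac{1}{n_2^2}\\sum_{i,j}\\lVert y_i-y_j\\rVert,

  which is nonnegative and zero iff the two distributions coincide.

Significance is assessed non-parametrically: each statistic is compared
against an empirical null built from perturbations of *unexpressed* genes —
genes not expressed in the assayed cell type, whose perturbation cannot
produce a true biological effect — with ``p = max(#{null >= observed}, 1)/K``
and a floor of K >= 1000 null genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .map_model import PermapError, SchemaError, UnitMatrix

__all__ = [
    "ConsistencyResult",
    "MagnitudeResult",
    "NullDistribution",
    "SignificanceResult",
    "SignalReport",
    "avgsim",
    "energy_distance",
    "consistency",
    "magnitude",
    "permutation_pvalue",
    "signal_benchmark",
    "write_signal_report",
]

MIN_NULL_GENES = 1000


@dataclass(frozen=True)
class ConsistencyResult:
    gene: str
    avgsim: float
    n_replicates: int


@dataclass(frozen=True)
class MagnitudeResult:
    gene: str
    energy: float
    n_query: int
    n_control: int


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null: one statistic per unexpressed gene."""

    metric: str  # "consistency" | "magnitude"
    values: np.ndarray

    @property
    def K(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SignificanceResult:
    gene: str
    metric: str
    statistic: float
    p_value: float


def _as_array(x) -> np.ndarray:
    if isinstance(x, UnitMatrix):
        return x.values()
    return np.asarray(x, dtype=float)


def avgsim(X, include_self: bool = False) -> float:
    """Mean pairwise cosine similarity among the rows of ``X``."""
    X = _as_array(X)
    n = X.shape[0]
    if n < 2:
        raise PermapError("avgsim needs >= 2 replicate units")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise PermapError("avgsim: zero-norm replicate unit")
    U = X / norms[:, None]
    G = U @ U.T
    iu = np.triu_indices(n, k=1)
    mean_pairs = float(G[iu].mean())
    if include_self:
        # literal all-ordered-pairs form, self-similarities included
        return ((n - 1) * mean_pairs + 1.0) / n
    return mean_pairs


def energy_distance(X, Y) -> float:
    """Energy distance between two samples of d-dimensional points."""
    X, Y = _as_array(X), _as_array(Y)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n1, n2 = X.shape[0], Y.shape[0]
    if n1 == 0 or n2 == 0:
        raise PermapError("energy distance needs non-empty samples")
    # all three terms via the same cdist path so E(X, X) cancels exactly
    cross = cdist(X, Y).sum() * 2.0 / (n1 * n2)
    within_x = 0.0 if n1 == 1 else cdist(X, X).sum() / n1**2
    within_y = 0.0 if n2 == 1 else cdist(Y, Y).sum() / n2**2
    return float(cross - within_x - within_y)


def consistency(units_of_gene: UnitMatrix, gene: str | None = None,
                include_self: bool = False) -> ConsistencyResult:
    """Replicate-consistency statistic for one perturbation's units."""
    if gene is None:
        labels = units_of_gene.perturbation.unique()
        if len(labels) != 1:
            raise PermapError(
                "units span multiple perturbations; pass gene explicitly"
            )
        gene = str(labels[0])
    value = avgsim(units_of_gene, include_self=include_self)
    return ConsistencyResult(gene, value, units_of_gene.n_units)


def magnitude(query: UnitMatrix, controls: UnitMatrix,
              gene: str | None = None) -> MagnitudeResult:
    """Energy-distance effect size of one perturbation versus controls."""
    if gene is None:
        labels = query.perturbation.unique()
        gene = str(labels[0]) if len(labels) == 1 else "<multiple>"
    value = energy_distance(query, controls)
    return MagnitudeResult(gene, value, query.n_units, controls.n_units)


def permutation_pvalue(observed: float, null: NullDistribution,
                       gene: str = "", min_k: int = MIN_NULL_GENES
                       ) -> SignificanceResult:
    """Upper-tail permutation p-value against the unexpressed-gene null.

    ``p = max(#{null >= observed}, 1) / K``; ties count as exceedances, and
    the clamp keeps p >= 1/K (never zero).
    """
    K = null.K
    if K < min_k:
        raise PermapError(
            f"null distribution has K={K} genes; at least {min_k} are "
            "required for a representative p-value"
        )
    count = int(np.sum(null.values >= observed))
    p = max(count, 1) / K
    return SignificanceResult(gene, null.metric, float(observed), float(p))


# ---------------------------------------------------------------------------
# full benchmark over a map's unit table
# ---------------------------------------------------------------------------

@dataclass
class SignalReport:
    """Per-gene signal statistics and p-values plus summary fractions.

    ``per_gene`` columns: gene, metric, statistic, p_value, significant.
    ``summary`` holds the fraction of expressed genes significant per metric,
    the intersection fraction, alpha and the null sizes used.
    """

    per_gene: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _gene_blocks(units: UnitMatrix):
    """Index arrays of units per non-control perturbation, insertion-ordered."""
    pert = units.perturbation.to_numpy()
    ctrl = units.is_control.to_numpy()
    order = {}
    for i in np.flatnonzero(~ctrl):
        order.setdefault(pert[i], []).append(i)
    return {g: np.asarray(ix) for g, ix in order.items()}


def signal_benchmark(units: UnitMatrix, alpha: float = 0.05,
                     min_null: int = MIN_NULL_GENES,
                     include_self: bool = False,
                     max_replicates: int | None = None,
                     seed: int = 0) -> SignalReport:
    """Consistency and magnitude benchmarks for every expressed gene.

    Null distributions are built from the unexpressed genes with the
    identical code path.  ``max_replicates`` optionally caps the replicate
    pool per gene with a seeded subsample (for very large pooled datasets).
    """
    expressed = units.is_expressed
    if expressed.isna().all() or not (expressed == False).any():  # noqa: E712
        raise SchemaError(
            "no unexpressed-gene units present; perturbation signal "
            "benchmarks cannot be calculated without an unexpressed-gene null"
        )
    X = units.values()
    ctrl_X = X[units.is_control.to_numpy()]
    if ctrl_X.shape[0] == 0:
        raise SchemaError("no control units present")
    rng = np.random.default_rng(seed)
    blocks = _gene_blocks(units)
    gene_expressed = {
        g: bool(units.is_expressed.iloc[ix[0]])
        for g, ix in blocks.items()
    }

    stats: dict[str, dict[str, float]] = {"consistency": {}, "magnitude": {}}
    n_reps: dict[str, int] = {}
    for g, ix in blocks.items():
        if max_replicates is not None and len(ix) > max_replicates:
            ix = np.sort(rng.choice(ix, size=max_replicates, replace=False))
        Xg = X[ix]
        n_reps[g] = len(ix)
        if len(ix) >= 2:
            stats["consistency"][g] = avgsim(Xg, include_self=include_self)
        stats["magnitude"][g] = energy_distance(Xg, ctrl_X)

    nulls = {}
    for metric in ("consistency", "magnitude"):
        vals = np.asarray([
            stats[metric][g] for g in blocks
            if not gene_expressed[g] and g in stats[metric]
        ])
        nulls[metric] = NullDistribution(metric, vals)

    rows = []
    for metric in ("consistency", "magnitude"):
        null = nulls[metric]
        for g in blocks:
            if not gene_expressed[g] or g not in stats[metric]:
                continue
            res = permutation_pvalue(stats[metric][g], null, gene=g,
                                     min_k=min_null)
            rows.append({
                "gene": g, "metric": metric,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant": res.p_value < alpha,
                "n_replicates": n_reps[g],
            })
    per_gene = pd.DataFrame(
        rows, columns=["gene", "metric", "statistic", "p_value",
                       "significant", "n_replicates"]
    )

    def _frac(metric: str) -> float:
        sub = per_gene[per_gene["metric"] == metric]
        return float(sub["significant"].mean()) if len(sub) else float("nan")

    sig_sets = {
        m: set(per_gene.loc[(per_gene["metric"] == m)
                            & per_gene["significant"], "gene"])
        for m in ("consistency", "magnitude")
    }
    tested = {
        m: set(per_gene.loc[per_gene["metric"] == m, "gene"])
        for m in ("consistency", "magnitude")
    }
    both_universe = tested["consistency"] & tested["magnitude"]
    frac_both = (
        len(sig_sets["consistency"] & sig_sets["magnitude"]) /
        len(both_universe) if both_universe else float("nan")
    )
    report = SignalReport(per_gene, {
        "alpha": alpha,
        "fraction_significant_consistency": _frac("consistency"),
        "fraction_significant_magnitude": _frac("magnitude"),
        "fraction_significant_both": frac_both,
        "K_consistency": nulls["consistency"].K,
        "K_magnitude": nulls["magnitude"].K,
        "n_expressed_tested_consistency": len(tested["consistency"]),
        "n_expressed_tested_magnitude": len(tested["magnitude"]),
    })
    return report


def write_signal_report(report: SignalReport, path) -> None:
    """Write the per-gene table; the summary goes to a JSON sidecar."""
    import json

    report.per_gene.to_csv(path, index=False)
    with open(str(path) + ".summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
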