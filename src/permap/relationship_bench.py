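"""Biological-relationship benchmarks.

A map "recapitulates" a known gene-gene relationship when that pair's
cosine similarity lands in the extreme tails of the map's full pairwise
similarity distribution.  Concretely, over all unordered off-diagonal gene
pairs in the map we take the ``tail`` and ``1 - tail`` empirical
percentiles (default 5th and 95th) as cuts; pairs strictly below the lower
cut or strictly above the upper cut are the *predicted links*.  Recall for
an annotation source is then

    100 * |predicted links ∩ annotated pairs| / |annotated pairs|,

where the denominator counts only annotated pairs whose *both* genes are
present in the map (so maps over different perturbation sets compare
fairly).  A random, uninformative map scores 2 * tail * 100 — 10% at the
default 5% tails.

``noise_sensitivity`` probes how replicate count drives recall: it
subsamples each gene's replicate pool to a given size, rebuilds the map,
and reports recall mean and standard deviation over repeated random draws
(three by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .efaar import PipelineConfig, run_pipeline
from .map_model import PermapError, SimilarityMatrix, UnitMatrix

__all__ = [
    "RecallResult",
    "NoiseSensitivityResult",
    "percentile_cuts",
    "recall",
    "benchmark_all",
    "noise_sensitivity",
    "subsample_replicates",
]


@dataclass(frozen=True)
class RecallResult:
    source_name: str
    recall_percent: float
    n_eval_pairs: int
    lower_cut: float
    upper_cut: float

    def as_dict(self) -> dict:
        return {
            "source": self.source_name,
            "recall_percent": self.recall_percent,
            "n_eval_pairs": self.n_eval_pairs,
            "lower_cut": self.lower_cut,
            "upper_cut": self.upper_cut,
        }


def percentile_cuts(sim: SimilarityMatrix, tail: float = 0.05
                    ) -> tuple[float, float]:
    """Lower/upper cuts: linear-interpolation empirical percentiles of the
    off-diagonal (upper-triangle) similarity values."""
    if not 0 < tail < 0.5:
        raise PermapError("tail must be in (0, 0.5)")
    vals = sim.offdiag_values()
    lo, hi = np.percentile(vals, [100 * tail, 100 * (1 - tail)])
    return float(lo), float(hi)


def _recall_with_cuts(sim: SimilarityMatrix, ann: AnnotationSet,
                      lo: float, hi: float) -> RecallResult:
    present = set(sim.genes)
    eval_pairs = [(a, b) for a, b in ann.pairs if a in present and b in present]
    if not eval_pairs:
        raise PermapError(
            f"annotation source {ann.source_name!r} has no pair with both "
            "genes in the map; recall is undefined"
        )
    ii = np.array([sim.index_of(a) for a, _ in eval_pairs])
    jj = np.array([sim.index_of(b) for _, b in eval_pairs])
    vals = sim.values[ii, jj]
    # ties at the cut are not predicted links (strictly below/above)
    hits = int(np.sum((vals < lo) | (vals > hi)))
    return RecallResult(
        ann.source_name, 100.0 * hits / len(eval_pairs),
        len(eval_pairs), lo, hi,
    )


def recall(sim: SimilarityMatrix, ann: AnnotationSet,
           tail: float = 0.05) -> RecallResult:
    """Percentile-tail recall of one annotation source against a map."""
    lo, hi = percentile_cuts(sim, tail)
    return _recall_with_cuts(sim, ann, lo, hi)


def benchmark_all(sim: SimilarityMatrix, sources: list[AnnotationSet],
                  tail: float = 0.05) -> list[RecallResult]:
    """Recall for each source, with the percentile cuts computed once."""
    if not sources:
        raise PermapError("benchmark_all needs >= 1 annotation source")
    lo, hi = percentile_cuts(sim, tail)
    return [_recall_with_cuts(sim, ann, lo, hi) for ann in sources]


# ---------------------------------------------------------------------------
# noise sensitivity: replicate subsampling
# ---------------------------------------------------------------------------

def subsample_replicates(units: UnitMatrix, level: int,
                         rng: np.random.Generator) -> UnitMatrix:
    """Keep at most ``level`` randomly chosen units per non-control gene.

    Controls are always kept in full (they anchor the alignment).  Genes
    with fewer than ``level`` units keep all of theirs; the fallback count
    is recorded in ``info``.
    """
    if level < 1:
        raise PermapError("sampling level must be >= 1")
    ctrl = units.is_control.to_numpy()
    pert = units.perturbation.to_numpy()
    keep = np.zeros(units.n_units, dtype=bool)
    keep[ctrl] = True
    fallback = 0
    for g in pd.unique(pert[~ctrl]):
        ix = np.flatnonzero((pert == g) & ~ctrl)
        if len(ix) <= level:
            keep[ix] = True
            if len(ix) < level:
                fallback += 1
        else:
            keep[rng.choice(ix, size=level, replace=False)] = True
    out = units.subset(keep)
    out.info["subsample"] = {"level": int(level),
                             "genes_below_level": int(fallback)}
    return out


@dataclass
class NoiseSensitivityResult:
    """Per-(level, repeat, source) recalls plus a mean/sd summary."""

    table: pd.DataFrame    # level, repeat, source, recall_percent, n_eval_pairs
    summary: pd.DataFrame  # level, source, mean_recall, sd_recall, n_repeats


def noise_sensitivity(units: UnitMatrix, config: PipelineConfig,
                      sources: list[AnnotationSet], levels: list[int],
                      repeats: int = 3, tail: float = 0.05,
                      seed: int = 0) -> NoiseSensitivityResult:
    """Rebuild the map on per-gene replicate subsamples and re-benchmark.

    One master seed spawns an independent child stream per (level, repeat)
    so results are reproducible and adding levels does not shift existing
    draws.
    """
    if repeats < 1:
        raise PermapError("repeats must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(levels) * repeats)
    rows = []
    for li, level in enumerate(levels):
        for rep in range(repeats):
            rng = np.random.default_rng(children[li * repeats + rep])
            sub = subsample_replicates(units, level, rng)
            _amap, sim = run_pipeline(sub, config)
            for res in benchmark_all(sim, sources, tail=tail):
                rows.append({
                    "level": level, "repeat": rep,
                    "source": res.source_name,
                    "recall_percent": res.recall_percent,
                    "n_eval_pairs": res.n_eval_pairs,
                })
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["level", "source"], sort=True)["recall_percent"]
        .agg(mean_recall="mean", sd_recall="std", n_repeats="count")
        .reset_index()
    )
    summary["sd_recall"] = summary["sd_recall"].fillna(0.0)
    return NoiseSensitivityResult(table, summary)
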