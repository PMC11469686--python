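"""The five map-building stages: Embed, Filter, Align, Aggregate, Relate.

A perturbative map is built by composing, in order,

* **Filter** — drop low-quality units (robust Gaussian outlier removal on
  intensity-type QC features, cell-count windows) and uninformative feature
  columns;
* **Embed** — optionally replace features by their top principal components,
  after a per-batch center/scale of the inputs;
* **Align** — remove batch effects, either by centering/scaling each feature
  to control statistics (per batch or globally) or by typical-variation
  normalization (TVN): a control-anchored PCA followed by global control
  scaling and per-batch correlation alignment (CORAL) of each batch's
  controls to a white frame;
* **Aggregate** — average the aligned replicate units of each perturbation;
* **Relate** — compute all pairwise cosine similarities between the
  aggregated gene embeddings.

Named presets reproduce the standard pipeline family: ``raw-cs``,
``raw-tvn``, ``pca``, ``pca-cs`` and ``pca-tvn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.covariance import EllipticEnvelope
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import cosine_similarity

from .map_model import (
    AggregatedMap,
    PermapError,
    SimilarityMatrix,
    UnitMatrix,
)

__all__ = [
    "FilterRule",
    "robust_gaussian_outlier",
    "range_filter",
    "drop_columns",
    "PipelineConfig",
    "pipeline_preset",
    "embed_pca",
    "apply_filters",
    "align_center_scale",
    "align_tvn",
    "aggregate_mean",
    "relate_cosine",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterRule:
    """A single unit/column filter; build via the factory helpers below."""

    kind: str
    params: dict = field(default_factory=dict)


def robust_gaussian_outlier(column_selector: str, contamination: float = 0.01,
                            seed: int = 0) -> FilterRule:
    """Remove the declared fraction of units farthest from a robust Gaussian
    fit of the columns whose names contain ``column_selector``."""
    if not 0 < contamination < 0.5:
        raise PermapError("contamination must be in (0, 0.5)")
    return FilterRule("robust_gaussian_outlier", {
        "column_selector": column_selector,
        "contamination": float(contamination),
        "seed": int(seed),
    })


def range_filter(column: str, low: float, high: float,
                 inclusive: bool = True) -> FilterRule:
    """Keep units whose ``column`` value lies in [low, high] (or (low, high))."""
    if low > high:
        raise PermapError("range_filter requires low <= high")
    return FilterRule("range_filter", {
        "column": column, "low": float(low), "high": float(high),
        "inclusive": bool(inclusive),
    })


def drop_columns(prefix: str) -> FilterRule:
    """Drop every feature column whose name starts with ``prefix``."""
    return FilterRule("drop_columns", {"prefix": prefix})


def _select_columns(units: UnitMatrix, selector: str) -> pd.DataFrame:
    cols = [c for c in units.features.columns if selector in c]
    frames = [units.features[cols]] if cols else []
    if units.qc is not None:
        qcols = [c for c in units.qc.columns if selector in c]
        if qcols:
            frames.append(units.qc[qcols])
    if not frames:
        raise PermapError(f"no columns match selector {selector!r}")
    return pd.concat(frames, axis=1)


def _apply_one(units: UnitMatrix, rule: FilterRule) -> UnitMatrix:
    p = rule.params
    if rule.kind == "robust_gaussian_outlier":
        X = _select_columns(units, p["column_selector"]).to_numpy(dtype=float)
        est = EllipticEnvelope(
            contamination=p["contamination"], random_state=p["seed"]
        ).fit(X)
        keep = est.predict(X) == 1
        return units.subset(keep)
    if rule.kind == "range_filter":
        vals = units.column(p["column"]).to_numpy(dtype=float)
        if p["inclusive"]:
            keep = (vals >= p["low"]) & (vals <= p["high"])
        else:
            keep = (vals > p["low"]) & (vals < p["high"])
        return units.subset(keep)
    if rule.kind == "drop_columns":
        cols = [c for c in units.features.columns
                if not c.startswith(p["prefix"])]
        return units.with_features(units.features[cols])
    raise PermapError(f"unknown filter kind {rule.kind!r}")


def apply_filters(units: UnitMatrix, rules: list[FilterRule]) -> UnitMatrix:
    """Apply filter rules in their declared order, logging removal counts."""
    log = []
    for rule in rules:
        before_units, before_dims = units.n_units, units.n_dims
        units = _apply_one(units, rule)
        log.append({
            "rule": rule.kind, **rule.params,
            "units_removed": before_units - units.n_units,
            "columns_removed": before_dims - units.n_dims,
        })
        if units.n_units == 0:
            raise PermapError(f"all units filtered out by rule {rule.kind!r}")
    units.info.setdefault("filters", []).extend(log)
    return units


# ---------------------------------------------------------------------------
# Embed
# ---------------------------------------------------------------------------

def _fix_pca_signs(components: np.ndarray, scores: np.ndarray):
    """Make each component's largest-magnitude loading positive, for
    reproducibility across linear-algebra backends."""
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return components * flip[:, None], scores * flip[None, :]


def _per_batch_zscore(units: UnitMatrix) -> np.ndarray:
    """Center and scale every feature within each batch, over all units."""
    X = units.values()
    out = np.empty_like(X)
    for b in units.batch.unique():
        m = (units.batch == b).to_numpy()
        mu = X[m].mean(axis=0)
        sd = X[m].std(axis=0, ddof=1) if m.sum() > 1 else np.ones(X.shape[1])
        sd = np.where(sd == 0, 1.0, sd)
        out[m] = (X[m] - mu) / sd
    return out


def embed_pca(units: UnitMatrix, k: int, fit_on: str = "all",
              prescale_per_batch: bool = True) -> UnitMatrix:
    """Project units onto their top-``k`` principal components.

    By default each feature is first centered and scaled within its batch
    (over all units), then a single PCA is fitted — on all units, or on
    controls only with ``fit_on="controls"`` — and every unit is projected.
    Explained-variance fractions are recorded in ``info``.
    """
    if fit_on not in ("all", "controls"):
        raise PermapError("fit_on must be 'all' or 'controls'")
    X = _per_batch_zscore(units) if prescale_per_batch else units.values()
    if fit_on == "controls":
        fit_X = X[units.is_control.to_numpy()]
        if fit_X.shape[0] < 2:
            raise PermapError("PCA on controls needs >= 2 control units")
    else:
        fit_X = X
    attainable = min(fit_X.shape)
    if k > attainable:
        raise PermapError(
            f"k={k} exceeds attainable rank {attainable} "
            f"({fit_X.shape[0]} fit units x {fit_X.shape[1]} dims)"
        )
    pca = PCA(n_components=k, svd_solver="full").fit(fit_X)
    comps, _ = _fix_pca_signs(pca.components_, np.empty((0, k)))
    scores = (X - pca.mean_) @ comps.T
    cols = [f"pc{i + 1}" for i in range(k)]
    out = units.with_features(pd.DataFrame(scores, columns=cols,
                                           index=units.unit_ids))
    out.info["pca"] = {
        "k": int(k),
        "fit_on": fit_on,
        "prescale_per_batch": bool(prescale_per_batch),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }
    return out


# ---------------------------------------------------------------------------
# Align
# ---------------------------------------------------------------------------

def _ref_stats(X: np.ndarray, feature_names, what: str):
    if X.shape[0] < 2:
        raise PermapError(f"{what}: needs >= 2 reference units, got {X.shape[0]}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        name = feature_names[int(np.argmax(sd == 0))]
        raise PermapError(f"{what}: zero standard deviation in feature {name!r}")
    return mu, sd


def align_center_scale(units: UnitMatrix, scope: str = "per_batch",
                       reference: str = "controls") -> UnitMatrix:
    """Center and scale each feature to reference-unit statistics.

    ``reference="controls"`` uses the control units (the usual choice);
    ``scope`` decides whether statistics are taken per batch or globally.
    """
    if scope not in ("per_batch", "global"):
        raise PermapError("scope must be 'per_batch' or 'global'")
    if reference not in ("controls", "all"):
        raise PermapError("reference must be 'controls' or 'all'")
    X = units.values().copy()
    names = list(units.features.columns)
    ctrl = units.is_control.to_numpy()
    ref_mask = ctrl if reference == "controls" else np.ones(len(X), bool)
    if scope == "global":
        mu, sd = _ref_stats(X[ref_mask], names, "global center/scale")
        X = (X - mu) / sd
    else:
        short = [b for b in units.batch.unique()
                 if (ref_mask & (units.batch == b).to_numpy()).sum() < 2]
        if short:
            raise PermapError(
                f"batches with < 2 reference units: {sorted(short)}"
            )
        for b in units.batch.unique():
            m = (units.batch == b).to_numpy()
            mu, sd = _ref_stats(X[m & ref_mask], names, f"batch {b!r}")
            X[m] = (X[m] - mu) / sd
    out = units.with_features(pd.DataFrame(X, columns=names,
                                           index=units.unit_ids))
    out.info["align"] = {"method": "center_scale", "scope": scope,
                         "reference": reference}
    return out


def _inv_sqrt(cov: np.ndarray, batch: str) -> np.ndarray:
    """Inverse principal square root with epsilon ridge regularization."""
    eps = 1e-6 * float(np.mean(np.diag(cov)))
    cov = cov + eps * np.eye(cov.shape[0])
    w, V = linalg.eigh(cov)
    if w.min() <= 0:
        raise PermapError(
            f"control covariance of batch {batch!r} is numerically singular"
        )
    return (V / np.sqrt(w)) @ V.T


def align_tvn(units: UnitMatrix) -> UnitMatrix:
    """Typical-variation normalization, anchored entirely on controls.

    Steps: (1) center/scale every feature to global control statistics;
    (2) fit PCA on the controls only (all attainable components) and project
    every unit; (3) center/scale the component scores to global control
    statistics; (4) per batch, CORAL: center by the batch-control mean and
    whiten by the batch-control covariance (inverse principal square root),
    so every batch's controls end up approximately white in a shared frame.
    """
    ctrl = units.is_control.to_numpy()
    if ctrl.sum() < 2:
        raise PermapError("TVN needs >= 2 control units globally")
    step1 = align_center_scale(units, scope="global", reference="controls")
    # centered control-fit PCA has rank <= n_controls - 1
    k = min(int(ctrl.sum()) - 1, step1.n_dims)
    step2 = embed_pca(step1, k=k, fit_on="controls", prescale_per_batch=False)
    step3 = align_center_scale(step2, scope="global", reference="controls")
    X = step3.values().copy()
    names = list(step3.features.columns)
    for b in step3.batch.unique():
        m = (step3.batch == b).to_numpy()
        cm = m & ctrl
        if cm.sum() < 2:
            raise PermapError(f"batch {b!r} has < 2 control units")
        mu = X[cm].mean(axis=0)
        cov = np.cov(X[cm], rowvar=False, ddof=1)
        X[m] = (X[m] - mu) @ _inv_sqrt(np.atleast_2d(cov), str(b))
    out = step3.with_features(pd.DataFrame(X, columns=names,
                                           index=units.unit_ids))
    out.info["align"] = {"method": "tvn", "pca_components": int(k)}
    return out


# ---------------------------------------------------------------------------
# Aggregate, Relate
# ---------------------------------------------------------------------------

def aggregate_mean(units: UnitMatrix) -> AggregatedMap:
    """Average the units of each non-control perturbation into one vector."""
    pert = units.subset(~units.is_control.to_numpy())
    if pert.n_units == 0:
        raise PermapError("no non-control units to aggregate")
    grouped = pert.features.groupby(pert.perturbation, sort=True).mean()
    counts = pert.perturbation.value_counts().sort_index()
    # carry the expressed flag to the gene level (constant within a gene)
    expressed = (
        pert.obs.groupby("perturbation", sort=True)["is_expressed"]
        .agg(lambda s: bool(s.iloc[0]) if s.notna().any() else None)
    )
    prov = dict(units.info)
    prov["aggregate"] = "mean"
    prov["replicate_counts"] = counts.to_dict()
    prov["is_expressed"] = expressed.to_dict()
    return AggregatedMap(grouped, prov)


def relate_cosine(amap: AggregatedMap) -> SimilarityMatrix:
    """All pairwise cosine similarities between aggregated gene embeddings."""
    X = amap.values()
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        gene = amap.genes[int(np.argmax(norms == 0))]
        raise PermapError(f"gene {gene!r} has a zero-norm aggregated vector")
    S = cosine_similarity(X)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(amap.genes, S)


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative description of one EFAAR pipeline.

    Stages run in the order filter -> embed -> align -> aggregate -> relate.
    ``embed``: ``"none"`` or ``"pca"`` (with ``pca_k``, ``pca_fit_on``,
    ``pca_prescale_per_batch``); ``align``: ``"none"``, ``"center_scale"``
    (with ``cs_scope``/``cs_reference``) or ``"tvn"``.
    """

    name: str = "custom"
    filters: list[FilterRule] = field(default_factory=list)
    embed: str = "none"
    pca_k: int = 128
    pca_fit_on: str = "all"
    pca_prescale_per_batch: bool = True
    align: str = "none"
    cs_scope: str = "per_batch"
    cs_reference: str = "controls"
    aggregate: str = "mean"
    relate: str = "cosine"
    seed: int = 0

    def __post_init__(self):
        if self.embed not in ("none", "pca"):
            raise PermapError(f"unknown embed stage {self.embed!r}")
        if self.align not in ("none", "center_scale", "tvn"):
            raise PermapError(f"unknown align stage {self.align!r}")
        if self.aggregate != "mean":
            raise PermapError(f"unknown aggregate stage {self.aggregate!r}")
        if self.relate != "cosine":
            raise PermapError(f"unknown relate stage {self.relate!r}")
        if self.embed == "pca" and self.pca_k < 1:
            raise PermapError("pca_k must be >= 1")

    def describe(self) -> dict:
        d = asdict(self)
        d["filters"] = [{"kind": r.kind, **r.params} for r in self.filters]
        return d


def pipeline_preset(name: str, k: int = 128, seed: int = 0,
                    filters: list[FilterRule] | None = None) -> PipelineConfig:
    """Named pipeline presets: raw, raw-cs, raw-tvn, pca, pca-cs, pca-tvn."""
    key = name.lower().replace("_", "-")
    base = dict(name=key, seed=seed, filters=list(filters or []))
    if key == "raw":
        return PipelineConfig(**base)
    if key == "raw-cs":
        return PipelineConfig(**base, align="center_scale",
                              cs_scope="per_batch", cs_reference="controls")
    if key == "raw-tvn":
        return PipelineConfig(**base, align="tvn")
    if key == "pca":
        return PipelineConfig(**base, embed="pca", pca_k=k)
    if key == "pca-cs":
        return PipelineConfig(**base, embed="pca", pca_k=k,
                              align="center_scale", cs_scope="per_batch",
                              cs_reference="controls")
    if key == "pca-tvn":
        return PipelineConfig(**base, embed="pca", pca_k=k, align="tvn")
    raise PermapError(f"unknown pipeline preset {name!r}")


def run_pipeline(units: UnitMatrix, config: PipelineConfig):
    """Execute a full EFAAR pipeline; returns (AggregatedMap, SimilarityMatrix).

    Provenance (the full config plus per-stage logs) is recorded on the
    aggregated map.
    """
    if config.filters:
        units = apply_filters(units, list(config.filters))
    if config.embed == "pca":
        units = embed_pca(units, k=config.pca_k, fit_on=config.pca_fit_on,
                          prescale_per_batch=config.pca_prescale_per_batch)
    if config.align == "center_scale":
        units = align_center_scale(units, scope=config.cs_scope,
                                   reference=config.cs_reference)
    elif config.align == "tvn":
        units = align_tvn(units)
    amap = aggregate_mean(units)
    amap.provenance["pipeline"] = config.describe()
    sim = relate_cosine(amap)
    return amap, sim
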