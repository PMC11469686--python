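"""Core data model for perturbative maps.

Three containers move through the pipeline:

``UnitMatrix``
    One row per perturbation *unit* (a cell in pooled single-cell screens,
    a well or guide in arrayed screens) with numeric feature columns plus
    metadata: the perturbation label, the batch label, a control flag and —
    for non-controls — an expressed flag.  Optional QC columns (intensity
    metrics, object counts) ride along and may be consumed by filters.

``AggregatedMap``
    One embedding vector per perturbed gene, obtained after filtering,
    alignment and replicate aggregation, together with a provenance record
    describing how it was built.

``SimilarityMatrix``
    The symmetric matrix of pairwise cosine similarities over the map's
    gene universe.

Interchange is via delimited tables with a declared column-role schema,
because upstream datasets use incompatible column conventions.  Gene labels
are case-preserved and matched case-sensitively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PermapError",
    "SchemaError",
    "TableSchema",
    "UnitMatrix",
    "AggregatedMap",
    "SimilarityMatrix",
    "read_unit_matrix",
    "write_unit_matrix",
    "read_aggregated_map",
    "write_aggregated_map",
]


class PermapError(Exception):
    """Base class for errors raised by permap."""


class SchemaError(PermapError):
    """A table does not match the declared column-role schema."""


# role-named columns used by the default on-disk layout
_STD = {
    "unit_id": "unit_id",
    "perturbation": "perturbation",
    "batch": "batch",
    "is_control": "is_control",
    "is_expressed": "is_expressed",
}


@dataclass(frozen=True)
class TableSchema:
    """Maps column names of a delimited unit table onto their roles.

    Every column not claimed by a role and not matching a ``qc_prefixes``
    entry is treated as a numeric feature column.
    """

    perturbation: str = "perturbation"
    batch: str = "batch"
    is_control: str = "is_control"
    is_expressed: str | None = "is_expressed"
    unit_id: str | None = "unit_id"
    qc_prefixes: tuple[str, ...] = ()

    def claimed(self) -> set[str]:
        cols = {self.perturbation, self.batch, self.is_control}
        if self.is_expressed:
            cols.add(self.is_expressed)
        if self.unit_id:
            cols.add(self.unit_id)
        return cols


def _as_bool(s: pd.Series, column: str) -> pd.Series:
    """Coerce a metadata column to boolean, accepting 0/1 and true/false text."""
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise SchemaError(f"column {column!r}: cannot interpret {bad!r} as a boolean")
    return out.astype(bool)


class UnitMatrix:
    """Unit-level embeddings plus metadata.

    Parameters
    ----------
    features
        Numeric frame, units x dimensions; the index holds unique unit ids.
    obs
        Per-unit metadata with columns ``perturbation``, ``batch``,
        ``is_control`` and ``is_expressed`` (nullable boolean; undefined for
        controls), sharing ``features``' index.
    qc
        Optional numeric QC columns on the same index.
    info
        Free-form record of processing performed so far (stage logs,
        explained-variance fractions, filter counts).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        obs: pd.DataFrame,
        qc: pd.DataFrame | None = None,
        info: dict | None = None,
    ):
        features = features.copy()
        obs = obs.copy()
        if not features.index.equals(obs.index):
            raise PermapError("features and obs must share the same unit index")
        if features.index.has_duplicates:
            dup = features.index[features.index.duplicated()][0]
            raise PermapError(f"duplicate unit id {dup!r}")
        vals = features.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = [c for c in features.columns
                   if not np.issubdtype(features[c].dtype, np.number)]
            raise SchemaError(f"non-numeric feature column(s): {bad}")
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise PermapError(
                f"missing feature value at unit {features.index[r]!r}, "
                f"column {features.columns[c]!r}"
            )
        for col in ("perturbation", "batch", "is_control"):
            if col not in obs.columns:
                raise SchemaError(f"obs is missing mandatory column {col!r}")
            if obs[col].isna().any():
                raise SchemaError(f"obs column {col!r} contains missing values")
        if "is_expressed" not in obs.columns:
            obs["is_expressed"] = pd.Series(pd.NA, index=obs.index, dtype="boolean")
        obs["is_control"] = _as_bool(obs["is_control"], "is_control").astype(bool)
        obs["is_expressed"] = obs["is_expressed"].astype("boolean")
        # expressed flag is defined only for non-controls
        obs.loc[obs["is_control"], "is_expressed"] = pd.NA
        if qc is not None:
            qc = qc.copy()
            if not qc.index.equals(features.index):
                raise PermapError("qc must share the unit index")
        self.features = features
        self.obs = obs
        self.qc = qc
        self.info: dict = dict(info or {})

    # -- basic introspection -------------------------------------------------
    @property
    def unit_ids(self) -> pd.Index:
        return self.features.index

    @property
    def n_units(self) -> int:
        return self.features.shape[0]

    @property
    def n_dims(self) -> int:
        return self.features.shape[1]

    @property
    def perturbation(self) -> pd.Series:
        return self.obs["perturbation"]

    @property
    def batch(self) -> pd.Series:
        return self.obs["batch"]

    @property
    def is_control(self) -> pd.Series:
        return self.obs["is_control"]

    @property
    def is_expressed(self) -> pd.Series:
        return self.obs["is_expressed"]

    def values(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def column(self, name: str) -> pd.Series:
        """Look up a feature or QC column by name."""
        if name in self.features.columns:
            return self.features[name]
        if self.qc is not None and name in self.qc.columns:
            return self.qc[name]
        raise SchemaError(f"no feature or QC column named {name!r}")

    # -- derived views -------------------------------------------------------
    def subset(self, mask) -> "UnitMatrix":
        """Row subset by boolean mask or index labels (order-preserving)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = self.features.index[mask]
        else:
            idx = pd.Index(mask)
        return UnitMatrix(
            self.features.loc[idx],
            self.obs.loc[idx],
            None if self.qc is None else self.qc.loc[idx],
            self.info,
        )

    def with_features(self, features: pd.DataFrame) -> "UnitMatrix":
        """Replace the feature block, keeping metadata and QC aligned."""
        if features.shape[0] != self.n_units:
            raise PermapError("replacement features must keep the unit count")
        features = features.set_axis(self.features.index, axis=0)
        return UnitMatrix(features, self.obs, self.qc, self.info)

    def controls(self) -> "UnitMatrix":
        return self.subset(self.is_control.to_numpy())

    def units_of(self, perturbation: str) -> "UnitMatrix":
        mask = (self.perturbation == perturbation).to_numpy()
        if not mask.any():
            raise PermapError(f"no units for perturbation {perturbation!r}")
        return self.subset(mask)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"UnitMatrix({self.n_units} units x {self.n_dims} dims, "
            f"{int(self.is_control.sum())} controls, "
            f"{self.batch.nunique()} batches)"
        )


@dataclass
class AggregatedMap:
    """One embedding vector per perturbed gene.

    ``vectors`` is a numeric frame indexed by gene label (ordered, unique);
    ``provenance`` records the pipeline that produced it.
    """

    vectors: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vectors.index.has_duplicates:
            dup = self.vectors.index[self.vectors.index.duplicated()][0]
            raise PermapError(f"duplicate gene label {dup!r}")
        vals = self.vectors.to_numpy(dtype=float)
        if np.isnan(vals).all(axis=1).any():
            raise PermapError("aggregated map contains an all-missing row")

    @property
    def genes(self) -> list[str]:
        return list(self.vectors.index)

    @property
    def n_genes(self) -> int:
        return self.vectors.shape[0]

    def values(self) -> np.ndarray:
        return self.vectors.to_numpy(dtype=float)


@dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene cosine similarity matrix in [-1, 1]."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise PermapError("similarity matrix shape does not match gene list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise PermapError("similarity matrix must be symmetric")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._pos[gene]
        except KeyError:
            raise PermapError(f"gene {gene!r} is not in the map") from None

    def lookup(self, gene_a: str, gene_b: str) -> float:
        return float(self.values[self.index_of(gene_a), self.index_of(gene_b)])

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle similarities: each unordered gene pair once."""
        iu = np.triu_indices(self.n_genes, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


# ---------------------------------------------------------------------------
# delimited-table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_unit_matrix(path, schema: TableSchema | None = None) -> UnitMatrix:
    """Read a unit table from a delimited file under a column-role schema.

    Columns not claimed by the schema and not matching a QC prefix are the
    feature columns; they must parse as numbers and contain no missing values.
    """
    schema = schema or TableSchema()
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for role, col in (
        ("perturbation", schema.perturbation),
        ("batch", schema.batch),
        ("is_control", schema.is_control),
    ):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} (role: {role})")
    if schema.unit_id and schema.unit_id in df.columns:
        df = df.set_index(schema.unit_id)
        df.index = df.index.astype(str)
    else:
        df.index = pd.Index([f"unit{i}" for i in range(len(df))])
    obs = pd.DataFrame(index=df.index)
    obs["perturbation"] = df[schema.perturbation].astype(str)
    obs["batch"] = df[schema.batch].astype(str)
    obs["is_control"] = _as_bool(df[schema.is_control], schema.is_control)
    if schema.is_expressed and schema.is_expressed in df.columns:
        raw = df[schema.is_expressed]
        expressed = pd.Series(pd.NA, index=df.index, dtype="boolean")
        defined = raw.notna()
        if defined.any():
            expressed[defined] = _as_bool(raw[defined], schema.is_expressed)
        obs["is_expressed"] = expressed
    claimed = schema.claimed()
    qc_cols = [
        c for c in df.columns
        if c not in claimed and any(c.startswith(p) for p in schema.qc_prefixes)
    ]
    feat_cols = [c for c in df.columns if c not in claimed and c not in qc_cols]
    feats = df[feat_cols].copy()
    for c in feat_cols:
        coerced = pd.to_numeric(feats[c], errors="coerce")
        bad = coerced.isna() & feats[c].notna()
        if bad.any():
            row = feats.index[bad][0]
            raise SchemaError(
                f"non-numeric feature value in column {c!r}, row {row!r}"
            )
        feats[c] = coerced
    qc = df[qc_cols].apply(pd.to_numeric) if qc_cols else None
    return UnitMatrix(feats.astype(float), obs, qc)


def write_unit_matrix(units: UnitMatrix, path) -> None:
    """Write a unit table readable by :func:`read_unit_matrix` with defaults."""
    out = pd.DataFrame(index=units.unit_ids)
    out[_STD["perturbation"]] = units.perturbation
    out[_STD["batch"]] = units.batch
    out[_STD["is_control"]] = units.is_control
    out[_STD["is_expressed"]] = units.is_expressed
    if units.qc is not None:
        for c in units.qc.columns:
            out[c] = units.qc[c]
    for c in units.features.columns:
        out[c] = units.features[c]
    out.index.name = _STD["unit_id"]
    # %.17g guarantees bit-exact float round-trips through text
    out.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def _sidecar(path) -> str:
    return str(path) + ".meta.json"


def write_aggregated_map(amap: AggregatedMap, path) -> None:
    """Write a gene-by-dimension table plus a sidecar provenance record."""
    out = amap.vectors.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sep_for(path), float_format="%.17g")
    with open(_sidecar(path), "w") as fh:
        json.dump(amap.provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_aggregated_map(path) -> AggregatedMap:
    df = pd.read_csv(path, sep=_sep_for(path), index_col="gene",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    try:
        with open(_sidecar(path)) as fh:
            prov = json.load(fh)
    except FileNotFoundError:
        prov = {}
    return AggregatedMap(df.astype(float), prov)
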