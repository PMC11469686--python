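"""Readers and normalizers for relationship-annotation sources.

Three kinds of ground-truth biology feed the benchmarks:

* scored gene-gene edge lists (StringDB-style protein links, thresholded
  at a confidence score, e.g. >= 950 on the 0-1000 scale);
* complex/cluster catalogs (CORUM- or HuMAP-style: complex name -> member
  genes), from which the union of all within-complex pairs is taken;
* gene-set collections in GMT format (term, description, members).

All pair sets are stored as deduplicated *unordered* pairs in canonical
order (lexicographically smaller gene first) with self-pairs dropped.
Gene symbols are matched case-sensitively; an optional alias map may be
applied at read time since symbol conventions differ across sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .map_model import PermapError, SchemaError

__all__ = [
    "AnnotationSet",
    "ComplexCatalog",
    "canonical_pair",
    "read_scored_edges",
    "read_complex_catalog",
    "read_gmt",
    "complexes_to_pairs",
    "source_overlap",
    "write_pairs",
    "read_pairs",
]

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair in canonical (sorted) order; self-pairs are invalid."""
    a, b = str(a).strip(), str(b).strip()
    if a == b:
        raise PermapError(f"self-pair ({a!r}, {b!r}) is not a relationship")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class AnnotationSet:
    """Deduplicated unordered gene pairs from one annotation source."""

    source_name: str
    pairs: frozenset[Pair]

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise PermapError(f"self-pair ({a!r}, {a!r}) in annotation set")
            if a > b:
                raise PermapError(f"pair ({a!r}, {b!r}) is not in canonical order")

    @classmethod
    def from_iterable(cls, source_name: str, pairs) -> "AnnotationSet":
        canon = set()
        for a, b in pairs:
            if str(a).strip() == str(b).strip():
                continue  # self-edges silently dropped on load
            canon.add(canonical_pair(a, b))
        return cls(source_name, frozenset(canon))

    @property
    def genes(self) -> set[str]:
        out = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ComplexCatalog:
    """Named gene clusters (protein complexes); clusters may overlap."""

    complexes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {}
        for name, members in self.complexes.items():
            seen, uniq = set(), []
            for g in members:
                g = str(g).strip()
                if g and g not in seen:
                    seen.add(g)
                    uniq.append(g)
            cleaned[str(name)] = uniq
        self.complexes = cleaned

    def __len__(self) -> int:
        return len(self.complexes)

    def items(self):
        return self.complexes.items()


def _apply_aliases(gene: str, aliases: dict[str, str] | None) -> str:
    gene = str(gene).strip()
    return aliases.get(gene, gene) if aliases else gene


def read_scored_edges(path, score_threshold: float,
                      columns: tuple[str, str, str] = ("gene_a", "gene_b", "score"),
                      sep: str | None = None,
                      aliases: dict[str, str] | None = None,
                      source_name: str | None = None) -> AnnotationSet:
    """Read a scored edge list, keeping edges with score >= threshold.

    Edges listed in both orientations collapse to one pair; self-edges are
    dropped.  ``columns`` names the (gene A, gene B, score) columns.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    ca, cb, cs = columns
    for c in (ca, cb, cs):
        if c not in df.columns:
            raise SchemaError(f"edge list is missing column {c!r}")
    scores = pd.to_numeric(df[cs], errors="coerce")
    if scores.isna().any():
        raise SchemaError(f"non-numeric score in column {cs!r}")
    keep = df[scores >= score_threshold]
    pairs = (
        (_apply_aliases(a, aliases), _apply_aliases(b, aliases))
        for a, b in zip(keep[ca], keep[cb])
    )
    name = source_name or str(path)
    return AnnotationSet.from_iterable(name, pairs)


def read_complex_catalog(path, sep: str | None = None,
                         columns: tuple[str, str] = ("complex", "gene"),
                         aliases: dict[str, str] | None = None) -> ComplexCatalog:
    """Read a two-column (complex, gene) membership table."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cc, cg = columns
    for c in (cc, cg):
        if c not in df.columns:
            raise SchemaError(f"complex catalog is missing column {c!r}")
    out: dict[str, list[str]] = {}
    for name, gene in zip(df[cc], df[cg]):
        out.setdefault(str(name), []).append(_apply_aliases(gene, aliases))
    return ComplexCatalog(out)


def read_gmt(path, aliases: dict[str, str] | None = None) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: term <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"GMT line {lineno}: expected term, description and "
                    f">= 1 gene, got {len(parts)} fields"
                )
            term, _desc, *genes = parts
            members, seen = [], set()
            for g in genes:
                g = _apply_aliases(g, aliases)
                if g and g not in seen:
                    seen.add(g)
                    members.append(g)
            sets[term] = members
    return sets


def complexes_to_pairs(catalog: ComplexCatalog,
                       source_name: str = "complexes") -> AnnotationSet:
    """Union of all unordered within-complex member pairs across complexes."""
    pairs = set()
    for _name, members in catalog.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(canonical_pair(members[i], members[j]))
    return AnnotationSet(source_name, frozenset(pairs))


def source_overlap(sources: list[AnnotationSet]) -> pd.DataFrame:
    """Pair-multiplicity breakdown across annotation sources.

    Returns one row per multiplicity m = 1..len(sources) with the number of
    unique pairs present in exactly m and in at least m sources.
    """
    if len(sources) < 2:
        raise PermapError("source_overlap needs >= 2 sources")
    counts: dict[Pair, int] = {}
    for src in sources:
        for p in src.pairs:
            counts[p] = counts.get(p, 0) + 1
    m_max = len(sources)
    exactly = {m: 0 for m in range(1, m_max + 1)}
    for m in counts.values():
        exactly[m] += 1
    rows = []
    for m in range(1, m_max + 1):
        rows.append({
            "multiplicity": m,
            "exactly_m": exactly[m],
            "at_least_m": sum(exactly[j] for j in range(m, m_max + 1)),
        })
    return pd.DataFrame(rows)


def write_pairs(ann: AnnotationSet, path) -> None:
    """Write an annotation set as a two-column delimited pair list."""
    df = pd.DataFrame(sorted(ann.pairs), columns=["gene_a", "gene_b"])
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df.to_csv(path, index=False, sep=sep)


def read_pairs(path, source_name: str | None = None) -> AnnotationSet:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for c in ("gene_a", "gene_b"):
        if c not in df.columns:
            raise SchemaError(f"pair list is missing column {c!r}")
    return AnnotationSet.from_iterable(
        source_name or str(path), zip(df["gene_a"], df["gene_b"])
    )
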