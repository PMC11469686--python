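"""Synthetic perturbation-screen generator with known ground truth.

The generator emulates the statistical structure the map-building and
benchmarking machinery assumes of a real genome-scale screen:

* each expressed gene has a fixed *true effect vector* in feature space;
  genes planted in the same complex share a latent direction (plus a small
  gene-specific jitter), so their aggregated profiles end up correlated;
* unexpressed genes have zero true effect — they are the material for the
  permutation null;
* every replicate unit of a gene is the gene effect plus isotropic
  Gaussian measurement noise, distorted by its batch's artifact;
* negative-control units carry batch artifacts and noise only;
* batch artifacts are affine: an additive offset drawn per batch, and a
  multiplicative per-feature scaling applied in a fixed latent orthogonal
  frame shared by all batches.  The latent frame makes the scaling
  *correlated* across observed features — as real batch effects are — so
  per-feature centering/scaling cannot fully undo it while covariance
  whitening (CORAL/TVN) can.

Ground truth is returned alongside the units: the planted complex catalog
and the within-complex pair set, ready for the relationship benchmarks.
All randomness flows from one master seed through a named-substream
registry, so adding a draw site never shifts existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, ComplexCatalog, complexes_to_pairs
from .map_model import PermapError, UnitMatrix

__all__ = ["SimConfig", "simulate", "write_simulation"]

CONTROL_LABEL = "nontargeting"
_JITTER = 0.25  # gene-specific jitter around a complex's shared direction


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic screen.

    ``effect_scale`` sets the per-feature standard deviation of true gene
    effects relative to ``noise_sd`` (the per-replicate measurement noise);
    ``batch_shift_scale`` the additive batch offset scale, and
    ``batch_scale_spread`` the standard deviation of per-feature log
    scalings applied in the shared latent frame.
    """

    n_genes: int = 1000           # expressed genes
    n_unexpressed: int = 1000     # null genes for the permutation null
    n_complexes: int = 20
    complex_size: int = 12
    effect_scale: float = 1.0
    dims: int = 32
    n_batches: int = 4
    replicates_per_gene: int = 4
    controls_per_batch: int = 32
    batch_shift_scale: float = 1.0
    batch_scale_spread: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "dims": self.dims,
            "n_batches": self.n_batches,
            "replicates_per_gene": self.replicates_per_gene,
            "controls_per_batch": self.controls_per_batch,
        }
        for name, v in counts.items():
            if v < 1:
                raise PermapError(f"{name} must be >= 1, got {v}")
        if self.n_unexpressed < 0 or self.n_complexes < 0:
            raise PermapError("n_unexpressed and n_complexes must be >= 0")
        if self.n_complexes and self.complex_size < 2:
            raise PermapError("complex_size must be >= 2")
        if self.n_complexes * self.complex_size > self.n_genes:
            raise PermapError(
                "n_complexes * complex_size exceeds n_genes; planted "
                "complexes must fit in the expressed gene set"
            )
        for name in ("effect_scale", "batch_shift_scale", "batch_scale_spread"):
            if getattr(self, name) < 0:
                raise PermapError(f"{name} must be nonnegative")
        if self.noise_sd <= 0:
            raise PermapError("noise_sd must be positive")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


def _orthonormal(rng: np.random.Generator, d: int) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((d, d)))
    return Q * np.sign(np.diag(R))


def simulate(config: SimConfig):
    """Generate one synthetic screen.

    Returns ``(units, catalog, planted_pairs)``: the unit-level table with
    metadata, the planted complex catalog, and the within-complex pair set.
    Fully deterministic given ``config.seed``.
    """
    c = config
    d = c.dims

    gene_names = [f"g{i + 1:05d}" for i in range(c.n_genes)]
    null_names = [f"u{i + 1:05d}" for i in range(c.n_unexpressed)]

    # true effects: complexes share a direction, others are independent
    rng_fx = _stream(c.seed, "effects")
    effects = {g: c.effect_scale * rng_fx.standard_normal(d)
               for g in gene_names}
    catalog: dict[str, list[str]] = {}
    rng_cx = _stream(c.seed, "complexes")
    for ci in range(c.n_complexes):
        members = gene_names[ci * c.complex_size:(ci + 1) * c.complex_size]
        direction = rng_cx.standard_normal(d)
        for g in members:
            jitter = _JITTER * rng_cx.standard_normal(d)
            effects[g] = c.effect_scale * (direction + jitter)
        catalog[f"complex{ci + 1:03d}"] = list(members)
    for g in null_names:
        effects[g] = np.zeros(d)

    # batch artifacts: offset + latent-frame diagonal scaling (affine)
    rng_b = _stream(c.seed, "batches")
    frame = _orthonormal(rng_b, d)
    batch_names = [f"b{i + 1:03d}" for i in range(c.n_batches)]
    batch_map = {}
    for b in batch_names:
        offset = c.batch_shift_scale * rng_b.standard_normal(d)
        scales = np.exp(c.batch_scale_spread * rng_b.standard_normal(d))
        A = frame @ np.diag(scales) @ frame.T
        batch_map[b] = (A, offset)

    rng_asg = _stream(c.seed, "assignment")
    rng_noise = _stream(c.seed, "noise")

    rows, pert, batch, is_ctrl, is_expr = [], [], [], [], []
    all_genes = gene_names + null_names
    for g in all_genes:
        batches_g = rng_asg.choice(c.n_batches, size=c.replicates_per_gene)
        for bi in batches_g:
            b = batch_names[bi]
            A, offset = batch_map[b]
            x = A @ (effects[g] + c.noise_sd * rng_noise.standard_normal(d))
            rows.append(x + offset)
            pert.append(g)
            batch.append(b)
            is_ctrl.append(False)
            is_expr.append(g in effects and not g.startswith("u"))
    for b in batch_names:
        A, offset = batch_map[b]
        for _ in range(c.controls_per_batch):
            x = A @ (c.noise_sd * rng_noise.standard_normal(d))
            rows.append(x + offset)
            pert.append(CONTROL_LABEL)
            batch.append(b)
            is_ctrl.append(True)
            is_expr.append(None)

    index = pd.Index([f"unit{i + 1:06d}" for i in range(len(rows))])
    features = pd.DataFrame(
        np.asarray(rows), index=index,
        columns=[f"f{j + 1:03d}" for j in range(d)],
    )
    obs = pd.DataFrame({
        "perturbation": pert,
        "batch": batch,
        "is_control": is_ctrl,
        "is_expressed": pd.array(is_expr, dtype="boolean"),
    }, index=index)
    units = UnitMatrix(features, obs, info={"simulation": asdict(c)})
    cat = ComplexCatalog(catalog)
    pairs = complexes_to_pairs(cat, source_name="planted_complexes")
    return units, cat, pairs


def write_simulation(units: UnitMatrix, catalog: ComplexCatalog,
                     pairs: AnnotationSet, prefix: str) -> dict[str, str]:
    """Write the unit table and ground-truth files; returns the paths."""
    from .annotations import write_pairs
    from .map_model import write_unit_matrix

    paths = {
        "units": f"{prefix}.units.csv",
        "catalog": f"{prefix}.complexes.csv",
        "pairs": f"{prefix}.pairs.csv",
    }
    write_unit_matrix(units, paths["units"])
    rows = [{"complex": name, "gene": g}
            for name, members in catalog.items() for g in members]
    pd.DataFrame(rows, columns=["complex", "gene"]).to_csv(
        paths["catalog"], index=False)
    write_pairs(pairs, paths["pairs"])
    return paths
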