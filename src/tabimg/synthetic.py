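"""Synthetic tables and planted layout instances with known structure.

Real use cases for the layout transform — gene-expression profiles,
molecular-descriptor tables — have groups of mutually correlated columns.
The generator here emulates that with a single-factor model per block:
feature f in block b is

    x_f = noise_sd * ( sqrt(rho) * z_b + sqrt(1 - rho) * eps_f )

with z_b the shared block factor and eps_f independent standard normals,
giving an exact within-block correlation of rho and (asymptotically) zero
between blocks.  Generation is O(M*N) and bit-reproducible for a fixed
seed.  Marginal distributions of real omics data (e.g. negative-binomial
counts) are deliberately not imitated.

Planted layout instances provide optimizer ground truth: a feature rank
matrix that is exactly the pixel rank matrix with rows/columns shuffled,
so the global optimum error is 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TabularDataset
from .ranking import DistanceSpec, ImageGrid, RankMatrix, pixel_distance_rank_matrix

__all__ = [
    "BlockStructureSpec",
    "generate_block_correlated_table",
    "block_membership",
    "generate_planted_layout_instance",
    "generate_paired_image_response",
]


@dataclass(frozen=True)
class BlockStructureSpec:
    """Parameters of the block-correlated generator (seed is mandatory)."""

    n_samples: int
    n_blocks: int
    block_size: int
    within_block_correlation: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be positive")
        if not (0.0 <= self.within_block_correlation < 1.0):
            raise ValueError("within_block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_features(self) -> int:
        return self.n_blocks * self.block_size


def generate_block_correlated_table(spec: BlockStructureSpec) -> TabularDataset:
    """Draw a table whose columns form ``n_blocks`` equally sized correlated blocks.

    Feature names encode block membership (``b03_f07`` is feature 7 of
    block 3), so the ground-truth grouping travels with the table.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_block_correlation
    m, nb, bs = spec.n_samples, spec.n_blocks, spec.block_size
    z = rng.standard_normal((m, nb))
    eps = rng.standard_normal((m, nb * bs))
    shared = np.repeat(z, bs, axis=1)
    values = spec.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps)
    names = [f"b{b:02d}_f{f:02d}" for b in range(nb) for f in range(bs)]
    ids = [f"s{i:04d}" for i in range(m)]
    return TabularDataset(values, sample_ids=ids, feature_names=names)


def block_membership(feature_names: list[str]) -> np.ndarray:
    """Recover block labels from generator feature names (``-1`` for others)."""
    labels = []
    for name in feature_names:
        if name.startswith("b") and "_f" in name:
            try:
                labels.append(int(name[1:].split("_")[0]))
                continue
            except ValueError:
                pass
        labels.append(-1)
    return np.array(labels)


def write_block_table(spec: BlockStructureSpec, table_path, sidecar_path=None) -> TabularDataset:
    """Generate and write the table plus a block-membership sidecar CSV."""
    data = generate_block_correlated_table(spec)
    data.write_csv(table_path)
    if sidecar_path is not None:
        pd.DataFrame({
            "feature_name": data.feature_names,
            "block": block_membership(data.feature_names),
        }).to_csv(sidecar_path, index=False)
    return data


def generate_planted_layout_instance(
    grid: ImageGrid, seed: int, spec: DistanceSpec | None = None
) -> tuple[RankMatrix, np.ndarray]:
    """A feature rank matrix that is a shuffled pixel rank matrix.

    Returns ``(R, truth)`` where ``R = Q[truth][:, truth]``; permuting R by
    the inverse of ``truth`` therefore recovers Q exactly, and the global
    optimum of the layout search is error 0.
    """
    if grid.size < 2:
        raise ValueError("grid must contain at least 2 pixels")
    q = pixel_distance_rank_matrix(grid, spec).ranks
    rng = np.random.default_rng(seed)
    truth = rng.permutation(grid.size)
    r = q[np.ix_(truth, truth)]
    return RankMatrix(r), truth


def generate_paired_image_response(
    n_pairs: int,
    shape_a: tuple[int, int],
    shape_b: tuple[int, int],
    alpha: float = 1.0,
    beta: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Image pairs with a planted linear response for model smoke tests.

    The target is ``alpha * mean(image_a) + beta * mean(image_b) + noise``,
    a signal any functioning regressor on image pairs should pick up.
    Setting ``alpha = beta = 0`` yields pure noise for negative controls.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(n_pairs, *shape_a))
    b = rng.uniform(size=(n_pairs, *shape_b))
    # spread the per-image means so the signal is not drowned by sampling noise
    a += rng.uniform(-0.3, 0.3, size=(n_pairs, 1, 1))
    b += rng.uniform(-0.3, 0.3, size=(n_pairs, 1, 1))
    y = (alpha * a.mean(axis=(1, 2)) + beta * b.mean(axis=(1, 2))
         + noise_sd * rng.standard_normal(n_pairs))
    return a, b, y
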