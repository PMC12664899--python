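"""Synthetic reference and pseudo-spatial benchmark generators.

The reference generator draws overdispersed (gamma-Poisson, i.e. negative
binomial) counts for K cell types, each overexpressing a disjoint block of
signature genes, plus a flat "background" type with no signature. The
pseudo-spatial generators place cells in one of two layouts — four stacked
horizontal rows, or four 100 x 100 squares — with each non-background type
confined to its own region and background cells dispersed uniformly over
all four regions; expression rows are sampled with replacement from
reference cells of the assigned type, then distorted by a per-gene
multiplicative lognormal batch shift so the spatial modality carries a
batch effect the integration stage has to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionDataset

BACKGROUND = "background"


@dataclass
class SyntheticReferenceSpec:
    n_types: int = 4                   # non-background types; background is added on top
    cells_per_type: int = 1000
    n_genes: int = 500
    signature_genes_per_type: int = 25
    signature_fold_change: float = 4.0
    dispersion: float = 2.0            # NB inverse-dispersion (gamma shape)
    depth_mean: float = 2000.0         # expected library size per cell
    batch_shift_sd: float = 0.3        # log-scale per-gene shift for the spatial modality
    seed: int = 0

    def __post_init__(self):
        if self.signature_fold_change <= 1:
            raise ValueError("signature_fold_change must exceed 1")
        if self.n_types * self.signature_genes_per_type > self.n_genes:
            raise ValueError(
                f"{self.n_types} x {self.signature_genes_per_type} signature genes "
                f"exceed the {self.n_genes} available genes")

    @property
    def type_names(self) -> list[str]:
        return [f"type_{i + 1}" for i in range(self.n_types)] + [BACKGROUND]


@dataclass
class PseudoLayout:
    """Geometry of a pseudo-spatial benchmark.

    ``hierarchical``: four unit-height horizontal rows stacked on
    [0, 4] x [0, 1] (cortical-layer-like), 400 background cells.
    ``block``: four 100 x 100 squares at the quadrants of a 200 x 200
    field (tumor-region-like), 300 background cells.
    """

    kind: str = "hierarchical"
    n_nonbg_types: int = 4
    cells_per_nonbg_type: int = 1000
    n_background: int | None = None  # default: 400 (hierarchical) / 300 (block)

    def __post_init__(self):
        if self.kind not in ("hierarchical", "block"):
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.n_background is None:
            self.n_background = 400 if self.kind == "hierarchical" else 300

    def region_bounds(self, region: int) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of region 0..3."""
        if self.kind == "hierarchical":
            return 0.0, 1.0, float(region), float(region + 1)
        ox, oy = (region % 2) * 100.0, (region // 2) * 100.0
        return ox, ox + 100.0, oy, oy + 100.0


def _type_means(spec: SyntheticReferenceSpec) -> np.ndarray:
    """Per-type expected gene proportions (rows sum to 1)."""
    k = spec.n_types + 1
    base = np.ones((k, spec.n_genes))
    for t in range(spec.n_types):
        lo = t * spec.signature_genes_per_type
        hi = lo + spec.signature_genes_per_type
        base[t, lo:hi] *= spec.signature_fold_change
    return base / base.sum(axis=1, keepdims=True)


def _nb_counts(props: np.ndarray, depth: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with mean depth_i * props_i and NB shape `dispersion`."""
    mean = depth[:, None] * props
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.int64)


def make_synthetic_reference(spec: SyntheticReferenceSpec | None = None) -> ExpressionDataset:
    """Labeled NB-count reference with disjoint per-type signature genes."""
    spec = spec or SyntheticReferenceSpec()
    rng = np.random.default_rng(spec.seed)
    means = _type_means(spec)
    blocks = []
    labels = []
    for t, name in enumerate(spec.type_names):
        depth = rng.gamma(shape=10.0, scale=spec.depth_mean / 10.0,
                          size=spec.cells_per_type)
        props = np.tile(means[t], (spec.cells_per_type, 1))
        blocks.append(_nb_counts(props, depth, spec.dispersion, rng))
        labels.extend([name] * spec.cells_per_type)
    counts = np.concatenate(blocks)
    n = counts.shape[0]
    return ExpressionDataset(
        counts=counts,
        gene_ids=[f"gene_{j + 1}" for j in range(spec.n_genes)],
        cell_ids=[f"ref_cell_{i + 1}" for i in range(n)],
        labels=pd.Categorical(labels),
        batch="reference",
    )


def make_pseudo_st(reference: ExpressionDataset, layout: PseudoLayout | None = None,
                   seed: int = 0, batch_shift_sd: float = 0.3) -> ExpressionDataset:
    """Pseudo-spatial dataset sampled with replacement from the reference.

    Each non-background type gets ``cells_per_nonbg_type`` cells confined
    to its region; background cells are spread uniformly over all four
    regions. Ground-truth labels are stored for evaluation. A seeded
    per-gene lognormal batch shift is applied (then re-rounded to counts).
    """
    layout = layout or PseudoLayout()
    if reference.labels is None:
        raise ValueError("reference must carry cell-type labels")
    rng = np.random.default_rng(seed)
    label_arr = np.asarray(reference.labels)
    type_names = [f"type_{i + 1}" for i in range(layout.n_nonbg_types)]
    for t in type_names + [BACKGROUND]:
        if t not in set(label_arr):
            raise ValueError(f"reference lacks required type {t!r}")

    rows, coords, truth = [], [], []
    for region, t in enumerate(type_names):
        pool = np.flatnonzero(label_arr == t)
        picks = rng.choice(pool, size=layout.cells_per_nonbg_type, replace=True)
        xmin, xmax, ymin, ymax = layout.region_bounds(region)
        xs = rng.uniform(xmin, xmax, size=len(picks))
        ys = rng.uniform(ymin, ymax, size=len(picks))
        rows.append(picks)
        coords.append(np.column_stack([xs, ys]))
        truth.extend([t] * len(picks))
    bg_pool = np.flatnonzero(label_arr == BACKGROUND)
    bg_picks = rng.choice(bg_pool, size=layout.n_background, replace=True)
    bg_regions = rng.integers(0, 4, size=layout.n_background)
    bounds = np.array([layout.region_bounds(r) for r in bg_regions])
    xs = rng.uniform(bounds[:, 0], bounds[:, 1])
    ys = rng.uniform(bounds[:, 2], bounds[:, 3])
    rows.append(bg_picks)
    coords.append(np.column_stack([xs, ys]))
    truth.extend([BACKGROUND] * layout.n_background)

    counts = reference.counts[np.concatenate(rows)].astype(float)
    if batch_shift_sd > 0:
        shift = rng.lognormal(mean=0.0, sigma=batch_shift_sd, size=counts.shape[1])
        counts = counts * shift
    counts = np.round(counts).astype(np.int64)
    n = counts.shape[0]
    return ExpressionDataset(
        counts=counts,
        gene_ids=list(reference.gene_ids),
        cell_ids=[f"st_cell_{i + 1}" for i in range(n)],
        coords=np.concatenate(coords),
        labels=pd.Categorical(truth),
        batch="spatial",
    )
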