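"""Downsampling simulator and synthetic scenario generator.

A Xenium-style spatial dataset differs from a matched scRNA-seq dataset
mainly in two ways this simulator reproduces: a reduced gene panel (only
genes shared with the spatial reference are kept) and a much lower
per-cell read depth.  Depth is matched by computing the ratio of mean
library sizes (spatial / scRNA-seq) and subsampling each scRNA-seq
cell's reads without replacement to ``round(library_size * ratio)``.
Cell-type labels carry over unchanged, giving a spatial-like matrix with
known ground truth.

The synthetic generator builds the matched pair from scratch: clustered
negative-binomial scRNA-seq counts with known labels, plus a
lower-depth, reduced-panel spatial reference, so every downstream stage
is testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import derive_seed
from .preprocess import CountMatrix

logger = logging.getLogger(__name__)

# (min library size, min detected genes) per stringency level.  The
# three levels are this package's presets, chosen to produce visibly
# different scenario sizes on synthetic fixtures.
FILTER_THRESHOLDS: dict[str, tuple[int, int]] = {
    "lenient": (50, 10),
    "medium": (150, 25),
    "strict": (300, 50),
}

# Spatial reference defaults: fraction of genes on the panel and depth
# relative to the scRNA-seq data, emulating a targeted in-situ panel.
PANEL_FRACTION = 0.2
PANEL_DEPTH = 0.1

NB_THETA = 10.0  # NB overdispersion of simulated counts
LIBSIZE_SIGMA = 0.3  # log-normal spread of per-cell library sizes


@dataclass
class SimulationSpec:
    """Record of the downsampling actually applied by :func:`simulate_xenium`."""

    scaling_factor: float
    shared_gene_ids: list[str]
    per_cell_targets: np.ndarray
    seed: int


def scaling_factor(sc: CountMatrix, xen: CountMatrix) -> float:
    """Ratio of mean library sizes: spatial reference over scRNA-seq."""
    sc_mean = sc.library_sizes().mean()
    xen_mean = xen.library_sizes().mean()
    if sc_mean == 0 or xen_mean == 0:
        raise ValueError(
            f"zero mean library size (scRNA-seq: {sc_mean}, spatial: {xen_mean})"
        )
    return float(xen_mean / sc_mean)


def downsample_cell(
    cell_counts: np.ndarray, target: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Subsample one cell's reads without replacement to ``target`` total.

    Draws from the multivariate hypergeometric distribution over the
    multiset of reads, so the output sums to ``target`` exactly and no
    entry exceeds its input.
    """
    counts = np.asarray(cell_counts)
    if counts.ndim != 1 or np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("cell_counts must be a 1-D non-negative integer vector")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if not 0 <= target <= total:
        raise ValueError(f"target {target} outside [0, library size {total}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, int(target))


def simulate_xenium(
    sc: CountMatrix, xen: CountMatrix, seed: int
) -> tuple[CountMatrix, SimulationSpec]:
    """Simulate a spatial dataset from an annotated scRNA-seq matrix.

    Restricts both matrices to their shared genes, computes the library
    size scaling factor on the restricted data, sets each cell's target
    depth to ``round(library_size * factor)`` (round-half-to-even,
    clamped to the cell's own library size -- subsampling cannot invent
    reads, so factors above 1 are clamped with a warning), and
    downsamples every cell without replacement.  Labels are inherited
    unchanged.
    """
    shared = [g for g in sc.gene_ids if g in set(xen.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between the scRNA-seq and spatial matrices")
    sc_idx = [sc.gene_ids.index(g) for g in shared]
    xen_idx = [xen.gene_ids.index(g) for g in shared]
    sc_counts = sc.dense()[sc_idx]
    xen_counts = xen.dense()[xen_idx]
    sc_shared = CountMatrix(sc_counts, shared, sc.cell_ids, labels=sc.labels)
    xen_shared = CountMatrix(xen_counts, shared, xen.cell_ids)
    factor = scaling_factor(sc_shared, xen_shared)
    if factor > 1:
        logger.warning(
            "scaling factor %.3f > 1: spatial reference is deeper than the "
            "scRNA-seq data; targets clamped to each cell's library size",
            factor,
        )
    lib = sc_shared.library_sizes()
    targets = np.clip(np.round(lib * factor), 0, lib).astype(np.int64)
    out = np.empty_like(sc_counts, dtype=np.int64)
    for c in range(sc_shared.n_cells):
        out[:, c] = downsample_cell(
            sc_counts[:, c], int(targets[c]), derive_seed(seed, "downsample", c)
        )
    simulated = CountMatrix(out, shared, list(sc.cell_ids), labels=sc.labels)
    spec = SimulationSpec(
        scaling_factor=factor,
        shared_gene_ids=shared,
        per_cell_targets=targets,
        seed=seed,
    )
    return simulated, spec


def apply_cell_filter(cm: CountMatrix, stringency: str) -> CountMatrix:
    """Drop low-quality cells at a preset stringency level.

    Cells must reach both the library-size and detected-gene thresholds
    of the level (lenient: 50/10, medium: 150/25, strict: 300/50); genes
    detected in no remaining cell are dropped.  Removal counts are
    logged.
    """
    if stringency not in FILTER_THRESHOLDS:
        raise ValueError(
            f"unknown stringency {stringency!r}; expected one of {sorted(FILTER_THRESHOLDS)}"
        )
    min_lib, min_genes = FILTER_THRESHOLDS[stringency]
    x = cm.dense()
    lib = x.sum(axis=0)
    detected = (x > 0).sum(axis=0)
    keep_cells = np.flatnonzero((lib >= min_lib) & (detected >= min_genes))
    if keep_cells.size == 0:
        raise ValueError(f"{stringency!r} filter removed all {cm.n_cells} cells")
    x = x[:, keep_cells]
    keep_genes = np.flatnonzero((x > 0).any(axis=1))
    logger.info(
        "%s filter: removed %d/%d cells and %d/%d genes",
        stringency,
        cm.n_cells - keep_cells.size,
        cm.n_cells,
        cm.n_genes - keep_genes.size,
        cm.n_genes,
    )
    return CountMatrix(
        x[keep_genes].astype(np.int64),
        [cm.gene_ids[g] for g in keep_genes],
        [cm.cell_ids[c] for c in keep_cells],
        labels=[cm.labels[c] for c in keep_cells] if cm.labels is not None else None,
    )


def generate_synthetic_scenario(
    n_cells: int = 600,
    n_genes: int = 2000,
    n_types: int = 3,
    de_fraction: float = 0.05,
    fold_change: float = 8.0,
    libsize_mean: float = 2000.0,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Generate a matched (scRNA-seq, spatial reference) synthetic pair.

    Gene base expression levels are heavy-tailed (log-normal); each cell
    type up-regulates its own disjoint ``de_fraction`` of genes by
    ``fold_change``; per-cell library sizes are log-normal around
    ``libsize_mean``; counts are negative-binomial (gamma-Poisson,
    theta=10).  The spatial reference reuses the same cells on a random
    20% gene panel downsampled to 10% relative depth.  Returns
    ``(sc, xen_reference)``; only ``sc`` carries labels.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if not 0 < de_fraction <= 1:
        raise ValueError(f"de_fraction must lie in (0, 1], got {de_fraction}")
    if not fold_change > 1:
        raise ValueError(f"fold_change must exceed 1, got {fold_change}")
    if n_types * de_fraction > 1:
        raise ValueError(
            f"cannot assign disjoint DE genes: {n_types} types x {de_fraction} > 1"
        )
    if n_cells < n_types or n_genes < n_types:
        raise ValueError("need at least one cell and one gene per type")
    rng = np.random.default_rng(seed)

    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    n_de = max(1, int(round(de_fraction * n_genes)))
    de_genes = rng.choice(n_genes, size=n_de * n_types, replace=False)
    type_means = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        type_means[de_genes[t * n_de : (t + 1) * n_de], t] *= fold_change
    type_props = type_means / type_means.sum(axis=0, keepdims=True)

    types = rng.permutation(np.arange(n_cells) % n_types)
    lib = rng.lognormal(
        np.log(libsize_mean) - LIBSIZE_SIGMA**2 / 2, LIBSIZE_SIGMA, n_cells
    )
    mu = type_props[:, types] * lib[None, :]
    lam = rng.gamma(shape=NB_THETA, scale=mu / NB_THETA)
    counts = rng.poisson(lam).astype(np.int64)

    gene_ids = [f"gene_{g:05d}" for g in range(n_genes)]
    cell_ids = [f"cell_{c:05d}" for c in range(n_cells)]
    labels = [f"type_{t}" for t in types]
    sc = CountMatrix(counts, gene_ids, cell_ids, labels=labels)

    panel = np.sort(rng.choice(n_genes, size=max(1, int(round(PANEL_FRACTION * n_genes))), replace=False))
    panel_counts = counts[panel]
    xen = np.empty_like(panel_counts)
    for c in range(n_cells):
        total = int(panel_counts[:, c].sum())
        xen[:, c] = downsample_cell(
            panel_counts[:, c], int(round(PANEL_DEPTH * total)), rng
        )
    xen_ref = CountMatrix(
        xen,
        [gene_ids[g] for g in panel],
        [f"xen_{c:05d}" for c in range(n_cells)],
    )
    return sc, xen_ref
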