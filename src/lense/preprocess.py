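"""Execute one preprocessing configuration on a count matrix.

A single pipeline run is: normalization -> feature selection -> per-gene
z-score scaling -> PCA -> shared-nearest-neighbor graph clustering at a
resolution -> 2-D embeddings (UMAP and first two PCs).  Every stochastic
stage consumes a deterministic sub-seed derived from the run seed, so a
run is bitwise reproducible.

Conventions inherited from the Seurat-style workflow this mirrors (the
source pipeline leaves them at their defaults): library-size scale
factor 1e4, natural logarithms, scaled values clipped at +10, SNN graph
on k=20 neighbors with Jaccard weights pruned below 1/15, UMAP with 30
neighbors and min_dist 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._util import derive_seed
from .config_grid import PipelineConfig, hvg_count

SCALE_FACTOR = 1e4
SCT_THETA = 100.0  # fixed NB overdispersion of the Pearson-residual transform
SCALE_CLIP = 10.0  # upper clip of per-gene z-scores
SNN_K = 20
SNN_PRUNE = 1.0 / 15.0
UMAP_N_NEIGHBORS = 30
UMAP_MIN_DIST = 0.3


@dataclass
class CountMatrix:
    """A genes x cells non-negative integer count matrix.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` array or scipy sparse matrix of
        non-negative integers.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    labels
        Optional per-cell ground-truth cell-type strings (benchmarking).
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene_ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts has {n_cells} columns but {len(self.cell_ids)} cell_ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids contain duplicates")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size and (np.min(data) < 0 or np.any(data != np.floor(data))):
            raise ValueError("counts must be non-negative integers")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n_cells:
                raise ValueError(
                    f"{len(self.labels)} labels for {n_cells} cells"
                )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float64 array (genes x cells)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.float64)
        return np.asarray(self.counts, dtype=np.float64)

    def library_sizes(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.float64)
        return np.asarray(self.counts, dtype=np.float64).sum(axis=0)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced for one configuration."""

    config: PipelineConfig
    pc_scores: np.ndarray  # cells x n_pcs
    embedding_umap: np.ndarray  # cells x 2
    embedding_pca: np.ndarray  # cells x 2 (first two PCs)
    cluster_labels: np.ndarray  # per-cell ints, contiguous from 0
    n_clusters: int
    seed: int
    selected_genes: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def config_id(self) -> str:
        return self.config.config_id


def _check_positive_libsizes(cm: CountMatrix, method: str) -> np.ndarray:
    lib = cm.library_sizes()
    if np.any(lib == 0):
        bad = [cm.cell_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(
            f"normalization {method!r} requires nonzero library sizes; "
            f"offending cells: {bad}"
        )
    return lib


def normalize(cm: CountMatrix, method: str) -> np.ndarray:
    """Apply one of the six normalization methods.

    Returns a dense genes x cells float matrix.  ``raw`` is the identity;
    ``rc`` rescales each cell to a library size of 1e4; ``lognorm`` is
    ``ln(rc + 1)``; ``log`` is ``ln(count + 1)``; ``clr`` is the
    per-cell centered log-ratio ``ln((x+1)/g)`` with ``g`` the geometric
    mean of ``x+1`` over genes in the cell; ``sct_analog`` computes
    Pearson residuals of a negative-binomial null model with fixed
    overdispersion theta=100, clipped at +/- sqrt(n_cells) -- an
    analytic stand-in for a regularized-NB regression transform.
    """
    x = cm.dense()
    if method == "raw":
        return x
    if method == "log":
        return np.log1p(x)
    if method == "rc":
        lib = _check_positive_libsizes(cm, method)
        return x / lib * SCALE_FACTOR
    if method == "lognorm":
        lib = _check_positive_libsizes(cm, method)
        return np.log1p(x / lib * SCALE_FACTOR)
    if method == "clr":
        _check_positive_libsizes(cm, method)
        logx = np.log1p(x)
        return logx - logx.mean(axis=0, keepdims=True)
    if method == "sct_analog":
        lib = cm.library_sizes()
        total = lib.sum()
        if total == 0:
            raise ValueError("sct_analog requires a nonzero total count")
        gene_frac = x.sum(axis=1, keepdims=True) / total
        mu = gene_frac * lib[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            resid = (x - mu) / np.sqrt(mu + mu**2 / SCT_THETA)
        resid[~np.isfinite(resid)] = 0.0  # genes with zero total count
        clip = np.sqrt(cm.n_cells)
        return np.clip(resid, -clip, clip)
    raise ValueError(f"unknown normalization method {method!r}")


def standardized_variance(cm: CountMatrix) -> np.ndarray:
    """Variance-stabilized per-gene dispersion statistic on raw counts.

    A compact analog of the Seurat "vst" ranking: fit a quadratic trend
    of log10(variance) on log10(mean) across genes, standardize each
    gene's counts by the trend-expected standard deviation (clipping at
    sqrt(n_cells)), and return the variance of the standardized values.
    Genes with zero variance score exactly 0.
    """
    x = cm.dense()
    n = cm.n_cells
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if n > 1 else np.zeros_like(mean)
    out = np.zeros(cm.n_genes)
    ok = (mean > 0) & (var > 0)
    if not np.any(ok):
        return out
    lm, lv = np.log10(mean[ok]), np.log10(var[ok])
    if np.unique(lm).size >= 3:
        coef = np.polyfit(lm, lv, deg=2)
        expected_var = 10.0 ** np.polyval(coef, lm)
    else:  # too few distinct means to fit a trend; use raw variances
        expected_var = 10.0**lv
    sd = np.sqrt(expected_var)
    clip = np.sqrt(n)
    z = np.clip((x[ok] - mean[ok, None]) / sd[:, None], -clip, clip)
    out[ok] = z.var(axis=1, ddof=1)
    return out


def select_features(
    normalized: np.ndarray, cm: CountMatrix, mode: str
) -> np.ndarray:
    """Return the ordered gene indices to keep under a feature mode.

    ``all`` keeps every gene in input order.  ``hvg_formula`` keeps the
    :func:`~lense.config_grid.hvg_count` top genes ranked by
    :func:`standardized_variance`, ties broken by gene order.
    """
    if normalized.size == 0:
        raise ValueError("empty expression matrix")
    n_genes = cm.n_genes
    if mode == "all":
        return np.arange(n_genes)
    if mode == "hvg_formula":
        k = hvg_count(n_genes)
        score = standardized_variance(cm)
        order = np.argsort(-score, kind="stable")  # stable => gene-order ties
        return np.sort(order[:k])
    raise ValueError(f"unknown feature_mode {mode!r}")


def scale_features(values: np.ndarray) -> np.ndarray:
    """Per-gene z-score with the upper clip at +10; zero-variance genes -> 0."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True) if values.shape[1] > 1 else None
    if sd is None:
        return np.zeros_like(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return np.minimum(z, SCALE_CLIP)


def snn_graph(pc_scores: np.ndarray, k: int = SNN_K, prune: float = SNN_PRUNE) -> igraph.Graph:
    """Jaccard-weighted shared-nearest-neighbor graph on PC scores.

    Each cell is linked to its k nearest Euclidean neighbors (self
    included); edge weight is the Jaccard overlap of the two neighbor
    sets, pruned below ``prune``.
    """
    n = pc_scores.shape[0]
    k_other = min(k - 1, n - 1)  # neighbor set = self + k-1 nearest others
    if k_other < 1:
        return igraph.Graph(n=n, directed=False)
    nn = NearestNeighbors(n_neighbors=k_other).fit(pc_scores)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    kk = k_other + 1
    rows = np.repeat(np.arange(n), kk)
    cols = np.hstack([np.arange(n)[:, None], idx]).ravel()
    a = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.float64), (rows, cols)), shape=(n, n)
    )
    shared = (a @ a.T).tocoo()
    jacc = shared.data / (2 * kk - shared.data)
    keep = (jacc >= prune) & (shared.row < shared.col)
    edges = np.column_stack([shared.row[keep], shared.col[keep]])
    g = igraph.Graph(n=n, edges=edges.tolist(), directed=False)
    g.es["weight"] = jacc[keep].tolist()
    return g


def cluster_snn(
    pc_scores: np.ndarray, resolution: float, seed: int
) -> np.ndarray:
    """Modularity community detection on the SNN graph, seeded.

    Uses the Leiden algorithm with the RB-configuration quality function,
    the standard resolution-parametrized modularity analog of
    Louvain-style graph clustering in this workflow.
    """
    g = snn_graph(pc_scores)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"] if g.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    _, labels = np.unique(membership, return_inverse=True)
    return labels


def umap_embed(pc_scores: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 2-D UMAP of the PC scores (30 neighbors, min_dist 0.3)."""
    import umap  # deferred: numba compilation is expensive at import

    n = pc_scores.shape[0]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        warnings.filterwarnings("ignore", message=".*n_neighbors is larger.*")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(UMAP_N_NEIGHBORS, max(2, n - 1)),
            min_dist=UMAP_MIN_DIST,
            random_state=int(seed),
        )
        return np.asarray(reducer.fit_transform(pc_scores), dtype=np.float64)


def run_pipeline(
    cm: CountMatrix, config: PipelineConfig, seed: int, compute_umap: bool = True
) -> PipelineResult:
    """Run one full preprocessing configuration on a count matrix.

    All randomness flows from ``seed`` through per-stage sub-seeds keyed
    by the config id, so results are reproducible independent of the
    order in which configurations execute.  ``compute_umap=False`` skips
    the UMAP stage (the dominant cost) for callers that only consume PC
    coordinates; the UMAP embedding is then an empty array.
    """
    if cm.n_cells <= config.n_pcs:
        raise ValueError(
            f"need more cells ({cm.n_cells}) than PCs ({config.n_pcs})"
        )
    if config.n_pcs < 2:
        raise ValueError("n_pcs must be >= 2 to define a 2-D PC embedding")
    normalized = normalize(cm, config.normalization)
    genes = select_features(normalized, cm, config.feature_mode)
    if config.n_pcs >= min(cm.n_cells, len(genes)):
        raise ValueError(
            f"n_pcs={config.n_pcs} must be < min(n_cells={cm.n_cells}, "
            f"n_selected_features={len(genes)})"
        )
    scaled = scale_features(normalized[genes])
    pca = PCA(n_components=config.n_pcs, svd_solver="full")
    pc_scores = pca.fit_transform(scaled.T)
    cid = config.config_id
    labels = cluster_snn(
        pc_scores, config.resolution, derive_seed(seed, "cluster", cid)
    )
    if compute_umap:
        emb_umap = umap_embed(pc_scores, derive_seed(seed, "umap", cid))
    else:
        emb_umap = np.empty((cm.n_cells, 0))
    return PipelineResult(
        config=config,
        pc_scores=pc_scores,
        embedding_umap=emb_umap,
        embedding_pca=pc_scores[:, :2].copy(),
        cluster_labels=labels,
        n_clusters=int(labels.max()) + 1,
        seed=seed,
        selected_genes=genes,
    )
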