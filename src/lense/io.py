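"""File readers/writers and the one-call selection workflow.

Counts are exchanged as 10x-style Matrix Market triplets (matrix.mtx +
features.tsv + barcodes.tsv, with an optional labels.tsv) or as dense
delimited text.  :func:`run_lense` is the one-line entry point: run the
whole configuration grid, render one image per candidate, play the
tournament, and return (and optionally persist) the winner's
preprocessing results together with the full trace and a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._util import derive_seed
from .config_grid import PipelineConfig, default_grid
from .preprocess import CountMatrix, PipelineResult, run_pipeline
from .render import EmbeddingImage, render_embedding
from .tournament import TournamentResult, run_tournament

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record of one selection run."""

    seed: int
    basis: str
    backend: str
    n_candidates: int
    grid: list[dict]
    winner_config_id: str = ""
    n_comparisons: int = 0
    timings_s: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _validate_integer_counts(mat, what: str) -> None:
    if sp.issparse(mat):
        data = mat.tocoo()
        bad = (data.data < 0) | (data.data != np.floor(data.data))
        if np.any(bad):
            k = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{what}: non-integer or negative entry {data.data[k]!r} at "
                f"(row {int(data.row[k])}, col {int(data.col[k])})"
            )
    else:
        arr = np.asarray(mat)
        bad = (arr < 0) | (arr != np.floor(arr))
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"{what}: non-integer or negative entry {arr[r, c]!r} at "
                f"(row {int(r)}, col {int(c)})"
            )


def read_counts(
    path: str | Path,
    format: str = "mtx_dir",
    labels_path: str | Path | None = None,
) -> CountMatrix:
    """Load a count matrix from disk.

    ``mtx_dir`` expects a directory with ``matrix.mtx``, ``features.tsv``
    and ``barcodes.tsv`` (1-based Matrix Market indices per the
    standard); orientation is auto-detected from the features file and
    transposed to genes x cells if needed.  ``dense_tsv`` expects a
    delimited table with gene ids as the index and cell ids as columns.
    An optional two-column labels TSV (cell_id, label) attaches
    ground-truth labels.
    """
    path = Path(path)
    if format == "mtx_dir":
        mat = scipy.io.mmread(path / "matrix.mtx")
        genes = _read_id_column(path / "features.tsv")
        cells = _read_id_column(path / "barcodes.tsv")
        if mat.shape == (len(cells), len(genes)) and mat.shape[0] != mat.shape[1]:
            logger.info("matrix.mtx is cells x genes; transposing to genes x cells")
            mat = mat.T
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither (genes={len(genes)}, "
                f"cells={len(cells)}) nor its transpose"
            )
        _validate_integer_counts(mat, str(path / "matrix.mtx"))
        counts = sp.csr_matrix(mat).astype(np.int64)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _validate_integer_counts(df.to_numpy(), str(path))
        counts = df.to_numpy(dtype=np.int64)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", header=0, dtype=str)
        mapping = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
        missing = [c for c in cells if c not in mapping]
        if missing:
            raise ValueError(f"labels missing for {len(missing)} cells, e.g. {missing[:3]}")
        labels = [mapping[c] for c in cells]
    return CountMatrix(counts, genes, cells, labels=labels)


def write_counts(cm: CountMatrix, outdir: str | Path) -> None:
    """Write a CountMatrix as a 10x-style triplet (plus labels.tsv if any)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(cm.counts))
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))
    if cm.labels is not None:
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("cell_id\tlabel\n")
            for c, l in zip(cm.cell_ids, cm.labels):
                fh.write(f"{c}\t{l}\n")


def _persist(
    outdir: Path,
    basis: str,
    results: Sequence[PipelineResult],
    images: Sequence[EmbeddingImage],
    winner: PipelineResult,
    tournament: TournamentResult,
    manifest: RunManifest,
) -> None:
    plots = outdir / "plots" / basis
    plots.mkdir(parents=True, exist_ok=True)
    for img in images:
        p = plots / f"{img.config_id.replace('|', '_')}.png"
        p.write_bytes(img.image_bytes)
        manifest.outputs.append(str(p))

    trace_path = outdir / "tournament.jsonl"
    with open(trace_path, "w") as fh:
        for rec in tournament.to_records():
            fh.write(json.dumps(rec) + "\n")
    manifest.outputs.append(str(trace_path))

    emb = winner.embedding_umap if basis == "umap" else winner.embedding_pca
    frames = {
        "winner_clusters.tsv": pd.DataFrame(
            {"cell_index": np.arange(len(winner.cluster_labels)), "cluster": winner.cluster_labels}
        ),
        "winner_embedding.tsv": pd.DataFrame(emb, columns=["dim1", "dim2"]),
    }
    for name, df in frames.items():
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        manifest.outputs.append(str(p))
    p = outdir / "winner_config.json"
    p.write_text(json.dumps(winner.config.to_dict(), indent=2))
    manifest.outputs.append(str(p))
    grid_path = outdir / "grid.json"
    grid_path.write_text(json.dumps(manifest.grid, indent=2))
    manifest.outputs.append(str(grid_path))
    manifest_path = outdir / "manifest.json"
    manifest.outputs.append(str(manifest_path))
    manifest_path.write_text(manifest.to_json())


def run_lense(
    counts: CountMatrix,
    grid: Sequence[PipelineConfig] | None = None,
    basis: str = "umap",
    backend=None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[PipelineResult, TournamentResult, RunManifest]:
    """Run the full grid, judge the images, return the winning pipeline.

    Each configuration is preprocessed with a sub-seed derived from
    (seed, config_id), its chosen-basis embedding rendered to a PNG, and
    the sequential tournament played over the images with ``backend``.
    By default UMAP images are judged; ``basis='pca'`` judges first-two-
    PC plots instead (UMAP computation is then skipped).  With
    ``outdir`` set, plots, the tournament trace, the winner's outputs
    and a manifest are persisted.
    """
    if basis not in ("umap", "pca"):
        raise ValueError(f"basis must be 'umap' or 'pca', got {basis!r}")
    if backend is None:
        raise ValueError("a judge backend is required")
    if grid is None:
        grid = default_grid()
    t0 = time.perf_counter()
    results: list[PipelineResult] = []
    images: list[EmbeddingImage] = []
    for config in grid:
        cid = config.config_id
        res = run_pipeline(
            counts,
            config,
            derive_seed(seed, "pipeline", cid),
            compute_umap=(basis == "umap"),
        )
        emb = res.embedding_umap if basis == "umap" else res.embedding_pca
        img = render_embedding(
            emb,
            res.cluster_labels,
            basis=basis,
            seed=derive_seed(seed, "render", cid),
            config_id=cid,
        )
        results.append(res)
        images.append(img)
    t1 = time.perf_counter()
    tournament = run_tournament(results, images, backend)
    t2 = time.perf_counter()
    winner = results[[c.config_id for c in grid].index(tournament.winner_config_id)]
    manifest = RunManifest(
        seed=seed,
        basis=basis,
        backend=type(backend).__name__,
        n_candidates=len(grid),
        grid=[c.to_dict() for c in grid],
        winner_config_id=tournament.winner_config_id,
        n_comparisons=len(tournament.comparisons),
        timings_s={"preprocess_and_render": round(t1 - t0, 3), "tournament": round(t2 - t1, 3)},
    )
    if outdir is not None:
        _persist(Path(outdir), basis, results, images, winner, tournament, manifest)
    return winner, tournament, manifest
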