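"""Clustering evaluation metrics and benchmark protocols.

Five higher-is-better quantities summarize one pipeline's clustering:
ARI and MI (in nats) compare the inferred clusters with ground-truth
cell types; Silhouette, CHI (Calinski-Harabasz) and 1-DBI
(Davies-Bouldin, sign-flipped so higher is better) measure cluster
geometry in the pipeline's own PC space under Euclidean distance.  The
benchmark protocols built on them: pairwise judge accuracy over sampled
plot pairs, the metric rank of the tournament winner, within-scenario
mean-0/sd-1 scaling for cross-scenario aggregation, and Pearson
correlation of rankings for reproducibility.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    mutual_info_score,
    silhouette_score,
)

from .config_grid import PipelineConfig
from .judge import majority_vote
from .preprocess import PipelineResult
from .render import EmbeddingImage

METRIC_NAMES = ("ari", "silhouette", "chi", "one_minus_dbi", "mi")


@dataclass
class MetricReport:
    """The five clustering-quality metrics for one pipeline result.

    Internal metrics (silhouette, chi, one_minus_dbi) are ``None`` --
    explicitly undefined, never fabricated -- when the clustering has a
    single cluster (or one cluster per cell); ARI and MI are always
    defined.
    """

    ari: float
    silhouette: float | None
    chi: float | None
    one_minus_dbi: float | None
    mi: float

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(
    result: PipelineResult,
    truth_labels: Sequence,
    use_truth_for_internal: bool = False,
) -> MetricReport:
    """Score one pipeline result against ground-truth cell types.

    ARI and MI (natural log) compare ``result.cluster_labels`` with
    ``truth_labels``.  The internal metrics are computed in the
    pipeline's n_pcs-dimensional PC space with Euclidean distance, by
    default on the pipeline's own cluster labels
    (``use_truth_for_internal=True`` switches to the ground-truth
    labels, for sensitivity analysis).  DBI is reported as ``1 - DBI``
    so that all five metrics are higher-is-better.
    """
    pred = np.asarray(result.cluster_labels)
    truth = np.asarray(truth_labels)
    if truth.shape[0] != pred.shape[0]:
        raise ValueError(
            f"{truth.shape[0]} truth labels for {pred.shape[0]} cells"
        )
    ari = float(adjusted_rand_score(truth, pred))
    mi = float(mutual_info_score(truth, pred))
    internal = truth if use_truth_for_internal else pred
    n = pred.shape[0]
    k = len(np.unique(internal))
    if 2 <= k <= n - 1:
        x = result.pc_scores
        silhouette = float(silhouette_score(x, internal, metric="euclidean"))
        chi = float(calinski_harabasz_score(x, internal))
        one_minus_dbi = 1.0 - float(davies_bouldin_score(x, internal))
    else:
        silhouette = chi = one_minus_dbi = None
    return MetricReport(ari=ari, silhouette=silhouette, chi=chi, one_minus_dbi=one_minus_dbi, mi=mi)


def metrics_table(
    results: Sequence[PipelineResult],
    truth_labels: Sequence,
    use_truth_for_internal: bool = False,
) -> pd.DataFrame:
    """Per-config metric table (rows: config_id, columns: the five metrics)."""
    rows = {
        r.config_id: compute_metrics(r, truth_labels, use_truth_for_internal).as_dict()
        for r in results
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))


def scale_across_methods(values) -> np.ndarray | pd.DataFrame:
    """Z-score each scenario (row) across methods (columns).

    Uses the sample (n-1) standard deviation, so each row of the output
    has mean 0 and sd 1 exactly.  A constant row is an error naming the
    scenario, since its scale is undefined.
    """
    df = values if isinstance(values, pd.DataFrame) else None
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two methods per scenario")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        name = df.index[flat[0]] if df is not None else flat[0]
        raise ValueError(f"scenario {name!r} has constant values across methods")
    out = (arr - mean) / sd
    if df is not None:
        return pd.DataFrame(out, index=df.index, columns=df.columns)
    return out


def _differs_in_one_step(a: PipelineConfig, b: PipelineConfig) -> bool:
    return (
        sum(
            getattr(a, f) != getattr(b, f)
            for f in ("normalization", "feature_mode", "n_pcs", "resolution")
        )
        == 1
    )


def pairwise_accuracy(
    configs: Sequence[PipelineConfig],
    images: Sequence[EmbeddingImage],
    metric_values: Sequence[float],
    backend,
    n_pairs: int = 20,
    pair_mode: str = "any",
    shots: int = 1,
    seed: int = 0,
) -> float:
    """Fraction of sampled plot pairs where the judge picks the better one.

    Samples ``n_pairs`` unordered candidate pairs without repetition
    (``pair_mode='single_step'`` restricts to config pairs differing in
    exactly one of the four grid factors); pairs with tied metric values
    are excluded, since "better" is undefined on a tie.  Each pair is
    judged once (``shots=1``) or by k-shot majority vote.
    """
    if not len(configs) == len(images) == len(metric_values):
        raise ValueError("configs, images and metric_values must align")
    if len(configs) < 2:
        raise ValueError("need at least two candidates")
    if pair_mode not in ("any", "single_step"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    vals = np.asarray(metric_values, dtype=np.float64)
    eligible = [
        (i, j)
        for i, j in itertools.combinations(range(len(configs)), 2)
        if vals[i] != vals[j]
        and (pair_mode == "any" or _differs_in_one_step(configs[i], configs[j]))
    ]
    if len(eligible) < n_pairs:
        raise ValueError(
            f"only {len(eligible)} eligible non-tied pairs available, need {n_pairs}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_pairs, replace=False)
    correct = 0
    for idx in chosen:
        i, j = eligible[idx]
        if shots == 1:
            decision = backend.compare(images[i], images[j])
        else:
            decision = majority_vote(backend, images[i], images[j], k=shots)
        picked_better = (decision.winner == 1) == (vals[i] > vals[j])
        correct += picked_better
    return correct / n_pairs


def rank_of_selected(
    winner_config_id: str, table: Mapping[str, float] | pd.Series
) -> int:
    """Metric rank of the tournament winner (1 = best; ties share the best rank)."""
    if isinstance(table, pd.Series):
        table = table.to_dict()
    if winner_config_id not in table:
        raise ValueError(f"winner {winner_config_id!r} not in the metric table")
    values = {k: v for k, v in table.items()}
    w = values[winner_config_id]
    if w is None or not np.isfinite(w):
        raise ValueError(f"metric undefined for winner {winner_config_id!r}")
    finite = [v for v in values.values() if v is not None and np.isfinite(v)]
    return 1 + sum(v > w for v in finite)


def ranking_correlation(ranking_a: Sequence[float], ranking_b: Sequence[float]) -> float:
    """Pearson correlation between two aligned pipeline rankings."""
    a = np.asarray(ranking_a, dtype=np.float64)
    b = np.asarray(ranking_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("rankings must be aligned 1-D vectors of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant ranking has undefined correlation")
    return float(pearsonr(a, b).statistic)
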