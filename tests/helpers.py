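"""Shared test utilities: scripted judge doubles, image stubs, and
independent brute-force implementations of the five clustering metrics
(the oracle route against which the package's scikit-learn-backed
implementations are checked)."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from lense.judge import JudgeDecision
from lense.render import EmbeddingImage, render_embedding

_TINY = render_embedding(
    np.array([[0.0, 0.0], [1.0, 1.0]]), np.array([0, 1]), "umap", seed=0, size=32
)


def make_image(config_id: str, basis: str = "umap") -> EmbeddingImage:
    """A small valid EmbeddingImage stub carrying an arbitrary config_id."""
    return EmbeddingImage(_TINY.image_bytes, basis, config_id, 32, 32)


class ScriptedTransport:
    """Transport double that replays a fixed list of replies (last repeats)."""

    def __init__(self, replies):
        self.replies = list(replies)
        self.calls: list[tuple[str, tuple[bytes, bytes]]] = []

    def __call__(self, prompt, images):
        self.calls.append((prompt, images))
        i = min(len(self.calls) - 1, len(self.replies) - 1)
        return self.replies[i]


class ScriptedBackend:
    """Backend double that replays a fixed winner sequence."""

    deterministic = True

    def __init__(self, winners):
        self.winners = list(winners)
        self.n_calls = 0

    def compare(self, image1, image2):
        w = self.winners[self.n_calls % len(self.winners)]
        self.n_calls += 1
        return JudgeDecision(
            winner=w, raw_responses=[str(w)], attempts=1, backend="scripted"
        )


class FailingBackend:
    deterministic = True

    def __init__(self, fail_at: int):
        self.fail_at = fail_at
        self.n_calls = 0

    def compare(self, image1, image2):
        self.n_calls += 1
        if self.n_calls >= self.fail_at:
            raise RuntimeError("backend exploded")
        return JudgeDecision(winner=1, raw_responses=["1"], attempts=1, backend="failing")


# ---------------------------------------------------------------------------
# Brute-force metric formulas (contingency / centroid / pairwise-distance),
# written independently of scikit-learn.

def brute_ari(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    nij = np.array([[(np.sum((a == x) & (b == y))) for y in ub] for x in ua])
    sum_ij = sum(math.comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(math.comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(math.comb(int(v), 2) for v in nij.sum(axis=0))
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0  # both partitions trivial
    return (sum_ij - expected) / (max_index - expected)


def brute_mi(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    mi = 0.0
    for x in np.unique(a):
        for y in np.unique(b):
            pxy = np.sum((a == x) & (b == y)) / n
            if pxy > 0:
                px, py = np.sum(a == x) / n, np.sum(b == y) / n
                mi += pxy * math.log(pxy / (px * py))
    return mi


def brute_silhouette(x, labels) -> float:
    x, labels = np.asarray(x, dtype=float), np.asarray(labels)
    n = len(labels)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            s[i] = 0.0
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def _centroids(x, labels):
    return {k: x[labels == k].mean(axis=0) for k in np.unique(labels)}


def brute_chi(x, labels) -> float:
    x, labels = np.asarray(x, dtype=float), np.asarray(labels)
    n, k = len(labels), len(np.unique(labels))
    overall = x.mean(axis=0)
    cents = _centroids(x, labels)
    between = sum(
        (labels == c).sum() * ((cents[c] - overall) ** 2).sum() for c in cents
    )
    within = sum(((x[labels == c] - cents[c]) ** 2).sum() for c in cents)
    return float((between / (k - 1)) / (within / (n - k)))


def brute_dbi(x, labels) -> float:
    x, labels = np.asarray(x, dtype=float), np.asarray(labels)
    ks = np.unique(labels)
    cents = _centroids(x, labels)
    scatter = {
        k: np.sqrt(((x[labels == k] - cents[k]) ** 2).sum(axis=1)).mean() for k in ks
    }
    worst = []
    for i in ks:
        worst.append(
            max(
                (scatter[i] + scatter[j]) / np.sqrt(((cents[i] - cents[j]) ** 2).sum())
                for j in ks
                if j != i
            )
        )
    return float(np.mean(worst))
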