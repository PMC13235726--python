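"""Pluggable pairwise comparators over embedding images.

The production judge sends two rendered embedding images plus a fixed
text prompt to a vision LLM and insists on a bare "1" or "2" answer,
re-prompting until it gets one (bounded by ``max_retries``).  For
offline tests and benchmarks, deterministic and noisy oracle judges
decide from known per-candidate scores instead of pixels.

A judge backend is any object with ``compare(image1, image2) ->
JudgeDecision`` and a boolean ``deterministic`` attribute.  The LLM
transport is likewise a plain callable ``(prompt: str, images:
tuple[bytes, bytes]) -> str`` so alternative vendors plug in without
touching the comparison protocol.
"""

from __future__ import annotations

import base64
import json
import os
import urllib.error
import urllib.request
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .render import EmbeddingImage

# The comparison prompt, with the embedding-basis word substituted in.
PROMPT_TEMPLATE = (
    "You will be shown two {basis} plots. Please carefully examine both. "
    "Image 1 is labeled ‘1’ and Image 2 is labeled ‘2’. "
    "Based on visual accuracy (cluster separation, boundary clarity, etc.), "
    "which one is better? Please respond with only: 1 or 2."
)

DEFAULT_MODEL = "gpt-4o-2024-08-06"
DEFAULT_MAX_RETRIES = 10

Transport = Callable[[str, tuple[bytes, bytes]], str]


class JudgeError(Exception):
    """Base class for judge failures."""


class JudgeProtocolError(JudgeError):
    """The judge never produced a valid '1'/'2' reply."""

    def __init__(self, message: str, raw_responses: Sequence[str]):
        super().__init__(message)
        self.raw_responses = list(raw_responses)


class JudgeTransportError(JudgeError):
    """The transport (network/API) failed, as opposed to the protocol."""


@dataclass
class JudgeDecision:
    """Outcome of one pairwise comparison."""

    winner: int  # 1 or 2
    raw_responses: list[str]
    attempts: int
    backend: str
    latency_note: str | None = None

    def __post_init__(self) -> None:
        if self.winner not in (1, 2):
            raise ValueError(f"winner must be 1 or 2, got {self.winner!r}")
        if self.attempts < 1 or self.attempts != len(self.raw_responses):
            raise ValueError(
                "attempts must be >= 1 and equal the number of raw responses"
            )


def prompt_for_basis(basis: str) -> str:
    """The comparison prompt for a given embedding basis ('umap'/'pca')."""
    if basis not in ("umap", "pca"):
        raise ValueError(f"basis must be 'umap' or 'pca', got {basis!r}")
    return PROMPT_TEMPLATE.format(basis=basis.upper())


def sanitize_reply(reply: str) -> str:
    """Strip whitespace and trailing punctuation from a judge reply."""
    return reply.strip().rstrip(".,;:!?").strip()


def llm_compare(
    transport: Transport,
    image1: EmbeddingImage,
    image2: EmbeddingImage,
    basis: str = "umap",
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> JudgeDecision:
    """Query a vision LLM until it answers exactly "1" or "2".

    The verbatim prompt plus both images are sent on every attempt;
    replies are sanitized (whitespace and trailing punctuation stripped)
    and anything other than "1" or "2" triggers a re-prompt, up to
    ``max_retries`` independent attempts.  All raw replies are recorded
    in the returned decision or the raised :class:`JudgeProtocolError`.
    """
    if max_retries < 1:
        raise ValueError("max_retries must be >= 1")
    prompt = prompt_for_basis(basis)
    raw: list[str] = []
    for _ in range(max_retries):
        try:
            reply = transport(prompt, (image1.image_bytes, image2.image_bytes))
        except JudgeError:
            raise
        except Exception as exc:  # network/API failure, not protocol
            raise JudgeTransportError(f"judge transport failed: {exc}") from exc
        raw.append(reply)
        answer = sanitize_reply(reply)
        if answer in ("1", "2"):
            return JudgeDecision(
                winner=int(answer),
                raw_responses=raw,
                attempts=len(raw),
                backend="llm",
            )
    raise JudgeProtocolError(
        f"no valid '1'/'2' reply after {max_retries} attempts", raw
    )


def oracle_compare(
    score1: float, score2: float, tie_rule: str = "first"
) -> JudgeDecision:
    """Pick the image with the strictly larger (higher-is-better) score.

    Ties go to image 1 under ``tie_rule='first'`` or raise under
    ``tie_rule='error'``.
    """
    if not (np.isfinite(score1) and np.isfinite(score2)):
        raise ValueError(f"scores must be finite, got {score1!r}, {score2!r}")
    if score1 == score2:
        if tie_rule == "first":
            winner = 1
        elif tie_rule == "error":
            raise ValueError(f"tied scores ({score1}) with tie_rule='error'")
        else:
            raise ValueError(f"unknown tie_rule {tie_rule!r}")
    else:
        winner = 1 if score1 > score2 else 2
    return JudgeDecision(
        winner=winner,
        raw_responses=[str(winner)],
        attempts=1,
        backend="oracle",
    )


def noisy_oracle_compare(
    score1: float,
    score2: float,
    p: float,
    rng: np.random.Generator | int,
    tie_rule: str = "first",
) -> JudgeDecision:
    """Oracle verdict with accuracy ``p``: flipped with probability 1-p.

    ``p`` must lie in (0.5, 1]; at p=1 this reduces exactly to
    :func:`oracle_compare`.  The flip stream comes from a seeded
    generator, so a fixed seed yields an identical decision sequence.
    """
    if not (0.5 < p <= 1.0):
        raise ValueError(f"p must lie in (0.5, 1], got {p}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    truth = oracle_compare(score1, score2, tie_rule=tie_rule)
    winner = truth.winner
    if p < 1.0 and rng.random() >= p:
        winner = 3 - winner
    return JudgeDecision(
        winner=winner,
        raw_responses=[str(winner)],
        attempts=1,
        backend=f"noisy_oracle(p={p})",
    )


def majority_vote(
    backend: "JudgeBackend",
    image1: EmbeddingImage,
    image2: EmbeddingImage,
    k: int = 5,
) -> JudgeDecision:
    """k-shot judging: ask ``k`` times, return the most frequent winner.

    ``k`` must be odd so a majority always exists; k=1 is a single
    comparison.  Raw responses from all shots are concatenated.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    decisions = [backend.compare(image1, image2) for _ in range(k)]
    winner = Counter(d.winner for d in decisions).most_common(1)[0][0]
    raw = [r for d in decisions for r in d.raw_responses]
    return JudgeDecision(
        winner=winner,
        raw_responses=raw,
        attempts=len(raw),
        backend=f"majority({k})@{decisions[0].backend}",
    )


@dataclass
class LLMJudge:
    """Vision-LLM backend: a transport plus the retry protocol."""

    transport: Transport
    basis: str = "umap"
    max_retries: int = DEFAULT_MAX_RETRIES
    deterministic: bool = False

    def compare(self, image1: EmbeddingImage, image2: EmbeddingImage) -> JudgeDecision:
        return llm_compare(
            self.transport, image1, image2, basis=self.basis, max_retries=self.max_retries
        )


@dataclass
class OracleJudge:
    """Deterministic judge keyed to per-candidate scores by config_id."""

    scores: Mapping[str, float]
    tie_rule: str = "first"
    deterministic: bool = True

    def compare(self, image1: EmbeddingImage, image2: EmbeddingImage) -> JudgeDecision:
        return oracle_compare(
            self.scores[image1.config_id],
            self.scores[image2.config_id],
            tie_rule=self.tie_rule,
        )


class NoisyOracleJudge:
    """Oracle judge with accuracy ``p``, drawing flips from a seeded stream."""

    deterministic = False

    def __init__(self, scores: Mapping[str, float], p: float, seed: int, tie_rule: str = "first"):
        if not (0.5 < p <= 1.0):
            raise ValueError(f"p must lie in (0.5, 1], got {p}")
        self.scores = scores
        self.p = p
        self.tie_rule = tie_rule
        self._rng = np.random.default_rng(seed)

    def compare(self, image1: EmbeddingImage, image2: EmbeddingImage) -> JudgeDecision:
        return noisy_oracle_compare(
            self.scores[image1.config_id],
            self.scores[image2.config_id],
            self.p,
            self._rng,
            tie_rule=self.tie_rule,
        )


@dataclass
class MajorityJudge:
    """Wrap any backend so every comparison is a k-shot majority vote."""

    inner: "JudgeBackend"
    k: int = 5

    @property
    def deterministic(self) -> bool:
        return self.inner.deterministic

    def compare(self, image1: EmbeddingImage, image2: EmbeddingImage) -> JudgeDecision:
        return majority_vote(self.inner, image1, image2, k=self.k)


@dataclass
class OpenAIChatTransport:
    """Minimal chat-with-images transport for the OpenAI-style HTTP API.

    Sends the prompt and both PNGs (base64 data URLs) in one user message
    and returns the text of the first choice.  Uses only the standard
    library; the API key is read from ``api_key_env``.  Never exercised
    in offline tests.
    """

    model: str = DEFAULT_MODEL
    api_key_env: str = "OPENAI_API_KEY"
    base_url: str = "https://api.openai.com/v1"
    timeout: float = 120.0

    def __call__(self, prompt: str, images: tuple[bytes, bytes]) -> str:
        key = os.environ.get(self.api_key_env)
        if not key:
            raise JudgeTransportError(
                f"environment variable {self.api_key_env} is not set"
            )
        content: list[dict] = [{"type": "text", "text": prompt}]
        for png in images:
            b64 = base64.b64encode(png).decode("ascii")
            content.append(
                {
                    "type": "image_url",
                    "image_url": {"url": f"data:image/png;base64,{b64}"},
                }
            )
        body = json.dumps(
            {"model": self.model, "messages": [{"role": "user", "content": content}]}
        ).encode("utf-8")
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=body,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {key}",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode("utf-8"))
        except urllib.error.URLError as exc:
            raise JudgeTransportError(f"API request failed: {exc}") from exc
        try:
            return payload["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise JudgeTransportError(
                f"unexpected API response shape: {payload!r}"
            ) from exc


class JudgeBackend:
    """Structural contract (see module docstring); not meant to be instantiated."""

    deterministic: bool

    def compare(self, image1: EmbeddingImage, image2: EmbeddingImage) -> JudgeDecision:
        raise NotImplementedError
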