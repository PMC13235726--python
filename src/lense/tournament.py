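"""Sequential pairwise selection over N candidate pipelines.

The selection procedure plays N-1 comparisons: the first pits candidates
1 and 2; comparison i pits candidate i+1 (the challenger, shown as image
2) against the winner so far (the incumbent, shown as image 1).  The
final incumbent wins.  A round-robin variant judges every unordered pair
once and ranks candidates by win count, for reproducibility analyses of
full rankings rather than a single winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .judge import JudgeDecision
from .render import EmbeddingImage


@dataclass
class TournamentResult:
    """Winner plus the full comparison trace of one sequential tournament."""

    winner_config_id: str
    comparisons: list[tuple[str, str, JudgeDecision]]  # (challenger, incumbent, decision)
    n_candidates: int

    def to_records(self) -> list[dict]:
        return [
            {
                "round": i + 1,
                "challenger": ch,
                "incumbent": inc,
                "winner": inc if d.winner == 1 else ch,
                "verdict": d.winner,
                "backend": d.backend,
                "attempts": d.attempts,
                "raw_responses": d.raw_responses,
            }
            for i, (ch, inc, d) in enumerate(self.comparisons)
        ]


class TournamentError(RuntimeError):
    """A backend failure mid-tournament; carries the partial trace."""

    def __init__(self, message: str, partial_trace: list[tuple[str, str, JudgeDecision]]):
        super().__init__(message)
        self.partial_trace = partial_trace


def _config_ids(results: Sequence, images: Sequence[EmbeddingImage]) -> list[str]:
    if len(results) != len(images):
        raise ValueError(
            f"{len(results)} results but {len(images)} images; lists must align"
        )
    if len(images) == 0:
        raise ValueError("no candidates to compare")
    ids = [img.config_id for img in images]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate config_ids among candidates")
    return ids


def run_tournament(
    results: Sequence,
    images: Sequence[EmbeddingImage],
    backend,
) -> TournamentResult:
    """Run the N-1-comparison sequential tournament.

    ``results`` and ``images`` are aligned per candidate; the judge only
    sees images (oracle backends key off ``image.config_id``).  With a
    single candidate there are zero comparisons and it wins outright.
    A backend error aborts the run, preserving the partial trace on the
    raised :class:`TournamentError`.
    """
    ids = _config_ids(results, images)
    incumbent = 0
    trace: list[tuple[str, str, JudgeDecision]] = []
    for challenger in range(1, len(ids)):
        try:
            decision = backend.compare(images[incumbent], images[challenger])
        except Exception as exc:
            raise TournamentError(
                f"judge failed comparing {ids[challenger]!r} vs {ids[incumbent]!r} "
                f"after {len(trace)} comparisons: {exc}",
                trace,
            ) from exc
        trace.append((ids[challenger], ids[incumbent], decision))
        if decision.winner == 2:
            incumbent = challenger
    return TournamentResult(
        winner_config_id=ids[incumbent],
        comparisons=trace,
        n_candidates=len(ids),
    )


def round_robin_ranking(
    results: Sequence,
    images: Sequence[EmbeddingImage],
    backend,
) -> list[int]:
    """Rank all candidates by win count over every unordered pair.

    Judges each of the N(N-1)/2 pairs once (earlier candidate shown as
    image 1), counts wins, and returns ranks aligned to the input order
    (rank 1 = most wins); ties are broken by input (grid) order.
    """
    ids = _config_ids(results, images)
    n = len(ids)
    if n < 2:
        raise ValueError("round robin needs at least two candidates")
    wins = [0] * n
    trace: list[tuple[str, str, JudgeDecision]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                decision = backend.compare(images[i], images[j])
            except Exception as exc:
                raise TournamentError(
                    f"judge failed comparing {ids[j]!r} vs {ids[i]!r} "
                    f"after {len(trace)} comparisons: {exc}",
                    trace,
                ) from exc
            trace.append((ids[j], ids[i], decision))
            wins[i if decision.winner == 1 else j] += 1
    order = sorted(range(n), key=lambda i: (-wins[i], i))
    ranks = [0] * n
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks
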