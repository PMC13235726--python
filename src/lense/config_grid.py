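"""Candidate preprocessing configurations and the HVG count formula.

The default grid crosses six normalization methods, two feature-selection
modes, two PC counts and three clustering resolutions, for 72 candidate
pipelines.  Enumeration order is fixed (normalization-major, then feature
mode, PC count, resolution) so that downstream tournament runs are
reproducible: under a noisy judge the selection can depend on the order
in which candidates are presented.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

NORMALIZATIONS: tuple[str, ...] = ("sct_analog", "lognorm", "clr", "rc", "log", "raw")
FEATURE_MODES: tuple[str, ...] = ("all", "hvg_formula")
DEFAULT_N_PCS: tuple[int, ...] = (5, 20)
DEFAULT_RESOLUTIONS: tuple[float, ...] = (0.2, 0.5, 1.0)


@dataclass(frozen=True)
class PipelineConfig:
    """One grid point: a complete preprocessing configuration.

    Attributes
    ----------
    normalization
        One of ``sct_analog`` (negative-binomial Pearson residuals, a
        variance-stabilizing transform), ``lognorm`` (library-size
        normalization to 1e4 followed by log1p), ``clr`` (centered
        log-ratio within each cell), ``rc`` (relative counts to 1e4),
        ``log`` (log1p of raw counts) or ``raw`` (no normalization).
    feature_mode
        ``all`` keeps every gene; ``hvg_formula`` keeps the top
        :func:`hvg_count` genes by standardized variance.
    n_pcs
        Number of principal components used for clustering.
    resolution
        Resolution parameter of the modularity-based graph clustering.
    """

    normalization: str
    feature_mode: str
    n_pcs: int
    resolution: float

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; expected one of {NORMALIZATIONS}"
            )
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(
                f"unknown feature_mode {self.feature_mode!r}; expected one of {FEATURE_MODES}"
            )
        if not (isinstance(self.n_pcs, int) and self.n_pcs > 0):
            raise ValueError(f"n_pcs must be a positive integer, got {self.n_pcs!r}")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution!r}")

    @property
    def config_id(self) -> str:
        """Stable key: the four field values joined by '|' in factor order."""
        res = format(float(self.resolution), "g")
        return f"{self.normalization}|{self.feature_mode}|{self.n_pcs}|{res}"

    def to_dict(self) -> dict:
        return {
            "normalization": self.normalization,
            "feature_mode": self.feature_mode,
            "n_pcs": self.n_pcs,
            "resolution": self.resolution,
            "config_id": self.config_id,
        }


def _validated(name: str, values: Iterable | None, default: Sequence) -> tuple:
    if values is None:
        return tuple(default)
    vals = tuple(values)
    if len(vals) == 0:
        raise ValueError(f"empty value list for grid factor {name!r}")
    return vals


def default_grid(
    normalizations: Iterable[str] | None = None,
    feature_modes: Iterable[str] | None = None,
    n_pcs: Iterable[int] | None = None,
    resolutions: Iterable[float] | None = None,
) -> list[PipelineConfig]:
    """Enumerate the candidate grid in canonical order.

    With no arguments this is the full 6 x 2 x 2 x 3 = 72-configuration
    default.  Each factor can be subset (or extended, for ``n_pcs`` and
    ``resolutions``) with an explicit value list; an empty list is an
    error naming the factor.  The order is deterministic:
    normalization-major, then feature mode, PC count, resolution.
    """
    norms = _validated("normalizations", normalizations, NORMALIZATIONS)
    modes = _validated("feature_modes", feature_modes, FEATURE_MODES)
    pcs = _validated("n_pcs", n_pcs, DEFAULT_N_PCS)
    ress = _validated("resolutions", resolutions, DEFAULT_RESOLUTIONS)
    grid = [
        PipelineConfig(n, m, int(p), float(r))
        for n, m, p, r in itertools.product(norms, modes, pcs, ress)
    ]
    ids = [c.config_id for c in grid]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate configurations in grid subset")
    return grid


def hvg_count(n_features: int) -> int:
    """Number of highly variable genes to keep out of ``n_features``.

    Computes ``2 * 10 ** (ceil(log10(I / 2)) - 1)`` for ``I`` total
    features, rounded to the nearest integer and clamped to ``[1, I]``.
    The formula picks the power of ten nearest below the feature count:
    2000 genes -> 200 HVGs, 100 -> 20, 20 -> 2.  The clamp only matters
    for degenerate inputs (I <= 3), where the raw formula drops below 1.
    """
    if not n_features >= 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    # ceil(log10(I/2)) == smallest integer k with 10**k >= I/2; computed
    # by integer search to avoid float log rounding at exact powers of 10.
    half = n_features / 2
    k = math.ceil(math.log10(half))
    while 10.0**k < half:
        k += 1
    while k > -10 and 10.0 ** (k - 1) >= half:
        k -= 1
    value = round(2 * 10.0 ** (k - 1))
    return max(1, min(int(value), n_features))
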