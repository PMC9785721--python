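"""Component-count suggestion from the singular-value spectrum of D."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraMatrix

__all__ = ["RankScan", "scan_rank"]


@dataclass
class RankScan:
    """Scree summary: leading singular values plus two rank heuristics.

    ``rank_by_drop`` places the cut at the largest consecutive drop ratio;
    ``rank_by_floor`` counts values above ``rel_floor * s_max``.
    ``suggested_rank`` is the drop heuristic when a clear drop exists
    (ratio >= the configured threshold), otherwise the floor count.
    """

    singular_values: np.ndarray
    drop_ratios: np.ndarray
    suggested_rank: int
    rank_by_drop: int
    rank_by_floor: int
    rel_floor: float
    drop_threshold: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.singular_values) > 1e-9 * self.singular_values[0]):
            raise ValueError("singular values must be non-increasing")
        if not 1 <= self.suggested_rank <= self.singular_values.size:
            raise ValueError("suggested_rank out of range")


def scan_rank(
    spectra: SpectraMatrix | np.ndarray,
    max_rank: int = 30,
    rel_floor: float = 0.01,
    drop_threshold: float = 5.0,
) -> RankScan:
    """SVD scree of the mixture matrix with a heuristic component count.

    No mean-centering is applied (MCR convention).  Both heuristics are
    reported; thresholds are configuration, not dogma.
    """
    d = spectra.values if isinstance(spectra, SpectraMatrix) else np.atleast_2d(spectra)
    if d.size == 0:
        raise ValueError("empty matrix")
    if max_rank < 1 or max_rank > min(d.shape):
        raise ValueError(f"max_rank must be in [1, {min(d.shape)}]")
    s = np.linalg.svd(d, compute_uv=False)[:max_rank]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(s[1:] > 0, s[:-1] / s[1:], np.inf)
    ratios = np.where(s[:-1] == 0, 1.0, ratios)  # 0/0 tail: no drop

    floor = rel_floor * s[0]
    rank_by_floor = max(1, int(np.sum(s > floor)))
    if ratios.size:
        best = int(np.argmax(ratios))  # ties: earliest drop wins
        rank_by_drop = best + 1
        has_drop = ratios[best] >= drop_threshold
    else:
        rank_by_drop, has_drop = 1, False
    suggested = rank_by_drop if has_drop else rank_by_floor
    return RankScan(
        singular_values=s,
        drop_ratios=ratios,
        suggested_rank=suggested,
        rank_by_drop=rank_by_drop,
        rank_by_floor=rank_by_floor,
        rel_floor=rel_floor,
        drop_threshold=drop_threshold,
    )
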