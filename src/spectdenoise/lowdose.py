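"""Reduced-dose and gated acquisition simulation by count thinning.

Low-dose acquisitions are simulated from standard-dose count data by binomial
subsampling: each detected event is independently kept with probability ``p``
(1/2, 1/4, 1/8 for the pipeline presets).  Operating on binned counts with a
per-bin Binomial(n, p) draw is distribution-identical to per-event Bernoulli
selection on the list-mode stream, and by the Poisson thinning theorem turns
Poisson(lam) bins into Poisson(p*lam) bins.  Cardiac gating partitions every
bin's events across gates with a multinomial draw, so gate sums reconstruct
the parent exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import ProjectionSet

__all__ = [
    "ThinResult",
    "binomial_thin",
    "split_gates",
    "crop_projections",
    "explode_to_events",
    "rebin_events",
]


@dataclass
class ThinResult:
    """Kept/rejected split of a projection set after binomial thinning."""

    kept: ProjectionSet
    rejected: ProjectionSet
    p: float
    seed: int


def binomial_thin(proj: ProjectionSet, p: float, seed: int) -> ThinResult:
    """Randomly keep each event with probability ``p``; return both halves.

    kept + rejected equals the parent bin-wise and exactly;
    ``kept.dose_fraction`` is the parent's dose fraction times ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"retention probability p must be in [0, 1], got {p}")
    if proj.counts is None:
        raise ValueError("projection set has no counts to thin")
    rng = np.random.default_rng(seed)
    kept_counts = rng.binomial(proj.counts, p).astype(proj.counts.dtype)
    rej_counts = proj.counts - kept_counts
    prov = {**proj.provenance, "stage": "binomial_thin", "seed": seed, "p": p}
    kept = replace(
        proj,
        counts=kept_counts,
        expected=None if proj.expected is None else proj.expected * p,
        dose_fraction=proj.dose_fraction * p if p > 0 else proj.dose_fraction,
        provenance=prov,
    )
    if p == 0.0:
        # dose_fraction must stay in (0, 1]; an all-rejected set keeps the
        # parent tag and carries p in provenance
        kept = replace(kept, dose_fraction=proj.dose_fraction)
    rejected = replace(
        proj,
        counts=rej_counts,
        expected=None if proj.expected is None else proj.expected * (1.0 - p),
        dose_fraction=proj.dose_fraction * (1.0 - p) if p < 1 else proj.dose_fraction,
        provenance={**prov, "arm": "rejected"},
    )
    return ThinResult(kept=kept, rejected=rejected, p=p, seed=seed)


def split_gates(
    proj: ProjectionSet,
    n_gates: int = 8,
    gate_weights: np.ndarray | None = None,
    seed: int = 0,
) -> list[ProjectionSet]:
    """Partition counts into cardiac gates with a per-bin multinomial draw."""
    if n_gates < 1:
        raise ValueError("n_gates must be >= 1")
    if proj.counts is None:
        raise ValueError("projection set has no counts to gate")
    if gate_weights is None:
        weights = np.full(n_gates, 1.0 / n_gates)
    else:
        weights = np.asarray(gate_weights, dtype=float)
        if weights.shape != (n_gates,):
            raise ValueError(f"gate_weights must have length {n_gates}")
        if np.any(weights < 0):
            raise ValueError("gate_weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"gate_weights must sum to 1, got {weights.sum()}")
    if n_gates == 1:
        return [replace(proj, gate=0, n_gates=1)]
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(proj.counts, weights)  # (..., n_gates)
    prov = {**proj.provenance, "stage": "split_gates", "seed": seed}
    out = []
    for g in range(n_gates):
        out.append(
            replace(
                proj,
                counts=np.ascontiguousarray(draws[..., g]).astype(proj.counts.dtype),
                expected=None if proj.expected is None else proj.expected * weights[g],
                gate=g,
                n_gates=n_gates,
                provenance={**prov, "gate_weight": float(weights[g])},
            )
        )
    return out


def crop_projections(proj: ProjectionSet, row_range: tuple[int, int]) -> ProjectionSet:
    """Zero detector rows outside ``row_range`` (half-open [lo, hi)).

    Mimics the manual exclusion of sub-diaphragmatic (liver) activity from
    the cardiac field of view; the grid shape is preserved so the network
    input stays 64 x 64.  Idempotent.
    """
    lo, hi = row_range
    n_rows = proj.geometry.detector_rows
    lo, hi = int(lo), int(hi)
    if not (0 <= lo < hi <= n_rows):
        raise ValueError(f"row_range {row_range} empty or outside [0, {n_rows})")
    mask = np.zeros(n_rows, dtype=bool)
    mask[lo:hi] = True

    def crop(arr):
        if arr is None:
            return None
        out = arr.copy()
        out[:, ~mask, :] = 0
        return out

    return replace(
        proj,
        counts=crop(proj.counts),
        expected=crop(proj.expected),
        provenance={**proj.provenance, "stage": "crop", "row_range": (lo, hi)},
    )


def explode_to_events(proj: ProjectionSet, seed: int = 0) -> np.ndarray:
    """Expand binned counts into a shuffled pseudo list-mode event table.

    Returns an (n_events, 3) integer array of (view, row, col) per event.
    Demonstration adapter: thinning this table event-by-event and re-binning
    is distribution-identical to :func:`binomial_thin` on the bins.
    """
    if proj.counts is None:
        raise ValueError("projection set has no counts")
    flat = proj.counts.ravel()
    idx = np.repeat(np.arange(flat.size), flat)
    rng = np.random.default_rng(seed)
    rng.shuffle(idx)
    return np.stack(np.unravel_index(idx, proj.counts.shape), axis=1)


def rebin_events(events: np.ndarray, like: ProjectionSet) -> ProjectionSet:
    """Re-bin an event table onto the grid of ``like``."""
    flat_idx = np.ravel_multi_index(tuple(events.T), like.geometry.shape)
    counts = np.bincount(flat_idx, minlength=int(np.prod(like.geometry.shape)))
    counts = counts.reshape(like.geometry.shape).astype(np.int64)
    return replace(like, counts=counts, expected=None,
                   provenance={**like.provenance, "stage": "rebin_events"})
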