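"""Source counting and most-probable wave paths.

A wavefront from one focal source enters the catheter's outer loop at
some pair (FO), reaches the inner loop (FI), and exits through the inner
(LI) and outer (LO) loops.  The four per-loop probability vectors
(first/last × outer/inner) therefore each carry one high-probability
entry per source, and ranking them yields one 4-tuple path per source:
rank r pairs the r-th largest entries of the four vectors positionally.

The number of sources is the maximum, over the four vectors, of the
number of significantly-above-chance entries: a second source may be
visible only in the exit (last-activation) statistics when both sources
lie in the same direction from the catheter, so no single vector can be
trusted alone.

A ranked entry whose probability falls below the chance level 1/D is
treated as uninformative: the rank-1 entry is reused for that vector and
the path is flagged degenerate (two sources entering through the same
pair but exiting differently produce exactly this pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationMatrix
from .geometry import PAIRS_PER_LOOP
from .stats import ProbabilityEstimate, compute_indicators, significant_pairs

__all__ = [
    "ProbablePath",
    "PathMatchedSample",
    "infer_source_count",
    "extract_probable_paths",
    "filter_path_matched",
]


@dataclass(frozen=True)
class ProbablePath:
    """Entry/exit pairs of one source's most probable wave path.

    FO/LO are outer-loop pair indices (first/last activated), FI/LI the
    inner-loop analogues.  ``entry_probabilities`` and ``entry_pvalues``
    record, per slot (FO, FI, LI, LO), the probability and raw p-value of
    the ranked entry that produced it; ``reused_slots`` marks slots where
    a below-chance ranked entry was replaced by the rank-1 pair.
    """

    source_rank: int
    FO: int
    FI: int
    LI: int
    LO: int
    entry_probabilities: tuple = ()
    entry_pvalues: tuple = ()
    reused_slots: tuple = ()

    def __post_init__(self) -> None:
        for name, v, lo, hi in (("FO", self.FO, 11, 19), ("LO", self.LO, 11, 19), ("FI", self.FI, 1, 9), ("LI", self.LI, 1, 9)):
            if not (lo <= v <= hi and v % 2 == 1):
                raise ValueError(f"{name} must be an odd pair index in [{lo}, {hi}], got {v}")

    @property
    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.FO, self.FI, self.LI, self.LO)

    @property
    def degenerate(self) -> bool:
        return self.FO == self.LO

    def __str__(self) -> str:  # e.g. "13-3-9-17"
        return "-".join(str(v) for v in self.as_tuple)


@dataclass(frozen=True)
class PathMatchedSample:
    """Activations whose observed first/last pattern matches a path."""

    path: ProbablePath
    activation_ids: np.ndarray
    strictness: str = "outer_only"

    def __post_init__(self) -> None:
        object.__setattr__(self, "activation_ids", np.asarray(self.activation_ids, dtype=int))

    @property
    def T_star(self) -> int:
        return len(self.activation_ids)


def infer_source_count(
    first_estimates: ProbabilityEstimate,
    last_estimates: ProbabilityEstimate,
    alpha: float = 0.1,
) -> int:
    """Number of sources = max significant-entry count over the 4 vectors."""
    best = 0
    for est in (first_estimates, last_estimates):
        for loop, sig in significant_pairs(est, alpha).items():
            best = max(best, len(sig))
    if best == 0:
        warnings.warn(
            "no pair is significantly above chance in any loop; "
            "assuming a single source (low confidence)",
            stacklevel=2,
        )
        return 1
    return best


def _ranked(pairs: np.ndarray, p: np.ndarray):
    """Pair indices sorted by descending probability, ties to smaller index."""
    order = np.lexsort((pairs, -p))
    return pairs[order], p[order]


def extract_probable_paths(
    first_estimates: ProbabilityEstimate,
    last_estimates: ProbabilityEstimate,
    n_sources: int,
) -> list[ProbablePath]:
    """Rank the four probability vectors and pair ranks positionally.

    Path r = (r-th largest outer-first, r-th largest inner-first, r-th
    largest inner-last, r-th largest outer-last).  A ranked entry with
    probability below chance (1/D) is replaced by that vector's rank-1
    pair and the slot flagged in ``reused_slots``.
    """
    if not 1 <= n_sources <= PAIRS_PER_LOOP:
        raise ValueError(f"n_sources must be in [1, {PAIRS_PER_LOOP}]")
    chance = 1.0 / PAIRS_PER_LOOP
    slots = [  # (estimate, loop) per path slot FO, FI, LI, LO
        (first_estimates, "outer"),
        (first_estimates, "inner"),
        (last_estimates, "inner"),
        (last_estimates, "outer"),
    ]
    ranked = []
    for est, loop in slots:
        pairs, p = _ranked(est.pairs(loop), est.p_star[loop])
        pv = {int(a): float(b) for a, b in zip(est.pairs(loop), est.p_value[loop])}
        ranked.append((pairs, p, pv))
    out = []
    for r in range(n_sources):
        chosen, probs, pvals, reused = [], [], [], []
        for pairs, p, pv in ranked:
            k = r
            if p[k] < chance:  # uninformative entry: fall back to the dominant pair
                k = 0
                reused.append(True)
            else:
                reused.append(False)
            chosen.append(int(pairs[k]))
            probs.append(float(p[k]))
            pvals.append(pv[int(pairs[k])])
        out.append(
            ProbablePath(
                source_rank=r + 1,
                FO=chosen[0],
                FI=chosen[1],
                LI=chosen[2],
                LO=chosen[3],
                entry_probabilities=tuple(probs),
                entry_pvalues=tuple(pvals),
                reused_slots=tuple(reused),
            )
        )
    return out


def filter_path_matched(
    matrix: ActivationMatrix,
    path: ProbablePath,
    strictness: str = "outer_only",
) -> PathMatchedSample:
    """Select the activations consistent with a path.

    ``outer_only`` requires the observed outer-loop first and last pairs
    to equal FO and LO; ``full`` additionally requires FI and LI.
    """
    if strictness not in ("outer_only", "full"):
        raise ValueError("strictness must be 'outer_only' or 'full'")
    first = compute_indicators(matrix, "first")
    last = compute_indicators(matrix, "last")
    from .stats import LOOP_PAIRS

    def observed(ind, loop):
        pairs = LOOP_PAIRS[loop]
        return pairs[np.argmax(ind.indicators[loop], axis=1)]

    ok = (observed(first, "outer") == path.FO) & (observed(last, "outer") == path.LO)
    if strictness == "full":
        ok &= (observed(first, "inner") == path.FI) & (observed(last, "inner") == path.LI)
    ids = matrix.activation_ids[ok]
    if len(ids) == 0:
        raise ValueError(
            f"no activation matches path {path}; collect more activations or "
            "re-derive the path at a different catheter position"
        )
    return PathMatchedSample(path=path, activation_ids=ids, strictness=strictness)
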