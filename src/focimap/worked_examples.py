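"""Bundled worked-example probability tables.

Two activation-probability tables from a simulated two-source mapping
session with a 20-electrode two-loop catheter, used throughout the docs
and tests as compact, human-checkable inputs to the hypothesis test,
source counting and path extraction:

* ``TWO_DISTANT_SOURCES`` — two focal sources in clearly different
  directions from the catheter; both are visible in the first- and the
  last-activation statistics of both loops.
* ``TWO_NEARBY_SOURCES`` — an abnormal source close to the normal one,
  so both wavefronts enter the catheter through the same pairs and the
  second source is visible only in the last-activation (exit)
  statistics.

Each table stores, per loop and mode, the estimated probabilities ``p*``
for the five pairs in ascending pair-index order (outer 11…19, inner
1…9).  p-values are not stored: they are recomputed from ``p*`` by the
hypothesis test, which the tests cross-check against the expected
rounded values below.
"""

from __future__ import annotations

import numpy as np

from .stats import LOOP_PAIRS, ProbabilityEstimate

__all__ = [
    "TWO_DISTANT_SOURCES",
    "TWO_NEARBY_SOURCES",
    "estimates_from_table",
]

# probabilities per (mode, loop), pairs ascending: outer 11-13-15-17-19, inner 1-3-5-7-9
TWO_DISTANT_SOURCES = {
    "first": {
        "outer": [0.31, 0.42, 0.09, 0.09, 0.05],
        "inner": [0.30, 0.45, 0.07, 0.09, 0.06],
    },
    "last": {
        "outer": [0.07, 0.10, 0.27, 0.47, 0.06],
        "inner": [0.08, 0.13, 0.03, 0.29, 0.45],
    },
}

# expected reported p-values for the same table (2 decimals, floored at 0.01)
TWO_DISTANT_SOURCES_PVALUES = {
    "first": {
        "outer": [0.06, 0.02, 0.33, 0.33, 0.40],
        "inner": [0.07, 0.01, 0.36, 0.33, 0.38],
    },
    "last": {
        "outer": [0.36, 0.31, 0.09, 0.01, 0.38],
        "inner": [0.34, 0.26, 0.44, 0.07, 0.01],
    },
}

TWO_NEARBY_SOURCES = {
    "first": {
        "outer": [0.02, 0.87, 0.07, 0.01, 0.01],
        "inner": [0.01, 0.89, 0.06, 0.01, 0.01],
    },
    "last": {
        "outer": [0.01, 0.02, 0.01, 0.74, 0.20],
        "inner": [0.01, 0.02, 0.01, 0.58, 0.37],
    },
}

TWO_NEARBY_SOURCES_PVALUES = {
    "first": {
        "outer": [0.46, 0.01, 0.36, 0.48, 0.48],
        "inner": [0.48, 0.01, 0.38, 0.48, 0.48],
    },
    "last": {
        "outer": [0.48, 0.46, 0.48, 0.01, 0.16],
        "inner": [0.48, 0.46, 0.48, 0.01, 0.03],
    },
}


def estimates_from_table(table: dict, mode: str) -> ProbabilityEstimate:
    """Wrap one mode of a worked-example table as a ProbabilityEstimate.

    p-values are recomputed from p* with the activation-order test; EL
    bounds are not part of the table and default to the trivial [0, 1].
    """
    from .stats import activation_pvalue

    p_star = {loop: np.asarray(table[mode][loop], dtype=float) for loop in table[mode]}
    return ProbabilityEstimate(
        mode=mode,
        p_star=p_star,
        lb={loop: np.zeros(len(LOOP_PAIRS[loop])) for loop in p_star},
        ub={loop: np.ones(len(LOOP_PAIRS[loop])) for loop in p_star},
        p_value={loop: np.array([activation_pvalue(p) for p in p_star[loop]]) for loop in p_star},
    )
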