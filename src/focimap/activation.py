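"""The local-activation-time (LAT) table: T activations × 10 bipolar pairs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import INNER_PAIR_INDICES, OUTER_PAIR_INDICES

__all__ = ["ActivationMatrix", "ALL_PAIR_INDICES", "loop_of_pair"]

ALL_PAIR_INDICES = tuple(INNER_PAIR_INDICES) + tuple(OUTER_PAIR_INDICES)


def loop_of_pair(pair_index: int) -> str:
    if pair_index in INNER_PAIR_INDICES:
        return "inner"
    if pair_index in OUTER_PAIR_INDICES:
        return "outer"
    raise ValueError(f"unknown bipolar pair index {pair_index}")


@dataclass(frozen=True)
class ActivationMatrix:
    """LATs for T activation cycles at the catheter's 10 bipolar pairs.

    ``lat`` is a (T, 10) array in ms; columns follow ascending pair index
    (1, 3, …, 9, 11, …, 19).  ``source_of_record`` optionally records, per
    (activation, pair), which generating source's wavefront arrived first —
    ground truth that only the synthetic simulator can supply.
    """

    lat: np.ndarray  # (T, 10), ms
    activation_ids: np.ndarray = None  # (T,), 1-based
    source_of_record: np.ndarray | None = None  # (T, 10) int, or None

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        if lat.ndim != 2 or lat.shape[1] != len(ALL_PAIR_INDICES):
            raise ValueError(f"lat must be (T, {len(ALL_PAIR_INDICES)}), got {lat.shape}")
        if lat.shape[0] < 1:
            raise ValueError("need at least one activation")
        if not np.isfinite(lat).all():
            raise ValueError("all LAT entries must be finite")
        object.__setattr__(self, "lat", lat)
        ids = self.activation_ids
        if ids is None:
            ids = np.arange(1, lat.shape[0] + 1)
        object.__setattr__(self, "activation_ids", np.asarray(ids, dtype=int))
        if len(self.activation_ids) != lat.shape[0]:
            raise ValueError("activation_ids length must match the number of rows")

    @property
    def n_activations(self) -> int:
        return self.lat.shape[0]

    @property
    def pair_indices(self) -> np.ndarray:
        return np.array(ALL_PAIR_INDICES)

    def column_of(self, pair_index: int) -> int:
        return ALL_PAIR_INDICES.index(pair_index)

    def loop_columns(self, loop: str) -> np.ndarray:
        """Column positions of one loop's five pairs, ascending pair index."""
        return np.array([k for k, p in enumerate(ALL_PAIR_INDICES) if loop_of_pair(p) == loop])

    def loop_lat(self, loop: str) -> np.ndarray:
        """(T, 5) LAT block for one loop."""
        return self.lat[:, self.loop_columns(loop)]

    def subset(self, row_indices) -> "ActivationMatrix":
        """Matrix restricted to the given 0-based row positions."""
        rows = np.asarray(row_indices, dtype=int)
        src = None if self.source_of_record is None else self.source_of_record[rows]
        return ActivationMatrix(self.lat[rows], self.activation_ids[rows], src)

    def subset_by_ids(self, activation_ids) -> "ActivationMatrix":
        pos = {a: k for k, a in enumerate(self.activation_ids)}
        return self.subset([pos[a] for a in activation_ids])
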