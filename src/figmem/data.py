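"""Person x item count-score container used by all model fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResponseMatrix"]


@dataclass
class ResponseMatrix:
    """Complete persons x items matrix of correct-association counts.

    ``scores[v, i]`` is the number of correctly remembered emblem-frame
    associations of person ``v`` on item ``i`` (0..max_score).  Items carry a
    radical level (1-3, visual information load) and an incidental id; persons
    optionally carry a condition-group label (presentation order).
    """

    scores: np.ndarray
    radical_levels: np.ndarray
    incidental_ids: np.ndarray
    item_ids: list = field(default_factory=list)
    person_ids: list = field(default_factory=list)
    groups: np.ndarray | None = None
    max_score: int = 20

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D persons x items matrix")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError("scores must be integers")
            self.scores = self.scores.astype(np.int64)
        if self.scores.min(initial=0) < 0 or self.scores.max(initial=0) > self.max_score:
            raise ValueError(f"scores must lie in 0..{self.max_score}")
        P, I = self.scores.shape
        self.radical_levels = np.asarray(self.radical_levels, dtype=int)
        self.incidental_ids = np.asarray(self.incidental_ids, dtype=int)
        if self.radical_levels.shape != (I,) or self.incidental_ids.shape != (I,):
            raise ValueError("item metadata length must match the number of items")
        if not self.item_ids:
            self.item_ids = [
                f"R{r}_I{i}" for r, i in zip(self.radical_levels, self.incidental_ids)
            ]
        if len(self.item_ids) != I:
            raise ValueError("item_ids length mismatch")
        if not self.person_ids:
            self.person_ids = [f"p{k + 1}" for k in range(P)]
        if len(self.person_ids) != P:
            raise ValueError("person_ids length mismatch")
        if len(set(self.person_ids)) != P:
            raise ValueError("duplicate person_id")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != (P,):
                raise ValueError("groups length must match the number of persons")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def n_obs(self) -> int:
        return self.scores.size

    def require_fittable(self) -> None:
        if self.n_persons < 2 or self.n_items < 2:
            raise ValueError("model fits need at least 2 persons and 2 items")

    def total_scores(self) -> np.ndarray:
        return self.scores.sum(axis=1)

    def subset_items(self, idx) -> "ResponseMatrix":
        idx = np.asarray(idx)
        return ResponseMatrix(
            scores=self.scores[:, idx],
            radical_levels=self.radical_levels[idx],
            incidental_ids=self.incidental_ids[idx],
            item_ids=[self.item_ids[j] for j in idx],
            person_ids=list(self.person_ids),
            groups=None if self.groups is None else self.groups.copy(),
            max_score=self.max_score,
        )
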