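"""Prioritized experience replay with a sum-tree index.

Transitions are stored FIFO up to capacity. Each record carries a priority
p_i > 0 (TD-error magnitude plus a floor); sampling draws record i with
probability p_i^alpha / sum_j p_j^alpha in O(log n) via a binary sum tree,
and returns importance weights (N * P(i))^-beta normalized by the batch
maximum so the weighted TD loss stays unbiased as beta -> 1. New records
enter at the current maximum priority so every experience is replayed at
least once with full weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TransitionRecord:
    """One logged or simulated experience tuple with its replay priority."""

    state: np.ndarray
    action: np.ndarray
    reward: float
    next_state: np.ndarray
    priority: float = 1.0

    def __post_init__(self) -> None:
        if self.priority <= 0:
            raise ValueError("priority must be > 0")


class SumTree:
    """Fixed-size binary indexed tree over leaf weights."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self.tree = np.zeros(2 * capacity)

    def set(self, leaf: int, value: float) -> None:
        i = leaf + self.capacity
        delta = value - self.tree[i]
        while i >= 1:
            self.tree[i] += delta
            i //= 2

    def get(self, leaf: int) -> float:
        return self.tree[leaf + self.capacity]

    @property
    def total(self) -> float:
        return self.tree[1]

    def find(self, mass: float) -> int:
        """Leaf index whose cumulative-weight interval contains ``mass``."""
        i = 1
        while i < self.capacity:
            left = 2 * i
            if mass <= self.tree[left]:
                i = left
            else:
                mass -= self.tree[left]
                i = left + 1
        return i - self.capacity


@dataclass
class PrioritizedBuffer:
    """FIFO replay buffer with proportional prioritized sampling."""

    capacity: int
    alpha: float = 0.6
    priority_floor: float = 1e-3
    seed: int = 0
    records: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        self._tree = SumTree(self.capacity)
        self._next = 0  # FIFO write cursor
        self._max_priority = 1.0
        self._rng = np.random.default_rng(self.seed)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: TransitionRecord) -> None:
        """Insert at the current max priority, evicting FIFO when full."""
        record.priority = self._max_priority
        if len(self.records) < self.capacity:
            self.records.append(record)
        else:
            self.records[self._next] = record
        self._tree.set(self._next, record.priority**self.alpha)
        self._next = (self._next + 1) % self.capacity

    def sample(self, n: int, beta: float):
        """Draw ``n`` records with replacement.

        Returns ``(records, importance weights, indices)``.
        """
        size = len(self.records)
        if size == 0:
            raise ValueError("cannot sample from an empty buffer")
        if n < 1:
            raise ValueError("need at least one draw")
        total = self._tree.total
        masses = self._rng.uniform(0.0, total, size=n)
        indices = np.array([self._tree.find(m) for m in masses], dtype=int)
        indices = np.minimum(indices, size - 1)  # guard fp edge at the boundary
        probs = np.array([self._tree.get(i) for i in indices]) / total
        weights = (size * probs) ** (-beta)
        weights /= weights.max()
        return [self.records[i] for i in indices], weights, indices

    def update_priorities(self, indices, td_errors) -> None:
        """Refresh priorities to |TD error| + floor after a critic update."""
        for i, td in zip(indices, np.asarray(td_errors, dtype=float)):
            p = abs(td) + self.priority_floor
            self.records[i].priority = p
            self._tree.set(int(i), p**self.alpha)
            self._max_priority = max(self._max_priority, p)

    def sampling_probabilities(self) -> np.ndarray:
        """Current P(i) over stored records (diagnostic)."""
        size = len(self.records)
        weights = np.array([self._tree.get(i) for i in range(size)])
        return weights / weights.sum()
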