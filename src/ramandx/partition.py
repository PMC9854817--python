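"""Stratified train/test partitioning.

The per-class rule is floor(train_frac * n_c) training members, chosen
uniformly at random, remainder to the test set — the rounding convention that
reproduces a 7:3 design of (241, 463, 100) as train (168, 324, 70) / test
(73, 139, 30).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .errors import ConfigError, DataError
from .types import CLASSES


@dataclass
class SplitResult:
    """Disjoint train/test index lists with per-class bookkeeping."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    per_class_counts: dict[str, tuple[int, int]]

    @property
    def n_train(self) -> int:
        return self.train_indices.size

    @property
    def n_test(self) -> int:
        return self.test_indices.size


def stratified_split(labels: np.ndarray, train_frac: float = 0.7, seed: int = 0) -> SplitResult:
    """Partition sample indices, preserving class proportions.

    Every class must have at least 2 members so both parts are non-trivial.
    Identical seeds give identical partitions.
    """
    if not 0 < train_frac < 1:
        raise ConfigError(f"train_frac must lie in (0, 1), got {train_frac}")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F]))
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    per_class: dict[str, tuple[int, int]] = {}
    present = [c for c in CLASSES if np.any(labels == c)]
    if not present:
        raise DataError("no recognised class labels present")
    for cls in present:
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise DataError(f"class {cls!r} has {members.size} member(s); need >= 2")
        members = members[rng.permutation(members.size)]
        n_train = int(math.floor(train_frac * members.size))
        train_parts.append(np.sort(members[:n_train]))
        test_parts.append(np.sort(members[n_train:]))
        per_class[cls] = (n_train, members.size - n_train)
    return SplitResult(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        per_class_counts=per_class,
    )
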