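"""Labelled dataset assembly: class-ratio subsampling and holdout splits.

Aquaporin-style datasets are tiny on the positive side and huge on the
negative side, so experiments run at controlled positive:negative ratios
(1:1, 1:2, ... or "all").  All positives are always kept; negatives are
subsampled uniformly without replacement with a recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .io import ProteinRecord


@dataclass(frozen=True)
class RatioSpec:
    """positives:negatives = 1:ratio, or ratio='all' to keep every negative."""

    ratio: Union[int, str] = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio != "all" and (not isinstance(self.ratio, int) or self.ratio < 1):
            raise ValueError(f"ratio must be a positive integer or 'all', got {self.ratio!r}")


def assemble(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    ratio: RatioSpec,
) -> list[ProteinRecord]:
    """Combine the full positive pool with a ratio-sized negative subsample.

    Negatives are drawn uniformly without replacement; the combined list is
    shuffled deterministically by the seed; labels 1/0 are attached.
    """
    if not pos or not neg:
        raise ValueError("both the positive and the negative pool must be non-empty")
    rng = np.random.default_rng(ratio.seed)
    if ratio.ratio == "all":
        chosen_neg = list(neg)
    else:
        n_needed = ratio.ratio * len(pos)
        if n_needed > len(neg):
            raise ValueError(
                f"ratio 1:{ratio.ratio} needs {n_needed} negatives but only "
                f"{len(neg)} are available"
            )
        idx = rng.choice(len(neg), size=n_needed, replace=False)
        chosen_neg = [neg[i] for i in idx]
    combined = [r.with_label(1) for r in pos] + [r.with_label(0) for r in chosen_neg]
    perm = rng.permutation(len(combined))
    return [combined[i] for i in perm]


def split_holdout(
    records: Sequence[ProteinRecord],
    fraction: float,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Stratified train/test split; test gets round(fraction * n) per class.

    The two sides are disjoint and their union is the input.  Raises if either
    side of either class would be empty.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    records = list(records)
    rng = np.random.default_rng(seed)
    train: list[ProteinRecord] = []
    test: list[ProteinRecord] = []
    for cls in (0, 1):
        members = [r for r in records if r.label == cls]
        if not members:
            raise ValueError(f"class {cls} absent from input")
        n_test = int(round(fraction * len(members)))
        if n_test == 0 or n_test == len(members):
            raise ValueError(
                f"fraction {fraction} leaves an empty side for class {cls} "
                f"({len(members)} samples)"
            )
        idx = rng.permutation(len(members))
        test.extend(members[i] for i in idx[:n_test])
        train.extend(members[i] for i in idx[n_test:])
    # deterministic shuffle so class blocks are not contiguous
    train = [train[i] for i in rng.permutation(len(train))]
    test = [test[i] for i in rng.permutation(len(test))]
    return train, test
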