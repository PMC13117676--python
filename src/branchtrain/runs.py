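"""Run (cluster) extraction and grouping from branch-label sequences.

A cluster is a maximal stretch of consecutive cells that chose the same
branch.  Clusters are indexed by *cluster order* (1 = the front-cell
cluster) and the final cluster of every train is flagged *censored*: it
was terminated by the end of the train, not by an opposite-branch choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .simulate import BranchSequence

__all__ = [
    "RunRecord",
    "RunLengthSample",
    "SymmetryResult",
    "EmptyGroupError",
    "extract_runs",
    "group_runs",
    "sample_from_lengths",
    "front_choice_symmetry",
]


class EmptyGroupError(ValueError):
    """Raised when a selector matches no cluster records."""


@dataclass(frozen=True)
class RunRecord:
    """One cluster: its train, order within the train, size, censoring."""

    train_id: str
    cluster_order: int
    length: int
    censored: bool


@dataclass(frozen=True)
class RunLengthSample:
    """A group of run lengths ready for inference.

    ``group`` records the selector that produced the sample
    (``"front"``, ``"rear_pooled"`` or ``"order:k"``; free-form for
    hand-built samples).
    """

    group: str
    records: tuple[RunRecord, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyGroupError(f"group '{self.group}' contains no clusters")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=np.int64)

    @property
    def censored_mask(self) -> np.ndarray:
        return np.array([r.censored for r in self.records], dtype=bool)

    @property
    def M(self) -> int:
        """Number of observed clusters."""
        return len(self.records)

    @property
    def total(self) -> int:
        """Total number of cells across the clusters."""
        return int(self.lengths.sum())

    @property
    def mean(self) -> float:
        """Observed mean run length <n>_obs."""
        return self.total / self.M


def extract_runs(seq: BranchSequence) -> list[RunRecord]:
    """Segment one train into its ordered clusters.

    The concatenated lengths reconstruct the train; exactly the last
    record is censored.
    """
    labels = seq.labels
    if labels.size == 0:
        raise ValueError("cannot extract runs from an empty sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    n_runs = starts.size
    return [
        RunRecord(
            train_id=seq.train_id,
            cluster_order=k + 1,
            length=int(ends[k] - starts[k]),
            censored=(k == n_runs - 1),
        )
        for k in range(n_runs)
    ]


def _parse_selector(selector: str) -> tuple[str, int | None]:
    if selector in ("front", "rear_pooled"):
        return selector, None
    if selector.startswith("order:"):
        k = int(selector.split(":", 1)[1])
        if k < 1:
            raise ValueError("cluster order must be >= 1")
        return "order", k
    raise ValueError(
        f"unknown selector {selector!r}; use 'front', 'rear_pooled' or 'order:k'"
    )


def group_runs(
    trains: Iterable[BranchSequence],
    selector: str = "front",
    censoring_policy: str = "complete",
) -> RunLengthSample:
    """Extract and group clusters from a collection of trains.

    Parameters
    ----------
    selector : str
        ``"front"`` keeps order-1 clusters, ``"rear_pooled"`` pools all
        clusters of order >= 2, ``"order:k"`` keeps order-k clusters.
    censoring_policy : str
        ``"complete"`` (default) keeps censored final runs at their
        observed length; ``"drop_censored"`` removes them.

    Raises
    ------
    EmptyGroupError
        If the selector (after censoring) matches no clusters.
    """
    if censoring_policy not in ("complete", "drop_censored"):
        raise ValueError(
            f"censoring_policy must be 'complete' or 'drop_censored', "
            f"got {censoring_policy!r}"
        )
    kind, k = _parse_selector(selector)
    records: list[RunRecord] = []
    n_trains = 0
    for seq in trains:
        n_trains += 1
        for rec in extract_runs(seq):
            if kind == "front" and rec.cluster_order != 1:
                continue
            if kind == "rear_pooled" and rec.cluster_order < 2:
                continue
            if kind == "order" and rec.cluster_order != k:
                continue
            if censoring_policy == "drop_censored" and rec.censored:
                continue
            records.append(rec)
    if n_trains == 0:
        raise ValueError("no trains given")
    if not records:
        raise EmptyGroupError(
            f"selector '{selector}' with policy '{censoring_policy}' "
            f"matched no clusters in {n_trains} trains"
        )
    return RunLengthSample(group=selector, records=tuple(records))


def sample_from_lengths(
    lengths: Sequence[int],
    group: str = "manual",
    censored: Sequence[bool] | None = None,
) -> RunLengthSample:
    """Build a :class:`RunLengthSample` directly from run lengths."""
    lengths = list(lengths)
    if censored is None:
        censored = [False] * len(lengths)
    recs = tuple(
        RunRecord(train_id=group, cluster_order=i + 1, length=int(n), censored=bool(c))
        for i, (n, c) in enumerate(zip(lengths, censored, strict=True))
    )
    return RunLengthSample(group=group, records=recs)


@dataclass(frozen=True)
class SymmetryResult:
    """Front-cell branch-choice counts and exact binomial symmetry test."""

    counts: dict
    n_trains: int
    p_value: float


def front_choice_symmetry(trains: Iterable[BranchSequence]) -> SymmetryResult:
    """Test whether front cells choose the two branches equally often.

    Requires absolute branch orientation (``label_names``) on every
    train; the front cell's choice is the direct readout of geometric
    junction bias.  Returns per-branch counts and the exact two-sided
    binomial p-value against probability 0.5.
    """
    counts: dict[str, int] = {}
    n = 0
    k_first = 0
    names: tuple[str, str] | None = None
    for seq in trains:
        if seq.label_names is None:
            raise ValueError(
                f"train {seq.train_id!r} lacks absolute left/right orientation "
                "(label_names); the symmetry check needs absolute labels"
            )
        names = seq.label_names
        first = int(seq.labels[0])
        counts[names[first]] = counts.get(names[first], 0) + 1
        k_first += 1 - first  # count of the first-named branch
        n += 1
    if n == 0:
        raise ValueError("no trains given")
    for name in names or ():
        counts.setdefault(name, 0)
    pval = float(stats.binomtest(k_first, n, 0.5).pvalue)
    return SymmetryResult(counts=counts, n_trains=n, p_value=pval)
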