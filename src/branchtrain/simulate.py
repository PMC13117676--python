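"""Monte Carlo generation of branch-selection sequences.

Trains are simulated cell by cell: the front cell picks a branch uniformly
(the junction is symmetric), and each follower repeats its predecessor's
choice with probability ``P_jj = p + alpha``.  A nonstationary variant lets
the interaction depend on the cluster order of the predecessor, which is
what a decaying leader influence looks like in this assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .markov import TransitionModel, expected_same_side_probability

__all__ = [
    "BranchSequence",
    "SimulationEnsemble",
    "OccupancySummary",
    "simulate_train",
    "simulate_train_nonstationary",
    "simulate_ensemble",
    "occupancy_summary",
    "run_length_histogram_summary",
]


@dataclass(eq=False)
class BranchSequence:
    """Ordered branch labels of one train; index 0 is the front cell.

    Labels live on an abstract binary alphabet {0, 1}.  ``label_names``
    maps them back to the physical branch names (e.g. ``("L", "R")`` or
    ``("Up", "Down")``) when the absolute orientation is known; it is
    ``None`` for simulated trains, where only the same/opposite structure
    is meaningful.
    """

    train_id: str
    labels: np.ndarray
    label_names: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-d sequence")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be drawn from the binary alphabet {0, 1}")

    def __len__(self) -> int:
        return int(self.labels.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BranchSequence):
            return NotImplemented
        return self.train_id == other.train_id and np.array_equal(
            self.labels, other.labels
        )

    def relabelled(self) -> "BranchSequence":
        """The same train with the two branches globally swapped."""
        return BranchSequence(self.train_id, 1 - self.labels, self.label_names)


@dataclass
class SimulationEnsemble:
    """A reproducible collection of simulated trains."""

    trials: int
    n_cells: int
    p: float
    alpha_by_order: tuple[float, ...]
    seed: int
    sequences: list[BranchSequence] = field(repr=False)

    @property
    def alpha(self) -> float | None:
        """Stationary interaction parameter, or None if order-dependent."""
        vals = set(self.alpha_by_order)
        return self.alpha_by_order[0] if len(vals) == 1 else None


@dataclass(frozen=True)
class OccupancySummary:
    """Across-trial mean +/- SD of branch occupancy relative to the leader."""

    n_cells: int
    trials: int
    mean_same: float
    sd_same: float
    mean_opposite: float
    sd_opposite: float


def simulate_train_nonstationary(
    n_cells: int,
    p: float,
    alpha_by_order: Sequence[float],
    rng: np.random.Generator,
    train_id: str = "sim",
) -> BranchSequence:
    """Simulate one train whose interaction depends on cluster order.

    The transition into cell ``i`` uses the alpha of the cluster order of
    cell ``i - 1`` at generation time (the leader-follower interface sets
    the coupling).  The last alpha in the list is reused for deeper
    orders.  Every ``p + alpha_k`` must be a valid probability.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    alphas = tuple(float(a) for a in alpha_by_order)
    if not alphas:
        raise ValueError("alpha_by_order must be non-empty")
    for a in alphas:
        TransitionModel(p, a)  # validates p + a in [0, 1]

    labels = np.empty(n_cells, dtype=np.int8)
    labels[0] = rng.integers(2)
    order = 1  # cluster order of the most recent cell
    for i in range(1, n_cells):
        pjj = p + alphas[min(order, len(alphas)) - 1]
        same = rng.random() < pjj
        labels[i] = labels[i - 1] if same else 1 - labels[i - 1]
        if not same:
            order += 1
    return BranchSequence(train_id, labels)


def simulate_train(
    n_cells: int,
    model: TransitionModel,
    rng: np.random.Generator,
    train_id: str = "sim",
) -> BranchSequence:
    """Simulate one train under a stationary interaction parameter."""
    return simulate_train_nonstationary(
        n_cells, model.p, (model.alpha,), rng, train_id=train_id
    )


def simulate_ensemble(
    trials: int,
    n_cells: int,
    model: TransitionModel | None = None,
    seed: int = 0,
    *,
    p: float = 0.5,
    alpha_by_order: Sequence[float] | None = None,
) -> SimulationEnsemble:
    """Simulate ``trials`` independent trains of ``n_cells`` cells.

    Either a stationary :class:`TransitionModel` or an explicit
    ``(p, alpha_by_order)`` pair may be given.  A single random stream,
    seeded with ``seed``, is consumed train by train, so results are fully
    reproducible.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if model is not None:
        p, alphas = model.p, (model.alpha,)
    elif alpha_by_order is not None:
        alphas = tuple(float(a) for a in alpha_by_order)
    else:
        raise ValueError("provide either a TransitionModel or alpha_by_order")

    rng = np.random.default_rng(seed)
    width = len(str(trials))
    seqs = [
        simulate_train_nonstationary(
            n_cells, p, alphas, rng, train_id=f"train{t + 1:0{width}d}"
        )
        for t in range(trials)
    ]
    return SimulationEnsemble(trials, n_cells, p, alphas, seed, seqs)


def occupancy_summary(ensemble: SimulationEnsemble) -> OccupancySummary:
    """Per-trial counts of cells on the front cell's branch, mean +/- SD.

    The closed-form expectation of the per-cell same-side probability is
    :func:`branchtrain.markov.expected_same_side_probability`; this
    summary is its Monte Carlo counterpart and reproduces the marginal
    occupancy readout, which is deliberately insensitive to interaction
    at a symmetric junction.
    """
    if not ensemble.sequences:
        raise ValueError("ensemble contains no sequences")
    same = np.array(
        [int((s.labels == s.labels[0]).sum()) for s in ensemble.sequences],
        dtype=float,
    )
    opp = ensemble.n_cells - same
    ddof = 1 if same.size > 1 else 0
    sd_same = float(same.std(ddof=ddof)) if same.size > 1 else 0.0
    sd_opp = float(opp.std(ddof=ddof)) if opp.size > 1 else 0.0
    return OccupancySummary(
        n_cells=ensemble.n_cells,
        trials=ensemble.trials,
        mean_same=float(same.mean()),
        sd_same=sd_same,
        mean_opposite=float(opp.mean()),
        sd_opposite=sd_opp,
    )


def run_length_histogram_summary(
    ensemble: SimulationEnsemble,
) -> dict[int, tuple[float, float]]:
    """Across-trial mean +/- SD of the per-trial cluster-size histogram.

    Returns ``{size: (mean count per trial, sd)}`` for every size observed
    in the ensemble; the SD is the sample (n-1) standard deviation, 0 for
    a single trial.
    """
    from .runs import extract_runs

    if not ensemble.sequences:
        raise ValueError("ensemble contains no sequences")
    max_n = ensemble.n_cells
    counts = np.zeros((ensemble.trials, max_n + 1))
    for t, seq in enumerate(ensemble.sequences):
        for rec in extract_runs(seq):
            counts[t, rec.length] += 1
    out: dict[int, tuple[float, float]] = {}
    ddof = 1 if ensemble.trials > 1 else 0
    for size in range(1, max_n + 1):
        col = counts[:, size]
        if col.any():
            sd = float(col.std(ddof=ddof)) if ensemble.trials > 1 else 0.0
            out[size] = (float(col.mean()), sd)
    return out


def expected_occupancy(n_cells: int, pjj: float) -> float:
    """Closed-form expected number of cells on the front cell's branch."""
    return float(
        sum(expected_same_side_probability(pjj, i) for i in range(1, n_cells + 1))
    )
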