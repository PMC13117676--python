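"""Two-state first-order Markov model of branch selection at a symmetric junction.

A single-cell train migrating through a one-cell-wide channel meets a
T-junction; each follower either takes the branch of the cell ahead of it
(a "same-branch" event, probability ``P_jj = p + alpha``) or the opposite
branch.  ``p`` is the baseline same-branch probability absent any
interaction (0.5 at an ideal symmetric junction) and ``alpha`` is the
effective leader-follower interaction: positive values are attractive,
negative values repulsive.

Under this chain, run lengths (cluster sizes: maximal stretches of
consecutive same-branch choices) are geometrically distributed,

    P(n) = P_jj^(n-1) * (1 - P_jj),    <n> = 1 / (1 - P_jj),

which is what makes run-length statistics a direct readout of the
interaction.  This module holds the model itself, the geometric run-length
law (plain and finite-train truncated), the closed-form branch-occupancy
probability, and exact enumeration of the independence null for finite
trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ENUMERATION_LIMIT",
    "TransitionModel",
    "NullEnumeration",
    "same_branch_probability",
    "run_length_pmf",
    "truncated_run_length_pmf",
    "expected_run_length",
    "expected_same_side_probability",
    "enumerate_null",
]

#: Largest train length for which the null model is enumerated exactly
#: (2^(N-1) relative patterns).  Longer trains go through the simulator.
ENUMERATION_LIMIT = 24


@dataclass(frozen=True)
class TransitionModel:
    """Branch-selection transition model ``P_jj = p + alpha``.

    Parameters
    ----------
    p : float
        Baseline same-branch probability in [0, 1]; 0.5 for an ideal
        symmetric junction.
    alpha : float
        Effective interaction parameter.  Must satisfy
        ``-p <= alpha <= 1 - p`` so that ``P_jj`` is a probability.
        ``alpha = 0`` reduces the chain to independent Bernoulli branching.
    """

    p: float = 0.5
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"baseline probability p={self.p} not in [0, 1]")
        if not -self.p <= self.alpha <= 1.0 - self.p:
            raise ValueError(
                f"alpha={self.alpha} outside the admissible interval "
                f"[-p, 1-p] = [{-self.p}, {1.0 - self.p}] for p={self.p}"
            )

    @property
    def pjj(self) -> float:
        """Same-branch transition probability ``p + alpha``."""
        return self.p + self.alpha


def same_branch_probability(model: TransitionModel) -> float:
    """Same-branch transition probability ``P_jj = p + alpha`` of *model*."""
    return model.pjj


def _check_pjj(pjj: float, allow_one: bool = False) -> None:
    hi_ok = pjj <= 1.0 if allow_one else pjj < 1.0
    if not (0.0 <= pjj and hi_ok):
        bound = "1" if allow_one else "1 (exclusive: P_jj = 1 gives infinite runs)"
        raise ValueError(f"P_jj={pjj} must be in [0, {bound}]")


def run_length_pmf(pjj: float, n):
    """Geometric run-length probability ``P(n) = pjj^(n-1) (1 - pjj)``.

    *n* may be a positive integer or an integer array.
    """
    _check_pjj(pjj)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("run length n must be >= 1")
    out = pjj ** (n_arr - 1) * (1.0 - pjj)
    return out if out.ndim else float(out)


def truncated_run_length_pmf(pjj: float, n: int, cap: int):
    """Run-length pmf for a run that cannot exceed *cap* cells.

    The final possible size absorbs the whole geometric tail:
    ``P(n) = pjj^(n-1) (1-pjj)`` for ``n < cap`` and ``pjj^(cap-1)`` for
    ``n = cap``, so the masses over ``1..cap`` sum exactly to 1.  This is
    the front-cluster size law in a train of ``cap`` cells.
    """
    _check_pjj(pjj, allow_one=True)
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("run length n must be >= 1")
    if np.any(n_arr > cap):
        raise ValueError(f"run length n={n} exceeds cap={cap}")
    out = np.where(
        n_arr < cap,
        pjj ** (n_arr - 1.0) * (1.0 - pjj),
        pjj ** (cap - 1.0),
    )
    return out if out.ndim else float(out)


def expected_run_length(pjj: float) -> float:
    """Mean run length ``<n> = 1 / (1 - pjj)`` of the geometric law."""
    _check_pjj(pjj)
    return 1.0 / (1.0 - pjj)


def expected_same_side_probability(pjj: float, i: int) -> float:
    """Probability that cell *i* occupies the front cell's branch.

    The relative state (same side as the leader or not) is itself a
    two-state chain with flip probability ``1 - pjj``; after ``i - 1``
    steps the occupancy probability is ``(1 + (2 pjj - 1)^(i-1)) / 2``.
    Cell 1 is the front cell and defines the reference branch.
    """
    if i < 1:
        raise ValueError("cell order i must be >= 1")
    return 0.5 * (1.0 + (2.0 * pjj - 1.0) ** (i - 1))


@dataclass(frozen=True)
class NullEnumeration:
    """Exact finite-train cluster statistics under Bernoulli branching.

    Attributes
    ----------
    n_cells : int
        Train length N.
    p : float
        Same-branch probability used to weight patterns.
    front_pmf : dict
        ``{n: P(front cluster has size n)}``, support 1..N.
    pooled_pmf : dict
        ``{n: expected fraction of clusters of size n}`` — the expected
        count of size-n clusters divided by the expected total cluster
        count, matching how clusters are pooled across trains.
    expected_cluster_count : float
        Expected number of clusters in one train.
    """

    n_cells: int
    p: float
    front_pmf: dict = field(repr=False)
    pooled_pmf: dict = field(repr=False)
    expected_cluster_count: float


def enumerate_null(n_cells: int, p: float, _chunk: int = 1 << 22) -> NullEnumeration:
    """Exhaustively enumerate cluster statistics of an N-cell train.

    All ``2^(N-1)`` same/opposite patterns relative to the front cell are
    enumerated; each is weighted ``p^#same * (1-p)^#opposite``.  Returns
    the exact front-cluster pmf, the pooled run-length pmf and the
    expected cluster count.  ``n_cells`` must not exceed
    :data:`ENUMERATION_LIMIT`; use the simulator for longer trains.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells > ENUMERATION_LIMIT:
        raise ValueError(
            f"n_cells={n_cells} exceeds the exact-enumeration limit "
            f"{ENUMERATION_LIMIT}; use the Monte Carlo simulator instead"
        )
    n = n_cells
    if n == 1:
        return NullEnumeration(1, p, {1: 1.0}, {1: 1.0}, 1.0)

    m = n - 1  # number of same/opposite transition bits
    total_patterns = 1 << m
    front = np.zeros(n + 1)
    size_counts = np.zeros(n + 1)  # weighted expected count of clusters per size

    for start in range(0, total_patterns, _chunk):
        ints = np.arange(start, min(start + _chunk, total_patterns), dtype=np.int64)
        # bits[:, j] == 1  <=>  cell j+2 chose the same branch as cell j+1
        bits = ((ints[:, None] >> np.arange(m)) & 1).astype(np.int8)
        nsame = bits.sum(axis=1, dtype=np.int64)
        w = p ** nsame.astype(float) * (1.0 - p) ** (m - nsame).astype(float)
        # prefix sums of same-bits for O(1) window checks
        cs = np.zeros((len(ints), m + 1), dtype=np.int32)
        np.cumsum(bits, axis=1, out=cs[:, 1:])
        for i in range(n):  # 0-based cell index where a cluster may start
            if i == 0:
                starts = np.ones(len(ints), dtype=bool)
            else:
                starts = bits[:, i - 1] == 0
            for size in range(1, n - i + 1):
                # transitions within the cluster are bits[i .. i+size-2]
                inside = (cs[:, i + size - 1] - cs[:, i]) == (size - 1)
                if i + size < n:
                    ends = bits[:, i + size - 1] == 0
                else:
                    ends = True
                mask = starts & inside & ends
                mass = float(w[mask].sum())
                size_counts[size] += mass
                if i == 0:
                    front[size] += mass

    expected_clusters = float(size_counts.sum())
    front_pmf = {k: float(front[k]) for k in range(1, n + 1)}
    pooled_pmf = {k: float(size_counts[k] / expected_clusters) for k in range(1, n + 1)}
    return NullEnumeration(n, p, front_pmf, pooled_pmf, expected_clusters)
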