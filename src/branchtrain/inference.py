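"""Interaction-parameter inference from run-length samples.

The observable is a sample of cluster sizes ``{n_1, ..., n_M}``.  Under
the first-order Markov branch-selection model these are geometric with
parameter ``P_jj = p + alpha``, so

    P_jj_hat = 1 - 1 / <n>_obs          (mean-based)
    P_jj_hat = sum(n_i - 1) / sum(n_i)  (maximum likelihood)

are two algebraically identical point estimators of the same-branch
probability, and ``alpha_hat = P_jj_hat - p``.  Uncertainty comes from a
nonparametric bootstrap over clusters (percentile intervals); deviation
from the independence null ``alpha = 0`` is tested with a
parametric-bootstrap likelihood-ratio test whose null replicates are
geometric samples with the observed number of clusters.

The statsmodels-style entry point is :class:`GeometricRunModel`, whose
``fit()`` returns a :class:`GeometricRunResults`; thin functional
wrappers are provided for one-off calculations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .runs import RunLengthSample, group_runs, sample_from_lengths
from .simulate import BranchSequence

__all__ = [
    "EstimateResult",
    "LRTResult",
    "GeometricRunModel",
    "GeometricRunResults",
    "alpha_from_mean",
    "estimate_alpha_mean",
    "estimate_alpha_mle",
    "log_likelihood",
    "bootstrap_estimate",
    "lrt_parametric_bootstrap",
]


def _check_p(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"baseline probability p={p} not in [0, 1]")


def alpha_from_mean(mean_run_length: float, p: float = 0.5) -> float:
    """Interaction estimate from a mean run length: ``1 - 1/<n> - p``.

    At a symmetric junction (p = 0.5) this is ``1/2 - 1/<n>_obs``.
    """
    _check_p(p)
    if mean_run_length < 1.0:
        raise ValueError("mean run length cannot be below 1")
    return 1.0 - 1.0 / mean_run_length - p


@dataclass(frozen=True)
class EstimateResult:
    """Point estimate of the interaction parameter for one group.

    ``se``, ``ci_low``, ``ci_high`` are populated by the bootstrap and
    are ``None`` for a bare point estimate.
    """

    group: str
    M: int
    mean_run_length: float
    pjj_hat: float
    alpha_hat: float
    p: float
    estimator: str
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    level: float | None = None
    B: int | None = None
    seed: int | None = None
    censoring: str = "complete"


@dataclass(frozen=True)
class LRTResult:
    """Parametric-bootstrap likelihood-ratio test against independence."""

    lambda_obs: float
    B: int
    p_value: float
    null_pjj: float
    seed: int | None
    replicates: np.ndarray = field(repr=False)


def _point_estimate(sample: RunLengthSample, p: float, estimator: str) -> EstimateResult:
    _check_p(p)
    lengths = sample.lengths
    if estimator == "mean":
        pjj_hat = 1.0 - 1.0 / sample.mean
    elif estimator == "mle":
        pjj_hat = float((lengths - 1).sum() / lengths.sum())
    else:
        raise ValueError(f"estimator must be 'mean' or 'mle', got {estimator!r}")
    return EstimateResult(
        group=sample.group,
        M=sample.M,
        mean_run_length=sample.mean,
        pjj_hat=pjj_hat,
        alpha_hat=pjj_hat - p,
        p=p,
        estimator=estimator,
    )


def estimate_alpha_mean(sample: RunLengthSample, p: float = 0.5) -> EstimateResult:
    """Mean-based point estimate ``alpha_hat = 1 - 1/<n>_obs - p``."""
    return _point_estimate(sample, p, "mean")


def estimate_alpha_mle(sample: RunLengthSample, p: float = 0.5) -> EstimateResult:
    """Maximum-likelihood point estimate ``P_jj_hat = sum(n_i-1)/sum(n_i)``."""
    return _point_estimate(sample, p, "mle")


def log_likelihood(
    sample: RunLengthSample | Sequence[int],
    pjj: float,
    censored: Sequence[bool] | None = None,
) -> float:
    """Geometric log-likelihood of a run-length sample at ``pjj``.

    ``sum_i [(n_i - 1) log pjj + log(1 - pjj)]`` with the convention
    ``0 * log 0 = 0``, so ``pjj = 0`` is admissible iff every run has
    length 1 (and returns -inf otherwise, not an exception).

    If a ``censored`` mask is given, censored runs contribute only the
    survival factor ``pjj^(n-1)`` (their termination was not observed);
    the default treats every run as completely observed.
    """
    if isinstance(sample, RunLengthSample):
        lengths = sample.lengths
    else:
        lengths = np.asarray(sample, dtype=np.int64)
    if np.any(lengths < 1):
        raise ValueError("run lengths must be >= 1")
    if not 0.0 <= pjj < 1.0:
        raise ValueError(f"pjj={pjj} must be in [0, 1)")
    if censored is None:
        n_complete = lengths.size
    else:
        cens = np.asarray(censored, dtype=bool)
        if cens.shape != lengths.shape:
            raise ValueError("censored mask must match the sample length")
        n_complete = int((~cens).sum())
    excess = int((lengths - 1).sum())
    if pjj == 0.0:
        return 0.0 if excess == 0 else -math.inf
    return excess * math.log(pjj) + n_complete * math.log1p(-pjj)


def _alpha_from_sums(totals, M, p):
    """Vectorised mean/MLE estimate from resampled totals."""
    return 1.0 - M / np.asarray(totals, dtype=float) - p


def bootstrap_estimate(
    sample: RunLengthSample,
    p: float = 0.5,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    estimator: str = "mean",
) -> EstimateResult:
    """Nonparametric bootstrap SE and percentile CI for ``alpha_hat``.

    The M observed cluster sizes are resampled with replacement B times
    and the estimator recomputed per resample; ``se`` is the SD of the
    replicates and the CI the percentile interval.  Because the estimator
    lives in ``[-p, 1-p)``, percentile limits saturate at exactly ``-p``
    for samples dominated by singleton runs.
    """
    if sample.M < 2:
        raise ValueError("bootstrap needs at least 2 clusters (M >= 2)")
    if not 0.0 < level < 1.0:
        raise ValueError("CI level must be in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    point = _point_estimate(sample, p, estimator)
    rng = np.random.default_rng(seed)
    lengths = sample.lengths
    idx = rng.integers(0, sample.M, size=(B, sample.M))
    totals = lengths[idx].sum(axis=1)
    alphas = _alpha_from_sums(totals, sample.M, p)
    lo, hi = np.quantile(alphas, [(1 - level) / 2, (1 + level) / 2])
    return replace(
        point,
        se=float(alphas.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        B=B,
        seed=seed,
    )


def _lambda_stat(totals, M: int, null_pjj: float) -> np.ndarray:
    """Deviance 2*[logL(pjj_hat) - logL(null)] as a function of sum(n_i).

    The geometric log-likelihood depends on the data only through
    ``S = sum(n_i)``; at the MLE ``pjj_hat = 1 - M/S``.
    """
    S = np.asarray(totals, dtype=float)
    M_f = float(M)
    excess = S - M_f
    with np.errstate(divide="ignore", invalid="ignore"):
        qhat = np.where(S > M_f, 1.0 - M_f / S, 0.0)
        l_hat = np.where(excess > 0, excess * np.log(qhat), 0.0) + M_f * np.log1p(-qhat)
    l_null = excess * math.log(null_pjj) + M_f * math.log1p(-null_pjj)
    return np.maximum(0.0, 2.0 * (l_hat - l_null))


def lrt_parametric_bootstrap(
    sample: RunLengthSample,
    p: float = 0.5,
    B: int = 9_999,
    seed: int | None = None,
) -> LRTResult:
    """Likelihood-ratio test of ``alpha = 0`` with a simulated null.

    ``Lambda_obs = 2 [log L(P_jj_hat) - log L(p)]`` (floored at 0) is
    compared against B replicate statistics, each computed from M runs
    drawn from the null geometric law with ``P_jj = p``.  The p-value
    uses the add-one convention ``(1 + #{Lambda_b >= Lambda_obs})/(B+1)``
    so it can never be exactly zero; its resolution floor is 1/(B+1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("null baseline p must lie strictly between 0 and 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    M = sample.M
    lam_obs = float(_lambda_stat(sample.total, M, p))
    rng = np.random.default_rng(seed)
    null_totals = rng.geometric(1.0 - p, size=(B, M)).sum(axis=1)
    lam_null = _lambda_stat(null_totals, M, p)
    p_value = (1.0 + int((lam_null >= lam_obs).sum())) / (B + 1.0)
    return LRTResult(
        lambda_obs=lam_obs,
        B=B,
        p_value=p_value,
        null_pjj=p,
        seed=seed,
        replicates=lam_null,
    )


class GeometricRunModel:
    """Geometric run-length model for one group of clusters.

    Parameters
    ----------
    sample : RunLengthSample
        The observed cluster sizes (see :func:`branchtrain.runs.group_runs`).
    p : float
        Baseline same-branch probability; 0.5 for a symmetric junction.

    Examples
    --------
    >>> from branchtrain import GeometricRunModel
    >>> model = GeometricRunModel.from_lengths([1, 1, 2, 1, 3])
    >>> res = model.fit(bootstrap=1000, seed=0)
    >>> round(res.alpha_hat, 3)
    -0.125
    """

    def __init__(self, sample: RunLengthSample, p: float = 0.5):
        _check_p(p)
        self.sample = sample
        self.p = p

    @classmethod
    def from_sequences(
        cls,
        trains: Iterable[BranchSequence],
        group: str = "front",
        censoring_policy: str = "complete",
        p: float = 0.5,
    ) -> "GeometricRunModel":
        """Build the model from branch-label sequences via run extraction."""
        return cls(group_runs(trains, group, censoring_policy), p=p)

    @classmethod
    def from_lengths(
        cls, lengths: Sequence[int], p: float = 0.5, group: str = "manual"
    ) -> "GeometricRunModel":
        """Build the model from raw cluster sizes."""
        return cls(sample_from_lengths(lengths, group=group), p=p)

    def loglike(self, pjj: float) -> float:
        """Geometric log-likelihood of the sample at ``pjj``."""
        return log_likelihood(self.sample, pjj)

    def fit(
        self,
        estimator: str = "mean",
        bootstrap: int = 10_000,
        ci_level: float = 0.95,
        seed: int | None = None,
    ) -> "GeometricRunResults":
        """Estimate alpha; ``bootstrap=0`` skips the uncertainty step."""
        if bootstrap:
            est = bootstrap_estimate(
                self.sample, self.p, B=bootstrap, level=ci_level,
                seed=seed, estimator=estimator,
            )
        else:
            est = _point_estimate(self.sample, self.p, estimator)
        return GeometricRunResults(self, est)


class GeometricRunResults:
    """Fitted interaction estimate with uncertainty and diagnostics."""

    def __init__(self, model: GeometricRunModel, estimate: EstimateResult):
        self.model = model
        self.estimate = estimate

    # convenience pass-throughs
    @property
    def alpha_hat(self) -> float:
        return self.estimate.alpha_hat

    @property
    def pjj_hat(self) -> float:
        return self.estimate.pjj_hat

    @property
    def mean_run_length(self) -> float:
        return self.estimate.mean_run_length

    @property
    def M(self) -> int:
        return self.estimate.M

    @property
    def se(self) -> float | None:
        return self.estimate.se

    def conf_int(self) -> tuple[float, float]:
        if self.estimate.ci_low is None:
            raise ValueError("no bootstrap was run; refit with bootstrap > 0")
        return (self.estimate.ci_low, self.estimate.ci_high)

    def lrt(self, B: int = 9_999, seed: int | None = None) -> LRTResult:
        """Parametric-bootstrap LRT of independence (alpha = 0)."""
        return lrt_parametric_bootstrap(self.model.sample, self.model.p, B=B, seed=seed)

    def summary(self) -> str:
        """Plain-text summary table (values rounded to 3 decimals)."""
        e = self.estimate
        lines = [
            "Geometric run-length model",
            "=" * 44,
            f"{'Group':<22}{e.group}",
            f"{'Clusters (M)':<22}{e.M}",
            f"{'Mean cluster size':<22}{e.mean_run_length:.3f}",
            f"{'P_jj (baseline p)':<22}{e.pjj_hat:.3f} ({e.p:g})",
            f"{'alpha':<22}{e.alpha_hat:+.3f}",
        ]
        if e.se is not None:
            lines.append(f"{'SE (bootstrap)':<22}{e.se:.3f}")
            lines.append(
                f"{int(round((e.level or 0) * 100))}% CI"
                f"{'':<15}[{e.ci_low:+.3f}, {e.ci_high:+.3f}]"
            )
            lines.append(f"{'Bootstrap B / seed':<22}{e.B} / {e.seed}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed cluster-size histogram against the fitted geometric law."""
        import matplotlib.pyplot as plt

        from .markov import run_length_pmf

        if ax is None:
            _, ax = plt.subplots()
        lengths = self.model.sample.lengths
        sizes = np.arange(1, lengths.max() + 1)
        obs = np.bincount(lengths, minlength=lengths.max() + 1)[1:] / lengths.size
        ax.bar(sizes, obs, width=0.8, alpha=0.6, label="observed")
        if self.pjj_hat < 1.0:
            ax.plot(
                sizes,
                run_length_pmf(self.pjj_hat, sizes),
                "o-",
                color="k",
                label=f"geometric fit (P_jj={self.pjj_hat:.2f})",
            )
        ax.set_xlabel("cluster size n")
        ax.set_ylabel("fraction of clusters")
        ax.legend()
        return ax
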