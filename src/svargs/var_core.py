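"""Core data model for multichannel time series and sparse VAR processes.

A VAR(p) process on k channels is

    Y_t = A_1 Y_{t-1} + ... + A_p Y_{t-p} + eps_t,   Cov(eps_t) = Sigma,

with sparse coefficient matrices ``A_l``.  This module holds the containers
(:class:`TimeSeries`, :class:`BlockPartition`, :class:`Support`,
:class:`SparseVARModel`), ordinary least-squares fitting on a fixed support,
companion-matrix stability checks, a random sparse *stable* model generator
and a seeded simulator.  Everything downstream (the greedy search, Granger
causality, the benchmark harness) is built on these primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "RankDeficiencyError",
    "TimeSeries",
    "BlockPartition",
    "Support",
    "SparseVARModel",
    "demean",
    "lagged_design",
    "ols_fit",
    "companion_matrix",
    "spectral_radius",
    "is_stable",
    "random_sparse_stable_var",
    "rescale_to_radius",
    "refit_model",
    "simulate",
]


class RankDeficiencyError(ValueError):
    """Raised when a regression design is (numerically) rank deficient."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeries:
    """Multichannel, possibly multi-trial, evenly sampled data.

    Parameters
    ----------
    trials:
        One ``(k, N_t)`` float array per trial (channels x time).  All trials
        must share the channel count ``k``; trial lengths may differ.
    channel_labels:
        Optional channel names; defaults to ``ch1..chk``.
    sampling_rate:
        Sampling frequency in Hz (default 1.0).
    """

    trials: tuple[np.ndarray, ...]
    channel_labels: tuple[str, ...] = ()
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        trials = tuple(np.asarray(t, dtype=float) for t in self.trials)
        if not trials:
            raise ValueError("TimeSeries needs at least one trial")
        k = trials[0].shape[0]
        for t in trials:
            if t.ndim != 2 or t.shape[0] != k:
                raise ValueError("all trials must be 2-D with a common channel count")
            if t.shape[1] < 1:
                raise ValueError("each trial needs at least one time point")
            if not np.all(np.isfinite(t)):
                raise ValueError("time series values must be finite")
        labels = self.channel_labels or tuple(f"ch{i + 1}" for i in range(k))
        if len(labels) != k:
            raise ValueError("channel_labels length must equal channel count")
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "channel_labels", tuple(str(x) for x in labels))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def k(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(t.shape[1] for t in self.trials)

    @classmethod
    def from_array(cls, values: np.ndarray, sampling_rate: float = 1.0,
                   channel_labels: Sequence[str] = ()) -> "TimeSeries":
        """Wrap a single ``(k, N)`` array as a one-trial series."""
        return cls((np.asarray(values, float),), tuple(channel_labels), sampling_rate)


def demean(ts: TimeSeries) -> TimeSeries:
    """Remove each channel's mean, independently per trial.

    The VAR model assumes a zero-mean process; any systematic offset is
    removed here before fitting.
    """
    trials = tuple(t - t.mean(axis=1, keepdims=True) for t in ts.trials)
    return TimeSeries(trials, ts.channel_labels, ts.sampling_rate)


@dataclass(frozen=True)
class BlockPartition:
    """Disjoint blocks ``K_1..K_J`` covering channel indices ``0..k-1``."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        blocks = tuple(tuple(int(i) for i in b) for b in self.blocks)
        if not blocks or any(len(b) == 0 for b in blocks):
            raise ValueError("partition blocks must be non-empty")
        flat = [i for b in blocks for i in b]
        if len(set(flat)) != len(flat):
            raise ValueError("partition blocks must be disjoint")
        if set(flat) != set(range(len(flat))):
            raise ValueError("partition blocks must cover 0..k-1 exactly")
        object.__setattr__(self, "blocks", blocks)

    @classmethod
    def atomic(cls, k: int) -> "BlockPartition":
        return cls(tuple((i,) for i in range(k)))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def k(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass(frozen=True)
class Support:
    """Set of (target_block, source_block, lag) triples defining a sparsity
    pattern over a :class:`BlockPartition` and a lag set."""

    entries: frozenset[tuple[int, int, int]]
    partition: BlockPartition
    lags: tuple[int, ...]

    def __post_init__(self) -> None:
        lags = tuple(sorted(int(l) for l in self.lags))
        if any(l <= 0 for l in lags):
            raise ValueError("lags must be positive")
        J = self.partition.n_blocks
        for (tb, sb, lag) in self.entries:
            if not (0 <= tb < J and 0 <= sb < J):
                raise ValueError(f"block index out of range in entry {(tb, sb, lag)}")
            if lag not in lags:
                raise ValueError(f"lag {lag} not in lag set {lags}")
        object.__setattr__(self, "entries", frozenset(self.entries))
        object.__setattr__(self, "lags", lags)

    def regressors_for(self, target_block: int) -> tuple[tuple[int, int], ...]:
        """Sorted ``(lag, source_block)`` regressor list for one target block."""
        regs = [(lag, sb) for (tb, sb, lag) in self.entries if tb == target_block]
        return tuple(sorted(regs))


@dataclass
class SparseVARModel:
    """Sparse VAR model: lag-indexed k x k coefficient matrices plus the
    residual covariance ``sigma``."""

    k: int
    lags: tuple[int, ...]
    coeffs: dict[int, sp.csr_matrix]
    sigma: np.ndarray
    partition: BlockPartition | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.lags = tuple(sorted(int(l) for l in self.lags))
        if any(l <= 0 for l in self.lags):
            raise ValueError("lags must be positive")
        coeffs: dict[int, sp.csr_matrix] = {}
        for lag, A in self.coeffs.items():
            A = sp.csr_matrix(A, shape=(self.k, self.k), dtype=float)
            A.eliminate_zeros()
            if not np.all(np.isfinite(A.data)):
                raise ValueError("coefficients must be finite")
            if A.nnz:
                coeffs[int(lag)] = A
        self.coeffs = coeffs
        if any(lag not in self.lags for lag in coeffs):
            raise ValueError("coefficient lag outside the model lag set")
        sigma = np.asarray(self.sigma, float)
        if sigma.shape != (self.k, self.k):
            raise ValueError("sigma must be k x k")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric (1e-10)")
        self.sigma = 0.5 * (sigma + sigma.T)
        if self.partition is None:
            self.partition = BlockPartition.atomic(self.k)
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i + 1}" for i in range(self.k))

    @property
    def order(self) -> int:
        return max(self.lags) if self.lags else 0

    def coeff_dense(self, lag: int) -> np.ndarray:
        A = self.coeffs.get(lag)
        return A.toarray() if A is not None else np.zeros((self.k, self.k))

    def support_triples(self) -> set[tuple[int, int, int]]:
        """Atomic nonzero positions as ``(row, col, lag)`` triples."""
        out: set[tuple[int, int, int]] = set()
        for lag, A in self.coeffs.items():
            coo = A.tocoo()
            out.update(zip(coo.row.tolist(), coo.col.tolist(), [lag] * coo.nnz))
        return out

    def equation_support(self) -> dict[int, list[tuple[int, int]]]:
        """Per-equation regressors: row -> sorted list of ``(lag, col)``."""
        eq: dict[int, list[tuple[int, int]]] = {i: [] for i in range(self.k)}
        for (r, c, lag) in self.support_triples():
            eq[r].append((lag, c))
        return {i: sorted(v) for i, v in eq.items()}

    @property
    def nnz(self) -> int:
        return sum(A.nnz for A in self.coeffs.values())


# ---------------------------------------------------------------------------
# regression primitives
# ---------------------------------------------------------------------------


def lagged_design(ts: TimeSeries, lags: Sequence[int], targets: Sequence[int],
                  regressors: Sequence[tuple[int, int]] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stack the VAR regression rows across trials.

    Rows are time points ``t = p_max .. N_t - 1`` of each trial (0-based), so
    no row mixes samples from two trials.  Regressor columns are ordered
    lag-major then channel (``(l_1, ch_0), (l_1, ch_1), ... (l_2, ch_0) ...``)
    unless an explicit ``regressors`` list of ``(lag, channel)`` pairs is
    given.  Responses are the ``targets`` channels at time ``t``.
    """
    lags = sorted(int(l) for l in lags)
    if not lags or lags[0] <= 0:
        raise ValueError("lags must be positive integers")
    p = lags[-1]
    if p >= min(ts.lengths):
        raise ValueError(
            f"maximum lag {p} must be smaller than the shortest trial "
            f"length {min(ts.lengths)}")
    if regressors is None:
        regressors = [(l, c) for l in lags for c in range(ts.k)]
    X_parts, Y_parts = [], []
    targets = list(targets)
    for trial in ts.trials:
        n_t = trial.shape[1] - p
        X = np.empty((n_t, len(regressors)))
        for j, (lag, ch) in enumerate(regressors):
            X[:, j] = trial[ch, p - lag:trial.shape[1] - lag]
        X_parts.append(X)
        Y_parts.append(trial[targets, p:].T)
    return np.vstack(X_parts), np.vstack(Y_parts)


def _solve_normal_equations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cholesky solve of ``X'X b = X'Y`` with a relative rank check."""
    G = X.T @ X
    d = np.sqrt(np.maximum(np.diag(G), 0.0))
    if np.any(d <= 0):
        raise RankDeficiencyError("design contains a zero column")
    scale = np.outer(d, d)
    try:
        c, low = scipy.linalg.cho_factor(G / scale, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise RankDeficiencyError("design is rank deficient") from exc
    except scipy.linalg.LinAlgError as exc:
        raise RankDeficiencyError("design is rank deficient") from exc
    if np.min(np.diag(c)) < 1e-7:
        raise RankDeficiencyError("design is numerically rank deficient")
    b = scipy.linalg.cho_solve((c, low), (X.T @ Y) / d[:, None])
    return b / d[:, None]


def ols_fit(ts: TimeSeries, support: Support, target_block: int,
            ) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS fit of one target block's equations on a fixed support.

    Returns ``(coefficients, residual_covariance, n_obs)``.  The coefficient
    matrix is ``a x m`` where ``a`` is the target block size and ``m`` the
    stacked regressor column count (support regressors sorted by
    ``(lag, source_block)``, channels of each source block in order).  The
    residual covariance uses the maximum-likelihood denominator ``n_obs``.
    An empty support returns the sample covariance of the responses.
    """
    part = support.partition
    targets = list(part.blocks[target_block])
    regs = support.regressors_for(target_block)
    cols = [(lag, ch) for (lag, sb) in regs for ch in part.blocks[sb]]
    X, Y = lagged_design(ts, support.lags, targets, regressors=cols or None)
    if not cols:
        X = X[:, :0]
    n_obs = Y.shape[0]
    if cols:
        if X.shape[0] <= X.shape[1]:
            raise RankDeficiencyError(
                "design must have more rows than columns "
                f"({X.shape[0]} rows, {X.shape[1]} columns)")
        B = _solve_normal_equations(X, Y)
        resid = Y - X @ B
        coeffs = B.T
    else:
        resid = Y
        coeffs = np.zeros((len(targets), 0))
    sigma = resid.T @ resid / n_obs
    return coeffs, sigma, n_obs


def refit_model(ts: TimeSeries, support_triples: Iterable[tuple[int, int, int]],
                lags: Sequence[int], sampling_rate: float | None = None,
                ) -> SparseVARModel:
    """OLS-refit a full k-channel model on an atomic ``(row, col, lag)``
    support, with the residual covariance taken across all equations."""
    ts = demean(ts)
    k = ts.k
    lags = sorted(set(int(l) for l in lags))
    eq: dict[int, list[tuple[int, int]]] = {i: [] for i in range(k)}
    for (r, c, lag) in support_triples:
        eq[int(r)].append((int(lag), int(c)))
    X, Y = lagged_design(ts, lags, list(range(k)))
    n = Y.shape[0]
    col_of = {(lag, c): j * k + c for j, lag in enumerate(lags) for c in range(k)}
    B = np.zeros((X.shape[1], k))
    for i in range(k):
        cols = [col_of[rc] for rc in sorted(eq[i])]
        if not cols:
            continue
        Xi = X[:, cols]
        if Xi.shape[0] <= Xi.shape[1]:
            raise RankDeficiencyError("too few rows for the requested support")
        B[cols, i] = _solve_normal_equations(Xi, Y[:, i:i + 1])[:, 0]
    resid = Y - X @ B
    sigma = resid.T @ resid / n
    coeffs = {}
    for j, lag in enumerate(lags):
        A = B[j * k:(j + 1) * k, :].T  # rows = equations, cols = channels
        if np.any(A):
            coeffs[lag] = sp.csr_matrix(A)
    return SparseVARModel(k=k, lags=tuple(lags), coeffs=coeffs, sigma=sigma,
                          channel_labels=ts.channel_labels)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------


def companion_matrix(model: SparseVARModel) -> np.ndarray:
    """First-order (k*p) x (k*p) embedding of the VAR(p)."""
    k, p = model.k, model.order
    if p == 0:
        return np.zeros((0, 0))
    F = np.zeros((k * p, k * p))
    for lag in model.lags:
        F[:k, (lag - 1) * k:lag * k] = model.coeff_dense(lag)
    if p > 1:
        F[k:, :-k] = np.eye(k * (p - 1))
    return F


def spectral_radius(model: SparseVARModel) -> float:
    F = companion_matrix(model)
    if F.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(F))))


def is_stable(model: SparseVARModel) -> bool:
    return spectral_radius(model) < 1.0


def rescale_to_radius(model: SparseVARModel, target: float) -> SparseVARModel:
    """Scale lag-l coefficients by ``(target/radius)**l``, which moves every
    companion eigenvalue by exactly the factor ``target/radius`` while
    preserving the sparsity pattern."""
    r = spectral_radius(model)
    if r == 0:
        return model
    c = target / r
    coeffs = {lag: model.coeffs[lag] * (c ** lag) for lag in model.coeffs}
    return SparseVARModel(k=model.k, lags=model.lags, coeffs=coeffs,
                          sigma=model.sigma, partition=model.partition,
                          channel_labels=model.channel_labels)


# ---------------------------------------------------------------------------
# random models and simulation
# ---------------------------------------------------------------------------


def _default_coef_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    """Magnitudes uniform on [0.1, 1] with random signs."""
    return rng.uniform(0.1, 1.0, size) * rng.choice([-1.0, 1.0], size)


def random_sparse_stable_var(
    k: int,
    order_range: tuple[int, int] = (5, 8),
    density: float = 0.02,
    coef_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    sigma: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    radius_cap: float = 0.95,
    max_rescale: int = 50,
) -> SparseVARModel:
    """Draw a random sparse stable VAR model.

    The order is uniform on ``order_range`` (inclusive) and exactly
    ``round(density * k**2 * p)`` coefficients are placed at uniformly random
    (lag, row, col) slots.  If the companion spectral radius is >=
    ``radius_cap`` all lag-l coefficients are rescaled by
    ``(radius_cap / radius)**l`` and the radius re-checked (at most
    ``max_rescale`` times); the geometric scaling respects the companion
    structure, so one pass normally lands exactly on the cap.
    """
    rng = np.random.default_rng(seed)
    p = int(rng.integers(order_range[0], order_range[1] + 1))
    n_slots = k * k * p
    nnz = int(round(density * n_slots))
    if nnz > n_slots:
        raise ValueError("density too high: more nonzeros than slots")
    if nnz < 1:
        raise ValueError("density too low: no nonzero coefficients")
    slots = rng.choice(n_slots, size=nnz, replace=False)
    sampler = coef_sampler or _default_coef_sampler
    values = np.asarray(sampler(rng, nnz), float)
    lag_idx, rc = np.divmod(slots, k * k)
    rows, cols = np.divmod(rc, k)
    sig = np.eye(k) if sigma is None else np.asarray(sigma, float)
    coeffs: dict[int, sp.csr_matrix] = {}
    for l in range(p):
        m = lag_idx == l
        if np.any(m):
            coeffs[l + 1] = sp.csr_matrix(
                (values[m], (rows[m], cols[m])), shape=(k, k))
    model = SparseVARModel(k=k, lags=tuple(range(1, p + 1)), coeffs=coeffs,
                           sigma=sig)
    for _ in range(max_rescale):
        r = spectral_radius(model)
        if r < radius_cap or r == 0:
            break
        model = rescale_to_radius(model, radius_cap * (1 - 1e-12))
    return model


def simulate(model: SparseVARModel, n_points: int, n_trials: int = 1,
             seed: int | np.random.Generator | None = None,
             burn_in: int | None = None,
             sampling_rate: float = 1.0) -> TimeSeries:
    """Simulate Gaussian-innovation trials from a stable model.

    ``burn_in`` initial samples (default ``10 * order``) are discarded per
    trial so the retained samples are approximately stationary.
    """
    if not is_stable(model):
        raise ValueError("model is unstable; refusing to simulate")
    rng = np.random.default_rng(seed)
    k, p = model.k, model.order
    if burn_in is None:
        burn_in = 10 * p
    A = [(lag, model.coeff_dense(lag)) for lag in model.lags]
    # PSD square root of sigma (allows the degenerate zero-noise case)
    w, V = np.linalg.eigh(model.sigma)
    if np.min(w) < -1e-10 * max(1.0, np.max(np.abs(w))):
        raise ValueError("sigma must be positive semi-definite")
    L = V * np.sqrt(np.clip(w, 0, None))
    trials = []
    for _ in range(n_trials):
        total = n_points + burn_in
        eps = rng.standard_normal((total, k)) @ L.T
        Y = np.zeros((total + p, k))
        for t in range(p, total + p):
            acc = eps[t - p]
            for lag, Al in A:
                acc = acc + Al @ Y[t - lag]
            Y[t] = acc
        trials.append(Y[p + burn_in:].T.copy())
    return TimeSeries(tuple(trials), sampling_rate=sampling_rate)
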