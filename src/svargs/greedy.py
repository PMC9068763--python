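"""Greedy sparse VAR search (SVARGS).

For each target block of variables the search starts from the trivial model
``r_t = eps_t`` and alternates

* an *entry* scan over every (source block, lag) regressor block not in the
  model: the block with the largest residual-covariance determinant ratio
  ``det(Sigma) / det(Sigma+)`` enters if the ratio is > 1 and its p-value is
  <= ``p_entry``;
* an *exit* scan over every regressor block in the model: the block with the
  smallest ratio ``det(Sigma-) / det(Sigma)`` leaves if its p-value is
  > ``p_exit = exit_ratio * p_entry``.

When a full entry+exit pass changes nothing, ``p_entry`` is escalated by a
small multiplicative factor, until it reaches ``p_max``.  Every support
change is recorded together with an extended-SBC score (a BIC with an extra
EBIC-style penalty ``2 * gamma * d * ln(q)`` over the candidate pool of
``q`` scalar slots), and the minimum-score model along the whole trajectory
is returned after a final OLS refit.

For atomic blocks the determinant-ratio test is the exact F-test of adding
one regressor; for larger blocks a Wilks-type chi-square approximation on
``n * ln(ratio)`` with ``a * b`` degrees of freedom is used.

All scans run on precomputed Gram matrices (Schur-complement updates of the
normal equations), so a scan costs O(m * q) instead of q full refits; the
refit path is retained (``use_fast=False``) and the two are equal to
rounding error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy import stats

from .var_core import (
    BlockPartition,
    RankDeficiencyError,
    SparseVARModel,
    Support,
    TimeSeries,
    demean,
    lagged_design,
    ols_fit,
)

__all__ = [
    "FitConfig",
    "Candidate",
    "TraceRecord",
    "FitTrace",
    "det_ratio",
    "gc_stat_pvalue",
    "entry_scan",
    "exit_scan",
    "extended_sbc",
    "fit_block",
    "svargs_fit",
]

logger = logging.getLogger(__name__)

_RANK_RTOL = 1e-10  # relative Schur-complement floor for candidate columns


@dataclass(frozen=True)
class FitConfig:
    """Tuning parameters of the greedy search.

    ``lags`` is the candidate lag set T (typically ``1..p_cutoff``).
    ``p_min``/``p_max`` bound the entry p-value schedule, which grows by
    ``increment_factor`` whenever a full pass makes no change;
    ``p_exit = exit_ratio * p_entry`` gates removals.  ``ebic_gamma``
    weights the extended-SBC penalty and ``max_sweeps`` caps the number of
    support changes per p_entry level.

    With ``scan_correction`` (the default) the entry statistic -- a maximum
    over the scanned candidate blocks -- is tested with its Sidak-corrected
    p-value, so ``p_entry`` is a per-scan (family-wise) level rather than a
    per-candidate one.  This keeps the false-entry rate per equation roughly
    constant as the candidate pool grows and is what makes the search usable
    when candidates outnumber observations; the default ``p_max = 0.3``
    yields a fraction of a false entry per equation after the extended-SBC
    selection.  ``scan_correction=False`` tests the winner as a single
    comparison, which is only advisable for small candidate pools.
    """

    lags: tuple[int, ...]
    p_min: float = 1e-6
    p_max: float = 0.3
    increment_factor: float = 1.3
    exit_ratio: float = 2.0
    ebic_gamma: float = 0.5
    max_sweeps: int = 200
    scan_correction: bool = True

    def __post_init__(self) -> None:
        lags = tuple(sorted(set(int(l) for l in self.lags)))
        if not lags or lags[0] <= 0:
            raise ValueError("lag set must contain positive integers")
        object.__setattr__(self, "lags", lags)
        if not (0 < self.p_min <= self.p_max < 1):
            raise ValueError("need 0 < p_min <= p_max < 1")
        if self.increment_factor <= 1:
            raise ValueError("increment_factor must be > 1")
        if self.exit_ratio <= 1:
            raise ValueError("exit_ratio must be > 1")

    @classmethod
    def from_order(cls, order: int, **kw) -> "FitConfig":
        return cls(lags=tuple(range(1, order + 1)), **kw)


@dataclass(frozen=True)
class Candidate:
    """One entry-scan winner: a (source block, lag) regressor block with its
    determinant ratio and fitted coefficient block."""

    source_block: int
    lag: int
    det_ratio: float
    coefficient_block: np.ndarray


@dataclass(frozen=True)
class TraceRecord:
    support: tuple[tuple[int, int], ...]  # sorted (lag, source_block) pairs
    score: float
    p_entry: float


@dataclass
class FitTrace:
    """Recorded models and extended-SBC scores along the greedy trajectory."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, support, score, p_entry) -> None:
        if not np.isfinite(score):
            raise ValueError("trace scores must be finite")
        self.records.append(TraceRecord(tuple(support), float(score), float(p_entry)))

    def best(self) -> TraceRecord:
        return min(self.records, key=lambda r: r.score)


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------


def det_ratio(sigma_before: np.ndarray, sigma_after: np.ndarray) -> float:
    """``det(Sigma_before) / det(Sigma_after)`` for SPD covariances."""
    sb = np.atleast_2d(np.asarray(sigma_before, float))
    sa = np.atleast_2d(np.asarray(sigma_after, float))
    s1, ld1 = np.linalg.slogdet(sb)
    s2, ld2 = np.linalg.slogdet(sa)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("covariance determinants must be positive")
    return float(np.exp(ld1 - ld2))


def gc_stat_pvalue(ratio: float, n_obs: int, a: int, b: int, m: int) -> float:
    """p-value of a determinant-ratio statistic for nested OLS models.

    ``a`` is the target block size, ``b`` the number of added regressor
    columns and ``m`` the regressor column count of the *smaller* model.
    For ``a = b = 1`` the mapping ``F = (ratio - 1) * (n_obs - m - 1)`` onto
    an F(1, n_obs - m - 1) law is exact; otherwise a large-sample chi-square
    on ``n_obs * ln(ratio)`` with ``a * b`` degrees of freedom is used.
    Ratios below 1 are not in the tested direction and give p = 1.
    """
    if n_obs <= m + 1:
        raise ValueError("n_obs must exceed the regressor count + 1")
    if ratio < 1.0:
        return 1.0
    if a == 1 and b == 1:
        df2 = n_obs - m - 1
        f_stat = (ratio - 1.0) * df2
        return float(stats.f.sf(f_stat, 1, df2))
    return float(stats.chi2.sf(n_obs * np.log(ratio), a * b))


# ---------------------------------------------------------------------------
# Gram-matrix fitter
# ---------------------------------------------------------------------------


class _GramFitter:
    """Per-target-block regression engine on precomputed Gram matrices.

    Maintains, for a current support (a sorted tuple of ``(lag, source
    block)`` pairs), the Cholesky factor of the support Gram block, the OLS
    coefficients and the residual cross-product matrix, and evaluates every
    single-block augmentation / deletion through Schur-complement updates.
    Scan results depend only on the support, so they are memoised.
    """

    def __init__(self, ts: TimeSeries, lags, partition: BlockPartition,
                 target_block: int):
        self.partition = partition
        self.j = target_block
        self.lags = tuple(sorted(set(int(l) for l in lags)))
        self.k = partition.k
        targets = list(partition.blocks[target_block])
        self.a = len(targets)
        X, Y = lagged_design(ts, self.lags, targets)
        self.n = Y.shape[0]
        self.G = X.T @ X
        self.H = X.T @ Y
        self.Syy = Y.T @ Y
        self._finish_init()

    @classmethod
    def from_shared(cls, shared: "_SharedGram", target_block: int) -> "_GramFitter":
        self = cls.__new__(cls)
        self.partition = shared.partition
        self.j = target_block
        self.lags = shared.lags
        self.k = shared.partition.k
        targets = list(shared.partition.blocks[target_block])
        self.a = len(targets)
        self.n = shared.n
        self.G = shared.G
        self.H = shared.H[:, targets]
        self.Syy = shared.Syy[np.ix_(targets, targets)]
        self._finish_init()
        return self

    def _finish_init(self) -> None:
        part, k = self.partition, self.k
        self.diagG = np.diag(self.G).copy()
        # column layout: lag-major then channel
        self._lag_pos = {lag: i for i, lag in enumerate(self.lags)}
        self._block_cols = {}
        for sb, chans in enumerate(part.blocks):
            for lag in self.lags:
                base = self._lag_pos[lag] * k
                self._block_cols[(lag, sb)] = np.array(
                    [base + c for c in chans], dtype=int)
        # candidate enumeration order: (lag, source block) lexicographic
        self._all_regs = tuple((lag, sb) for lag in self.lags
                               for sb in range(part.n_blocks))
        self._reg_index = {r: i for i, r in enumerate(self._all_regs)}
        self._atomic = all(len(b) == 1 for b in part.blocks)
        if self._atomic:
            self._reg_cols_flat = np.array(
                [self._block_cols[r][0] for r in self._all_regs], dtype=int)
        self._scan_cache: dict[tuple, tuple] = {}
        self._state_key = None

    # -- state ------------------------------------------------------------

    def cols_of(self, regs) -> np.ndarray:
        if not regs:
            return np.array([], dtype=int)
        return np.concatenate([self._block_cols[r] for r in regs])

    def _set_state(self, regs: tuple[tuple[int, int], ...]) -> None:
        if self._state_key == regs:
            return
        s = self.cols_of(regs)
        m = len(s)
        if m:
            Gss = self.G[np.ix_(s, s)]
            d = np.sqrt(self.diagG[s])
            c, low = scipy.linalg.cho_factor(Gss / np.outer(d, d), lower=True)
            if np.min(np.diag(c)) < 1e-7:
                raise RankDeficiencyError("support design is rank deficient")
            self._chol = (c, low, d)
            beta = scipy.linalg.cho_solve((c, low), self.H[s] / d[:, None])
            self.beta = beta / d[:, None]
            self.E = self.Syy - self.H[s].T @ self.beta
            Gs_all = self.G[s, :]
            W = scipy.linalg.cho_solve((c, low), Gs_all / d[:, None]) / d[:, None]
            self._den_all = self.diagG - np.einsum("ij,ij->j", Gs_all, W)
            self._num_base = self.H - Gs_all.T @ self.beta  # q x a
            self._Gs_all = Gs_all
            self._W = W
        else:
            self._chol = None
            self.beta = np.zeros((0, self.a))
            self.E = self.Syy.copy()
            self._den_all = self.diagG.copy()
            self._num_base = self.H.copy()
            self._Gs_all = np.zeros((0, self.G.shape[0]))
            self._W = self._Gs_all
        self.s_cols = s
        sign, ld = np.linalg.slogdet(np.atleast_2d(self.E))
        # a singular residual cross-product (perfect fit) is representable:
        # entries then have infinite ratio, removals infinite penalty
        self.logdetE = ld if sign > 0 else -np.inf
        self._state_key = regs

    def n_cols(self, regs) -> int:
        return sum(len(self._block_cols[r]) for r in regs)

    # -- scans ------------------------------------------------------------

    def entry_scan(self, regs) -> tuple[int, int, float, int, int] | None:
        """Best augmentation: ``(lag, source_block, ratio, b, n_scanned)``."""
        regs = tuple(sorted(regs))
        key = ("entry", regs)
        if key in self._scan_cache:
            return self._scan_cache[key]
        self._set_state(regs)
        present = set(regs)
        m = len(self.s_cols)
        best = None
        if self._atomic and self.a == 1:
            rss = float(self.E[0, 0])
            order_cols = self._reg_cols_flat
            num = self._num_base[order_cols, 0] ** 2
            den = self._den_all[order_cols]
            valid = den > _RANK_RTOL * self.diagG[order_cols]
            if present:
                drop = np.array([self._reg_index[r] for r in present])
                valid[drop] = False
            if self.n <= m + 2:  # need >= 1 residual df after entry
                valid[:] = False
            if np.any(valid):
                dr = np.where(valid, num / np.where(valid, den, 1.0), -np.inf)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratios = np.where(dr >= rss, np.inf, rss / (rss - dr))
                ratios = np.where(valid, ratios, -np.inf)
                i = int(np.argmax(ratios))
                if ratios[i] > 0:
                    lag, sb = self._all_regs[i]
                    best = (lag, sb, float(ratios[i]), 1, int(valid.sum()))
        else:
            n_scanned = 0
            for (lag, sb) in self._all_regs:
                if (lag, sb) in present:
                    continue
                c = self._block_cols[(lag, sb)]
                b = len(c)
                if self.n <= m + b + 1:
                    continue
                Rcc = self.G[np.ix_(c, c)] - self._Gs_all[:, c].T @ self._W[:, c]
                try:
                    cf = scipy.linalg.cho_factor(Rcc, lower=True)
                except scipy.linalg.LinAlgError:
                    continue
                if np.min(np.diag(cf[0])) ** 2 < _RANK_RTOL * np.max(self.diagG[c]):
                    continue
                n_scanned += 1
                Rcy = self._num_base[c, :]
                Eplus = self.E - Rcy.T @ scipy.linalg.cho_solve(cf, Rcy)
                sign, ld = np.linalg.slogdet(np.atleast_2d(Eplus))
                ratio = np.inf if sign <= 0 else float(np.exp(self.logdetE - ld))
                if best is None or ratio > best[2]:
                    best = (lag, sb, ratio, b)
            if best is not None:
                best = best + (n_scanned,)
        self._scan_cache[key] = best
        return best

    def exit_scan(self, regs) -> tuple[int, int, float, int] | None:
        """Worst member: returns ``(lag, source_block, ratio, b)`` with the
        minimal ``det(Sigma-) / det(Sigma)``."""
        regs = tuple(sorted(regs))
        if not regs:
            return None
        key = ("exit", regs)
        if key in self._scan_cache:
            return self._scan_cache[key]
        self._set_state(regs)
        c, low, d = self._chol
        m = len(self.s_cols)
        inv = scipy.linalg.cho_solve((c, low), np.eye(m) / d[:, None]) / d[None, :]
        worst = None
        pos = 0
        offsets = {}
        for r in regs:
            b = len(self._block_cols[r])
            offsets[r] = (pos, pos + b)
            pos += b
        for r in regs:
            lo, hi = offsets[r]
            Bd = self.beta[lo:hi, :]
            Vdd = inv[lo:hi, lo:hi]
            Eminus = self.E + Bd.T @ np.linalg.solve(Vdd, Bd)
            sign, ld = np.linalg.slogdet(np.atleast_2d(Eminus))
            ratio = np.inf if sign <= 0 else float(np.exp(ld - self.logdetE))
            if worst is None or ratio < worst[2]:
                worst = (r[0], r[1], ratio, hi - lo)
        self._scan_cache[key] = worst
        return worst

    # -- scoring ----------------------------------------------------------

    def sbc(self, regs, gamma: float) -> float:
        """Extended SBC: ``n ln det(Sigma_hat) + d ln n + 2 gamma d ln q``."""
        self._set_state(tuple(sorted(regs)))
        d = self.a * len(self.s_cols)
        q_slots = self.a * self.k * len(self.lags)
        # floor keeps the score finite on (near-)interpolating supports
        logdetE = max(self.logdetE, self.a * np.log(1e-280))
        logdet_sigma = logdetE - self.a * np.log(self.n)
        return float(self.n * logdet_sigma + d * np.log(self.n)
                     + 2.0 * gamma * d * np.log(q_slots))

    def coefficients(self, regs) -> np.ndarray:
        self._set_state(tuple(sorted(regs)))
        return self.beta.T.copy()

    def sigma(self, regs) -> np.ndarray:
        self._set_state(tuple(sorted(regs)))
        return self.E / self.n


class _SharedGram:
    """Full-design Gram matrices shared across target blocks of one fit."""

    def __init__(self, ts: TimeSeries, lags, partition: BlockPartition):
        self.partition = partition
        self.lags = tuple(sorted(set(int(l) for l in lags)))
        X, Y = lagged_design(ts, self.lags, list(range(ts.k)))
        self.X, self.Y = X, Y
        self.n = Y.shape[0]
        self.G = X.T @ X
        self.H = X.T @ Y
        self.Syy = Y.T @ Y


# ---------------------------------------------------------------------------
# public scan wrappers (slow refit path available for cross-checking)
# ---------------------------------------------------------------------------


def _refit_sigma(ts, partition, lags, regs, target_block):
    entries = frozenset((target_block, sb, lag) for (lag, sb) in regs)
    sup = Support(entries, partition, tuple(lags))
    _, sigma, n = ols_fit(ts, sup, target_block)
    return sigma, n


def entry_scan(ts: TimeSeries, current, target_block: int, config: FitConfig,
               partition: BlockPartition | None = None,
               use_fast: bool = True) -> Candidate | None:
    """Best single-block augmentation of ``current`` (a collection of
    ``(lag, source_block)`` pairs) for one target block.

    With ``use_fast=False`` every candidate is evaluated by a full OLS refit
    (the reference path); the default Gram-update path must agree with it to
    rounding error.
    """
    ts = demean(ts)
    partition = partition or BlockPartition.atomic(ts.k)
    regs = tuple(sorted(current))
    if use_fast:
        f = _GramFitter(ts, config.lags, partition, target_block)
        best = f.entry_scan(regs)
        if best is None:
            return None
        lag, sb, ratio, b, _ = best
        coef = f.coefficients(tuple(sorted(regs + ((lag, sb),))))
        cols = tuple(sorted(regs + ((lag, sb),)))
        idx = cols.index((lag, sb))
        lo = f.n_cols(cols[:idx])
        return Candidate(sb, lag, ratio, coef[:, lo:lo + b])
    # slow reference path
    sigma0, n = _refit_sigma(ts, partition, config.lags, regs, target_block)
    best = None
    m = sum(len(partition.blocks[sb]) for (_, sb) in regs)
    for lag in config.lags:
        for sb in range(partition.n_blocks):
            if (lag, sb) in regs:
                continue
            b = len(partition.blocks[sb])
            if n <= m + b + 1:
                continue
            try:
                sigma1, _ = _refit_sigma(ts, partition, config.lags,
                                         regs + ((lag, sb),), target_block)
                ratio = det_ratio(sigma0, sigma1)
            except (RankDeficiencyError, ValueError):
                continue
            if best is None or ratio > best[2]:
                best = (lag, sb, ratio, b)
    if best is None:
        return None
    lag, sb, ratio, b = best
    coef, _, _ = ols_fit(
        ts, Support(frozenset((target_block, s, l) for (l, s)
                              in regs + ((lag, sb),)),
                    partition, config.lags), target_block)
    cols = tuple(sorted(regs + ((lag, sb),)))
    idx = cols.index((lag, sb))
    lo = sum(len(partition.blocks[s]) for (_, s) in cols[:idx])
    return Candidate(sb, lag, ratio, coef[:, lo:lo + b])


def exit_scan(ts: TimeSeries, current, target_block: int, config: FitConfig,
              partition: BlockPartition | None = None,
              use_fast: bool = True) -> Candidate | None:
    """Member of ``current`` with the smallest removal determinant ratio."""
    ts = demean(ts)
    partition = partition or BlockPartition.atomic(ts.k)
    regs = tuple(sorted(current))
    if not regs:
        return None
    if use_fast:
        f = _GramFitter(ts, config.lags, partition, target_block)
        worst = f.exit_scan(regs)
        if worst is None:
            return None
        lag, sb, ratio, b = worst
        return Candidate(sb, lag, ratio, np.zeros((0, 0)))
    sigma0, _ = _refit_sigma(ts, partition, config.lags, regs, target_block)
    worst = None
    for (lag, sb) in regs:
        reduced = tuple(r for r in regs if r != (lag, sb))
        sigma1, _ = _refit_sigma(ts, partition, config.lags, reduced, target_block)
        ratio = det_ratio(sigma1, sigma0)
        if worst is None or ratio < worst[2]:
            worst = (lag, sb, ratio)
    lag, sb, ratio = worst
    return Candidate(sb, lag, ratio, np.zeros((0, 0)))


def extended_sbc(ts: TimeSeries, support, target_block: int, config: FitConfig,
                 partition: BlockPartition | None = None) -> float:
    """Extended-SBC score of one target block's support; lower is better."""
    ts = demean(ts)
    partition = partition or BlockPartition.atomic(ts.k)
    if isinstance(support, Support):
        regs = support.regressors_for(target_block)
    else:
        regs = tuple(sorted(support))
    f = _GramFitter(ts, config.lags, partition, target_block)
    return f.sbc(regs, config.ebic_gamma)


# ---------------------------------------------------------------------------
# the greedy loop
# ---------------------------------------------------------------------------


def _fit_block_on(fitter: _GramFitter, config: FitConfig):
    """Run the entry/exit/escalate loop for one target block.

    Returns ``(best_regs, coefficients, sigma, trace)``.
    """
    a = fitter.a
    n = fitter.n
    regs: tuple[tuple[int, int], ...] = ()
    trace = FitTrace()
    trace.append(regs, fitter.sbc(regs, config.ebic_gamma), config.p_min)
    p_entry = config.p_min
    while True:
        seen = {regs}
        sweeps = 0
        while True:
            changed = False
            cand = fitter.entry_scan(regs)
            if cand is not None:
                lag, sb, ratio, b, n_scanned = cand
                if ratio > 1.0:
                    m = fitter.n_cols(regs)
                    p = gc_stat_pvalue(ratio, n, a, b, m)
                    if config.scan_correction and n_scanned > 1:
                        # Sidak correction: the entry statistic is the max
                        # over n_scanned candidate blocks
                        p = float(-np.expm1(
                            n_scanned * np.log1p(-min(p, 1.0 - 1e-16))))
                    if p <= p_entry:
                        regs = tuple(sorted(regs + ((lag, sb),)))
                        changed = True
            worst = fitter.exit_scan(regs)
            if worst is not None:
                lag, sb, ratio, b = worst
                m_reduced = fitter.n_cols(regs) - b
                p = gc_stat_pvalue(ratio, n, a, b, m_reduced)
                if p > config.exit_ratio * p_entry:
                    regs = tuple(r for r in regs if r != (lag, sb))
                    changed = True
            if not changed:
                break
            trace.append(regs, fitter.sbc(regs, config.ebic_gamma), p_entry)
            sweeps += 1
            if regs in seen:
                break  # revisited state: this p_entry level cannot settle
            seen.add(regs)
            if sweeps >= config.max_sweeps:
                warnings.warn(
                    f"greedy search for block {fitter.j} exceeded "
                    f"max_sweeps={config.max_sweeps}; keeping best recorded model",
                    RuntimeWarning)
                break
        if p_entry >= config.p_max:
            break
        p_entry = p_entry * config.increment_factor
    best = trace.best().support
    return best, fitter.coefficients(best), fitter.sigma(best), trace


def fit_block(ts: TimeSeries, target_block: int, config: FitConfig,
              partition: BlockPartition | None = None):
    """Greedy fit of one target block; see :func:`svargs_fit`.

    Returns ``(support, coefficients, sigma, trace)`` where ``support`` is a
    :class:`~svargs.var_core.Support` restricted to this target block.
    """
    ts = demean(ts)
    partition = partition or BlockPartition.atomic(ts.k)
    fitter = _GramFitter(ts, config.lags, partition, target_block)
    regs, coef, sigma, trace = _fit_block_on(fitter, config)
    entries = frozenset((target_block, sb, lag) for (lag, sb) in regs)
    support = Support(entries, partition, config.lags)
    return support, coef, sigma, trace


def svargs_fit(ts: TimeSeries, config: FitConfig,
               partition: BlockPartition | None = None) -> SparseVARModel:
    """Fit a sparse VAR model by the greedy block search.

    Each block of the partition (default: one block per channel) is fitted
    independently; the assembled model carries the full residual covariance
    (cross-block terms computed from the final residuals).  The per-block
    fit traces are attached as ``model.fit_traces``.
    """
    ts = demean(ts)
    k = ts.k
    partition = partition or BlockPartition.atomic(k)
    shared = _SharedGram(ts, config.lags, partition)
    lags = shared.lags
    col_of = {(lag, c): i * k + c for i, lag in enumerate(lags) for c in range(k)}
    B = np.zeros((shared.X.shape[1], k))
    traces = []
    for j in range(partition.n_blocks):
        fitter = _GramFitter.from_shared(shared, j)
        regs, coef, _, trace = _fit_block_on(fitter, config)
        traces.append(trace)
        rows = list(partition.blocks[j])
        pos = 0
        for (lag, sb) in regs:
            for c in partition.blocks[sb]:
                for ri, r in enumerate(rows):
                    B[col_of[(lag, c)], r] = coef[ri, pos]
                pos += 1
        logger.debug("block %d: %d regressor blocks selected", j, len(regs))
    resid = shared.Y - shared.X @ B
    sigma = resid.T @ resid / shared.n
    coeffs = {}
    for i, lag in enumerate(lags):
        A = B[i * k:(i + 1) * k, :].T
        if np.any(A):
            coeffs[lag] = sp.csr_matrix(A)
    model = SparseVARModel(k=k, lags=lags, coeffs=coeffs, sigma=sigma,
                           partition=partition, channel_labels=ts.channel_labels)
    model.fit_traces = traces
    return model
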