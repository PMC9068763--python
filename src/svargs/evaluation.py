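"""Simulation-study harness: model-recovery error measures and benchmark.

The benchmark draws random sparse stable VAR models (orders uniform on 5-8,
density uniform in a size-specific range), simulates N time points, fits
with the greedy search using a lag cutoff two above the true order, and
summarises support- and coefficient-recovery errors per system size and
data length.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .greedy import FitConfig, svargs_fit
from .var_core import SparseVARModel, is_stable, random_sparse_stable_var, simulate

__all__ = [
    "RecoveryReport",
    "DENSITY_RANGES",
    "support_errors",
    "coefficient_errors",
    "run_benchmark",
    "summarize_benchmark",
]

# density ranges (fractions of the k^2 * p coefficient slots) per system size
DENSITY_RANGES: dict[int, tuple[float, float]] = {
    35: (0.012, 0.024),
    100: (0.004, 0.009),
    300: (0.0013, 0.0025),
    500: (0.0008, 0.0018),
}


@dataclass
class RecoveryReport:
    """Error measures of one fitted model against the generating truth."""

    true_nonzero_count: int
    unpredicted_percent: float
    spurious_per_100: float
    relative_spurious_weight: float
    normalized_rmse: float
    normalized_bias: float
    order_error: float
    coefficient_correlation: float
    fit_seconds: float


def support_errors(true_model: SparseVARModel, fitted_model: SparseVARModel,
                   ) -> tuple[float, float, float]:
    """Support-recovery errors ``(unpredicted_percent, spurious_per_100,
    order_error)``.

    ``unpredicted_percent`` is the false-negative rate: 100 x (true
    nonzeros absent from the fit) / (true nonzeros).  ``spurious_per_100``
    counts fitted nonzeros absent from the truth per 100 true ones.
    ``order_error`` is the mean over equations of |max fitted lag - max
    true lag| (an empty equation has max lag 0).
    """
    true = true_model.support_triples()
    if not true:
        raise ValueError("true model has no nonzero coefficients")
    fit = fitted_model.support_triples()
    n_true = len(true)
    unpredicted = 100.0 * len(true - fit) / n_true
    spurious = 100.0 * len(fit - true) / n_true
    k = true_model.k

    def max_lags(triples):
        out = np.zeros(k)
        for (r, _, lag) in triples:
            out[r] = max(out[r], lag)
        return out

    order_error = float(np.abs(max_lags(fit) - max_lags(true)).mean())
    return unpredicted, spurious, order_error


def coefficient_errors(true_model: SparseVARModel, fitted_model: SparseVARModel,
                       ) -> tuple[float, float, float, float]:
    """Coefficient-recovery errors ``(relative_spurious_weight,
    normalized_rmse, normalized_bias, correlation)``.

    Correlation is the Pearson correlation of true vs fitted coefficient
    values over the union support (absent entries count as 0).  RMSE and
    bias are computed over the correctly predicted true nonzeros;
    ``normalized_rmse = ||fitted - true|| / ||true||`` on that set, the
    bias is the mean of ``(fitted - true)`` scaled by the rms of the true
    nonzeros, and the relative spurious weight is the norm of the spurious
    coefficients over the norm of all true ones.
    """
    true = true_model.support_triples()
    fit = fitted_model.support_triples()
    union = sorted(true | fit)
    tv = np.array([true_model.coeff_dense(l)[r, c] for (r, c, l) in union])
    fv = np.array([fitted_model.coeff_dense(l)[r, c] for (r, c, l) in union])
    if len(union) < 2 or np.std(tv) == 0 or np.std(fv) == 0:
        corr = 1.0 if np.allclose(tv, fv) else 0.0
    else:
        corr = float(np.corrcoef(tv, fv)[0, 1])
    true_vals = np.array([true_model.coeff_dense(l)[r, c]
                          for (r, c, l) in sorted(true)])
    true_norm = float(np.linalg.norm(true_vals))
    hit = sorted(true & fit)
    if hit:
        tv_h = np.array([true_model.coeff_dense(l)[r, c] for (r, c, l) in hit])
        fv_h = np.array([fitted_model.coeff_dense(l)[r, c] for (r, c, l) in hit])
        nrmse = float(np.linalg.norm(fv_h - tv_h) / np.linalg.norm(tv_h))
        scale = float(np.sqrt(np.mean(true_vals ** 2)))
        nbias = float(np.mean(fv_h - tv_h) / scale)
    else:
        nrmse = float("nan")
        nbias = float("nan")
    spur = sorted(fit - true)
    if spur:
        sv = np.array([fitted_model.coeff_dense(l)[r, c] for (r, c, l) in spur])
        rsw = float(np.linalg.norm(sv) / true_norm)
    else:
        rsw = 0.0
    return rsw, nrmse, nbias, corr


def evaluate_fit(true_model: SparseVARModel, fitted_model: SparseVARModel,
                 fit_seconds: float = float("nan")) -> RecoveryReport:
    unp, spur, oerr = support_errors(true_model, fitted_model)
    rsw, nrmse, nbias, corr = coefficient_errors(true_model, fitted_model)
    return RecoveryReport(
        true_nonzero_count=len(true_model.support_triples()),
        unpredicted_percent=unp,
        spurious_per_100=spur,
        relative_spurious_weight=rsw,
        normalized_rmse=nrmse,
        normalized_bias=nbias,
        order_error=oerr,
        coefficient_correlation=corr,
        fit_seconds=fit_seconds,
    )


def run_benchmark(sizes, data_lengths, reps: int, seed: int | None = None,
                  densities: dict[int, tuple[float, float]] | None = None,
                  order_range: tuple[int, int] = (5, 8),
                  cutoff_extra: int = 2,
                  config_kwargs: dict | None = None) -> pd.DataFrame:
    """Run the model-recovery benchmark.

    For every ``(k, N, rep)``: draw a random stable model (order uniform on
    ``order_range``, density uniform in the size-specific range), simulate
    ``N`` points, fit with lag set ``1 .. true order + cutoff_extra``, and
    record a :class:`RecoveryReport` row.  Returns a tidy DataFrame with
    columns ``k, N, rep`` plus the report fields.
    """
    densities = {**DENSITY_RANGES, **(densities or {})}
    rows = []
    ss = np.random.SeedSequence(seed)
    for k in sizes:
        if k not in densities:
            raise ValueError(f"no density range known for k={k}; pass one")
        lo, hi = densities[k]
        for N in data_lengths:
            for rep in range(reps):
                rng = np.random.default_rng(ss.spawn(1)[0])
                density = rng.uniform(lo, hi)
                model = random_sparse_stable_var(
                    k, order_range=order_range, density=density, seed=rng)
                assert is_stable(model)
                ts = simulate(model, N, seed=rng)
                cfg = FitConfig.from_order(model.order + cutoff_extra,
                                           **(config_kwargs or {}))
                t0 = time.perf_counter()
                fitted = svargs_fit(ts, cfg)
                dt = time.perf_counter() - t0
                report = evaluate_fit(model, fitted, dt)
                rows.append({"k": k, "N": N, "rep": rep, **asdict(report)})
    columns = ["k", "N", "rep", "true_nonzero_count", "unpredicted_percent",
               "spurious_per_100", "relative_spurious_weight",
               "normalized_rmse", "normalized_bias", "order_error",
               "coefficient_correlation", "fit_seconds"]
    return pd.DataFrame(rows, columns=columns)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of every error measure per (k, N)."""
    metrics = [c for c in results.columns if c not in ("k", "N", "rep")]
    return results.groupby(["k", "N"])[metrics].agg(["mean", "std"])
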