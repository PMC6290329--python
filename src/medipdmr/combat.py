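"""Empirical-Bayes location-scale batch adjustment of RPKM matrices.

The model follows the classic ComBat formulation: on log(RPKM + eps) each
region's values are standardized against a covariate-preserving linear fit,
per-batch location (gamma) and scale (delta^2) parameters are estimated and
shrunk toward batch-wise parametric priors (normal on gamma, inverse-gamma on
delta^2, moment-matched), and the standardized data are rescaled without the
batch terms.  Multiple batch factors are corrected sequentially in the order
given.  A ``shrink=False`` mode disables the EB priors, reducing the method
to a direct per-region location-scale correction (the limiting oracle).

The adjusted matrix is exponentiated back to the RPKM scale; downstream
count-model testing uses the exact inverse of the depth scaling
(``normalize.rpkm_to_reads_per_kb``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import CountMatrix, NormalizationError

__all__ = ["BatchModel", "fit_and_adjust", "back_to_reads_per_kb", "ConfoundingError"]

LOG_EPS = 0.5


class ConfoundingError(ValueError):
    """Batch indicator is collinear with a kept covariate."""


@dataclass
class BatchModel:
    batch_factor: str
    batch_levels: list
    gamma_hat: pd.DataFrame      # batch x region
    gamma_star: pd.DataFrame
    delta_sq_hat: pd.DataFrame
    delta_sq_star: pd.DataFrame
    grand_mean: pd.Series
    pooled_var: pd.Series
    shrink: bool = True
    priors: dict = field(default_factory=dict)

    def to_yaml_dict(self) -> dict:
        return {
            "batch_factor": self.batch_factor,
            "batch_levels": [str(b) for b in self.batch_levels],
            "shrink": self.shrink,
            "priors": {k: [float(x) for x in np.atleast_1d(v)] for k, v in self.priors.items()},
        }


def _design_matrix(meta: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Intercept + treatment-coded dummies for each categorical covariate."""
    parts = [np.ones((len(meta), 1))]
    for c in columns:
        dummies = pd.get_dummies(meta[c].astype(str), drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=200):
    """Iterative EB solution for the parametric batch priors (per batch)."""
    n = (~np.isnan(sdat)).sum(axis=0).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((sdat - g_new[None, :]) ** 2, axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _adjust_one_factor(
    logv: np.ndarray,           # samples x regions
    batch: pd.Series,
    covariate_design: np.ndarray,
    shrink: bool,
) -> tuple[np.ndarray, dict]:
    levels = list(pd.unique(batch))
    n_samples, n_regions = logv.shape
    batch_dummies = np.column_stack([(batch == lv).to_numpy(dtype=float) for lv in levels])
    counts = batch_dummies.sum(axis=0)
    if (counts < 2).any():
        small = [str(levels[i]) for i in np.where(counts < 2)[0]]
        raise ValueError(f"each batch level needs >= 2 samples; too small: {small}")

    # confounding check: covariates (beyond intercept) must add rank to batch dummies
    cov_extra = covariate_design[:, 1:]
    design = np.hstack([batch_dummies, cov_extra])
    if np.linalg.matrix_rank(design) < batch_dummies.shape[1] + cov_extra.shape[1]:
        raise ConfoundingError(
            "batch factor is confounded (collinear) with kept covariates; "
            "cannot separate batch from covariate effects"
        )

    # per-region fit: batch means + covariate effects
    B_hat, *_ = np.linalg.lstsq(design, logv, rcond=None)
    n_batches = len(levels)
    grand_mean = (counts / n_samples) @ B_hat[:n_batches]
    stand_mean = np.outer(np.ones(n_samples), grand_mean) + cov_extra @ B_hat[n_batches:]
    resid = logv - design @ B_hat
    pooled_var = (resid**2).sum(axis=0) / n_samples
    pooled_var = np.maximum(pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)

    Z = (logv - stand_mean) / sd[None, :]

    gamma_hat = np.vstack([Z[batch.to_numpy() == lv].mean(axis=0) for lv in levels])
    delta_hat = np.vstack([Z[batch.to_numpy() == lv].var(axis=0, ddof=1) for lv in levels])
    delta_hat = np.maximum(delta_hat, 1e-12)

    priors = {}
    if shrink:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, lv in enumerate(levels):
            sdat = Z[batch.to_numpy() == lv]
            g_bar, t2 = gamma_hat[i].mean(), gamma_hat[i].var()
            t2 = max(t2, 1e-12)
            a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
            if not np.isfinite(a) or not np.isfinite(b):
                gamma_star[i], delta_star[i] = gamma_hat[i], delta_hat[i]
            else:
                gamma_star[i], delta_star[i] = _it_sol(
                    sdat, gamma_hat[i], delta_hat[i], g_bar, t2, a, b
                )
            priors[f"batch_{lv}"] = (g_bar, t2, a, b)
    else:
        gamma_star, delta_star = gamma_hat, delta_hat
    delta_star = np.maximum(delta_star, 1e-12)

    Z_adj = Z.copy()
    for i, lv in enumerate(levels):
        mask = batch.to_numpy() == lv
        Z_adj[mask] = (Z[mask] - gamma_star[i][None, :]) / np.sqrt(delta_star[i])[None, :]
    adjusted = Z_adj * sd[None, :] + stand_mean
    fit = {
        "levels": levels,
        "gamma_hat": gamma_hat,
        "gamma_star": gamma_star,
        "delta_hat": delta_hat,
        "delta_star": delta_star,
        "grand_mean": grand_mean,
        "pooled_var": pooled_var,
        "priors": priors,
    }
    return adjusted, fit


def fit_and_adjust(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    batch_factors: list[str] | str,
    keep_covariates: list[str] | None = None,
    shrink: bool = True,
    eps: float = LOG_EPS,
) -> tuple[CountMatrix, list[BatchModel]]:
    """Adjust an RPKM matrix for one or more batch factors, preserving covariates.

    Batch factors are corrected sequentially in the order listed.  Returns
    the adjusted matrix (state ``batch_adjusted``, still on the RPKM scale)
    and one fitted :class:`BatchModel` per factor.
    """
    if matrix.state != "rpkm":
        raise NormalizationError(f"batch adjustment expects state='rpkm', got {matrix.state!r}")
    if isinstance(batch_factors, str):
        batch_factors = [batch_factors]
    keep_covariates = keep_covariates or []
    meta = metadata.set_index("sample_id").loc[list(matrix.samples)]

    logv = np.log(matrix.values.to_numpy(dtype=float).T + eps)  # samples x regions
    cov_design = _design_matrix(meta, keep_covariates)
    models = []
    for factor in batch_factors:
        batch = meta[factor]
        if batch.nunique() < 2:
            # nothing to correct; identity by the single-batch invariant
            levels = list(pd.unique(batch))
            models.append(
                BatchModel(
                    batch_factor=factor,
                    batch_levels=levels,
                    gamma_hat=pd.DataFrame(0.0, index=levels, columns=matrix.region_ids),
                    gamma_star=pd.DataFrame(0.0, index=levels, columns=matrix.region_ids),
                    delta_sq_hat=pd.DataFrame(1.0, index=levels, columns=matrix.region_ids),
                    delta_sq_star=pd.DataFrame(1.0, index=levels, columns=matrix.region_ids),
                    grand_mean=pd.Series(logv.mean(axis=0), index=matrix.region_ids),
                    pooled_var=pd.Series(logv.var(axis=0), index=matrix.region_ids),
                    shrink=shrink,
                )
            )
            continue
        logv, fit = _adjust_one_factor(logv, batch, cov_design, shrink)
        rid = matrix.region_ids
        models.append(
            BatchModel(
                batch_factor=factor,
                batch_levels=fit["levels"],
                gamma_hat=pd.DataFrame(fit["gamma_hat"], index=fit["levels"], columns=rid),
                gamma_star=pd.DataFrame(fit["gamma_star"], index=fit["levels"], columns=rid),
                delta_sq_hat=pd.DataFrame(fit["delta_hat"], index=fit["levels"], columns=rid),
                delta_sq_star=pd.DataFrame(fit["delta_star"], index=fit["levels"], columns=rid),
                grand_mean=pd.Series(fit["grand_mean"], index=rid),
                pooled_var=pd.Series(fit["pooled_var"], index=rid),
                shrink=shrink,
                priors=fit["priors"],
            )
        )

    adj = np.exp(logv) - eps
    out = matrix.copy_with(
        pd.DataFrame(adj.T, index=matrix.region_ids, columns=matrix.samples),
        "batch_adjusted",
        batch_factors=batch_factors,
    )
    return out, models


def back_to_reads_per_kb(adjusted: CountMatrix) -> CountMatrix:
    """Return batch-adjusted RPKM to the reads/kb scale for count testing.

    Applies the exact inverse of the depth scaling (multiply by N_i / 1e6);
    values may be non-integer, negatives are clipped to 0 and counted.
    """
    if adjusted.state != "batch_adjusted":
        raise NormalizationError(
            f"back_to_reads_per_kb expects state='batch_adjusted', got {adjusted.state!r}"
        )
    from .normalize import rpkm_to_reads_per_kb

    return rpkm_to_reads_per_kb(adjusted, clip_negative=True)
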