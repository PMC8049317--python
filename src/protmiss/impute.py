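"""Imputation engines for protein matrices.

Five methods behind one dispatch, spanning the two missingness
assumptions a proteomics analyst must weigh:

* ``lowest_value`` — MNAR: a missing intensity is taken to mean the
  protein was below the instrument's detection sensitivity, so the cell
  is replaced by a floor value (the constant 1 on the log scale by
  default, optionally the global observed minimum).
* ``ppca`` — MAR: probabilistic PCA fitted by EM over observed entries;
  masked cells take the posterior-mean low-rank reconstruction.
* ``em`` — MAR: multivariate-normal EM; masked cells take their
  conditional expectation given the observed cells of the same sample.
* ``chained_equations`` — MAR: chained-equations (MICE-style) sweeps of
  per-protein regularised linear regressions, with a seeded residual
  noise draw by default and a deterministic conditional-mean mode.
* ``iterative_forest`` — MAR: MissForest-style iterative random-forest
  regression with the standard stopping rule (first increase in the
  normalised change of imputed values between rounds).

All methods preserve observed cells exactly and return a matrix with an
empty mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from .matrix import ProteinMatrix

__all__ = [
    "ImputationResult",
    "METHODS",
    "impute",
    "impute_lowest_value",
    "impute_ppca",
    "impute_em",
    "impute_chained",
    "impute_forest",
]

log = logging.getLogger("protmiss")

METHODS = ("lowest_value", "chained_equations", "iterative_forest", "ppca", "em")

#: Aliases accepted by the dispatcher / CLI.
_METHOD_ALIASES = {
    "lowest": "lowest_value",
    "lowest_value": "lowest_value",
    "mice": "chained_equations",
    "chained": "chained_equations",
    "chained_equations": "chained_equations",
    "forest": "iterative_forest",
    "missforest": "iterative_forest",
    "iterative_forest": "iterative_forest",
    "ppca": "ppca",
    "em": "em",
}

# Ridge on covariance/regression problems where proteins may outnumber samples.
RIDGE_EPS = 1e-6


@dataclass
class ImputationResult:
    """A completed matrix plus the provenance needed to reproduce it."""

    completed: ProteinMatrix
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    n_iterations_run: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.completed.mask.any():
            raise ValueError("ImputationResult.completed must have an empty mask")


def _completed_matrix(m: ProteinMatrix, filled: np.ndarray) -> ProteinMatrix:
    """Assemble the output grid: observed cells copied bit-for-bit, masked cells
    taken from ``filled``."""
    values = np.where(m.mask, filled, m.values)
    values[~m.mask] = m.values[~m.mask]  # exact observed-value preservation
    return ProteinMatrix(
        list(m.sample_ids), list(m.protein_ids), values,
        np.zeros_like(m.mask),
    )


def _require_observed_per_protein(m: ProteinMatrix, method: str) -> None:
    empty = np.flatnonzero(m.mask.all(axis=0))
    if empty.size:
        names = [m.protein_ids[j] for j in empty]
        raise ValueError(
            f"method {method!r} needs at least one observed value per protein; "
            f"fully missing proteins: {names}"
        )


def impute(
    m: ProteinMatrix,
    method: str,
    params: dict[str, Any] | None = None,
    seed: int | None = None,
) -> ImputationResult:
    """Dispatch to one of the five imputation engines.

    ``method`` accepts canonical names (:data:`METHODS`) and the common
    aliases ``lowest``, ``mice``, ``chained``, ``forest``, ``missforest``.
    Model-based methods reject proteins with zero observed values;
    ``lowest_value`` accepts them.
    """
    params = dict(params or {})
    canonical = _METHOD_ALIASES.get(method)
    if canonical is None:
        raise ValueError(f"unknown imputation method {method!r}; expected one of {METHODS}")
    if canonical != "lowest_value":
        _require_observed_per_protein(m, canonical)
    if canonical == "lowest_value":
        return impute_lowest_value(m, **params)
    if canonical == "ppca":
        return impute_ppca(m, seed=seed, **params)
    if canonical == "em":
        return impute_em(m, **params)
    if canonical == "chained_equations":
        return impute_chained(m, seed=seed, **params)
    return impute_forest(m, seed=seed, **params)


# ---------------------------------------------------------------------------
# lowest value (MNAR)
# ---------------------------------------------------------------------------

def impute_lowest_value(
    m: ProteinMatrix, fill: float = 1.0, use_observed_min: bool = False
) -> ImputationResult:
    """Replace every masked cell by a detection-floor constant.

    ``fill`` defaults to 1, the lowest possible value on the log scale;
    ``use_observed_min=True`` substitutes the global observed minimum
    instead (for readers who interpret the floor as the dataset minimum).
    Deterministic; accepts fully missing proteins.
    """
    if use_observed_min:
        observed = m.values[~m.mask]
        if observed.size == 0:
            raise ValueError("no observed values to take a minimum from")
        fill = float(observed.min())
    filled = np.full(m.shape, float(fill))
    return ImputationResult(
        completed=_completed_matrix(m, filled),
        method="lowest_value",
        params={"fill": float(fill), "use_observed_min": use_observed_min},
        seed=None,
        n_iterations_run=0,
        converged=True,
    )


# ---------------------------------------------------------------------------
# probabilistic PCA (MAR)
# ---------------------------------------------------------------------------

def impute_ppca(
    m: ProteinMatrix,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> ImputationResult:
    """EM imputation under a probabilistic-PCA model.

    The model is x = μ + W t + ε with an isotropic noise term whose
    variance is the mean of the trailing eigenvalues.  Each EM pass fits
    the model to the currently completed matrix (eigendecomposition of the
    sample covariance) and replaces masked cells with the posterior-mean
    reconstruction μ + V diag((λ−σ²)/λ) Vᵀ (x−μ); iteration stops when the
    relative change of the imputed values drops below ``tol``.

    Non-convergence is not an error: the result is returned with
    ``converged=False`` and a warning in the run log.
    """
    _require_observed_per_protein(m, "ppca")
    n, p = m.shape
    if not 1 <= n_components < min(n, p):
        raise ValueError(
            f"n_components must satisfy 1 <= k < min(n_samples, n_proteins) "
            f"= {min(n, p)}; got {n_components}"
        )
    X = m.values.copy()
    miss = m.mask
    col_means = np.nanmean(np.where(miss, np.nan, X), axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = X.mean(axis=0)
        Xc = X - mu
        # eigendecomposition via SVD of the centred completed matrix
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        lam = s**2 / max(n - 1, 1)
        k = n_components
        total_var = lam.sum()
        trailing = total_var - lam[:k].sum()
        sigma2 = trailing / max(p - k, 1)
        lam_k = np.maximum(lam[:k], sigma2 + 1e-300)
        shrink = (lam_k - sigma2) / lam_k          # per-component posterior shrinkage
        recon = mu + (Xc @ Vt[:k].T * shrink) @ Vt[:k]
        old = X[miss]
        new = recon[miss]
        X[miss] = new
        denom = np.linalg.norm(old) + 1e-300
        if np.linalg.norm(new - old) / denom < tol:
            converged = True
            break
    if not converged and miss.any():
        log.warning("ppca imputation did not converge in %d iterations", max_iter)
    if not miss.any():
        converged = True

    return ImputationResult(
        completed=_completed_matrix(m, X),
        method="ppca",
        params={"n_components": n_components, "max_iter": max_iter, "tol": tol},
        seed=seed,
        n_iterations_run=it if miss.any() else 0,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# multivariate-normal EM (MAR)
# ---------------------------------------------------------------------------

def impute_em(
    m: ProteinMatrix, max_iter: int = 500, tol: float = 1e-6
) -> ImputationResult:
    """EM under a multivariate-normal model.

    Each iteration re-estimates μ and Σ from the completed data (with a
    small ridge of ``1e-6 ×`` the mean diagonal because proteins may
    outnumber samples) and replaces masked cells with the conditional
    expectation μ_m + Σ_mo Σ_oo⁻¹ (x_o − μ_o) given the observed cells of
    the same sample, iterating those conditional-mean updates to a fixed
    point.
    """
    _require_observed_per_protein(m, "em")
    n, p = m.shape
    miss = m.mask
    X = m.values.copy()
    col_means = np.nanmean(np.where(miss, np.nan, X), axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])

    # group samples sharing a missingness pattern so Σ_oo is factored once
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)

    converged = not miss.any()
    it = 0
    for it in range(1, max_iter + 1):
        if not miss.any():
            break
        mu = X.mean(axis=0)
        Sigma = np.cov(X, rowvar=False, bias=True)
        Sigma = np.atleast_2d(Sigma)
        ridge = RIDGE_EPS * float(np.mean(np.diag(Sigma)))
        Sigma[np.diag_indices_from(Sigma)] += max(ridge, 1e-12)
        old = X[miss].copy()
        for key, rows in patterns.items():
            pat = np.frombuffer(key, dtype=bool)
            mi = np.flatnonzero(pat)
            if mi.size == 0:
                continue
            oi = np.flatnonzero(~pat)
            if oi.size == 0:
                X[np.ix_(rows, mi)] = mu[mi]
                continue
            Soo = Sigma[np.ix_(oi, oi)]
            Smo = Sigma[np.ix_(mi, oi)]
            try:
                coef = np.linalg.solve(Soo, Smo.T)          # (o, m)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular covariance in EM imputation even after ridge "
                    "regularisation; raise the missingness threshold or use "
                    "another method"
                ) from exc
            X[np.ix_(rows, mi)] = mu[mi] + (X[np.ix_(rows, oi)] - mu[oi]) @ coef
        new = X[miss]
        denom = np.linalg.norm(old) + 1e-300
        if np.linalg.norm(new - old) / denom < tol:
            converged = True
            break
    if not converged and miss.any():
        log.warning("em imputation did not converge in %d iterations", max_iter)

    return ImputationResult(
        completed=_completed_matrix(m, X),
        method="em",
        params={"max_iter": max_iter, "tol": tol},
        seed=None,
        n_iterations_run=it if miss.any() else 0,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# chained equations (MAR)
# ---------------------------------------------------------------------------

def impute_chained(
    m: ProteinMatrix,
    n_iterations: int = 10,
    seed: int | None = None,
    deterministic: bool = False,
    alpha: float = 1e-2,
) -> ImputationResult:
    """Chained-equations (MICE-style) imputation.

    Masked cells start at the observed column means; each sweep cycles
    over proteins, regressing each one on all others over the currently
    completed data with a ridge-regularised linear model (``alpha``), and
    refreshes that protein's masked cells with the prediction plus a
    seeded Gaussian residual draw.  ``deterministic=True`` drops the noise
    draw (pure conditional-mean updates).
    """
    _require_observed_per_protein(m, "chained_equations")
    n, p = m.shape
    if p < 2:
        raise ValueError("chained-equations imputation needs at least 2 proteins")
    rng = np.random.default_rng(seed)
    miss = m.mask
    X = m.values.copy()
    col_means = np.nanmean(np.where(miss, np.nan, X), axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])

    targets = [j for j in range(p) if miss[:, j].any()]
    sweeps = 0
    for sweeps in range(1, n_iterations + 1) if targets else [0]:
        if not targets:
            break
        for j in targets:
            obs_rows = ~miss[:, j]
            other = np.delete(np.arange(p), j)
            model = Ridge(alpha=alpha)
            model.fit(X[np.ix_(obs_rows, other)], X[obs_rows, j])
            resid = X[obs_rows, j] - model.predict(X[np.ix_(obs_rows, other)])
            sd = float(np.std(resid, ddof=min(len(resid) - 1, other.size + 1)) if len(resid) > 1 else 0.0)
            pred = model.predict(X[np.ix_(miss[:, j], other)])
            if not deterministic and sd > 0:
                pred = pred + rng.normal(0.0, sd, size=pred.shape)
            X[miss[:, j], j] = pred

    return ImputationResult(
        completed=_completed_matrix(m, X),
        method="chained_equations",
        params={"n_iterations": n_iterations, "deterministic": deterministic, "alpha": alpha},
        seed=seed,
        n_iterations_run=sweeps,
        converged=True,
    )


# ---------------------------------------------------------------------------
# iterative random forest (MAR)
# ---------------------------------------------------------------------------

def impute_forest(
    m: ProteinMatrix,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int | None = None,
) -> ImputationResult:
    """MissForest-style iterative random-forest imputation.

    Proteins are visited in order of increasing missingness; each round a
    random forest regresses the protein on all other (currently
    completed) proteins over its observed rows and refreshes its masked
    cells.  Rounds stop at the first increase of the normalised change
    Δ = Σ(X_new − X_old)² / Σ X_new² over imputed cells — the standard
    stopping rule — returning the values from the round before the
    increase; ``converged`` is False only if ``max_iter`` is exhausted
    before the rule fires.
    """
    _require_observed_per_protein(m, "iterative_forest")
    n, p = m.shape
    if p < 2:
        raise ValueError("iterative-forest imputation needs at least 2 proteins")
    miss = m.mask
    X = m.values.copy()
    col_means = np.nanmean(np.where(miss, np.nan, X), axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])

    order = np.argsort(miss.sum(axis=0), kind="stable")
    targets = [j for j in order if miss[:, j].any()]
    rng = np.random.default_rng(seed)

    prev_delta = np.inf
    rounds = 0
    converged = not targets
    best = X.copy()
    for rounds in range(1, max_iter + 1) if targets else [0]:
        if not targets:
            break
        X_old = X.copy()
        for j in targets:
            obs_rows = ~miss[:, j]
            other = np.delete(np.arange(p), j)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(X[np.ix_(obs_rows, other)], X[obs_rows, j])
            X[miss[:, j], j] = forest.predict(X[np.ix_(miss[:, j], other)])
        num = float(((X[miss] - X_old[miss]) ** 2).sum())
        den = float((X[miss] ** 2).sum()) + 1e-300
        delta = num / den
        if delta >= prev_delta:
            X = best            # revert to the round before the increase
            converged = True
            break
        prev_delta = delta
        best = X.copy()

    return ImputationResult(
        completed=_completed_matrix(m, X),
        method="iterative_forest",
        params={"max_iter": max_iter, "n_trees": n_trees},
        seed=seed,
        n_iterations_run=rounds,
        converged=converged,
    )
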