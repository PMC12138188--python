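"""Maximum-likelihood fitting of the two-feature CCM and the Wald Z-test.

For each feature pair the five free parameters (two intrinsic rates, two
gain/loss asymmetries, one interaction coefficient) are estimated by
maximising the pruning log-likelihood with a quasi-Newton optimiser.
Standard errors come from the inverse observed information (a numerical
Hessian at the optimum); the interaction coefficient divided by its
standard error is the Wald Z statistic, referred to the standard normal
for a two-sided P-value of H0: beta_12 = 0.

Fits that do not converge, or whose curvature is not positive definite,
are flagged rather than patched; so are fits whose |Z| exceeds a cap,
since runaway magnitudes (|Z| in the tens of thousands) indicate a failed
fit, not signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConstantFeatureError, MissingTipError
from .model import (
    CCMParameters,
    TreeIndex,
    build_rate_matrix,
    pruning_log_likelihood,
)

#: Default cap on |Z| beyond which a fit is marked invalid.
DEFAULT_Z_CAP = 100.0


@dataclass(frozen=True)
class FitResult:
    """Outcome of one pairwise CCM fit."""

    estimates: CCMParameters
    log_likelihood: float
    standard_errors: tuple[float, ...] | None
    z_interaction: float
    p_interaction: float
    converged: bool
    valid: bool
    iterations: int
    message: str = ""


def z_to_p(z: float) -> float:
    """Two-sided standard-normal tail probability ``2 * Phi(-|z|)``."""
    z = float(z)
    if not np.isfinite(z):
        raise ValueError(f"Z statistic must be finite, got {z}")
    return float(2.0 * stats.norm.sf(abs(z)))


def _tip_indices_from_profiles(
    index: TreeIndex, profiles: pd.DataFrame
) -> np.ndarray:
    """Joint state index per leaf from two 0/1 columns (column 0 = bit 0)."""
    out = np.empty(index.n_leaves, dtype=np.intp)
    col0 = profiles.iloc[:, 0]
    col1 = profiles.iloc[:, 1]
    for i, label in enumerate(index.leaf_labels):
        if label not in profiles.index:
            raise MissingTipError(f"leaf {label!r} has no profile row")
        out[i] = int(col0[label]) + 2 * int(col1[label])
    return out


def _fitch_changes(index: TreeIndex, leaf_states: np.ndarray) -> int:
    """Parsimony count of 0/1 changes on the tree (Fitch, binary states)."""
    sets = np.zeros(index.n_nodes, dtype=np.uint8)
    sets[: index.n_leaves] = np.uint8(1) << leaf_states.astype(np.uint8)
    changes = 0
    for pos in range(index.left_child.size):
        a = sets[index.left_child[pos]]
        b = sets[index.right_child[pos]]
        inter = a & b
        if inter:
            sets[index.n_leaves + pos] = inter
        else:
            sets[index.n_leaves + pos] = a | b
            changes += 1
    return changes


def _initial_point(index: TreeIndex, tip_idx: np.ndarray) -> np.ndarray:
    """Scale-aware start: alpha from parsimony flips per unit tree length."""
    total = max(index.total_length, 1e-9)
    x0 = np.zeros(5)
    for k in range(2):
        leaf_states = (tip_idx >> k) & 1
        changes = _fitch_changes(index, leaf_states)
        if changes > 0:
            x0[k] = float(np.clip(np.log(changes / total), -3.0, 3.0))
    return x0


def _params_from_vector(theta: np.ndarray) -> CCMParameters:
    return CCMParameters.for_pair(*(float(v) for v in theta))


def _neg_log_likelihood(
    theta: np.ndarray,
    index: TreeIndex,
    tip_idx: np.ndarray,
    root_dist: np.ndarray | None,
    ridge: float,
) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        Q = build_rate_matrix(_params_from_vector(theta))
        if not np.all(np.isfinite(Q)):  # absurd proposals overflow exp
            return 1e12
        ll = pruning_log_likelihood(index, tip_idx, Q, root_dist)
    penalty = ridge * float(np.sum(theta[2:] ** 2)) if ridge else 0.0
    if not np.isfinite(ll):
        return 1e12
    return -ll + penalty


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_ccm(
    tree: dendropy.Tree | TreeIndex,
    profiles: pd.DataFrame,
    *,
    ridge: float = 0.0,
    gtol: float = 1e-6,
    maxiter: int = 500,
    root_dist: np.ndarray | None = None,
    z_cap: float | None = None,
) -> FitResult:
    """Fit the two-feature CCM to a pair of presence/absence profiles.

    Parameters
    ----------
    tree
        Rooted binary tree (or a pre-built :class:`TreeIndex`) whose leaves
        match the profile rows.
    profiles
        DataFrame with exactly two 0/1 columns indexed by genome ID.  Each
        column must contain at least one 0 and one 1; constant columns are
        rejected (the upstream abundance filter normally removes them).
    ridge
        Optional penalty weight on the beta terms; 0 (pure ML) by default.
    z_cap
        When given, the validity screen is applied before returning.
    """
    if profiles.shape[1] != 2:
        raise ValueError("profiles must have exactly two feature columns")
    for name in profiles.columns:
        values = set(profiles[name].astype(int))
        if values != {0, 1}:
            raise ConstantFeatureError(
                f"feature {name!r} is constant across genomes "
                f"(values {sorted(values)}); it cannot be fit"
            )
    index = tree if isinstance(tree, TreeIndex) else TreeIndex.from_tree(tree)
    tip_idx = _tip_indices_from_profiles(index, profiles)

    def nll(theta: np.ndarray) -> float:
        return _neg_log_likelihood(theta, index, tip_idx, root_dist, ridge)

    x0 = _initial_point(index, tip_idx)
    f0 = nll(x0)
    res = optimize.minimize(
        nll, x0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
    )
    theta = res.x
    fun = float(res.fun)
    # BFGS with finite-difference gradients often stops on "precision loss"
    # at what is numerically the optimum; accept when the gradient is small.
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * max(
        1.0, abs(fun)
    )
    converged = bool(res.success or grad_ok)
    if fun > f0 + 1e-9:  # never report a point worse than the start
        theta, fun, converged = x0, f0, False

    estimates = _params_from_vector(theta)
    std_errors: tuple[float, ...] | None = None
    z = np.nan
    p = np.nan
    message = res.message
    if converged:
        try:
            H = _numerical_hessian(nll, theta)
            eigvals = np.linalg.eigvalsh((H + H.T) / 2.0)
            if np.all(eigvals > 0):
                cov = np.linalg.inv((H + H.T) / 2.0)
                diag = np.diag(cov)
                if np.all(diag > 0):
                    std_errors = tuple(float(np.sqrt(d)) for d in diag)
        except np.linalg.LinAlgError:
            std_errors = None
        if std_errors is not None and std_errors[4] > 0:
            z = float(theta[4] / std_errors[4])
            if np.isfinite(z):
                p = z_to_p(z)
        if std_errors is None:
            message = (message + "; " if message else "") + (
                "observed information not positive definite"
            )
    fit = FitResult(
        estimates=estimates,
        log_likelihood=-fun + (ridge * float(np.sum(theta[2:] ** 2)) if ridge else 0.0),
        standard_errors=std_errors,
        z_interaction=z,
        p_interaction=p,
        converged=converged,
        valid=bool(converged and std_errors is not None and np.isfinite(z)),
        iterations=int(res.nit),
        message=message,
    )
    if z_cap is not None:
        fit = validity_screen(fit, z_cap)
    return fit


def validity_screen(fit: FitResult, z_cap: float = DEFAULT_Z_CAP) -> FitResult:
    """Mark fits with runaway |Z|, missing SEs or non-convergence invalid.

    Failed optimisations produce Z magnitudes orders beyond any genuine
    signal; a cap far above plausible values separates the two regimes.
    """
    if z_cap <= 0:
        raise ValueError("z_cap must be positive")
    ok = (
        fit.converged
        and fit.standard_errors is not None
        and np.isfinite(fit.z_interaction)
        and abs(fit.z_interaction) <= z_cap
    )
    if ok == fit.valid:
        return fit if ok else dataclasses.replace(fit, valid=False)
    return dataclasses.replace(fit, valid=ok)
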