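"""Data conditioning: quantile normalization, deconfounding, soft-impute.

The chain is ordered normalize -> deconfound -> impute and the order is
enforced through the matrices' provenance tags.  Quantile normalization
is the rank-based inverse Gaussian transform with Blom offsets,
Phi^{-1}((rank - 3/8)/(n + 1/4)), with average ranks for ties; it makes
every variable's margin Gaussian so that Pearson screening and CCA are
insensitive to the wildly different raw scales (latencies, volumes,
counts).  Deconfounding replaces each variable by its least-squares
residual on an intercept plus the five nuisance covariates, fitted on
the rows where that variable is observed.  Soft-impute completes the
matrix by alternating SVD reconstruction with soft-thresholded singular
values and restoration of the observed cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ConfoundSet, SubjectMatrix

BLOM_A = 0.375  # (3/8, 1/4) offsets: quantiles bounded away from 0 and 1


class ConstantVariableWarning(UserWarning):
    pass


def inverse_normal_transform(values, mask=None):
    """Rank-based inverse Gaussian transform of one variable.

    Masked entries stay masked; observed entries are replaced by
    Phi^{-1}((rank - 3/8)/(n_obs + 1/4)) with average ranks for ties.
    Output is a strictly monotone function of the input ranks.

    Raises
    ------
    ValueError
        Fewer than 3 observed values, or all observed values identical
        (a constant carries no rank information).
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(len(values), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    obs = values[~mask]
    if len(obs) < 3:
        raise ValueError("need >= 3 observed values")
    if np.all(obs == obs[0]):
        raise ValueError("constant variable has no rank information")
    ranks = stats.rankdata(obs, method="average")
    q = (ranks - BLOM_A) / (len(obs) + 1 - 2 * BLOM_A)
    out = np.zeros_like(values)
    out[~mask] = stats.norm.ppf(q)
    return out


def quantile_normalize(m: SubjectMatrix) -> SubjectMatrix:
    """Columnwise inverse-normal transform; constant columns are dropped
    with a warning rather than silently zeroed."""
    m.require_provenance("raw")
    keep, cols = [], []
    out_vals = np.zeros_like(m.values)
    for j, vid in enumerate(m.variables):
        try:
            out_vals[:, j] = inverse_normal_transform(m.values[:, j], m.mask[:, j])
        except ValueError as err:
            warnings.warn(f"dropping {vid!r}: {err}", ConstantVariableWarning)
            continue
        keep.append(j)
        cols.append(vid)
    out = SubjectMatrix(list(m.subjects), cols, out_vals[:, keep],
                        m.mask[:, keep].copy(), "normalized")
    return out


def normalize_confounds(c: ConfoundSet) -> ConfoundSet:
    vals = np.column_stack(
        [inverse_normal_transform(c.values[:, j]) for j in range(c.values.shape[1])]
    )
    return ConfoundSet(list(c.subjects), vals)


@dataclass
class DeconfoundModel:
    """Per-variable least-squares coefficients on [intercept, confounds]."""

    variable_ids: list
    coefficients: np.ndarray          # variables x (1 + n_confounds)
    n_rows_fitted: np.ndarray
    confound_names: tuple = ()
    flagged: list = field(default_factory=list)  # rank-deficient fits


def regress_out(m: SubjectMatrix, c: ConfoundSet):
    """Residualize every variable on the five confounds.

    Each variable is fitted over its own observed rows; the mask is
    preserved.  Confounds should be quantile-normalized first.  If the
    confound matrix is rank-deficient over a variable's rows, the
    residual is computed on the maximal independent column subset and the
    variable is flagged.

    Returns the deconfounded matrix and the fitted :class:`DeconfoundModel`.
    """
    m.require_provenance("normalized")
    if list(c.subjects) != list(m.subjects):
        raise ValueError("confounds and matrix must cover the same subjects")
    n, p = m.shape
    X_full = np.column_stack([np.ones(n), c.values])
    coefs = np.zeros((p, X_full.shape[1]))
    fitted_rows = np.zeros(p, dtype=int)
    flagged = []
    out = m.copy()
    for j in range(p):
        rows = ~m.mask[:, j]
        X = X_full[rows]
        y = m.values[rows, j]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            flagged.append(m.variables[j])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)  # minimum-norm on deficiency
        coefs[j] = beta
        fitted_rows[j] = rows.sum()
        out.values[rows, j] = y - X @ beta
    out.advance_provenance("deconfounded")
    model = DeconfoundModel(list(m.variables), coefs, fitted_rows,
                            tuple(c.names), flagged)
    return out, model


@dataclass
class ImputationState:
    """Diagnostics of one soft-impute run."""

    lambda_: float
    n_iter: int
    converged: bool
    final_change: float
    objective: list = field(default_factory=list)


def _soft_svd(A, lam, rank=None):
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    s_shrunk = np.maximum(s - lam, 0.0)
    if rank is not None:
        s_shrunk[rank:] = 0.0
    return (U * s_shrunk) @ Vt, s


def select_lambda(m: SubjectMatrix, rank_target: int) -> float:
    """Shrinkage level aimed at an effective rank of ``rank_target``:
    the (rank_target + 1)-th singular value of the mean-filled matrix,
    so that shrinkage suppresses everything beyond the target rank."""
    filled, _ = _center_fill(m)
    s = np.linalg.svd(filled, compute_uv=False)
    if rank_target >= len(s):
        return 0.0
    return float(s[rank_target])


def _center_fill(m):
    vals = np.where(m.mask, np.nan, m.values)
    col_mean = np.nanmean(vals, axis=0)
    centered = vals - col_mean
    return np.nan_to_num(centered, nan=0.0), col_mean


def soft_impute(m: SubjectMatrix, lam="auto", tol=1e-6, max_iter=500,
                rank_target=30, rank=None, center=True):
    """Iterative PCA imputation with soft shrinkage of singular values.

    Columns are centered over their observed entries; masked cells start
    at the column mean (zero after centering).  Each iteration computes
    the SVD of the current completion, shrinks every singular value by
    ``lam`` (soft threshold), reconstructs, and restores the observed
    cells.  Iteration stops when the relative Frobenius change of the
    imputed cells falls below ``tol``.

    ``lam="auto"`` picks the shrinkage level whose effective rank is
    about ``rank_target``.  ``rank`` optionally truncates the
    reconstruction to a fixed rank as well (the regularized
    iterative-PCA variant), which is what makes completion with small
    ``lam`` exact on genuinely low-rank data.  ``center=False`` skips
    the column centering (useful when the uncentered matrix itself is
    the low-rank object).

    Observed cells of the returned matrix are bit-equal to the input;
    the matrix is fully observed.

    Returns the completed :class:`SubjectMatrix` and an
    :class:`ImputationState` with convergence diagnostics.
    """
    m.require_provenance("normalized", "deconfounded")
    if (m.n_observed() < 2).any():
        raise ValueError("every column needs >= 2 observed entries")
    if lam == "auto":
        lam = select_lambda(m, rank_target)
    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    if center:
        filled, col_mean = _center_fill(m)
    else:
        filled = np.where(m.mask, 0.0, m.values)
        col_mean = np.zeros(m.shape[1])
    obs = ~m.mask
    if not m.mask.any():
        out = m.copy()
        out.advance_provenance("imputed")
        return out, ImputationState(lam, 0, True, 0.0, [])

    centered_obs = filled[obs]
    state = ImputationState(lam, 0, False, np.inf, [])
    current = filled
    prev_missing = current[m.mask]
    for it in range(1, max_iter + 1):
        recon, s = _soft_svd(current, lam, rank)
        nxt = current.copy()
        nxt[m.mask] = recon[m.mask]
        nxt[obs] = centered_obs
        # objective: 1/2 sum_obs (resid^2) + lam * nuclear norm of recon
        resid = (recon - nxt)[obs]
        s_recon = np.maximum(s - lam, 0.0)
        state.objective.append(0.5 * float((resid**2).sum()) + lam * float(s_recon.sum()))
        new_missing = nxt[m.mask]
        denom = max(np.linalg.norm(prev_missing), 1e-12)
        change = np.linalg.norm(new_missing - prev_missing) / denom
        state.n_iter = it
        state.final_change = float(change)
        current = nxt
        prev_missing = new_missing
        if change < tol:
            state.converged = True
            break
    if not state.converged:
        warnings.warn(f"soft_impute: no convergence in {max_iter} iterations "
                      f"(last relative change {state.final_change:.2e})")

    completed = current + col_mean
    completed[obs] = m.values[obs]  # bit-exact restoration
    out = SubjectMatrix(list(m.subjects), list(m.variables), completed,
                        np.zeros_like(m.mask), m.provenance)
    out.advance_provenance("imputed")
    return out, state
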