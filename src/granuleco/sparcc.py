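"""SparCC: correlation inference for compositional count data.

Read counts only carry relative information, so naive correlations between
relative abundances are biased by the closure. SparCC works from the
log-ratio variances t_ij = Var(log(x_i/x_j)), which are invariant to the
closure, and solves for basis variances w_i under the sparsity
approximation that the average basis correlation is ~0:

    t_ij = w_i + w_j - 2 r_ij sqrt(w_i w_j),   sum_j r_ij ~ 0
    => sum_{j != i} t_ij = (p - 2) w_i + sum_j w_j.

Strongly correlated pairs violate the approximation, so the most correlated
pair above a threshold is iteratively excluded from the linear system and
the basis is re-solved. Fractions are drawn from a Dirichlet posterior
(counts + 1) and the point estimate is the median correlation over the
inner draws. Pseudo p-values come from a permutation bootstrap that
shuffles each ASV's counts independently across samples.
"""
from __future__ import annotations

import numpy as np

__all__ = ["sparcc_correlations", "sparcc_basis_correlations"]


def _log_ratio_variance_matrix(frac: np.ndarray) -> np.ndarray:
    """t_ij = Var(log(x_i/x_j)) from an n x p fraction matrix."""
    logf = np.log(frac)
    v = logf.var(axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _solve_basis(t_work: np.ndarray, m_diag: np.ndarray) -> np.ndarray:
    """Solve the SparCC linear system for basis variances.

    ``m_diag`` tracks per-component pair exclusions: the system matrix is
    all-ones with diagonal ``m_diag`` (p-1 when nothing is excluded).
    """
    p = t_work.shape[0]
    m = np.ones((p, p))
    np.fill_diagonal(m, m_diag)
    w = np.linalg.solve(m, t_work.sum(axis=1))
    # the sparsity approximation can yield non-positive variances for weak
    # components; their correlations are unidentifiable in this draw and
    # are masked out (the median over Dirichlet draws absorbs the loss)
    pos = w > 0
    if not pos.any():
        raise ValueError("basis variance system has no positive solution")
    repaired = ~pos
    if repaired.any():
        w = w.copy()
        w[repaired] = w[pos].min()
    return w, repaired


def sparcc_basis_correlations(
    t: np.ndarray,
    n_exclude_iter: int = 10,
    exclude_threshold: float = 0.1,
) -> np.ndarray:
    """Basis correlations from one log-ratio variance matrix.

    Runs up to ``n_exclude_iter`` rounds of excluding the most correlated
    remaining pair whose |r| exceeds ``exclude_threshold``; components
    reduced to fewer than 3 usable pairs stop being excluded further.
    """
    p = t.shape[0]
    if p < 4:
        raise ValueError("SparCC needs at least 4 components")
    t_work = t.copy()
    m_diag = np.full(p, float(p - 1))
    excluded = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(excluded, True)
    r = None
    repaired = np.zeros(p, dtype=bool)
    for _ in range(n_exclude_iter + 1):
        w, repaired = _solve_basis(t_work, m_diag)
        sq = np.sqrt(np.outer(w, w))
        r = (w[:, None] + w[None, :] - t) / (2.0 * sq)
        np.fill_diagonal(r, 1.0)
        cand = np.abs(np.where(excluded, 0.0, r))
        cand[repaired, :] = 0.0
        cand[:, repaired] = 0.0
        # a component may lose only a small share of its pairs, otherwise
        # the shrinking system drives its basis variance to a runaway
        max_loss = max(2.0, 0.1 * (p - 1))
        frozen = m_diag <= (p - 1) - max_loss
        cand[frozen, :] = 0.0
        cand[:, frozen] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclude_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        t_work[i, j] = t_work[j, i] = 0.0
        m_diag[i] -= 1.0
        m_diag[j] -= 1.0
    r = np.clip(r, -1.0, 1.0)
    if repaired.any():
        r[repaired, :] = np.nan
        r[:, repaired] = np.nan
        np.fill_diagonal(r, 1.0)
    return r


def _point_estimate(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_inner: int,
    n_exclude_iter: int,
    exclude_threshold: float,
    blocks=None,
) -> np.ndarray:
    n, p = counts.shape
    rs = np.empty((n_inner, p, p))
    for k in range(n_inner):
        frac = rng.standard_gamma(counts + 1.0)
        if blocks is None:
            frac /= frac.sum(axis=1, keepdims=True)
        else:
            for sl in blocks:
                frac[:, sl] /= frac[:, sl].sum(axis=1, keepdims=True)
        t = _log_ratio_variance_matrix(frac)
        rs[k] = sparcc_basis_correlations(t, n_exclude_iter, exclude_threshold)
    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # all-NaN slices -> NaN
            r = np.nanmedian(rs, axis=0)
    np.fill_diagonal(r, 1.0)
    return r


def sparcc_correlations(
    counts: np.ndarray,
    n_inner: int = 20,
    n_exclude_iter: int = 10,
    exclude_threshold: float = 0.1,
    n_boot: int = 100,
    n_inner_boot: int = 5,
    seed: int | None = None,
    blocks=None,
) -> tuple[np.ndarray, np.ndarray]:
    """SparCC correlation matrix and bootstrap pseudo p-values.

    Parameters
    ----------
    counts : ndarray (n_samples, n_asvs)
        Integer read counts.
    n_inner : int
        Dirichlet posterior draws for the point estimate (median over draws).
    n_exclude_iter, exclude_threshold :
        Strong-pair exclusion rounds and threshold of the sparsity solver.
    n_boot : int
        Permutation bootstraps for p-values; each shuffles every ASV column
        independently across samples. ``n_boot=0`` skips p-values.
    n_inner_boot : int
        Dirichlet draws per bootstrap replicate (smaller than ``n_inner``
        because only the null |r| distribution is needed).
    seed : int
        RNG seed; the whole computation is deterministic per seed.
    blocks : sequence of slices, optional
        Close each column block separately in the Dirichlet draw (used for
        the inter-kingdom case where the two kingdoms were sequenced as
        separate compositions).

    Returns
    -------
    (r, p) : correlation matrix in [-1, 1] and two-sided pseudo p-values
        with the (B+1) convention; both symmetric, unit/zero diagonal.
    """
    counts = np.asarray(counts)
    n, p = counts.shape
    if n < 10:
        raise ValueError("SparCC needs at least 10 samples")
    if p < 4:
        raise ValueError("SparCC needs at least 4 ASVs")
    rng = np.random.default_rng(seed)
    r = _point_estimate(
        counts, rng, n_inner, n_exclude_iter, exclude_threshold, blocks
    )
    if n_boot <= 0:
        return r, np.full((p, p), np.nan)
    exceed = np.zeros((p, p))
    for _ in range(n_boot):
        shuffled = counts.copy()
        for j in range(p):
            shuffled[:, j] = shuffled[rng.permutation(n), j]
        r_null = _point_estimate(
            shuffled, rng, n_inner_boot, n_exclude_iter, exclude_threshold, blocks
        )
        with np.errstate(invalid="ignore"):
            exceed += np.nan_to_num(np.abs(r_null), nan=-1.0) >= np.abs(r) - 1e-12
    pval = (exceed + 1.0) / (n_boot + 1.0)
    pval[np.isnan(r)] = np.nan
    np.fill_diagonal(pval, 0.0)
    return r, pval
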