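"""Distance-based RDA, permutation forward selection and variance partitioning.

Community succession is related to explanatory variables by distance-based
redundancy analysis (dbRDA): the dissimilarity matrix (Bray-Curtis by
default) is embedded by principal coordinates analysis (Gower
double-centering), and the positive-eigenvalue site coordinates are
regressed on the predictors. Explained variation is reported as R^2 =
constrained inertia / total positive inertia and as Ezekiel-adjusted R^2;
significance comes from permuting sample rows. Predictor sets are chosen by
greedy forward selection with permutation tests, and the explained
variation is decomposed into unique and shared fractions of three
explanatory sets (abiotic, biotic, stage) by inclusion-exclusion on
adjusted R^2 over the seven possible models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pcoa",
    "OrdinationResult",
    "dbrda",
    "forward_select_predictors",
    "VarPartResult",
    "variance_partition",
]


def pcoa(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix.

    Gower double-centering followed by eigendecomposition. Returns
    ``(coordinates, eigenvalues)`` with eigenvalues in non-increasing order
    (negative ones reported, not used for coordinates) and coordinates on
    the positive-eigenvalue axes scaled by sqrt(eigenvalue).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-10, 1e-10 * abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return coords, eigval


def _design_matrix(predictors: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Standardized numeric design: z-scored columns, dummies for categoricals."""
    if predictors.shape[1] == 0:
        return np.empty((len(predictors), 0)), []
    cols, names = [], []
    for c in predictors.columns:
        col = predictors[c]
        if np.issubdtype(col.dtype, np.number):
            v = col.to_numpy(dtype=float)
            if np.any(~np.isfinite(v)):
                raise ValueError(f"missing values in predictor {c!r}")
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
            names.append(c)
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(f"{c}[{dc}]")
    return np.column_stack(cols), names


def _aliased_columns(x: np.ndarray, names: list) -> list:
    """Columns that do not increase the design rank (greedy scan)."""
    aliased, basis = [], np.empty((x.shape[0], 0))
    rank = 0
    for k in range(x.shape[1]):
        trial = np.column_stack([basis, x[:, k]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            basis, rank = trial, r
        else:
            aliased.append(names[k])
    return aliased


@dataclass
class OrdinationResult:
    """dbRDA fit summary."""

    site_scores: np.ndarray  # constrained site coordinates
    eigenvalues: np.ndarray  # all PCoA eigenvalues (negatives reported)
    r2: float
    adj_r2: float
    p_value: float
    n_perm: int
    rank: int


def _fit_stats(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(constrained SS, residual SS) of centered response y on centered x."""
    total = float((y**2).sum())
    if x.shape[1] == 0:
        return 0.0, total
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    ss_c = float((fitted**2).sum())
    return ss_c, total - ss_c


def dbrda(
    dist: np.ndarray,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> OrdinationResult:
    """Distance-based redundancy analysis.

    PCoA site coordinates (positive axes) are regressed on the standardized
    predictor matrix; R^2 = constrained inertia / total positive inertia,
    adjusted by Ezekiel's formula; the p-value permutes the sample rows of
    the predictors with the (B+1) convention. Rank-deficient designs raise
    an error naming the aliased columns.
    """
    coords, eigval = pcoa(dist)
    y = coords - coords.mean(axis=0)
    x, names = _design_matrix(predictors)
    n = y.shape[0]
    if x.shape[1] > 0:
        if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
            raise ValueError(
                f"collinear predictors, aliased: {_aliased_columns(x - x.mean(axis=0), names)}"
            )
        x = x - x.mean(axis=0)
    m = x.shape[1]
    ss_c, ss_r = _fit_stats(y, x)
    total = ss_c + ss_r
    r2 = ss_c / total if total > 0 else 0.0
    if m == 0:
        return OrdinationResult(np.zeros((n, 0)), eigval, 0.0, 0.0, 1.0, 0, 0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m) if n - 1 - m > 0 else np.nan
    f_obs = (ss_c / m) / (ss_r / (n - 1 - m)) if ss_r > 0 else np.inf
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        ss_cp, ss_rp = _fit_stats(y, xp)
        fp = (ss_cp / m) / (ss_rp / (n - 1 - m)) if ss_rp > 0 else np.inf
        if fp >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1.0) / (n_perm + 1.0)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    keep = s > 1e-9
    return OrdinationResult(u[:, keep] * s[keep], eigval, r2, adj, p, n_perm, m)


def _adj_r2(dist_coords: np.ndarray, x: np.ndarray) -> float:
    """Ezekiel-adjusted R^2; df uses the design rank, so collinear columns
    (e.g. the same gradient appearing in two explanatory sets) do not
    inflate the penalty."""
    y = dist_coords
    n = y.shape[0]
    m = int(np.linalg.matrix_rank(x)) if x.shape[1] else 0
    if m == 0:
        return 0.0
    ss_c, ss_r = _fit_stats(y, x)
    r2 = ss_c / (ss_c + ss_r)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)


def forward_select_predictors(
    dist: np.ndarray,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int | None = None,
) -> list:
    """Greedy permutation forward selection of ordination predictors.

    At each step the candidate with the smallest permutation p-value for
    its marginal (partial-F) contribution enters, provided p <= alpha and
    the adjusted R^2 of the model increases; otherwise selection stops.
    With ``alpha=1`` the adjusted-R^2 guard is waived, so every candidate
    eventually enters in order of contribution. Deterministic for a fixed
    seed. May return an empty list.
    """
    if candidates.shape[1] == 0:
        raise ValueError("need at least one candidate")
    coords, _ = pcoa(dist)
    y = coords - coords.mean(axis=0)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    selected: list = []
    while True:
        x_sel, _ = _design_matrix(candidates[selected]) if selected else (
            np.empty((n, 0)),
            [],
        )
        x_sel = x_sel - x_sel.mean(axis=0) if x_sel.shape[1] else x_sel
        adj_now = _adj_r2(y, x_sel)
        best = None
        for c in candidates.columns:
            if c in selected:
                continue
            x_try, _ = _design_matrix(candidates[selected + [c]])
            x_try = x_try - x_try.mean(axis=0)
            if np.linalg.matrix_rank(x_try) < x_try.shape[1]:
                continue
            m_new = x_try.shape[1]
            df_c = m_new - x_sel.shape[1]
            ss_c0, _ = _fit_stats(y, x_sel)
            ss_c1, ss_r1 = _fit_stats(y, x_try)
            denom_df = n - 1 - m_new
            if denom_df <= 0 or ss_r1 <= 0:
                continue
            f_obs = ((ss_c1 - ss_c0) / df_c) / (ss_r1 / denom_df)
            x_c, _ = _design_matrix(candidates[[c]])
            x_c = x_c - x_c.mean(axis=0)
            hits = 0
            for _ in range(n_perm):
                x_p = np.column_stack([x_sel, x_c[rng.permutation(n)]])
                ss_c1p, ss_r1p = _fit_stats(y, x_p)
                fp = ((ss_c1p - ss_c0) / df_c) / (ss_r1p / denom_df)
                if fp >= f_obs - 1e-12:
                    hits += 1
            p = (hits + 1.0) / (n_perm + 1.0)
            adj_new = _adj_r2(y, x_try)
            if best is None or p < best[0] or (p == best[0] and adj_new > best[1]):
                best = (p, adj_new, c)
        if best is None:
            break
        p, adj_new, c = best
        if p <= alpha and (adj_new > adj_now or alpha >= 1.0):
            selected.append(c)
        else:
            break
    return selected


@dataclass
class VarPartResult:
    """Three-set variance partition on adjusted R^2.

    ``fractions`` holds the 7 inclusion-exclusion components plus the
    residual; individual fractions may be negative (adjusted-R^2
    convention); everything sums to 1.
    """

    fractions: dict
    adj_r2_models: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"component": k, "fraction": v} for k, v in self.fractions.items()]
        )


def variance_partition(
    dist: np.ndarray,
    set_abiotic: pd.DataFrame,
    set_biotic: pd.DataFrame,
    set_stage: pd.DataFrame,
    labels=("abiotic", "biotic", "stage"),
) -> VarPartResult:
    """Partition explained variation among three explanatory sets.

    Fits the 7 dbRDA models formed by the non-empty subsets of the three
    sets and decomposes the adjusted R^2 into unique fractions, pairwise
    shared fractions, the triple-shared fraction and the residual.
    """
    sets = {labels[0]: set_abiotic, labels[1]: set_biotic, labels[2]: set_stage}
    for k, v in sets.items():
        if v.shape[1] == 0:
            raise ValueError(f"explanatory set {k!r} is empty")
    coords, _ = pcoa(dist)
    y = coords - coords.mean(axis=0)

    for k, v in sets.items():
        x, names = _design_matrix(v)
        xc = x - x.mean(axis=0)
        if np.linalg.matrix_rank(xc) < xc.shape[1]:
            raise ValueError(
                f"rank-deficient explanatory set {k!r}: aliased "
                f"{_aliased_columns(xc, names)}"
            )

    def adj(cols: list) -> float:
        # combined models tolerate across-set collinearity: the fit is a
        # projection and the df penalty uses the design rank
        df = pd.concat([sets[k] for k in cols], axis=1)
        x, _ = _design_matrix(df)
        return _adj_r2(y, x - x.mean(axis=0))

    a_, b_, c_ = labels
    r = {
        "A": adj([a_]),
        "B": adj([b_]),
        "C": adj([c_]),
        "AB": adj([a_, b_]),
        "AC": adj([a_, c_]),
        "BC": adj([b_, c_]),
        "ABC": adj([a_, b_, c_]),
    }
    ua = r["ABC"] - r["BC"]
    ub = r["ABC"] - r["AC"]
    uc = r["ABC"] - r["AB"]
    sab = r["ABC"] - r["C"] - ua - ub
    sac = r["ABC"] - r["B"] - ua - uc
    sbc = r["ABC"] - r["A"] - ub - uc
    sabc = r["ABC"] - ua - ub - uc - sab - sac - sbc
    fractions = {
        f"{a_}": ua,
        f"{b_}": ub,
        f"{c_}": uc,
        f"{a_}|{b_}": sab,
        f"{a_}|{c_}": sac,
        f"{b_}|{c_}": sbc,
        "all": sabc,
        "residual": 1.0 - r["ABC"],
    }
    return VarPartResult(fractions, r)
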