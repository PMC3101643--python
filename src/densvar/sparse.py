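"""Lasso regression of a base density on ensemble-member densities.

The statistical test at the heart of the package: the base conformer's
electron density over a grid region G is modeled as a (sparse) linear
combination of the members' densities,

    minimize  Σ_g (y_g − Σ_i ω_i x_gi)²  +  λ Σ_i |ω_i|

solved by cyclic coordinate descent with soft-thresholding. Members whose
coefficients vanish (or are insignificant in a post-selection OLS refit)
are labeled truly variable; members with significant nonzero coefficients
are noise variants of the base.

Columns are scaled to unit Euclidean norm before fitting (making λ
comparable across regions); reported weights are on the original scale.
No intercept is used and columns are not centered: densities share a zero
baseline and physical units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("densvar.sparse")

from densvar.structures import Conformer
from densvar.density import DensityGrid, GridRegion, extract_density, fragment_box

KKT_RTOL = 1e-6


@dataclass
class RegressionProblem:
    """y = base density over a region; X columns = member densities there.

    Columns with (near-)zero norm are dropped on construction and recorded
    in ``dropped_labels`` — a member contributing nothing to the region
    cannot be fit there.
    """

    y: np.ndarray
    X: np.ndarray
    member_labels: list[str]
    region: GridRegion | None = None
    dropped_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be (len(y), n_members)")
        if self.X.shape[1] != len(self.member_labels):
            raise ValueError("one label per column required")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one member column")
        norms = np.linalg.norm(self.X, axis=0)
        dead = norms <= 1e-12 * max(norms.max(), 1.0)
        if np.any(dead):
            self.dropped_labels = [
                lab for lab, d in zip(self.member_labels, dead) if d
            ] + self.dropped_labels
            self.member_labels = [lab for lab, d in zip(self.member_labels, dead) if not d]
            self.X = self.X[:, ~dead]
            if self.X.shape[1] == 0:
                raise ValueError("every member column is zero over the region")
            norms = norms[~dead]
        self.col_norms = norms

    @property
    def n_members(self) -> int:
        return self.X.shape[1]

    def scaled_X(self) -> np.ndarray:
        return self.X / self.col_norms

    def lambda_max(self) -> float:
        """Smallest λ at which the all-zero solution is optimal: max|2 x̃ᵢᵀy|."""
        return float(np.max(np.abs(2.0 * self.scaled_X().T @ self.y)))


@dataclass
class LassoFit:
    """Solution of the L1 problem at one λ.

    ``weights`` are on the original column scale; ``weights_scaled`` are the
    coefficients of the unit-norm columns actually optimized (the scale on
    which λ, the objective and the KKT residuals live).
    """

    weights: np.ndarray
    weights_scaled: np.ndarray
    lam: float
    objective: float
    n_iter: int
    converged: bool
    member_labels: list[str]


@dataclass
class RegularizationPath:
    lam_grid: np.ndarray
    weight_matrix: np.ndarray  # (n_lam, n_members), original scale
    l1_ratio: np.ndarray  # |ω̃|₁ / |ω̃(λ→0⁺)|₁
    member_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.lam_grid):
            for j, lab in enumerate(self.member_labels):
                rows.append(
                    {"lam": lam, "member": lab,
                     "weight": self.weight_matrix[i, j], "l1_ratio": self.l1_ratio[i]}
                )
        return pd.DataFrame(rows)


@dataclass
class VariabilityReport:
    """Per-member classification: noise variant vs truly variable."""

    member_labels: list[str]
    weights: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    labels: list[str]  # "noise_variant" | "truly_variable"
    lam: float
    r_squared: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "member": self.member_labels,
                "weight": self.weights,
                "t": self.t_statistics,
                "p": self.p_values,
                "label": self.labels,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "lam": self.lam,
            "alpha": self.alpha,
            "r_squared": self.r_squared,
            "members": self.to_frame().to_dict(orient="records"),
        }

    def n_truly_variable(self) -> int:
        return sum(1 for lab in self.labels if lab == "truly_variable")


@dataclass
class WindowProfile:
    """Per-(residue-or-fragment, member) weights from region-restricted fits."""

    residues: np.ndarray  # center residue index (or fragment start)
    member_labels: list[str]
    weights: np.ndarray  # (n_rows, n_members), original scale
    window_size: int
    lam: float | str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, res in enumerate(self.residues):
            for j, lab in enumerate(self.member_labels):
                rows.append({"residue": int(res), "member": lab,
                             "weight": self.weights[i, j]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------

def build_problem(
    base_map: DensityGrid,
    member_maps: list[DensityGrid],
    region: GridRegion | None = None,
    member_labels: list[str] | None = None,
) -> RegressionProblem:
    """Extract y (base density) and X (member densities) over a region."""
    if not member_maps:
        raise ValueError("need at least one member map")
    for m in member_maps:
        if not base_map.same_layout(m):
            raise ValueError("all maps must share the same cell and grid shape")
    if region is None:
        region = GridRegion.full(base_map.shape)
    y = extract_density(base_map, region)
    X = np.column_stack([extract_density(m, region) for m in member_maps])
    if member_labels is None:
        member_labels = [f"member_{i:02d}" for i in range(len(member_maps))]
    return RegressionProblem(y=y, X=X, member_labels=list(member_labels), region=region)


# ---------------------------------------------------------------------------
# Coordinate-descent solver
# ---------------------------------------------------------------------------

def _soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def _cd_solve(
    gram: np.ndarray,
    xty: np.ndarray,
    lam: float,
    nonneg: bool,
    w0: np.ndarray | None,
    tol: float,
    max_iter: int,
    objective_history: list | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Cyclic coordinate descent on ωᵀGω − 2ωᵀc + λ|ω|₁."""
    k = len(xty)
    w = np.zeros(k) if w0 is None else w0.copy()
    half_lam = lam / 2.0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for i in range(k):
            # partial residual correlation: x̃ᵢᵀ(y − Σ_{j≠i} x̃_j ω_j)
            c_i = xty[i] - gram[i] @ w + gram[i, i] * w[i]
            if nonneg:
                w_new = max(c_i - half_lam, 0.0) / gram[i, i]
            else:
                w_new = _soft_threshold(c_i, half_lam) / gram[i, i]
            delta = abs(w_new - w[i])
            if delta > max_delta:
                max_delta = delta
            w[i] = w_new
        if objective_history is not None:
            objective_history.append(
                float(w @ gram @ w - 2 * w @ xty + lam * np.abs(w).sum())
            )
        if max_delta < tol:
            return w, it, True
    return w, max_iter, False


def lasso_objective(y: np.ndarray, X: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Σ (y − Xω)² + λ Σ|ω| on the arrays as given."""
    resid = y - X @ w
    return float(resid @ resid + lam * np.abs(w).sum())


def lasso_fit(
    p: RegressionProblem,
    lam: float,
    nonneg: bool = False,
    normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    warm_start: np.ndarray | None = None,
    objective_history: list | None = None,
) -> LassoFit:
    """Solve the L1-penalized least-squares problem at one λ.

    With ``normalize=True`` (default) the penalty applies to the unit-norm
    column coefficients; ``weights`` are reported back on the original
    column scale. Non-convergence is reported via ``converged`` rather than
    silently ignored.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    Xs = p.scaled_X() if normalize else p.X
    gram = Xs.T @ Xs
    xty = Xs.T @ p.y
    w, n_iter, converged = _cd_solve(
        gram, xty, lam, nonneg, warm_start, tol, max_iter, objective_history
    )
    obj = float(p.y @ p.y - 2 * w @ xty + w @ gram @ w + lam * np.abs(w).sum())
    weights = w / p.col_norms if normalize else w
    return LassoFit(
        weights=weights, weights_scaled=w, lam=lam, objective=obj,
        n_iter=n_iter, converged=converged, member_labels=list(p.member_labels),
    )


def kkt_violation(p: RegressionProblem, fit: LassoFit, nonneg: bool = False,
                  normalize: bool = True) -> float:
    """Worst stationarity violation, in units of λ_max (0 = certified optimum).

    For ω_i ≠ 0: |2x̃ᵢᵀ(y − X̃ω) − λ·sign(ω_i)| must vanish; for ω_i = 0 the
    correlation |2x̃ᵢᵀ(y − X̃ω)| may not exceed λ.
    """
    Xs = p.scaled_X() if normalize else p.X
    w = fit.weights_scaled
    grad = 2.0 * Xs.T @ (p.y - Xs @ w)
    lam_max = max(p.lambda_max(), 1e-300)
    worst = 0.0
    for i in range(len(w)):
        if nonneg:
            if w[i] > 0:
                worst = max(worst, abs(grad[i] - fit.lam))
            else:
                worst = max(worst, max(grad[i] - fit.lam, 0.0))
        else:
            if w[i] != 0.0:
                worst = max(worst, abs(grad[i] - fit.lam * np.sign(w[i])))
            else:
                worst = max(worst, max(abs(grad[i]) - fit.lam, 0.0))
    return worst / lam_max


def default_lambda_grid(p: RegressionProblem, n: int = 30, ratio: float = 1e-4) -> np.ndarray:
    """Decreasing logarithmic grid from λ_max down to λ_max·ratio."""
    lam_max = p.lambda_max()
    if lam_max <= 0:
        return np.array([1.0, ratio])
    return np.geomspace(lam_max, lam_max * ratio, n)


def regularization_path(
    p: RegressionProblem,
    lam_grid: np.ndarray | None = None,
    nonneg: bool = False,
    tol: float = 1e-10,
) -> RegularizationPath:
    """Warm-started fits along a decreasing λ grid.

    ``l1_ratio`` normalizes |ω̃|₁ by its value at λ → 0⁺ (fit at a tiny λ).
    """
    if lam_grid is None:
        lam_grid = default_lambda_grid(p)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(np.diff(lam_grid) >= 0) or np.any(lam_grid <= 0):
        raise ValueError("lam_grid must be strictly decreasing and positive")
    weights = np.zeros((len(lam_grid), p.n_members))
    l1 = np.zeros(len(lam_grid))
    warm = None
    for i, lam in enumerate(lam_grid):
        fit = lasso_fit(p, lam, nonneg=nonneg, tol=tol, warm_start=warm)
        warm = fit.weights_scaled
        weights[i] = fit.weights
        l1[i] = np.abs(fit.weights_scaled).sum()
    ref_fit = lasso_fit(p, max(p.lambda_max() * 1e-10, 1e-300), nonneg=nonneg,
                        tol=tol, warm_start=warm)
    ref = np.abs(ref_fit.weights_scaled).sum()
    l1_ratio = l1 / ref if ref > 0 else np.zeros_like(l1)
    return RegularizationPath(
        lam_grid=lam_grid, weight_matrix=weights,
        l1_ratio=np.clip(l1_ratio, 0.0, 1.0), member_labels=list(p.member_labels),
    )


def cv_lambda(
    p: RegressionProblem,
    k: int = 5,
    lam_grid: np.ndarray | None = None,
    seed: int = 0,
    nonneg: bool = False,
    tol: float = 1e-8,
    rule: str = "1se",
) -> float:
    """Select λ by seeded row-wise k-fold cross-validation.

    ``rule="1se"`` (default) returns the largest λ whose mean held-out
    squared error is within one standard error of the minimum — the
    standard sparsity-favoring choice, needed here because the CV curve is
    nearly flat over decades of λ (grid points of a smooth density are far
    from independent, so the raw minimum systematically under-penalizes).
    ``rule="min"`` returns the error-minimizing λ, ties broken toward the
    larger (sparser) value.
    """
    n = len(p.y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("more folds than rows")
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    if lam_grid is None:
        lam_grid = default_lambda_grid(p)
    lam_grid = np.asarray(lam_grid, dtype=float)
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(n) % k)
    Xs = p.scaled_X()
    err = np.zeros((k, len(lam_grid)))
    for f in range(k):
        test = fold == f
        train = ~test
        Xtr, ytr = Xs[train], p.y[train]
        gram = Xtr.T @ Xtr
        xty = Xtr.T @ ytr
        warm = None
        for i, lam in enumerate(lam_grid):
            w, _, _ = _cd_solve(gram, xty, lam, nonneg, warm, tol, 100_000)
            warm = w
            resid = p.y[test] - Xs[test] @ w
            err[f, i] = resid @ resid / test.sum()
    mean_err = err.mean(axis=0)
    log.debug("CV curve: %s", np.array2string(mean_err, precision=4))
    best = int(np.argmin(mean_err))
    if rule == "min":
        ok = mean_err <= mean_err[best] * (1 + 1e-9) + 1e-300
    else:
        se = err.std(axis=0, ddof=1)[best] / np.sqrt(k)
        ok = mean_err <= mean_err[best] + se
    return float(lam_grid[np.argmax(ok)])  # grid is decreasing: first ok = largest λ


# ---------------------------------------------------------------------------
# Post-selection inference and classification
# ---------------------------------------------------------------------------

def coef_significance(
    p: RegressionProblem, support: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS refit on the support columns; per-member (t, p) and uncentered R².

    Members off-support get t = 0, p = 1. Collinear support columns are
    dropped from the refit (pivoted-QR rank detection) and treated as
    off-support. No intercept (densities have a zero baseline).
    """
    support = np.asarray(support, dtype=bool)
    if support.shape != (p.n_members,):
        raise ValueError("support mask must have one entry per member")
    n = len(p.y)
    t_stats = np.zeros(p.n_members)
    p_values = np.ones(p.n_members)
    if not np.any(support):
        return t_stats, p_values, 0.0
    idx = np.flatnonzero(support)
    Xs = p.scaled_X()[:, idx]
    Q, R = np.linalg.qr(Xs, mode="reduced")
    diag = np.abs(np.diag(R))
    keep_local = diag > 1e-10 * max(diag.max(), 1.0)
    if not np.all(keep_local):
        idx = idx[keep_local]
        Xs = p.scaled_X()[:, idx]
        Q, R = np.linalg.qr(Xs, mode="reduced")
    k = len(idx)
    if k >= n:
        raise ValueError("support size must be smaller than the number of rows")
    beta = np.linalg.solve(R, Q.T @ p.y)
    resid = p.y - Xs @ beta
    rss = float(resid @ resid)
    dof = n - k
    sigma2 = rss / dof
    Rinv = np.linalg.solve(R, np.eye(k))
    var_beta = sigma2 * np.sum(Rinv**2, axis=1)
    se = np.sqrt(np.maximum(var_beta, 1e-300))
    t_local = beta / se
    p_local = 2.0 * stats.t.sf(np.abs(t_local), dof)
    t_stats[idx] = t_local
    p_values[idx] = p_local
    tss = float(p.y @ p.y)
    r_squared = 1.0 - rss / tss if tss > 0 else 0.0
    return t_stats, p_values, r_squared


def classify_ensemble(
    base_map: DensityGrid,
    member_maps: list[DensityGrid],
    region: GridRegion | None = None,
    lam: float | str = "cv",
    alpha: float = 0.05,
    nonneg: bool = False,
    seed: int = 0,
    member_labels: list[str] | None = None,
    weight_rel_tol: float = 0.1,
) -> VariabilityReport:
    """Full statistical test: Lasso fit, refit t-test, per-member labels.

    A member is a "noise_variant" iff its coefficient survives the L1
    penalty (ω_i ≠ 0), its post-selection p-value is ≤ alpha, AND its
    coefficient is non-negligible (|ω̃_i| ≥ weight_rel_tol · max|ω̃|);
    otherwise it is "truly_variable". The relative-magnitude condition
    implements "ω approaches zero": with tens of thousands of (spatially
    correlated) grid points, the refit t-test will certify even a
    coefficient two orders of magnitude below the dominant one.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = build_problem(base_map, member_maps, region, member_labels)
    if lam == "cv":
        lam_val = cv_lambda(p, seed=seed, nonneg=nonneg)
    else:
        lam_val = float(lam)
    fit = lasso_fit(p, lam_val, nonneg=nonneg)
    support = fit.weights_scaled != 0.0
    t_stats, p_values, r_squared = coef_significance(p, support)
    w_abs = np.abs(fit.weights_scaled)
    w_floor = weight_rel_tol * (w_abs.max() if w_abs.size else 0.0)
    labels = [
        "noise_variant" if (s and pv <= alpha and wa >= w_floor) else "truly_variable"
        for s, pv, wa in zip(support, p_values, w_abs)
    ]
    # members dropped at problem construction contributed nothing: variable
    all_labels = list(p.member_labels) + list(p.dropped_labels)
    n_drop = len(p.dropped_labels)
    return VariabilityReport(
        member_labels=all_labels,
        weights=np.concatenate([fit.weights, np.zeros(n_drop)]),
        t_statistics=np.concatenate([t_stats, np.zeros(n_drop)]),
        p_values=np.concatenate([p_values, np.ones(n_drop)]),
        labels=labels + ["truly_variable"] * n_drop,
        lam=lam_val,
        r_squared=r_squared,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Windowed / fragment analyses
# ---------------------------------------------------------------------------

def _region_fit_row(
    base_conf: Conformer,
    base_map: DensityGrid,
    member_maps: list[DensityGrid],
    res_range: tuple[int, int],
    margin: float,
    lam: float | str,
    nonneg: bool,
    member_labels: list[str],
    seed: int,
) -> np.ndarray:
    region = fragment_box(base_conf, res_range, margin, base_map)
    p = build_problem(base_map, member_maps, region, member_labels)
    lam_val = cv_lambda(p, seed=seed, nonneg=nonneg) if lam == "cv" else float(lam)
    fit = lasso_fit(p, lam_val, nonneg=nonneg)
    row = np.zeros(len(member_labels))
    pos = {lab: j for j, lab in enumerate(member_labels)}
    for lab, w in zip(fit.member_labels, fit.weights):
        row[pos[lab]] = w
    return row  # dropped members keep weight 0


def windowed_profile(
    base_conf: Conformer,
    base_map: DensityGrid,
    member_maps: list[DensityGrid],
    window: int = 3,
    margin: float = 2.0,
    lam: float | str = 10.0,
    nonneg: bool = False,
    member_labels: list[str] | None = None,
    seed: int = 0,
) -> WindowProfile:
    """Per-residue Lasso over sliding windows centered on each residue.

    The region for residue r is the bounding box (plus margin) of residues
    [r − window//2, r + window//2], clipped at chain ends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if member_labels is None:
        member_labels = [f"member_{i:02d}" for i in range(len(member_maps))]
    residues = np.unique(base_conf.residue_indices)
    half = window // 2
    rows = []
    for r in residues:
        lo = max(int(residues.min()), int(r) - half)
        hi = min(int(residues.max()), int(r) + half)
        rows.append(
            _region_fit_row(base_conf, base_map, member_maps, (lo, hi), margin,
                            lam, nonneg, member_labels, seed)
        )
    return WindowProfile(
        residues=residues, member_labels=list(member_labels),
        weights=np.array(rows), window_size=window, lam=lam,
    )


def fragment_profile(
    base_conf: Conformer,
    base_map: DensityGrid,
    member_maps: list[DensityGrid],
    fragment_size: int = 4,
    margin: float = 2.0,
    lam: float | str = 10.0,
    nonneg: bool = False,
    member_labels: list[str] | None = None,
    seed: int = 0,
) -> WindowProfile:
    """Chain split into consecutive fragments, one Lasso per fragment."""
    if fragment_size < 1:
        raise ValueError("fragment_size must be >= 1")
    if member_labels is None:
        member_labels = [f"member_{i:02d}" for i in range(len(member_maps))]
    residues = np.unique(base_conf.residue_indices)
    starts = residues[::fragment_size]
    rows = []
    for s in starts:
        lo = int(s)
        hi = min(int(residues.max()), lo + fragment_size - 1)
        rows.append(
            _region_fit_row(base_conf, base_map, member_maps, (lo, hi), margin,
                            lam, nonneg, member_labels, seed)
        )
    return WindowProfile(
        residues=starts, member_labels=list(member_labels),
        weights=np.array(rows), window_size=fragment_size, lam=lam,
    )


def average_weight(profile: WindowProfile) -> np.ndarray:
    """Mean weight per member over all rows (residues or fragments)."""
    if profile.weights.size == 0:
        raise ValueError("empty profile")
    return profile.weights.mean(axis=0)
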