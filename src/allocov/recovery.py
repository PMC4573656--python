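"""Recovery of missing fit statistics for allometric biomass equations.

Many published biomass equations report only a sample size n and a
coefficient of determination R², yet the model-error variance of a biomass
prediction needs the residual variance sigma_e² and the q x q covariance
matrix of the estimated coefficients.  The procedures here construct
*substitutes* for those missing statistics by resampling the explanatory
variables (DBH, HT) from an inventory sample of the population the
equation will be applied to:

basic
    For each of B without-replacement samples of size n, set
    sigma2_b = V(predictions) * (1/R² - 1) and cov_b = sigma2_b (FᵗF)⁻¹
    with F the gradient matrix on the sample; average over B.
refit
    A parametric bootstrap: pseudo-responses y* = f(x|b) + e* with e*
    drawn from a scaled t-distribution with n-q degrees of freedom,
    re-estimate the coefficients by (iterative) least squares, average the
    per-fit covariance matrices.  If any pseudo-response would be negative
    (impossible for biomass), the replicate switches to multiplicative
    gamma residuals with mean 1 and variance 1/nu, nu chosen so the total
    variance matches what additive residuals would have produced.
robust
    A sandwich form (FᵗF)⁻¹ (Σ e_i² g_i g_iᵗ) (FᵗF)⁻¹ with simulated
    residuals from a heavy-tailed t-distribution with floor(0.5 n) degrees
    of freedom, guarding against a mismatch between the (unknown) fitting
    sample and the target population.

Weighted variants replace FᵗF by FᵗWF with diagonal sum-to-one weights
w_j proportional to 1/DBH_j² (or user-supplied inclusion weights),
mirroring a weighted original fit.

The three procedures are exposed both as scikit-learn style estimators
(``BasicRecovery().fit(trees)`` with trailing-underscore fitted
attributes) and as plain functions returning :class:`RecoveredStats`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .equations import (
    BASIS_FUNCTIONS,
    BiomassEquation,
    FitStats,
    TreeRecord,
    _fitted_values,
    _gradient_rows,
    trees_to_arrays,
)
from .exceptions import (
    ConvergenceError,
    DegenerateSampleError,
    InputError,
    NoSolutionError,
    SingularDesignError,
    UnsupportedCaseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryConfig",
    "RecoveredStats",
    "BasicRecovery",
    "RefitRecovery",
    "RobustRecovery",
    "recover_residual_variance",
    "basic_recovery",
    "weighted_recovery",
    "refit_recovery",
    "robust_recovery",
    "solve_gamma_nu",
    "offdiagonal_recovery",
    "mc_error_monitor",
    "make_psd",
    "least_squares_refit",
]

CONDITION_WARN_THRESHOLD = 1e8


@dataclass(frozen=True)
class RecoveryConfig:
    """Settings shared by the recovery procedures.

    B is the number of resampling replicates (800 keeps the Monte Carlo
    error in the determinant of the recovered covariance matrix below
    about 4 %).  ``n`` overrides the fitting sample size to emulate
    (defaults to the published n).  The same seed and config always
    reproduce byte-identical results; per-replicate random substreams are
    spawned from the root seed so increasing B extends, rather than
    reshuffles, the replicate sequence.
    """

    B: int = 800
    n: int | None = None
    method: str = "basic"
    weighted: bool = False
    seed: int = 0
    max_redraws: int = 10
    max_failure_frac: float = 0.05

    def __post_init__(self):
        if self.B < 1:
            raise InputError(f"B must be >= 1, got {self.B}")
        if self.method not in ("basic", "refit", "robust"):
            raise InputError(f"unknown method {self.method!r}")


@dataclass
class RecoveredStats:
    """Substitute fit statistics produced by a recovery procedure.

    ``sigma2_resid`` and ``cov`` live on the fitted scale of the equation
    (log scale for log-linear equations).  ``mc_error_det_pct`` is the
    relative standard error (%) of the B-average determinant of the
    recovered covariance matrix, the Monte Carlo convergence monitor.
    """

    sigma2_resid: float
    cov: np.ndarray
    B_used: int
    mc_error_det_pct: float
    method: str
    condition_number: float
    repair_count: int = 0
    gamma_fallback_count: int = 0
    per_replicate_dets: np.ndarray | None = field(default=None, repr=False)


def recover_residual_variance(eq: BiomassEquation, trees: Sequence[TreeRecord],
                              r_squared: float) -> float:
    """Substitute residual variance from predictions and R² on one sample.

    sigma2 = V(f(x|b)) * (1/R² - 1), with V the n-1 denominator sample
    variance of the predictions on the fitted scale.  At R²=1 the
    recovered variance is zero; it grows without bound as R² -> 0.
    """
    if len(trees) < 2:
        raise InputError("need at least 2 trees to recover a residual variance")
    if not 0 < r_squared <= 1:
        raise InputError(f"r_squared must be in (0, 1], got {r_squared!r}")
    preds = _predict_fitted(eq, *trees_to_arrays(trees))
    return _sigma2_from_preds(preds, r_squared)


def _predict_fitted(eq, dbh, ht):
    from .equations import _require_inputs

    _require_inputs(eq, dbh, ht)
    return _fitted_values(eq, dbh, ht)


def _sigma2_from_preds(preds: np.ndarray, r_squared: float) -> float:
    v = float(np.var(preds, ddof=1))
    if v == 0.0:
        raise DegenerateSampleError("zero prediction variance: all trees identical")
    return v * (1.0 / r_squared - 1.0)


def solve_gamma_nu(pred_mean: float, pred_var: float, target_var: float) -> float:
    """Shape nu of a mean-1 gamma multiplicative error matching a target variance.

    Solves V(y_hat * e) = V(y_hat) + nu⁻¹ (mean(y_hat)² + V(y_hat)) for nu,
    a first-order approximation to the exact product-variance formula
    (which has no real-valued solution in typical biomass settings).
    """
    if not pred_var > 0:
        raise InputError(f"pred_var must be > 0, got {pred_var!r}")
    if not target_var > pred_var:
        raise NoSolutionError(
            f"no real-valued nu: target_var ({target_var!r}) must exceed "
            f"pred_var ({pred_var!r})")
    return (pred_mean**2 + pred_var) / (target_var - pred_var)


def make_psd(matrix: np.ndarray) -> tuple[np.ndarray, bool]:
    """Symmetrize and clip negative eigenvalues to zero; report whether repaired."""
    sym = 0.5 * (matrix + matrix.T)
    w, V = np.linalg.eigh(sym)
    tol = -1e-12 * max(1.0, float(np.max(np.abs(w))))
    if np.all(w >= tol):
        return sym, bool(np.any(np.abs(matrix - matrix.T) > 1e-12 * np.max(np.abs(matrix) + 1e-300)))
    repaired = (V * np.clip(w, 0.0, None)) @ V.T
    return 0.5 * (repaired + repaired.T), True


def mc_error_monitor(per_replicate_covs_or_dets) -> float:
    """Monte Carlo error (%) of the B-average determinant of the recovered matrix.

    Defined as 100 * [SD of per-replicate determinants / sqrt(B)] divided by
    the absolute mean determinant: the relative standard error of the
    B-average.  Accepts a list of q x q matrices or a vector of
    precomputed determinants.
    """
    arr = np.asarray(per_replicate_covs_or_dets, dtype=float)
    dets = np.linalg.det(arr) if arr.ndim == 3 else arr
    if dets.size < 2:
        raise InputError("need at least 2 replicates for a Monte Carlo error")
    mean = float(np.mean(dets))
    if mean == 0.0:
        raise InputError("mean determinant is zero; Monte Carlo error undefined")
    return 100.0 * float(np.std(dets, ddof=1)) / np.sqrt(dets.size) / abs(mean)


def _normalized_weights(eq: BiomassEquation, dbh: np.ndarray,
                        inclusion_weights: np.ndarray | None = None) -> np.ndarray:
    """Sum-to-one diagonal weights: 1/DBH² rule or inverse inclusion probability."""
    if inclusion_weights is not None:
        w = np.asarray(inclusion_weights, dtype=float)
        if np.any(w <= 0):
            raise InputError("inclusion weights must be positive")
    else:
        w = dbh**-2.0
    return w / w.sum()


def _inverse_with_cond(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Invert a symmetric normal-equations matrix via SVD, returning cond₂."""
    U, s, Vt = np.linalg.svd(A)
    if s[-1] <= max(A.shape) * np.finfo(float).eps * s[0]:
        raise SingularDesignError(
            "singular normal-equations matrix in replicate",
            condition_number=float(s[0] / s[-1]) if s[-1] > 0 else float("inf"))
    return (Vt.T / s) @ U.T, float(s[0] / s[-1])


class _BaseRecoveryEstimator(BaseEstimator):
    """Shared resampling loop for the three recovery procedures.

    Parameters follow sklearn conventions: stored verbatim at construction,
    validated in :meth:`fit`.  ``fit`` takes the inventory tree list (the
    population to resample from, with any trees used to fit the original
    equation already excluded) and sets

    - ``sigma2_resid_`` : recovered residual variance (fitted scale),
    - ``cov_`` : recovered q x q coefficient covariance matrix (PSD),
    - ``mc_error_det_pct_`` : Monte Carlo error monitor,
    - ``condition_number_``, ``repair_count_``, ``B_used_``.
    """

    method: str = ""

    def __init__(self, equation: BiomassEquation = None, fit_stats: FitStats = None,
                 B: int = 800, n: int | None = None, weighted: bool = False,
                 seed: int = 0, max_redraws: int = 10, max_failure_frac: float = 0.05):
        self.equation = equation
        self.fit_stats = fit_stats
        self.B = B
        self.n = n
        self.weighted = weighted
        self.seed = seed
        self.max_redraws = max_redraws
        self.max_failure_frac = max_failure_frac

    # -- per-replicate hook ------------------------------------------------
    def _replicate_cov(self, rng, dbh, ht, sigma2_b, n, idx):
        raise NotImplementedError

    def fit(self, X: Sequence[TreeRecord], y=None):
        eq, fs = self.equation, self.fit_stats
        if eq is None or fs is None:
            raise InputError("equation and fit_stats are required")
        if not eq.recoverable:
            raise UnsupportedCaseError(
                f"equation {eq.name!r} is flagged non-recoverable: its published "
                "fit statistics do not describe a single least-squares fit")
        n = int(self.n if self.n is not None else fs.n)
        if n <= eq.q:
            raise InputError(f"fitting sample size n={n} must exceed q={eq.q}")
        if self.weighted and eq.weight_rule == "none" and self._inclusion_weights(X) is None:
            raise InputError(
                f"weighted recovery requested but equation {eq.name!r} has "
                "weight_rule='none' and no inclusion weights were given")
        dbh_all, ht_all = trees_to_arrays(X)
        if eq.needs_height and ht_all is None:
            raise InputError(f"equation {eq.name!r} needs tree heights")
        N = len(dbh_all)
        if N < n:
            raise InputError(f"population of {N} trees is smaller than n={n}")

        B = int(self.B)
        children = np.random.SeedSequence(self.seed).spawn(B)
        covs = np.empty((B, eq.q, eq.q))
        sig2s = np.empty(B)
        conds = np.empty(B)
        failures = 0
        self.gamma_fallback_count_ = 0
        for b in range(B):
            rng = np.random.default_rng(children[b])
            for attempt in range(self.max_redraws + 1):
                idx = rng.choice(N, size=n, replace=False)
                dbh = dbh_all[idx]
                ht = ht_all[idx] if ht_all is not None else None
                try:
                    preds = _fitted_values(eq, dbh, ht)
                    sigma2_b = _sigma2_from_preds(preds, fs.r_squared)
                    cov_b, cond = self._replicate_cov(rng, dbh, ht, sigma2_b, n, idx)
                    break
                except (SingularDesignError, DegenerateSampleError, ConvergenceError) as exc:
                    if attempt == self.max_redraws:
                        raise ConvergenceError(
                            f"replicate {b} failed {self.max_redraws + 1} times: {exc}"
                        ) from exc
                    failures += 1
                    logger.debug("replicate %d attempt %d redrawn: %s", b, attempt, exc)
            covs[b] = cov_b
            sig2s[b] = sigma2_b
            conds[b] = cond
        if failures > self.max_failure_frac * B * self.max_redraws:
            raise ConvergenceError(
                f"{failures} replicate failures exceed the allowed fraction")

        mean_cov = covs.mean(axis=0)
        dets = np.linalg.det(covs)
        cov, repaired = make_psd(mean_cov)
        if repaired:
            logger.info("recovered covariance required a PSD repair")
        self.sigma2_resid_ = float(sig2s.mean())
        self.cov_ = cov
        self.B_used_ = B
        self.per_replicate_dets_ = dets
        if B > 1 and np.mean(dets) != 0.0:
            self.mc_error_det_pct_ = mc_error_monitor(dets)
        elif np.std(dets) == 0.0:
            self.mc_error_det_pct_ = 0.0  # exactly repeated (e.g. zero) matrices
        else:
            self.mc_error_det_pct_ = float("inf")
        self.repair_count_ = int(repaired)
        svals = np.linalg.svd(cov, compute_uv=False)
        self.condition_number_ = float(svals[0] / svals[-1]) if svals[-1] > 0 else float("inf")
        if self.condition_number_ > CONDITION_WARN_THRESHOLD:
            warnings.warn(
                f"recovered covariance matrix is ill-conditioned "
                f"(cond={self.condition_number_:.3g}); inverting it may amplify errors",
                stacklevel=2)
        return self

    def _inclusion_weights(self, X):
        return getattr(self, "inclusion_weights", None)

    def _weights(self, dbh, idx=None):
        if not self.weighted:
            return None
        incl = self._inclusion_weights(None)
        if incl is not None and idx is not None:
            incl = incl[idx]
        return _normalized_weights(self.equation, dbh, incl)

    def _normal_matrix(self, F, dbh, idx=None):
        w = self._weights(dbh, idx)
        return F.T @ F if w is None else F.T @ (w[:, None] * F)

    @property
    def results_(self) -> RecoveredStats:
        return RecoveredStats(
            sigma2_resid=self.sigma2_resid_, cov=self.cov_, B_used=self.B_used_,
            mc_error_det_pct=self.mc_error_det_pct_, method=self.method,
            condition_number=self.condition_number_, repair_count=self.repair_count_,
            gamma_fallback_count=self.gamma_fallback_count_,
            per_replicate_dets=self.per_replicate_dets_)


class BasicRecovery(_BaseRecoveryEstimator):
    """Basic (and weighted) recovery: cov_b = sigma2_b (FᵗF)⁻¹ averaged over B."""

    method = "basic"

    def _replicate_cov(self, rng, dbh, ht, sigma2_b, n, idx):
        F = _gradient_rows(self.equation, dbh, ht)
        inv, cond = _inverse_with_cond(self._normal_matrix(F, dbh, idx))
        return sigma2_b * inv, cond


class RobustRecovery(_BaseRecoveryEstimator):
    """Sandwich recovery with simulated heavy-tailed residuals.

    Residuals e_i are drawn from a t-distribution with floor(0.5 n) degrees
    of freedom, scaled so the distribution variance equals the recovered
    sigma2_b; the sandwich (FᵗF)⁻¹ (Σ e_i² g_i g_iᵗ) (FᵗF)⁻¹ is averaged
    over B.  The low df reflect the small samples (6-30 trees) behind most
    published biomass equations.
    """

    method = "robust"

    def _replicate_cov(self, rng, dbh, ht, sigma2_b, n, idx):
        df = n // 2
        if df < 3:
            raise NoSolutionError(
                f"robust recovery needs floor(0.5 n) >= 3 degrees of freedom "
                f"(t variance undefined for df <= 2); got df={df} from n={n}")
        F = _gradient_rows(self.equation, dbh, ht)
        # scale so Var(e) = sigma2_b given Var(t_df) = df/(df-2)
        e = rng.standard_t(df, size=n) * np.sqrt(sigma2_b * (df - 2) / df)
        w = self._weights(dbh, idx)
        Fw = F if w is None else w[:, None] * F
        inv, cond = _inverse_with_cond(self._normal_matrix(F, dbh, idx))
        meat = Fw.T @ (e[:, None] ** 2 * Fw)
        return inv @ meat @ inv, cond


class RefitRecovery(_BaseRecoveryEstimator):
    """Parametric-bootstrap recovery: simulate responses, re-fit, average covs."""

    method = "refit"

    def _replicate_cov(self, rng, dbh, ht, sigma2_b, n, idx):
        eq = self.equation
        q = eq.q
        preds = _fitted_values(eq, dbh, ht)
        df = n - q
        if df < 3:
            raise NoSolutionError(f"refit recovery needs n - q >= 3, got {df}")
        e = rng.standard_t(df, size=n) * np.sqrt(sigma2_b * (df - 2) / df)
        y = preds + e
        if eq.scale == "identity" and sigma2_b > 0 and np.any(y < 0):
            # negative pseudo-biomass: switch to multiplicative gamma residuals
            nu = solve_gamma_nu(float(preds.mean()), float(np.var(preds, ddof=1)),
                                float(np.var(preds, ddof=1)) + sigma2_b)
            y = preds * rng.gamma(shape=nu, scale=1.0 / nu, size=n)
            self.gamma_fallback_count_ += 1
        b_star, F_star = self._least_squares_fit(dbh, ht, y, idx)
        resid = y - _fitted_values(eq, dbh, ht, b_star)
        w = self._weights(dbh, idx)
        if w is None:
            sigma2_star = float(resid @ resid) / df
            A = F_star.T @ F_star
        else:
            sigma2_star = float(n * (w * resid**2).sum()) / df
            A = F_star.T @ (w[:, None] * F_star)
        inv, cond = _inverse_with_cond(A)
        return sigma2_star * inv, cond

    def _least_squares_fit(self, dbh, ht, y, idx=None):
        return least_squares_refit(self.equation, dbh, ht, y,
                                   weights=self._weights(dbh, idx))


def least_squares_refit(eq: BiomassEquation, dbh: np.ndarray,
                        ht: np.ndarray | None, y: np.ndarray,
                        weights: np.ndarray | None = None):
    """(Weighted, iterative) least-squares fit of an equation's coefficients.

    Linear-in-basis and log-linear forms use a direct (weighted) lstsq;
    nonlinear forms use Levenberg-Marquardt started at the stored
    coefficients.  Returns (b*, gradient matrix F evaluated at b*).
    """
    sw = None if weights is None else np.sqrt(weights)
    if eq.form in ("linear-in-basis", "log-linear"):
        X = np.column_stack([BASIS_FUNCTIONS[t](dbh, ht) for t in eq.basis])
        Xw = X if sw is None else sw[:, None] * X
        yw = y if sw is None else sw * y
        b_star, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < eq.q:
            raise SingularDesignError("rank-deficient design in least-squares fit")
        return b_star, X

    def resid_fn(b):
        r = y - _fitted_values(eq, dbh, ht, np.asarray(b))
        return r if sw is None else sw * r

    sol = optimize.least_squares(resid_fn, x0=np.asarray(eq.coefficients),
                                 method="lm", max_nfev=200 * eq.q)
    if not sol.success:
        raise ConvergenceError(f"nonlinear re-fit failed: {sol.message}")
    return sol.x, _gradient_rows(eq, dbh, ht, sol.x)


def _run(cls, eq, population, fit, cfg: RecoveryConfig, **kw) -> RecoveredStats:
    est = cls(equation=eq, fit_stats=fit, B=cfg.B, n=cfg.n, weighted=cfg.weighted,
              seed=cfg.seed, max_redraws=cfg.max_redraws,
              max_failure_frac=cfg.max_failure_frac, **kw)
    return est.fit(population).results_


def basic_recovery(eq, population, fit, cfg: RecoveryConfig) -> RecoveredStats:
    """Functional wrapper over :class:`BasicRecovery` (unweighted)."""
    return _run(BasicRecovery, eq, population, fit,
                RecoveryConfig(**{**cfg.__dict__, "weighted": False, "method": "basic"}))


def weighted_recovery(eq, population, fit, cfg: RecoveryConfig,
                      inclusion_weights=None) -> RecoveredStats:
    """Weighted recovery, cov = sigma2 (FᵗWF)⁻¹ with sum-to-one weights.

    Weights follow the equation's weight rule (1/DBH²) unless explicit
    inclusion weights (inverse selection probabilities) are given.
    """
    if eq.weight_rule == "none" and inclusion_weights is None:
        raise InputError(
            f"equation {eq.name!r} has weight_rule='none'; weighted recovery "
            "needs a weight rule or explicit inclusion weights")
    est = BasicRecovery(equation=eq, fit_stats=fit, B=cfg.B, n=cfg.n, weighted=True,
                        seed=cfg.seed, max_redraws=cfg.max_redraws,
                        max_failure_frac=cfg.max_failure_frac)
    if inclusion_weights is not None:
        est.inclusion_weights = np.asarray(inclusion_weights, dtype=float)
    return est.fit(population).results_


def refit_recovery(eq, population, fit, cfg: RecoveryConfig) -> RecoveredStats:
    """Functional wrapper over :class:`RefitRecovery`."""
    return _run(RefitRecovery, eq, population, fit, cfg)


def robust_recovery(eq, population, fit, cfg: RecoveryConfig) -> RecoveredStats:
    """Functional wrapper over :class:`RobustRecovery`."""
    return _run(RobustRecovery, eq, population, fit, cfg)


def offdiagonal_recovery(eq: BiomassEquation, trees: Sequence[TreeRecord],
                         coef_se: Sequence[float], robust: bool = False,
                         cfg: RecoveryConfig | None = None) -> np.ndarray:
    """Covariance matrix from published coefficient SEs plus gradient correlations.

    When SEs of the coefficients are published but their covariances are
    not, the off-diagonals are recovered as the Pearson correlation of the
    gradient components across inventory trees times the geometric mean of
    the variances.  With ``robust=True`` the correlation is weighted by
    1/|e_i| with e_i simulated t-residuals (floor(0.5 n) df), down-weighting
    trees that would carry large residuals.
    """
    cfg = cfg or RecoveryConfig()
    se = np.asarray(coef_se, dtype=float)
    if se.ndim != 1 or len(se) != eq.q:
        raise InputError(f"coef_se must have length q={eq.q}")
    if np.any(se <= 0):
        raise InputError("coef_se entries must all be positive")
    if len(trees) < 3:
        raise InputError("need at least 3 trees for gradient correlations")
    dbh, ht = trees_to_arrays(trees)
    G = _gradient_rows(eq, dbh, ht)
    if np.any(np.var(G, axis=0) == 0):
        const = np.where(np.var(G, axis=0) == 0)[0]
        raise DegenerateSampleError(
            f"gradient component(s) {const.tolist()} constant across trees; "
            "correlation undefined")
    if robust:
        n = cfg.n if cfg.n is not None else len(trees)
        df = max(int(n) // 2, 3)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        w = 1.0 / np.abs(rng.standard_t(df, size=len(trees)))
    else:
        w = np.ones(len(trees))
    w = w / w.sum()
    mean = w @ G
    Gc = G - mean
    C = Gc.T @ (w[:, None] * Gc)
    d = np.sqrt(np.diag(C))
    corr = np.clip(C / np.outer(d, d), -1.0, 1.0)
    cov = corr * np.outer(se, se)
    np.fill_diagonal(cov, se**2)
    cov, repaired = make_psd(cov)
    if repaired:
        logger.info("off-diagonal recovery needed a PSD repair")
    return cov
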