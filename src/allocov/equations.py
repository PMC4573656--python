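"""Allometric biomass equations: representation, prediction, gradients, registry.

A biomass equation predicts above-ground biomass (AGB, kg per tree) from
stem diameter at breast height (DBH, cm) and, for some forms, total tree
height (HT, m).  Five functional forms cover the common shapes found in the
biomass-equation literature:

``linear-in-basis``
    AGB = b·x where x is a vector of regressor transforms of (DBH, HT),
    e.g. (DBH², √(DBH·HT)).
``nested-square``
    AGB = (b₁·DBH + b₂·√HT)².
``power``
    AGB = b₁·DBH^b₂.
``log-linear``
    log(AGB) = b·x with x transforms of log(DBH); fitted on the log scale,
    predictions back-transform with a plain exponential (no bias
    correction).
``exp-ratio``
    AGB = exp(b₁ + b₂·DBH/(DBH + b₃)) — the generalized temperate-zone
    shape; kept in the registry for prediction but flagged as unsuitable
    for covariance recovery because its published fit statistics describe
    the set of models being generalized, not a single least-squares fit.

Gradients with respect to the coefficient vector are analytic for the five
forms and are always evaluated on the *fitted* scale (the log scale for
log-linear equations), which is the scale on which least-squares fit
statistics such as R² and the residual SD live.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .exceptions import InputError, LookupError_, SingularDesignError

__all__ = [
    "TreeRecord",
    "FitStats",
    "BiomassEquation",
    "GradientMatrix",
    "predict_agb",
    "predict_fitted_scale",
    "gradient",
    "gradient_matrix",
    "finite_difference_gradient",
    "builtin_registry",
    "trees_to_arrays",
    "BASIS_FUNCTIONS",
]

FORMS = ("linear-in-basis", "nested-square", "power", "log-linear", "exp-ratio")


@dataclass(frozen=True)
class TreeRecord:
    """One inventory tree: species label, DBH in cm, optional height in m."""

    species: str
    dbh_cm: float
    ht_m: float | None = None
    plot_id: str | None = None

    def __post_init__(self):
        if not self.dbh_cm > 0:
            raise InputError(f"dbh_cm must be > 0, got {self.dbh_cm!r}")
        if self.ht_m is not None and not self.ht_m > 0:
            raise InputError(f"ht_m must be > 0 when present, got {self.ht_m!r}")


@dataclass(frozen=True)
class FitStats:
    """Published fit statistics of a biomass equation.

    Parameters
    ----------
    n : fitting sample size.
    r_squared : coefficient of determination on the fitted scale, in (0, 1].
        Plain or adjusted; ``r_squared_is_adjusted`` records which was
        supplied (no conversion is attempted).
    residual_sd : optional residual SD (sigma_e hat) on the fitted scale.
    coef_se : optional standard errors of the coefficients, length q.
    """

    n: int
    r_squared: float
    residual_sd: float | None = None
    coef_se: tuple[float, ...] | None = None
    r_squared_is_adjusted: bool | None = None

    def __post_init__(self):
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise InputError(f"n must be a positive integer, got {self.n!r}")
        if not 0 < self.r_squared <= 1:
            raise InputError(f"r_squared must be in (0, 1], got {self.r_squared!r}")
        if self.residual_sd is not None and not self.residual_sd > 0:
            raise InputError("residual_sd must be positive when present")
        if self.coef_se is not None:
            object.__setattr__(self, "coef_se", tuple(float(s) for s in self.coef_se))
            if any(s <= 0 for s in self.coef_se):
                raise InputError("coef_se entries must be positive")


# Named regressor transforms usable in a linear basis.  Each maps vectorized
# (dbh, ht) -> values; ht may be None for transforms that ignore it.
BASIS_FUNCTIONS: dict[str, Callable] = {
    "1": lambda d, h: np.ones_like(d),
    "dbh": lambda d, h: d,
    "dbh^2": lambda d, h: d**2,
    "sqrt(dbh*ht)": lambda d, h: np.sqrt(d * h),
    "sqrt(ht)": lambda d, h: np.sqrt(h),
    "log(dbh)": lambda d, h: np.log(d),
    "log(dbh)^2": lambda d, h: np.log(d) ** 2,
}

_NEEDS_HT = {"sqrt(dbh*ht)", "sqrt(ht)"}


@dataclass(frozen=True)
class BiomassEquation:
    """A fitted allometric biomass equation.

    ``coefficients`` are stored exactly as printed in the source the
    equation came from (no re-rounding).  ``scale`` is the scale of the
    response during fitting: ``"log"`` means the fitted response was
    log(AGB) and predictions back-transform by exp without bias correction.
    ``weight_rule`` records the weighting used in the original fit;
    ``"inverse-dbh-squared"`` is the common w_j proportional to 1/DBH_j².
    """

    name: str
    form: str
    coefficients: tuple[float, ...]
    basis: tuple[str, ...] = ()
    scale: str = "identity"
    weight_rule: str = "none"
    recoverable: bool = True
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.form not in FORMS:
            raise InputError(f"unknown form {self.form!r}; expected one of {FORMS}")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "basis", tuple(self.basis))
        if self.scale not in ("identity", "log"):
            raise InputError(f"scale must be 'identity' or 'log', got {self.scale!r}")
        if self.weight_rule not in ("none", "inverse-dbh-squared"):
            raise InputError(f"unknown weight_rule {self.weight_rule!r}")
        q = len(self.coefficients)
        if q < 1:
            raise InputError("at least one coefficient required")
        if self.form in ("linear-in-basis", "log-linear"):
            if len(self.basis) != q:
                raise InputError(
                    f"{self.form} needs one basis transform per coefficient "
                    f"(q={q}, got {len(self.basis)} basis terms)"
                )
            unknown = [b for b in self.basis if b not in BASIS_FUNCTIONS]
            if unknown:
                raise InputError(f"unknown basis transforms {unknown}; known: {sorted(BASIS_FUNCTIONS)}")
        elif self.form == "nested-square" and q != 2:
            raise InputError("nested-square form has exactly 2 coefficients")
        elif self.form == "power" and q != 2:
            raise InputError("power form has exactly 2 coefficients")
        elif self.form == "exp-ratio" and q != 3:
            raise InputError("exp-ratio form has exactly 3 coefficients")
        if self.form == "log-linear" and self.scale != "log":
            raise InputError("log-linear form implies scale='log'")

    @property
    def q(self) -> int:
        return len(self.coefficients)

    @property
    def needs_height(self) -> bool:
        if self.form == "nested-square":
            return True
        if self.form in ("linear-in-basis", "log-linear"):
            return any(b in _NEEDS_HT for b in self.basis)
        return False

    def with_coefficients(self, coefficients: Sequence[float]) -> "BiomassEquation":
        return replace(self, coefficients=tuple(float(c) for c in coefficients))


@dataclass(frozen=True)
class GradientMatrix:
    """Stacked per-tree gradient rows F-hat (n x q), evaluated at b-hat."""

    values: np.ndarray
    evaluated_at: tuple[float, ...]


def trees_to_arrays(trees: Sequence[TreeRecord]) -> tuple[np.ndarray, np.ndarray | None]:
    """Convert tree records to (dbh, ht) arrays; ht is None if any is missing."""
    dbh = np.array([t.dbh_cm for t in trees], dtype=float)
    if any(t.ht_m is None for t in trees):
        return dbh, None
    return dbh, np.array([t.ht_m for t in trees], dtype=float)


def _require_inputs(eq: BiomassEquation, dbh: np.ndarray, ht: np.ndarray | None) -> None:
    if np.any(dbh <= 0):
        raise InputError(f"non-positive DBH in input for equation {eq.name!r}")
    if eq.needs_height:
        if ht is None:
            raise InputError(f"equation {eq.name!r} requires tree height (ht_m) but it is missing")
        if np.any(ht <= 0):
            raise InputError(f"non-positive HT in input for equation {eq.name!r}")


def _fitted_values(eq: BiomassEquation, dbh: np.ndarray, ht: np.ndarray | None,
                   coefficients: np.ndarray | None = None) -> np.ndarray:
    b = np.asarray(eq.coefficients if coefficients is None else coefficients, dtype=float)
    if eq.form in ("linear-in-basis", "log-linear"):
        X = np.column_stack([BASIS_FUNCTIONS[t](dbh, ht) for t in eq.basis])
        return X @ b
    if eq.form == "nested-square":
        return (b[0] * dbh + b[1] * np.sqrt(ht)) ** 2
    if eq.form == "power":
        return b[0] * dbh ** b[1]
    if eq.form == "exp-ratio":
        return np.exp(b[0] + b[1] * dbh / (dbh + b[2]))
    raise AssertionError(eq.form)


def _gradient_rows(eq: BiomassEquation, dbh: np.ndarray, ht: np.ndarray | None,
                   coefficients: np.ndarray | None = None) -> np.ndarray:
    """n x q matrix of d f / d b on the fitted scale."""
    b = np.asarray(eq.coefficients if coefficients is None else coefficients, dtype=float)
    if eq.form in ("linear-in-basis", "log-linear"):
        # linear model: gradient is the regressor vector (log scale for log-linear)
        return np.column_stack([BASIS_FUNCTIONS[t](dbh, ht) for t in eq.basis])
    if eq.form == "nested-square":
        u = b[0] * dbh + b[1] * np.sqrt(ht)
        return np.column_stack([2.0 * u * dbh, 2.0 * u * np.sqrt(ht)])
    if eq.form == "power":
        return np.column_stack([dbh ** b[1], b[0] * dbh ** b[1] * np.log(dbh)])
    if eq.form == "exp-ratio":
        r = dbh / (dbh + b[2])
        f = np.exp(b[0] + b[1] * r)
        return np.column_stack([f, f * r, -f * b[1] * dbh / (dbh + b[2]) ** 2])
    raise AssertionError(eq.form)


def predict_fitted_scale(eq: BiomassEquation, trees: Sequence[TreeRecord]) -> np.ndarray:
    """Predictions on the scale the equation was fitted on (log for log-linear)."""
    dbh, ht = trees_to_arrays(trees)
    _require_inputs(eq, dbh, ht)
    return _fitted_values(eq, dbh, ht)


def predict_agb(eq: BiomassEquation, tree: TreeRecord) -> float:
    """Predicted AGB (kg) for one tree; exp back-transform for log-scale equations.

    No bias-correction factor is applied to the back-transform.
    """
    dbh, ht = trees_to_arrays([tree])
    _require_inputs(eq, dbh, ht)
    val = float(_fitted_values(eq, dbh, ht)[0])
    return math.exp(val) if eq.scale == "log" else val


def gradient(eq: BiomassEquation, tree: TreeRecord) -> np.ndarray:
    """Gradient of f w.r.t. the coefficients at one tree, on the fitted scale."""
    dbh, ht = trees_to_arrays([tree])
    _require_inputs(eq, dbh, ht)
    g = _gradient_rows(eq, dbh, ht)[0]
    if not np.all(np.isfinite(g)):
        raise InputError(f"non-finite gradient for equation {eq.name!r} at tree {tree!r}")
    return g


def gradient_matrix(eq: BiomassEquation, trees: Sequence[TreeRecord]) -> GradientMatrix:
    """Stack per-tree gradients into F-hat; raises on a rank-deficient design."""
    if len(trees) < eq.q:
        raise InputError(f"need at least q={eq.q} trees, got {len(trees)}")
    dbh, ht = trees_to_arrays(trees)
    _require_inputs(eq, dbh, ht)
    F = _gradient_rows(eq, dbh, ht)
    if not np.all(np.isfinite(F)):
        bad = np.where(~np.isfinite(F).all(axis=1))[0]
        raise InputError(f"non-finite gradient rows at tree indices {bad.tolist()}")
    s = np.linalg.svd(F, compute_uv=False)
    if s[-1] <= max(F.shape) * np.finfo(float).eps * s[0]:
        cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
        raise SingularDesignError(
            f"gradient matrix for {eq.name!r} is rank deficient "
            f"(rank < q={eq.q}, condition number {cond:.3g})",
            condition_number=cond,
        )
    return GradientMatrix(values=F, evaluated_at=eq.coefficients)


def finite_difference_gradient(eq: BiomassEquation, tree: TreeRecord,
                               rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient; oracle/fallback for the analytic one."""
    dbh, ht = trees_to_arrays([tree])
    _require_inputs(eq, dbh, ht)
    b = np.asarray(eq.coefficients, dtype=float)
    g = np.empty(eq.q)
    for k in range(eq.q):
        h = rel_step * max(abs(b[k]), 1.0)
        bp, bm = b.copy(), b.copy()
        bp[k] += h
        bm[k] -= h
        g[k] = (_fitted_values(eq, dbh, ht, bp)[0] - _fitted_values(eq, dbh, ht, bm)[0]) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# Built-in registry: the German BWI-1987 species-group equations and the
# Mexican NFI species equations, with their published fit statistics.
# ---------------------------------------------------------------------------

def _german_linear(name, b1, b2, r2, sig2_1e3, weighted):
    eq = BiomassEquation(
        name=name, form="linear-in-basis", coefficients=(b1, b2),
        basis=("dbh^2", "sqrt(dbh*ht)"),
        weight_rule="inverse-dbh-squared" if weighted else "none",
        meta={"sigma2_e_1e3_kg": sig2_1e3, "source": "BWI-1987 species groups"},
    )
    return eq, FitStats(n=50, r_squared=r2)


def _german_nested(name, b1, b2, r2, sig2_1e3, weighted):
    eq = BiomassEquation(
        name=name, form="nested-square", coefficients=(b1, b2),
        weight_rule="inverse-dbh-squared" if weighted else "none",
        meta={"sigma2_e_1e3_kg": sig2_1e3, "source": "BWI-1987 species groups"},
    )
    return eq, FitStats(n=50, r_squared=r2)


def _generalized(name, b1, b2, b3):
    # Generalized temperate-zone equations: printed R² describes the set of
    # generalized models, not a least-squares fit; recovery from it fails.
    eq = BiomassEquation(
        name=name, form="exp-ratio", coefficients=(b1, b2, b3),
        recoverable=False,
        meta={"note": "generalized temperate-zone equation; fit statistics "
                      "incompatible with covariance recovery"},
    )
    return eq, FitStats(n=50, r_squared=0.99)


def _mexican_log(name, coefs, basis, r2, sigma_e, n):
    eq = BiomassEquation(
        name=name, form="log-linear", coefficients=coefs, basis=basis,
        scale="log", meta={"source": "Mexican NFI (Chiapas)"},
    )
    return eq, FitStats(n=n, r_squared=r2, residual_sd=sigma_e, r_squared_is_adjusted=True)


def _mexican_power(name, b1, b2, r2, sigma_e, n):
    eq = BiomassEquation(
        name=name, form="power", coefficients=(b1, b2),
        meta={"source": "Mexican NFI (Michoacan, Quercus)"},
    )
    return eq, FitStats(n=n, r_squared=r2, residual_sd=sigma_e)


def builtin_registry() -> dict[str, tuple[BiomassEquation, FitStats]]:
    """All built-in equations with their published fit statistics.

    German entries (n=50 each): four equations per species group — linear and
    nested-square, each unweighted and weighted by 1/DBH².  Numbers 13-15 are
    generalized temperate-zone equations flagged ``recoverable=False``.
    Mexican entries: four log-log equations and three Quercus power
    equations with printed adjusted R², residual SD, and n.
    """
    reg: dict[str, tuple[BiomassEquation, FitStats]] = {}
    # unweighted German equations
    reg["beech_1"] = _german_linear("beech_1", 0.901, -6.382, 0.96, 75.3, False)
    reg["beech_2"] = _german_nested("beech_2", 9.645, -0.648, 0.95, 79.2, False)
    reg["spruce_5"] = _german_linear("spruce_5", 0.447, -1.189, 0.98, 18.7, False)
    reg["spruce_6"] = _german_nested("spruce_6", 0.634, -0.426, 0.98, 18.2, False)
    reg["pine_9"] = _german_linear("pine_9", 0.450, -0.014, 0.98, 14.5, False)
    reg["pine_10"] = _german_linear("pine_10", 0.658, -0.124, 0.98, 14.5, False)
    # weighted (w_j proportional to 1/DBH_j^2)
    reg["beech_3"] = _german_linear("beech_3", 0.887, -6.487, 0.96, 74.4, True)
    reg["beech_4"] = _german_nested("beech_4", 10.127, -1.167, 0.95, 75.3, True)
    reg["spruce_7"] = _german_linear("spruce_7", 0.492, -1.409, 0.97, 19.0, True)
    reg["spruce_8"] = _german_nested("spruce_8", 0.689, -0.064, 0.97, 18.7, True)
    reg["pine_11"] = _german_linear("pine_11", 0.479, -1.927, 0.97, 14.7, True)
    reg["pine_12"] = _german_linear("pine_12", 0.690, -0.205, 0.97, 14.5, True)
    # generalized temperate-zone equations (prediction only)
    reg["beech_generalized_13"] = _generalized("beech_generalized_13", 0.006, 10.933, 21.216)
    reg["spruce_generalized_14"] = _generalized("spruce_generalized_14", -1.694, 10.825, 11.816)
    reg["pine_generalized_15"] = _generalized("pine_generalized_15", -2.688, 10.745, 8.062)
    # Mexican log-log equations
    reg["guazuma_ulmifolia"] = _mexican_log(
        "guazuma_ulmifolia", (-1.62, 2.12), ("1", "log(dbh)"), 0.97, 0.48, 18)
    reg["inga_vera"] = _mexican_log(
        "inga_vera", (-4.04, 4.00, -0.29), ("1", "log(dbh)", "log(dbh)^2"), 0.97, 0.39, 15)
    reg["ochroma_pyramidale"] = _mexican_log(
        "ochroma_pyramidale", (-2.45, 2.30), ("1", "log(dbh)"), 0.90, 0.96, 16)
    reg["trichospernum_mexicanum"] = _mexican_log(
        "trichospernum_mexicanum", (-2.82, 2.42), ("1", "log(dbh)"), 0.96, 0.40, 16)
    # Mexican Quercus power equations
    reg["quercus_castenea"] = _mexican_power("quercus_castenea", 0.0416, 2.7154, 0.97, 11.6, 38)
    reg["quercus_latea"] = _mexican_power("quercus_latea", 0.0333, 2.6648, 0.92, 12.8, 7)
    reg["quercus_spp"] = _mexican_power("quercus_spp", 0.0342, 2.7590, 0.93, 15.7, 45)
    return reg


def get_equation(name: str) -> tuple[BiomassEquation, FitStats]:
    """Look up one registry entry; unknown names raise with the available list."""
    reg = builtin_registry()
    if name not in reg:
        raise LookupError_(
            f"unknown equation {name!r}; available: {', '.join(sorted(reg))}")
    return reg[name]
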