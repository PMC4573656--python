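"""Propagation of fit statistics to model-error variances of AGB estimates.

The model error in a single tree's predicted biomass combines the residual
variance with the delta-method contribution of coefficient uncertainty:

    V(AGB_j) = sigma_e² + gᵗ cov(b) g,      g = df/db at the tree.

For the mean over the n_s inventory trees of a species the residual term
declines at rate 1/n_s while the coefficient term is driven by the
*average* gradient:

    V(mean AGB_s) = sigma_e²/n_s + ḡᵗ cov(b) ḡ.

Per-hectare stocks scale the per-tree mean by an estimated stem density
lambda (stems/ha), with variance lambda² V(mean) + mean² V(lambda) under a
zero-covariance assumption.  For log-scale equations the variances live on
the log scale; by the delta method the SE of log-AGB is approximately the
relative SE of AGB, which is how log-scale error budgets convert to
percent errors on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equations import BiomassEquation, TreeRecord, gradient, predict_agb, trees_to_arrays
from .equations import _gradient_rows, _require_inputs
from .exceptions import InputError, UnsupportedCaseError
from .recovery import RecoveredStats

__all__ = [
    "SpeciesPanel",
    "ErrorBudget",
    "tree_error_variance",
    "species_mean_error_variance",
    "per_hectare_error_variance",
    "combine_species",
    "relative_error",
    "species_error_budget",
    "KG_PER_MG",
]

KG_PER_MG = 1000.0  # single place for the kg <-> Mg conversion


@dataclass
class SpeciesPanel:
    """The n_s inventory trees of one species, with optional stem density."""

    species: str
    trees: list[TreeRecord]
    stem_density: float | None = None        # lambda_s, stems per hectare
    stem_density_var: float | None = None    # V(lambda_s)

    def __post_init__(self):
        if len(self.trees) < 1:
            raise InputError("a species panel needs at least one tree")
        if self.stem_density is not None and not self.stem_density > 0:
            raise InputError("stem_density must be positive when present")
        if self.stem_density_var is not None:
            if self.stem_density is None:
                raise InputError("stem_density_var requires stem_density")
            if self.stem_density_var < 0:
                raise InputError("stem_density_var must be >= 0")


@dataclass
class ErrorBudget:
    """Model-error variances at the three reporting scales for one species."""

    species: str
    mean_agb_kg: float
    per_tree_var: float              # kg² (log² for log-scale equations)
    species_mean_var: float          # kg² (log² for log-scale equations)
    per_ha_var: float | None         # Mg² ha⁻²
    relative_error_pct: float
    log_scale: bool = False


def tree_error_variance(eq: BiomassEquation, tree: TreeRecord,
                        stats: RecoveredStats) -> float:
    """Out-of-sample model-error variance of one tree's AGB prediction.

    Returned on the fitted scale: kg² for identity-scale equations,
    log-scale variance for log-linear equations.
    """
    cov = np.asarray(stats.cov, dtype=float)
    if cov.shape != (eq.q, eq.q):
        raise InputError(f"cov must be {eq.q}x{eq.q}, got {cov.shape}")
    g = gradient(eq, tree)
    return float(stats.sigma2_resid + g @ cov @ g)


def species_mean_error_variance(eq: BiomassEquation, panel: SpeciesPanel,
                                stats: RecoveredStats,
                                average_quadratic_forms: bool = False) -> float:
    """Model-error variance of the mean AGB over the panel's n_s trees.

    Default is sigma2/n_s plus the quadratic form of cov in the gradient
    *averaged over trees*.  ``average_quadratic_forms=True`` instead
    averages per-tree quadratic forms gᵢᵗ cov gᵢ — a mathematically
    different quantity (it ignores gradient-averaging cancellation) kept
    only as an opt-in diagnostic.
    """
    cov = np.asarray(stats.cov, dtype=float)
    if cov.shape != (eq.q, eq.q):
        raise InputError(f"cov must be {eq.q}x{eq.q}, got {cov.shape}")
    dbh, ht = trees_to_arrays(panel.trees)
    _require_inputs(eq, dbh, ht)
    G = _gradient_rows(eq, dbh, ht)
    n_s = len(panel.trees)
    if average_quadratic_forms:
        quad = float(np.mean(np.einsum("ij,jk,ik->i", G, cov, G)))
    else:
        gbar = G.mean(axis=0)
        quad = float(gbar @ cov @ gbar)
    return stats.sigma2_resid / n_s + quad


def per_hectare_error_variance(mean_agb_mg: float, mean_agb_var_mg2: float,
                               lambda_hat: float, lambda_var: float) -> float:
    """Model-error variance of a per-hectare AGB stock (Mg² ha⁻²).

    lambda² V(mean AGB) + mean² V(lambda), assuming zero covariance between
    the stem-density estimate and the mean per-tree biomass.
    """
    for nm, v in (("mean_agb_mg", mean_agb_mg), ("mean_agb_var_mg2", mean_agb_var_mg2),
                  ("lambda_hat", lambda_hat), ("lambda_var", lambda_var)):
        if v < 0:
            raise InputError(f"{nm} must be >= 0, got {v!r}")
    return lambda_hat**2 * mean_agb_var_mg2 + mean_agb_mg**2 * lambda_var


def combine_species(per_species_vars: Sequence[float],
                    shared_equation: bool = False) -> float:
    """Total variance over species under independence of model errors.

    Refuses when species are declared to share one biomass equation:
    shared coefficients induce a covariance of model errors across species
    that a plain sum would ignore.
    """
    if shared_equation:
        raise UnsupportedCaseError(
            "species sharing one biomass equation have correlated model "
            "errors; summing their variances is not valid")
    vars_ = [float(v) for v in per_species_vars]
    if any(v < 0 for v in vars_):
        raise InputError("variances must be >= 0")
    return float(sum(vars_))


def relative_error(estimate: float, variance: float) -> float:
    """Relative error 100 * sqrt(variance) / estimate, in percent."""
    if not estimate > 0:
        raise InputError(f"estimate must be > 0, got {estimate!r}")
    if variance < 0:
        raise InputError(f"variance must be >= 0, got {variance!r}")
    return 100.0 * float(np.sqrt(variance)) / estimate


def species_error_budget(eq: BiomassEquation, panel: SpeciesPanel,
                         stats: RecoveredStats) -> ErrorBudget:
    """Assemble the full error budget for one species panel.

    For identity-scale equations the relative error is 100·sqrt(V)/mean on
    the kg scale; for log-scale equations the log-scale SE is itself the
    (delta-method) relative SE, so relative_error_pct = 100·sqrt(V_log).
    """
    preds = np.array([predict_agb(eq, t) for t in panel.trees])
    mean_agb = float(preds.mean())
    mean_var = species_mean_error_variance(eq, panel, stats)
    per_tree = float(np.mean([tree_error_variance(eq, t, stats) for t in panel.trees]))
    log_scale = eq.scale == "log"
    if log_scale:
        rel = 100.0 * float(np.sqrt(mean_var))
        mean_var_kg2 = (rel / 100.0 * mean_agb) ** 2  # delta-method natural scale
    else:
        rel = relative_error(mean_agb, mean_var)
        mean_var_kg2 = mean_var
    per_ha = None
    if panel.stem_density is not None:
        per_ha = per_hectare_error_variance(
            mean_agb / KG_PER_MG, mean_var_kg2 / KG_PER_MG**2,
            panel.stem_density, panel.stem_density_var or 0.0)
    return ErrorBudget(species=panel.species, mean_agb_kg=mean_agb,
                       per_tree_var=per_tree, species_mean_var=mean_var,
                       per_ha_var=per_ha, relative_error_pct=rel,
                       log_scale=log_scale)
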