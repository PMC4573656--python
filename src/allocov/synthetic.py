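"""Seeded synthetic tree populations and the fit-hide-recover-compare harness.

Published national-inventory summaries give only moments — mean and SD of
DBH and HT per species — so testable populations are generated by
moment-matching a chosen distribution family (lognormal by default, gamma
as a sensitivity check) and coupling DBH and HT through a Gaussian copula
on the log scale (default correlation 0.7, a typical diameter-height
association in even-aged stands).  Optionally, each tree carries a
reference AGB equal to an equation prediction times a multiplicative
uniform error on [0.9, 1.1], emulating how the German BWI-1987 reference
biomass values were constructed.

The validation harness closes the loop the recovery procedures are meant
for: fit an equation to a random sample (producing the *actual* covariance
matrix and R²), hide the covariance, recover a substitute from fresh
samples of the remaining population, and compare recovered to actual with
Box's M test and propagated relative errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .comparison import MTestResult, box_m_test
from .equations import (
    BiomassEquation,
    FitStats,
    TreeRecord,
    _fitted_values,
    trees_to_arrays,
)
from .exceptions import InputError, SingularDesignError
from .propagation import SpeciesPanel, species_error_budget
from .recovery import (
    RecoveredStats,
    RecoveryConfig,
    basic_recovery,
    least_squares_refit,
    refit_recovery,
    robust_recovery,
    weighted_recovery,
)

__all__ = [
    "PopulationSpec",
    "Population",
    "ActualFit",
    "ValidationScenario",
    "ValidationOutcome",
    "generate_population",
    "sample_inventory",
    "simulate_actual_fit",
    "validation_experiment",
    "GERMAN_POPULATIONS",
    "MEXICAN_POPULATIONS",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Target moments and distributional family of a synthetic population."""

    species: str
    n_trees: int
    dbh_mean: float
    dbh_sd: float
    ht_mean: float | None = None
    ht_sd: float | None = None
    dbh_ht_corr: float = 0.7
    dbh_family: str = "lognormal"
    agb_equation: BiomassEquation | None = None
    agb_rule: str = "none"
    noise_interval: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise InputError("n_trees must be >= 1")
        if not (self.dbh_mean > 0 and self.dbh_sd > 0):
            raise InputError("dbh moments must be positive")
        if (self.ht_mean is None) != (self.ht_sd is None):
            raise InputError("ht_mean and ht_sd must be given together")
        if self.ht_mean is not None and not (self.ht_mean > 0 and self.ht_sd > 0):
            raise InputError("ht moments must be positive")
        if not -1 <= self.dbh_ht_corr <= 1:
            raise InputError("dbh_ht_corr must be in [-1, 1]")
        if self.dbh_family not in ("lognormal", "gamma"):
            raise InputError(f"unknown dbh_family {self.dbh_family!r}")
        if self.agb_rule not in ("none", "equation-times-uniform-noise"):
            raise InputError(f"unknown agb_rule {self.agb_rule!r}")
        if self.agb_rule != "none" and self.agb_equation is None:
            raise InputError("agb_rule needs an agb_equation")


class Population(Sequence):
    """A generated tree list; behaves as a sequence of TreeRecord.

    ``agb`` holds the per-tree reference biomass (kg) when the spec's
    agb_rule was set, else None.
    """

    def __init__(self, trees: list[TreeRecord], agb: np.ndarray | None,
                 spec: PopulationSpec):
        self.trees = trees
        self.agb = agb
        self.spec = spec

    def __len__(self):
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given natural-scale mean and SD."""
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def generate_population(spec: PopulationSpec) -> Population:
    """Draw a deterministic (seeded) population matched to the spec's moments.

    DBH and HT marginals are moment-matched (lognormal closed form; gamma
    shape/scale = (m/s)², s²/m) and coupled through a Gaussian copula with
    the requested log-scale correlation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    with_ht = spec.ht_mean is not None
    if with_ht:
        rho = spec.dbh_ht_corr
        L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        z = rng.standard_normal((spec.n_trees, 2)) @ L.T
        z_d, z_h = z[:, 0], z[:, 1]
    else:
        z_d, z_h = rng.standard_normal(spec.n_trees), None

    if spec.dbh_family == "lognormal":
        mu, sg = _lognormal_params(spec.dbh_mean, spec.dbh_sd)
        dbh = np.exp(mu + sg * z_d)
    else:
        shape = (spec.dbh_mean / spec.dbh_sd) ** 2
        scale = spec.dbh_sd**2 / spec.dbh_mean
        dbh = sps.gamma.ppf(sps.norm.cdf(z_d), shape, scale=scale)
    ht = None
    if with_ht:
        mu_h, sg_h = _lognormal_params(spec.ht_mean, spec.ht_sd)
        ht = np.exp(mu_h + sg_h * z_h)

    trees = [TreeRecord(species=spec.species, dbh_cm=float(d),
                        ht_m=float(h) if ht is not None else None)
             for d, h in zip(dbh, ht if ht is not None else np.full(len(dbh), np.nan))]
    agb = None
    if spec.agb_rule == "equation-times-uniform-noise":
        pred = _fitted_values(spec.agb_equation, dbh, ht)
        if spec.agb_equation.scale == "log":
            pred = np.exp(pred)
        lo, hi = spec.noise_interval
        agb = pred * rng.uniform(lo, hi, size=len(dbh))
    return Population(trees, agb, spec)


def sample_inventory(population: Sequence[TreeRecord], n: int,
                     pps_by_basal_area: bool = False,
                     seed: int = 0) -> list[TreeRecord]:
    """Without-replacement inventory sample; PPS mode weights by basal area.

    Under PPS, inclusion probability is proportional to DBH² (basal area at
    breast height), emulating angle-count style selection.
    """
    N = len(population)
    if n > N:
        raise InputError(f"cannot sample n={n} from population of {N}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if pps_by_basal_area:
        dbh = np.array([t.dbh_cm for t in population])
        p = dbh**2 / (dbh**2).sum()
        idx = rng.choice(N, size=n, replace=False, p=p)
    else:
        idx = rng.choice(N, size=n, replace=False)
    return [population[i] for i in idx]


@dataclass
class ActualFit:
    """Ground truth from a simulated model fit: what recovery must approximate."""

    coefficients: np.ndarray
    cov: np.ndarray              # textbook sigma2 (FᵗF)⁻¹ at the fit
    sigma2: float
    fit_stats: FitStats          # the (n, R²) a publication would print
    fit_indices: np.ndarray      # population indices of the fitting trees


def simulate_actual_fit(eq: BiomassEquation, population: Sequence[TreeRecord],
                        n: int, noise_sd: float | None = None, seed: int = 0,
                        responses: np.ndarray | None = None,
                        pps_by_basal_area: bool = False) -> ActualFit:
    """Fit the equation to a simulated sample and keep the true fit statistics.

    Responses are, in order of precedence: the supplied ``responses`` array
    (population-aligned, fitted scale for log equations handled
    internally), or model predictions plus Gaussian noise of SD
    ``noise_sd`` on the fitted scale.  Returns the fitted coefficients, the
    textbook covariance sigma2 (FᵗF)⁻¹ (the "actual" matrix that recovery
    procedures will try to substitute), and the printed-style (n, R²).
    """
    if n <= eq.q:
        raise InputError(f"n={n} must exceed q={eq.q}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    N = len(population)
    dbh_all, ht_all = trees_to_arrays(population)
    if pps_by_basal_area:
        p = dbh_all**2 / (dbh_all**2).sum()
        idx = rng.choice(N, size=n, replace=False, p=p)
    else:
        idx = rng.choice(N, size=n, replace=False)
    dbh = dbh_all[idx]
    ht = ht_all[idx] if ht_all is not None else None
    pred_true = _fitted_values(eq, dbh, ht)
    if responses is not None:
        y = np.asarray(responses, dtype=float)[idx]
        if eq.scale == "log":
            y = np.log(y)
    elif noise_sd is not None:
        y = pred_true + rng.normal(0.0, noise_sd, size=n)
    else:
        raise InputError("either responses or noise_sd is required")

    w = None
    if eq.weight_rule == "inverse-dbh-squared":
        w = dbh**-2.0
        w = w / w.sum()
    b_hat, F = least_squares_refit(eq, dbh, ht, y, weights=w)
    resid = y - _fitted_values(eq, dbh, ht, b_hat)
    dfres = n - eq.q
    if w is None:
        sigma2 = float(resid @ resid) / dfres
        A = F.T @ F
        sse, sst = float(resid @ resid), float(np.sum((y - y.mean()) ** 2))
    else:
        sigma2 = float(n * (w * resid**2).sum()) / dfres
        A = F.T @ (w[:, None] * F)
        ybar = float(w @ y)
        sse, sst = float((w * resid**2).sum()), float((w * (y - ybar) ** 2).sum())
    if sst == 0:
        raise SingularDesignError("zero response variance in simulated fit")
    r2 = max(min(1.0 - sse / sst, 1.0), np.finfo(float).tiny)
    try:
        cov = sigma2 * np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"singular fit design: {exc}") from exc
    return ActualFit(coefficients=np.asarray(b_hat), cov=cov, sigma2=sigma2,
                     fit_stats=FitStats(n=n, r_squared=float(r2)),
                     fit_indices=idx)


# ---------------------------------------------------------------------------
# The fit-hide-recover-compare experiment
# ---------------------------------------------------------------------------

@dataclass
class ValidationScenario:
    """Configuration of one fit-hide-recover-compare run."""

    equation: BiomassEquation
    population_spec: PopulationSpec
    n_fit: int = 50
    B: int = 800
    seed: int = 0
    methods: tuple[str, ...] = ("basic", "refit", "robust")
    weighted: bool = False
    noise_sd: float | None = None          # Gaussian noise on the fitted scale
    use_population_agb: bool = False       # fit to the generated reference AGB


@dataclass
class ValidationOutcome:
    actual_cov: np.ndarray
    actual_sigma2: float
    fit_stats: FitStats
    fitted_coefficients: np.ndarray
    recovered: dict[str, RecoveredStats]
    mtests: dict[str, MTestResult]
    relative_errors: dict[str, float]      # includes the "actual" benchmark


def validation_experiment(scenario: ValidationScenario) -> ValidationOutcome:
    """Run the full validation loop for one scenario.

    Generates the population, simulates the original model fit (the
    "actual" statistics), removes the fitting trees from the population as
    a real recovery would have to, recovers substitutes with each
    configured method, tests each substitute against the actual matrix
    with Box's M, and propagates every matrix to the relative model error
    of the species-mean AGB.
    """
    sc = scenario
    pop = generate_population(sc.population_spec)
    responses = pop.agb if sc.use_population_agb else None
    actual = simulate_actual_fit(sc.equation, pop, sc.n_fit,
                                 noise_sd=sc.noise_sd, seed=sc.seed,
                                 responses=responses)
    keep = np.setdiff1d(np.arange(len(pop)), actual.fit_indices)
    remaining = [pop[i] for i in keep]

    runners = {"basic": weighted_recovery if sc.weighted else basic_recovery,
               "refit": refit_recovery, "robust": robust_recovery}
    recovered, mtests, rel = {}, {}, {}
    n = actual.fit_stats.n
    for i, method in enumerate(sc.methods):
        cfg = RecoveryConfig(B=sc.B, method=method if method != "basic" else "basic",
                             weighted=sc.weighted,
                             seed=int(np.random.SeedSequence([sc.seed, i]).generate_state(1)[0] % 2**31))
        recovered[method] = runners[method](sc.equation, remaining,
                                            actual.fit_stats, cfg)
        rec_cov = recovered[method].cov
        scale = max(float(np.abs(actual.cov).max()), float(np.abs(rec_cov).max()))
        coef_scale = max(1.0, float(np.max(np.abs(actual.coefficients)) ** 2))
        if scale < 1e-12 * coef_scale or np.allclose(actual.cov, rec_cov,
                                                     atol=1e-12 * scale):
            # degenerate (noise-free) limit: identical matrices, M undefined
            df = sc.equation.q * (sc.equation.q + 1) // 2
            mtests[method] = MTestResult(M=0.0, chi2=0.0, df=df, p_value=1.0)
        else:
            mtests[method] = box_m_test([actual.cov, rec_cov], [n, n])

    panel = SpeciesPanel(species=sc.population_spec.species, trees=remaining)
    actual_stats = RecoveredStats(sigma2_resid=actual.sigma2, cov=actual.cov,
                                  B_used=0, mc_error_det_pct=0.0, method="actual",
                                  condition_number=float(np.linalg.cond(actual.cov)))
    rel["actual"] = species_error_budget(sc.equation, panel, actual_stats).relative_error_pct
    for method, stats_ in recovered.items():
        rel[method] = species_error_budget(sc.equation, panel, stats_).relative_error_pct
    return ValidationOutcome(actual_cov=actual.cov, actual_sigma2=actual.sigma2,
                             fit_stats=actual.fit_stats,
                             fitted_coefficients=actual.coefficients,
                             recovered=recovered, mtests=mtests,
                             relative_errors=rel)


# Printed inventory summaries as ready-made population specs.  German rows:
# tree counts and DBH/HT mean (SD) per species group, BWI-1987.  Mexican
# rows: NFI 2004-2009 plot summaries (stem densities per hectare attached).
GERMAN_POPULATIONS: dict[str, PopulationSpec] = {
    "BEECH": PopulationSpec("BEECH", 1595, 35.0, 15.0, 25.0, 7.0),
    "SPRUCE": PopulationSpec("SPRUCE", 2221, 30.0, 12.0, 24.0, 7.0),
    "PINE": PopulationSpec("PINE", 1221, 33.0, 12.0, 23.0, 6.0),
}

MEXICAN_POPULATIONS: dict[str, PopulationSpec] = {
    "guazuma_ulmifolia": PopulationSpec("guazuma_ulmifolia", 177, 12.9, 5.1, 5.5, 2.4),
    "inga_vera": PopulationSpec("inga_vera", 37, 17.1, 9.5, 12.0, 4.1),
    "ochroma_pyramidale": PopulationSpec("ochroma_pyramidale", 144, 13.9, 6.2, 10.1, 2.6),
    "trichospernum_mexicanum": PopulationSpec("trichospernum_mexicanum", 612, 13.9, 6.5, 9.6, 3.3),
    "quercus_castenea": PopulationSpec("quercus_castenea", 416, 16.6, 7.7, 7.1, 2.6),
    "quercus_latea": PopulationSpec("quercus_latea", 37, 17.2, 8.5, 9.5, 3.2),
    "quercus_spp": PopulationSpec("quercus_spp", 420, 16.6, 7.7, 7.0, 2.6),
}

MEXICAN_STEM_DENSITY: dict[str, float] = {
    "guazuma_ulmifolia": 201.0, "inga_vera": 103.0, "ochroma_pyramidale": 49.0,
    "trichospernum_mexicanum": 156.0, "quercus_castenea": 612.0,
    "quercus_latea": 231.0, "quercus_spp": 553.0,
}
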