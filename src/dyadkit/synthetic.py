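"""Synthetic dyadic data with known APIM/MIM/CFM structure.

Every estimator in the package can be validated without external data by
simulating multivariate-normal dyad scores from a population whose path
structure is known, then checking that fitting recovers it.  Default
population values echo the regime of the packaged couples example
(predictor SDs near 4.3-4.5, outcome SDs near 6.6, actor effects near
-0.45 for the APIM), so recovery experiments resemble realistic
questionnaire data rather than an idealized unit-variance world.

Gaussian data only: that is the maximum-likelihood estimator's own
assumption, and the point of the generator is estimator validation, not
robustness stress-testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sem
from .dyad_data import DyadTable
from .models import (
    DyadDesign,
    build_apim,
    build_cfm,
    build_mim,
    feedback_label,
)
from .sem import PathModel, UsageError

__all__ = [
    "GeneratorSpec",
    "default_population",
    "implied_population_covariance",
    "simulate_dyads",
    "recovery_experiment",
    "RecoveryResult",
]

FRAMEWORKS = ("apim", "mim", "cfm")


def _default_design() -> DyadDesign:
    return DyadDesign()


def default_population(framework: str, design: DyadDesign | None = None) -> dict:
    """Default population parameters (keyed by model label) per framework."""
    design = design or _default_design()
    r1, r2 = design.roles
    x1, x2 = design.x(r1), design.x(r2)
    y1, y2 = design.y(r1), design.y(r2)
    exog = {f"var:{x1}": 18.4, f"var:{x2}": 19.8, f"cov:{x1}~{x2}": 4.0}
    if framework == "apim":
        return {
            f"actor:{r1}": -0.45,
            f"actor:{r2}": -0.45,
            f"partner:{r2}->{r1}": -0.2,
            f"partner:{r1}->{r2}": -0.2,
            **exog,
            f"resvar:{y1}": 36.7,
            f"resvar:{y2}": 39.7,
            f"rescov:{y1}~{y2}": 14.0,
        }
    if framework == "mim":
        return {
            f"actor:{r1}": -0.37,
            f"actor:{r2}": -0.36,
            f"feedback:{r2}->{r1}": 0.57,
            f"feedback:{r1}->{r2}": 0.33,
            **exog,
            f"resvar:{y1}": 33.6,
            f"resvar:{y2}": 34.5,
            f"rescov:{y1}~{y2}": -18.1,
        }
    if framework == "cfm":
        lx, ly = f"{design.predictor}_dyad", f"{design.outcome}_dyad"
        return {
            "latent_effect": -1.44,
            f"var:{lx}": 3.95,
            f"resvar:{ly}": 10.3,
            f"resvar:{x1}": 14.4,
            f"resvar:{x2}": 15.8,
            f"resvar:{y1}": 24.2,
            f"resvar:{y2}": 26.0,
            f"rescov:{r1}": -4.0,
            f"rescov:{r2}": -3.4,
        }
    raise UsageError(f"unknown framework {framework!r}; use one of {FRAMEWORKS}")


def _builder(framework: str, design: DyadDesign, variant: str = "basic") -> PathModel:
    if framework == "apim":
        return build_apim(design, variant)
    if framework == "mim":
        return build_mim(design, variant)
    if framework == "cfm":
        return build_cfm(design)
    raise UsageError(f"unknown framework {framework!r}; use one of {FRAMEWORKS}")


@dataclass
class GeneratorSpec:
    """Population specification for the dyad simulator.

    ``params`` maps model parameter labels (as produced by the builders in
    :mod:`dyadkit.models`) to population values; omitted labels take the
    framework defaults.  ``means`` default to zero for all four observed
    variables.  The implied population covariance must be positive
    definite, and an MIM population must have a stable feedback loop
    (``|b12 * b21| < 1``).
    """

    framework: str
    n: int = 141
    params: dict = field(default_factory=dict)
    means: Sequence[float] | None = None
    seed: int = 0
    design: DyadDesign = field(default_factory=_default_design)

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise UsageError(
                f"unknown framework {self.framework!r}; use one of {FRAMEWORKS}"
            )
        if self.n < 1:
            raise UsageError("n must be at least 1")
        full = default_population(self.framework, self.design)
        unknown = set(self.params) - set(full)
        if unknown:
            raise UsageError(f"unknown parameter labels {sorted(unknown)}")
        full.update(self.params)
        self.params = full
        if self.means is None:
            self.means = np.zeros(4)
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (4,):
            raise UsageError("means must have length 4 (design variable order)")
        if self.framework == "mim":
            r1, r2 = self.design.roles
            prod = (
                self.params[feedback_label(self.design, r2, r1)]
                * self.params[feedback_label(self.design, r1, r2)]
            )
            if abs(prod) >= 1.0:
                raise UsageError(
                    f"feedback product {prod:.3f} must have absolute value < 1 "
                    "for a stable reduced form"
                )
        cov = implied_population_covariance(self)
        eigs = np.linalg.eigvalsh(cov.to_numpy())
        if eigs.min() <= 0:
            raise UsageError(
                f"implied population covariance is not positive definite "
                f"(min eigenvalue {eigs.min():.3e})"
            )

    def model(self, variant: str = "basic") -> PathModel:
        return _builder(self.framework, self.design, variant)


def implied_population_covariance(spec: GeneratorSpec) -> pd.DataFrame:
    """Population covariance of the four observed scores.

    APIM and CFM use the RAM identity shared with the estimation engine.
    The MIM is assembled through its reduced form ``Y = (I-B)^-1 (G X + e)``
    so the nonrecursive structure is handled explicitly; the two routes
    agree, which the test suite checks.
    """
    design = spec.design
    names = design.variable_order
    if spec.framework in ("apim", "cfm"):
        model = _builder(spec.framework, design)
        cov = sem.implied_covariance(model, spec.params)
        return pd.DataFrame(cov, index=names, columns=names)
    # MIM reduced form
    r1, r2 = design.roles
    x1, x2 = design.x(r1), design.x(r2)
    y1, y2 = design.y(r1), design.y(r2)
    p = spec.params
    Sxx = np.array(
        [[p[f"var:{x1}"], p[f"cov:{x1}~{x2}"]], [p[f"cov:{x1}~{x2}"], p[f"var:{x2}"]]]
    )
    Se = np.array(
        [
            [p[f"resvar:{y1}"], p[f"rescov:{y1}~{y2}"]],
            [p[f"rescov:{y1}~{y2}"], p[f"resvar:{y2}"]],
        ]
    )
    G = np.diag([p[f"actor:{r1}"], p[f"actor:{r2}"]])
    B = np.array(
        [
            [0.0, p[feedback_label(design, r2, r1)]],
            [p[feedback_label(design, r1, r2)], 0.0],
        ]
    )
    M = np.linalg.inv(np.eye(2) - B)
    Syy = M @ (G @ Sxx @ G.T + Se) @ M.T
    Sxy = Sxx @ G.T @ M.T
    cov = np.block([[Sxx, Sxy], [Sxy.T, Syy]])
    return pd.DataFrame(cov, index=names, columns=names)


def _draw_scores(spec: GeneratorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    cov = implied_population_covariance(spec).to_numpy()
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 4))
    return spec.means + z @ L.T


def simulate_dyads(spec: GeneratorSpec, seed: int | None = None) -> DyadTable:
    """Draw ``spec.n`` dyads from the implied multivariate normal.

    Bit-for-bit reproducible for a fixed seed (``spec.seed`` unless
    overridden).  Columns follow the design's canonical naming, so the
    table round-trips through :func:`dyadkit.dyad_data.read_dyad_table`.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    scores = _draw_scores(spec, spec.n, rng)
    design = spec.design
    df = pd.DataFrame(scores, columns=list(design.variable_order))
    df.insert(0, "dyad_id", np.arange(1, spec.n + 1))
    return DyadTable(df, design.roles, (design.predictor, design.outcome))


@dataclass
class RecoveryResult:
    """Parameter-recovery summary over Monte Carlo replicates."""

    table: pd.DataFrame  # index (n, label); bias/RMSE/coverage columns
    rejection_rate: dict  # n -> equality-test rejection rate (if requested)
    nonconvergence: dict  # n -> fraction of failed replicates
    valid: bool  # False when any cell exceeds 5% non-convergence


def _replicate_rng(seed: int, n_index: int, rep: int) -> np.random.Generator:
    # counter scheme: one master seed, children keyed by (grid cell, replicate)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(n_index, rep))
    )


def recovery_experiment(
    spec: GeneratorSpec,
    replicates: int = 500,
    n_grid: Sequence[int] = (1000,),
    alpha: float = 0.05,
    equality: str | None = None,
    compute_se: bool = True,
    n_mult: str = "n",
) -> RecoveryResult:
    """Simulate-and-refit experiment: bias, RMSE and Wald coverage.

    For each grid sample size, ``replicates`` datasets are drawn from
    ``spec`` and the matching basic model is refitted.  When ``equality``
    names a constraint (``"actor"``, ``"partner"`` or ``"feedback"``) whose
    population values are equal, the corresponding chi-square difference
    test is run each replicate and its rejection rate reported — under a
    true constraint this estimates the test's type-I error.
    """
    if replicates < 50:
        raise UsageError("use at least 50 replicates for stable summaries")
    model = spec.model()
    truth = {lb: spec.params[lb] for lb in model.free_labels}
    constrained = None
    if equality is not None:
        constrained = spec.model(f"{equality}_equal")
        tied = [lb for lb in model.free_labels if lb.startswith(equality)]
        vals = {spec.params[lb] for lb in tied}
        if len(vals) > 1:
            raise UsageError(
                f"population does not satisfy the {equality}-equality constraint"
            )
    rows = []
    rejection: dict[int, float] = {}
    nonconv: dict[int, float] = {}
    for ni, n in enumerate(n_grid):
        estimates = np.full((replicates, model.n_free), np.nan)
        ses = np.full((replicates, model.n_free), np.nan)
        rejects = 0
        tested = 0
        failed = 0
        for rep in range(replicates):
            rng = _replicate_rng(spec.seed, ni, rep)
            scores = _draw_scores(spec, n, rng)
            S = np.cov(scores, rowvar=False, ddof=1)
            try:
                fit = sem.fit_ml(
                    model, S, n, n_mult=n_mult, compute_se=compute_se, seed=rep
                )
                if not fit.converged:
                    failed += 1
                    continue
            except sem.SemError:
                failed += 1
                continue
            estimates[rep] = fit.params["estimate"].to_numpy()
            if compute_se:
                ses[rep] = fit.params["se"].to_numpy()
            if constrained is not None:
                try:
                    cfit = sem.fit_ml(
                        constrained, S, n, n_mult=n_mult, compute_se=False, seed=rep
                    )
                    cmp_ = sem.chisq_diff_test(cfit, fit)
                    tested += 1
                    rejects += cmp_.pvalue < alpha
                except sem.SemError:
                    pass
        ok = ~np.isnan(estimates[:, 0])
        est = estimates[ok]
        for j, lb in enumerate(model.free_labels):
            true_val = truth[lb]
            mean_est = est[:, j].mean()
            row = {
                "n": n,
                "label": lb,
                "truth": true_val,
                "mean_estimate": mean_est,
                "bias": mean_est - true_val,
                "rmse": float(np.sqrt(np.mean((est[:, j] - true_val) ** 2))),
                "sd_estimate": est[:, j].std(ddof=1),
            }
            if compute_se:
                se_ok = ses[ok][:, j]
                z975 = 1.959963984540054
                covered = np.abs(est[:, j] - true_val) <= z975 * se_ok
                row["mean_se"] = float(np.nanmean(se_ok))
                row["coverage"] = float(np.mean(covered))
            rows.append(row)
        nonconv[n] = failed / replicates
        if constrained is not None and tested:
            rejection[n] = rejects / tested
    table = pd.DataFrame(rows).set_index(["n", "label"])
    valid = all(f <= 0.05 for f in nonconv.values())
    return RecoveryResult(table, rejection, nonconv, valid)
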