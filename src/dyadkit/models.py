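"""Builders and post-processors for the three classical dyadic frameworks.

For distinguishable dyads with one predictor X and one outcome Y per
member, three covariance-structure models dominate applied work:

* **APIM** (actor-partner interdependence model): each member's Y is
  regressed on both members' X.  Actor effects ``a1, a2`` capture the
  within-person association; partner effects ``p12, p21`` the cross-person
  one.  The exogenous X-X covariance absorbs partner similarity on the
  predictor and the residual Y-Y covariance the unexplained
  nonindependence.  The basic model is saturated (df = 0).

* **MIM** (mutual influence model): instead of partner X paths, the two
  outcomes influence each other directly (``Y1 <-> Y2`` feedback), making
  the model nonrecursive.  Each X serves as the instrument that identifies
  the feedback path into the other member's outcome; the basic model is
  just-identified.  Each member's X affects the partner's Y only
  indirectly, through the member's own Y.

* **CFM** (common fate model): couple-level latent variables, each
  measured by the two members' scores with unit loadings, carry the X-Y
  effect; within-person residual covariances absorb individual-level
  association (df = 1).

Gender (role) equality of effects is tested by fitting variants whose path
labels are shared, and comparing chi-squares of nested models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import sem
from .dyad_data import SummaryMoments
from .sem import FitResult, Fixed, Free, PathModel, UsageError

__all__ = [
    "DyadDesign",
    "HypothesisReport",
    "build_apim",
    "build_mim",
    "build_cfm",
    "mim_indirect_effects",
    "cfm_latent_r2",
    "run_hypothesis_suite",
    "APIM_VARIANTS",
    "MIM_VARIANTS",
]

APIM_VARIANTS = ("basic", "actor_equal", "partner_equal", "both_equal")
MIM_VARIANTS = ("basic", "actor_equal", "feedback_equal", "both_equal")


@dataclass(frozen=True)
class DyadDesign:
    """Mapping of roles and variables into the 4-variable dyadic layout.

    ``roles`` orders the two distinguishable members; ``predictor`` and
    ``outcome`` are the per-member variable names.  Observed columns follow
    the ``"<variable>_<role>"`` convention of :mod:`dyadkit.dyad_data`.
    """

    roles: tuple[str, str] = ("man", "woman")
    predictor: str = "anxiety"
    outcome: str = "satisfaction"

    def __post_init__(self) -> None:
        if len(self.roles) != 2 or self.roles[0] == self.roles[1]:
            raise UsageError("a dyad design needs two distinct roles")
        if self.predictor == self.outcome:
            raise UsageError("predictor and outcome variables must differ")

    def x(self, role: str) -> str:
        return f"{self.predictor}_{role}"

    def y(self, role: str) -> str:
        return f"{self.outcome}_{role}"

    @property
    def variable_order(self) -> tuple[str, str, str, str]:
        """(x1, x2, y1, y2): predictors first, members in role order."""
        r1, r2 = self.roles
        return (self.x(r1), self.x(r2), self.y(r1), self.y(r2))

    def covariance(self, moments: SummaryMoments) -> pd.DataFrame:
        """Sample covariance over the four analysis variables, design order."""
        m = moments.reorder(self.variable_order)
        return pd.DataFrame(m.covariance(), index=m.names, columns=m.names)

    def swapped(self) -> "DyadDesign":
        return DyadDesign((self.roles[1], self.roles[0]), self.predictor, self.outcome)


def _exogenous_block(design: DyadDesign) -> dict:
    r1, r2 = design.roles
    x1, x2 = design.x(r1), design.x(r2)
    return {
        (x1, x1): Free(f"var:{x1}"),
        (x2, x2): Free(f"var:{x2}"),
        (x1, x2): Free(f"cov:{x1}~{x2}"),
    }


def _residual_block(design: DyadDesign) -> dict:
    r1, r2 = design.roles
    y1, y2 = design.y(r1), design.y(r2)
    return {
        (y1, y1): Free(f"resvar:{y1}"),
        (y2, y2): Free(f"resvar:{y2}"),
        (y1, y2): Free(f"rescov:{y1}~{y2}"),
    }


def actor_label(design: DyadDesign, role: str, pooled: bool = False) -> str:
    return "actor" if pooled else f"actor:{role}"


def partner_label(
    design: DyadDesign, from_role: str, to_role: str, pooled: bool = False
) -> str:
    return "partner" if pooled else f"partner:{from_role}->{to_role}"


def feedback_label(
    design: DyadDesign, from_role: str, to_role: str, pooled: bool = False
) -> str:
    return "feedback" if pooled else f"feedback:{from_role}->{to_role}"


def build_apim(design: DyadDesign, variant: str = "basic") -> PathModel:
    """Actor-partner interdependence model over the four observed scores.

    Variants tie labels to impose gender-equality constraints:
    ``actor_equal`` pools the two actor effects, ``partner_equal`` the two
    partner effects, ``both_equal`` both, giving df = 0/1/1/2.
    """
    if variant not in APIM_VARIANTS:
        raise UsageError(f"unknown APIM variant {variant!r}; use one of {APIM_VARIANTS}")
    tie_a = variant in ("actor_equal", "both_equal")
    tie_p = variant in ("partner_equal", "both_equal")
    r1, r2 = design.roles
    paths = {
        (design.y(r1), design.x(r1)): Free(actor_label(design, r1, tie_a)),
        (design.y(r2), design.x(r2)): Free(actor_label(design, r2, tie_a)),
        (design.y(r1), design.x(r2)): Free(partner_label(design, r2, r1, tie_p)),
        (design.y(r2), design.x(r1)): Free(partner_label(design, r1, r2, tie_p)),
    }
    covs = {**_exogenous_block(design), **_residual_block(design)}
    return PathModel(
        observed=design.variable_order,
        paths=paths,
        covariances=covs,
        name=f"APIM[{variant}]",
    )


def build_mim(design: DyadDesign, variant: str = "basic") -> PathModel:
    """Mutual influence model: actor paths plus reciprocal outcome paths.

    Nonrecursive and just-identified in its basic form; each member's
    predictor identifies the feedback path into the other member's
    outcome.  ``feedback_equal`` pools the two reciprocal paths.
    """
    if variant not in MIM_VARIANTS:
        raise UsageError(f"unknown MIM variant {variant!r}; use one of {MIM_VARIANTS}")
    tie_a = variant in ("actor_equal", "both_equal")
    tie_b = variant in ("feedback_equal", "both_equal")
    r1, r2 = design.roles
    paths = {
        (design.y(r1), design.x(r1)): Free(actor_label(design, r1, tie_a)),
        (design.y(r2), design.x(r2)): Free(actor_label(design, r2, tie_a)),
        (design.y(r1), design.y(r2)): Free(feedback_label(design, r2, r1, tie_b)),
        (design.y(r2), design.y(r1)): Free(feedback_label(design, r1, r2, tie_b)),
    }
    covs = {**_exogenous_block(design), **_residual_block(design)}
    return PathModel(
        observed=design.variable_order,
        paths=paths,
        covariances=covs,
        name=f"MIM[{variant}]",
    )


def latent_names(design: DyadDesign) -> tuple[str, str]:
    """Names of the couple-level latent predictor and outcome."""
    return f"{design.predictor}_dyad", f"{design.outcome}_dyad"


def build_cfm(design: DyadDesign, latent_scaling: str = "unit_loadings") -> PathModel:
    """Common fate model with couple-level latent predictor and outcome.

    With the default ``unit_loadings`` scaling, all four factor loadings
    are fixed to 1 and the latent variances/residual are free (9 free
    parameters, df = 1).  ``fixed_variance`` instead fixes the latent
    predictor variance to 1 and frees a shared loading per construct (a
    tau-equivalent parameterization, df = 0); it is provided for scale
    sensitivity checks, not as the default.
    """
    r1, r2 = design.roles
    lx, ly = latent_names(design)
    x1, x2 = design.x(r1), design.x(r2)
    y1, y2 = design.y(r1), design.y(r2)
    if latent_scaling == "unit_loadings":
        loadings = {
            (x1, lx): Fixed(1.0),
            (x2, lx): Fixed(1.0),
            (y1, ly): Fixed(1.0),
            (y2, ly): Fixed(1.0),
        }
        lx_var = Free(f"var:{lx}")
    elif latent_scaling == "fixed_variance":
        loadings = {
            (x1, lx): Free(f"loading:{design.predictor}"),
            (x2, lx): Free(f"loading:{design.predictor}"),
            (y1, ly): Free(f"loading:{design.outcome}"),
            (y2, ly): Free(f"loading:{design.outcome}"),
        }
        lx_var = Fixed(1.0)
    else:
        raise UsageError(
            "latent_scaling must be 'unit_loadings' or 'fixed_variance'"
        )
    paths = {**loadings, (ly, lx): Free("latent_effect")}
    covs = {
        (lx, lx): lx_var,
        (ly, ly): Free(f"resvar:{ly}"),
        (x1, x1): Free(f"resvar:{x1}"),
        (x2, x2): Free(f"resvar:{x2}"),
        (y1, y1): Free(f"resvar:{y1}"),
        (y2, y2): Free(f"resvar:{y2}"),
        (x1, y1): Free(f"rescov:{r1}"),
        (x2, y2): Free(f"rescov:{r2}"),
    }
    return PathModel(
        observed=design.variable_order,
        latent=(lx, ly),
        paths=paths,
        covariances=covs,
        name=f"CFM[{latent_scaling}]",
    )


# ---------------------------------------------------------------------------
# Post-processors


def mim_indirect_effects(fit: FitResult) -> pd.DataFrame:
    """Indirect effects of each member's predictor on the partner's outcome.

    In the MIM, X1 reaches Y2 only through Y1, so the indirect effect is
    ``actor1 * feedback(Y1 -> Y2)``.  Standard errors use the first-order
    delta method on the estimated parameter covariance.
    """
    model = fit.model
    if fit.vcov is None:
        raise UsageError("indirect effects need a fit with standard errors")
    obs = set(model.observed)
    actor_into: dict[str, str] = {}
    feedback: list[tuple[str, str, str]] = []  # (src_y, dst_y, label)
    for (dst, src), entry in model.paths.items():
        if isinstance(entry, Fixed):
            continue
        if entry.label.startswith("actor"):
            actor_into[dst] = entry.label
        elif entry.label.startswith("feedback"):
            feedback.append((src, dst, entry.label))
    if not feedback or not actor_into:
        raise UsageError("model does not look like a mutual influence model")
    rows = []
    for src_y, dst_y, fb_label in sorted(
        feedback, key=lambda t: model.observed.index(t[1])
    ):
        a_label = actor_into[src_y]
        a = fit.estimate(a_label)
        b = fit.estimate(fb_label)
        est = a * b
        V = fit.vcov.loc[[a_label, fb_label], [a_label, fb_label]].to_numpy()
        grad = np.array([b, a])
        var = float(grad @ V @ grad)
        se = np.sqrt(var) if var > 0 else np.nan
        z = est / se if np.isfinite(se) and se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "path": f"{a_label} x {fb_label}",
                "through": src_y,
                "outcome": dst_y,
                "estimate": est,
                "se": se,
                "z": z,
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows).set_index("path")


def cfm_latent_r2(fit: FitResult) -> float:
    """Percent of latent-outcome variance explained in a common fate model.

    ``R^2 = b^2 * phi / (b^2 * phi + psi)`` where ``b`` is the latent
    regression, ``phi`` the latent predictor variance and ``psi`` the
    latent residual variance.  A negative fitted ``psi`` (Heywood case) is
    clipped to zero with a warning.
    """
    model = fit.model
    if len(model.latent) != 2 or "latent_effect" not in model.free_labels:
        raise UsageError("fit is not from a common fate model")
    into = {dst for (dst, src), e in model.paths.items() if src in model.latent and dst in model.latent}
    ly = into.pop()
    lx = next(lv for lv in model.latent if lv != ly)
    b = fit.estimate("latent_effect")
    phi_entry = model.covariances[(lx, lx)]
    phi = (
        phi_entry.value if isinstance(phi_entry, Fixed) else fit.estimate(phi_entry.label)
    )
    psi = fit.estimate(model.covariances[(ly, ly)].label)
    if psi < 0:
        import warnings

        warnings.warn(
            f"negative latent residual variance {psi:.4f} clipped to 0 "
            "when computing explained variance",
            stacklevel=2,
        )
        psi = 0.0
    total = b * b * phi + psi
    return 100.0 * (b * b * phi / total) if total > 0 else np.nan


# ---------------------------------------------------------------------------
# Hypothesis suite


@dataclass(frozen=True)
class HypothesisRecord:
    id: int
    description: str
    test: str
    statistic: float
    pvalue: float
    supported: bool
    detail: dict = field(default_factory=dict)


@dataclass
class HypothesisReport:
    """Decisions for the seven standard dyadic hypotheses at level alpha."""

    alpha: float
    records: list[HypothesisRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "description": r.description,
                    "test": r.test,
                    "statistic": r.statistic,
                    "pvalue": r.pvalue,
                    "supported": r.supported,
                }
                for r in self.records
            ]
        ).set_index("id")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "hypotheses": [
                {
                    "id": r.id,
                    "description": r.description,
                    "test": r.test,
                    "statistic": None if np.isnan(r.statistic) else float(r.statistic),
                    "pvalue": None if np.isnan(r.pvalue) else float(r.pvalue),
                    "supported": bool(r.supported),
                    "detail": r.detail,
                }
                for r in self.records
            ],
        }

    def to_text(self) -> str:
        lines = [f"Hypothesis decisions at alpha = {self.alpha}"]
        for r in self.records:
            verdict = "supported" if r.supported else "not supported"
            lines.append(
                f"H{r.id}: {r.description}\n     {r.test}: statistic = "
                f"{r.statistic:.3f}, p = {r.pvalue:.3f} -> {verdict}"
            )
        return "\n".join(lines)


def run_hypothesis_suite(
    moments: SummaryMoments,
    design: DyadDesign,
    alpha: float = 0.05,
    n_mult: str = "n",
) -> HypothesisReport:
    """Test the seven standard dyadic hypotheses from summary moments.

    H1/H2: actor and partner effects in the saturated APIM (H2 combines
    the per-direction tests with the pooled partner effect from the
    equality-constrained variant, since a pooled effect can be reliable
    even when one direction alone is not).  H3/H4: gender differences in
    actor/partner effects via chi-square difference tests.  H5/H6: the
    analogous feedback tests in the MIM.  H7: the couple-level effect in
    the CFM.
    """
    S = design.covariance(moments)
    n = moments.n
    r1, r2 = design.roles

    apim_fits = {
        v: sem.fit_ml(build_apim(design, v), S, n, n_mult=n_mult)
        for v in ("basic", "actor_equal", "partner_equal")
    }
    mim_fits = {
        v: sem.fit_ml(build_mim(design, v), S, n, n_mult=n_mult)
        for v in ("basic", "feedback_equal")
    }
    cfm_fit = sem.fit_ml(build_cfm(design), S, n, n_mult=n_mult)

    m1 = apim_fits["basic"]
    records: list[HypothesisRecord] = []

    # H1: actor effects
    actor_p = {r: float(m1.params.loc[actor_label(design, r), "pvalue"]) for r in design.roles}
    worst = max(actor_p, key=lambda r: actor_p[r])
    records.append(
        HypothesisRecord(
            1,
            "each member's predictor is associated with their own outcome "
            "(actor effects)",
            "z tests of both actor paths, saturated APIM",
            float(m1.params.loc[actor_label(design, worst), "z"]),
            actor_p[worst],
            all(p < alpha for p in actor_p.values()),
            {
                r: {
                    "estimate": m1.estimate(actor_label(design, r)),
                    "pvalue": actor_p[r],
                }
                for r in design.roles
            },
        )
    )

    # H2: partner effects (per direction + pooled)
    m3 = apim_fits["partner_equal"]
    pooled_p = float(m3.params.loc["partner", "pvalue"])
    detail = {
        f"{a}->{b}": {
            "estimate": m1.estimate(partner_label(design, a, b)),
            "pvalue": float(m1.params.loc[partner_label(design, a, b), "pvalue"]),
        }
        for a, b in ((r1, r2), (r2, r1))
    }
    detail["pooled"] = {"estimate": m3.estimate("partner"), "pvalue": pooled_p}
    records.append(
        HypothesisRecord(
            2,
            "each member's predictor is associated with the partner's outcome "
            "(partner effects)",
            "z test of the pooled partner path (equality-constrained APIM), "
            "per-direction tests reported",
            float(m3.params.loc["partner", "z"]),
            pooled_p,
            pooled_p < alpha,
            detail,
        )
    )

    # H3/H4: equality of actor / partner effects
    for hid, variant, what in (
        (3, "actor_equal", "actor"),
        (4, "partner_equal", "partner"),
    ):
        cmp_ = sem.chisq_diff_test(apim_fits[variant], m1)
        records.append(
            HypothesisRecord(
                hid,
                f"the two {what} effects differ between roles",
                f"chi-square difference, {what}-equal APIM vs saturated APIM",
                cmp_.delta_chisq,
                cmp_.pvalue,
                cmp_.pvalue < alpha,
                {"delta_df": cmp_.delta_df},
            )
        )

    # H5: dyadic feedback
    m5 = mim_fits["basic"]
    fb = {
        f"{a}->{b}": {
            "estimate": m5.estimate(feedback_label(design, a, b)),
            "pvalue": float(m5.params.loc[feedback_label(design, a, b), "pvalue"]),
            "z": float(m5.params.loc[feedback_label(design, a, b), "z"]),
        }
        for a, b in ((r1, r2), (r2, r1))
    }
    best_dir = min(fb, key=lambda k: fb[k]["pvalue"])
    records.append(
        HypothesisRecord(
            5,
            "the two members' outcomes feed back on one another (mutual influence)",
            "z tests of both feedback paths, basic MIM",
            fb[best_dir]["z"],
            fb[best_dir]["pvalue"],
            any(v["pvalue"] < alpha for v in fb.values()),
            fb,
        )
    )

    # H6: equality of feedback effects
    cmp_ = sem.chisq_diff_test(mim_fits["feedback_equal"], m5)
    records.append(
        HypothesisRecord(
            6,
            "the two feedback effects differ between roles",
            "chi-square difference, feedback-equal MIM vs basic MIM",
            cmp_.delta_chisq,
            cmp_.pvalue,
            cmp_.pvalue < alpha,
            {"delta_df": cmp_.delta_df},
        )
    )

    # H7: couple-level effect
    records.append(
        HypothesisRecord(
            7,
            "the couple-level predictor is associated with the couple-level outcome",
            "z test of the latent regression, CFM",
            float(cfm_fit.params.loc["latent_effect", "z"]),
            float(cfm_fit.params.loc["latent_effect", "pvalue"]),
            float(cfm_fit.params.loc["latent_effect", "pvalue"]) < alpha,
            {
                "estimate": cfm_fit.estimate("latent_effect"),
                "explained_variance_pct": cfm_latent_r2(cfm_fit),
            },
        )
    )
    return HypothesisReport(alpha, records)
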