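"""Maximum-likelihood covariance-structure estimation for small path models.

Models are specified in RAM form: a directed-path matrix ``A`` (entry
``A[i, j]`` is the path from variable ``j`` to variable ``i``), a symmetric
variance/covariance matrix ``S``, and a filter ``F`` selecting the observed
variables.  The model-implied covariance of the observed variables is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

which covers recursive path models, nonrecursive (feedback) models, and
latent-variable models alike.  Parameters are *labelled*; entries sharing a
label share one free parameter, which is how equality constraints are
imposed.

Estimation minimizes the normal-theory ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

and reports ``chi2 = N_mult * F_ML(theta_hat)``.  By default ``N_mult = n``
and the input sample covariance (``n-1`` denominator, the descriptive
convention) is rescaled internally by ``(n-1)/n``, matching the common
ML convention of covariance-SEM software; ``n_mult="n-1"`` switches to the
Wishart-likelihood convention used by other packages.  Only the covariance
structure is fitted; means are treated as saturated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemError",
    "MatrixDomainError",
    "NonrecursiveInstabilityError",
    "UnderIdentifiedError",
    "ConvergenceError",
    "OracleScopeError",
    "UsageError",
    "Fixed",
    "Free",
    "PathModel",
    "FitResult",
    "ModelComparison",
    "implied_covariance",
    "ml_discrepancy",
    "fit_ml",
    "fit_indices",
    "chisq_diff_test",
    "saturated_path_oracle",
    "default_start_values",
]


class SemError(Exception):
    """Base class for estimation errors."""


class MatrixDomainError(SemError):
    """A covariance matrix is outside the positive-definite domain."""


class NonrecursiveInstabilityError(SemError):
    """(I - A) is singular: a feedback loop has unit gain."""


class UnderIdentifiedError(SemError):
    """More free parameters than observed moments (df < 0)."""


class ConvergenceError(SemError):
    """The optimizer failed to converge; carries the best point found."""

    def __init__(self, message: str, theta: Mapping[str, float] | None = None):
        super().__init__(message)
        self.theta = dict(theta) if theta else None


class OracleScopeError(SemError):
    """The closed-form oracle only handles just-identified systems."""


class UsageError(SemError):
    """Invalid combination of arguments (e.g. non-nested comparison)."""


# ---------------------------------------------------------------------------
# Parameter entries and the RAM model


@dataclass(frozen=True)
class Fixed:
    """A fixed matrix entry (e.g. a factor loading set to 1)."""

    value: float


@dataclass(frozen=True)
class Free:
    """A free matrix entry; entries sharing ``label`` share one parameter."""

    label: str
    start: float | None = None


Entry = Fixed | Free


class PathModel:
    """RAM-form path model over named variables.

    Parameters
    ----------
    observed, latent : sequences of variable names (observed first in the
        internal order).
    paths : mapping ``(dst, src) -> Fixed | Free`` of directed paths
        ``src -> dst``.  Absent entries are structural zeros.
    covariances : mapping ``(a, b) -> Fixed | Free`` of variance
        (``a == b``) and covariance entries; symmetric by construction.
    """

    def __init__(
        self,
        observed: Sequence[str],
        paths: Mapping[tuple[str, str], Entry],
        covariances: Mapping[tuple[str, str], Entry],
        latent: Sequence[str] = (),
        name: str = "model",
    ):
        self.observed = tuple(observed)
        self.latent = tuple(latent)
        self.variables = self.observed + self.latent
        self.name = name
        if len(set(self.variables)) != len(self.variables):
            raise UsageError("variable names must be unique")
        index = {v: i for i, v in enumerate(self.variables)}
        for dst, src in paths:
            if dst not in index or src not in index:
                raise UsageError(f"path ({dst!r}, {src!r}) names unknown variables")
        self.paths = dict(paths)
        covs: dict[tuple[str, str], Entry] = {}
        for (a, b), entry in covariances.items():
            if a not in index or b not in index:
                raise UsageError(f"covariance ({a!r}, {b!r}) names unknown variables")
            key = (a, b) if index[a] <= index[b] else (b, a)
            if key in covs and covs[key] != entry:
                raise UsageError(f"conflicting entries for covariance {key}")
            covs[key] = entry
        self.covariances = covs
        self._index = index
        self._compile()

    # -- structure ---------------------------------------------------------

    def _compile(self) -> None:
        k = len(self.variables)
        labels: list[str] = []
        starts: dict[str, float] = {}

        def register(entry: Entry) -> int:
            if entry.label not in starts:
                labels.append(entry.label)
                starts[entry.label] = entry.start if entry.start is not None else np.nan
            elif entry.start is not None and np.isnan(starts[entry.label]):
                starts[entry.label] = entry.start
            return labels.index(entry.label)

        A0 = np.zeros((k, k))
        S0 = np.zeros((k, k))
        a_slots: list[tuple[int, int, int]] = []  # (row, col, theta index)
        s_slots: list[tuple[int, int, int]] = []
        for (dst, src), entry in sorted(
            self.paths.items(), key=lambda kv: (self._index[kv[0][0]], self._index[kv[0][1]])
        ):
            i, j = self._index[dst], self._index[src]
            if isinstance(entry, Fixed):
                A0[i, j] = entry.value
            else:
                a_slots.append((i, j, register(entry)))
        variance_labels: set[str] = set()
        for (a, b), entry in sorted(
            self.covariances.items(), key=lambda kv: (self._index[kv[0][0]], self._index[kv[0][1]])
        ):
            i, j = self._index[a], self._index[b]
            if isinstance(entry, Fixed):
                S0[i, j] = S0[j, i] = entry.value
            else:
                s_slots.append((i, j, register(entry)))
                if i == j:
                    variance_labels.add(entry.label)
        self.free_labels: tuple[str, ...] = tuple(labels)
        self.variance_labels = frozenset(variance_labels)
        self._A0, self._S0 = A0, S0
        self._a_slots = a_slots
        self._s_slots = s_slots
        self._starts = starts

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    @property
    def n_moments(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def declared_starts(self) -> dict[str, float]:
        return {k: v for k, v in self._starts.items() if not np.isnan(v)}

    # -- numerics ----------------------------------------------------------

    def theta_vector(self, theta: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(theta, Mapping):
            missing = [lb for lb in self.free_labels if lb not in theta]
            if missing:
                raise UsageError(f"missing parameter values for {missing}")
            return np.array([theta[lb] for lb in self.free_labels], dtype=float)
        vec = np.asarray(theta, dtype=float)
        if vec.shape != (self.n_free,):
            raise UsageError(f"theta must have length {self.n_free}")
        return vec

    def matrices(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """(A, S) matrices at the given parameter values."""
        vec = self.theta_vector(theta)
        A = self._A0.copy()
        S = self._S0.copy()
        for i, j, t in self._a_slots:
            A[i, j] = vec[t]
        for i, j, t in self._s_slots:
            S[i, j] = vec[t]
            S[j, i] = vec[t]
        return A, S

    def _feedback_cycle(self) -> list[str] | None:
        """A directed cycle among path entries, if one exists."""
        adjacency: dict[str, list[str]] = {v: [] for v in self.variables}
        for dst, src in self.paths:
            adjacency[src].append(dst)
        color: dict[str, int] = {}
        stack: list[str] = []

        def visit(v: str) -> list[str] | None:
            color[v] = 1
            stack.append(v)
            for w in adjacency[v]:
                if color.get(w, 0) == 1:
                    return stack[stack.index(w):] + [w]
                if color.get(w, 0) == 0:
                    found = visit(w)
                    if found:
                        return found
            stack.pop()
            color[v] = 2
            return None

        for v in self.variables:
            if color.get(v, 0) == 0:
                found = visit(v)
                if found:
                    return found
        return None

    # -- serialization -----------------------------------------------------

    @staticmethod
    def _entry_to_dict(entry: Entry) -> dict:
        if isinstance(entry, Fixed):
            return {"fixed": entry.value}
        d = {"label": entry.label}
        if entry.start is not None:
            d["start"] = entry.start
        return d

    @staticmethod
    def _entry_from_dict(d: Mapping) -> Entry:
        if "fixed" in d:
            return Fixed(float(d["fixed"]))
        return Free(str(d["label"]), d.get("start"))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "observed": list(self.observed),
            "latent": list(self.latent),
            "paths": [
                {"to": dst, "from": src, **self._entry_to_dict(e)}
                for (dst, src), e in self.paths.items()
            ],
            "covariances": [
                {"between": [a, b], **self._entry_to_dict(e)}
                for (a, b), e in self.covariances.items()
            ],
        }

    def to_text(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathModel":
        return cls(
            observed=d["observed"],
            latent=d.get("latent", ()),
            paths={(p["to"], p["from"]): cls._entry_from_dict(p) for p in d["paths"]},
            covariances={
                tuple(c["between"]): cls._entry_from_dict(c) for c in d["covariances"]
            },
            name=d.get("name", "model"),
        )


# ---------------------------------------------------------------------------
# Implied covariance and the ML discrepancy


def implied_covariance(model: PathModel, theta) -> np.ndarray:
    """Model-implied covariance ``F (I-A)^-1 S (I-A)^-T F^T``."""
    A, S = model.matrices(theta)
    k = len(model.variables)
    I = np.eye(k)
    try:
        B = np.linalg.solve(I - A, I)
    except np.linalg.LinAlgError:
        cycle = model._feedback_cycle()
        loop = " -> ".join(cycle) if cycle else "unknown"
        raise NonrecursiveInstabilityError(
            f"(I - A) is singular; the feedback loop {loop} has unit gain"
        ) from None
    full = B @ S @ B.T
    p = model.n_observed
    sigma = full[:p, :p]
    return (sigma + sigma.T) / 2


def _chol_logdet(M: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise MatrixDomainError(f"{what} matrix is not positive definite") from None
    return L, 2.0 * float(np.log(np.diag(L)).sum())


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy ``ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``.

    Nonnegative, and zero exactly when ``Sigma == S``.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise UsageError("S and Sigma must be square matrices of equal size")
    p = S.shape[0]
    L, logdet_sigma = _chol_logdet(Sigma, "implied")
    _, logdet_s = _chol_logdet(S, "sample")
    half = np.linalg.solve(L, S)
    trace = float(np.linalg.solve(L.T, half).trace())
    return logdet_sigma + trace - logdet_s - p


# ---------------------------------------------------------------------------
# Closed-form oracle for just-identified path systems


def saturated_path_oracle(
    S, equations: Mapping[str, Sequence[str]], names: Sequence[str] | None = None
) -> dict[tuple[str, str], float]:
    """Solve a just-identified observed-variable path system from moments.

    ``equations`` maps each outcome to its predictors.  Exogenous variables
    (those never appearing as outcomes) serve as instruments, so recursive
    equations reduce to normal (OLS) equations and feedback equations to
    instrumental-moment equations.  Each equation must satisfy the
    just-identification order condition: the number of instruments equals
    the number of predictors.
    """
    if isinstance(S, pd.DataFrame):
        names = tuple(S.columns)
        S = S.to_numpy(dtype=float)
    elif names is None:
        raise UsageError("names required when S is a bare array")
    S = np.asarray(S, dtype=float)
    idx = {nm: i for i, nm in enumerate(names)}
    outcomes = set(equations)
    exogenous = [nm for nm in names if nm not in outcomes]
    coefs: dict[tuple[str, str], float] = {}
    for y, preds in equations.items():
        preds = list(preds)
        if len(exogenous) != len(preds):
            raise OracleScopeError(
                f"equation for {y!r} is not just-identified: "
                f"{len(exogenous)} instruments for {len(preds)} predictors"
            )
        G = np.array([[S[idx[z], idx[x]] for x in preds] for z in exogenous])
        g = np.array([S[idx[z], idx[y]] for z in exogenous])
        try:
            b = np.linalg.solve(G, g)
        except np.linalg.LinAlgError:
            raise OracleScopeError(
                f"moment equations for {y!r} are singular"
            ) from None
        for x, bx in zip(preds, b):
            coefs[(y, x)] = float(bx)
    return coefs


def default_start_values(model: PathModel, S: np.ndarray) -> dict[str, float]:
    """Data-driven start values for :func:`fit_ml`.

    Observed-variable paths start at their (instrumental) moment-equation
    solution, averaged across slots sharing a label; free variance and
    covariance slots then start at the entries of ``(I-A) S (I-A)^T``,
    which is exact for saturated models.  Latent-variable slots fall back
    to cross-indicator heuristics (shared variance between two unit-loading
    indicators estimates the latent variance).
    """
    S = np.asarray(S, dtype=float)
    starts: dict[str, float] = {}
    obs = set(model.observed)
    idx = model._index
    # observed-path starts via per-outcome moment equations
    equations: dict[str, list[str]] = {}
    path_labels: dict[tuple[str, str], str] = {}
    latent_paths = False
    for (dst, src), entry in model.paths.items():
        if isinstance(entry, Fixed):
            continue
        if dst in obs and src in obs:
            equations.setdefault(dst, []).append(src)
            path_labels[(dst, src)] = entry.label
        else:
            latent_paths = True
    if equations:
        try:
            sol = saturated_path_oracle(S, equations, names=model.observed)
            grouped: dict[str, list[float]] = {}
            for key, val in sol.items():
                grouped.setdefault(path_labels[key], []).append(val)
            for label, vals in grouped.items():
                starts[label] = float(np.mean(vals))
        except OracleScopeError:
            for label in set(path_labels.values()):
                starts.setdefault(label, 0.0)
    # latent heuristics: latent variance from the covariance of two
    # unit-loading indicators; latent paths from cross-block covariances
    lat_var_guess: dict[str, float] = {}
    if model.latent:
        indicators: dict[str, list[str]] = {lv: [] for lv in model.latent}
        for (dst, src), entry in model.paths.items():
            if src in model.latent and dst in obs:
                indicators[src].append(dst)
        mean_var = float(np.mean(np.diag(S)))
        for lv, inds in indicators.items():
            if len(inds) >= 2:
                guess = abs(S[idx[inds[0]], idx[inds[1]]])
            else:
                guess = 0.5 * mean_var
            lat_var_guess[lv] = max(guess, 0.05 * mean_var)
        for (dst, src), entry in model.paths.items():
            if isinstance(entry, Fixed) or entry.label in starts:
                continue
            if src in model.latent and dst in model.latent:
                xi, yi = indicators.get(src, []), indicators.get(dst, [])
                if xi and yi:
                    cross = np.mean([S[idx[a], idx[b]] for a in xi for b in yi])
                    starts[entry.label] = float(cross / lat_var_guess[src])
                else:
                    starts[entry.label] = 0.0
            elif entry.label not in starts:
                starts[entry.label] = 0.0
    # variance/covariance starts from the residual transform (exact when
    # the observed paths are exact and there are no latents)
    theta0 = [starts.get(lb, 0.0) for lb in model.free_labels]
    A, _ = model.matrices(theta0)
    k = len(model.variables)
    p = model.n_observed
    IA = np.eye(k) - A
    Sfull = np.zeros((k, k))
    Sfull[:p, :p] = S
    resid = IA @ Sfull @ IA.T
    grouped_s: dict[str, list[float]] = {}
    for (a, b), entry in model.covariances.items():
        if isinstance(entry, Fixed) or entry.label in starts:
            continue
        i, j = idx[a], idx[b]
        if a in obs and b in obs and not latent_paths:
            grouped_s.setdefault(entry.label, []).append(float(resid[i, j]))
        elif a in model.latent and b in model.latent:
            if a == b:
                guess = lat_var_guess.get(a, 1.0)
                # endogenous latent: part of its variance is explained
                grouped_s.setdefault(entry.label, []).append(0.5 * guess)
            else:
                grouped_s.setdefault(entry.label, []).append(0.0)
        elif a == b and a in obs:
            lv = next(
                (
                    src
                    for (dst, src) in model.paths
                    if dst == a and src in model.latent
                ),
                None,
            )
            base = S[i, i] - lat_var_guess.get(lv, 0.0)
            grouped_s.setdefault(entry.label, []).append(
                max(base, 0.05 * float(S[i, i]))
            )
        else:
            grouped_s.setdefault(entry.label, []).append(0.0)
    for label, vals in grouped_s.items():
        starts[label] = float(np.mean(vals))
    for label in model.free_labels:
        starts.setdefault(label, 0.0)
    # guard: variances must start positive
    for label in model.variance_labels:
        if starts[label] <= 0:
            starts[label] = 0.1 * float(np.mean(np.diag(S)))
    return starts


# ---------------------------------------------------------------------------
# Fit indices


def fit_indices(
    chisq: float,
    df: int,
    n: int,
    baseline_chisq: float,
    baseline_df: int,
    S: np.ndarray,
    Sigma: np.ndarray,
) -> dict:
    """Standard incremental and absolute fit indices.

    The baseline (independence) model fixes all covariances among observed
    variables to zero with free variances.  TLI is reported capped at 1
    with the raw value retained; RMSEA is 0 by convention (flagged) for
    saturated models.
    """
    if df == 0 and chisq > 1e-6:
        raise UsageError("df = 0 with nonzero chi-square is inconsistent")
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    d = np.sqrt(np.diag(S))
    std_resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices_from(S)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))
    num = max(chisq - df, 0.0)
    denom = max(baseline_chisq - baseline_df, chisq - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    saturated = df == 0
    if saturated:
        tli_raw = 1.0
        rmsea = 0.0
        ratio = np.nan
    else:
        ratio = chisq / df
        base_ratio = baseline_chisq / baseline_df if baseline_df > 0 else np.nan
        tli_raw = (
            (base_ratio - ratio) / (base_ratio - 1.0)
            if np.isfinite(base_ratio) and base_ratio != 1.0
            else np.nan
        )
        rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * n)))
    return {
        "chisq_df_ratio": ratio,
        "cfi": float(cfi),
        "tli": float(min(tli_raw, 1.0)) if np.isfinite(tli_raw) else np.nan,
        "tli_raw": float(tli_raw) if np.isfinite(tli_raw) else np.nan,
        "rmsea": rmsea,
        "srmr": srmr,
        "rmsea_defined": not saturated,
    }


# ---------------------------------------------------------------------------
# ML fitting


@dataclass
class FitResult:
    """Estimates, standard errors, chi-square and fit indices for one model."""

    model: PathModel
    params: pd.DataFrame  # index: label; columns: estimate, se, z, pvalue
    chisq: float
    df: int
    pvalue: float
    discrepancy: float
    indices: dict
    converged: bool
    n: int
    n_mult: str
    vcov: pd.DataFrame | None
    sigma: np.ndarray
    sample_cov: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def estimate(self, label: str) -> float:
        return float(self.params.loc[label, "estimate"])

    def se(self, label: str) -> float:
        return float(self.params.loc[label, "se"])

    def theta(self) -> dict[str, float]:
        return dict(zip(self.params.index, self.params["estimate"]))

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "n": int(self.n),
            "n_mult": self.n_mult,
            "converged": bool(self.converged),
            "chisq": float(self.chisq),
            "df": int(self.df),
            "pvalue": None if np.isnan(self.pvalue) else float(self.pvalue),
            "indices": {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.indices.items()
            },
            "parameters": {
                lb: {
                    "estimate": float(row["estimate"]),
                    "se": None if np.isnan(row["se"]) else float(row["se"]),
                    "z": None if np.isnan(row["z"]) else float(row["z"]),
                    "pvalue": None if np.isnan(row["pvalue"]) else float(row["pvalue"]),
                }
                for lb, row in self.params.iterrows()
            },
            "warnings": list(self.warnings),
        }

    def table(self) -> str:
        lines = [f"Model: {self.model.name}  (n = {self.n})"]
        lines.append(f"{'parameter':<34}{'estimate':>10}{'SE':>10}{'z':>8}{'p':>8}")
        for lb, row in self.params.iterrows():
            se = f"{row['se']:.3f}" if np.isfinite(row["se"]) else "-"
            z = f"{row['z']:.2f}" if np.isfinite(row["z"]) else "-"
            p = f"{row['pvalue']:.3f}" if np.isfinite(row["pvalue"]) else "-"
            lines.append(f"{lb:<34}{row['estimate']:>10.3f}{se:>10}{z:>8}{p:>8}")
        pv = "-" if np.isnan(self.pvalue) else f"{self.pvalue:.3f}"
        lines.append(
            f"chi2 = {self.chisq:.3f}, df = {self.df}, p = {pv}, "
            f"CFI = {self.indices['cfi']:.3f}, TLI = {self.indices['tli']:.3f}, "
            f"RMSEA = {self.indices['rmsea']:.3f}, SRMR = {self.indices['srmr']:.3f}"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio (chi-square difference) comparison of nested models."""

    delta_chisq: float
    delta_df: int
    pvalue: float


def _prepare_sample_cov(S, model: PathModel) -> np.ndarray:
    if isinstance(S, pd.DataFrame):
        missing = [v for v in model.observed if v not in S.columns]
        if missing:
            raise UsageError(f"sample covariance lacks variables {missing}")
        S = S.loc[list(model.observed), list(model.observed)].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    p = model.n_observed
    if S.shape != (p, p):
        raise UsageError(f"sample covariance must be {p}x{p} in model variable order")
    return (S + S.T) / 2


def _numerical_hessian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    k = len(x)
    h = 1e-4 * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


_PENALTY = 1e10


def fit_ml(
    model: PathModel,
    S,
    n: int,
    *,
    n_mult: str = "n",
    start: Mapping[str, float] | None = None,
    compute_se: bool = True,
    max_restarts: int = 5,
    seed: int = 0,
    repair: bool = False,
) -> FitResult:
    """Fit a :class:`PathModel` to a sample covariance by ML.

    ``S`` is the descriptive (``n-1`` denominator) sample covariance, as an
    array in ``model.observed`` order or a labelled DataFrame.  With the
    default ``n_mult="n"`` it is rescaled by ``(n-1)/n`` internally and
    ``chi2 = n * F_ML``; with ``"n-1"`` it is used as-is and
    ``chi2 = (n-1) * F_ML``.

    Standard errors come from the pseudo-inverse of the numerically
    differentiated Hessian of ``N_mult * F_ML / 2`` at the optimum; z tests
    are two-sided standard normal.  Negative fitted variances are reported
    with a Heywood-case warning rather than failing.
    """
    if model.df < 0:
        raise UnderIdentifiedError(
            f"model {model.name!r} has {model.n_free} free parameters for "
            f"{model.n_moments} moments (df = {model.df})"
        )
    if n_mult not in ("n", "n-1"):
        raise UsageError("n_mult must be 'n' or 'n-1'")
    if n < 2:
        raise UsageError("n must be at least 2")
    S_in = _prepare_sample_cov(S, model)
    min_eig = float(np.linalg.eigvalsh(S_in).min())
    if min_eig <= 0:
        if not repair or min_eig < -1e-6 * np.trace(S_in):
            raise MatrixDomainError(
                f"sample covariance is not positive definite "
                f"(min eigenvalue {min_eig:.3e}); pass repair=True for a "
                "nearest-PD adjustment of rounding-level deficiency"
            )
        w, v = np.linalg.eigh(S_in)
        floor = 1e-8 * np.trace(S_in) / len(w)
        S_in = (v * np.maximum(w, floor)) @ v.T
    if n_mult == "n":
        S_fit = S_in * (n - 1) / n
        N = n
    else:
        S_fit = S_in
        N = n - 1

    starts = default_start_values(model, S_fit)
    starts.update(model.declared_starts())
    if start:
        starts.update(start)
    x0 = np.array([starts[lb] for lb in model.free_labels], dtype=float)

    def objective(x: np.ndarray) -> float:
        try:
            sigma = implied_covariance(model, x)
            return ml_discrepancy(S_fit, sigma)
        except (MatrixDomainError, NonrecursiveInstabilityError):
            return _PENALTY + float(np.sum(x**2))

    # optimize in a rescaled parameter space so paths (O(1)) and variances
    # (O(var scale)) present comparable curvature to the quasi-Newton updates
    scale = np.maximum(1.0, np.abs(x0))

    def scaled_objective(y: np.ndarray) -> float:
        return objective(scale * y)

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    y_try = x0 / scale
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            scaled_objective, y_try, method="BFGS", options={"gtol": 1e-7, "maxiter": 500}
        )
        if best is None or res.fun < best.fun:
            best = res
        grad_ok = np.max(np.abs(res.jac)) < 1e-6
        if grad_ok and res.fun < _PENALTY:
            converged = True
            best = res
            break
        y_try = x0 / scale + 0.1 * rng.standard_normal(len(x0))
    assert best is not None
    theta_hat = scale * best.x
    fmin = float(best.fun)
    if fmin >= _PENALTY:
        raise ConvergenceError(
            f"model {model.name!r}: no admissible parameter point found",
            dict(zip(model.free_labels, theta_hat)),
        )
    if not converged:
        warnings.warn(
            f"model {model.name!r}: gradient norm criterion not met after "
            f"{max_restarts} restarts; returning best point",
            stacklevel=2,
        )

    chisq = max(N * fmin, 0.0)
    df = model.df
    pvalue = float(stats.chi2.sf(chisq, df)) if df > 0 else np.nan
    sigma_hat = implied_covariance(model, theta_hat)

    # independence baseline: free variances, zero covariances -> MLE is diag(S)
    p = model.n_observed
    _, logdet_s = _chol_logdet(S_fit, "sample")
    baseline_f = float(np.log(np.diag(S_fit)).sum()) - logdet_s
    baseline_chisq = N * baseline_f
    baseline_df = p * (p - 1) // 2
    indices = fit_indices(chisq, df, n, baseline_chisq, baseline_df, S_fit, sigma_hat)

    warn_list: list[str] = []
    for lb, val in zip(model.free_labels, theta_hat):
        if lb in model.variance_labels and val < 0:
            warn_list.append(f"Heywood case: variance parameter {lb!r} = {val:.4f} < 0")

    se = np.full(len(theta_hat), np.nan)
    vcov_df = None
    if compute_se:
        H = _numerical_hessian(lambda x: 0.5 * N * objective(x), theta_hat)
        cond = np.linalg.cond(H)
        if not np.isfinite(cond) or cond > 1e10:
            warn_list.append(
                f"information matrix ill-conditioned (cond = {cond:.2e}); "
                "standard errors may be unreliable"
            )
        vcov = np.linalg.pinv(H)
        diag = np.diag(vcov)
        bad = diag <= 0
        if bad.any():
            warn_list.append(
                "nonpositive information for "
                + ", ".join(np.array(model.free_labels)[bad])
            )
        se = np.where(bad, np.nan, np.sqrt(np.abs(diag)))
        vcov_df = pd.DataFrame(
            vcov, index=model.free_labels, columns=model.free_labels
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = theta_hat / se
    pz = 2.0 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame(
        {"estimate": theta_hat, "se": se, "z": z, "pvalue": pz},
        index=list(model.free_labels),
    )
    for w in warn_list:
        warnings.warn(w, stacklevel=2)
    return FitResult(
        model=model,
        params=params,
        chisq=float(chisq),
        df=df,
        pvalue=pvalue,
        discrepancy=fmin,
        indices=indices,
        converged=converged,
        n=n,
        n_mult=n_mult,
        vcov=vcov_df,
        sigma=sigma_hat,
        sample_cov=S_fit,
        warnings=warn_list,
    )


def chisq_diff_test(restricted: FitResult, full: FitResult) -> ModelComparison:
    """Chi-square difference (likelihood-ratio) test for nested models.

    The restricted model must have more degrees of freedom than the full
    one (e.g. equality constraints imposed on a saturated model).  A
    difference below the numerical tolerance ``-1e-6`` is clipped to zero.
    """
    ddf = restricted.df - full.df
    if ddf <= 0:
        raise UsageError(
            f"restricted model must have more df than full model "
            f"({restricted.df} vs {full.df})"
        )
    if restricted.n != full.n or restricted.n_mult != full.n_mult:
        raise UsageError("models were fitted with different sample conventions")
    d = restricted.chisq - full.chisq
    if d < -1e-6:
        warnings.warn(
            f"negative chi-square difference {d:.3e}; models may not be nested "
            "or one fit did not converge",
            stacklevel=2,
        )
    d = max(d, 0.0)
    return ModelComparison(float(d), int(ddf), float(stats.chi2.sf(d, ddf)))
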