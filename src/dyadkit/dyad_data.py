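"""Reading, scoring and summarizing dyadic data.

Dyadic designs collect the same variables from both members of a pair
(husband/wife, caregiver/patient, ...).  This module handles the wide,
one-row-per-dyad representation used throughout the package: each analysis
variable appears once per member role, and the two roles are
*distinguishable* (they carry meaningful, distinct names).

Beyond raw tables, published reports often print only summary moments —
sample size, means, standard deviations and a correlation matrix.  Those
moments fully determine every covariance-structure model in this package,
so :class:`SummaryMoments` is a first-class input: models can be fitted
without access to the raw data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DyadDataError",
    "ConfigurationError",
    "DataError",
    "InsufficientDataError",
    "DegenerateComparisonError",
    "ScaleDefinition",
    "DyadTable",
    "SummaryMoments",
    "read_dyad_table",
    "score_scale",
    "cronbach_alpha",
    "summarize_dyads",
    "paired_t_from_summary",
    "moments_to_covariance",
    "correlation_pvalue",
]


class DyadDataError(ValueError):
    """Base class for dyadic-data errors."""


class ConfigurationError(DyadDataError):
    """A column mapping or configuration document is invalid."""


class DataError(DyadDataError):
    """The data themselves violate a structural requirement."""


class InsufficientDataError(DyadDataError):
    """Too few complete dyads for the requested summary."""


class DegenerateComparisonError(DyadDataError):
    """A paired comparison with zero difference variance."""


# ---------------------------------------------------------------------------
# Scale scoring


@dataclass(frozen=True)
class ScaleDefinition:
    """A sum-scored questionnaire scale.

    Parameters
    ----------
    name : str
        Scale name, e.g. ``"EMS"`` (10-item marital-satisfaction scale,
        items rated 1-5, totals 10-50) or ``"HADS-A"`` (7-item anxiety
        subscale, items rated 0-3, totals 0-21).
    n_items : int
        Number of items *k*.
    item_min, item_max : int
        Response range shared by every item.
    reverse_items : frozenset[int]
        1-based indices of reverse-keyed items; these are recoded as
        ``item_min + item_max - x`` before summing.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    reverse_items: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigurationError("a scale needs at least one item")
        if self.item_min >= self.item_max:
            raise ConfigurationError("item_min must be below item_max")
        bad = set(self.reverse_items) - set(range(1, self.n_items + 1))
        if bad:
            raise ConfigurationError(
                f"reverse item indices {sorted(bad)} outside 1..{self.n_items}"
            )
        object.__setattr__(self, "reverse_items", frozenset(self.reverse_items))

    @property
    def score_range(self) -> tuple[int, int]:
        """Attainable total-score range ``(k*min, k*max)``."""
        return self.n_items * self.item_min, self.n_items * self.item_max


def score_scale(items: np.ndarray, scale: ScaleDefinition) -> np.ndarray:
    """Sum-score item responses, reverse-coding negatively keyed items.

    ``items`` is ``(k,)`` for a single respondent or ``(n, k)`` for many.
    Returns a scalar array ``()`` or ``(n,)`` of totals, guaranteed to lie
    within ``scale.score_range``.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
        squeeze = True
    elif arr.ndim == 2:
        squeeze = False
    else:
        raise DataError("items must be 1- or 2-dimensional")
    if arr.shape[1] != scale.n_items:
        raise DataError(
            f"expected {scale.n_items} items for scale {scale.name!r}, got {arr.shape[1]}"
        )
    out_of_range = (arr < scale.item_min) | (arr > scale.item_max) | ~np.isfinite(arr)
    if out_of_range.any():
        idx = int(np.argwhere(out_of_range.any(axis=0)).ravel()[0]) + 1
        raise DataError(
            f"item {idx} of scale {scale.name!r} has responses outside "
            f"[{scale.item_min}, {scale.item_max}]"
        )
    recoded = arr.copy()
    for i in scale.reverse_items:
        recoded[:, i - 1] = scale.item_min + scale.item_max - arr[:, i - 1]
    totals = recoded.sum(axis=1)
    return totals[0] if squeeze else totals


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``alpha = k/(k-1) * (1 - sum(var_item) / var_total)`` with sample
    (``ddof=1``) variances, for an ``(n_respondents, k)`` response matrix.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DataError("cronbach_alpha needs a 2-D matrix with >= 2 items")
    if arr.shape[0] < 3:
        raise DataError("cronbach_alpha needs >= 3 respondents")
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DataError("total-score variance is zero; reliability undefined")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


# ---------------------------------------------------------------------------
# Dyad tables


@dataclass
class DyadTable:
    """Wide-format dyadic dataset: one row per dyad.

    Columns follow the canonical naming ``"<variable>_<role>"`` plus a
    ``dyad_id`` column.  Rows with missing analysis values are retained but
    reported by :meth:`incomplete_mask`; summaries use listwise deletion.
    """

    data: pd.DataFrame
    roles: tuple[str, str]
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        self.roles = tuple(self.roles)  # type: ignore[assignment]
        self.variables = tuple(self.variables)  # type: ignore[assignment]
        if len(self.roles) != 2 or self.roles[0] == self.roles[1]:
            raise ConfigurationError("exactly two distinct member roles are required")
        if "dyad_id" not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, "dyad_id", np.arange(1, len(self.data) + 1))
        if self.data["dyad_id"].duplicated().any():
            dup = self.data["dyad_id"][self.data["dyad_id"].duplicated()].iloc[0]
            raise DataError(f"duplicate dyad_id {dup!r}")
        for var in self.variables:
            for role in self.roles:
                if self.column(var, role) not in self.data.columns:
                    raise ConfigurationError(
                        f"missing column for variable {var!r}, role {role!r}"
                    )

    @staticmethod
    def column(variable: str, role: str) -> str:
        return f"{variable}_{role}"

    @property
    def n_dyads(self) -> int:
        return len(self.data)

    @property
    def analysis_columns(self) -> list[str]:
        return [self.column(v, r) for v in self.variables for r in self.roles]

    def incomplete_mask(self, variables: Sequence[str] | None = None) -> pd.Series:
        """Boolean mask of rows missing any requested analysis value."""
        variables = tuple(variables) if variables is not None else self.variables
        cols = [self.column(v, r) for v in variables for r in self.roles]
        return self.data[cols].isna().any(axis=1)

    def scores(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        variables = tuple(variables) if variables is not None else self.variables
        cols = [self.column(v, r) for v in variables for r in self.roles]
        return self.data[cols]

    def write(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        variables: Sequence[str],
        roles: Sequence[str],
        dyad_id: Sequence | None = None,
    ) -> "DyadTable":
        """Build a table from an ``(n, 2v)`` score matrix.

        Column order of ``scores`` is variable-major: for each variable,
        the two roles in order.
        """
        variables = tuple(variables)
        roles = tuple(roles)
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            scores = scores[None, :]
        cols = [cls.column(v, r) for v in variables for r in roles]
        if scores.shape[1] != len(cols):
            raise DataError(
                f"score matrix has {scores.shape[1]} columns, expected {len(cols)}"
            )
        df = pd.DataFrame(scores, columns=cols)
        if dyad_id is not None:
            df.insert(0, "dyad_id", list(dyad_id))
        return cls(df, roles, variables)


def read_dyad_table(path, config: Mapping) -> DyadTable:
    """Read a delimited wide-format file into a :class:`DyadTable`.

    ``config`` maps file columns onto (role, variable) slots::

        roles: [man, woman]
        variables:
          anxiety: {man: anx_m, woman: anx_w}
          satisfaction: {man: ms_m, woman: ms_w}
        dyad_id: couple        # optional
        sep: ","               # optional, tab accepted

    Every variable must be mapped for both roles; a missing mapped column
    raises :class:`ConfigurationError` naming the (role, variable) pair.
    """
    roles = tuple(config.get("roles", ()))
    if len(roles) != 2:
        raise ConfigurationError("config must list exactly two roles")
    var_map = config.get("variables")
    if not isinstance(var_map, Mapping) or not var_map:
        raise ConfigurationError("config must map variables to per-role columns")
    sep = config.get("sep", ",")
    df = pd.read_csv(path, sep=sep)
    rename: dict[str, str] = {}
    for var, cols in var_map.items():
        if not isinstance(cols, Mapping):
            raise ConfigurationError(
                f"variable {var!r} must map each role to a column name"
            )
        for role in roles:
            if role not in cols:
                raise ConfigurationError(
                    f"no column mapped for variable {var!r}, role {role!r}"
                )
            src = cols[role]
            if src not in df.columns:
                raise ConfigurationError(
                    f"column {src!r} (variable {var!r}, role {role!r}) "
                    f"not found in {path}"
                )
            rename[src] = DyadTable.column(var, role)
    id_col = config.get("dyad_id")
    if id_col is not None:
        if id_col not in df.columns:
            raise ConfigurationError(f"dyad_id column {id_col!r} not found in {path}")
        rename[id_col] = "dyad_id"
    df = df.rename(columns=rename)
    keep = (["dyad_id"] if id_col is not None else []) + [
        DyadTable.column(v, r) for v in var_map for r in roles
    ]
    return DyadTable(df[keep], roles, tuple(var_map))


# ---------------------------------------------------------------------------
# Summary moments


@dataclass
class SummaryMoments:
    """Sample size, means, SDs and correlations for dyadic variables.

    ``names`` lists the ``2v`` per-member variable names in a fixed order;
    ``correlations`` is the matching symmetric matrix with unit diagonal.
    SDs follow the conventional ``n-1`` (sample) denominator.  The optional
    ``corr_pvalues`` matrix carries two-sided p-values from the t transform
    ``t = r*sqrt((n-2)/(1-r^2))``.
    """

    n: int
    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    correlations: np.ndarray
    corr_pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = tuple(self.names)  # type: ignore[assignment]
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        k = len(self.names)
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise DataError("means and sds must match the number of variable names")
        if self.correlations.shape != (k, k):
            raise DataError("correlation matrix shape must match variable names")
        if not np.allclose(self.correlations, self.correlations.T, atol=1e-10):
            raise DataError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlations), 1.0, atol=1e-10):
            raise DataError("correlation matrix diagonal must be 1")
        off = self.correlations[~np.eye(k, dtype=bool)]
        if np.any(np.abs(off) > 1.0 + 1e-12):
            raise DataError("correlations must lie in [-1, 1]")
        if np.any(self.sds <= 0):
            raise DataError("standard deviations must be positive")
        min_eig = float(np.linalg.eigvalsh(self.correlations).min())
        if -1e-8 < min_eig < 0:
            warnings.warn(
                f"correlation matrix is marginally non-PSD (min eigenvalue "
                f"{min_eig:.2e}), consistent with printed-value rounding",
                stacklevel=2,
            )

    def covariance(self, repair: bool = False) -> np.ndarray:
        """Covariance matrix implied by SDs and correlations."""
        return moments_to_covariance(self, repair=repair)[0]

    def reorder(self, names: Sequence[str]) -> "SummaryMoments":
        """Return a copy with variables permuted into ``names`` order."""
        idx = [self.names.index(nm) for nm in names]
        return SummaryMoments(
            n=self.n,
            names=tuple(names),
            means=self.means[idx],
            sds=self.sds[idx],
            correlations=self.correlations[np.ix_(idx, idx)],
            corr_pvalues=None
            if self.corr_pvalues is None
            else np.asarray(self.corr_pvalues)[np.ix_(idx, idx)],
        )

    def to_dict(self) -> dict:
        d = {
            "n": int(self.n),
            "names": list(self.names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "correlations": self.correlations.tolist(),
        }
        if self.corr_pvalues is not None:
            d["corr_pvalues"] = np.asarray(self.corr_pvalues).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SummaryMoments":
        return cls(
            n=int(d["n"]),
            names=tuple(d["names"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            correlations=np.asarray(d["correlations"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "SummaryMoments":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def moments_to_covariance(
    moments: SummaryMoments, repair: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance matrix and mean vector implied by summary moments.

    ``cov[i, j] = r[i, j] * sd[i] * sd[j]``.  If the matrix is non-PSD
    beyond rounding tolerance (smallest eigenvalue below ``-1e-8`` on the
    correlation scale), raises unless ``repair=True``, in which case
    negative eigenvalues are clipped to zero (nearest-PSD projection).
    """
    cov = moments.correlations * np.outer(moments.sds, moments.sds)
    min_eig = float(np.linalg.eigvalsh(moments.correlations).min())
    if min_eig <= -1e-8:
        if not repair:
            raise DataError(
                f"moments imply a non-PSD covariance (min correlation eigenvalue "
                f"{min_eig:.2e}); pass repair=True for a nearest-PSD projection"
            )
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        cov = (cov + cov.T) / 2
    return cov, moments.means.copy()


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson correlation via the t transform."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 0.0, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def summarize_dyads(
    table: DyadTable, variables: Sequence[str] | None = None
) -> SummaryMoments:
    """Descriptive summary of a dyad table after listwise deletion.

    Returns :class:`SummaryMoments` over the ``2v`` per-member columns
    (variable-major order), including pairwise correlation p-values.
    Requires at least 3 complete dyads.
    """
    variables = tuple(variables) if variables is not None else table.variables
    scores = table.scores(variables).dropna()
    if len(scores) < 3:
        raise InsufficientDataError(
            f"only {len(scores)} complete dyads; at least 3 required"
        )
    values = scores.to_numpy(dtype=float)
    n = len(values)
    corr = np.corrcoef(values, rowvar=False)
    pvals = correlation_pvalue(corr, n)
    np.fill_diagonal(pvals, np.nan)
    return SummaryMoments(
        n=n,
        names=tuple(scores.columns),
        means=values.mean(axis=0),
        sds=values.std(axis=0, ddof=1),
        correlations=corr,
        corr_pvalues=pvals,
    )


class PairedT(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def paired_t_from_summary(
    mean1: float, mean2: float, sd1: float, sd2: float, r12: float, n: int
) -> PairedT:
    """Paired t test reconstructed from summary moments.

    ``t = (mean1 - mean2) / sqrt((sd1^2 + sd2^2 - 2*r12*sd1*sd2)/n)`` with
    ``n - 1`` degrees of freedom: the variance of the within-dyad
    difference follows from the two SDs and their correlation, so the test
    needs no raw data.
    """
    if n < 2:
        raise DataError("paired t test requires n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise DataError("standard deviations must be positive")
    if not -1.0 <= r12 <= 1.0:
        raise DataError("correlation must lie in [-1, 1]")
    diff_var = sd1**2 + sd2**2 - 2.0 * r12 * sd1 * sd2
    if diff_var <= 0:
        raise DegenerateComparisonError(
            "difference variance is zero; the two measures are identical"
        )
    t = (mean1 - mean2) / np.sqrt(diff_var / n)
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return PairedT(float(t), df, float(p))
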