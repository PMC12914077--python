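"""Covariate strata and the ecological-bias correction at the core of HRR.

A stratum is one joint combination of the individual-level covariates.  With
the default covariate set — age group (2), multidisciplinary-meeting
presentation (2), supportive-care screening (2), clinical stage (4),
comorbidity (2), ECOG performance status (3) — there are K = 2*2*2*4*2*3 = 192
strata.  The within-area joint covariate distribution ``f_jtk`` (probability
that a patient in area j, period t falls in stratum k) is estimated
empirically from the individual records.

The aggregate-level risk for an area-period is the individual-level risk
marginalized over that distribution,

    p_jt = sum_k f_jtk * p_jtk,

which is what lets an aggregate Binomial/Poisson model share parameters with
the individual logistic model without incurring ecological bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover
    from .model import ModelParameters

__all__ = [
    "COVARIATES",
    "StrataDefinition",
    "StrataDistribution",
    "default_strata",
    "enumerate_strata",
    "estimate_f",
    "marginal_risk",
    "stratum_design_matrix",
]

#: Individual covariates in their canonical order, with category labels.
#: The first label of each covariate is the reference level of the design.
COVARIATES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("age_group", ("le60", "gt60")),
    ("mdm", ("no", "yes")),
    ("scs", ("no", "yes")),
    ("stage", ("I", "II", "III", "IV")),
    ("comorbidity", ("no", "yes")),
    ("ecog", ("good", "poor", "not_stated")),
)


@dataclass(frozen=True)
class StrataDefinition:
    """Names and category labels of the individual covariates."""

    covariates: tuple[tuple[str, tuple[str, ...]], ...] = COVARIATES

    def __post_init__(self) -> None:
        for name, levels in self.covariates:
            if len(levels) < 1:
                raise ValueError(f"covariate {name} needs at least one category")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.covariates)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(levels) for _, levels in self.covariates)

    @property
    def n_strata(self) -> int:
        return int(np.prod(self.counts))

    @property
    def design_columns(self) -> tuple[str, ...]:
        """Non-reference dummy columns, e.g. ``stage_IV``."""
        cols = []
        for name, levels in self.covariates:
            cols.extend(f"{name}_{lev}" for lev in levels[1:])
        return tuple(cols)

    def levels(self, name: str) -> tuple[str, ...]:
        for n, lv in self.covariates:
            if n == name:
                return lv
        raise KeyError(name)

    def index_of(self, codes) -> int:
        """Stratum index of a tuple of per-covariate level codes."""
        return int(np.ravel_multi_index(tuple(np.asarray(codes)), self.counts))

    def codes_of(self, k: int) -> tuple[int, ...]:
        return tuple(int(c) for c in np.unravel_index(k, self.counts))


def default_strata() -> StrataDefinition:
    return StrataDefinition()


def enumerate_strata(defn: StrataDefinition) -> list[tuple[int, ...]]:
    """All strata as level-code tuples in lexicographic order.

    The list index is the stratum index; ``defn.index_of`` inverts it.
    """
    return [defn.codes_of(k) for k in range(defn.n_strata)]


def stratum_design_matrix(defn: StrataDefinition) -> np.ndarray:
    """(K, P) dummy design for the strata, reference levels dropped.

    Column order follows ``defn.design_columns``.
    """
    K = defn.n_strata
    codes = np.array(enumerate_strata(defn))
    cols = []
    for v, (_, levels) in enumerate(defn.covariates):
        for lev_idx in range(1, len(levels)):
            cols.append((codes[:, v] == lev_idx).astype(float))
    if not cols:
        return np.zeros((K, 0))
    return np.column_stack(cols)


def records_stratum_codes(records: pd.DataFrame, defn: StrataDefinition) -> np.ndarray:
    """Map each record to its stratum index; unknown categories raise."""
    per_cov = []
    for name, levels in defn.covariates:
        cat = pd.Categorical(records[name], categories=list(levels))
        if (cat.codes < 0).any():
            bad = set(records[name][cat.codes < 0])
            raise ValueError(f"unknown categories {bad!r} for covariate {name}")
        per_cov.append(cat.codes.astype(np.int64))
    return np.ravel_multi_index(tuple(per_cov), defn.counts)


@dataclass
class StrataDistribution:
    """Empirical within-area covariate distribution and at-risk counts.

    ``f[j, t, k]`` holds the stratum probabilities (rows sum to 1 where
    ``n_at_risk[j, t] > 0`` and are all-zero for empty cells) for periods
    ``t = 1 .. n_periods`` stored at index ``t - 1``.
    """

    f: np.ndarray  # (J, T, K)
    n_at_risk: np.ndarray  # (J, T)
    defn: StrataDefinition = field(default_factory=default_strata)

    def __post_init__(self) -> None:
        if self.f.shape[:2] != self.n_at_risk.shape:
            raise ValueError("f and n_at_risk shapes disagree")
        if (self.f < 0).any():
            raise ValueError("f must be nonnegative")
        occupied = self.n_at_risk > 0
        sums = self.f.sum(axis=2)
        if not np.allclose(sums[occupied], 1.0, atol=1e-9):
            raise ValueError("f must sum to 1 for every occupied (area, period)")

    @property
    def n_areas(self) -> int:
        return self.f.shape[0]

    @property
    def n_periods(self) -> int:
        return self.f.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (area_id, period, stratum, f, n_at_risk)."""
        J, T, K = self.f.shape
        j, t, k = np.meshgrid(range(J), range(1, T + 1), range(K), indexing="ij")
        return pd.DataFrame(
            {
                "area_id": j.ravel(),
                "period": t.ravel(),
                "stratum": k.ravel(),
                "f": self.f.ravel(),
                "n_at_risk": np.repeat(self.n_at_risk.ravel(), K),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def estimate_f(
    records: pd.DataFrame,
    defn: StrataDefinition | None = None,
    n_areas: int | None = None,
    n_periods: int | None = None,
) -> StrataDistribution:
    """Empirical ``f_jtk`` from individual records.

    Cells with no records keep ``f = 0`` throughout and ``n_at_risk = 0``;
    they contribute nothing downstream (no aggregate likelihood term).
    """
    defn = defn or default_strata()
    J = n_areas if n_areas is not None else int(records["area_id"].max()) + 1
    T = n_periods if n_periods is not None else int(records["period"].max())
    K = defn.n_strata
    strat = records_stratum_codes(records, defn)
    area = records["area_id"].to_numpy(dtype=np.int64)
    per = records["period"].to_numpy(dtype=np.int64) - 1
    if (area < 0).any() or (area >= J).any():
        raise ValueError("area_id out of range")
    if (per < 0).any() or (per >= T).any():
        raise ValueError("period out of range")
    counts = np.zeros((J, T, K))
    np.add.at(counts, (area, per, strat), 1.0)
    n_at_risk = counts.sum(axis=2)
    f = np.divide(counts, n_at_risk[:, :, None], out=np.zeros_like(counts),
                  where=n_at_risk[:, :, None] > 0)
    f[n_at_risk == 0] = 0.0
    return StrataDistribution(f=f, n_at_risk=n_at_risk, defn=defn)


def centered_period(t: int | np.ndarray, n_periods: int) -> np.ndarray:
    """Centered period index c(t) = t - (T+1)/2, removing the collinearity
    between the linear and quadratic temporal terms (c(t) = t - 2 for T=3)."""
    return np.asarray(t, dtype=float) - (n_periods + 1) / 2.0


def marginal_risk(
    params: "ModelParameters",
    f_jt: np.ndarray,
    z_j: np.ndarray,
    u_j: float,
    v_j: float,
    t: int,
    defn: StrataDefinition | None = None,
    n_periods: int = 3,
) -> float:
    """Area-period risk: the individual risk marginalized over ``f_jt``.

    Computes the stratum risks from the full linear predictor

        logit(p_jtk) = mu + beta x_k + gamma z_j + u_j + v_j
                       + delta1 c(t) + delta2 c(t)^2

    and returns the exact convex combination ``sum_k f_jtk p_jtk``, which
    therefore always lies between the smallest and largest stratum risk.
    """
    defn = defn or default_strata()
    f_jt = np.asarray(f_jt, dtype=float)
    if f_jt.shape != (defn.n_strata,):
        raise ValueError(f"f_jt must have length {defn.n_strata}")
    if abs(f_jt.sum() - 1.0) > 1e-9:
        raise ValueError("f_jt must sum to 1 (tolerance 1e-9)")
    X = stratum_design_matrix(defn)
    c = centered_period(t, n_periods)
    eta = (
        params.mu
        + X @ np.asarray(params.beta, dtype=float)
        + float(np.dot(np.asarray(z_j, dtype=float), np.asarray(params.gamma, dtype=float)))
        + u_j
        + v_j
        + params.delta1 * c
        + params.delta2 * c**2
    )
    return float(f_jt @ expit(eta))
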