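"""The joint HRR model: likelihoods, priors, and the overdispersion check.

The model couples two views of the same outcome process:

* individual level — each patient's 30-day mortality indicator is Bernoulli
  with ``logit(p_ijt) = mu + beta x_ijt + gamma z_j + u_j + v_j
  + delta1 c(t) + delta2 c(t)^2``;
* aggregate level — the area-period death count is Binomial (or Poisson,
  selectable) with risk ``p_jt = sum_k f_jtk p_jtk`` marginalized over the
  within-area covariate distribution.

The full likelihood is the product of the two, per the hierarchical related
regression construction.  Regression coefficients carry BUGS-style
Normal(0, precision 0.725) priors — the precision implied by a 95% prior
odds-ratio interval of (0.1, 10) — the intercept an improper flat prior, the
structured effects the Besag ICAR prior, the unstructured effects an i.i.d.
normal, and the precisions Gamma hyperpriors.

Records are collapsed to (area, period, stratum) cells before evaluation:
patients in the same cell share a linear predictor, so the Bernoulli product
reduces exactly to per-cell binomial kernels, and the aggregate risk is a
weighted sum over the same cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from .spatial import AdjacencyStructure, icar_logdensity_unnorm
from .strata import (
    StrataDefinition,
    StrataDistribution,
    centered_period,
    default_strata,
    estimate_f,
    records_stratum_codes,
    stratum_design_matrix,
)

__all__ = [
    "ModelParameters",
    "PriorSpec",
    "CellData",
    "build_cells",
    "individual_loglik",
    "aggregate_loglik",
    "joint_loglik",
    "log_prior",
    "prior_precision_from_or_range",
    "overdispersion_statistic",
]


@dataclass
class ModelParameters:
    """One point in parameter space.

    ``beta`` are individual-level log-odds ratios (one per non-reference
    design column), ``gamma`` area-level log-odds ratios, ``u``/``v`` the
    structured/unstructured spatial effects, ``delta1``/``delta2`` the linear
    and quadratic coefficients on the centered period index, and
    ``tau_u2``/``tau_v2`` the corresponding variance hyperparameters.
    """

    mu: float
    beta: np.ndarray
    gamma: np.ndarray
    u: np.ndarray
    v: np.ndarray
    delta1: float = 0.0
    delta2: float = 0.0
    tau_u2: float = 1.0
    tau_v2: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float)) if np.size(self.gamma) else np.zeros(0)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.u) != len(self.v):
            raise ValueError("u and v must have equal length")
        if self.tau_u2 <= 0 or self.tau_v2 <= 0:
            raise ValueError("variance hyperparameters must be positive")

    @classmethod
    def null(cls, n_beta: int, n_gamma: int, n_areas: int) -> "ModelParameters":
        return cls(
            mu=0.0,
            beta=np.zeros(n_beta),
            gamma=np.zeros(n_gamma),
            u=np.zeros(n_areas),
            v=np.zeros(n_areas),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration.

    ``coef_precision`` is the normal precision on every non-intercept
    regression coefficient (beta, gamma, delta1, delta2); the intercept is
    improper flat.  Precisions 1/tau_u2 and 1/tau_v2 carry
    Gamma(shape, rate) hyperpriors with the conventional disease-mapping
    default Gamma(0.5, 0.0005).
    """

    coef_precision: float = 0.725
    prec_shape: float = 0.5
    prec_rate: float = 0.0005

    def __post_init__(self) -> None:
        if self.coef_precision <= 0 or self.prec_shape <= 0 or self.prec_rate <= 0:
            raise ValueError("prior precisions and gamma hyperparameters must be positive")


def prior_precision_from_or_range(
    or_low: float, or_high: float, level: float = 0.95
) -> float:
    """Normal prior precision implied by a central prior interval on an OR.

    Assuming the log odds ratio is N(0, sigma^2) with probability ``level``
    that the OR lies in the log-symmetric interval ``(or_low, or_high)``
    (so ``or_low * or_high = 1``), the implied precision is
    ``(z_{(1+level)/2} / ln(or_high))^2``.  The default weakly informative
    interval (0.1, 10) gives 0.725 to three decimals.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if or_low <= 0 or or_high <= 0 or or_high <= or_low:
        raise ValueError("need 0 < or_low < or_high")
    if abs(np.log(or_low) + np.log(or_high)) > 1e-8:
        raise ValueError("interval must be symmetric on the log-OR scale (or_low * or_high = 1)")
    z = stats.norm.ppf((1 + level) / 2)
    return float((z / np.log(or_high)) ** 2)


# ---------------------------------------------------------------------------
# collapsed cell representation


@dataclass
class CellData:
    """Records collapsed to occupied (area, period, stratum) cells.

    ``design[c]`` is the full fixed-effect row ``[1 | x_k | z_j | c(t) |
    c(t)^2]`` of cell ``c`` (time columns present only when the study has
    more than one period); ``f`` its share of the area-period at-risk count.
    Cells are sorted by (area, period) so each area occupies a contiguous
    block, which the sampler exploits.
    """

    design: np.ndarray  # (ncells, F)
    area: np.ndarray  # (ncells,)
    period: np.ndarray  # (ncells,) 1-based
    cell_jt: np.ndarray  # (ncells,) flat index area * T + (period-1)
    y: np.ndarray  # deaths per cell
    n: np.ndarray  # patients per cell
    f: np.ndarray  # f_jtk of the cell within its (j, t)
    y_jt: np.ndarray  # (J*T,) aggregate deaths
    n_jt: np.ndarray  # (J*T,) aggregate at-risk
    z: np.ndarray  # (J, Q) area covariates
    n_areas: int
    n_periods: int
    param_names: tuple[str, ...]
    defn: StrataDefinition = field(default_factory=default_strata)
    beta_slice: slice = field(default_factory=lambda: slice(0, 0))
    gamma_slice: slice = field(default_factory=lambda: slice(0, 0))
    time_slice: slice = field(default_factory=lambda: slice(0, 0))

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.design.shape[1]

    def fixed_vector(self, params: ModelParameters) -> np.ndarray:
        """Pack (mu, beta, gamma, delta1, delta2) in design-column order."""
        beta = np.asarray(params.beta, float).ravel()
        gamma = np.asarray(params.gamma, float).ravel()
        if len(beta) != self.beta_slice.stop - self.beta_slice.start:
            raise ValueError("beta length does not match the design")
        if len(gamma) != self.gamma_slice.stop - self.gamma_slice.start:
            raise ValueError("gamma length does not match the design")
        parts = [np.atleast_1d(float(params.mu)), beta]
        if self.gamma_slice.stop > self.gamma_slice.start:
            parts.append(gamma)
        if self.time_slice.stop > self.time_slice.start:
            parts.append(np.array([params.delta1, params.delta2]))
        vec = np.concatenate(parts)
        if len(vec) != self.n_fixed:
            raise ValueError("parameter dimensions do not match the design")
        return vec

    def linear_predictor(self, params: ModelParameters) -> np.ndarray:
        if len(params.u) != self.n_areas:
            raise ValueError(f"u must have length {self.n_areas}")
        eta = self.design @ self.fixed_vector(params)
        return eta + params.u[self.area] + params.v[self.area]

    def marginal_risks(self, params: ModelParameters) -> np.ndarray:
        """p_jt for every (area, period), NaN where no one is at risk."""
        p = expit(self.linear_predictor(params))
        s = np.zeros(self.n_areas * self.n_periods)
        np.add.at(s, self.cell_jt, self.f * p)
        s[self.n_jt == 0] = np.nan
        return s


def build_cells(
    records: pd.DataFrame,
    z: np.ndarray | pd.DataFrame | None,
    adjacency: AdjacencyStructure | None = None,
    defn: StrataDefinition | None = None,
    n_areas: int | None = None,
    n_periods: int | None = None,
    columns: list[str] | None = None,
    z_names: list[str] | None = None,
) -> CellData:
    """Collapse a registry to cells and assemble the fixed-effect design.

    ``columns`` restricts the individual-level design to a subset of
    ``defn.design_columns`` (used by forward model selection); ``None`` keeps
    all.  ``z`` is the (J, Q) area-covariate design (may be None/empty).
    Temporal columns (centered linear + quadratic) are included whenever the
    study spans more than one period.
    """
    defn = defn or default_strata()
    if "outcome" not in records or records["outcome"].isna().any():
        raise ValueError("records must carry binary outcomes")
    out = records["outcome"].to_numpy()
    if not np.isin(out, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    J = n_areas if n_areas is not None else (
        adjacency.n_areas if adjacency is not None else int(records["area_id"].max()) + 1
    )
    T = n_periods if n_periods is not None else int(records["period"].max())

    if z is None:
        zmat = np.zeros((J, 0))
        znames: list[str] = []
    elif isinstance(z, pd.DataFrame):
        zmat = z.to_numpy(dtype=float)
        znames = list(z.columns)
    else:
        zmat = np.asarray(z, dtype=float)
        if zmat.ndim == 1:
            zmat = zmat[:, None]
        znames = z_names or [f"z{q}" for q in range(zmat.shape[1])]
    if zmat.shape[0] != J:
        raise ValueError(f"area covariates cover {zmat.shape[0]} areas, expected {J}")

    area = records["area_id"].to_numpy(dtype=np.int64)
    per = records["period"].to_numpy(dtype=np.int64)
    strat = records_stratum_codes(records, defn)
    jt = area * T + (per - 1)
    key = jt * defn.n_strata + strat
    uniq, inv = np.unique(key, return_inverse=True)
    ncells = len(uniq)
    ncell = np.bincount(inv, minlength=ncells).astype(float)
    ycell = np.bincount(inv, weights=out.astype(float), minlength=ncells)
    cell_jt = (uniq // defn.n_strata).astype(np.int64)
    cell_k = (uniq % defn.n_strata).astype(np.int64)
    cell_area = cell_jt // T
    cell_per = (cell_jt % T + 1).astype(np.int64)

    n_jt = np.zeros(J * T)
    np.add.at(n_jt, cell_jt, ncell)
    y_jt = np.zeros(J * T)
    np.add.at(y_jt, cell_jt, ycell)
    fcell = ncell / n_jt[cell_jt]

    Xk = stratum_design_matrix(defn)
    all_cols = list(defn.design_columns)
    if columns is None:
        keep = list(range(len(all_cols)))
    else:
        missing = [c for c in columns if c not in all_cols]
        if missing:
            raise ValueError(f"unknown design columns {missing}")
        keep = [all_cols.index(c) for c in columns]
    Xi = Xk[cell_k][:, keep]

    parts = [np.ones((ncells, 1)), Xi]
    names = ["mu"] + [f"beta:{all_cols[i]}" for i in keep]
    beta_slice = slice(1, 1 + len(keep))
    gstart = 1 + len(keep)
    if zmat.shape[1]:
        parts.append(zmat[cell_area])
        names += [f"gamma:{nm}" for nm in znames]
    gamma_slice = slice(gstart, gstart + zmat.shape[1])
    tstart = gamma_slice.stop
    if T > 1:
        c = centered_period(cell_per, T)
        parts.append(np.column_stack([c, c**2]))
        names += ["delta1", "delta2"]
        time_slice = slice(tstart, tstart + 2)
    else:
        time_slice = slice(tstart, tstart)

    order = np.argsort(cell_jt, kind="stable")
    design = np.column_stack(parts)[order]
    return CellData(
        design=np.ascontiguousarray(design),
        area=cell_area[order],
        period=cell_per[order],
        cell_jt=cell_jt[order],
        y=ycell[order],
        n=ncell[order],
        f=fcell[order],
        y_jt=y_jt,
        n_jt=n_jt,
        z=zmat,
        n_areas=J,
        n_periods=T,
        param_names=tuple(names),
        defn=defn,
        beta_slice=beta_slice,
        gamma_slice=gamma_slice,
        time_slice=time_slice,
    )


# ---------------------------------------------------------------------------
# likelihoods


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def individual_loglik(params: ModelParameters, cells: CellData) -> float:
    """Sum of Bernoulli log-likelihoods over all individual records.

    Evaluated on the collapsed cells:  y*eta - n*log(1+e^eta) per cell equals
    the per-record sum exactly (no binomial coefficient enters a Bernoulli
    product).
    """
    eta = cells.linear_predictor(params)
    return float(np.sum(cells.y * eta - cells.n * _softplus(eta)))


def aggregate_loglik(
    params: ModelParameters, cells: CellData, family: str = "binomial"
) -> float:
    """Aggregate-level log-likelihood over occupied (area, period) cells.

    Binomial: ``log C(N, y) + y log p + (N - y) log(1 - p)`` with the
    marginalized risk ``p = p_jt``; Poisson: mean ``N_jt * p_jt``.  For rare
    outcomes (p <= 0.05) the two agree closely.
    """
    if (cells.y_jt > cells.n_jt).any():
        raise ValueError("aggregate deaths exceed at-risk counts")
    occ = cells.n_jt > 0
    if not occ.any():
        return 0.0
    p = cells.marginal_risks(params)[occ]
    y = cells.y_jt[occ]
    n = cells.n_jt[occ]
    if family == "binomial":
        ll = (
            gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * np.log(p) + (n - y) * np.log1p(-p)
        )
    elif family == "poisson":
        mean = n * p
        ll = y * np.log(mean) - mean - gammaln(y + 1)
    else:
        raise ValueError("family must be 'binomial' or 'poisson'")
    return float(ll.sum())


def joint_loglik(
    params: ModelParameters, cells: CellData, family: str = "binomial"
) -> float:
    """The HRR joint log-likelihood: individual + aggregate components."""
    return individual_loglik(params, cells) + aggregate_loglik(params, cells, family)


def log_prior(
    params: ModelParameters,
    prior: PriorSpec,
    adj: AdjacencyStructure,
    include_time: bool = True,
    n_gamma: int | None = None,
) -> float:
    """Joint log-prior density (up to the ICAR normalizing constant).

    Normal(0, ``coef_precision``) on beta, gamma and the temporal
    coefficients; flat on mu (contributes 0); the sum-to-zero ICAR term for
    u with its rank-deficient normalizer ``(rank/2) log(1/tau_u2)``; i.i.d.
    normal for v; Gamma hyperpriors on both precisions.
    """
    prec = prior.coef_precision
    coefs = np.concatenate([
        np.asarray(params.beta, float).ravel(),
        np.asarray(params.gamma, float).ravel(),
        [params.delta1, params.delta2] if include_time else [],
    ])
    lp = float(np.sum(stats.norm.logpdf(coefs, scale=prec**-0.5)))
    # structured spatial effect: pairwise-difference ICAR kernel
    lp += adj.rank / 2.0 * np.log(1.0 / params.tau_u2)
    lp += icar_logdensity_unnorm(params.u, adj, params.tau_u2)
    # unstructured effect
    lp += float(np.sum(stats.norm.logpdf(params.v, scale=params.tau_v2**0.5)))
    # precision hyperpriors
    for tau2 in (params.tau_u2, params.tau_v2):
        lp += float(
            stats.gamma.logpdf(1.0 / tau2, a=prior.prec_shape, scale=1.0 / prior.prec_rate)
        )
    return lp


# ---------------------------------------------------------------------------
# overdispersion


def overdispersion_statistic(
    y: np.ndarray,
    n: np.ndarray,
    p_fit: np.ndarray,
    family: str = "poisson",
    n_params: int = 1,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Pearson dispersion ratio and a parametric-bootstrap significance flag.

    ``ratio = X^2 / (ncells - n_params)`` with ``X^2 = sum (y - mu)^2 / V``
    under the chosen family (Poisson: V = mu; binomial: V = n p (1-p)).
    The flag is True when the bootstrap p-value of ``ratio`` under the fitted
    model falls below ``alpha`` — evidence that the equal-mean-variance
    assumption fails and the Poisson family is inadequate.
    """
    rng = rng or np.random.default_rng(0)
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    p_fit = np.asarray(p_fit, float)
    df = len(y) - n_params
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")

    def pearson(yy: np.ndarray) -> float:
        mu = n * p_fit
        if family == "poisson":
            v = mu
        elif family == "binomial":
            v = n * p_fit * (1 - p_fit)
        else:
            raise ValueError("family must be 'binomial' or 'poisson'")
        return float(np.sum((yy - mu) ** 2 / v) / df)

    ratio = pearson(y)
    if family == "poisson":
        sims = rng.poisson(n * p_fit, size=(n_boot, len(y)))
    else:
        sims = rng.binomial(n.astype(int), p_fit, size=(n_boot, len(y)))
    boot = np.array([pearson(s.astype(float)) for s in sims])
    pval = float((np.sum(boot >= ratio) + 1) / (n_boot + 1))
    return ratio, pval < alpha
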