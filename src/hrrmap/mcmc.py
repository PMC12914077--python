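"""Posterior sampling for the joint HRR model.

`run_mcmc` drives one compiled Metropolis-within-Gibbs chain per requested
chain: scalar random-walk updates for the fixed effects, one adapted joint
random-walk move over the whole fixed-effect block per sweep (the intercept
and covariate coefficients are strongly correlated a posteriori, and
single-site moves alone traverse that ridge slowly), single-site updates for
the structured (ICAR) and unstructured spatial effects, conjugate Gibbs
draws for the two precision parameters, and sum-to-zero re-centering of the
structured field each sweep.  Scalar proposal scales adapt toward a 0.44
acceptance rate and the block proposal covariance is estimated from the
chain, both during burn-in only.

The study's full protocol (100,000 iterations, 50,000 burn-in, 2 chains) is
the default; tests and examples use shorter desk-scale runs of the same
sampler.  Chain 1 starts at zero effects and unit precisions; later chains
start over-dispersed (alternating +/- one prior standard deviation on the
fixed effects) so that between-chain convergence diagnostics are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .model import CellData, PriorSpec
from .spatial import AdjacencyStructure

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "run_mcmc",
    "posterior_summary",
    "adaptive_rw_sampler",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC protocol: iterations, burn-in, chains, thinning, adaptation."""

    n_iterations: int = 100_000
    burn_in: int = 50_000
    n_chains: int = 2
    thin: int = 1
    seed: int = 0
    family: str = "binomial"
    target_accept: float = 0.44
    adapt_interval: int = 50
    use_aggregate: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be positive")
        if self.family not in ("binomial", "poisson"):
            raise ValueError("family must be 'binomial' or 'poisson'")


@dataclass
class PosteriorSamples:
    """Retained draws, one array of shape (n_chains, n_draws[, ...]) each.

    ``fixed`` covers the intercept and all regression coefficients in
    ``fixed_names`` order; ``u``/``v`` the spatial effects; ``tau2`` the
    variance parameters (structured, unstructured); ``deviance`` the
    -2*log-likelihood of each retained draw.
    """

    fixed: np.ndarray  # (C, D, F)
    u: np.ndarray  # (C, D, J)
    v: np.ndarray  # (C, D, J)
    tau2: np.ndarray  # (C, D, 2)
    deviance: np.ndarray  # (C, D)
    fixed_names: tuple[str, ...]
    acceptance: dict[str, np.ndarray] = field(default_factory=dict)
    config: SamplerConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.fixed.shape[0]

    @property
    def n_draws(self) -> int:
        return self.fixed.shape[1]

    @property
    def n_areas(self) -> int:
        return self.u.shape[2]

    def names(self) -> list[str]:
        return (
            list(self.fixed_names)
            + [f"u[{j}]" for j in range(self.n_areas)]
            + [f"v[{j}]" for j in range(self.n_areas)]
            + ["tau2_u", "tau2_v"]
        )

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_draws)."""
        if name in self.fixed_names:
            return self.fixed[:, :, self.fixed_names.index(name)]
        if name.startswith("u[") and name.endswith("]"):
            return self.u[:, :, int(name[2:-1])]
        if name.startswith("v[") and name.endswith("]"):
            return self.v[:, :, int(name[2:-1])]
        if name == "tau2_u":
            return self.tau2[:, :, 0]
        if name == "tau2_v":
            return self.tau2[:, :, 1]
        raise KeyError(name)

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        rows = []
        for name in self.names():
            arr = self.get(name)
            for chain in range(self.n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": chain,
                            "iteration": np.arange(self.n_draws),
                            "parameter": name,
                            "value": arr[chain],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _cell_starts(cells: CellData) -> np.ndarray:
    return np.searchsorted(cells.area, np.arange(cells.n_areas + 1)).astype(np.int64)


def _flat_neighbors(adj: AdjacencyStructure) -> tuple[np.ndarray, np.ndarray]:
    ptr = np.zeros(adj.n_areas + 1, dtype=np.int64)
    idx = []
    for i, nbrs in enumerate(adj.neighbor_lists):
        ptr[i + 1] = ptr[i] + len(nbrs)
        idx.extend(nbrs)
    return np.asarray(idx, dtype=np.int64), ptr


def run_mcmc(
    cells: CellData,
    adjacency: AdjacencyStructure,
    config: SamplerConfig | None = None,
    prior: PriorSpec | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior; deterministic given ``config.seed``."""
    config = config or SamplerConfig()
    prior = prior or PriorSpec()
    if adjacency.n_areas != cells.n_areas:
        raise ValueError("adjacency and cell data disagree on the number of areas")

    F = cells.n_fixed
    coef_prec = np.full(F, prior.coef_precision)
    coef_prec[0] = 0.0  # improper flat prior on the intercept
    nbr_idx, nbr_ptr = _flat_neighbors(adjacency)
    starts = _cell_starts(cells)
    prior_sd = prior.coef_precision ** -0.5

    out_fixed, out_u, out_v, out_tau, out_dev = [], [], [], [], []
    acc_fixed, acc_u, acc_v, acc_block = [], [], [], []
    for chain in range(config.n_chains):
        theta0 = np.zeros(F)
        if chain > 0:
            signs = np.where(np.arange(F) % 2 == 0, 1.0, -1.0) * (-1.0) ** chain
            theta0 = signs * prior_sd
        res = _kernel.run_chain(
            np.ascontiguousarray(cells.design),
            cells.area.astype(np.int64),
            cells.cell_jt.astype(np.int64),
            cells.f.astype(np.float64),
            cells.y.astype(np.float64),
            cells.n.astype(np.float64),
            cells.y_jt.astype(np.float64),
            cells.n_jt.astype(np.float64),
            starts,
            nbr_idx,
            nbr_ptr,
            adjacency.components.astype(np.int64),
            adjacency.n_components,
            adjacency.rank,
            coef_prec,
            np.ascontiguousarray(cells.z, dtype=np.float64),
            cells.gamma_slice.start,
            prior.prec_shape,
            prior.prec_rate,
            prior.prec_shape,
            prior.prec_rate,
            0 if config.family == "binomial" else 1,
            1 if config.use_aggregate else 0,
            theta0,
            np.zeros(adjacency.n_areas),
            np.zeros(adjacency.n_areas),
            1.0,
            1.0,
            config.n_iterations,
            config.burn_in,
            config.thin,
            int((config.seed + 1_000_003 * chain) % 2**31),
            config.target_accept,
            config.adapt_interval,
        )
        theta_d, u_d, v_d, tau_d, dev_d, acc, _ = res
        if not np.isfinite(dev_d).all():
            raise RuntimeError(
                f"non-finite log-likelihood in chain {chain}; "
                f"last draw: {theta_d[-1]!r}"
            )
        out_fixed.append(theta_d)
        out_u.append(u_d)
        out_v.append(v_d)
        out_tau.append(tau_d)
        out_dev.append(dev_d)
        acc_fixed.append(acc[:F])
        acc_u.append(acc[F : F + adjacency.n_areas])
        acc_v.append(acc[F + adjacency.n_areas : F + 2 * adjacency.n_areas])
        acc_block.append(acc[F + 2 * adjacency.n_areas])

    return PosteriorSamples(
        fixed=np.stack(out_fixed),
        u=np.stack(out_u),
        v=np.stack(out_v),
        tau2=np.stack(out_tau),
        deviance=np.stack(out_dev),
        fixed_names=cells.param_names,
        acceptance={
            "fixed": np.stack(acc_fixed),
            "u": np.stack(acc_u),
            "v": np.stack(acc_v),
            "block": np.asarray(acc_block),
        },
        config=config,
    )


def posterior_summary(
    samples: PosteriorSamples | np.ndarray,
    level: float = 0.95,
    names: list[str] | None = None,
    or_scale: bool = False,
) -> pd.DataFrame:
    """Per-parameter posterior mean, sd and equal-tailed credible interval.

    With ``or_scale=True`` the draws are exponentiated before summarizing
    (odds-ratio scale).  Requires at least 100 retained draws per parameter.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if isinstance(samples, PosteriorSamples):
        names = names if names is not None else samples.names()
        arrays = {n: samples.pooled(n) for n in names}
    else:
        arr = np.atleast_2d(np.asarray(samples, dtype=float))
        names = names or [f"p{i}" for i in range(arr.shape[0] if arr.ndim > 1 else 1)]
        if arr.shape[0] != len(names):
            arr = arr.T
        arrays = {n: arr[i].ravel() for i, n in enumerate(names)}
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for n, x in arrays.items():
        if x.size == 0:
            raise ValueError(f"no draws for parameter {n}")
        if x.size < 100:
            raise ValueError(f"need >= 100 retained draws, got {x.size} for {n}")
        if or_scale:
            x = np.exp(x)
        rows.append(
            {
                "parameter": n,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "lower": float(np.quantile(x, lo)),
                "upper": float(np.quantile(x, hi)),
                "n_draws": int(x.size),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def adaptive_rw_sampler(
    logpdf,
    x0: float,
    n_iterations: int = 10_000,
    burn_in: int = 2_000,
    seed: int = 0,
    target_accept: float = 0.44,
    adapt_interval: int = 50,
) -> np.ndarray:
    """Scalar adaptive random-walk Metropolis for an arbitrary log-density.

    The same adaptation scheme as the main sampler's scalar updates
    (Robbins-Monro on the log proposal scale during burn-in, frozen after),
    exposed for calibration checks against closed-form posteriors.
    Returns the retained draws.
    """
    rng = np.random.default_rng(seed)
    x = float(x0)
    lp = float(logpdf(x))
    ls, acc, nwin = np.log(0.5), 0, 0
    out = np.empty(n_iterations - burn_in)
    for it in range(n_iterations):
        prop = x + np.exp(ls) * rng.standard_normal()
        lpp = float(logpdf(prop))
        if np.log(rng.random()) < lpp - lp:
            x, lp = prop, lpp
            acc += 1
        if it < burn_in and (it + 1) % adapt_interval == 0:
            nwin += 1
            delta = min(0.5, 4.0 / np.sqrt(nwin))
            ls += delta * (acc / adapt_interval - target_accept)
            acc = 0
        if it >= burn_in:
            out[it - burn_in] = x
    return out
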