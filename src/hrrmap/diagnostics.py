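"""Convergence and model-fit diagnostics.

Three instruments from the BUGS tradition:

* the Gelman-Rubin potential scale reduction factor (here called BGR after
  the Brooks-Gelman-Rubin plots it summarizes), computed from the standard
  between/within-chain variance decomposition;
* the Monte-Carlo standard error of the posterior mean, estimated by batch
  means (50 batches by default), with the conventional pass rule
  MC error < 5% of the posterior standard deviation;
* the Deviance Information Criterion DIC = Dbar + pD with
  pD = Dbar - D(theta_bar), evaluated with the same likelihood family the
  model was fitted with.

Model selection follows a forward-addition rule: start from the
single-variable model with the lowest DIC, then add variables in order of
their single-variable DIC, retaining an addition only when it lowers the
DIC by at least five points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = [
    "bgr_statistic",
    "mc_error",
    "dic",
    "dic_from_samples",
    "select_model",
    "SelectionTrace",
    "DiagnosticsReport",
    "compute_report",
]

BGR_THRESHOLD = 1.1
MC_ERROR_THRESHOLD = 0.05
DIC_IMPROVEMENT = 5.0


def bgr_statistic(chains: np.ndarray) -> float:
    """Potential scale reduction factor over parallel chains.

    ``chains`` is (m, n) with m >= 2 chains of equal length n >= 10.
    Returns sqrt(((n-1)/n * W + B/n) / W); identical chains give the
    analytic floor sqrt((n-1)/n), diverged chains give values far above 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains must have length >= 10")
    means = chains.mean(axis=1)
    W = float(chains.var(axis=1, ddof=1).mean())
    B = float(n * means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


def mc_error(chain: np.ndarray, n_batches: int = 50) -> tuple[float, float]:
    """Batch-means Monte-Carlo standard error of the posterior mean.

    Returns ``(mc_se, ratio_to_sd)``.  The chain is split into ``n_batches``
    consecutive batches (trailing remainder dropped); the MC error is the
    standard deviation of batch means over sqrt(n_batches).  The ratio is
    NaN for a degenerate (constant) chain, which callers must flag as a
    failure rather than a pass.
    """
    chain = np.asarray(chain, dtype=float).ravel()
    if len(chain) < 8 * n_batches:
        raise ValueError(
            f"chain too short ({len(chain)}) for {n_batches} batch means"
        )
    L = len(chain) // n_batches
    bm = chain[: L * n_batches].reshape(n_batches, L).mean(axis=1)
    mc_se = float(bm.std(ddof=1) / np.sqrt(n_batches))
    sd = float(chain.std(ddof=1))
    ratio = mc_se / sd if sd > 0 else float("nan")
    return mc_se, ratio


def dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> dict[str, float]:
    """DIC components from posterior deviance draws.

    ``Dbar`` is the posterior mean deviance, ``D_at_mean`` the deviance at
    the posterior-mean parameters, ``pD = Dbar - D_at_mean`` the effective
    number of parameters, and ``DIC = Dbar + pD``.  Non-finite draws are
    excluded and counted.
    """
    dev = np.asarray(deviance_draws, dtype=float).ravel()
    finite = np.isfinite(dev)
    n_bad = int((~finite).sum())
    if finite.sum() == 0:
        raise ValueError("no finite deviance draws")
    dbar = float(dev[finite].mean())
    pd_ = dbar - float(deviance_at_mean)
    return {
        "Dbar": dbar,
        "D_at_mean": float(deviance_at_mean),
        "pD": pd_,
        "DIC": dbar + pd_,
        "n_nonfinite": n_bad,
    }


def dic_from_samples(samples: PosteriorSamples, cells, family: str | None = None) -> dict[str, float]:
    """DIC for a fitted HRR model, using the fitted likelihood family."""
    from .model import ModelParameters, joint_loglik, individual_loglik

    family = family or (samples.config.family if samples.config else "binomial")
    use_agg = samples.config.use_aggregate if samples.config else True
    fixed_mean = samples.fixed.reshape(-1, samples.fixed.shape[2]).mean(axis=0)
    names = list(samples.fixed_names)
    nb = cells.beta_slice
    ng = cells.gamma_slice
    params = ModelParameters(
        mu=fixed_mean[0],
        beta=fixed_mean[nb],
        gamma=fixed_mean[ng] if ng.stop > ng.start else np.zeros(0),
        u=samples.u.reshape(-1, samples.n_areas).mean(axis=0),
        v=samples.v.reshape(-1, samples.n_areas).mean(axis=0),
        delta1=fixed_mean[cells.time_slice.start] if cells.time_slice.stop > cells.time_slice.start else 0.0,
        delta2=fixed_mean[cells.time_slice.start + 1] if cells.time_slice.stop > cells.time_slice.start else 0.0,
    )
    ll = joint_loglik(params, cells, family) if use_agg else individual_loglik(params, cells)
    return dic(samples.deviance, -2.0 * ll)


@dataclass
class SelectionTrace:
    """Record of a forward DIC selection run."""

    single_dics: dict[str, float]
    steps: list[dict] = field(default_factory=list)
    selected: tuple[str, ...] = ()
    final_dic: float = float("nan")


def select_model(
    variables: list[str],
    dic_fn,
    threshold: float = DIC_IMPROVEMENT,
) -> SelectionTrace:
    """Forward DIC-guided variable selection.

    ``dic_fn(vars: tuple[str, ...]) -> float`` must fit the model containing
    exactly those variables (on the same data and likelihood family) and
    return its DIC.  Selection starts from the single-variable model with
    the lowest DIC, then tries the remaining variables in order of their
    single-variable DIC; an addition is retained only when it reduces the
    DIC by at least ``threshold`` (a drop of exactly ``threshold`` counts).
    """
    if not variables:
        raise ValueError("empty candidate set")
    singles = {var: float(dic_fn((var,))) for var in variables}
    order = sorted(variables, key=lambda var: singles[var])
    current = (order[0],)
    current_dic = singles[order[0]]
    trace = SelectionTrace(single_dics=singles)
    trace.steps.append(
        {"candidate": order[0], "dic": current_dic, "delta": float("nan"), "retained": True}
    )
    for var in order[1:]:
        trial = current + (var,)
        trial_dic = float(dic_fn(trial))
        delta = trial_dic - current_dic
        retained = delta <= -threshold
        trace.steps.append(
            {"candidate": var, "dic": trial_dic, "delta": delta, "retained": retained}
        )
        if retained:
            current, current_dic = trial, trial_dic
    trace.selected = current
    trace.final_dic = current_dic
    return trace


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics plus DIC, with pass flags."""

    table: pd.DataFrame  # parameter, bgr, mc_se, mc_ratio, bgr_pass, mc_pass
    dic: dict[str, float]
    all_pass: bool

    def to_json(self, path=None) -> str:
        obj = {
            "parameters": self.table.reset_index().to_dict(orient="records"),
            "dic": self.dic,
            "all_pass": bool(self.all_pass),
        }
        text = json.dumps(obj, indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [self.table.to_string(), ""]
        lines.append(
            "DIC: Dbar={Dbar:.2f}  D(mean)={D_at_mean:.2f}  pD={pD:.2f}  DIC={DIC:.2f}".format(
                **self.dic
            )
        )
        lines.append(f"all checks pass: {self.all_pass}")
        return "\n".join(lines)


def compute_report(
    samples: PosteriorSamples,
    cells=None,
    parameters: list[str] | None = None,
    n_batches: int = 50,
) -> DiagnosticsReport:
    """BGR and MC-error for each parameter, and the DIC when data are given.

    MC error is computed per chain and pooled as the root-mean-square over
    chains divided by sqrt(n_chains); the ratio uses the pooled posterior sd.
    """
    names = parameters if parameters is not None else samples.names()
    rows = []
    for name in names:
        arr = samples.get(name)
        bgr = bgr_statistic(arr) if samples.n_chains >= 2 else float("nan")
        ses = [mc_error(arr[c], n_batches)[0] for c in range(samples.n_chains)]
        mc_se = float(np.sqrt(np.mean(np.square(ses)) / samples.n_chains))
        sd = float(arr.std(ddof=1))
        ratio = mc_se / sd if sd > 0 else float("nan")
        rows.append(
            {
                "parameter": name,
                "bgr": bgr,
                "mc_se": mc_se,
                "mc_ratio": ratio,
                "bgr_pass": bool(bgr < BGR_THRESHOLD) if np.isfinite(bgr) else False,
                "mc_pass": bool(ratio < MC_ERROR_THRESHOLD) if np.isfinite(ratio) else False,
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    dic_res = (
        dic_from_samples(samples, cells)
        if cells is not None
        else {"Dbar": float("nan"), "D_at_mean": float("nan"), "pD": float("nan"), "DIC": float("nan")}
    )
    all_pass = bool(table["bgr_pass"].all() and table["mc_pass"].all())
    return DiagnosticsReport(table=table, dic=dic_res, all_pass=all_pass)


def trace_plot(samples: PosteriorSamples, parameters: list[str], path) -> None:
    """Write trace plots (one panel per parameter) as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(parameters), 1, figsize=(8, 2 * len(parameters)), squeeze=False)
    for ax, name in zip(axes[:, 0], parameters):
        arr = samples.get(name)
        for c in range(arr.shape[0]):
            ax.plot(arr[c], lw=0.5)
        ax.set_ylabel(name)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
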