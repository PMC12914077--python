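"""Study outputs: descriptive tables, adjusted-OR tables, risk surfaces.

Covers the reporting surface of the analysis: crude rates with Wilson score
confidence intervals, cohort composition tables, posterior odds-ratio tables
with credible intervals and significance flags, the standardized relative
risk (SRR) surface per area and period with exceedance probabilities, the
structured share of spatial variation, and choropleth export to GeoJSON.

SRR here is the covariate-standardized area-period risk divided by the
pooled standardized risk: for each posterior draw, every (area, period)
risk is recomputed over the pooled covariate distribution (so composition
differences cannot masquerade as spatial risk), and the reference is the
at-risk-weighted average of those standardized risks.  Under a model with
no spatial or temporal effects the ratio is identically 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from .mcmc import PosteriorSamples
from .model import CellData
from .strata import centered_period, stratum_design_matrix

__all__ = [
    "crude_rate",
    "wilson_ci",
    "descriptive_table",
    "aor_table",
    "SRRSurface",
    "srr_surface",
    "spatial_variance_fraction",
    "choropleth_export",
]


def crude_rate(deaths: int, n: int) -> float:
    """Percentage dead, rounded to two decimals (e.g. 285/6704 -> 4.25)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= deaths <= n:
        raise ValueError("need 0 <= deaths <= n")
    return round(100.0 * deaths / n, 2)


def wilson_ci(deaths: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion, as percentages to 2 dp."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lo, hi = proportion_confint(deaths, n, alpha=1 - level, method="wilson")
    return round(100.0 * lo, 2), round(100.0 * hi, 2)


def descriptive_table(records: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Counts and percentages per category, by variable.

    Percentages are to two decimals and sum to 100 per variable up to
    rounding.  Categories follow the declared categorical ordering when
    present.
    """
    if variables is None:
        variables = [
            c for c in records.columns if c not in ("patient_id", "area_id", "period", "outcome")
        ]
    n = len(records)
    rows = []
    for var in variables:
        counts = records[var].value_counts(sort=False, dropna=False)
        for cat, cnt in counts.items():
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "count": int(cnt),
                    "percent": round(100.0 * cnt / n, 2),
                }
            )
    return pd.DataFrame(rows)


def aor_table(
    samples: PosteriorSamples,
    coefficients: list[str] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Odds-ratio-scale posterior summaries with significance flags.

    Draws (log-odds scale) are exponentiated, then summarized by their mean
    and equal-tailed credible interval.  A coefficient is flagged
    significant when the interval excludes 1.
    """
    if coefficients is None:
        coefficients = [n for n in samples.fixed_names if n != "mu"]
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name in coefficients:
        draws = np.exp(samples.pooled(name))
        if draws.size == 0:
            raise ValueError(f"no draws for {name}")
        lo, hi = float(np.quantile(draws, lo_q)), float(np.quantile(draws, hi_q))
        rows.append(
            {
                "parameter": name,
                "aor": float(draws.mean()),
                "lower": lo,
                "upper": hi,
                "significant": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class SRRSurface:
    """Posterior SRR summaries per (area, period).

    Arrays are (J, T); ``exceedance[j, t]`` is P(SRR > 1).  Cells with no
    one at risk carry NaN and are flagged in ``empty``.
    """

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    exceedance: np.ndarray
    empty: np.ndarray

    @property
    def n_areas(self) -> int:
        return self.mean.shape[0]

    @property
    def n_periods(self) -> int:
        return self.mean.shape[1]

    def to_frame(self) -> pd.DataFrame:
        J, T = self.mean.shape
        j, t = np.meshgrid(range(J), range(1, T + 1), indexing="ij")
        return pd.DataFrame(
            {
                "area_id": j.ravel(),
                "period": t.ravel(),
                "srr_mean": self.mean.ravel(),
                "srr_lower": self.lower.ravel(),
                "srr_upper": self.upper.ravel(),
                "exceedance": self.exceedance.ravel(),
                "empty": self.empty.ravel(),
            }
        )


def srr_surface(
    samples: PosteriorSamples,
    cells: CellData,
    level: float = 0.95,
    max_draws: int = 1000,
) -> SRRSurface:
    """Standardized relative risk surface from posterior draws.

    For each draw, every (area, period) risk is standardized to the pooled
    covariate distribution (at-risk-weighted strata frequencies over the
    whole study), then divided by the at-risk-weighted average of those
    standardized risks.
    """
    J, T = cells.n_areas, cells.n_periods
    # pooled covariate distribution over the collapsed cells
    Xd = cells.design  # rows already carry x_k; reuse unique stratum rows
    pool_w = cells.n / cells.n.sum()

    C, D = samples.n_chains, samples.n_draws
    total = C * D
    step = max(1, total // max_draws)
    fixed = samples.fixed.reshape(total, -1)[::step]
    u = samples.u.reshape(total, J)[::step]
    v = samples.v.reshape(total, J)[::step]
    ndraw = fixed.shape[0]

    occupied = (cells.n_jt > 0).reshape(J, T)
    w_jt = cells.n_jt / cells.n_jt.sum()

    # fixed-effect contribution of each pooled cell, excluding area and time
    # columns (those are swapped per target area-period below)
    beta_cols = list(range(cells.beta_slice.start, cells.beta_slice.stop))
    Xi = Xd[:, [0] + beta_cols]  # intercept + individual covariates
    srr = np.full((ndraw, J, T), np.nan)
    cvals = centered_period(np.arange(1, T + 1), T) if T > 1 else np.zeros(T)
    has_time = cells.time_slice.stop > cells.time_slice.start
    gamma_cols = list(range(cells.gamma_slice.start, cells.gamma_slice.stop))
    for d in range(ndraw):
        th = fixed[d]
        base = Xi @ np.concatenate([[th[0]], th[cells.beta_slice]])
        zoff = cells.z @ th[gamma_cols] if gamma_cols else np.zeros(J)
        for t in range(T):
            toff = (
                th[cells.time_slice.start] * cvals[t]
                + th[cells.time_slice.start + 1] * cvals[t] ** 2
                if has_time
                else 0.0
            )
            # standardized risk for every area at period t
            eta = base[None, :] + (zoff + u[d] + v[d])[:, None] + toff
            p_std = expit(eta) @ pool_w  # (J,)
            srr[d, :, t] = p_std
        ref = float((srr[d] * w_jt.reshape(J, T))[occupied].sum() / w_jt.reshape(J, T)[occupied].sum())
        srr[d] /= ref
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    mean = srr.mean(axis=0)
    lower = np.quantile(srr, lo_q, axis=0)
    upper = np.quantile(srr, hi_q, axis=0)
    exceed = (srr > 1.0).mean(axis=0)
    empty = ~occupied
    for arr in (mean, lower, upper, exceed):
        arr[empty] = np.nan
    return SRRSurface(mean=mean, lower=lower, upper=upper, exceedance=exceed, empty=empty)


def spatial_variance_fraction(samples: PosteriorSamples) -> float:
    """Posterior mean share of spatial variation that is structured, in %.

    Per draw, the empirical-variance partition var(u) / (var(u) + var(v));
    draws with no spatial variation at all are excluded (all-degenerate
    input raises).
    """
    J = samples.n_areas
    u = samples.u.reshape(-1, J)
    v = samples.v.reshape(-1, J)
    var_u = u.var(axis=1, ddof=1)
    var_v = v.var(axis=1, ddof=1)
    tot = var_u + var_v
    ok = tot > 0
    if not ok.any():
        raise ValueError("both spatial fields are degenerate in every draw")
    return float(100.0 * np.mean(var_u[ok] / tot[ok]))


def choropleth_export(
    surface: SRRSurface,
    polygons,
    out_dir,
    stem: str = "srr",
) -> list[Path]:
    """One GeoJSON per period with SRR mean, CrI and exceedance properties.

    Polygon order defines the area ids; a count mismatch lists the missing
    or extra ids exhaustively.
    """
    from shapely.geometry import mapping

    polys = list(polygons)
    if len(polys) != surface.n_areas:
        got = set(range(len(polys)))
        want = set(range(surface.n_areas))
        raise ValueError(
            f"polygon/area id mismatch; missing {sorted(want - got)}, extra {sorted(got - want)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(surface.n_periods):
        feats = []
        for j, poly in enumerate(polys):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {
                        "area_id": j,
                        "period": t + 1,
                        "srr_mean": _jsonable(surface.mean[j, t]),
                        "srr_lower": _jsonable(surface.lower[j, t]),
                        "srr_upper": _jsonable(surface.upper[j, t]),
                        "exceedance": _jsonable(surface.exceedance[j, t]),
                        "empty": bool(surface.empty[j, t]),
                    },
                }
            )
        path = out_dir / f"{stem}_period{t + 1}.geojson"
        path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        paths.append(path)
    return paths


def _jsonable(x: float) -> float | None:
    return None if not np.isfinite(x) else float(x)
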