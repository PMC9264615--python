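"""Model evaluation and the traditional-vs-route-specific comparison.

Goodness of fit between predicted and observed tissue amounts is summarized
by fold-error fractions (a prediction is "within k-fold" when
``max(obs/pred, pred/obs) <= k``, the WHO 2-fold adequacy convention, taken
inclusively), RMSE and adjusted R^2 (linear %ID scale by default; log10
optional), and per-pair observed/predicted ratios.

The route-extrapolation experiment contrasts two parameterizations of a
non-IV route: the *traditional* small-molecule approach (copy every
particle-specific parameter from the IV-calibrated set, add only the
route-entry parameters) against *route-specific* calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .datasets import ROUTE_ENTRY_PARAMS
from .pbpk import (
    ExposureScenario,
    NanoKineticParams,
    PhysiologyRat,
    Route,
    dose_metrics,
    simulate,
)


@dataclass
class EvaluationReport:
    """Fold-error and goodness-of-fit summary over prediction/observation pairs."""

    n_pairs: int
    n_excluded: int
    frac_within_2fold: float
    frac_within_3fold: float
    rmse: float
    adj_r2: float
    op_ratios: np.ndarray  # observed / predicted, per valid pair

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_excluded": self.n_excluded,
            "frac_within_2fold": self.frac_within_2fold,
            "frac_within_3fold": self.frac_within_3fold,
            "rmse": self.rmse,
            "adj_r2": self.adj_r2,
        }


def fold_error_stats(
    pairs: pd.DataFrame, scale: str = "linear", fold_tol: float = 1e-12
) -> EvaluationReport:
    """Evaluate prediction/observation pairs.

    ``pairs`` needs columns ``observed`` and ``predicted``.  Pairs with a
    non-positive member are excluded from the ratio metrics (and, on the
    log10 scale, from all metrics) but counted.  A ratio exactly at the
    boundary counts as within the fold (inclusive).
    """
    if scale not in ("linear", "log10"):
        raise ValueError("scale must be 'linear' or 'log10'")
    obs = np.asarray(pairs["observed"], float)
    pred = np.asarray(pairs["predicted"], float)
    finite = np.isfinite(obs) & np.isfinite(pred)
    positive = finite & (obs > 0) & (pred > 0)
    n_valid = int(positive.sum())
    if n_valid == 0:
        raise ValueError("no valid prediction/observation pairs")

    ratios = obs[positive] / pred[positive]
    fold = np.maximum(ratios, 1.0 / ratios)
    frac2 = float(np.mean(fold <= 2.0 + fold_tol))
    frac3 = float(np.mean(fold <= 3.0 + fold_tol))

    if scale == "log10":
        o, p = np.log10(obs[positive]), np.log10(pred[positive])
        n_excl = int((~positive).sum())
    else:
        o, p = obs[finite], pred[finite]
        n_excl = int((~positive).sum())
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))

    # adjusted R^2 of the observed-vs-predicted regression (slope+intercept)
    n = o.size
    if n > 2 and np.ptp(p) > 0:
        x = np.column_stack([np.ones(n), p])
        coef, _, _, _ = np.linalg.lstsq(x, o, rcond=None)
        rss = float(np.sum((o - x @ coef) ** 2))
        tss = float(np.sum((o - o.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    else:
        adj_r2 = float("nan")

    return EvaluationReport(
        n_pairs=n_valid,
        n_excluded=n_excl,
        frac_within_2fold=frac2,
        frac_within_3fold=frac3,
        rmse=rmse,
        adj_r2=float(adj_r2),
        op_ratios=ratios,
    )


def traditional_extrapolation(
    iv_params: NanoKineticParams,
    route: Route | str,
    route_addons: Mapping[str, float] | NanoKineticParams | None = None,
) -> NanoKineticParams:
    """Traditional route-to-route extrapolation of an IV-calibrated set.

    Every particle-specific parameter (distribution, permeability, uptake,
    release, excretion) is copied from the IV set; only the route-entry
    parameters for the target route are taken from ``route_addons`` (a
    mapping of flat names, or a parameter set to pull them from).  IV in, IV
    out.  A missing required addon raises.
    """
    route = Route.parse(route)
    params = iv_params.copy()
    needed = ROUTE_ENTRY_PARAMS[route]
    if not needed:
        return params
    if route_addons is None:
        raise ValueError(f"route {route.value!r} requires addons: {list(needed)}")
    for name in needed:
        if isinstance(route_addons, NanoKineticParams):
            value = route_addons.get(name)
        elif name in route_addons:
            value = route_addons[name]
        else:
            raise ValueError(f"missing route addon {name!r} for route {route.value!r}")
        params = params.with_value(name, float(value))
    return params


def predictions_for(
    phys: PhysiologyRat,
    params: NanoKineticParams,
    scenario: ExposureScenario,
    observations: pd.DataFrame,
) -> pd.DataFrame:
    """Pair one route's observations with model predictions.

    ``observations`` is a tidy table (tissue/time_h/value/unit) for a single
    (route, size); returns it with a ``predicted`` column added.
    """
    times = sorted(set(observations["time_h"].astype(float)))
    traj = simulate(phys, params, scenario, extra_times=times, rtol=1e-7, atol=1e-10)
    metrics = dose_metrics(traj, scenario, windows=())
    from .datasets import canonical_tissue

    preds = []
    for row in observations.itertuples(index=False):
        table = metrics.pct_ipld if row.unit == "pct_ipld" else metrics.pct_id
        preds.append(table[(canonical_tissue(row.tissue), float(row.time_h))])
    out = observations.copy()
    out["predicted"] = preds
    out = out.rename(columns={"value": "observed"})
    return out


def compare_approaches(
    data_by_route: Mapping[Route, pd.DataFrame],
    iv_calibration: NanoKineticParams,
    route_calibrations: Mapping[Route, NanoKineticParams],
    phys: PhysiologyRat,
    scenarios: Mapping[Route, ExposureScenario],
    scale: str = "linear",
) -> tuple[Dict[Route, Dict[str, EvaluationReport]], pd.DataFrame]:
    """Traditional vs route-specific evaluation on each non-IV route.

    For every route the traditional set copies the IV calibration and takes
    route-entry parameters from the route-specific set; both parameterizations
    are scored against the same observations.  Returns per-route report pairs
    and a summary table ranked by 2-fold fraction (ties broken by RMSE).
    """
    reports: Dict[Route, Dict[str, EvaluationReport]] = {}
    rows = []
    for route in sorted(data_by_route, key=lambda r: r.value):
        obs = data_by_route[route]
        route_params = route_calibrations[route]
        trad_params = traditional_extrapolation(iv_calibration, route, route_params)
        pair = {}
        for label, params in (
            ("traditional", trad_params),
            ("route_specific", route_params),
        ):
            paired = predictions_for(phys, params, scenarios[route], obs)
            pair[label] = fold_error_stats(paired, scale=scale)
            rows.append({"route": route.value, "approach": label, **pair[label].as_dict()})
        reports[route] = pair
    summary = pd.DataFrame(rows).sort_values(
        ["route", "frac_within_2fold", "rmse"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return reports, summary
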