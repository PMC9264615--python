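"""QSAR link: multivariate linear regression from particle physicochemistry
to route-specific biodistribution parameters.

Candidate descriptors are hydrodynamic diameter (HD, nm), surface area (SA),
zeta potential (ZP, mV) and their transforms log(HD), log(SA), log(|ZP|) and
the log-transformed administered particle number log(NPs) -- seven candidate
predictors in total.  "Stepwise" selection is realized as an exhaustive,
deterministic search over all C(7,1) + C(7,2) = 28 one- and two-predictor
subsets (models with three or more predictors are not considered); the
minimum-BIC model among those with an overall F-test p < 0.05 is selected,
falling back to the best-BIC model flagged non-significant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Mapping, Sequence

import numpy as np
from scipy import stats

from .pbpk import NanoKineticParams

logger = logging.getLogger("nanopbpk")

#: candidate predictor names, in slot order
CANDIDATES = ("hd", "sa", "zp", "log_hd", "log_sa", "log_zp", "log_nps")

#: condition-number threshold above which a predictor subset is skipped
COLLINEARITY_THRESHOLD = 1e8

_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class PhysChemDescriptors:
    """Measured particle descriptors plus derived log transforms.

    ``log_zp`` is the natural log of |ZP| (the study particles are all
    negatively charged, so the magnitude carries the information).
    """

    hd: float  # hydrodynamic diameter, nm
    sa: float  # surface area
    zp: float  # zeta potential, mV
    n_particles: float  # administered particle count

    def __post_init__(self) -> None:
        if self.hd <= 0 or self.sa <= 0 or self.n_particles <= 0:
            raise ValueError("hd, sa and n_particles must be > 0")

    @property
    def log_hd(self) -> float:
        return math.log(self.hd)

    @property
    def log_sa(self) -> float:
        return math.log(self.sa)

    @property
    def log_zp(self) -> float:
        return math.log(abs(self.zp))

    @property
    def log_nps(self) -> float:
        return math.log(self.n_particles)

    def value(self, name: str) -> float:
        if name not in CANDIDATES:
            raise KeyError(f"unknown descriptor: {name!r}")
        return float(getattr(self, name))


def design_matrix(
    descriptors: Sequence[PhysChemDescriptors], predictors: Sequence[str]
) -> np.ndarray:
    """Design matrix with intercept column for the chosen predictors."""
    x = np.column_stack(
        [np.ones(len(descriptors))]
        + [np.array([d.value(p) for d in descriptors]) for p in predictors]
    )
    return x


@dataclass
class RegressionModel:
    """One selected regression: response <- subset of descriptors.

    BIC follows the ``n log(RSS/n) + k log(n)`` convention with k counting
    the intercept and slopes, so values are internally comparable across
    subsets (the absolute scale may differ from other software by an
    additive constant).
    """

    response: str
    route: str
    predictors: tuple[str, ...]
    beta0: float
    betas: Dict[str, float]
    bic: float
    adj_r2: float
    p_value: float
    significant: bool = True
    training_range: Dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "route": self.route,
            "predictors": list(self.predictors),
            "beta0": self.beta0,
            "betas": dict(self.betas),
            "bic": self.bic,
            "adj_r2": self.adj_r2,
            "p_value": self.p_value,
            "significant": self.significant,
            "training_range": {k: list(v) for k, v in self.training_range.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegressionModel":
        return cls(
            response=d["response"],
            route=d["route"],
            predictors=tuple(d["predictors"]),
            beta0=float(d["beta0"]),
            betas={k: float(v) for k, v in d["betas"].items()},
            bic=float(d["bic"]),
            adj_r2=float(d["adj_r2"]),
            p_value=float(d["p_value"]),
            significant=bool(d.get("significant", True)),
            training_range={k: tuple(v) for k, v in d.get("training_range", {}).items()},
        )


def _fit_subset(
    y: np.ndarray, descriptors: Sequence[PhysChemDescriptors], subset: tuple[str, ...]
) -> tuple[np.ndarray, float, float, float] | None:
    """OLS fit of one subset; returns (coef, bic, adj_r2, p) or None if the
    design is rank-deficient / collinear beyond the condition threshold."""
    x = design_matrix(descriptors, subset)
    n, k1 = x.shape  # k1 = 1 + number of slopes
    if np.linalg.cond(x) > COLLINEARITY_THRESHOLD:
        logger.info("skipping collinear predictor subset %s", subset)
        return None
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < k1:
        logger.info("skipping rank-deficient predictor subset %s", subset)
        return None
    resid = y - x @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    k_slopes = k1 - 1
    dof = n - k1
    if dof <= 0:
        return None
    bic = n * math.log(max(rss, _RSS_FLOOR) / n) + k1 * math.log(n)
    if tss == 0:
        return None  # constant response carries no signal
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof
    if rss < _RSS_FLOOR * max(tss, 1.0):
        p_value = 0.0  # numerically perfect fit
    else:
        f_stat = ((tss - rss) / k_slopes) / (rss / dof)
        p_value = float(stats.f.sf(f_stat, k_slopes, dof))
    return coef, bic, adj_r2, p_value


def stepwise_fit(
    param_values: Sequence[float],
    descriptors: Sequence[PhysChemDescriptors],
    response: str = "",
    route: str = "",
    alpha: float = 0.05,
    max_predictors: int = 2,
) -> RegressionModel:
    """Exhaustive best-subset regression over 1..max_predictors predictors.

    Selection: minimum BIC among subsets whose overall F-test p < ``alpha``;
    if no subset is significant, the best-BIC subset is returned flagged
    ``significant=False``.  Ties resolve toward fewer predictors, then
    candidate order -- the search is fully deterministic.  A constant
    response yields an intercept-only fallback flagged non-significant.
    """
    y = np.asarray(param_values, float)
    if y.size < 3:
        raise ValueError("need at least 3 size points to fit")
    if y.size != len(descriptors):
        raise ValueError("response and descriptor lengths differ")

    t_range = {
        name: (
            min(d.value(name) for d in descriptors),
            max(d.value(name) for d in descriptors),
        )
        for name in CANDIDATES
    }

    def intercept_only() -> RegressionModel:
        return RegressionModel(
            response=response,
            route=route,
            predictors=(),
            beta0=float(y.mean()),
            betas={},
            bic=float(y.size * math.log(max(float(np.var(y)), _RSS_FLOOR)) ),
            adj_r2=float("nan"),
            p_value=1.0,
            significant=False,
            training_range=t_range,
        )

    if np.allclose(y, y[0]):
        return intercept_only()

    fits = []
    for k in range(1, max_predictors + 1):
        for subset in combinations(CANDIDATES, k):
            result = _fit_subset(y, descriptors, subset)
            if result is not None:
                fits.append((subset, *result))
    if not fits:
        return intercept_only()

    def sort_key(item):
        subset, _, bic, _, _ = item
        return (bic, len(subset), tuple(CANDIDATES.index(s) for s in subset))

    significant = [f for f in fits if f[4] < alpha]
    pool = significant if significant else fits
    subset, coef, bic, adj_r2, p_value = min(pool, key=sort_key)
    return RegressionModel(
        response=response,
        route=route,
        predictors=subset,
        beta0=float(coef[0]),
        betas={name: float(c) for name, c in zip(subset, coef[1:])},
        bic=float(bic),
        adj_r2=float(adj_r2),
        p_value=float(p_value),
        significant=bool(significant),
        training_range=t_range,
    )


#: applicable particle-size domain of the calibrated models, nm
APPLICABLE_HD_RANGE = (1.4, 200.0)


def predict_parameter(
    model: RegressionModel,
    descriptors: PhysChemDescriptors,
    floor_at_zero: bool = True,
) -> float:
    """Forward prediction ``beta0 + sum beta_i x_i`` for one particle.

    Warns (without failing) when a descriptor falls outside the training
    hull or the particle size is outside the applicable 1.4-200 nm domain;
    negative predictions for rate/capacity responses are floored at 0 with a
    warning.
    """
    if not APPLICABLE_HD_RANGE[0] <= descriptors.hd <= APPLICABLE_HD_RANGE[1]:
        warnings.warn(
            f"hydrodynamic diameter {descriptors.hd:g} nm outside the applicable "
            f"{APPLICABLE_HD_RANGE[0]}-{APPLICABLE_HD_RANGE[1]} nm domain",
            stacklevel=2,
        )
    for name in model.predictors:
        rng = model.training_range.get(name)
        if rng and not rng[0] <= descriptors.value(name) <= rng[1]:
            warnings.warn(
                f"descriptor {name!r}={descriptors.value(name):g} outside the "
                f"training range {rng}; extrapolating",
                stacklevel=2,
            )
    value = model.beta0 + sum(
        beta * descriptors.value(name) for name, beta in model.betas.items()
    )
    if floor_at_zero and value < 0:
        warnings.warn(
            f"negative prediction {value:g} for {model.response!r} floored at 0",
            stacklevel=2,
        )
        return 0.0
    return float(value)


def build_param_set(
    models: Mapping[str, RegressionModel],
    descriptors: PhysChemDescriptors,
    fallback: NanoKineticParams,
    epsilon: float = 1e-9,
) -> NanoKineticParams:
    """Kinetic parameter set with QSAR predictions overriding the fallback.

    ``models`` maps flat parameter names (e.g. ``k_max_liver``) to fitted
    regressions.  Predictions violating the parameter invariants (zero or
    negative rates/capacities) are repaired to a small positive epsilon with
    a warning; parameters without a model are copied from ``fallback``.
    """
    params = fallback.copy()
    for name, model in models.items():
        value = predict_parameter(model, descriptors, floor_at_zero=False)
        if value <= 0 and not name.startswith("permeability"):
            warnings.warn(
                f"QSAR prediction for {name!r} was {value:g}; repaired to {epsilon:g}",
                stacklevel=2,
            )
            value = epsilon
        params = params.with_value(name, value)
    params.validate()
    return params
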