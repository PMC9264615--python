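"""Study designs, packaged reference parameters, synthetic data and file I/O.

The synthetic-data generator emulates the design of the rat gold-nanoparticle
biodistribution studies the model is meant for: particle core sizes 1.4-200 nm
(23 nm for inhalation), microgram-scale doses, dissected-organ sampling at
1-24 h (out to 672 h for inhalation) over blood, lung, liver, spleen, GI
tract, kidney, remaining tissues, urine and feces, with multiplicative
lognormal measurement noise.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .pbpk import (
    TISSUES,
    ExposureScenario,
    NanoKineticParams,
    PhysiologyRat,
    Route,
    default_physiology,
    dose_metrics,
    make_scenario,
    simulate,
)

logger = logging.getLogger("nanopbpk")

#: study-table tissue abbreviations -> canonical names
TISSUE_ABBREV = {
    "Bl": "blood",
    "Lu": "lung",
    "Li": "liver",
    "Sp": "spleen",
    "Ki": "kidney",
    "GI": "gi",
    "Rt": "rest",
    "U": "urine",
}
_CANONICAL = set(TISSUE_ABBREV.values()) | {"feces"}

#: tidy observation-table schema
OBS_COLUMNS = ["route", "size_nm", "tissue", "time_h", "dose_ug", "value", "unit", "sd", "n"]
VALID_UNITS = {"pct_id", "pct_ipld", "ug"}


def canonical_tissue(name: str) -> str:
    """Map a study-table abbreviation or canonical name to canonical form."""
    if name in TISSUE_ABBREV:
        return TISSUE_ABBREV[name]
    low = str(name).strip().lower()
    if low in _CANONICAL:
        return low
    raise ValueError(f"unknown tissue name: {name!r}")


# ---------------------------------------------------------------------------
# packaged reference parameter sets (synthetic reference values)
# ---------------------------------------------------------------------------


def hydrodynamic_diameter(size_nm: float) -> float:
    """Hydrodynamic diameter (nm) from core size: corona-swollen core."""
    return 1.18 * size_nm + 2.6


def default_descriptors(size_nm: float, dose_ug: float):
    """Physicochemical descriptors for a citrate-coated gold particle.

    Synthetic reference values: hydrodynamic diameter from the core size,
    per-particle surface area (1e2 nm^2), particle count from the dose and
    bulk gold density (19.3 g/cm^3), and a mildly size-dependent negative
    zeta potential in the -47..-37 mV band.
    """
    from .qsar import PhysChemDescriptors  # local import to avoid a cycle

    hd = hydrodynamic_diameter(size_nm)
    sa = math.pi * hd**2 / 100.0
    mass_per_particle_ug = 19.3 * (math.pi / 6.0) * size_nm**3 * 1e-15
    n_particles = dose_ug / mass_per_particle_ug
    zp = -46.0 + 0.045 * size_nm
    return PhysChemDescriptors(hd=hd, sa=sa, zp=zp, n_particles=n_particles)


# route modifiers on uptake/release: nanoparticle biodistribution is
# route-divergent (different biomolecular coronas), so the generating truth
# differs across routes by these factors
_ROUTE_KMAX = {
    Route.IV: {},
    Route.ORAL: {"liver": 0.5, "kidney": 2.5, "spleen": 0.6},
    Route.IT: {"lung": 12.0, "liver": 1.8, "kidney": 1.5, "spleen": 1.4},
    Route.IH: {"lung": 8.0, "liver": 1.5, "kidney": 1.3},
}
_ROUTE_KREL = {
    Route.IV: {},
    Route.ORAL: {"liver": 2.0, "kidney": 0.5},
    Route.IT: {"lung": 0.6},
    Route.IH: {"lung": 0.5},
}


def default_params(size_nm: float = 5.0, route: Route | str = Route.IV) -> NanoKineticParams:
    """Reference nanoparticle kinetic parameter set per size and route.

    Synthetic reference values with smooth, monotone size dependence: uptake
    rates and capacities grow mildly with hydrodynamic diameter, urinary
    elimination falls off steeply with size (glomerular filtration cut-off),
    and the route modifiers encode route-divergent uptake/release kinetics.
    """
    route = Route.parse(route)
    hd = hydrodynamic_diameter(size_nm)
    k_max = {
        "liver": 8.0 + 0.06 * hd,
        "spleen": 12.0 + 0.08 * hd,
        "kidney": 1.2 + 0.01 * hd,
        "lung": 0.4 + 0.004 * hd,
        "gi": 0.5,
        "rest": 0.2,
    }
    a_cap = {
        "liver": 40.0 + 0.5 * hd,
        "spleen": 8.0 + 0.1 * hd,
        "kidney": 4.0,
        "lung": 12.0 + 0.15 * hd,
        "gi": 20.0,
        "rest": 60.0,
    }
    k_release = {
        "liver": 0.04,
        "spleen": 0.02,
        "kidney": 0.08,
        "lung": 0.05,
        "gi": 0.10,
        "rest": 0.05,
    }
    for t, f in _ROUTE_KMAX[route].items():
        k_max[t] *= f
    for t, f in _ROUTE_KREL[route].items():
        k_release[t] *= f

    params = NanoKineticParams(
        distribution={t: 0.15 for t in TISSUES},
        permeability={
            "lung": 0.001,
            "liver": 0.03,
            "spleen": 0.03,
            "gi": 0.005,
            "kidney": 0.01,
            "rest": 0.0005,
        },
        k_max=k_max,
        a_cap=a_cap,
        k_release=k_release,
        k_urine=0.4 * math.exp(-size_nm / 6.0) + 0.003,
        k_bile=0.003,
        k_feces=0.35,
    )
    if route is Route.ORAL:
        params.k_gi_abs = 5e-4
        params.k_reabs = 1e-4
    elif route is Route.IT:
        params.k_mucociliary = 0.03
        params.k_lung_trans = 0.008
        params.k_gi_abs = 5e-4
    elif route is Route.IH:
        params.k_mucociliary = 0.02
        params.k_lung_trans = 0.004
        params.k_gi_abs = 5e-4
    params.validate()
    return params


#: route-entry parameters copied from route-specific sets under the
#: traditional route-to-route extrapolation
ROUTE_ENTRY_PARAMS = {
    Route.IV: (),
    Route.ORAL: ("k_gi_abs", "k_reabs", "k_feces"),
    Route.IT: ("k_mucociliary", "k_lung_trans", "k_gi_abs", "k_feces"),
    Route.IH: ("k_mucociliary", "k_lung_trans", "k_gi_abs", "k_feces"),
}


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """One route's calibration-study design (sizes, doses, times, tissues)."""

    route: Route
    sizes_nm: tuple[float, ...]
    dose_ug: Dict[float, float]  # size -> dose
    sampling_times_h: tuple[float, ...]
    tissues: tuple[str, ...]
    n_replicates: int = 4

    def __post_init__(self) -> None:
        self.route = Route.parse(self.route)
        self.sizes_nm = tuple(float(s) for s in self.sizes_nm)
        self.sampling_times_h = tuple(float(t) for t in self.sampling_times_h)
        self.tissues = tuple(canonical_tissue(t) for t in self.tissues)
        if any(t <= 0 for t in self.sampling_times_h):
            raise ValueError("sampling times must be positive")
        for s in self.sizes_nm:
            if float(self.dose_ug[s]) <= 0:
                raise ValueError(f"dose for size {s} nm must be > 0")

    def scenario(self, size_nm: float) -> ExposureScenario:
        return make_scenario(
            self.route, float(self.dose_ug[float(size_nm)]), self.sampling_times_h
        )


def load_study_designs() -> Dict[Route, StudyDesign]:
    """Load the packaged multi-route calibration-study design fixture."""
    text = resources.files("nanopbpk.data").joinpath("study_designs.yaml").read_text()
    raw = yaml.safe_load(text)
    designs: Dict[Route, StudyDesign] = {}
    for entry in raw["designs"]:
        design = StudyDesign(
            route=entry["route"],
            sizes_nm=entry["sizes_nm"],
            dose_ug={float(k): float(v) for k, v in entry["dose_ug"].items()},
            sampling_times_h=entry["sampling_times_h"],
            tissues=entry["tissues"],
            n_replicates=int(entry.get("n_replicates", 4)),
        )
        designs[design.route] = design
    return designs


# ---------------------------------------------------------------------------
# synthetic observations
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Specification for one synthetic multi-study observation table.

    ``true_params`` maps (route, size_nm) to the generating kinetic truth;
    designs without an entry fall back to :func:`default_params`.
    ``noise_gsd`` is the multiplicative lognormal measurement noise
    (geometric SD, >= 1; 1 means noise-free).
    """

    designs: Sequence[StudyDesign]
    true_params: Dict[tuple[Route, float], NanoKineticParams] = field(default_factory=dict)
    noise_gsd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_gsd < 1.0:
            raise ValueError("noise_gsd must be >= 1")


def generate_synthetic(
    spec: SyntheticSpec,
    phys: PhysiologyRat | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate every design point and add lognormal replicate noise.

    Returns a tidy observation table (one row per replicate animal-group
    measurement) with columns :data:`OBS_COLUMNS`.  All randomness flows
    through a generator seeded with ``spec.seed``.
    """
    phys = phys or default_physiology()
    rng = np.random.default_rng(spec.seed)
    sigma = math.log(spec.noise_gsd)
    rows = []
    for design in spec.designs:
        unit = "pct_ipld" if design.route is Route.IH else "pct_id"
        for size in design.sizes_nm:
            params = spec.true_params.get((design.route, size))
            if params is None:
                params = default_params(size, design.route)
            scenario = design.scenario(size)
            try:
                traj = simulate(phys, params, scenario, rtol=rtol, atol=atol)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for route={design.route.value} size={size} nm"
                ) from exc
            metrics = dose_metrics(traj, scenario, windows=())
            table = metrics.pct_ipld if unit == "pct_ipld" else metrics.pct_id
            for tissue in design.tissues:
                for t in design.sampling_times_h:
                    f = table[(tissue, float(t))]
                    eps = rng.normal(0.0, sigma, size=design.n_replicates)
                    for y in f * np.exp(eps):
                        rows.append(
                            {
                                "route": design.route.value,
                                "size_nm": size,
                                "tissue": tissue,
                                "time_h": float(t),
                                "dose_ug": scenario.administered_dose,
                                "value": float(y),
                                "unit": unit,
                                "sd": np.nan,
                                "n": 1,
                            }
                        )
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


# ---------------------------------------------------------------------------
# readers / writers (lossless tidy-CSV round trips)
# ---------------------------------------------------------------------------


def write_observations(df: pd.DataFrame, path) -> None:
    _validate_observations(df)
    df.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_observations(df)
    return df


def _validate_observations(df: pd.DataFrame) -> None:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    for col in ("time_h", "dose_ug"):
        bad = df.index[df[col] < 0] if col == "time_h" else df.index[df[col] <= 0]
        if len(bad):
            raise ValueError(
                f"invalid {col} at row {int(bad[0])}: {df.loc[bad[0], col]!r}"
            )
    bad_unit = df.index[~df["unit"].isin(VALID_UNITS)]
    if len(bad_unit):
        raise ValueError(
            f"invalid unit at row {int(bad_unit[0])}: {df.loc[bad_unit[0], 'unit']!r}"
        )
    df["tissue"].map(canonical_tissue)  # raises on unknown names


def write_params(params: NanoKineticParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def read_params(path) -> NanoKineticParams:
    with open(path) as fh:
        return NanoKineticParams.from_dict(yaml.safe_load(fh))


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def trajectory_frame(traj, scenario=None, size_nm: float | None = None) -> pd.DataFrame:
    """Tidy export of a trajectory: route, size_nm, tissue, time, amount, %."""
    from .pbpk import ID_OBSERVABLES

    scenario = scenario or traj.scenario
    dose = scenario.administered_dose
    ipld = scenario.peripheral_lung_dose if scenario.route is Route.IH else None
    rows = []
    for obs in ID_OBSERVABLES:
        series = traj.observable_amount(obs)
        for t, a in zip(traj.times, series):
            rows.append(
                {
                    "route": scenario.route.value,
                    "size_nm": size_nm,
                    "tissue": obs,
                    "time_h": float(t),
                    "amount_ug": float(a),
                    "pct_id": 100.0 * a / dose,
                    "pct_ipld": (100.0 * a / ipld) if ipld else np.nan,
                }
            )
    return pd.DataFrame(rows)


def load_packaged_regressions() -> pd.DataFrame:
    """Packaged route-specific regression coefficient table (IV block).

    Transcribed published coefficients linking particle physicochemistry to
    biodistribution parameters after intravenous dosing.  Predictor identity
    is recorded where known (liver maximum-uptake row: HD and SA); rows whose
    predictor labels could not be recovered carry x1/x2 placeholders and are
    usable only for inspection, not forward prediction.
    """
    text = resources.files("nanopbpk.data").joinpath("iv_regression_models.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def write_models(models: Mapping[str, "object"], path) -> None:
    """Serialize a map of fitted regression models to JSON."""
    payload = {name: m.to_dict() for name, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_models(path) -> dict:
    from .qsar import RegressionModel

    with open(path) as fh:
        payload = json.load(fh)
    return {name: RegressionModel.from_dict(d) for name, d in payload.items()}
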