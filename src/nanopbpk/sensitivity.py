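"""Local one-at-a-time sensitivity analysis on tissue AUCs.

The normalized sensitivity coefficient (NSC) of an output AUC with respect to
a parameter p is the relative AUC change divided by the relative parameter
change, here by forward finite difference at a +1% perturbation:
``NSC = [(AUC(1.01 p) - AUC(p)) / AUC(p)] / 0.01``.  Parameters with
|NSC| >= 0.5 for at least one output are flagged highly sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import pandas as pd

from .pbpk import (
    AUC_OUTPUTS,
    ExposureScenario,
    NanoKineticParams,
    PhysiologyRat,
    simulate,
)

#: |NSC| threshold above which a parameter is called highly sensitive
SENSITIVE_THRESHOLD = 0.5

_SIM_KW = dict(rtol=1e-8, atol=1e-12)


class UndefinedNSCError(ValueError):
    """Baseline AUC is zero; the relative sensitivity is undefined."""


def normalized_sensitivity(
    f: Callable[[float], float],
    p0: float,
    delta: float = 0.01,
    central: bool = False,
) -> float:
    """Finite-difference NSC of a scalar function at ``p0``.

    Forward difference by default (the +1% convention); ``central=True``
    uses +/- delta/... a symmetric two-point difference as a cross-check.
    """
    if p0 == 0:
        raise ValueError("cannot perturb a zero-valued parameter relatively")
    base = f(p0)
    if base == 0:
        raise UndefinedNSCError("baseline output is zero; NSC undefined")
    if central:
        up, down = f(p0 * (1 + delta)), f(p0 * (1 - delta))
        return ((up - down) / base) / (2 * delta)
    return ((f(p0 * (1 + delta)) - base) / base) / delta


def _auc_map(
    phys: PhysiologyRat,
    params: NanoKineticParams,
    scenario: ExposureScenario,
    windows: Sequence[float],
) -> Dict[tuple[str, float], float]:
    traj = simulate(phys, params, scenario, extra_times=windows, **_SIM_KW)
    return {(t, w): traj.auc(t, w) for t in AUC_OUTPUTS for w in windows}


def _perturbed(
    params: NanoKineticParams, scenario: ExposureScenario, name: str, factor: float
) -> tuple[NanoKineticParams, ExposureScenario]:
    if name == "dose":
        import copy

        sc = copy.copy(scenario)
        sc.dose_ug = scenario.administered_dose * factor
        return params, sc
    return params.with_value(name, params.get(name) * factor), scenario


def nsc(
    phys: PhysiologyRat,
    params: NanoKineticParams,
    scenario: ExposureScenario,
    parameter_name: str,
    output_tissue: str,
    window: float,
    delta: float = 0.01,
    central: bool = False,
) -> float:
    """NSC of one tissue AUC over [0, window] w.r.t. one named parameter.

    ``parameter_name`` is any flat kinetic-parameter name (see
    :meth:`NanoKineticParams.parameter_names`) or ``"dose"``.
    """
    windows = (float(window),)
    base = _auc_map(phys, params, scenario, windows)[(output_tissue, window)]
    if base == 0:
        raise UndefinedNSCError(
            f"baseline AUC for {output_tissue!r} over [0, {window}] h is zero"
        )

    def auc_at(factor: float) -> float:
        pp, sc = _perturbed(params, scenario, parameter_name, factor)
        return _auc_map(phys, pp, sc, windows)[(output_tissue, window)]

    if central:
        return ((auc_at(1 + delta) - auc_at(1 - delta)) / base) / (2 * delta)
    return ((auc_at(1 + delta) - base) / base) / delta


@dataclass
class SensitivityResult:
    """NSC values and high-sensitivity flags as a tidy table."""

    table: pd.DataFrame  # columns: parameter, tissue, window_h, nsc, sensitive

    def nsc_value(self, parameter: str, tissue: str, window: float) -> float:
        t = self.table
        row = t[
            (t.parameter == parameter) & (t.tissue == tissue) & (t.window_h == window)
        ]
        if row.empty:
            raise KeyError((parameter, tissue, window))
        return float(row.nsc.iloc[0])

    def sensitive_parameters(self) -> list[str]:
        return sorted(self.table.loc[self.table.sensitive, "parameter"].unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def nsc_table(
    phys: PhysiologyRat,
    params: NanoKineticParams,
    scenario: ExposureScenario,
    windows: Sequence[float] = (24.0, 672.0),
    parameters: Sequence[str] | None = None,
    delta: float = 0.01,
) -> SensitivityResult:
    """NSC of every AUC output x window w.r.t. every kinetic parameter.

    One baseline and one perturbed simulation per parameter (all outputs and
    windows read from the same integrated AUC accumulators); deterministic.
    Parameters whose baseline value is zero (inactive pathways for the route)
    are reported with NSC 0.
    """
    windows = tuple(float(w) for w in windows)
    if parameters is None:
        parameters = NanoKineticParams.parameter_names()
    base = _auc_map(phys, params, scenario, windows)
    rows = []
    for name in parameters:
        p0 = scenario.administered_dose if name == "dose" else params.get(name)
        if p0 == 0:
            vals = {key: 0.0 for key in base}
        else:
            pp, sc = _perturbed(params, scenario, name, 1 + delta)
            pert = _auc_map(phys, pp, sc, windows)
            vals = {}
            for key, b in base.items():
                if b == 0:
                    raise UndefinedNSCError(f"baseline AUC is zero for {key}")
                vals[key] = ((pert[key] - b) / b) / delta
        for (tissue, w), v in vals.items():
            rows.append(
                {
                    "parameter": name,
                    "tissue": tissue,
                    "window_h": w,
                    "nsc": v,
                    "sensitive": abs(v) >= SENSITIVE_THRESHOLD,
                }
            )
    return SensitivityResult(pd.DataFrame(rows))
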