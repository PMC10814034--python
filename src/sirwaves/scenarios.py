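"""Shipped scenarios, configuration handling and the run driver.

Each scenario encodes the parameterization of one of the canonical wave
studies: a basic tanh-pulse wave (N = 10^7, S0 = 9,999,999, tau = 0.00825,
rho = 0.00775), parameter sweeps around it (initial spreaders, population,
transmission rate, recovery rate), the dissipative cubic-family waves
(N = 10^6, S0 = 900,000, tau = 0.009 with rho implied), and a four-wave
increasing wavetrain on the basic parameters.

Scenarios round-trip losslessly through YAML/JSON; unknown keys are
rejected.  ``run_scenario`` solves every curve, computes its metrics, and
certifies the closed form in place: the ODE residual must stay below 1e-5
and the Taylor validity bound below 0.1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .analytic_solutions import (
    RESIDUAL_THRESHOLD,
    RiccatiWaveM2,
    WaveM3,
    residual_m2,
    residual_m3,
)
from .chain_reduction import VALIDITY_THRESHOLD, validity_bound
from .core_model import SIRParams, integrate_sir
from .exceptions import ConfigError, UnknownScenarioError
from .wave_metrics import compute_metrics
from .wavetrain import WaveSegment, WavetrainSpec, compose_wavetrain

__all__ = [
    "Scenario",
    "load_scenario",
    "run_scenario",
    "available_scenarios",
    "scenario_to_dict",
    "scenario_from_dict",
]

log = logging.getLogger("sirwaves")

_MODELS = ("m2-d0", "m3", "sir", "wavetrain")


@dataclass(frozen=True)
class Scenario:
    """A named, reproducible parameterization.

    ``variations`` maps curve labels to parameter overrides applied on top
    of ``params``; the base parameterization itself is curve "1" where a
    figure shows numbered curves.
    """

    name: str
    model: str
    params: dict
    t_end: float | None = None
    n_points: int = 2001
    variations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.model == "m3" and "rho" in self.params:
            raise ConfigError(
                "rho is not a free parameter of the cubic (m3) family; it is fixed "
                "by rho = tau (1 - S0/(3N))")


_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(Scenario)}

_BASIC = {"N": 1e7, "S0": 9_999_999.0, "I0": 1.0, "R0": 0.0, "tau": 0.00825, "rho": 0.00775}
_BASIC_M3 = {"N": 1e6, "S0": 900_000.0, "tau": 0.009}


def _m2(name, variations=None, **over):
    params = {**_BASIC, **over}
    return Scenario(name=name, model="m2-d0", params=params, variations=variations or {})


_SCENARIOS: dict[str, Scenario] = {}


def _register(s: Scenario) -> Scenario:
    _SCENARIOS[s.name] = s
    return s


_register(_m2("fig1_basic"))
_register(_m2("fig2_s0_sweep", variations={
    "2": {"S0": 9_999_990.0, "I0": 10.0},
    "3": {"S0": 9_999_900.0, "I0": 100.0},
    "4": {"S0": 9_999_000.0, "I0": 1000.0},
    "5": {"S0": 9_990_000.0, "I0": 10_000.0},
}))
_register(_m2("fig3_s0_sweep", variations={
    "2": {"S0": 9_999_990.0, "I0": 10.0},
    "3": {"S0": 9_999_900.0, "I0": 100.0},
    "4": {"S0": 9_999_000.0, "I0": 1000.0},
    "5": {"S0": 9_990_000.0, "I0": 10_000.0},
}))
_register(_m2("fig4_n_sweep", variations={
    "2": {"N": 5_000_000.0, "S0": 4_999_999.0},
    "3": {"N": 2_500_000.0, "S0": 2_499_999.0},
    "4": {"N": 1_000_000.0, "S0": 999_999.0},
}))
_register(_m2("fig5_tau_sweep", variations={
    "2": {"tau": 0.008},
    "3": {"tau": 0.0085},
    "4": {"tau": 0.00875},   # corrected reading; the printed 0.0875 ships separately
    "5": {"tau": 0.009},
}))
_register(_m2("fig5_curve4_printed", tau=0.0875))
_register(_m2("fig5_curve4_corrected", tau=0.00875))
_register(_m2("fig6_rho_sweep", variations={
    "2": {"rho": 0.00785},
    "3": {"rho": 0.075},
    "4": {"rho": 0.7},
}))
_register(_m2("fig7_i0_sweep", variations={
    "2": {"S0": 9_999_990.0, "I0": 10.0},
    "3": {"S0": 9_999_900.0, "I0": 100.0},
    "4": {"S0": 9_999_000.0, "I0": 1000.0},
    "5": {"S0": 9_990_000.0, "I0": 10_000.0},
}))
_register(Scenario(name="fig8_wavetrain", model="wavetrain", params={
    "N": _BASIC["N"], "I0": _BASIC["I0"],
    "segments": [{"tau": _BASIC["tau"], "rho": _BASIC["rho"], "peak_fraction": 1.5}] * 3
    + [{"tau": _BASIC["tau"], "rho": _BASIC["rho"], "peak_fraction": 2.0}],
}))
_register(Scenario(name="fig9_basic", model="m3", params=dict(_BASIC_M3), variations={
    "2": {"S0": 850_000.0},   # I(0) = 1.5e5
    "3": {"S0": 500_000.0},   # I(0) = 5e5
    "4": {"S0": 200_000.0},   # I(0) = 8e5
}))
_register(Scenario(name="fig10_tau_sweep", model="m3", params=dict(_BASIC_M3), variations={
    "2": {"tau": 0.0005},
    "3": {"tau": 0.002},
    "4": {"tau": 0.005},
}))
_register(Scenario(name="fig10_curve2", model="m3",
                   params={**_BASIC_M3, "tau": 0.0005}))


def available_scenarios() -> list[str]:
    return sorted(_SCENARIOS)


def scenario_to_dict(s: Scenario) -> dict:
    return dataclasses.asdict(s)


def scenario_from_dict(d: dict) -> Scenario:
    if not isinstance(d, dict) or not d:
        raise ConfigError("empty or malformed scenario definition")
    unknown = set(d) - _SCENARIO_FIELDS
    if unknown:
        raise ConfigError(f"unknown scenario fields: {sorted(unknown)}")
    missing = {"name", "model", "params"} - set(d)
    if missing:
        raise ConfigError(f"scenario is missing required fields: {sorted(missing)}")
    return Scenario(**d)


def scenario_to_yaml(s: Scenario) -> str:
    return yaml.safe_dump(scenario_to_dict(s), sort_keys=False)


def scenario_from_yaml(text: str) -> Scenario:
    data = yaml.safe_load(text)
    if data is None:
        raise ConfigError("empty config file")
    return scenario_from_dict(data)


def load_scenario(name: str) -> Scenario:
    """A shipped scenario by name, or a scenario parsed from a YAML/JSON path."""
    if name in _SCENARIOS:
        return _SCENARIOS[name]
    path = Path(name)
    if path.exists():
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text) if text.strip() else None
            if data is None:
                raise ConfigError(f"empty config file: {path}")
            return scenario_from_dict(data)
        return scenario_from_yaml(text)
    raise UnknownScenarioError(
        f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}")


def _curves(scenario: Scenario) -> dict[str, dict]:
    curves = {"1": dict(scenario.params)}
    for label, over in scenario.variations.items():
        curves[label] = {**scenario.params, **over}
    return curves


def _auto_grid(scenario: Scenario, wave) -> np.ndarray:
    if scenario.t_end is not None:
        t_end = scenario.t_end
    else:
        tm = wave.peak_time
        if isinstance(wave, WaveM3):
            # pulse decays like exp(-g t/2) in the tail: six e-foldings past the peak
            t_end = tm + 6.0 / wave.growth_scale
        else:
            t_end = 3.0 * tm if tm > 0 else 10.0 / wave.params.rho
    return np.linspace(0.0, t_end, scenario.n_points)


def run_scenario(scenario: Scenario, out_dir: str | Path | None = None,
                 fmt: str = "csv") -> dict:
    """Solve every curve of a scenario, with metrics and certification.

    Returns a bundle ``{curve_label: {"trajectory", "metrics", "certification"}}``
    plus an overall ``"certified"`` flag.  Certification requires the closed
    form's ODE residual < 1e-5 and the Taylor validity bound < 0.1 along the
    wave (numeric-SIR runs certify trivially: they are the oracle).
    """
    log.info("scenario %s: model=%s curves=%d", scenario.name, scenario.model,
             1 + len(scenario.variations))
    out: dict = {"name": scenario.name, "model": scenario.model, "curves": {}}
    if scenario.model == "wavetrain":
        segs = [WaveSegment(**s) for s in scenario.params["segments"]]
        spec = WavetrainSpec(N=scenario.params["N"], I0=scenario.params["I0"], segments=segs)
        train = compose_wavetrain(spec)
        out["wavetrain"] = train
        out["certified"] = True
        log.info("scenario %s: train_class=%s amplitudes=%s", scenario.name,
                 train.train_class, [f"{a:.6g}" for a in train.segment_amplitudes])
        if out_dir is not None:
            _write_frame(train.frame, Path(out_dir) / f"{scenario.name}.{fmt}", fmt)
        return out
    certified = True
    for label, p in _curves(scenario).items():
        if scenario.model == "m2-d0":
            params = SIRParams(N=p["N"], tau=p["tau"], rho=p["rho"],
                               S0=p["S0"], I0=p.get("I0", p["N"] - p["S0"] - p.get("R0", 0.0)),
                               R0=p.get("R0", 0.0))
            wave = RiccatiWaveM2(params=params, D=p.get("D", 0.0), E=p.get("E", 1.0))
            t = _auto_grid(scenario, wave)
            traj = wave.trajectory(t)
            # residual check on its own fine grid: the finite-difference error
            # must sit well below the certification threshold
            t_fine = np.linspace(0.0, t[-1], 50001)
            residual = residual_m2(params, wave.D, wave.E, t_fine)
            metrics = compute_metrics(wave)
        elif scenario.model == "m3":
            wave = WaveM3(N=p["N"], S0=p["S0"], tau=p["tau"])
            t = _auto_grid(scenario, wave)
            traj = wave.trajectory(t)
            t_fine = np.linspace(0.0, t[-1], 50001)
            residual = residual_m3(wave.N, wave.S0, wave.tau, t_fine)
            metrics = compute_metrics(wave)
        else:  # full SIR
            params = SIRParams(N=p["N"], tau=p["tau"], rho=p["rho"],
                               S0=p["S0"], I0=p.get("I0", 0.0), R0=p.get("R0", 0.0))
            t_end = scenario.t_end or 10.0 / params.rho
            traj = integrate_sir(params, t_end, scenario.n_points)
            residual = 0.0
            metrics = compute_metrics(traj)
        # certify the emitted window: max bound over the sampled trajectory
        if scenario.model in ("m2-d0", "m3"):
            order = 2 if scenario.model == "m2-d0" else 3
            validity = float(np.max(validity_bound(
                traj.params, np.maximum(traj.R, 0.0), M=order)))
        else:
            validity = 0.0
        ok = residual < RESIDUAL_THRESHOLD and validity < VALIDITY_THRESHOLD
        certified &= ok
        log.info("scenario %s curve %s: Im=%.6g tm=%.6g residual=%.3g validity=%.3g ok=%s",
                 scenario.name, label, metrics.Im, metrics.tm, residual, validity, ok)
        out["curves"][label] = {
            "trajectory": traj,
            "metrics": metrics,
            "certification": {"max_residual": residual, "validity_max": validity,
                              "certified": ok},
        }
        if out_dir is not None:
            path = Path(out_dir) / f"{scenario.name}_curve{label}.{fmt}"
            if fmt == "csv":
                traj.write_csv(path)
            else:
                traj.write_json(path)
    out["certified"] = certified
    return out


def _write_frame(frame, path: Path, fmt: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.10g")
    else:
        path.write_text(frame.to_json(orient="columns"))
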