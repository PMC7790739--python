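"""Reproducible experiment presets.

Each preset bundles a full engine configuration for one of the standard
in-silico experiments: single-cell sensitivity scans, wild-type crypts
under the imposed-gradient Wnt models (both gradient extents and both
contact-inhibition thresholds), division-based Wnt crypts (reservoir
sizes 10%/20%, division noise 0/10%/20%), and mutant washout ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .engine import EngineConfig
from .mechanics import CryptDomain
from .wnt_field import WntConfig

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "list_presets"]


@dataclass
class ExperimentPreset:
    name: str
    description: str
    config: EngineConfig | None  # None for single-cell scans
    scan: dict = field(default_factory=dict)


def _crypt(wnt: WntConfig, theta_CI: float, t_max: float = 200.0,
           seed: int = 0) -> EngineConfig:
    return EngineConfig(domain=CryptDomain(), wnt=wnt, theta_CI=theta_CI,
                        t_max=t_max, seed=seed)


def _build() -> dict[str, ExperimentPreset]:
    presets: dict[str, ExperimentPreset] = {}

    presets["cell_scan_ph_kh"] = ExperimentPreset(
        name="cell_scan_ph_kh",
        description=("single-cell cycle duration over the Hippo binding "
                     "rate pH and saturation constant K_H at maximal Wnt"),
        config=None,
        scan={"mode": "pH_KH",
              "axis1": [0.0, 5e3, 1e4, 2e4, 2.6e4, 4e4, 8e4],
              "axis2": [5.0, 10.0, 20.0, 40.0, 80.0]})
    presets["cell_scan_wnt_ph"] = ExperimentPreset(
        name="cell_scan_wnt_ph",
        description=("single-cell cycle duration over Wnt level and pH "
                     "at K_H = 20 nM"),
        config=None,
        scan={"mode": "W_pH",
              "axis1": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
              "axis2": [0.0, 5e3, 1e4, 2e4, 2.6e4, 4e4, 8e4]})

    for mode in ("M_E1", "M_E2"):
        for theta_W in (0.4, 1.0):
            for theta_CI in (0.6, 0.9):
                name = (f"wildtype_{mode.replace('_', '').lower()}"
                        f"_w{int(theta_W * 100)}_ci{int(theta_CI * 100)}")
                presets[name] = ExperimentPreset(
                    name=name,
                    description=(f"wild-type crypt, {mode} imposed Wnt "
                                 f"gradient to {theta_W:.0%} of crypt "
                                 f"height, CI at {theta_CI:.0%} of "
                                 "equilibrium volume"),
                    config=_crypt(WntConfig(mode=mode, theta_W=theta_W),
                                  theta_CI))

    for rho in (0.1, 0.2):
        for sigma in (0.0, 0.1, 0.2):
            name = f"division_wnt_r{int(rho * 100)}_s{int(sigma * 100)}"
            presets[name] = ExperimentPreset(
                name=name,
                description=(f"wild-type crypt, division-based Wnt with "
                             f"{rho:.0%} reservoir and sigma={sigma} "
                             "division noise"),
                config=_crypt(WntConfig(mode="M_I", rho=rho, sigma=sigma),
                              theta_CI=0.9))

    for mode, low, high, label in (("M_E1", 0.4, 1.0, "w"),
                                   ("M_I", 0.1, 0.2, "r")):
        for setting in (low, high):
            for theta_CI in (0.6, 0.75, 0.9):
                if mode == "M_E1":
                    wnt = WntConfig(mode=mode, theta_W=setting)
                else:
                    wnt = WntConfig(mode=mode, rho=setting, sigma=0.0)
                name = (f"washout_{mode.replace('_', '').lower()}"
                        f"_{label}{int(setting * 100)}"
                        f"_ci{int(theta_CI * 100)}")
                presets[name] = ExperimentPreset(
                    name=name,
                    description=(f"mutant washout ensemble, {mode}, "
                                 f"{label}={setting}, CI at "
                                 f"{theta_CI:.0%}"),
                    config=_crypt(wnt, theta_CI, t_max=1000.0))

    return presets


PRESETS = _build()


def get_preset(name: str, seed: int | None = None) -> ExperimentPreset:
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: "
            f"{', '.join(sorted(PRESETS))}") from None
    if seed is not None and preset.config is not None:
        preset = replace(preset, config=replace(preset.config, seed=seed))
    return preset


def list_presets() -> list[str]:
    return sorted(PRESETS)
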