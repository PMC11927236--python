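"""Parameter containers for the doxorubicin PK/PD model of MM1R myeloma cultures.

The pharmacokinetic (PK) constants describe doxorubicin transport between the
extracellular medium, the free cytosolic pool and the DNA-bound pool of a
culture well; they were identified on dedicated uptake experiments and are
treated as fixed here. The pharmacodynamic (PD) parameters govern logistic
growth of the living-cell population and the drug-induced death rate, and are
the quantities the estimation machinery fits.

Units: concentrations in nM, times in hours, volumes in microlitres, cell
populations in cells per well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "PKParams",
    "PDParams",
    "DEFAULT_PK",
    "DEFAULT_PD",
    "DEFAULT_N0",
    "load_params",
    "save_params",
]

#: Hill exponents of the saturable efflux rate. Structural constants of the
#: transport model, never fitted.
HILL_NUM = 1.31
HILL_DEN = 2.31


@dataclass(frozen=True)
class PKParams:
    """Doxorubicin transport constants plus the bound-drug decay rate.

    Attributes
    ----------
    vmax : float
        Amplitude of the saturable efflux rate, nM/h.
    kth : float
        Bound-drug level giving half-maximal efflux drive, nM.
    k_fe : float
        Extracellular-to-intracellular uptake rate, 1/h.
    k_bf : float
        Free-to-DNA-bound binding rate, 1/h.
    v_e, v_i : float
        Extracellular and intracellular compartment volumes, µL. Fixed
        constants: the PK subsystem does not scale with the cell count.
    gamma : float
        First-order decay of DNA-bound drug (dilution with division plus
        degradation, lumped), 1/h. May be zero.
    hill_num, hill_den : float
        Structural exponents of the efflux nonlinearity.
    """

    vmax: float = 1.65e4
    kth: float = 464.0
    k_fe: float = 5.63e-4
    k_bf: float = 1.22
    v_e: float = 100.0
    v_i: float = 0.07
    gamma: float = 0.0044
    hill_num: float = HILL_NUM
    hill_den: float = HILL_DEN

    def __post_init__(self) -> None:
        for name in ("vmax", "kth", "k_fe", "k_bf", "v_e", "v_i", "hill_num", "hill_den"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PKParams.{name} must be strictly positive")
        if self.gamma < 0:
            raise ValueError("PKParams.gamma must be nonnegative")

    def with_gamma(self, gamma: float) -> "PKParams":
        return replace(self, gamma=float(gamma))


#: Per-arm initial cell counts (cells) at the end of drug exposure, keyed by
#: the administered dose in nM.
DEFAULT_N0: dict[float, float] = {
    0.0: 10370.0,
    10.0: 12080.0,
    20.0: 19586.0,
    40.0: 5596.0,
    50.0: 5411.0,
    200.0: 8101.0,
    450.0: 3785.0,
    900.0: 3394.0,
}


@dataclass(frozen=True)
class PDParams:
    """Logistic growth / drug-kill parameters of the cell population.

    Attributes
    ----------
    k_p : float
        Proliferation rate, 1/h.
    theta : float
        Carrying capacity of a culture well, cells.
    kd_max : float
        Maximal drug-induced death rate, 1/h.
    xb_hs : float
        Bound-drug level at half-maximal death rate, nM.
    n0 : mapping
        Initial living-cell count per experimental arm (dose in nM -> cells).
    """

    k_p: float = 0.0198
    theta: float = 262209.0
    kd_max: float = 0.0435
    xb_hs: float = 47.5
    n0: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_N0))

    def __post_init__(self) -> None:
        for name in ("k_p", "theta", "kd_max", "xb_hs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PDParams.{name} must be strictly positive")
        for arm, v in self.n0.items():
            if not v > 0:
                raise ValueError(f"PDParams.n0[{arm}] must be strictly positive")

    def n0_for(self, arm: float) -> float:
        try:
            return float(self.n0[float(arm)])
        except KeyError as exc:
            raise KeyError(f"no initial count defined for arm {arm} nM") from exc


DEFAULT_PK = PKParams()
DEFAULT_PD = PDParams()

# File keys use the field-style symbol names of the model description.
_PK_KEYS = {
    "Vmax": "vmax",
    "kth": "kth",
    "kFE": "k_fe",
    "kBF": "k_bf",
    "VE": "v_e",
    "VI": "v_i",
    "gamma": "gamma",
}
_PD_KEYS = {"kp": "k_p", "theta": "theta", "Kdmax": "kd_max", "XBHS": "xb_hs"}


def load_params(path: str | Path) -> tuple[PKParams, PDParams]:
    """Read a YAML/JSON parameter file with ``pk`` and ``pd`` blocks.

    Keys follow the symbol names (Vmax, kth, kFE, kBF, VE, VI, gamma; kp,
    theta, Kdmax, XBHS, N0). Missing entries fall back to the defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    pk_block = data.get("pk", {})
    pd_block = data.get("pd", {})
    pk_kwargs = {field_: float(pk_block[key]) for key, field_ in _PK_KEYS.items() if key in pk_block}
    pd_kwargs = {field_: float(pd_block[key]) for key, field_ in _PD_KEYS.items() if key in pd_block}
    if "N0" in pd_block:
        pd_kwargs["n0"] = {float(k): float(v) for k, v in pd_block["N0"].items()}
    return PKParams(**pk_kwargs), PDParams(**pd_kwargs)


def save_params(pk: PKParams, pd: PDParams, path: str | Path) -> None:
    """Write parameters as a YAML/JSON file readable by :func:`load_params`."""
    data = {
        "pk": {key: getattr(pk, field_) for key, field_ in _PK_KEYS.items()},
        "pd": {
            **{key: getattr(pd, field_) for key, field_ in _PD_KEYS.items()},
            "N0": {str(k): float(v) for k, v in pd.n0.items()},
        },
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
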