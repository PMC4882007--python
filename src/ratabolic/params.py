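"""Physiological parameter containers and flat-file (TOML) configuration.

Units are uniform across the package: masses in grams, energies in kcal,
time in days, drug doses in mg/kg.  Two frozen dataclasses hold every
constant of the energy-balance model:

``ModelParams``
    Tissue energy densities and deposition costs, diet-induced
    thermogenesis, mass-specific metabolic rates, physical activity,
    basal thermogenesis, the constant energy-partition slope, and the
    baseline food intake.

``DrugParams``
    The dose-dependent Hill effect of drug treatment on energy
    expenditure, plus the treatment window.

The shipped defaults for ``rho_*``, ``eta_*`` and ``beta`` are literature
placeholders (rodent energy densities / deposition costs and a
Sprague-Dawley diet-induced-thermogenesis fraction); ``gamma_*`` are
Kleiber-scaled placeholders for a 350 g lean rat.  Override any of them
from a TOML config when tissue-level values for a specific colony are
available — every operation in the package reads them from these
dataclasses, never from hard-coded numbers.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class ModelParams:
    """Constants of the two-compartment energy-balance model.

    Attributes
    ----------
    rho_fm, rho_ffm : float
        Energy densities of fat and fat-free mass (kcal/g).  Must satisfy
        ``rho_fm > rho_ffm > 0``.
    eta_fm, eta_ffm : float
        Deposition (synthesis) costs per gram of tissue laid down (kcal/g).
    beta : float
        Diet-induced thermogenesis fraction applied to intake above
        baseline (dimensionless, in [0, 1)).
    gamma_fm, gamma_ffm : float
        Mass-specific metabolic rates of the two compartments
        (kcal/g/day).
    lam : float
        Physical-activity coefficient per gram of total body weight
        (kcal/g/day).
    k : float
        Basal thermogenesis offset (kcal/day); may be negative.
    alpha : float
        Constant energy-partition slope dFFM/dFM (g/g).
    i0 : float
        Baseline food intake (kcal/day), the reference for the
        diet-induced thermogenesis term.
    """

    rho_fm: float = 9.4
    rho_ffm: float = 1.8
    eta_fm: float = 0.18
    eta_ffm: float = 0.23
    beta: float = 0.24
    gamma_fm: float = 0.01
    gamma_ffm: float = 0.10
    lam: float = 0.087
    k: float = 0.0
    alpha: float = 0.92
    i0: float = 107.0

    def __post_init__(self) -> None:
        if not (self.rho_fm > self.rho_ffm > 0.0):
            raise ValueError(
                f"require rho_fm > rho_ffm > 0, got rho_fm={self.rho_fm}, "
                f"rho_ffm={self.rho_ffm}"
            )
        if self.eta_fm < 0.0 or self.eta_ffm < 0.0:
            raise ValueError("deposition costs eta_fm, eta_ffm must be >= 0")
        if not (0.0 <= self.beta < 1.0):
            raise ValueError(f"beta must lie in [0, 1), got {self.beta}")
        for name in ("gamma_fm", "gamma_ffm", "lam"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.alpha == self.alpha and abs(self.alpha) < 1e6):
            raise ValueError(f"alpha must be finite, got {self.alpha}")
        if self.i0 < 0.0:
            raise ValueError("baseline intake i0 must be >= 0")

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DrugParams:
    """Hill-type drug effect on energy expenditure.

    The effect ``d(X) = d0 + dmax * X / (ed50 + X)`` (kcal/day) is applied
    during the half-open treatment window ``[t_start, t_end)``.  ``d0`` is
    the handling stress of administration, present in every dosed *and*
    vehicle group of a drug study.

    Attributes
    ----------
    d0 : float
        Handling-stress effect (kcal/day).
    dmax : float
        Maximal drug effect (kcal/day).
    ed50 : float
        Half-maximal dose (mg/kg); must be positive.
    t_start, t_end : float
        Treatment window in study days; defaults to [0, 23).
    """

    d0: float = 13.0
    dmax: float = 37.0
    ed50: float = 10.0
    t_start: float = 0.0
    t_end: float = 23.0

    def __post_init__(self) -> None:
        if self.ed50 <= 0.0:
            raise ValueError(f"ed50 must be > 0, got {self.ed50}")
        if not self.t_start < self.t_end:
            raise ValueError(
                f"treatment window requires t_start < t_end, got "
                f"[{self.t_start}, {self.t_end})"
            )

    def replace(self, **changes: float) -> "DrugParams":
        return dataclasses.replace(self, **changes)


#: TOML template for ``ratabolic config``; one key per parameter, with units.
DEFAULT_CONFIG_TOML = """\
# ratabolic model configuration.
# rho_*/eta_*/beta are literature placeholders (rodent tissue energetics);
# gamma_* are Kleiber-scaled placeholders for a 350 g lean rat.
# Override from colony-specific tissue values where available.

[model]
rho_fm = 9.4      # kcal/g, energy density of fat mass
rho_ffm = 1.8     # kcal/g, energy density of fat-free mass
eta_fm = 0.18     # kcal/g, fat deposition cost
eta_ffm = 0.23    # kcal/g, fat-free deposition cost
beta = 0.24       # -, diet-induced thermogenesis fraction of (I - I0)
gamma_fm = 0.01   # kcal/g/day, fat-mass metabolic rate
gamma_ffm = 0.10  # kcal/g/day, fat-free-mass metabolic rate
lam = 0.087       # kcal/g/day, physical activity per gram body weight
k = 0.0           # kcal/day, basal thermogenesis offset
alpha = 0.92      # g/g, constant energy-partition slope dFFM/dFM
i0 = 107.0        # kcal/day, baseline food intake

[drug]
d0 = 13.0         # kcal/day, handling stress
dmax = 37.0       # kcal/day, maximal drug effect
ed50 = 10.0       # mg/kg, half-maximal dose
t_start = 0.0     # day, treatment window start
t_end = 23.0      # day, treatment window end (exclusive)
"""


def load_config(path: str | Path) -> tuple[ModelParams, DrugParams | None]:
    """Read ``ModelParams`` (table ``[model]``) and optional ``DrugParams``
    (table ``[drug]``) from a flat TOML file.

    Unknown keys raise ``ValueError`` so typos do not silently fall back to
    defaults.
    """
    with open(path, "rb") as fh:
        raw: dict[str, Any] = tomllib.load(fh)
    model_kw = dict(raw.get("model", {}))
    _check_keys(model_kw, ModelParams, "model")
    params = ModelParams(**model_kw)
    drug = None
    if "drug" in raw:
        drug_kw = dict(raw["drug"])
        _check_keys(drug_kw, DrugParams, "drug")
        drug = DrugParams(**drug_kw)
    return params, drug


def apply_overrides(
    params: ModelParams,
    drug: DrugParams | None,
    overrides: list[str],
) -> tuple[ModelParams, DrugParams | None]:
    """Apply ``key=value`` command-line overrides to parameter sets.

    Keys are matched against ``ModelParams`` first, then ``DrugParams``.
    """
    model_fields = {f.name for f in dataclasses.fields(ModelParams)}
    drug_fields = {f.name for f in dataclasses.fields(DrugParams)}
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must be key=value, got {item!r}")
        key, _, val = item.partition("=")
        key = key.strip()
        value = float(val)
        if key in model_fields:
            params = params.replace(**{key: value})
        elif key in drug_fields:
            if drug is None:
                drug = DrugParams()
            drug = drug.replace(**{key: value})
        else:
            raise ValueError(f"unknown parameter {key!r}")
    return params, drug


def _check_keys(kw: dict[str, Any], cls: type, table: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(kw) - known)
    if unknown:
        raise ValueError(f"unknown keys in [{table}]: {', '.join(unknown)}")
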