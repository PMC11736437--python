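"""Parameter containers and presets for C-controlled restriction-modification systems.

The deterministic model of the P.CR promoter is fully specified by three
dimensionless *internal* parameters fixed per system by the biophysics of
C-protein/DNA interaction,

* ``p``      -- binding-strength ratio of the distal (activating, DBS) versus
  proximal (repressing, PBS) C-dimer binding site, ``p = K_d3 / K_d2``,
* ``omega``  -- cooperativity between dimers bound at DBS and PBS
  (tetramer formation), ``omega = K_d2 * K_d3 / K_d23``,
* ``alpha``  -- dimer-formation parameter, ``alpha = sqrt(K_d1 / K_d2)``,

and two *external* parameters that depend on physiological conditions,

* ``s``      -- promoter leakage, basal-to-maximal transcription-rate ratio,
* ``r``      -- overall C expression strength, proportional to plasmid copy
  number and inversely proportional to cell growth rate.

Presets for the three experimentally characterized systems (Esp1396I, AhdI,
EcoRV) are registered here, together with their P.M-architecture parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "DissociationConstants",
    "InternalParams",
    "ExternalParams",
    "PMParams",
    "SystemPreset",
    "infer_internal_params",
    "load_preset",
    "preset_names",
    "save_presets",
    "load_presets_file",
]

ARCHITECTURES = ("esp1396i", "ahdi", "ecorv")


def _require_positive(name: str, value) -> float:
    if value is None:
        raise ValueError(f"missing required constant: {name}")
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class DissociationConstants:
    """Measured dissociation constants, all in a common concentration unit.

    ``kd1``: C monomer-dimer dimerization; ``kd2``: C-dimer/DBS; ``kd3``:
    C-dimer/PBS; ``kd23``: DBS+PBS tetramer (concentration squared);
    ``kd_m``: repressor/P.M (architecture dependent); ``kD_m``: M
    dimerization (AhdI only).
    """

    kd1: float
    kd2: float
    kd3: float
    kd23: float
    kd_m: Optional[float] = None
    kD_m: Optional[float] = None

    def __post_init__(self):
        for name in ("kd1", "kd2", "kd3", "kd23"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))
        for name in ("kd_m", "kD_m"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _require_positive(name, v))


@dataclass(frozen=True)
class InternalParams:
    """Dimensionless internal parameters (p, omega, alpha) of one R-M system."""

    p: float
    omega: float
    alpha: float

    def __post_init__(self):
        for name in ("p", "omega", "alpha"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class ExternalParams:
    """External parameters: leakage ``s`` (>= 0) and expression strength ``r`` (> 0)."""

    s: float
    r: float

    def __post_init__(self):
        s = float(self.s)
        if not math.isfinite(s) or s < 0:
            raise ValueError(f"s must be finite and >= 0, got {self.s!r}")
        _require_positive("r", self.r)


@dataclass(frozen=True)
class PMParams:
    """P.M promoter architecture and its parameters.

    ``phi`` is the maximal P.M-to-P.CR expression-rate ratio. ``gamma``
    (Esp1396I only) is the DBS-to-P.M dissociation-constant ratio
    K_d2/K_dM governing C-dimer repression of P.M. ``alpha_m`` (AhdI only)
    is the M dimer-formation parameter sqrt(K_DM/K_dM).
    """

    architecture: str
    phi: float = 1.0
    gamma: Optional[float] = None
    alpha_m: Optional[float] = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        _require_positive("phi", self.phi)
        if self.architecture == "esp1396i":
            _require_positive("gamma", self.gamma)
        if self.architecture == "ahdi":
            _require_positive("alpha_m", self.alpha_m)


@dataclass(frozen=True)
class SystemPreset:
    """A named, fully parameterized R-M system.

    ``k_rc`` is the R-to-C proportionality constant (R and C are
    co-transcribed, so total R tracks total C linearly); it defaults to 1
    (arbitrary units). ``s_default`` is the leakage inferred from
    expression data where available (None where unknown).
    """

    name: str
    internal: InternalParams
    pm: PMParams
    s_default: Optional[float] = None
    k_rc: float = 1.0
    provenance: str = ""

    def __post_init__(self):
        _require_positive("k_rc", self.k_rc)
        if self.s_default is not None and not (0 <= float(self.s_default) <= 1):
            raise ValueError(f"s_default must lie in [0, 1], got {self.s_default!r}")


def infer_internal_params(kds: DissociationConstants) -> InternalParams:
    """Map measured dissociation constants to the internal parameters.

    p = kd3/kd2, omega = kd2*kd3/kd23, alpha = sqrt(kd1/kd2). Scale
    invariant: a common concentration rescaling of (kd1, kd2, kd3) with
    kd23 scaled by its square leaves the result unchanged.
    """
    return InternalParams(
        p=kds.kd3 / kds.kd2,
        omega=kds.kd2 * kds.kd3 / kds.kd23,
        alpha=math.sqrt(kds.kd1 / kds.kd2),
    )


# Internal parameters from the published binding measurements for each
# system; alpha values with exact symbolic forms are stored as such,
# evaluated in double precision.
_PRESETS: dict[str, SystemPreset] = {
    "esp1396i": SystemPreset(
        name="esp1396i",
        internal=InternalParams(p=25.0, omega=130.0, alpha=16.9),
        pm=PMParams(architecture="esp1396i", phi=1.0, gamma=5.1),
        s_default=0.2,
        provenance="internal params from Esp1396I binding measurements; "
        "gamma from measured K_d2/K_dM; s from steady-state-vs-copy-number fit",
    ),
    "ahdi": SystemPreset(
        name="ahdi",
        internal=InternalParams(p=20.0, omega=3000.0, alpha=5.0 * math.sqrt(2.0)),
        pm=PMParams(architecture="ahdi", phi=0.2, alpha_m=2.0 * math.sqrt(5.0)),
        s_default=0.0043,
        provenance="internal params from AhdI binding measurements; "
        "alpha_m, phi from M-repressor constants; s from activity-curve fit",
    ),
    "ecorv": SystemPreset(
        name="ecorv",
        internal=InternalParams(p=5.0, omega=1.0, alpha=4.2),
        pm=PMParams(architecture="ecorv", phi=1.0),
        s_default=None,
        provenance="internal params from EcoRV binding measurements; "
        "leakage s not experimentally constrained",
    ),
}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def load_preset(name: str) -> SystemPreset:
    """Return the registered preset for ``name`` (case-insensitive)."""
    key = str(name).lower()
    if key not in _PRESETS:
        raise KeyError(
            f"unknown system preset {name!r}; valid names: {', '.join(_PRESETS)}"
        )
    return _PRESETS[key]


# ---------------------------------------------------------------------------
# serialization


def _preset_to_dict(preset: SystemPreset) -> dict:
    d = asdict(preset)
    # drop architecture-inapplicable Nones for a tidy file
    d["pm"] = {k: v for k, v in d["pm"].items() if v is not None}
    return d


def _preset_from_dict(d: dict) -> SystemPreset:
    return SystemPreset(
        name=d["name"],
        internal=InternalParams(**d["internal"]),
        pm=PMParams(**d["pm"]),
        s_default=d.get("s_default"),
        k_rc=d.get("k_rc", 1.0),
        provenance=d.get("provenance", ""),
    )


def save_presets(path, presets: Optional[dict[str, SystemPreset]] = None) -> None:
    """Write the preset registry as YAML (or JSON if the suffix is .json)."""
    presets = presets if presets is not None else _PRESETS
    payload = {name: _preset_to_dict(p) for name, p in presets.items()}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def load_presets_file(path) -> dict[str, SystemPreset]:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return {name: _preset_from_dict(d) for name, d in payload.items()}
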