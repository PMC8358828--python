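"""Layered tissue media, optical properties and blood-flow scenarios.

The head is represented as a laterally infinite slab of five layers —
skin, skull, cerebrospinal fluid (CSF), gray matter and white matter —
stacked along the depth axis, with the last layer semi-infinite.  Each
layer carries its absorption coefficient ``mua`` (1/cm), reduced
scattering coefficient ``musp`` (1/cm), scattering anisotropy ``g``,
refractive index ``n``, thickness (mm) and an effective Brownian
diffusion coefficient ``D`` (mm^2/s), the quantity recovered by diffuse
correlation spectroscopy as the blood flow index (BFi).

The packaged default optical properties are literature values for the
two pulsed-laser wavelengths commonly used in time-domain DCS, 765 and
1064 nm.  Skull absorption is 1.22x skin absorption; CSF scattering is
near zero but kept positive so photon transport remains well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Layer",
    "LayeredMedium",
    "FlowScenario",
    "default_head_slab",
    "two_layer_slab",
    "homogeneous_slab",
    "thicken_extracerebral",
    "make_flow_scenario",
    "load_medium",
    "dump_medium",
    "SUPERFICIAL_LAYERS",
    "BRAIN_LAYERS",
    "EXTRACEREBRAL_LAYERS",
]

#: speed of light in vacuum, mm/ps
C0_MM_PS = 0.299792458

#: layer names belonging to the dynamic superficial group (scalp)
SUPERFICIAL_LAYERS = ("skin",)
#: layer names belonging to the brain group
BRAIN_LAYERS = ("gray_matter", "white_matter", "brain")
#: layers whose thickness counts toward the extracerebral stack
EXTRACEREBRAL_LAYERS = ("skin", "skull", "csf")

#: default (musp 1/cm, mua 1/cm) per tissue and wavelength
_OPTICAL_TABLE = {
    765: {
        "skin": (9.68, 0.076),
        "skull": (9.68, 0.093),
        "csf": (0.1, 0.025),
        "white_matter": (9.68, 0.188),
        "gray_matter": (9.68, 0.188),
    },
    1064: {
        "skin": (8.37, 0.105),
        "skull": (8.37, 0.128),
        "csf": (0.09, 0.122),
        "white_matter": (8.37, 0.173),
        "gray_matter": (8.37, 0.173),
    },
}

#: baseline Brownian diffusion coefficients, mm^2/s (skull and CSF static)
_BASELINE_D = {
    "skin": 1e-6,
    "skull": 0.0,
    "csf": 0.0,
    "gray_matter": 6e-6,
    "white_matter": 6e-6,
}


@dataclass(frozen=True)
class Layer:
    """One tissue layer of the slab."""

    name: str
    mua_cm: float
    musp_cm: float
    g: float = 0.9
    n: float = 1.4
    thickness_mm: float = math.inf
    D_mm2s: float = 0.0

    def __post_init__(self) -> None:
        if self.mua_cm < 0:
            raise ValueError(f"layer {self.name!r}: mua must be >= 0")
        if self.musp_cm <= 0:
            raise ValueError(f"layer {self.name!r}: musp must be > 0")
        if not 0 <= self.g < 1:
            raise ValueError(f"layer {self.name!r}: need 0 <= g < 1")
        if self.n <= 0:
            raise ValueError(f"layer {self.name!r}: n must be > 0")
        if self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.D_mm2s < 0:
            raise ValueError(f"layer {self.name!r}: D must be >= 0")

    @property
    def mus_cm(self) -> float:
        """Scattering coefficient mus = musp/(1-g), 1/cm."""
        return self.musp_cm / (1.0 - self.g)


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered stack of layers; the last layer is semi-infinite."""

    layers: tuple[Layer, ...]
    exterior_index: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        if not math.isinf(self.layers[-1].thickness_mm):
            raise ValueError("last layer must be semi-infinite")
        for layer in self.layers[:-1]:
            if math.isinf(layer.thickness_mm):
                raise ValueError("only the last layer may be semi-infinite")
        if self.exterior_index <= 0:
            raise ValueError("exterior_index must be > 0")

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers)

    @property
    def tops_mm(self) -> np.ndarray:
        """Depth of the lower boundary of each layer (last is inf), mm."""
        tops = np.cumsum([layer.thickness_mm for layer in self.layers])
        return tops

    def mua_cm(self) -> np.ndarray:
        return np.array([layer.mua_cm for layer in self.layers])

    def musp_cm(self) -> np.ndarray:
        return np.array([layer.musp_cm for layer in self.layers])

    def g(self) -> np.ndarray:
        return np.array([layer.g for layer in self.layers])

    def n(self) -> np.ndarray:
        return np.array([layer.n for layer in self.layers])

    def D_mm2s(self) -> np.ndarray:
        return np.array([layer.D_mm2s for layer in self.layers])

    def layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def with_D(self, d_map: Mapping[str, float]) -> "LayeredMedium":
        """Copy of the medium with layer D values replaced per ``d_map``."""
        new = tuple(
            replace(layer, D_mm2s=d_map.get(layer.name, layer.D_mm2s))
            for layer in self.layers
        )
        return replace(self, layers=new)

    def extracerebral_thickness_mm(self) -> float:
        """Surface-to-cortex distance: total thickness of skin+skull+CSF."""
        return sum(
            layer.thickness_mm
            for layer in self.layers
            if layer.name in EXTRACEREBRAL_LAYERS
        )

    def to_dict(self) -> dict:
        return {
            "exterior_index": self.exterior_index,
            "layers": [
                {
                    "name": layer.name,
                    "mua_cm": layer.mua_cm,
                    "musp_cm": layer.musp_cm,
                    "g": layer.g,
                    "n": layer.n,
                    "thickness_mm": (
                        None
                        if math.isinf(layer.thickness_mm)
                        else layer.thickness_mm
                    ),
                    "D_mm2s": layer.D_mm2s,
                }
                for layer in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LayeredMedium":
        layers = tuple(
            Layer(
                name=ld["name"],
                mua_cm=float(ld["mua_cm"]),
                musp_cm=float(ld["musp_cm"]),
                g=float(ld.get("g", 0.9)),
                n=float(ld.get("n", 1.4)),
                thickness_mm=(
                    math.inf
                    if ld.get("thickness_mm") in (None, "inf")
                    else float(ld["thickness_mm"])
                ),
                D_mm2s=float(ld.get("D_mm2s", 0.0)),
            )
            for ld in d["layers"]
        )
        return cls(layers=layers, exterior_index=float(d.get("exterior_index", 1.0)))


@dataclass(frozen=True)
class FlowScenario:
    """Baseline and perturbed per-layer diffusion coefficients.

    Only the target group ("brain" or "superficial") differs between the
    two states; static layers (skull, CSF) stay at D = 0 in both.
    """

    baseline: dict[str, float]
    perturbed: dict[str, float]
    perturbed_target: str
    ratio: float

    def __post_init__(self) -> None:
        if set(self.baseline) != set(self.perturbed):
            raise ValueError("baseline and perturbed must cover the same layers")
        group = (
            BRAIN_LAYERS if self.perturbed_target == "brain" else SUPERFICIAL_LAYERS
        )
        for name, d0 in self.baseline.items():
            if name in group:
                continue
            if self.perturbed[name] != d0:
                raise ValueError(
                    f"layer {name!r} outside target group changed between states"
                )


def default_head_slab(
    wavelength_nm: int,
    *,
    skin_mm: float = 4.0,
    skull_mm: float = 7.0,
    csf_mm: float = 3.0,
    gray_mm: float = 4.0,
) -> LayeredMedium:
    """Five-layer head-analogue slab with packaged optical properties.

    The default thickness split (skin 4 / skull 7 / CSF 3 mm) gives a
    14-mm surface-to-cortex distance typical of an adult forehead; gray
    matter is 4 mm of cortex above semi-infinite white matter.  g = 0.9
    and n = 1.4 in every layer.
    """
    if wavelength_nm not in _OPTICAL_TABLE:
        raise ValueError(
            f"unsupported wavelength {wavelength_nm} nm; "
            f"choose from {sorted(_OPTICAL_TABLE)}"
        )
    table = _OPTICAL_TABLE[wavelength_nm]
    thickness = {
        "skin": skin_mm,
        "skull": skull_mm,
        "csf": csf_mm,
        "gray_matter": gray_mm,
        "white_matter": math.inf,
    }
    layers = tuple(
        Layer(
            name=name,
            musp_cm=table[name][0],
            mua_cm=table[name][1],
            g=0.9,
            n=1.4,
            thickness_mm=thickness[name],
            D_mm2s=_BASELINE_D[name],
        )
        for name in ("skin", "skull", "csf", "gray_matter", "white_matter")
    )
    return LayeredMedium(layers=layers, exterior_index=1.0)


def two_layer_slab(
    *,
    top_mm: float = 10.0,
    musp_cm: float = 9.68,
    mua_top_cm: float = 0.076,
    mua_deep_cm: float = 0.188,
    D_top: float = 1e-6,
    D_deep: float = 6e-6,
    g: float = 0.9,
    n: float = 1.4,
) -> LayeredMedium:
    """Reduced superficial-over-deep slab used for qualitative gate studies.

    A dynamic scalp-like layer of ``top_mm`` sits over a semi-infinite
    brain-like layer; optical properties default to the 765-nm skin and
    brain values.
    """
    return LayeredMedium(
        layers=(
            Layer("skin", mua_top_cm, musp_cm, g, n, top_mm, D_top),
            Layer("brain", mua_deep_cm, musp_cm, g, n, math.inf, D_deep),
        )
    )


def homogeneous_slab(
    mua_cm: float,
    musp_cm: float,
    *,
    D: float = 6e-6,
    g: float = 0.9,
    n: float = 1.4,
    name: str = "medium",
) -> LayeredMedium:
    """Semi-infinite homogeneous medium (phantom or inverse-model geometry)."""
    return LayeredMedium(
        layers=(Layer(name, mua_cm, musp_cm, g, n, math.inf, D),)
    )


def thicken_extracerebral(medium: LayeredMedium, extra_mm: float) -> LayeredMedium:
    """Grow the skin+skull stack by ``extra_mm``, split proportionally.

    Emulates a subject with a thicker extracerebral layer; all optical
    properties and dynamics are unchanged.
    """
    if extra_mm < 0:
        raise ValueError("extra_mm must be >= 0")
    if extra_mm == 0:
        return medium
    grow = [
        layer.name for layer in medium.layers if layer.name in ("skin", "skull")
    ]
    if not grow:
        raise ValueError("medium has no skin/skull layers to thicken")
    total = sum(medium.layer(name).thickness_mm for name in grow)
    new_layers = tuple(
        replace(
            layer,
            thickness_mm=layer.thickness_mm * (1.0 + extra_mm / total),
        )
        if layer.name in grow
        else layer
        for layer in medium.layers
    )
    return replace(medium, layers=new_layers)


def make_flow_scenario(
    medium: LayeredMedium, target: str, ratio: float
) -> FlowScenario:
    """Baseline/perturbed D pair with the target group scaled by ``ratio``.

    ``target`` is ``"brain"`` (deep flow change, the quantity of
    interest) or ``"superficial"`` (scalp crosstalk).  The canonical
    perturbation is ratio = 1.2, a 20% flow increase.
    """
    if target == "brain":
        group = BRAIN_LAYERS
    elif target == "superficial":
        group = SUPERFICIAL_LAYERS
    else:
        raise ValueError(f"unknown target {target!r}; use 'brain' or 'superficial'")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    baseline = {layer.name: layer.D_mm2s for layer in medium.layers}
    perturbed = {
        name: d * ratio if name in group else d for name, d in baseline.items()
    }
    return FlowScenario(
        baseline=baseline, perturbed=perturbed, perturbed_target=target, ratio=ratio
    )


def load_medium(path) -> LayeredMedium:
    """Read a medium from a YAML/JSON config file."""
    with open(path) as fh:
        return LayeredMedium.from_dict(yaml.safe_load(fh))


def dump_medium(medium: LayeredMedium, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(medium.to_dict(), fh, sort_keys=False)
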