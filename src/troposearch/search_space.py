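"""Hyperparameter search space and solution-vector decoding.

A candidate configuration is encoded as a vector of ``D`` floats in [0, 1]
(one "gorilla" position).  Each element is decoded into a concrete
hyperparameter value by :func:`map_element`: list-like domains of length L are
indexed with the 1-based rule ``idx = clamp(ceil(v * L), 1, L)`` and
continuous ranges are interpolated linearly, ``lo + v * (hi - lo)``.

The default space spans 15 hyperparameters of a transfer-learning image
classifier (loss, batch size, dropout, fine-tuning ratio, optimizer, pixel
scaling, and the data-augmentation block) and consumes 16 solution elements:
the brightness range is an ordered pair and takes two slots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import yaml

__all__ = [
    "HyperparameterSpec",
    "SearchSpace",
    "Solution",
    "HyperparameterConfig",
    "build_default_space",
    "map_element",
    "map_solution",
]

LOSS_NAMES = (
    "Categorical Crossentropy",
    "Categorical Hinge",
    "KLDivergence",
    "Poisson",
    "Squared Hinge",
    "Hinge",
)

OPTIMIZER_NAMES = (
    "Adam",
    "NAdam",
    "AdaGrad",
    "AdaDelta",
    "AdaMax",
    "RMSProp",
    "SGD",
    "Ftrl",
    "SGD Nesterov",
    "RMSProp Centered",
    "Adam AMSGrad",
)

SCALING_NAMES = ("Normalize", "Standard", "Min-Max", "Max-Abs")

_KINDS = {"categorical", "discrete-numeric", "continuous-range", "boolean", "pair-range"}
_LIST_KINDS = {"categorical", "discrete-numeric", "boolean"}


@dataclass(frozen=True)
class HyperparameterSpec:
    """One hyperparameter: a name, a domain kind, and the values it can take.

    ``domain`` is an ordered tuple of admissible values for list-like kinds
    (categorical / discrete-numeric / boolean) or a ``(lo, hi)`` bound pair for
    continuous-range and pair-range kinds.  ``slots`` is the number of solution
    elements the spec consumes: 1, or 2 for a pair-range.
    """

    name: str
    kind: str
    domain: tuple
    slots: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in _LIST_KINDS:
            if len(self.domain) == 0:
                raise ValueError(f"{self.name}: empty domain")
        else:
            lo, hi = self.domain
            if not lo <= hi:
                raise ValueError(f"{self.name}: bounds must satisfy lo <= hi")
        if self.slots not in (1, 2):
            raise ValueError(f"{self.name}: slots must be 1 or 2")
        if (self.kind == "pair-range") != (self.slots == 2):
            raise ValueError(f"{self.name}: pair-range specs (and only those) take 2 slots")

    @property
    def is_list(self) -> bool:
        return self.kind in _LIST_KINDS


@dataclass(frozen=True)
class SearchSpace:
    """An ordered collection of :class:`HyperparameterSpec` entries."""

    specs: tuple[HyperparameterSpec, ...]

    @property
    def D(self) -> int:
        """Total solution dimensionality (sum of slots)."""
        return sum(s.slots for s in self.specs)

    def __getitem__(self, name: str) -> HyperparameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for s in self.specs:
            out[s.name] = {"kind": s.kind, "domain": list(s.domain), "slots": s.slots}
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SearchSpace":
        specs = tuple(
            HyperparameterSpec(
                name=name,
                kind=entry["kind"],
                domain=tuple(entry["domain"]),
                slots=entry.get("slots", 2 if entry["kind"] == "pair-range" else 1),
            )
            for name, entry in data.items()
        )
        return cls(specs=specs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SearchSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


Solution = np.ndarray  # vector of D floats in [0, 1]


@dataclass
class HyperparameterConfig:
    """A fully decoded training configuration.

    The augmentation sub-parameters are always decoded; when
    ``apply_augmentation`` is False they are retained but marked inactive
    (``active_augmentation()`` returns None for them).
    """

    loss_name: str
    batch_size: int
    dropout: float
    tl_learn_ratio: int
    optimizer_name: str
    scaling_technique: str
    apply_augmentation: bool
    rotation_deg: int
    width_shift: float
    height_shift: float
    shear: float
    zoom: float
    horizontal_flip: bool
    vertical_flip: bool
    brightness_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.batch_size not in range(4, 49, 4):
            raise ValueError(f"batch_size {self.batch_size} not in 4..48 step 4")
        if not 0.0 <= self.dropout <= 0.6:
            raise ValueError(f"dropout {self.dropout} outside [0, 0.6]")
        if self.tl_learn_ratio not in range(1, 101):
            raise ValueError(f"tl_learn_ratio {self.tl_learn_ratio} not in 1..100")
        lo, hi = self.brightness_range
        if not (0.5 <= lo <= hi <= 2.0):
            raise ValueError(f"brightness_range {self.brightness_range} invalid")
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.loss_name!r}")
        if self.optimizer_name not in OPTIMIZER_NAMES:
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")
        if self.scaling_technique not in SCALING_NAMES:
            raise ValueError(f"unknown scaling technique {self.scaling_technique!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["brightness_range"] = list(self.brightness_range)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "HyperparameterConfig":
        d = dict(d)
        d["brightness_range"] = tuple(d["brightness_range"])
        return cls(**d)

    def active_augmentation(self) -> dict[str, Any] | None:
        """The augmentation block, or None when augmentation is switched off."""
        if not self.apply_augmentation:
            return None
        return {
            "rotation_deg": self.rotation_deg,
            "width_shift": self.width_shift,
            "height_shift": self.height_shift,
            "shear": self.shear,
            "zoom": self.zoom,
            "horizontal_flip": self.horizontal_flip,
            "vertical_flip": self.vertical_flip,
            "brightness_range": self.brightness_range,
        }


def build_default_space() -> SearchSpace:
    """The default 15-hyperparameter space (16 solution elements).

    Boolean domains follow the (Yes, No) = (True, False) listing order, so an
    element of 0 decodes to True.
    """
    specs = (
        HyperparameterSpec("loss", "categorical", LOSS_NAMES),
        HyperparameterSpec("batch_size", "discrete-numeric", tuple(range(4, 49, 4))),
        HyperparameterSpec("dropout", "continuous-range", (0.0, 0.6)),
        HyperparameterSpec("tl_learn_ratio", "discrete-numeric", tuple(range(1, 101))),
        HyperparameterSpec("optimizer", "categorical", OPTIMIZER_NAMES),
        HyperparameterSpec("scaling", "categorical", SCALING_NAMES),
        HyperparameterSpec("apply_augmentation", "boolean", (True, False)),
        HyperparameterSpec("rotation", "discrete-numeric", tuple(range(0, 46))),
        HyperparameterSpec("width_shift", "continuous-range", (0.0, 0.25)),
        HyperparameterSpec("height_shift", "continuous-range", (0.0, 0.25)),
        HyperparameterSpec("shear", "continuous-range", (0.0, 0.25)),
        HyperparameterSpec("zoom", "continuous-range", (0.0, 0.25)),
        HyperparameterSpec("horizontal_flip", "boolean", (True, False)),
        HyperparameterSpec("vertical_flip", "boolean", (True, False)),
        HyperparameterSpec("brightness", "pair-range", (0.5, 2.0), slots=2),
    )
    space = SearchSpace(specs=specs)
    assert space.D == 16
    return space


def map_element(value: float, spec: HyperparameterSpec):
    """Decode a single solution element against one hyperparameter spec.

    List-like domains of length L use the 1-based index
    ``clamp(ceil(value * L), 1, L)``; continuous bounds interpolate linearly.
    ``value`` must lie in [0, 1].
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"solution element {value} outside [0, 1]")
    if spec.is_list:
        L = len(spec.domain)
        idx = min(max(math.ceil(value * L), 1), L)
        return spec.domain[idx - 1]
    lo, hi = spec.domain
    return lo + value * (hi - lo)


def map_solution(solution: Sequence[float], space: SearchSpace) -> HyperparameterConfig:
    """Decode a full solution vector into a :class:`HyperparameterConfig`.

    Elements are consumed in spec order; a pair-range spec consumes two
    elements, each interpolated over its bounds, returned sorted ascending.
    """
    values = np.asarray(solution, dtype=float).ravel()
    if values.size != space.D:
        raise ValueError(f"solution has {values.size} elements, space expects {space.D}")
    decoded: dict[str, Any] = {}
    pos = 0
    for spec in space.specs:
        if spec.kind == "pair-range":
            pair = sorted(map_element(values[pos + k], spec) for k in range(2))
            decoded[spec.name] = (float(pair[0]), float(pair[1]))
        else:
            decoded[spec.name] = map_element(float(values[pos]), spec)
        pos += spec.slots
    return HyperparameterConfig(
        loss_name=decoded["loss"],
        batch_size=int(decoded["batch_size"]),
        dropout=float(decoded["dropout"]),
        tl_learn_ratio=int(decoded["tl_learn_ratio"]),
        optimizer_name=decoded["optimizer"],
        scaling_technique=decoded["scaling"],
        apply_augmentation=bool(decoded["apply_augmentation"]),
        rotation_deg=int(decoded["rotation"]),
        width_shift=float(decoded["width_shift"]),
        height_shift=float(decoded["height_shift"]),
        shear=float(decoded["shear"]),
        zoom=float(decoded["zoom"]),
        horizontal_flip=bool(decoded["horizontal_flip"]),
        vertical_flip=bool(decoded["vertical_flip"]),
        brightness_range=decoded["brightness"],
    )
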