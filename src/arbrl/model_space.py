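"""The factorial hypothesis space of arbitration model variants.

Three factors are fully crossed:

* goal-driven MF controller: ``1MF`` / ``3Q`` / ``3MF``  (3 levels)
* complexity effect on the MB<->MF transition rates: Null, or
  {Interaction1, Interaction2} x {excitatory, inhibitory} x
  {bidirectional, MB->MF, MF->MB}  (1 + 2*2*3 = 13 levels)
* complexity effect on exploration (softmax temperature): null /
  explorative / exploitative  (3 levels)

giving 3 x 13 x 3 = 117 variants.  The baseline ``1MF_null_noexp``
(alias ``lee2014``) is the original uncertainty-only arbitration scheme;
``3Q_int2_exc_mf2mb_explore`` (alias ``best``) is the variant that best
accounted for behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .arbitration import DIRECTIONS, EXPLORATION_EFFECTS, SIGNS, TRANSITION_VARIANTS
from .config import ConfigError, TaskConfig
from .learners import MF_TYPES
from .task_env import StateSpaceModel, build_state_space

_INTERACTION_TAG = {"Interaction1": "int1", "Interaction2": "int2"}
_SIGN_TAG = {"excitatory": "exc", "inhibitory": "inh"}
_DIRECTION_TAG = {"bidirectional": "bi", "mb2mf": "mb2mf", "mf2mb": "mf2mb"}
_EXPLORATION_TAG = {"null": "noexp", "explorative": "explore", "exploitative": "exploit"}

_UNTAG = {
    **{v: ("interaction", k) for k, v in _INTERACTION_TAG.items()},
    **{v: ("sign", k) for k, v in _SIGN_TAG.items()},
    **{v: ("direction", k) for k, v in _DIRECTION_TAG.items()},
}

#: default fitting bounds (not printed in the source study; config-overridable)
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "eta": (1e-3, 1.0 - 1e-3),
    "A": (1e-3, 1.0),
    "B": (1e-2, 100.0),
    "c": (-10.0, 10.0),
    "tau_base": (1e-2, 10.0),
}

ALIASES = {
    "lee2014": "1MF_null_noexp",
    "best": "3Q_int2_exc_mf2mb_explore",
}


@dataclass(frozen=True)
class ModelVariantSpec:
    """One point of the 3 x 13 x 3 hypothesis space."""

    mf_type: str                 # 1MF | 3Q | 3MF
    interaction: str             # Null | Interaction1 | Interaction2
    sign: str | None             # excitatory | inhibitory (None iff Null)
    direction: str | None        # bidirectional | mb2mf | mf2mb (None iff Null)
    exploration: str             # null | explorative | exploitative

    def __post_init__(self) -> None:
        if self.mf_type not in MF_TYPES:
            raise ConfigError(f"unknown mf_type {self.mf_type!r}")
        if self.interaction not in TRANSITION_VARIANTS:
            raise ConfigError(f"unknown interaction {self.interaction!r}")
        if self.exploration not in EXPLORATION_EFFECTS:
            raise ConfigError(f"unknown exploration effect {self.exploration!r}")
        if self.interaction == "Null":
            if self.sign is not None or self.direction is not None:
                raise ConfigError("Null transition modulation carries no sign/direction")
        else:
            if self.sign not in SIGNS or self.direction not in DIRECTIONS:
                raise ConfigError("modulated variants need a sign and a direction")

    # -- string ids --------------------------------------------------------
    @property
    def variant_id(self) -> str:
        if self.interaction == "Null":
            trans = "null"
        else:
            trans = "_".join(
                (_INTERACTION_TAG[self.interaction], _SIGN_TAG[self.sign],
                 _DIRECTION_TAG[self.direction])
            )
        return f"{self.mf_type}_{trans}_{_EXPLORATION_TAG[self.exploration]}"

    @classmethod
    def from_id(cls, variant_id: str) -> "ModelVariantSpec":
        variant_id = ALIASES.get(variant_id.lower(), variant_id)
        parts = variant_id.split("_")
        if len(parts) not in (3, 5):
            raise ConfigError(f"malformed variant id {variant_id!r}")
        mf = parts[0]
        exp_tag = parts[-1]
        exploration = {v: k for k, v in _EXPLORATION_TAG.items()}.get(exp_tag)
        if exploration is None:
            raise ConfigError(f"unknown exploration tag {exp_tag!r}")
        if len(parts) == 3:
            if parts[1] != "null":
                raise ConfigError(f"malformed variant id {variant_id!r}")
            return cls(mf, "Null", None, None, exploration)
        fields = {}
        for tag in parts[1:4]:
            if tag not in _UNTAG:
                raise ConfigError(f"unknown variant tag {tag!r}")
            key, val = _UNTAG[tag]
            fields[key] = val
        return cls(mf, fields["interaction"], fields["sign"], fields["direction"],
                   exploration)

    # -- free parameters ---------------------------------------------------
    @property
    def mf_param_names(self) -> tuple[str, ...]:
        if self.mf_type == "3MF":
            return ("eta_mf_red", "eta_mf_blue", "eta_mf_silver")
        return ("eta_mf",)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["eta_mb", *self.mf_param_names, "A_mf2mb", "A_mb2mf", "B"]
        if self.interaction == "Interaction1":
            names.append("c")
        names.append("tau_base")
        return tuple(names)

    def param_bounds(
        self, bounds: Mapping[str, tuple[float, float]] | None = None
    ) -> tuple[tuple[float, float], ...]:
        b = dict(DEFAULT_BOUNDS)
        if bounds:
            b.update(bounds)
        out = []
        for name in self.param_names:
            if name.startswith("eta"):
                out.append(b["eta"])
            elif name.startswith("A_"):
                out.append(b["A"])
            elif name == "B":
                out.append(b["B"])
            elif name == "c":
                out.append(b["c"])
            else:
                out.append(b["tau_base"])
        return tuple(out)

    def params_to_dict(self, values: Sequence[float]) -> dict[str, float]:
        names = self.param_names
        if len(values) != len(names):
            raise ConfigError(
                f"{self.variant_id} expects {len(names)} parameters, got {len(values)}"
            )
        return dict(zip(names, map(float, values)))


def transition_modulation_levels() -> list[tuple[str, str | None, str | None]]:
    """The 13 levels of the transition-modulation factor, in canonical order."""
    levels: list[tuple[str, str | None, str | None]] = [("Null", None, None)]
    for inter in ("Interaction1", "Interaction2"):
        for sign in SIGNS:
            for direction in DIRECTIONS:
                levels.append((inter, sign, direction))
    return levels


def enumerate_variants() -> list[ModelVariantSpec]:
    """All 117 variants in a stable lexicographic order over
    (mf_type, interaction, sign, direction, exploration)."""
    out = []
    for mf in MF_TYPES:
        for inter, sign, direction in transition_modulation_levels():
            for exp in EXPLORATION_EFFECTS:
                out.append(ModelVariantSpec(mf, inter, sign, direction, exp))
    return out


def variant_param_spec(spec: ModelVariantSpec) -> dict[str, tuple[float, float]]:
    """Ordered free-parameter names with their default fitting bounds."""
    return dict(zip(spec.param_names, spec.param_bounds()))


def instantiate(
    spec: ModelVariantSpec | str,
    params: Mapping[str, float] | Sequence[float],
    model: StateSpaceModel | None = None,
    config: TaskConfig | None = None,
    **agent_options,
):
    """Wire learners + arbitrator into a runnable :class:`ArbitrationAgent`.

    ``params`` may be a name->value mapping or a sequence in
    ``spec.param_names`` order; values are validated against the bounds'
    signs (rates positive, learning rates in [0, 1]).
    """
    from .agent import ArbitrationAgent  # local import to avoid a cycle

    if isinstance(spec, str):
        spec = ModelVariantSpec.from_id(spec)
    if model is None:
        model = build_state_space(config)
    if not isinstance(params, Mapping):
        params = spec.params_to_dict(list(params))
    else:
        missing = set(spec.param_names) - set(params)
        extra = set(params) - set(spec.param_names)
        if missing or extra:
            raise ConfigError(
                f"parameter mismatch for {spec.variant_id}: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
    return ArbitrationAgent(model=model, spec=spec, params=dict(params), **agent_options)
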