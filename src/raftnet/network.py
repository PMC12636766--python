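"""Declarative PPI network specs, the contact-reaction engine, and the
diagrammatic sign-product predictor.

A network is a set of component types (each with a disk radius, a copy
count, and per-state domain preferences) plus contact reactions: when an
*actor* inclusion touches a *substrate* inclusion in the matching state,
the substrate switches to a product state with some probability per sweep.
Reaction rates ignore the surrounding lipid configuration, so reactions
are genuinely non-equilibrium; when the product state carries a different
domain preference (partition switching, palmitoylation-like) the boundary
spins change instantly and the configurational ensemble itself leaves the
Boltzmann distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .inclusions import ComponentType, detect_contacts

__all__ = [
    "ReactionRule",
    "NetworkSpec",
    "NetworkValidationError",
    "ReactionEvent",
    "load_network",
    "save_network",
    "bundled_network",
    "apply_reactions",
    "sign_predict",
    "INDETERMINATE",
]

#: Returned by :func:`sign_predict` when pathway sign products disagree.
INDETERMINATE = 0


class NetworkValidationError(ValueError):
    """A network spec violates the schema; the message carries field paths."""


@dataclass
class ReactionRule:
    """``actor + substrate -> actor + substrate'`` contact reaction.

    ``activity_sign`` is +1 if firing pushes the tracked target toward
    its active state, -1 if away from it (the sign written above the
    pathway arrow in the cascade diagram).  The actor never changes
    state by firing.
    """

    actor: tuple[str, str]
    substrate: tuple[str, str]
    product_state: str
    rate: float = 1.0
    activity_sign: int = +1

    def __post_init__(self) -> None:
        self.actor = tuple(self.actor)
        self.substrate = tuple(self.substrate)
        if not 0.0 <= self.rate <= 1.0:
            raise NetworkValidationError(
                f"rule {self.actor}->{self.product_state}: rate must be in "
                f"[0, 1], got {self.rate}"
            )
        if self.activity_sign not in (+1, -1):
            raise NetworkValidationError(
                f"rule {self.actor}: activity_sign must be +1 or -1"
            )


@dataclass
class NetworkSpec:
    components: list[ComponentType]
    rules: list[ReactionRule] = field(default_factory=list)
    target: str = ""
    target_active_state: str = "active"

    def __post_init__(self) -> None:
        self.validate()

    def component(self, name: str) -> ComponentType:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"no component named {name!r}")

    def validate(self) -> None:
        if not self.components:
            raise NetworkValidationError("components: list must be non-empty")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise NetworkValidationError("components: duplicate names")
        byname = {c.name: c for c in self.components}
        for i, rule in enumerate(self.rules):
            for role, (cname, cstate) in (
                ("actor", rule.actor),
                ("substrate", rule.substrate),
            ):
                if cname not in byname:
                    raise NetworkValidationError(
                        f"rules[{i}].{role}: unknown component {cname!r}"
                    )
                if cstate not in byname[cname].states:
                    raise NetworkValidationError(
                        f"rules[{i}].{role}: component {cname!r} has no "
                        f"state {cstate!r}"
                    )
            sub = byname[rule.substrate[0]]
            if rule.product_state not in sub.states:
                raise NetworkValidationError(
                    f"rules[{i}].product_state: component {sub.name!r} has "
                    f"no state {rule.product_state!r}"
                )
        if self.target:
            if self.target not in byname:
                raise NetworkValidationError(
                    f"target: unknown component {self.target!r}"
                )
            if self.target_active_state not in byname[self.target].states:
                raise NetworkValidationError(
                    f"target_active_state: {self.target!r} has no state "
                    f"{self.target_active_state!r}"
                )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "target_active_state": self.target_active_state,
            "components": [
                {
                    "name": c.name,
                    "radius": c.radius,
                    "count": c.count,
                    "mobility": c.mobility,
                    "states": list(c.states),
                    "boundary_pref": dict(c.boundary_pref),
                }
                for c in self.components
            ],
            "rules": [
                {
                    "actor": list(r.actor),
                    "substrate": list(r.substrate),
                    "product_state": r.product_state,
                    "rate": r.rate,
                    "activity_sign": r.activity_sign,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        try:
            comps = [
                ComponentType(
                    name=c["name"],
                    radius=int(c.get("radius", 0)),
                    states=tuple(c.get("states", ("active",))),
                    boundary_pref={
                        str(k): int(v) for k, v in c["boundary_pref"].items()
                    },
                    count=int(c.get("count", 1)),
                    mobility=float(c.get("mobility", 0.1)),
                )
                for c in d.get("components", [])
            ]
            rules = [
                ReactionRule(
                    actor=tuple(r["actor"]),
                    substrate=tuple(r["substrate"]),
                    product_state=str(r["product_state"]),
                    rate=float(r.get("rate", 1.0)),
                    activity_sign=int(r.get("activity_sign", +1)),
                )
                for r in d.get("rules", [])
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise NetworkValidationError(f"malformed network spec: {exc}") from exc
        return cls(
            components=comps,
            rules=rules,
            target=str(d.get("target", "")),
            target_active_state=str(d.get("target_active_state", "active")),
        )

    def with_radius(self, radius: int) -> "NetworkSpec":
        """A copy of this network with every component's radius replaced."""
        comps = [replace(c, radius=radius) for c in self.components]
        return NetworkSpec(
            components=comps,
            rules=list(self.rules),
            target=self.target,
            target_active_state=self.target_active_state,
        )


def load_network(path: str | Path) -> NetworkSpec:
    """Load and validate a network spec from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise NetworkValidationError(f"{path}: top level must be a mapping")
    return NetworkSpec.from_dict(doc)


def save_network(spec: NetworkSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def bundled_network(name: str) -> NetworkSpec:
    """Load a network bundled with the package (``"fig1"`` or ``"fig5"``)."""
    fname = name if name.endswith(".yaml") else f"{name}_network.yaml"
    ref = resources.files("raftnet.data").joinpath(fname)
    doc = yaml.safe_load(ref.read_text())
    return NetworkSpec.from_dict(doc)


@dataclass
class ReactionEvent:
    sweep: int
    rule_index: int
    actor_id: int
    substrate_id: int


def sign_predict(network: NetworkSpec) -> int:
    """Diagrammatic prediction of d(activity)/d(tau) sign.

    For every rule, multiply the *contact sign* (+1 if the actor and the
    substrate's pre-reaction state partition into different domains, so
    their contact rate rises with tau; -1 if they share a domain) by the
    rule's ``activity_sign``.  If all rules agree, that common product is
    the predicted sign of the slope of target activity with respect to
    tau; otherwise :data:`INDETERMINATE` (0) is returned.
    """
    if not network.rules:
        return INDETERMINATE
    products = []
    for i, rule in enumerate(network.rules):
        actor = network.component(rule.actor[0])
        sub = network.component(rule.substrate[0])
        try:
            b_actor = actor.boundary_pref[rule.actor[1]]
            b_sub = sub.boundary_pref[rule.substrate[1]]
        except KeyError as exc:
            raise NetworkValidationError(
                f"rules[{i}]: state {exc} has no boundary preference"
            ) from exc
        contact_sign = +1 if b_actor != b_sub else -1
        products.append(contact_sign * rule.activity_sign)
    first = products[0]
    return first if all(p == first for p in products) else INDETERMINATE


def apply_reactions(
    state, network: NetworkSpec, rng: np.random.Generator, sweep: int = 0
) -> list[ReactionEvent]:
    """One reaction pass over the current contact configuration, in place.

    Every contacting inclusion pair is checked against every rule in both
    actor/substrate orientations; eligible events fire in randomized order
    with probability ``rule.rate``.  A substrate modified in this pass is
    not modified again in the same pass.  Firing changes only the
    substrate's state label and, when the new state has a different
    boundary preference, rewrites its boundary spins immediately -- the
    detailed-balance-violating step.

    This is the reference implementation mirroring the compiled engine
    used by the scheduler.
    """
    contacts = detect_contacts(state)
    incs = state.inclusions
    events: list[tuple[int, int, int]] = []
    for (i, j) in contacts:
        for r, rule in enumerate(network.rules):
            for a, s in ((i, j), (j, i)):
                if (
                    incs[a].type.name == rule.actor[0]
                    and incs[s].type.name == rule.substrate[0]
                ):
                    events.append((a, s, r))
    order = rng.permutation(len(events)) if events else []
    modified: set[int] = set()
    fired: list[ReactionEvent] = []
    for idx in order:
        a, s, r = events[int(idx)]
        rule = network.rules[r]
        if s in modified:
            continue
        if incs[a].state != rule.actor[1] or incs[s].state != rule.substrate[1]:
            continue
        if rng.random() >= rule.rate:
            continue
        sub = incs[s]
        sub.state = rule.product_state
        modified.add(s)
        off, bnd = sub.type.footprint
        sites = (np.asarray(sub.center) + off[bnd]) % state.L
        state.sval[sites[:, 0], sites[:, 1]] = sub.boundary_pref
        fired.append(
            ReactionEvent(sweep=sweep, rule_index=r, actor_id=a, substrate_id=s)
        )
    return fired
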