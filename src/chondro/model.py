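"""Core data model for two-layer (signaling + gene-regulatory) networks.

A network component is a biological entity that may exist in a *fast* layer
(protein activation) and/or a *slow* layer (gene expression).  Interactions
are signed, layer-tagged influences; update rules combine the upstream
influences of one component in one layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "LAYERS",
    "ROLES",
    "COMBINERS",
    "ComponentSpec",
    "InteractionSpec",
    "UpdateRuleSpec",
    "LayeredNetwork",
    "NetworkValidationError",
]

LAYERS = ("fast", "slow")
ROLES = (
    "growth_factor",
    "receptor",
    "kinase",
    "transcription_factor",
    "ecm_protein",
    "other_signaling",
    "gene_only",
)
COMBINERS = ("additive", "product")

DEFAULT_SATURATION = 1.0


class NetworkValidationError(ValueError):
    """Raised when a network definition violates a structural invariant."""


@dataclass(frozen=True)
class ComponentSpec:
    """A biological component (one variable of the model).

    Parameters
    ----------
    id : str
        Unique symbolic name (conventionally upper case, e.g. ``"SOX9"``).
    role : str
        One of :data:`ROLES`.
    has_fast_layer, has_slow_layer : bool
        Whether the component carries a protein-activation (fast) and/or a
        gene-expression (slow) sub-variable.  At least one must be true.
    annotation : str
        Free-text note (e.g. gene correspondence).
    """

    id: str
    role: str = "other_signaling"
    has_fast_layer: bool = True
    has_slow_layer: bool = True
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("component id must be non-empty")
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"unknown role {self.role!r} for component {self.id!r}"
            )
        if not (self.has_fast_layer or self.has_slow_layer):
            raise NetworkValidationError(
                f"component {self.id!r} must participate in at least one layer"
            )

    def participates(self, layer: str) -> bool:
        return self.has_fast_layer if layer == "fast" else self.has_slow_layer


@dataclass(frozen=True)
class InteractionSpec:
    """A signed, layer-tagged influence from ``source`` onto ``target``."""

    source: str
    target: str
    sign: int
    layer: str
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise NetworkValidationError(
                f"interaction {self.source}->{self.target}: sign must be +1/-1"
            )
        if self.layer not in LAYERS:
            raise NetworkValidationError(
                f"interaction {self.source}->{self.target}: layer must be fast/slow"
            )
        if self.provenance not in ("curated", "inferred"):
            raise NetworkValidationError(
                f"interaction {self.source}->{self.target}: "
                f"unknown provenance {self.provenance!r}"
            )


@dataclass(frozen=True)
class UpdateRuleSpec:
    """Update rule for one (component, layer).

    ``terms`` is an ordered tuple of ``(source_id, sign)`` pairs.  An empty
    term list marks the component as an *input* in that layer: it holds its
    current value unless clamped.
    """

    target: str
    layer: str
    terms: tuple = ()
    combiner: str = "additive"
    saturation: float = DEFAULT_SATURATION

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise NetworkValidationError(f"rule for {self.target!r}: bad layer")
        if self.combiner not in COMBINERS:
            raise NetworkValidationError(
                f"rule for {self.target!r}: unknown combiner {self.combiner!r}"
            )
        if not self.saturation > 0:
            raise NetworkValidationError(
                f"rule for {self.target!r}: saturation must be positive"
            )
        object.__setattr__(self, "terms", tuple((str(s), int(g)) for s, g in self.terms))
        for src, sign in self.terms:
            if sign not in (+1, -1):
                raise NetworkValidationError(
                    f"rule for {self.target!r}: term sign must be +1/-1"
                )

    @property
    def is_input(self) -> bool:
        return len(self.terms) == 0

    def activators(self) -> list:
        return [s for s, g in self.terms if g > 0]

    def inhibitors(self) -> list:
        return [s for s, g in self.terms if g < 0]


@dataclass(eq=False)
class LayeredNetwork:
    """A validated two-layer regulatory network.

    Equality compares the component set, the interaction *multiset* and the
    rule table, so serialization round trips that reorder records still
    compare equal.
    """

    components: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    rules: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        ids = [c.id for c in self.components]
        dupes = [i for i, n in Counter(ids).items() if n > 1]
        if dupes:
            raise NetworkValidationError(f"duplicate component ids: {dupes}")
        known = set(ids)
        comp_lookup = {c.id: c for c in self.components}
        for inter in self.interactions:
            for end in (inter.source, inter.target):
                if end not in known:
                    raise NetworkValidationError(
                        f"interaction references unknown component {end!r}"
                    )
            if not comp_lookup[inter.target].participates(inter.layer):
                raise NetworkValidationError(
                    f"interaction {inter.source}->{inter.target} targets layer "
                    f"{inter.layer!r} but the component does not participate in it"
                )
        seen_rules = set()
        comp_by_id = {c.id: c for c in self.components}
        for rule in self.rules:
            key = (rule.target, rule.layer)
            if key in seen_rules:
                raise NetworkValidationError(
                    f"duplicate rule for component {rule.target!r} "
                    f"in layer {rule.layer!r}"
                )
            seen_rules.add(key)
            comp = comp_by_id.get(rule.target)
            if comp is None:
                raise NetworkValidationError(
                    f"rule targets unknown component {rule.target!r}"
                )
            if not comp.participates(rule.layer):
                raise NetworkValidationError(
                    f"rule for {rule.target!r} in layer {rule.layer!r} but the "
                    "component does not participate in that layer"
                )
            for src, _ in rule.terms:
                if src not in known:
                    raise NetworkValidationError(
                        f"rule for {rule.target!r} references unknown source {src!r}"
                    )
        for comp in self.components:
            for layer in LAYERS:
                if comp.participates(layer) and (comp.id, layer) not in seen_rules:
                    raise NetworkValidationError(
                        f"missing rule for component {comp.id!r} in layer {layer!r}"
                    )

    # -- lookups -----------------------------------------------------------

    @property
    def component_ids(self) -> list:
        return [c.id for c in self.components]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def component(self, cid: str) -> ComponentSpec:
        for c in self.components:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def rule(self, cid: str, layer: str) -> UpdateRuleSpec:
        for r in self.rules:
            if r.target == cid and r.layer == layer:
                return r
        raise KeyError((cid, layer))

    def has_component(self, cid: str) -> bool:
        return any(c.id == cid for c in self.components)

    # -- equality ----------------------------------------------------------

    def _signature(self):
        return (
            frozenset(self.components),
            Counter(self.interactions),
            {(r.target, r.layer): (r.terms, r.combiner, r.saturation) for r in self.rules},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LayeredNetwork):
            return NotImplemented
        return self._signature() == other._signature()

    def __repr__(self) -> str:
        return (
            f"<LayeredNetwork {self.metadata.get('name', '?')}: "
            f"{self.n_components} components, {self.n_interactions} interactions>"
        )

    def with_metadata(self, **kv) -> "LayeredNetwork":
        md = dict(self.metadata)
        md.update(kv)
        return LayeredNetwork(
            components=list(self.components),
            interactions=list(self.interactions),
            rules=list(self.rules),
            metadata=md,
        )


def synthesize_rules(
    components: Sequence[ComponentSpec],
    interactions: Sequence[InteractionSpec],
    combiner_overrides: Optional[Mapping] = None,
    saturation_overrides: Optional[Mapping] = None,
    saturation_default: float = DEFAULT_SATURATION,
) -> list:
    """Build one rule per (component, participating layer) from edge rows.

    Terms follow interaction row order.  ``combiner_overrides`` and
    ``saturation_overrides`` map ``(component_id, layer)`` to a combiner name
    or saturation constant respectively.
    """
    combiner_overrides = dict(combiner_overrides or {})
    saturation_overrides = dict(saturation_overrides or {})
    incoming: dict = {}
    for inter in interactions:
        incoming.setdefault((inter.target, inter.layer), []).append(
            (inter.source, inter.sign)
        )
    rules = []
    for comp in components:
        for layer in LAYERS:
            if not comp.participates(layer):
                continue
            key = (comp.id, layer)
            rules.append(
                UpdateRuleSpec(
                    target=comp.id,
                    layer=layer,
                    terms=tuple(incoming.get(key, ())),
                    combiner=combiner_overrides.get(key, "additive"),
                    saturation=float(saturation_overrides.get(key, saturation_default)),
                )
            )
    return rules
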