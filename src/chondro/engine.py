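"""Semi-quantitative dynamics with two priority classes.

Every component carries up to two sub-variables in ``[0, 1]``: a *fast*
protein-activation level and a *slow* gene-expression level.  The value a
component exposes to its consumers (its *global activity*) is the product of
the two; a layer a component does not participate in contributes the neutral
value 1.

Updates are asynchronous and stochastic.  Fast sub-variables are relaxed in
random order until a whole pass changes none of them beyond the tolerance;
then a single randomly chosen slow sub-variable is updated.  The cycle
repeats until re-evaluating every rule moves no sub-variable beyond the
tolerance (a stable state), or the step caps are hit.  One *step* is one
sub-variable update event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .model import LayeredNetwork, UpdateRuleSpec

__all__ = [
    "EngineConfig",
    "SystemState",
    "SimulationTrace",
    "Engine",
    "evaluate_rule",
    "global_activity",
    "simulate",
    "is_stable",
]


@dataclass(frozen=True)
class EngineConfig:
    """Simulation parameters.

    ``max_total_steps`` caps the number of sub-variable update events per
    simulation; ``max_fast_passes`` caps the number of whole-layer passes in
    one fast relaxation.  ``stability_scope`` selects whether the stability
    tolerance applies per sub-variable (default) or per global activity.
    """

    tolerance: float = 1e-2
    max_fast_passes: int = 1000
    max_total_steps: int = 100_000
    seed: Optional[int] = None
    stability_scope: str = "subvariable"

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.max_fast_passes <= 0 or self.max_total_steps <= 0:
            raise ValueError("step caps must be positive")
        if self.stability_scope not in ("subvariable", "global"):
            raise ValueError("stability_scope must be 'subvariable' or 'global'")


@dataclass
class SystemState:
    """Fast/slow sub-variable vectors indexed by component id."""

    ids: tuple
    fast: np.ndarray
    slow: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.fast = np.asarray(self.fast, dtype=float).copy()
        self.slow = np.asarray(self.slow, dtype=float).copy()
        if self.fast.shape != (len(self.ids),) or self.slow.shape != (len(self.ids),):
            raise ValueError("state vectors must match the component list")
        for name, vec in (("fast", self.fast), ("slow", self.slow)):
            if not np.all((vec >= 0) & (vec <= 1)):
                raise ValueError(f"{name} sub-variables must lie in [0, 1]")

    # -- constructors ------------------------------------------------------

    @classmethod
    def neutral(cls, net: LayeredNetwork) -> "SystemState":
        n = net.n_components
        return cls(tuple(net.component_ids), np.ones(n), np.ones(n))

    @classmethod
    def from_dicts(
        cls,
        net: LayeredNetwork,
        fast: Optional[Mapping] = None,
        slow: Optional[Mapping] = None,
    ) -> "SystemState":
        state = cls.neutral(net)
        index = {cid: i for i, cid in enumerate(state.ids)}
        for mapping, vec in ((fast or {}, state.fast), (slow or {}, state.slow)):
            for cid, level in mapping.items():
                vec[index[cid]] = float(level)
        return state

    @classmethod
    def uniform_random(cls, net: LayeredNetwork, rng: np.random.Generator) -> "SystemState":
        state = cls.neutral(net)
        for i, comp in enumerate(net.components):
            if comp.has_fast_layer:
                state.fast[i] = rng.uniform()
            if comp.has_slow_layer:
                state.slow[i] = rng.uniform()
        return state

    # -- accessors ---------------------------------------------------------

    def index(self, cid: str) -> int:
        try:
            return self.ids.index(cid)
        except ValueError:
            raise KeyError(cid) from None

    def global_activity(self, cid: str) -> float:
        i = self.index(cid)
        return float(self.fast[i] * self.slow[i])

    def global_vector(self) -> np.ndarray:
        return self.fast * self.slow

    def copy(self) -> "SystemState":
        return SystemState(self.ids, self.fast, self.slow)

    def as_dict(self) -> dict:
        return {
            cid: {
                "fast": float(self.fast[i]),
                "slow": float(self.slow[i]),
                "global": float(self.fast[i] * self.slow[i]),
            }
            for i, cid in enumerate(self.ids)
        }


@dataclass
class SimulationTrace:
    final: SystemState
    converged: bool
    steps_used: int
    history: Optional[list] = None


def global_activity(state: SystemState, component: str) -> float:
    """Product of a component's gene-expression and protein-activation levels."""
    return state.global_activity(component)


def evaluate_rule(rule: UpdateRuleSpec, state: SystemState) -> float:
    """Evaluate one update rule against the sources' global activities.

    The additive combiner returns
    ``clamp((sum of activators - sum of inhibitors) / saturation)``; the
    product combiner returns ``clamp(prod(activators) * prod(1 - inhibitors))``.
    An empty rule returns the component's current level in the rule's layer.
    """
    cur = state.fast if rule.layer == "fast" else state.slow
    if rule.is_input:
        return float(cur[state.index(rule.target)])
    acts = [state.global_activity(s) for s in rule.activators()]
    inhs = [state.global_activity(s) for s in rule.inhibitors()]
    if rule.combiner == "additive":
        raw = (sum(acts) - sum(inhs)) / rule.saturation
    else:
        raw = float(np.prod(acts)) * float(np.prod([1.0 - v for v in inhs]))
    if not np.isfinite(raw):
        raise ValueError(f"rule for {rule.target!r}/{rule.layer} produced a non-finite value")
    return min(1.0, max(0.0, float(raw)))


class _CompiledRule:
    __slots__ = ("comp", "act", "inh", "additive", "saturation")

    def __init__(self, comp: int, act, inh, additive: bool, saturation: float):
        self.comp = comp
        self.act = np.asarray(act, dtype=np.intp)
        self.inh = np.asarray(inh, dtype=np.intp)
        self.additive = additive
        self.saturation = saturation

    def evaluate(self, g: np.ndarray) -> float:
        if self.additive:
            raw = (g[self.act].sum() - g[self.inh].sum()) / self.saturation
        else:
            raw = float(np.prod(g[self.act])) * float(np.prod(1.0 - g[self.inh]))
        if raw <= 0.0:
            return 0.0
        if raw >= 1.0:
            return 1.0
        return float(raw)


class Engine:
    """Compiled simulator for one network under one configuration."""

    def __init__(self, net: LayeredNetwork, config: Optional[EngineConfig] = None):
        self.net = net
        self.config = config or EngineConfig()
        self.ids = tuple(net.component_ids)
        self._index = {cid: i for i, cid in enumerate(self.ids)}
        self._rules = {"fast": [], "slow": []}
        for rule in net.rules:
            if rule.is_input:
                continue
            self._rules[rule.layer].append(
                _CompiledRule(
                    comp=self._index[rule.target],
                    act=[self._index[s] for s in rule.activators()],
                    inh=[self._index[s] for s in rule.inhibitors()],
                    additive=rule.combiner == "additive",
                    saturation=rule.saturation,
                )
            )

    # -- clamps ------------------------------------------------------------

    def _clamp_array(self, clamps: Optional[Mapping]) -> np.ndarray:
        levels = np.full(len(self.ids), np.nan)
        for cid, level in (clamps or {}).items():
            if cid not in self._index:
                raise KeyError(f"clamp targets unknown component {cid!r}")
            level = float(level)
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"clamp level for {cid!r} must lie in [0, 1]")
            levels[self._index[cid]] = level
        return levels

    def apply_clamps(self, state: SystemState, clamps: Mapping) -> SystemState:
        """Return a copy of ``state`` with clamped components frozen at their level.

        The sub-variables are set so that the component's global activity
        equals the clamp level: the level is written to the fast layer when
        the component has one (with the slow layer at 1), otherwise to the
        slow layer.
        """
        out = state.copy()
        for cid, level in clamps.items():
            i = self._index[cid]
            comp = self.net.components[i]
            if comp.has_fast_layer:
                out.fast[i] = float(level)
                if comp.has_slow_layer:
                    out.slow[i] = 1.0
            else:
                out.slow[i] = float(level)
        return out

    # -- dynamics ----------------------------------------------------------

    def _relax_fast(self, fast, slow, g, free_mask, rng, budget, history, step0):
        """Asynchronous fast-layer passes until pseudo-stability or caps."""
        tol = self.config.tolerance
        rules = [r for r in self._rules["fast"] if free_mask[r.comp]]
        steps = 0
        if not rules:
            return steps
        order = np.arange(len(rules))
        for _ in range(self.config.max_fast_passes):
            rng.shuffle(order)
            max_delta = 0.0
            for k in order:
                if steps >= budget:
                    return steps
                rule = rules[k]
                new = rule.evaluate(g)
                delta = abs(new - fast[rule.comp])
                fast[rule.comp] = new
                g[rule.comp] = new * slow[rule.comp]
                steps += 1
                if history is not None:
                    history.append((step0 + steps, "fast", self.ids[rule.comp], new))
                if delta > max_delta:
                    max_delta = delta
            if max_delta <= tol:
                break
        return steps

    def _is_stable_arrays(self, fast, slow, g, free_mask) -> bool:
        tol = self.config.tolerance
        if self.config.stability_scope == "global":
            for layer in ("fast", "slow"):
                cur = fast if layer == "fast" else slow
                other = slow if layer == "fast" else fast
                for rule in self._rules[layer]:
                    if not free_mask[rule.comp]:
                        continue
                    new = rule.evaluate(g)
                    if abs(new * other[rule.comp] - g[rule.comp]) > tol:
                        return False
            return True
        for layer in ("fast", "slow"):
            cur = fast if layer == "fast" else slow
            for rule in self._rules[layer]:
                if not free_mask[rule.comp]:
                    continue
                if abs(rule.evaluate(g) - cur[rule.comp]) > tol:
                    return False
        return True

    def run(
        self,
        initial: SystemState,
        clamps: Optional[Mapping] = None,
        rng: Optional[np.random.Generator] = None,
        max_steps: Optional[int] = None,
        record_history: bool = False,
    ) -> SimulationTrace:
        """Run the priority-class asynchronous scheme from ``initial``.

        Stops when the state is stable at the configured tolerance or when
        ``max_steps`` (default: the config's ``max_total_steps``) update
        events have been spent.
        """
        if tuple(initial.ids) != self.ids:
            raise ValueError("state indexing does not match the network")
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        clamp_levels = self._clamp_array(clamps)
        clamped = ~np.isnan(clamp_levels)
        free_mask = ~clamped
        budget = self.config.max_total_steps if max_steps is None else int(max_steps)

        state = self.apply_clamps(initial, clamps or {})
        fast, slow = state.fast, state.slow
        g = fast * slow
        g[clamped] = clamp_levels[clamped]

        history: Optional[list] = [] if record_history else None
        slow_rules = [r for r in self._rules["slow"] if free_mask[r.comp]]
        steps = 0
        converged = False
        while True:
            used = self._relax_fast(fast, slow, g, free_mask, rng, budget - steps, history, steps)
            steps += used
            if self._is_stable_arrays(fast, slow, g, free_mask):
                converged = True
                break
            if steps >= budget:
                break
            if not slow_rules:
                # Fast-only network: a pseudo-stable pass can still sit off a
                # fixed point (every per-variable change <= tol); keep
                # relaxing while updates are being made.
                if used == 0:
                    break
                continue
            rule = slow_rules[rng.integers(len(slow_rules))]
            new = rule.evaluate(g)
            slow[rule.comp] = new
            g[rule.comp] = new * fast[rule.comp]
            steps += 1
            if history is not None:
                history.append((steps, "slow", self.ids[rule.comp], new))

        final = SystemState(self.ids, fast, slow)
        return SimulationTrace(final=final, converged=converged, steps_used=steps, history=history)

    def is_stable(self, state: SystemState, clamps: Optional[Mapping] = None) -> bool:
        if tuple(state.ids) != self.ids:
            raise ValueError("state indexing does not match the network")
        clamp_levels = self._clamp_array(clamps)
        clamped = ~np.isnan(clamp_levels)
        g = state.fast * state.slow
        g[clamped] = clamp_levels[clamped]
        return self._is_stable_arrays(state.fast.copy(), state.slow.copy(), g, ~clamped)


def simulate(
    net: LayeredNetwork,
    initial: SystemState,
    clamps: Optional[Mapping] = None,
    config: Optional[EngineConfig] = None,
    rng: Optional[np.random.Generator] = None,
    record_history: bool = False,
) -> SimulationTrace:
    """Convenience wrapper building an :class:`Engine` for a single run."""
    return Engine(net, config).run(initial, clamps=clamps, rng=rng, record_history=record_history)


def is_stable(
    net: LayeredNetwork,
    state: SystemState,
    config: Optional[EngineConfig] = None,
    clamps: Optional[Mapping] = None,
) -> bool:
    """True iff re-evaluating every non-input, unclamped rule moves nothing
    beyond the tolerance."""
    return Engine(net, config).is_stable(state, clamps=clamps)
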