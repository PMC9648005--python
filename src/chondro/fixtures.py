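"""Toy networks, brute-force oracles and synthetic expression data.

Everything here exists so the simulator, the attractor analysis, the
perturbation screen and the inference pipeline can be exercised end-to-end
without any external data.  All outputs are bit-reproducible under a fixed
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Engine, EngineConfig, SystemState
from .grn.expression import ExpressionMatrix
from .model import (
    ComponentSpec,
    InteractionSpec,
    LayeredNetwork,
    synthesize_rules,
)

__all__ = [
    "FixtureSpec",
    "ExpressionGenSpec",
    "make_fixture",
    "brute_force_attractors",
    "simulate_expression",
]

FIXTURE_KINDS = (
    "toggle_switch",
    "source_toggle",
    "chain",
    "random_layered",
    "mini_chondro",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy network.

    Kinds
    -----
    ``toggle_switch``
        Two mutually inhibiting, self-activating fast components (saturation
        0.5).  Fixed points: (0,0), (1,0), (0,1); the (0,0) basin has
        measure zero under random initialization.
    ``source_toggle``
        A constant source driving two cross-inhibiting fast components; with
        the source clamped at 1 the only grid fixed points are (1,0) and
        (0,1), both reachable, which makes it the reference fixture for
        Monte Carlo vs. grid-oracle equivalence.
    ``chain``
        A linear activation chain of ``n_components`` fast components; under
        a clamped head it has a unique fixed point.
    ``random_layered``
        A seed-deterministic random two-layer network.
    """

    kind: str
    n_components: int = 3
    seed: int = 0
    saturation: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def make_fixture(spec: FixtureSpec) -> LayeredNetwork:
    if spec.kind == "toggle_switch":
        return _toggle_switch()
    if spec.kind == "source_toggle":
        return _source_toggle()
    if spec.kind == "chain":
        return _chain(spec.n_components, spec.saturation)
    if spec.kind == "mini_chondro":
        return _mini_chondro()
    return _random_layered(spec.n_components, spec.seed)


def _fast_only(cid: str, role: str = "other_signaling") -> ComponentSpec:
    return ComponentSpec(id=cid, role=role, has_fast_layer=True, has_slow_layer=False)


def _toggle_switch() -> LayeredNetwork:
    interactions = [
        InteractionSpec("A", "A", +1, "fast"),
        InteractionSpec("B", "A", -1, "fast"),
        InteractionSpec("B", "B", +1, "fast"),
        InteractionSpec("A", "B", -1, "fast"),
    ]
    components = [_fast_only("A"), _fast_only("B")]
    rules = synthesize_rules(components, interactions, saturation_default=0.5)
    return LayeredNetwork(
        components=components,
        interactions=interactions,
        rules=rules,
        metadata={"name": "toggle_switch"},
    )


def _source_toggle() -> LayeredNetwork:
    interactions = [
        InteractionSpec("S", "A", +1, "fast"),
        InteractionSpec("B", "A", -1, "fast"),
        InteractionSpec("S", "B", +1, "fast"),
        InteractionSpec("A", "B", -1, "fast"),
    ]
    components = [_fast_only("S", role="growth_factor"), _fast_only("A"), _fast_only("B")]
    rules = synthesize_rules(components, interactions, saturation_default=0.5)
    return LayeredNetwork(
        components=components,
        interactions=interactions,
        rules=rules,
        metadata={"name": "source_toggle"},
    )


def _chain(n: int, saturation: float) -> LayeredNetwork:
    ids = [f"C{i}" for i in range(n)]
    components = [_fast_only(cid) for cid in ids]
    interactions = [
        InteractionSpec(ids[i], ids[i + 1], +1, "fast") for i in range(n - 1)
    ]
    rules = synthesize_rules(components, interactions, saturation_default=saturation)
    return LayeredNetwork(
        components=components,
        interactions=interactions,
        rules=rules,
        metadata={"name": f"chain{n}"},
    )


def _random_layered(n: int, seed: int) -> LayeredNetwork:
    rng = np.random.default_rng(seed)
    ids = [f"N{i}" for i in range(n)]
    components = [
        ComponentSpec(
            id=cid,
            role="transcription_factor" if rng.uniform() < 0.3 else "other_signaling",
            has_fast_layer=True,
            has_slow_layer=bool(rng.uniform() < 0.7),
        )
        for cid in ids
    ]
    interactions = []
    for target in components:
        layers = [l for l in ("fast", "slow") if target.participates(l)]
        for layer in layers:
            k = int(rng.integers(0, min(3, n)))
            sources = rng.choice(n, size=k, replace=False)
            for s in sources:
                interactions.append(
                    InteractionSpec(
                        source=ids[int(s)],
                        target=target.id,
                        sign=1 if rng.uniform() < 0.7 else -1,
                        layer=layer,
                    )
                )
    rules = synthesize_rules(components, interactions)
    return LayeredNetwork(
        components=components,
        interactions=interactions,
        rules=rules,
        metadata={"name": f"random_layered_{n}_{seed}"},
    )


def _mini_chondro() -> LayeredNetwork:
    """A 9-component phenotype switch with named marker components.

    Two master regulators (SOX9, RUNX2) form a mutually inhibiting switch
    reinforced by secreted feedback (GF, CYT); five slow-layer markers track
    the winning side.  Attractors: a SOX9-high "healthy" state, a
    RUNX2-high "hypertrophic" state, and a trivial all-off state.
    """
    fast = [
        InteractionSpec("SOX9", "SOX9", +1, "fast"),
        InteractionSpec("GF", "SOX9", +1, "fast"),
        InteractionSpec("RUNX2", "SOX9", -1, "fast"),
        InteractionSpec("CYT", "SOX9", -1, "fast"),
        InteractionSpec("RUNX2", "RUNX2", +1, "fast"),
        InteractionSpec("CYT", "RUNX2", +1, "fast"),
        InteractionSpec("SOX9", "RUNX2", -1, "fast"),
        InteractionSpec("GF", "RUNX2", -1, "fast"),
        InteractionSpec("SOX9", "GF", +1, "fast"),
        InteractionSpec("RUNX2", "CYT", +1, "fast"),
    ]
    slow = [
        InteractionSpec("SOX9", "NKX3.2", +1, "slow"),
        InteractionSpec("SOX9", "COL-II", +1, "slow"),
        InteractionSpec("RUNX2", "COL-X", +1, "slow"),
        InteractionSpec("RUNX2", "MMP13", +1, "slow"),
        InteractionSpec("RUNX2", "IHH", +1, "slow"),
    ]
    components = [
        _fast_only("SOX9", role="transcription_factor"),
        _fast_only("RUNX2", role="transcription_factor"),
        _fast_only("GF", role="growth_factor"),
        _fast_only("CYT", role="growth_factor"),
        ComponentSpec("NKX3.2", role="transcription_factor", has_fast_layer=False),
        ComponentSpec("COL-II", role="ecm_protein", has_fast_layer=False),
        ComponentSpec("COL-X", role="ecm_protein", has_fast_layer=False),
        ComponentSpec("MMP13", role="ecm_protein", has_fast_layer=False),
        ComponentSpec("IHH", role="growth_factor", has_fast_layer=False),
    ]
    interactions = fast + slow
    rules = synthesize_rules(components, interactions, saturation_default=1.0)
    return LayeredNetwork(
        components=components,
        interactions=interactions,
        rules=rules,
        metadata={"name": "mini_chondro"},
    )


# ---------------------------------------------------------------------------
# brute-force fixed-point oracle
# ---------------------------------------------------------------------------


def brute_force_attractors(
    net: LayeredNetwork,
    grid_step: float = 0.05,
    clamps: Optional[dict] = None,
    config: Optional[EngineConfig] = None,
) -> list:
    """Enumerate the sub-variable grid and return every stable grid state.

    Exponential in the number of free sub-variables, so restricted to
    networks with at most 4 components.  ``clamps`` fixes components at a
    level exactly as the engine does.
    """
    if net.n_components > 4:
        raise ValueError("brute-force oracle is limited to <= 4 components")
    config = config or EngineConfig()
    engine = Engine(net, config)
    clamps = dict(clamps or {})
    levels = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)

    free_axes = []  # (component index, layer)
    for i, comp in enumerate(net.components):
        if comp.id in clamps:
            continue
        if comp.has_fast_layer:
            free_axes.append((i, "fast"))
        if comp.has_slow_layer:
            free_axes.append((i, "slow"))

    stable = []
    base = SystemState.neutral(net)
    for combo in itertools.product(levels, repeat=len(free_axes)):
        state = base.copy()
        for (i, layer), level in zip(free_axes, combo):
            (state.fast if layer == "fast" else state.slow)[i] = level
        state = engine.apply_clamps(state, clamps)
        if engine.is_stable(state, clamps=clamps):
            stable.append(state)
    return stable


# ---------------------------------------------------------------------------
# synthetic expression data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionGenSpec:
    """Linear-Gaussian generative model for a multi-batch expression matrix.

    ``edges`` is a sequence of ``(source, target, sign)`` tuples forming an
    acyclic regulatory structure; root genes are sampled standard normal and
    children are signed weighted sums of their parents plus Gaussian noise.
    Per-batch location/scale distortions and a phenotype mean-shift on
    ``phenotype_genes`` are applied on top.
    """

    edges: tuple
    n_samples: int = 200
    n_batches: int = 1
    genes: tuple = ()
    edge_weight: float = 1.0
    noise_sd: float = 0.3
    batch_shift_sd: float = 2.0
    batch_scale_sd: float = 0.3
    phenotype_genes: tuple = ()
    phenotype_effect: float = 1.5
    phenotype_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", tuple((str(s), str(t), int(g)) for s, t, g in self.edges)
        )
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "phenotype_genes", tuple(self.phenotype_genes))
        if self.n_samples < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @classmethod
    def random(
        cls,
        n_genes: int = 20,
        n_tfs: int = 5,
        targets_per_tf: int = 3,
        seed: int = 0,
        **overrides,
    ) -> "ExpressionGenSpec":
        """A random TF -> target structure with ``n_tfs`` root regulators."""
        rng = np.random.default_rng(seed)
        tfs = [f"TF{i}" for i in range(n_tfs)]
        targets = [f"G{i}" for i in range(n_genes - n_tfs)]
        edges = []
        for tf in tfs:
            chosen = rng.choice(len(targets), size=min(targets_per_tf, len(targets)), replace=False)
            for t in chosen:
                edges.append((tf, targets[int(t)], 1 if rng.uniform() < 0.7 else -1))
        return cls(edges=tuple(edges), genes=tuple(tfs + targets), seed=seed, **overrides)

    @property
    def tf_ids(self) -> list:
        return sorted({s for s, _, _ in self.edges})


def _topological_order(genes: Sequence[str], edges) -> list:
    parents: dict = {g: [] for g in genes}
    for s, t, _ in edges:
        parents[t].append(s)
    order, mark = [], {}

    def visit(g: str) -> None:
        state = mark.get(g)
        if state == "done":
            return
        if state == "busy":
            raise ValueError("cyclic dependency in expression generator edges")
        mark[g] = "busy"
        for p in parents[g]:
            visit(p)
        mark[g] = "done"
        order.append(g)

    for g in genes:
        visit(g)
    return order


def simulate_expression(spec: ExpressionGenSpec):
    """Generate an annotated expression matrix with known regulatory structure.

    Returns ``(ExpressionMatrix, true_edges)`` where ``true_edges`` is the
    planted ``(source, target, sign)`` list.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes) if spec.genes else sorted(
        {g for e in spec.edges for g in (e[0], e[1])}
    )
    order = _topological_order(genes, spec.edges)
    parents: dict = {g: [] for g in genes}
    for s, t, sign in spec.edges:
        parents[t].append((s, sign))

    n = spec.n_samples
    data = {}
    for g in order:
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        if parents[g]:
            data[g] = sum(sign * spec.edge_weight * data[s] for s, sign in parents[g]) + noise
        else:
            data[g] = rng.normal(0.0, 1.0, size=n)

    X = np.stack([data[g] for g in genes])

    n_oa = int(round(spec.phenotype_fraction * n))
    phenotype = np.array(["OA"] * n_oa + ["WT"] * (n - n_oa))
    rng.shuffle(phenotype)
    if spec.phenotype_genes:
        gi = [genes.index(g) for g in spec.phenotype_genes]
        X[np.ix_(gi, np.flatnonzero(phenotype == "OA"))] += spec.phenotype_effect

    batch = np.array([f"batch{i % spec.n_batches}" for i in range(n)])
    if spec.n_batches > 1:
        for b in dict.fromkeys(batch):
            cols = np.flatnonzero(batch == b)
            shift = rng.normal(0.0, spec.batch_shift_sd, size=len(genes))
            scale = np.exp(rng.normal(0.0, spec.batch_scale_sd, size=len(genes)))
            X[:, cols] = X[:, cols] * scale[:, None] + shift[:, None]

    values = pd.DataFrame(X, index=genes, columns=[f"s{i}" for i in range(n)])
    matrix = ExpressionMatrix(
        values=values, batch=pd.Series(batch), phenotype=pd.Series(phenotype)
    )
    return matrix, list(spec.edges)
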