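"""Single, pairwise, scenario and dose-grid perturbation experiments.

A perturbation clamps one or more components at fixed global-activity levels
for a finite number of update events, releases them, lets the system relax
freely, and classifies the final state against the known attractors.  Every
condition is repeated ``n_reps`` times; the whole block is repeated
``n_experiments`` times to report dispersion.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .attractors import Attractor
from .engine import Engine, EngineConfig, SystemState
from .model import LayeredNetwork

__all__ = [
    "PerturbationCondition",
    "TransitionOutcome",
    "MarkovSummary",
    "DoseGrid",
    "run_condition",
    "enumerate_single",
    "enumerate_pairwise",
    "screen_single",
    "screen_pairwise",
    "markov_summary",
    "select_candidates",
    "dose_grid",
]

DEFAULT_DURATION = 1000
DEFAULT_N_REPS = 100
DEFAULT_N_EXPERIMENTS = 3


@dataclass(frozen=True)
class PerturbationCondition:
    """Clamp specification applied from a source attractor."""

    clamps: tuple  # ordered tuple of (component id, level)
    duration: int = DEFAULT_DURATION
    source_label: Optional[str] = None

    def __init__(self, clamps, duration: int = DEFAULT_DURATION, source_label=None):
        if isinstance(clamps, Mapping):
            clamps = tuple(clamps.items())
        clamps = tuple((str(c), float(v)) for c, v in clamps)
        if len(clamps) < 1:
            raise ValueError("a condition must clamp at least one component")
        for cid, level in clamps:
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"clamp level for {cid!r} must lie in [0, 1]")
        if duration <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "clamps", clamps)
        object.__setattr__(self, "duration", int(duration))
        object.__setattr__(self, "source_label", source_label)

    @property
    def clamp_dict(self) -> dict:
        return dict(self.clamps)

    @property
    def condition_id(self) -> str:
        body = "|".join(f"{cid}={level:g}" for cid, level in self.clamps)
        src = self.source_label or "?"
        return f"{src}:{body}"


@dataclass
class TransitionOutcome:
    """Per-destination transition percentages for one condition."""

    condition: PerturbationCondition
    n_reps: int
    n_experiments: int
    pct_to: dict
    replicate_sd: dict

    def healthy_pct(self) -> float:
        return self.pct_to.get("Healthy", 0.0)

    def none_pct(self) -> float:
        return self.pct_to.get("None", 0.0)

    def to_record(self) -> dict:
        return {
            "condition_id": self.condition.condition_id,
            "clamps": list(self.condition.clamps),
            "duration": self.condition.duration,
            "source": self.condition.source_label,
            "n_reps": self.n_reps,
            "n_experiments": self.n_experiments,
            "pct_to": self.pct_to,
            "replicate_sd": self.replicate_sd,
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "TransitionOutcome":
        cond = PerturbationCondition(
            clamps=[tuple(c) for c in rec["clamps"]],
            duration=rec["duration"],
            source_label=rec.get("source"),
        )
        return cls(
            condition=cond,
            n_reps=rec["n_reps"],
            n_experiments=rec["n_experiments"],
            pct_to=dict(rec["pct_to"]),
            replicate_sd=dict(rec["replicate_sd"]),
        )


@dataclass
class MarkovSummary:
    """Attractor-to-attractor transition matrix under a condition ensemble."""

    matrix: pd.DataFrame  # rows: source labels; columns: destination labels

    def exit_probability(self, label: str) -> float:
        return float(1.0 - self.matrix.loc[label, label])


@dataclass
class DoseGrid:
    comp_x: str
    comp_y: str
    levels_x: tuple
    levels_y: tuple
    cells: dict  # (level_x, level_y) -> TransitionOutcome

    def pct_table(self, destination: str) -> pd.DataFrame:
        data = [
            [self.cells[(lx, ly)].pct_to.get(destination, 0.0) for lx in self.levels_x]
            for ly in self.levels_y
        ]
        return pd.DataFrame(data, index=list(self.levels_y), columns=list(self.levels_x))


def _classify_final(state: SystemState, references: Sequence[Attractor], match_tol: float) -> str:
    g = state.global_vector()
    for ref in references:
        if np.abs(g - ref.global_profile).max() <= match_tol:
            return ref.label
    return "Unknown"


def run_condition(
    net: LayeredNetwork,
    attractor: Attractor,
    cond: PerturbationCondition,
    references: Sequence[Attractor],
    n_reps: int = DEFAULT_N_REPS,
    n_experiments: int = DEFAULT_N_EXPERIMENTS,
    config: Optional[EngineConfig] = None,
    seed: Optional[int] = None,
    match_tol: float = 1e-2,
    engine: Optional[Engine] = None,
) -> TransitionOutcome:
    """Impose ``cond`` from ``attractor`` and tally destination states.

    Each repetition starts at the attractor profile, holds the clamps for
    ``cond.duration`` update events (stopping early once stable under the
    clamps, which cannot change the outcome), releases them, simulates to
    convergence and matches the final state against ``references`` within
    ``match_tol`` (max-norm on global activities).  Unmatched or unconverged
    repetitions count as ``"Unknown"``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    config = config or EngineConfig()
    engine = engine or Engine(net, config)
    clamps = cond.clamp_dict
    for cid in clamps:
        if not net.has_component(cid):
            raise KeyError(f"condition clamps unknown component {cid!r}")

    labels = sorted({ref.label for ref in references} | {"Unknown"})
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    per_experiment = []
    start = attractor.state
    for exp_seq in master.spawn(n_experiments):
        counts = {label: 0 for label in labels}
        for rep_seq in exp_seq.spawn(n_reps):
            rng = np.random.default_rng(rep_seq)
            held = engine.run(start, clamps=clamps, rng=rng, max_steps=cond.duration)
            freed = engine.run(held.final, rng=rng)
            if not freed.converged:
                counts["Unknown"] += 1
                continue
            counts[_classify_final(freed.final, references, match_tol)] += 1
        per_experiment.append({k: 100.0 * v / n_reps for k, v in counts.items()})

    pct_to = {
        label: float(np.mean([e[label] for e in per_experiment])) for label in labels
    }
    replicate_sd = {
        label: float(np.std([e[label] for e in per_experiment], ddof=0))
        for label in labels
    }
    return TransitionOutcome(
        condition=cond,
        n_reps=n_reps,
        n_experiments=n_experiments,
        pct_to=pct_to,
        replicate_sd=replicate_sd,
    )


def enumerate_single(
    components: Sequence[str],
    duration: int = DEFAULT_DURATION,
    source_label: Optional[str] = None,
) -> list:
    """All ``2N`` single-component conditions (each clamped to 0 and to 1)."""
    return [
        PerturbationCondition(clamps=[(cid, level)], duration=duration, source_label=source_label)
        for cid in components
        for level in (0.0, 1.0)
    ]


def enumerate_pairwise(
    components: Sequence[str],
    duration: int = DEFAULT_DURATION,
    source_label: Optional[str] = None,
) -> list:
    """All ``C(N, 2) * 4`` pairwise conditions (each unordered pair at 00/01/10/11)."""
    conditions = []
    for a, b in itertools.combinations(components, 2):
        for la, lb in ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)):
            conditions.append(
                PerturbationCondition(
                    clamps=[(a, la), (b, lb)], duration=duration, source_label=source_label
                )
            )
    return conditions


def _run_screen(
    net,
    attractor,
    conditions,
    references,
    n_reps,
    n_experiments,
    config,
    seed,
    match_tol,
    out_path=None,
):
    config = config or EngineConfig()
    engine = Engine(net, config)
    done: dict = {}
    if out_path and os.path.exists(out_path):
        with open(out_path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rec = json.loads(line)
                    done[rec["condition_id"]] = TransitionOutcome.from_record(rec)
    sink = open(out_path, "a") if out_path else None
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    condition_seeds = master.generate_state(len(conditions), dtype=np.uint64)
    outcomes = []
    try:
        for cond, cond_seed in zip(conditions, condition_seeds):
            if cond.condition_id in done:
                outcomes.append(done[cond.condition_id])
                continue
            outcome = run_condition(
                net,
                attractor,
                cond,
                references,
                n_reps=n_reps,
                n_experiments=n_experiments,
                config=config,
                seed=int(cond_seed),
                match_tol=match_tol,
                engine=engine,
            )
            outcomes.append(outcome)
            if sink is not None:
                sink.write(json.dumps(outcome.to_record()) + "\n")
                sink.flush()
    finally:
        if sink is not None:
            sink.close()
    return outcomes


def screen_single(
    net: LayeredNetwork,
    attractor: Attractor,
    references: Sequence[Attractor],
    n_reps: int = DEFAULT_N_REPS,
    n_experiments: int = DEFAULT_N_EXPERIMENTS,
    config: Optional[EngineConfig] = None,
    seed: Optional[int] = None,
    match_tol: float = 1e-2,
    duration: int = DEFAULT_DURATION,
    out_path: Optional[str] = None,
) -> list:
    """Clamp every component to 0 and to 1 from ``attractor`` (2N conditions)."""
    conditions = enumerate_single(net.component_ids, duration=duration, source_label=attractor.label)
    return _run_screen(
        net, attractor, conditions, references, n_reps, n_experiments, config, seed, match_tol, out_path
    )


def screen_pairwise(
    net: LayeredNetwork,
    attractor: Attractor,
    references: Sequence[Attractor],
    n_reps: int = DEFAULT_N_REPS,
    n_experiments: int = DEFAULT_N_EXPERIMENTS,
    config: Optional[EngineConfig] = None,
    seed: Optional[int] = None,
    match_tol: float = 1e-2,
    duration: int = DEFAULT_DURATION,
    out_path: Optional[str] = None,
) -> list:
    """Run all pairwise clamp combinations; streams JSON-lines and resumes
    from ``out_path`` when it already holds finished conditions."""
    conditions = enumerate_pairwise(net.component_ids, duration=duration, source_label=attractor.label)
    return _run_screen(
        net, attractor, conditions, references, n_reps, n_experiments, config, seed, match_tol, out_path
    )


def markov_summary(screens: Mapping) -> MarkovSummary:
    """Transition matrix under the uniform single-perturbation ensemble.

    ``screens`` maps each source attractor label to its list of single
    perturbation outcomes.  Entry ``(s, t)`` is the mean over conditions of
    the fraction of repetitions ending in ``t``; rows are renormalized so
    they sum to 1.0 exactly.
    """
    sources = list(screens)
    if not sources:
        raise ValueError("markov_summary requires at least one source state")
    destinations = sorted(
        set(sources)
        | {label for outs in screens.values() for o in outs for label in o.pct_to}
    )
    rows = []
    for src in sources:
        outcomes = screens[src]
        if not outcomes:
            raise ValueError(f"no outcomes for source state {src!r}")
        row = np.zeros(len(destinations))
        for out in outcomes:
            for j, dest in enumerate(destinations):
                row[j] += out.pct_to.get(dest, 0.0) / 100.0
        row /= len(outcomes)
        row /= row.sum()
        rows.append(row)
    matrix = pd.DataFrame(rows, index=sources, columns=destinations)
    return MarkovSummary(matrix=matrix)


def select_candidates(
    screen: Iterable[TransitionOutcome],
    min_healthy_pct: float = 70.0,
    max_none_pct: float = 5.0,
    exclude: Iterable[str] = (),
) -> dict:
    """Bin conditions reaching the healthy state often enough.

    Keeps outcomes with at least ``min_healthy_pct`` percent of repetitions
    ending Healthy and strictly less than ``max_none_pct`` percent ending in
    the None state, drops conditions clamping any excluded component, and
    bins the survivors by Healthy percentage: ``"100-90"``, ``"89-80"``,
    ``"79-70"`` (bin edges follow the selection floor).
    """
    for name, val in (("min_healthy_pct", min_healthy_pct), ("max_none_pct", max_none_pct)):
        if not 0.0 <= val <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100]")
    exclude = set(exclude)
    bins = {"100-90": [], "89-80": [], "79-70": []}
    for outcome in screen:
        if exclude & {cid for cid, _ in outcome.condition.clamps}:
            continue
        healthy = outcome.healthy_pct()
        if healthy < min_healthy_pct or outcome.none_pct() >= max_none_pct:
            continue
        if healthy >= 90.0:
            bins["100-90"].append(outcome)
        elif healthy >= 80.0:
            bins["89-80"].append(outcome)
        else:
            bins["79-70"].append(outcome)
    for bucket in bins.values():
        bucket.sort(key=lambda o: -o.healthy_pct())
    return bins


def dose_grid(
    net: LayeredNetwork,
    attractor: Attractor,
    comp_x: str,
    comp_y: str,
    levels: Sequence[float],
    references: Sequence[Attractor] = (),
    levels_y: Optional[Sequence[float]] = None,
    n_reps: int = DEFAULT_N_REPS,
    n_experiments: int = DEFAULT_N_EXPERIMENTS,
    config: Optional[EngineConfig] = None,
    seed: Optional[int] = None,
    match_tol: float = 1e-2,
    duration: int = DEFAULT_DURATION,
) -> DoseGrid:
    """Clamp ``comp_x`` x ``comp_y`` over a grid of levels (ratio sweeps
    between receptor pairs are a special case)."""
    levels_x = tuple(float(v) for v in levels)
    levels_y = tuple(float(v) for v in (levels_y if levels_y is not None else levels))
    if not levels_x or not levels_y:
        raise ValueError("dose_grid requires at least one level per axis")
    for cid in (comp_x, comp_y):
        if not net.has_component(cid):
            raise KeyError(f"unknown component {cid!r}")
    conditions = [
        PerturbationCondition(
            clamps=[(comp_x, lx), (comp_y, ly)], duration=duration, source_label=attractor.label
        )
        for lx in levels_x
        for ly in levels_y
    ]
    outcomes = _run_screen(
        net, attractor, conditions, references, n_reps, n_experiments, config, seed, match_tol
    )
    cells = {
        (lx, ly): outcome
        for (lx, ly), outcome in zip(
            ((lx, ly) for lx in levels_x for ly in levels_y), outcomes
        )
    }
    return DoseGrid(comp_x=comp_x, comp_y=comp_y, levels_x=levels_x, levels_y=levels_y, cells=cells)
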