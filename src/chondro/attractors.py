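"""Monte Carlo attractor discovery, state grouping and phenotype labeling."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .engine import Engine, EngineConfig, SystemState
from .model import LayeredNetwork

__all__ = [
    "Attractor",
    "PhenotypeSignature",
    "CanalizationResult",
    "AmbiguousPhenotypeError",
    "group_states",
    "classify_profile",
    "classify_attractor",
    "monte_carlo",
    "load_signatures",
    "default_signatures",
    "save_canalization",
    "load_attractors",
]


class AmbiguousPhenotypeError(ValueError):
    """Raised when two or more phenotype signatures match the same profile."""


@dataclass(frozen=True)
class PhenotypeSignature:
    """Marker-based phenotype definition.

    A profile matches when every component in ``high`` exceeds ``1 - band``
    and every component in ``low`` falls below ``band``.
    """

    label: str
    high: frozenset = frozenset()
    low: frozenset = frozenset()
    band: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "high", frozenset(self.high))
        object.__setattr__(self, "low", frozenset(self.low))
        if self.high & self.low:
            raise ValueError(f"signature {self.label!r}: high and low sets overlap")
        if not 0 < self.band < 0.5:
            raise ValueError(f"signature {self.label!r}: band must lie in (0, 0.5)")

    def matches(self, profile: Mapping) -> bool:
        return all(profile[c] > 1 - self.band for c in self.high) and all(
            profile[c] < self.band for c in self.low
        )


@dataclass
class Attractor:
    """A grouped stable state with its basin statistics."""

    ids: tuple
    global_profile: np.ndarray
    fast_profile: np.ndarray
    slow_profile: np.ndarray
    label: str = "Unknown"
    basin_fraction: float = 0.0
    support: int = 0

    def activity(self, cid: str) -> float:
        return float(self.global_profile[self.ids.index(cid)])

    @property
    def profile(self) -> dict:
        return {cid: float(v) for cid, v in zip(self.ids, self.global_profile)}

    @property
    def state(self) -> SystemState:
        return SystemState(self.ids, self.fast_profile, self.slow_profile)


@dataclass
class CanalizationResult:
    attractors: list
    n_init: int
    clamps: dict
    unconverged_fraction: float

    def basin_table(self) -> dict:
        return {a.label: a.basin_fraction for a in self.attractors}

    def find(self, label: str) -> Attractor:
        for a in self.attractors:
            if a.label == label:
                return a
        raise KeyError(label)


def _state_matrix(states: Sequence[SystemState], on: str) -> np.ndarray:
    if on == "global":
        return np.stack([s.global_vector() for s in states])
    if on == "subvariables":
        return np.stack([np.concatenate([s.fast, s.slow]) for s in states])
    raise ValueError(f"unknown grouping space {on!r}")


def group_states(states: Sequence[SystemState], tol: float = 1e-2, on: str = "global"):
    """Single-linkage grouping under max-componentwise difference ``<= tol``.

    By default states are compared on their global-activity vectors; pass
    ``on="subvariables"`` to compare the concatenated fast/slow vectors.
    Returns a list of ``(representative_state, member_count)`` pairs, where
    the representative averages the members componentwise (fast, slow and
    global profiles alike).  States are deduplicated at 1e-6 resolution
    before the quadratic linkage step.
    """
    states = list(states)
    if not states:
        return []
    vectors = _state_matrix(states, on)
    rounded = np.round(vectors, 6)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)

    m = len(uniq)
    parent = np.arange(m)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m - 1):
        close = np.flatnonzero(np.abs(uniq[i + 1 :] - uniq[i]).max(axis=1) <= tol) + i + 1
        ri = find(i)
        for j in close:
            rj = find(j)
            if ri != rj:
                parent[rj] = ri
                ri = find(i)

    roots = np.array([find(i) for i in range(m)])
    state_groups = roots[inverse]
    results = []
    ids = tuple(states[0].ids)
    fast = np.stack([s.fast for s in states])
    slow = np.stack([s.slow for s in states])
    for root in np.unique(state_groups):
        members = np.flatnonzero(state_groups == root)
        rep = SystemState(ids, fast[members].mean(axis=0), slow[members].mean(axis=0))
        results.append((rep, len(members)))
    results.sort(key=lambda pair: -pair[1])
    return results


def classify_profile(
    profile: Mapping,
    signatures: Iterable[PhenotypeSignature],
) -> str:
    """Label a global-activity profile, ``"Unknown"`` if no signature matches."""
    matched = [sig for sig in signatures if sig.matches(profile)]
    if len(matched) > 1:
        raise AmbiguousPhenotypeError(
            f"profile satisfies multiple signatures: {[s.label for s in matched]}"
        )
    return matched[0].label if matched else "Unknown"


def classify_attractor(attr: Attractor, signatures: Iterable[PhenotypeSignature]) -> str:
    return classify_profile(attr.profile, signatures)


def monte_carlo(
    net: LayeredNetwork,
    n_init: int,
    clamps: Optional[Mapping] = None,
    config: Optional[EngineConfig] = None,
    signatures: Optional[Sequence[PhenotypeSignature]] = None,
    group_tol: float = 1e-2,
    group_on: str = "global",
) -> CanalizationResult:
    """Estimate attractors and basins from uniform random initializations.

    Each unclamped sub-variable is drawn i.i.d. uniform on ``[0, 1]``; each
    initialization is simulated to convergence; converged finals are grouped
    with :func:`group_states`.  Replicate seeds derive deterministically from
    the master seed in ``config.seed``.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    config = config or EngineConfig()
    clamps = dict(clamps or {})
    engine = Engine(net, config)
    master = np.random.SeedSequence(config.seed)
    finals = []
    n_unconverged = 0
    for child in master.spawn(n_init):
        rng = np.random.default_rng(child)
        initial = SystemState.uniform_random(net, rng)
        trace = engine.run(initial, clamps=clamps, rng=rng)
        if trace.converged:
            finals.append(trace.final)
        else:
            n_unconverged += 1

    attractors = []
    for rep, count in group_states(finals, tol=group_tol, on=group_on):
        attr = Attractor(
            ids=tuple(rep.ids),
            global_profile=rep.global_vector(),
            fast_profile=rep.fast,
            slow_profile=rep.slow,
            basin_fraction=count / n_init,
            support=count,
        )
        if signatures is not None:
            attr.label = classify_attractor(attr, signatures)
        attractors.append(attr)
    return CanalizationResult(
        attractors=attractors,
        n_init=n_init,
        clamps=clamps,
        unconverged_fraction=n_unconverged / n_init,
    )


# ---------------------------------------------------------------------------
# configuration and serialization
# ---------------------------------------------------------------------------


def _parse_signatures(doc: Mapping) -> list:
    band = float(doc.get("band", 0.2))
    sigs = []
    for entry in doc.get("signatures", []):
        sigs.append(
            PhenotypeSignature(
                label=str(entry["label"]),
                high=frozenset(entry.get("high") or ()),
                low=frozenset(entry.get("low") or ()),
                band=float(entry.get("band", band)),
            )
        )
    return sigs


def load_signatures(path: str) -> list:
    """Read phenotype signatures from a YAML file."""
    with open(path) as fh:
        return _parse_signatures(yaml.safe_load(fh) or {})


def default_signatures() -> list:
    """The packaged marker signatures (Healthy / Hypertrophic / None)."""
    text = resources.files("chondro").joinpath("data/signatures.yaml").read_text()
    return _parse_signatures(yaml.safe_load(text))


def save_canalization(result: CanalizationResult, path: str) -> None:
    doc = {
        "n_init": result.n_init,
        "clamps": result.clamps,
        "unconverged_fraction": result.unconverged_fraction,
        "attractors": [
            {
                "ids": list(a.ids),
                "fast": [float(v) for v in a.fast_profile],
                "slow": [float(v) for v in a.slow_profile],
                "label": a.label,
                "basin_fraction": a.basin_fraction,
                "support": a.support,
            }
            for a in result.attractors
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_attractors(path: str) -> list:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for entry in doc["attractors"]:
        fast = np.asarray(entry["fast"], dtype=float)
        slow = np.asarray(entry["slow"], dtype=float)
        out.append(
            Attractor(
                ids=tuple(entry["ids"]),
                global_profile=fast * slow,
                fast_profile=fast,
                slow_profile=slow,
                label=entry.get("label", "Unknown"),
                basin_fraction=entry.get("basin_fraction", 0.0),
                support=entry.get("support", 0),
            )
        )
    return out
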