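"""Consensus rule, Spearman signing, and network integration of inferred edges."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ..model import InteractionSpec, LayeredNetwork, UpdateRuleSpec
from .expression import ExpressionMatrix
from .scoring import EdgeScoreMatrix

__all__ = ["ConsensusEdge", "method_threshold", "consensus", "integrate_edges"]


@dataclass(frozen=True)
class ConsensusEdge:
    """A TF -> target edge retained by all three scorers, signed by Spearman."""

    source: str
    target: str
    per_method_pass: tuple
    spearman: float
    sign: int
    scores: tuple = ()  # (method, score) pairs, for reporting


def method_threshold(matrix: EdgeScoreMatrix) -> float:
    """The mean-minus-SD acceptance threshold over a method's finite scores."""
    vals = matrix.finite_values()
    if vals.size == 0:
        raise ValueError(f"score matrix for {matrix.method!r} has no finite entries")
    return float(vals.mean() - vals.std(ddof=0))


def consensus(scores: Sequence[EdgeScoreMatrix], m: ExpressionMatrix) -> list:
    """Intersect the per-method pass-sets and sign survivors by correlation.

    An edge passes one method when its score strictly exceeds that method's
    mean-minus-SD threshold; only edges passing every supplied method are
    kept.  Each kept edge is signed by the Spearman correlation between the
    source and target expression profiles; zero-variance pairs (undefined
    correlation) are dropped with a warning.
    """
    if not scores:
        raise ValueError("consensus requires at least one score matrix")
    first = scores[0]
    for other in scores[1:]:
        if other.tfs != first.tfs or other.genes != first.genes:
            raise ValueError("score matrices must share identical TF/gene indexing")
    thresholds = [method_threshold(s) for s in scores]

    edges = []
    values = m.values
    for tf in first.tfs:
        for gene in first.genes:
            if tf == gene:
                continue
            entry = [float(s.scores.loc[tf, gene]) for s in scores]
            if not all(np.isfinite(entry)):
                continue
            passes = tuple(v > thr for v, thr in zip(entry, thresholds))
            if not all(passes):
                continue
            x = values.loc[tf].to_numpy(dtype=float)
            y = values.loc[gene].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"dropping consensus edge {tf}->{gene}: zero-variance profile",
                    stacklevel=2,
                )
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            if not np.isfinite(rho) or rho == 0:
                warnings.warn(
                    f"dropping consensus edge {tf}->{gene}: undefined correlation sign",
                    stacklevel=2,
                )
                continue
            edges.append(
                ConsensusEdge(
                    source=tf,
                    target=gene,
                    per_method_pass=passes,
                    spearman=rho,
                    sign=1 if rho > 0 else -1,
                    scores=tuple((s.method, v) for s, v in zip(scores, entry)),
                )
            )
    return edges


def integrate_edges(
    net: LayeredNetwork,
    edges: Iterable[ConsensusEdge],
    mapping: Optional[Mapping] = None,
) -> LayeredNetwork:
    """Append inferred edges to the slow (transcriptional) layer.

    ``mapping`` translates gene ids to network component ids (identity by
    default).  Edges duplicating an existing slow-layer interaction between
    the same pair are skipped and reported via a warning; the integration
    report is also stored under ``metadata["integration_report"]``.
    """
    mapping = dict(mapping or {})

    def to_component(gene: str) -> str:
        cid = mapping.get(gene, gene)
        if not net.has_component(cid):
            raise KeyError(f"gene {gene!r} does not map to a network component")
        return cid

    existing = {(i.source, i.target, i.layer) for i in net.interactions}
    interactions = list(net.interactions)
    rules = {(r.target, r.layer): r for r in net.rules}
    added, skipped = [], []
    for edge in edges:
        src = to_component(edge.source)
        dst = to_component(edge.target)
        if (src, dst, "slow") in existing:
            skipped.append((src, dst))
            continue
        if not net.component(dst).has_slow_layer:
            raise ValueError(
                f"cannot integrate {src}->{dst}: target has no slow layer"
            )
        interactions.append(
            InteractionSpec(source=src, target=dst, sign=edge.sign, layer="slow", provenance="inferred")
        )
        existing.add((src, dst, "slow"))
        rule = rules[(dst, "slow")]
        rules[(dst, "slow")] = UpdateRuleSpec(
            target=rule.target,
            layer=rule.layer,
            terms=rule.terms + ((src, edge.sign),),
            combiner=rule.combiner,
            saturation=rule.saturation,
        )
        added.append((src, dst))
    if skipped:
        warnings.warn(f"skipped duplicate inferred edges: {skipped}", stacklevel=2)
    metadata = dict(net.metadata)
    metadata["integration_report"] = {"added": added, "skipped_duplicates": skipped}
    return LayeredNetwork(
        components=list(net.components),
        interactions=interactions,
        rules=list(rules.values()),
        metadata=metadata,
    )
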