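"""Reading and writing network models.

Two on-disk formats are supported:

* **edge_table** — a TSV with columns ``source, target, sign, layer,
  provenance`` plus an optional YAML *rules sidecar* (``<stem>.rules.yaml``)
  declaring components without edges, layer participation, roles, and
  combiner/saturation overrides.
* **sbml_qual** — a minimal SBML-qual (Level 3) document.  Each layer of a
  component maps to one qualitative species named ``<ID>__fast`` /
  ``<ID>__slow``; rule exceptions are carried as attributes in a private
  namespace so the document round-trips.
"""

from __future__ import annotations

import csv
import os
import xml.etree.ElementTree as ET
from typing import Optional

import yaml

from .model import (
    DEFAULT_SATURATION,
    LAYERS,
    ComponentSpec,
    InteractionSpec,
    LayeredNetwork,
    NetworkValidationError,
    UpdateRuleSpec,
    synthesize_rules,
)

__all__ = ["load_network", "write_network", "sidecar_path"]

EDGE_COLUMNS = ("source", "target", "sign", "layer", "provenance")

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
CHONDRO_NS = "https://chondro.invalid/sbml-annotations"

_SIGN_TO_STR = {1: "+", -1: "-"}
_STR_TO_SIGN = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


def sidecar_path(path: str) -> str:
    """Return the conventional rules-sidecar path for an edge table."""
    stem, _ = os.path.splitext(path)
    return stem + ".rules.yaml"


def load_network(path: str, format: str = "edge_table", sidecar: Optional[str] = None) -> LayeredNetwork:
    """Load a :class:`LayeredNetwork` from ``path``.

    Parameters
    ----------
    path : str
        Input file.
    format : {"edge_table", "sbml_qual"}
    sidecar : str, optional
        Rules sidecar for the edge-table format; defaults to
        ``<stem>.rules.yaml`` next to ``path`` when that file exists.
    """
    if format == "edge_table":
        return _load_edge_table(path, sidecar)
    if format == "sbml_qual":
        return _load_sbml_qual(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: LayeredNetwork, path: str, format: str = "edge_table") -> None:
    """Write ``net`` so that :func:`load_network` round-trips to an equal model."""
    if format == "edge_table":
        _write_edge_table(net, path)
    elif format == "sbml_qual":
        _write_sbml_qual(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# edge table
# ---------------------------------------------------------------------------


def _load_edge_table(path: str, sidecar: Optional[str]) -> LayeredNetwork:
    if sidecar is None:
        cand = sidecar_path(path)
        sidecar = cand if os.path.exists(cand) else None
    side = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            side = yaml.safe_load(fh) or {}

    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise NetworkValidationError(f"{path}: empty file (expected a header row)")
        missing = set(EDGE_COLUMNS[:4]) - set(reader.fieldnames)
        if missing:
            raise NetworkValidationError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sign = _STR_TO_SIGN.get(str(row["sign"]).strip())
            if sign is None:
                raise NetworkValidationError(
                    f"{path}:{lineno}: bad sign {row['sign']!r} (expected + or -)"
                )
            rows.append(
                InteractionSpec(
                    source=row["source"].strip(),
                    target=row["target"].strip(),
                    sign=sign,
                    layer=row["layer"].strip(),
                    provenance=(row.get("provenance") or "curated").strip() or "curated",
                )
            )

    comp_cfg = side.get("components") or {}
    ids = list(dict.fromkeys(comp_cfg))
    for inter in rows:
        for cid in (inter.source, inter.target):
            if cid not in comp_cfg and cid not in ids:
                ids.append(cid)
    components = []
    for cid in ids:
        cfg = comp_cfg.get(cid) or {}
        components.append(
            ComponentSpec(
                id=cid,
                role=cfg.get("role", "other_signaling"),
                has_fast_layer=bool(cfg.get("has_fast_layer", True)),
                has_slow_layer=bool(cfg.get("has_slow_layer", True)),
                annotation=cfg.get("annotation", ""),
            )
        )

    combiner_overrides = {}
    saturation_overrides = {}
    for entry in side.get("rules") or []:
        key = (entry["target"], entry["layer"])
        if "combiner" in entry:
            combiner_overrides[key] = entry["combiner"]
        if "saturation" in entry:
            saturation_overrides[key] = float(entry["saturation"])
    rules = synthesize_rules(
        components,
        rows,
        combiner_overrides=combiner_overrides,
        saturation_overrides=saturation_overrides,
        saturation_default=float(side.get("saturation_default", DEFAULT_SATURATION)),
    )
    metadata = dict(side.get("metadata") or {})
    metadata.setdefault("name", os.path.splitext(os.path.basename(path))[0])
    metadata.setdefault("format", "edge_table")
    return LayeredNetwork(components=components, interactions=rows, rules=rules, metadata=metadata)


def _write_edge_table(net: LayeredNetwork, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_COLUMNS)
        for inter in net.interactions:
            writer.writerow(
                [inter.source, inter.target, _SIGN_TO_STR[inter.sign], inter.layer, inter.provenance]
            )
    side: dict = {
        "metadata": dict(net.metadata),
        "components": {
            c.id: {
                "role": c.role,
                "has_fast_layer": c.has_fast_layer,
                "has_slow_layer": c.has_slow_layer,
                **({"annotation": c.annotation} if c.annotation else {}),
            }
            for c in net.components
        },
        "rules": [
            {
                "target": r.target,
                "layer": r.layer,
                "combiner": r.combiner,
                "saturation": r.saturation,
            }
            for r in net.rules
            if r.combiner != "additive" or r.saturation != DEFAULT_SATURATION
        ],
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# SBML-qual
# ---------------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _c(attr: str) -> str:
    return f"{{{CHONDRO_NS}}}{attr}"


def _species_id(cid: str, layer: str) -> str:
    return f"{cid}__{layer}"


def _split_species_id(sid: str):
    for layer in LAYERS:
        suffix = f"__{layer}"
        if sid.endswith(suffix):
            return sid[: -len(suffix)], layer
    raise NetworkValidationError(
        f"qualitative species {sid!r} does not follow the <ID>__fast/<ID>__slow "
        "naming convention"
    )


def _write_sbml_qual(net: LayeredNetwork, path: str) -> None:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("qual", QUAL_NS)
    ET.register_namespace("chondro", CHONDRO_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(
        root,
        f"{{{SBML_NS}}}model",
        {"id": str(net.metadata.get("name", "model")).replace(" ", "_") or "model"},
    )
    los = ET.SubElement(model, _q("listOfQualitativeSpecies"))
    for comp in net.components:
        for layer in LAYERS:
            if not comp.participates(layer):
                continue
            attrs = {
                _q("id"): _species_id(comp.id, layer),
                _q("maxLevel"): "1",
                _q("constant"): "false",
                _c("role"): comp.role,
            }
            if comp.annotation:
                attrs[_c("annotation")] = comp.annotation
            ET.SubElement(los, _q("qualitativeSpecies"), attrs)
    lot = ET.SubElement(model, _q("listOfTransitions"))
    rule_by_key = {(r.target, r.layer): r for r in net.rules}
    incoming: dict = {}
    for inter in net.interactions:
        incoming.setdefault((inter.target, inter.layer), []).append(inter)
    for comp in net.components:
        for layer in LAYERS:
            if not comp.participates(layer):
                continue
            rule = rule_by_key[(comp.id, layer)]
            tr = ET.SubElement(
                lot,
                _q("transition"),
                {
                    _q("id"): f"tr_{comp.id}_{layer}",
                    _c("combiner"): rule.combiner,
                    _c("saturation"): repr(rule.saturation),
                },
            )
            inters = incoming.get((comp.id, layer), [])
            if inters:
                loi = ET.SubElement(tr, _q("listOfInputs"))
                for inter in inters:
                    src_comp = net.component(inter.source)
                    src_layer = layer if src_comp.participates(layer) else (
                        "slow" if layer == "fast" else "fast"
                    )
                    ET.SubElement(
                        loi,
                        _q("input"),
                        {
                            _q("qualitativeSpecies"): _species_id(inter.source, src_layer),
                            _q("transitionEffect"): "none",
                            _q("sign"): "positive" if inter.sign > 0 else "negative",
                            _c("provenance"): inter.provenance,
                        },
                    )
            loo = ET.SubElement(tr, _q("listOfOutputs"))
            ET.SubElement(
                loo,
                _q("output"),
                {
                    _q("qualitativeSpecies"): _species_id(comp.id, layer),
                    _q("transitionEffect"): "assignmentLevel",
                },
            )
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _load_sbml_qual(path: str) -> LayeredNetwork:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise NetworkValidationError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise NetworkValidationError(f"{path}: no <model> element")

    layer_flags: dict = {}
    comp_meta: dict = {}
    order: list = []
    for sp in model.iter(_q("qualitativeSpecies")):
        sid = sp.get(_q("id")) or sp.get("id")
        if sid is None:
            raise NetworkValidationError(f"{path}: qualitativeSpecies without id")
        cid, layer = _split_species_id(sid)
        if cid not in layer_flags:
            layer_flags[cid] = {"fast": False, "slow": False}
            order.append(cid)
        layer_flags[cid][layer] = True
        meta = comp_meta.setdefault(cid, {})
        if sp.get(_c("role")):
            meta["role"] = sp.get(_c("role"))
        if sp.get(_c("annotation")):
            meta["annotation"] = sp.get(_c("annotation"))

    components = [
        ComponentSpec(
            id=cid,
            role=comp_meta.get(cid, {}).get("role", "other_signaling"),
            has_fast_layer=layer_flags[cid]["fast"],
            has_slow_layer=layer_flags[cid]["slow"],
            annotation=comp_meta.get(cid, {}).get("annotation", ""),
        )
        for cid in order
    ]

    interactions = []
    rules = []
    for tr in model.iter(_q("transition")):
        outputs = tr.findall(f"{_q('listOfOutputs')}/{_q('output')}")
        if len(outputs) != 1:
            raise NetworkValidationError(f"{path}: transitions must have exactly one output")
        out_id = outputs[0].get(_q("qualitativeSpecies")) or outputs[0].get("qualitativeSpecies")
        target, layer = _split_species_id(out_id)
        terms = []
        for inp in tr.findall(f"{_q('listOfInputs')}/{_q('input')}"):
            in_id = inp.get(_q("qualitativeSpecies")) or inp.get("qualitativeSpecies")
            source, _ = _split_species_id(in_id)
            sign_str = inp.get(_q("sign")) or inp.get("sign") or "positive"
            sign = 1 if sign_str == "positive" else -1
            provenance = inp.get(_c("provenance"), "curated")
            interactions.append(
                InteractionSpec(source=source, target=target, sign=sign, layer=layer, provenance=provenance)
            )
            terms.append((source, sign))
        rules.append(
            UpdateRuleSpec(
                target=target,
                layer=layer,
                terms=tuple(terms),
                combiner=tr.get(_c("combiner"), "additive"),
                saturation=float(tr.get(_c("saturation"), DEFAULT_SATURATION)),
            )
        )
    metadata = {"name": model.get("id", "model"), "format": "sbml_qual"}
    return LayeredNetwork(components=components, interactions=interactions, rules=rules, metadata=metadata)
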