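"""Bidirectional codec between :class:`QcRecord` and FHIR R4 JSON.

A record is carried as a ``MolecularSequence`` resource with one nested
extension tree under the QcMetrics canonical url: stage → (group →)
field, mirroring how published QC profiles lay the elements out.

Two wire dialects are supported:

``paper``
    Unit-bearing leaves carry a sibling ``"units"`` key next to the bare
    ``valueDecimal``/``valueInteger`` (e.g. ``{"url": "dnaIntegrity",
    "units": "bp", "valueDecimal": 60000}``).  This is not legal FHIR R4
    extension syntax but reproduces the originating system's output
    byte-for-byte, which matters when comparing against archived
    resources.

``strict_fhir``
    Unit-bearing leaves use ``valueQuantity`` with a UCUM-style unit
    string; everything else uses the ordinary typed ``value[x]`` keys.
    This is the interoperable default for writing.

Reading auto-detects the dialect and is tolerant: unknown sub-extensions
are collected, not fatal, and numeric values arriving as strings are
coerced by the domain model.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

from .elements import (
    BY_FHIR_PATH,
    ELEMENTS,
    Kind,
    QC_METRICS_URL,
    STAGES,
    STAGE_URLS,
)
from .model import QcRecord, ValidationReport, Issue, make_record, validate_record

ResourceDocument = Dict[str, Any]

_VALUE_KEYS = ("valueDecimal", "valueInteger", "valueString", "valueDate", "valueQuantity")


class Dialect(str, enum.Enum):
    PAPER = "paper"
    STRICT_FHIR = "strict_fhir"


class CodecError(ValueError):
    """Fatal parse/encode failure (wrong resourceType, ambiguous leaf, ...)."""


class EncodeValidationError(CodecError):
    """Refusal to encode a record that fails validation."""

    def __init__(self, report: ValidationReport):
        self.report = report
        msgs = "; ".join(i.message for i in report.errors)
        super().__init__(f"record fails validation: {msgs}")


def _json_number(v: float | int):
    """Decimals without trailing zeros: 60000.0 serializes as 60000."""
    if isinstance(v, float) and v.is_integer():
        return int(v)
    return v


def _encode_leaf(el, value, dialect: Dialect) -> List[dict]:
    if el.kind == Kind.GENE_LIST:
        return [{"url": el.url, "valueString": g} for g in value]
    node: Dict[str, Any] = {"url": el.url}
    if el.kind == Kind.DATE:
        node["valueDate"] = value.isoformat()
    elif el.kind in (Kind.STRING, Kind.CODE):
        node["valueString"] = value.value if isinstance(value, enum.Enum) else str(value)
    elif el.kind == Kind.INTEGER:
        if el.unit and dialect == Dialect.STRICT_FHIR:
            node["valueQuantity"] = {"value": int(value), "unit": el.unit}
        else:
            if el.unit:
                node["units"] = el.unit
            node["valueInteger"] = int(value)
    else:  # decimal
        num = _json_number(float(value))
        if el.unit and dialect == Dialect.STRICT_FHIR:
            node["valueQuantity"] = {"value": num, "unit": el.unit}
        else:
            if el.unit and dialect == Dialect.PAPER:
                node["units"] = el.unit
            node["valueDecimal"] = num
    return [node]


def to_fhir(record: QcRecord, dialect: Dialect = Dialect.STRICT_FHIR,
            qc_url: str = QC_METRICS_URL) -> ResourceDocument:
    """Encode a validated record as a MolecularSequence JSON document.

    Raises :class:`EncodeValidationError` if the record has validation
    errors.  Absent fields are omitted entirely — never ``null``, and no
    empty extension arrays are emitted.
    """
    dialect = Dialect(dialect)
    report = validate_record(record)
    if not report.ok:
        raise EncodeValidationError(report)

    doc: ResourceDocument = {"resourceType": "MolecularSequence"}
    doc["identifier"] = [{"value": record.record_id}]
    if record.patient_ref:
        doc["patient"] = {"reference": record.patient_ref}

    stage_nodes: List[dict] = []
    for stage in STAGES:
        children: List[dict] = []
        groups: Dict[str, dict] = {}
        for el in ELEMENTS:
            if el.stage != stage:
                continue
            value = record.get(el.path)
            if value is None:
                continue
            leaves = _encode_leaf(el, value, dialect)
            if len(el.fhir_path) == 3:  # stage/group/field
                g = groups.get(el.fhir_path[1])
                if g is None:
                    g = {"url": el.fhir_path[1], "extension": []}
                    groups[el.fhir_path[1]] = g
                    children.append(g)
                g["extension"].extend(leaves)
            else:
                children.extend(leaves)
        if children:
            stage_nodes.append({"url": STAGE_URLS[stage], "extension": children})
    if stage_nodes:
        doc["extension"] = [{"url": qc_url, "extension": stage_nodes}]
    return doc


# ---------------------------------------------------------------------------
# Decoding

@dataclass
class DecodeResult:
    record: QcRecord
    dialect: Dialect
    ignored: List[str] = field(default_factory=list)  # dotted url chains not in the profile


def _iter_leaves(doc: ResourceDocument, qc_url: str):
    """Yield (url_chain, node) for every node under the QcMetrics tree."""
    for ext in doc.get("extension", []) or []:
        if ext.get("url") != qc_url:
            continue
        stack = [((), ext)]
        while stack:
            chain, node = stack.pop()
            for child in node.get("extension", []) or []:
                sub = chain + (child.get("url", ""),)
                yield sub, child
                if "extension" in child:
                    stack.append((sub, child))


def detect_dialect(doc: ResourceDocument, qc_url: str = QC_METRICS_URL) -> Dialect:
    """Paper dialect iff any 'units' sibling or a bare numeric value under
    a unit-bearing element; otherwise strict (valueQuantity or nothing
    distinguishing — parsing is identical in that case)."""
    for chain, node in _iter_leaves(doc, qc_url):
        if "units" in node:
            return Dialect.PAPER
        el = BY_FHIR_PATH.get(chain)
        if el is not None and el.unit and (
                "valueDecimal" in node or "valueInteger" in node):
            return Dialect.PAPER
    return Dialect.STRICT_FHIR


def _leaf_value(node: dict, chain: Tuple[str, ...]):
    """Raw scalar from a leaf node, tolerant of representation."""
    if "units" in node and "valueQuantity" in node:
        raise CodecError(
            f"ambiguous leaf at {'.'.join(chain)}: both 'units' and valueQuantity")
    if "valueQuantity" in node:
        q = node["valueQuantity"]
        if not isinstance(q, dict) or "value" not in q:
            raise CodecError(f"malformed valueQuantity at {'.'.join(chain)}")
        return q["value"]
    for k in ("valueDecimal", "valueInteger", "valueString", "valueDate"):
        if k in node:
            return node[k]
    return None


def decode(doc: ResourceDocument, dialect: Optional[Dialect] = None,
           qc_url: str = QC_METRICS_URL) -> DecodeResult:
    """Parse a MolecularSequence document into a record.

    Unknown sub-extension urls are collected in ``ignored`` (FHIR
    extensions are open by design); a wrong resourceType is fatal.
    """
    if not isinstance(doc, dict) or doc.get("resourceType") != "MolecularSequence":
        raise CodecError(
            f"expected resourceType MolecularSequence, got {doc.get('resourceType')!r}"
            if isinstance(doc, dict) else "document is not a JSON object")
    detected = Dialect(dialect) if dialect is not None else detect_dialect(doc, qc_url)

    flat: Dict[str, Any] = {}
    ignored: List[str] = []
    for chain, node in _iter_leaves(doc, qc_url):
        el = BY_FHIR_PATH.get(chain)
        if el is None:
            # interior group/stage nodes are known prefixes, not leaves
            if any(e.fhir_path[: len(chain)] == chain for e in ELEMENTS):
                continue
            ignored.append(".".join(chain))
            continue
        value = _leaf_value(node, chain)
        if value is None:
            ignored.append(".".join(chain))
            continue
        if el.kind == Kind.GENE_LIST:
            flat.setdefault(el.path, [])
            flat[el.path].append(str(value))
        else:
            flat[el.path] = value

    rid = None
    for ident in doc.get("identifier", []) or []:
        if isinstance(ident, dict) and ident.get("value"):
            rid = str(ident["value"])
            break
    if rid is None and doc.get("id"):
        rid = str(doc["id"])
    if rid is None:
        raise CodecError("resource has no identifier or id to use as record_id")
    flat["record_id"] = rid
    patient = doc.get("patient")
    if isinstance(patient, dict) and patient.get("reference"):
        flat["patient_ref"] = patient["reference"]
    return DecodeResult(record=make_record(flat), dialect=detected, ignored=ignored)


def from_fhir(doc: ResourceDocument, dialect: Optional[Dialect] = None,
              qc_url: str = QC_METRICS_URL) -> QcRecord:
    return decode(doc, dialect, qc_url).record


# ---------------------------------------------------------------------------
# Profile (StructureDefinition) emission and resource-level validation

_TYPE_CODES = {
    Kind.STRING: "string",
    Kind.CODE: "code",
    Kind.DECIMAL: "decimal",
    Kind.INTEGER: "integer",
    Kind.DATE: "date",
    Kind.GENE_LIST: "string",
}


def emit_profile(qc_url: str = QC_METRICS_URL) -> ResourceDocument:
    """The QcMetrics profile as a FHIR R4 StructureDefinition.

    Derivation ``constraint`` on MolecularSequence; one element
    definition per QC data element, cardinality 0..1 (0..* for the
    repeated gene-symbol element).  Unit-bearing leaves are typed
    Quantity, matching the strict dialect.  Output is deterministic.
    """
    elements: List[dict] = [{
        "id": "MolecularSequence.extension:QcMetrics",
        "path": "MolecularSequence.extension",
        "sliceName": "QcMetrics",
        "short": "NGS quality-control metrics",
        "min": 0, "max": "1",
        "type": [{"code": "Extension", "profile": [qc_url]}],
    }]
    seen_groups = set()
    for el in ELEMENTS:
        prefix = "MolecularSequence.extension:QcMetrics"
        for depth, url in enumerate(el.fhir_path):
            eid = prefix + ".extension:" + url
            is_leaf = depth == len(el.fhir_path) - 1
            if not is_leaf:
                if eid not in seen_groups:
                    seen_groups.add(eid)
                    elements.append({
                        "id": eid,
                        "path": "MolecularSequence" + ".extension" * (depth + 2),
                        "sliceName": url,
                        "min": 0, "max": "1",
                        "type": [{"code": "Extension"}],
                    })
            else:
                code = "Quantity" if el.unit else _TYPE_CODES[el.kind]
                elements.append({
                    "id": eid,
                    "path": "MolecularSequence" + ".extension" * (depth + 2),
                    "sliceName": url,
                    "short": el.short,
                    "min": 0,
                    "max": "*" if el.kind == Kind.GENE_LIST else "1",
                    "type": [{"code": code}],
                })
            prefix = eid
    return {
        "resourceType": "StructureDefinition",
        "id": "QcMetrics",
        "url": qc_url,
        "name": "QcMetrics",
        "status": "active",
        "fhirVersion": "4.0.1",
        "kind": "resource",
        "abstract": False,
        "type": "MolecularSequence",
        "baseDefinition": "http://hl7.org/fhir/StructureDefinition/MolecularSequence",
        "derivation": "constraint",
        "differential": {"element": elements},
    }


def profile_leaf_urls(profile: ResourceDocument) -> set:
    """Slice names of leaf element definitions (those with a scalar type)."""
    leaves = set()
    for el in profile["differential"]["element"]:
        types = {t["code"] for t in el.get("type", [])}
        if types and types != {"Extension"}:
            leaves.add(el["sliceName"])
    return leaves


def _expected_value_key(el, dialect: Dialect) -> str:
    if el.kind == Kind.DATE:
        return "valueDate"
    if el.kind in (Kind.STRING, Kind.CODE, Kind.GENE_LIST):
        return "valueString"
    if el.unit and dialect == Dialect.STRICT_FHIR:
        return "valueQuantity"
    return "valueInteger" if el.kind == Kind.INTEGER else "valueDecimal"


def validate_resource(doc: ResourceDocument,
                      dialect: Optional[Dialect] = None,
                      qc_url: str = QC_METRICS_URL) -> ValidationReport:
    """Structural conformance against the profile, then value ranges.

    Unknown sub-extensions warn (extensions are open); a wrong value-type
    key for a documented element errors; value ranges and missing-element
    warnings are delegated to the domain-level validator.  Paths use
    dotted FHIRPath-like syntax rooted at QcMetrics for structural
    issues, dotted record paths for value issues.
    """
    issues: List[Issue] = []
    if not isinstance(doc, dict) or doc.get("resourceType") != "MolecularSequence":
        issues.append(Issue(
            path="resourceType", severity="error", code="wrong-resource-type",
            message="resource is not a MolecularSequence"))
        return ValidationReport(issues=issues).sorted()
    dialect = Dialect(dialect) if dialect is not None else detect_dialect(doc, qc_url)

    for chain, node in _iter_leaves(doc, qc_url):
        dotted = "QcMetrics." + ".".join(chain)
        el = BY_FHIR_PATH.get(chain)
        if el is None:
            if any(e.fhir_path[: len(chain)] == chain for e in ELEMENTS):
                continue
            issues.append(Issue(
                path=dotted, severity="warning", code="unknown-extension",
                message=f"sub-extension {chain[-1]!r} is not part of the profile"))
            continue
        present = [k for k in _VALUE_KEYS if k in node]
        if "units" in node and "valueQuantity" in node:
            issues.append(Issue(path=dotted, severity="error", code="ambiguous-units",
                                message="both 'units' sibling and valueQuantity present"))
            continue
        if "units" in node and dialect == Dialect.STRICT_FHIR:
            issues.append(Issue(
                path=dotted, severity="error", code="units-key-not-fhir",
                message="'units' sibling key is not legal in strict FHIR"))
        expected = _expected_value_key(el, dialect)
        if not present:
            issues.append(Issue(
                path=dotted, severity="error", code="no-value",
                message="leaf extension carries no value[x]"))
        elif present != [expected]:
            issues.append(Issue(
                path=dotted, severity="error", code="wrong-value-type",
                message=f"expected {expected}, found {present}"))

    try:
        result = decode(doc, dialect, qc_url)
    except CodecError as exc:
        issues.append(Issue(path="QcMetrics", severity="error",
                            code="undecodable", message=str(exc)))
        return ValidationReport(issues=issues).sorted()
    issues.extend(validate_record(result.record).issues)
    return ValidationReport(issues=issues).sorted()


# ---------------------------------------------------------------------------
# JSON / NDJSON plumbing

def canonical_json(doc: ResourceDocument) -> str:
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def write_ndjson(docs, path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(canonical_json(doc) + "\n")
            n += 1
    return n


def read_ndjson(path) -> List[ResourceDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(json.loads(line))
    return docs
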