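"""File-backed FHIR-style resource repository.

Stands in for a full FHIR server at desk scale: one canonical-JSON file
per MolecularSequence resource under a root directory, an in-memory id
index rebuilt from the directory on open, create/read with POST/GET
semantics, linear-scan search over parsed records (documented O(n),
adequate to ~10^4 resources), NDJSON bulk import/export, and a
bearer-token remote push contract.
"""

from __future__ import annotations

import json
import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .codec import (
    CodecError,
    ResourceDocument,
    canonical_json,
    from_fhir,
    read_ndjson,
    validate_resource,
    write_ndjson,
)
from .elements import BY_PATH
from .model import QcRecord, ValidationReport

logger = logging.getLogger(__name__)

_ID_RE = re.compile(r"^[A-Za-z0-9._-]{1,64}$")  # FHIR logical-id charset


class StoreError(Exception):
    pass


class NotFoundError(StoreError):
    pass


class ConflictError(StoreError):
    """Same id re-created with different content."""


class RejectedError(StoreError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__("resource failed validation: "
                         + "; ".join(i.message for i in report.errors))


@dataclass(frozen=True)
class MetricRange:
    path: str
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self):
        if self.path not in BY_PATH or not BY_PATH[self.path].numeric:
            raise ValueError(f"metric_range on unknown or non-numeric path: {self.path!r}")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError("metric_range min must be <= max")


@dataclass(frozen=True)
class SearchFilter:
    """Conjunctive record filter over the dashboard facets.

    All unset fields match everything; an empty filter matches all
    records.  The year facet derives from the sampling date's year, so
    records without a sampling date never match a year filter.
    """

    specimen_type: Optional[str] = None
    sequencing_type: Optional[str] = None
    year: Optional[int] = None
    metric_range: Optional[MetricRange] = None

    def matches(self, record: QcRecord) -> bool:
        sp = record.sample_prep
        if self.specimen_type is not None:
            if sp.specimen_type is None or sp.specimen_type.value != self.specimen_type:
                return False
        if self.sequencing_type is not None:
            if sp.sequencing_type is None or sp.sequencing_type.value != self.sequencing_type:
                return False
        if self.year is not None:
            if sp.sampling_date is None or sp.sampling_date.year != self.year:
                return False
        if self.metric_range is not None:
            mr = self.metric_range
            v = record.get(mr.path)
            if v is None:
                return False
            v = float(v)
            if mr.min is not None and v < mr.min:
                return False
            if mr.max is not None and v > mr.max:
                return False
        return True


def _id_sort_key(rid: str) -> Tuple:
    return (0, int(rid), "") if rid.isdigit() else (1, 0, rid)


class QcStore:
    """Directory-backed resource store; safe to reopen at any time."""

    def __init__(self, root: Path | str):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.last_search_skipped = 0
        self._reindex()

    def _reindex(self) -> None:
        self._index: Dict[str, Path] = {}
        for p in sorted(self.root.glob("*.json")):
            self._index[p.stem] = p

    def __len__(self) -> int:
        return len(self._index)

    def ids(self) -> List[str]:
        return sorted(self._index, key=_id_sort_key)

    def _next_id(self) -> str:
        numeric = [int(i) for i in self._index if i.isdigit()]
        return str(max(numeric, default=0) + 1)

    def create(self, doc: ResourceDocument) -> str:
        """POST semantics: validate, assign an id if absent, persist.

        Idempotent per client-supplied id: re-creating the same id with
        identical canonical content returns the same id; different
        content raises :class:`ConflictError`.
        """
        report = validate_resource(doc)
        if not report.ok:
            raise RejectedError(report)
        rid = doc.get("id")
        if rid is not None:
            rid = str(rid)
            if not _ID_RE.match(rid):
                raise StoreError(f"illegal resource id: {rid!r}")
            if rid in self._index:
                if self._index[rid].read_text(encoding="utf-8") == canonical_json(doc):
                    return rid
                raise ConflictError(f"id {rid!r} exists with different content")
        else:
            rid = self._next_id()
            doc = dict(doc)
            doc["id"] = rid
        path = self.root / f"{rid}.json"
        path.write_text(canonical_json(doc), encoding="utf-8")
        self._index[rid] = path
        return rid

    def read(self, rid: str) -> ResourceDocument:
        path = self._index.get(str(rid))
        if path is None:
            raise NotFoundError(f"no resource with id {rid!r}")
        return json.loads(path.read_text(encoding="utf-8"))

    def search(self, flt: SearchFilter = SearchFilter()) -> List[ResourceDocument]:
        """All resources whose parsed record satisfies every set filter
        field, in deterministic id order.  Unparseable resources are
        skipped with a warning and tallied in ``last_search_skipped``."""
        out = []
        skipped = 0
        for rid in self.ids():
            doc = self.read(rid)
            try:
                record = from_fhir(doc)
            except (CodecError, ValueError) as exc:
                logger.warning("skipping unparseable resource %s: %s", rid, exc)
                skipped += 1
                continue
            if flt.matches(record):
                out.append(doc)
        self.last_search_skipped = skipped
        return out

    def search_records(self, flt: SearchFilter = SearchFilter()) -> List[QcRecord]:
        return [from_fhir(doc) for doc in self.search(flt)]

    # -- bulk ---------------------------------------------------------------

    def import_ndjson(self, path) -> Dict[str, int]:
        """Import one resource per line; malformed or invalid lines are
        counted as rejected and never abort the batch."""
        imported = rejected = 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    doc = json.loads(line)
                    self.create(doc)
                    imported += 1
                except (json.JSONDecodeError, StoreError) as exc:
                    logger.warning("rejected NDJSON line: %s", exc)
                    rejected += 1
        return {"imported": imported, "rejected": rejected}

    def export_ndjson(self, path, flt: SearchFilter = SearchFilter()) -> int:
        return write_ndjson(self.search(flt), path)


# ---------------------------------------------------------------------------
# Remote push (FHIR REST client contract)

class RemoteError(StoreError):
    def __init__(self, status: int, outcome: Optional[dict] = None):
        self.status = status
        self.outcome = outcome
        detail = ""
        if outcome:
            detail = ": " + json.dumps(outcome)[:200]
        super().__init__(f"remote server returned HTTP {status}{detail}")


def push_remote(doc: ResourceDocument, endpoint: str, token: str,
                timeout: float = 10.0) -> str:
    """POST a resource to ``{endpoint}/MolecularSequence`` with a bearer
    token; returns the server-assigned id from the Location header (or
    the response body's ``id``).  A locally-invalid document is refused
    before any network traffic."""
    report = validate_resource(doc)
    if not report.ok:
        raise RejectedError(report)
    url = endpoint.rstrip("/") + "/MolecularSequence"
    body = canonical_json(doc).encode("utf-8")
    req = urllib.request.Request(
        url, data=body, method="POST",
        headers={"Authorization": f"Bearer {token}",
                 "Content-Type": "application/fhir+json"})
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            location = resp.headers.get("Location", "")
            payload = resp.read()
    except urllib.error.HTTPError as exc:
        outcome = None
        try:
            outcome = json.loads(exc.read().decode("utf-8"))
        except Exception:
            pass
        raise RemoteError(exc.code, outcome) from exc
    except urllib.error.URLError as exc:
        raise StoreError(f"cannot reach {url}: {exc.reason}") from exc
    m = re.search(r"MolecularSequence/([A-Za-z0-9._-]+)", location)
    if m:
        return m.group(1)
    try:
        rid = json.loads(payload.decode("utf-8")).get("id")
        if rid:
            return str(rid)
    except Exception:
        pass
    raise StoreError("server response carried no resource id")
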