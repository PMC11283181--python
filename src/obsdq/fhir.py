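"""HL7 FHIR R5 message interface for the ``$quality_check`` operation.

Records travel as a message Bundle: one MessageHeader (event
``quality_check``) plus one Observation per record, each record field coded
as an Observation component (the component code is the dictionary column's
FHIR code, by default the column name).  The response Bundle carries one
Observation per scored record (``valueQuantity`` = fused score, one
component per dimension sub-score, findings as string-valued components), a
Device resource describing the model, and a MessageHeader responding to the
request's id.

Everything here is plain JSON construction and structural validation —
profile conformance is checked against the in-repo expectations, not an
external terminology server — so the service adds no arithmetic of its own:
the score in the response is exactly the library's ``score_table`` output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import MODEL_VERSION, QualityEngine
from .records_io import DataDictionary, RecordTable, normalize_table

CODE_SYSTEM = "http://example.org/obsdq/columns"
EVENT_SYSTEM = "http://example.org/obsdq/events"
EVENT_CODE = "quality_check"
OPERATION = "$quality_check"


class FHIRProtocolError(ValueError):
    """Payload is not an acceptable quality-check message Bundle."""

    def __init__(self, diagnostics: str, code: str = "invalid"):
        super().__init__(diagnostics)
        self.outcome = operation_outcome("error", code, diagnostics)


def operation_outcome(severity: str, code: str, diagnostics: str) -> dict:
    return {
        "resourceType": "OperationOutcome",
        "issue": [{"severity": severity, "code": code, "diagnostics": diagnostics}],
    }


def _column_code(spec) -> str:
    return spec.fhir_code or spec.name


# ---------------------------------------------------------------------------
# request construction / parsing


def build_request(table: RecordTable, bundle_id: str = "quality-check-request") -> dict:
    """Serialize a record table as a $quality_check message Bundle."""
    entries = [
        {
            "fullUrl": f"urn:uuid:{bundle_id}-header",
            "resource": {
                "resourceType": "MessageHeader",
                "id": f"{bundle_id}-header",
                "eventCoding": {"system": EVENT_SYSTEM, "code": EVENT_CODE},
                "source": {"endpoint": "urn:obsdq:client"},
            },
        }
    ]
    id_col = next((c.name for c in table.dictionary.columns if c.kind == "identifier"), None)
    for i in range(len(table)):
        components = []
        for spec in table.dictionary.columns:
            v = table.df[spec.name].iloc[i]
            if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
                continue
            comp: dict = {"code": {"coding": [{"system": CODE_SYSTEM, "code": _column_code(spec)}]}}
            if spec.is_numeric and not table.malformed[spec.name].iloc[i]:
                q = {"value": float(v)}
                if spec.unit:
                    q["unit"] = spec.unit
                comp["valueQuantity"] = q
            else:
                comp["valueString"] = str(v)
            components.append(comp)
        rid = str(table.df[id_col].iloc[i]) if id_col else f"record-{i}"
        entries.append(
            {
                "fullUrl": f"urn:uuid:{bundle_id}-obs-{i}",
                "resource": {
                    "resourceType": "Observation",
                    "id": rid,
                    "status": "final",
                    "code": {"coding": [{"system": CODE_SYSTEM, "code": "obstetric-record"}]},
                    "component": components,
                },
            }
        )
    return {"resourceType": "Bundle", "id": bundle_id, "type": "message", "entry": entries}


def validate_message_bundle(payload: dict) -> tuple[dict, list[dict]]:
    """Structural profile check; returns (message header, observation resources)."""
    if not isinstance(payload, dict) or payload.get("resourceType") != "Bundle":
        raise FHIRProtocolError("payload is not a FHIR Bundle")
    if payload.get("type") != "message":
        raise FHIRProtocolError("Bundle.type must be 'message'")
    entries = payload.get("entry", [])
    headers = [
        e["resource"] for e in entries
        if isinstance(e.get("resource"), dict)
        and e["resource"].get("resourceType") == "MessageHeader"
    ]
    if len(headers) != 1:
        raise FHIRProtocolError(
            f"message Bundle must contain exactly one MessageHeader, found {len(headers)}",
            code="structure",
        )
    observations = [
        e["resource"] for e in entries
        if isinstance(e.get("resource"), dict)
        and e["resource"].get("resourceType") == "Observation"
    ]
    return headers[0], observations


def parse_request(
    payload: dict, dictionary: DataDictionary
) -> tuple[RecordTable, list[str]]:
    """Map a request Bundle's Observations onto dictionary rows.

    Unknown component codes are collected as warnings, never fatal.
    """
    header, observations = validate_message_bundle(payload)
    event = (header.get("eventCoding") or {}).get("code")
    if event != EVENT_CODE:
        raise FHIRProtocolError(f"unsupported message event {event!r}", code="not-supported")
    code_map = {_column_code(spec): spec.name for spec in dictionary.columns}
    warnings: list[str] = []
    rows = []
    for obs in observations:
        row = {c: np.nan for c in dictionary.names}
        id_col = next((c.name for c in dictionary.columns if c.kind == "identifier"), None)
        if id_col and obs.get("id") is not None:
            row[id_col] = str(obs["id"])
        for comp in obs.get("component", []):
            codings = (comp.get("code") or {}).get("coding") or [{}]
            code = codings[0].get("code")
            if code not in code_map:
                warnings.append(f"unknown component code {code!r} ignored")
                continue
            col = code_map[code]
            if "valueQuantity" in comp:
                row[col] = comp["valueQuantity"].get("value")
            elif "valueString" in comp:
                row[col] = comp["valueString"]
            elif "valueInteger" in comp:
                row[col] = comp["valueInteger"]
            else:
                warnings.append(f"component {code!r} carries no supported value[x]")
        rows.append(row)
    df = pd.DataFrame(rows, columns=dictionary.names)
    if not rows:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in dictionary.names})
    table = normalize_table(df, dictionary, provenance="fhir-request")
    return table, warnings


# ---------------------------------------------------------------------------
# response construction


def _device_resource(engine: QualityEngine) -> dict:
    return {
        "resourceType": "Device",
        "id": "obsdq-model",
        "status": "active",
        "deviceName": [{"name": "obsdq quality engine", "type": "model-name"}],
        "version": [
            {"value": MODEL_VERSION},
            {"value": f"weights:{engine.weights.digest()}"},
            {"value": f"trained:{engine.trained_at}"},
        ],
    }


def quality_check(payload: dict, engine: QualityEngine) -> dict:
    """Run the $quality_check operation: parse, score, serialize.

    Deterministic for fixed model files; per-record scoring failures become
    error components on that record's Observation, the batch still returns.
    """
    table, warnings = parse_request(payload, engine.dictionary)
    header, _ = validate_message_bundle(payload)
    reports, summary = engine.score_table(table) if len(table) else ([], {"n": 0})

    entries = [
        {
            "fullUrl": "urn:uuid:quality-check-response-header",
            "resource": {
                "resourceType": "MessageHeader",
                "id": "quality-check-response-header",
                "eventCoding": {"system": EVENT_SYSTEM, "code": EVENT_CODE},
                "response": {"identifier": header.get("id", ""), "code": "ok"},
                "source": {"endpoint": "urn:obsdq:server"},
            },
        },
        {"fullUrl": "urn:uuid:obsdq-model", "resource": _device_resource(engine)},
    ]
    for i, rep in enumerate(reports):
        components = []
        for name, sub in rep.subscores.items():
            components.append(
                {
                    "code": {"coding": [{"system": CODE_SYSTEM, "code": f"subscore-{name}"}]},
                    "valueQuantity": {"value": float(sub)},
                }
            )
        for f in rep.findings:
            components.append(
                {
                    "code": {"coding": [{"system": CODE_SYSTEM, "code": f"finding-{f.detector}"}]},
                    "valueString": f.message,
                }
            )
        obs: dict = {
            "resourceType": "Observation",
            "id": rep.record_id,
            "status": "final",
            "code": {"coding": [{"system": CODE_SYSTEM, "code": "record-quality-score"}]},
            "device": {"reference": "#obsdq-model"},
            "component": components,
        }
        if math.isnan(rep.score):
            obs["dataAbsentReason"] = {"text": "scoring failed; see error component"}
        else:
            obs["valueQuantity"] = {"value": float(rep.score)}
        entries.append({"fullUrl": f"urn:uuid:quality-response-obs-{i}", "resource": obs})
    bundle = {
        "resourceType": "Bundle",
        "id": "quality-check-response",
        "type": "message",
        "entry": entries,
    }
    if warnings:
        bundle["meta"] = {"tag": [{"system": CODE_SYSTEM, "code": "warning", "display": w}
                                  for w in warnings]}
    return bundle


def validate_response(bundle: dict) -> list[str]:
    """Structural profile check of a response Bundle; returns problem list."""
    problems = []
    try:
        header, observations = validate_message_bundle(bundle)
    except FHIRProtocolError as exc:
        return [str(exc)]
    if "response" not in header:
        problems.append("response MessageHeader lacks .response")
    devices = [
        e["resource"] for e in bundle.get("entry", [])
        if e.get("resource", {}).get("resourceType") == "Device"
    ]
    if len(devices) != 1:
        problems.append(f"expected exactly one Device, found {len(devices)}")
    for obs in observations:
        if "valueQuantity" in obs:
            v = obs["valueQuantity"].get("value")
            if v is None or not 0.0 <= float(v) <= 1.0:
                problems.append(f"Observation {obs.get('id')}: score {v!r} outside [0,1]")
        elif "dataAbsentReason" not in obs:
            problems.append(f"Observation {obs.get('id')}: neither score nor dataAbsentReason")
    return problems


# ---------------------------------------------------------------------------
# minimal HTTP transport (POST /$quality_check, application/fhir+json)


def make_server(engine: QualityEngine, host: str = "127.0.0.1", port: int = 8080):
    """Build (not start) a stdlib HTTP server exposing the operation."""
    from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

    class Handler(BaseHTTPRequestHandler):
        def do_POST(self):  # noqa: N802 (stdlib naming)
            if self.path.rstrip("/") not in (f"/{OPERATION}", OPERATION):
                self._send(404, operation_outcome("error", "not-found", self.path))
                return
            try:
                length = int(self.headers.get("Content-Length", 0))
                payload = json.loads(self.rfile.read(length) or b"{}")
            except json.JSONDecodeError as exc:
                self._send(400, operation_outcome("error", "invalid", f"bad JSON: {exc}"))
                return
            try:
                self._send(200, quality_check(payload, engine))
            except FHIRProtocolError as exc:
                self._send(422, exc.outcome)

        def _send(self, status: int, body: dict):
            data = json.dumps(body).encode()
            self.send_response(status)
            self.send_header("Content-Type", "application/fhir+json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def log_message(self, fmt, *args):  # record counts only, no clinical values
            pass

    return ThreadingHTTPServer((host, port), Handler)
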