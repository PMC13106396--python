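"""The AI Fairness Provenance Record (AFPR): a tamper-evident audit container.

An AFPR document bundles, as one schema-validated JSON object:

* ``data_provenance`` — how the cohort was produced (spec, seed, feature
  descriptions, demographic composition, known limitations);
* ``model_development`` — an ordered log of training/tuning decisions with
  configs, metrics and rationale;
* ``inference_log`` — per-prediction provenance entries, hash-chained so any
  alteration, reordering or deletion is detectable;
* ``audit`` — fairness reports, permutation results, CV summaries,
  counterfactual results and the sensitivity table.

Hash chain: each entry's ``entry_hash`` is SHA-256 over the previous entry's
hash concatenated with the canonical serialization of the entry's other
fields (UTF-8, lexicographically sorted keys, no insignificant whitespace,
shortest round-trip floats). The first entry chains from a genesis constant
of 64 zero hex characters. Patient references are salted SHA-256 hashes of
patient ids; the salt lives outside the document.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from typing import Callable, Optional

import pydantic
from pydantic import BaseModel, Field

__all__ = [
    "GENESIS_HASH",
    "AFPRDocument",
    "InferenceLogEntry",
    "DataProvenance",
    "DevelopmentLogEntry",
    "AuditSection",
    "canonical_json",
    "patient_reference",
    "append_entry",
    "verify_chain",
    "validate_document",
    "render_report",
    "afpr_schema",
    "severity_band",
]

GENESIS_HASH = "0" * 64

SCHEMA_VERSION = "1.0"


def canonical_json(obj) -> str:
    """Canonical serialization: sorted keys, compact separators, UTF-8."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def patient_reference(patient_id: str, salt: str) -> str:
    """Salted hash of a patient id (raw identifiers never enter the record)."""
    return _sha256(f"{salt}:{patient_id}")


class InferenceLogEntry(BaseModel):
    """One hash-chained per-prediction record."""

    sequence: int = Field(ge=1)
    entry_id: str
    timestamp: str
    model_version: str
    patient_ref: str
    payload: dict
    prev_hash: str = Field(pattern=r"^[0-9a-f]{64}$")
    entry_hash: str = Field(pattern=r"^[0-9a-f]{64}$")

    def compute_hash(self) -> str:
        body = self.model_dump(exclude={"entry_hash"})
        prev = body.pop("prev_hash")
        return _sha256(prev + canonical_json(body))


class DataProvenance(BaseModel):
    cohort_spec: dict
    seed: int
    feature_descriptions: dict[str, str]
    demographic_composition: dict
    known_limitations: list[str] = Field(default_factory=list)


class DevelopmentLogEntry(BaseModel):
    step: str
    timestamp: str
    config: dict
    metrics: dict = Field(default_factory=dict)
    rationale: str = ""


class AuditSection(BaseModel):
    """Audit results; optional blocks absent when a stage was not run."""

    fairness: dict[str, dict] = Field(default_factory=dict)
    permutation: dict[str, dict] = Field(default_factory=dict)
    cv: dict[str, dict] = Field(default_factory=dict)
    counterfactual: dict[str, dict] = Field(default_factory=dict)
    sensitivity: Optional[list[dict]] = None


class AFPRDocument(BaseModel):
    schema_version: str = SCHEMA_VERSION
    data_provenance: DataProvenance
    model_development: list[DevelopmentLogEntry] = Field(default_factory=list)
    inference_log: list[InferenceLogEntry] = Field(default_factory=list)
    audit: AuditSection
    chain_head: str = GENESIS_HASH
    complete: bool = True

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.model_dump(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AFPRDocument":
        return cls.model_validate(json.loads(text))


def _default_clock() -> datetime:
    return datetime.now(timezone.utc)


def append_entry(
    document: AFPRDocument,
    payload: dict,
    model_version: str,
    patient_ref: str,
    clock: Callable[[], datetime] = _default_clock,
) -> AFPRDocument:
    """Append one inference entry, extending the hash chain.

    Only the new entry's hashes are computed; earlier entries are untouched.
    A payload that is not a JSON-serializable mapping is rejected with the
    document unchanged.
    """
    if not isinstance(payload, dict):
        raise ValueError("payload must be a mapping")
    try:
        canonical_json(payload)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"payload is not JSON-serializable: {exc}") from exc
    prev = document.inference_log[-1].entry_hash if document.inference_log else GENESIS_HASH
    seq = len(document.inference_log) + 1
    entry = InferenceLogEntry(
        sequence=seq,
        entry_id=f"e{seq:06d}",
        timestamp=clock().isoformat(),
        model_version=model_version,
        patient_ref=patient_ref,
        payload=payload,
        prev_hash=prev,
        entry_hash=GENESIS_HASH,  # placeholder, replaced below
    )
    entry.entry_hash = entry.compute_hash()
    document.inference_log.append(entry)
    document.chain_head = entry.entry_hash
    return document


def verify_chain(document: AFPRDocument) -> tuple[bool, Optional[int]]:
    """Recompute every hash; return (ok, first inconsistent sequence number)."""
    prev = GENESIS_HASH
    for i, entry in enumerate(document.inference_log):
        if entry.sequence != i + 1:
            return False, i + 1
        if entry.prev_hash != prev or entry.compute_hash() != entry.entry_hash:
            return False, entry.sequence
        prev = entry.entry_hash
    if document.chain_head != prev:
        n = len(document.inference_log)
        return False, n if n else 0
    return True, None


def validate_document(document) -> list[str]:
    """Schema violations as ``json.path: message`` strings; empty iff valid."""
    if isinstance(document, AFPRDocument):
        document = document.model_dump()
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ValueError(f"unparseable document: {exc}") from exc
    try:
        AFPRDocument.model_validate(document)
    except pydantic.ValidationError as exc:
        return [
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        ]
    return []


def afpr_schema() -> dict:
    """The AFPR JSON Schema (draft form, generated from the models)."""
    return AFPRDocument.model_json_schema()


def severity_band(value: float) -> str:
    """Disparity severity band: low (<0.1), moderate (0.1-0.2), high (>0.2)."""
    v = abs(value)
    if v < 0.1:
        return "low"
    if v <= 0.2:
        return "moderate"
    return "high"


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _fmt(x, nd: int = 3) -> str:
    if x is None:
        return "undefined"
    if isinstance(x, bool):
        return "yes" if x else "no"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def render_report(document: AFPRDocument) -> str:
    """Deterministic Markdown fairness-audit report for a valid AFPR document.

    Numbers are rounded to 3 decimals for display only; the underlying
    document keeps full precision.
    """
    problems = validate_document(document)
    if problems:
        raise ValueError(f"document does not validate: {problems}")
    audit = document.audit
    if not (audit.fairness or audit.permutation or audit.cv
            or audit.counterfactual or audit.sensitivity):
        raise ValueError("document has an empty audit section; nothing to report")

    lines: list[str] = ["# Fairness Audit Report", ""]
    dp = document.data_provenance
    lines += [
        f"Schema version {document.schema_version}. Cohort seed {dp.seed}; "
        f"n = {dp.cohort_spec.get('n_patients', '?')} patients.",
        "",
    ]

    if audit.fairness:
        lines += ["## Group metrics and disparities", ""]
        for model_name in sorted(audit.fairness):
            rep = audit.fairness[model_name]
            lines += [f"### {model_name}", ""]
            lines += ["| group | n | selection rate | TPR | FPR |",
                      "|---|---|---|---|---|"]
            for glabel in sorted(rep.get("groups", {})):
                gm = rep["groups"][glabel]
                lines.append(
                    f"| {glabel} | {gm['n']} | {_fmt(gm['selection_rate'])} "
                    f"| {_fmt(gm['TPR'])} | {_fmt(gm['FPR'])} |"
                )
            dpd, eod = rep.get("DPD"), rep.get("EOD")
            perm = audit.permutation.get(model_name, {})
            sig = perm.get("significance", "")
            p = perm.get("p_value")
            lines += [
                "",
                f"DPD = {_fmt(dpd)} ({severity_band(dpd)}), "
                f"EOD = {_fmt(eod)} ({severity_band(eod)})"
                + (f", permutation p = {_fmt(p, 4)}{sig if sig != 'ns' else ' (ns)'}"
                   if p is not None else ""),
                "",
            ]

    if audit.cv:
        lines += ["## Cross-validated estimates (95% t intervals)", ""]
        lines += ["| model | metric | mean | SD | 95% CI |", "|---|---|---|---|---|"]
        for model_name in sorted(audit.cv):
            summary = audit.cv[model_name].get("summary", {})
            for metric in ("accuracy", "roc_auc", "dpd", "eod"):
                if metric in summary:
                    s = summary[metric]
                    lines.append(
                        f"| {model_name} | {metric} | {_fmt(s['mean'])} | {_fmt(s['sd'])} "
                        f"| [{_fmt(s['ci_low'])}, {_fmt(s['ci_high'])}] |"
                    )
        lines.append("")

    if audit.counterfactual:
        lines += ["## Counterfactual gender-flip analysis", ""]
        for model_name in sorted(audit.counterfactual):
            cf = audit.counterfactual[model_name]
            lines.append(
                f"- {model_name}: {cf['n_flipped']} of {cf['n_boundary']} boundary cases "
                f"(|p - {_fmt(cf['threshold'], 1)}| <= {_fmt(cf['margin'], 2)}) changed class "
                f"({_fmt(100 * cf['flip_fraction'], 1)}%)."
            )
        lines.append("")

    if audit.sensitivity:
        lines += ["## Bias-magnitude sensitivity sweep", ""]
        lines += ["| beta_true | learned coefficient | EOD | p | detected |",
                  "|---|---|---|---|---|"]
        for row in audit.sensitivity:
            lines.append(
                f"| {_fmt(row['beta_true'], 2)} | {_fmt(row['learned_coefficient'])} "
                f"| {_fmt(row['EOD'])} | {_fmt(row['p_value'], 4)} | {_fmt(row['detected'])} |"
            )
        lines.append("")

    if document.model_development:
        lines += ["## Model development timeline", ""]
        for e in document.model_development:
            metrics = ", ".join(f"{k}={_fmt(v)}" for k, v in sorted(e.metrics.items()))
            lines.append(f"- {e.timestamp} — {e.step}" + (f" ({metrics})" if metrics else "")
                         + (f": {e.rationale}" if e.rationale else ""))
        lines.append("")

    ok, bad = verify_chain(document)
    lines.append(
        f"Inference log: {len(document.inference_log)} entries; hash chain "
        + ("verified." if ok else f"BROKEN at entry {bad}.")
    )
    lines.append("")
    return "\n".join(lines)
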