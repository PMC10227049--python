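"""Keyword-driven extraction of HPLC records from plain-text reports.

Supporting-information sections of asymmetric-catalysis papers report
enantioseparations in a near-uniform format: a compound name anchored
by an (S)/(R) handedness marker, the verification word "HPLC", the
column, an eluent ratio like "98/02", a flow rate in mL/min, and two
retention times (major and minor enantiomer).  The parser locates each
field by configurable regular expressions and never raises on
malformed text — failures are encoded in the record status with
diagnostics, so a corpus sweep always completes.

Molecule-name resolution to SMILES is a pluggable dictionary lookup;
no network access is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ChirsepError, ContractError

_NUM = r"\d+(?:\.\d+)?"


@dataclass
class PatternTable:
    """Configurable extraction patterns; defaults cover the common dialect."""

    handedness: str = r"\(([SR])\)-([^\s,;:]+)"
    hplc_token: str = r"HPLC"
    column: str = (
        r"(?:Chiralpak|Chiralcel|Daicel)\s+([A-Z]{2}(?:-[A-Z0-9])?)"
        r"|\b(AD-H|OD-H|OJ-H|AS-H|IA|IB|IC|ID|IE|IF|IG)\b"
    )
    proportion: str = rf"({_NUM})\s*[/:]\s*({_NUM})"
    flow_rate: str = rf"({_NUM})\s*mL\s*/\s*min"
    retention: str = rf"(?:t\s*[Rr]\d*\s*=?\s*|retention\s+times?\s*(?:of|=)?\s*)({_NUM})\s*min"


@dataclass
class RawReport:
    text: str
    source_id: str = ""

    def __post_init__(self):
        if not self.text:
            raise ContractError("empty report text")


@dataclass
class ExtractedRecord:
    status: str                       # ok | dropped_no_hplc | dropped_malformed
    source_id: str = ""
    molecule_name: Optional[str] = None
    handedness: Optional[str] = None  # "S" | "R"
    column_name: Optional[str] = None
    proportion_text: Optional[str] = None
    proportion: Optional[float] = None
    flow_rate: Optional[float] = None
    rt_major: Optional[float] = None
    rt_minor: Optional[float] = None
    diagnostics: list[str] = field(default_factory=list)


def normalize_proportion(text: str, ndigits: int = 6) -> float:
    """Eluent ratio "A/B" → fraction of the minor component, B/(A+B).

    "98/02" → 0.02; order-insensitive inputs like "2/98" normalize to
    the same minor-component fraction.
    """
    m = re.fullmatch(rf"\s*({_NUM})\s*[/:]\s*({_NUM})\s*", text)
    if not m:
        raise ContractError(f"proportion text {text!r} does not match 'A/B'")
    a, b = float(m.group(1)), float(m.group(2))
    if a + b == 0:
        raise ContractError("proportion components sum to zero")
    return round(min(a, b) / (a + b), ndigits)


def _normalize_column(raw: str) -> str:
    return raw.replace("-", "").upper()


def parse_report(report: RawReport, patterns: Optional[PatternTable] = None) -> ExtractedRecord:
    """Extract one candidate record from one report.

    The (S)/(R) marker anchors the molecule name; a report without the
    token "HPLC" is dropped; any missing downstream field yields
    ``dropped_malformed`` naming the field.
    """
    pt = patterns or PatternTable()
    text = report.text
    rec = ExtractedRecord(status="ok", source_id=report.source_id)

    m = re.search(pt.handedness, text)
    if not m:
        rec.status = "dropped_malformed"
        rec.diagnostics.append("no (S)/(R) handedness marker found")
        return rec
    rec.handedness, rec.molecule_name = m.group(1), m.group(2)

    if not re.search(pt.hplc_token, text):
        rec.status = "dropped_no_hplc"
        rec.diagnostics.append("verification token 'HPLC' absent")
        return rec

    cm = re.search(pt.column, text)
    if cm:
        rec.column_name = _normalize_column(next(g for g in cm.groups() if g))
    else:
        rec.diagnostics.append("missing field: column")

    pm = re.search(pt.proportion, text)
    if pm:
        rec.proportion_text = pm.group(0)
        rec.proportion = normalize_proportion(f"{pm.group(1)}/{pm.group(2)}")
    else:
        rec.diagnostics.append("missing field: proportion")

    fm = re.search(pt.flow_rate, text)
    if fm:
        rec.flow_rate = float(fm.group(1))
    else:
        rec.diagnostics.append("missing field: flow_rate")

    rts = [float(x) for x in re.findall(pt.retention, text)]
    if len(rts) >= 2:
        rec.rt_major, rec.rt_minor = rts[0], rts[1]
    else:
        rec.diagnostics.append(f"missing field: retention times (found {len(rts)})")

    if rec.diagnostics:
        rec.status = "dropped_malformed"
    return rec


def parse_corpus(reports, patterns: Optional[PatternTable] = None) -> list[ExtractedRecord]:
    return [parse_report(r, patterns) for r in reports]


# -- name resolution -------------------------------------------------------


@dataclass
class Resolution:
    name: str
    smiles: Optional[str]

    @property
    def resolved(self) -> bool:
        return self.smiles is not None


def resolve_name(molecule_name: str, resolver: Mapping[str, str]) -> Resolution:
    """Resolve a molecule name to SMILES via an offline dictionary.

    ``resolver`` is any mapping (a dict, a shelve, an adapter wrapping a
    web service for users who accept network calls); a miss returns an
    unresolved status rather than raising.
    """
    try:
        smiles = resolver.get(molecule_name)
    except AttributeError:
        raise ContractError("resolver must be a mapping with .get")
    return Resolution(molecule_name, smiles)


def records_to_frame(records: list[ExtractedRecord]):
    """Tabulate extracted records (ok and dropped) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "status": r.status, "source_id": r.source_id,
                "molecule_name": r.molecule_name, "handedness": r.handedness,
                "column_name": r.column_name, "proportion_text": r.proportion_text,
                "proportion": r.proportion, "flow_rate": r.flow_rate,
                "rt_major": r.rt_major, "rt_minor": r.rt_minor,
                "diagnostics": "; ".join(r.diagnostics),
            }
            for r in records
        ]
    )
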