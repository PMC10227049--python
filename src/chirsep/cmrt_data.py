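"""Reading, filtering and consistency analysis of chiral retention-time tables.

The on-disk dialect is a plain CSV with one experimental observation
per row: SMILES, column name, elution proportion (fraction of the minor
mobile-phase component), flow rate (mL/min) and retention time (min),
plus optional handedness/pair/provenance bookkeeping.  A schema map
lets renamed headers be ingested.

The module also implements the target transformation RTv = RT × v
(retention time times flow rate, approximately flow-invariant by the
chromatographic process equation), the standard record filters, the
RTv-consistency statistic over repeated measurements at different flow
rates, and Tanimoto-similarity grouping of test molecules against a
training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

from .constants import RTV_MAX
from .errors import ContractError, SchemaError

CANONICAL_COLUMNS = (
    "smiles", "column_name", "elution_proportion", "flow_rate", "rt",
    "handedness_label", "pair_id", "source_id",
)
REQUIRED_COLUMNS = CANONICAL_COLUMNS[:5]
HANDEDNESS_LABELS = ("major", "minor", "unknown")


@dataclass
class MoleculeRecord:
    """One experimental observation: molecule + condition + retention time."""

    smiles: str
    column_name: str
    elution_proportion: float
    flow_rate: float
    rt: float
    handedness_label: str = "unknown"
    pair_id: Optional[str] = None
    source_id: Optional[str] = None
    unpaired: bool = False   # set when the enantiomer partner was filtered out

    def __post_init__(self):
        if self.rt <= 0 or self.flow_rate <= 0:
            raise ContractError(f"rt and flow_rate must be positive: {self}")
        if not 0.0 <= self.elution_proportion <= 1.0:
            raise ContractError(f"elution_proportion outside [0, 1]: {self}")
        if self.handedness_label not in HANDEDNESS_LABELS:
            raise ContractError(f"unknown handedness label {self.handedness_label!r}")

    @property
    def rtv(self) -> float:
        return rtv(self.rt, self.flow_rate)


@dataclass
class ChromEquationParams:
    """Symbols of the chromatographic process equation.

    RT = t0·(1 + K·Vs/Vm) ≈ (Vm + K·Vs)/v.  The pipeline never fits
    these individually; the type documents the model behind the RTv
    target.
    """

    t0: float
    K: float
    Vm: float
    Vs: float


@dataclass
class LoadResult:
    records: list[MoleculeRecord]
    rejects: pd.DataFrame

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def rtv(rt: float, flow_rate: float) -> float:
    """RTv = RT × v, in min·mL/min; the flow-invariant prediction target."""
    if rt <= 0 or flow_rate <= 0:
        raise ContractError(f"rt and flow_rate must be positive, got rt={rt}, v={flow_rate}")
    return rt * flow_rate


def _normalize_proportion_cell(value) -> float:
    if isinstance(value, str) and "/" in value:
        from .report_extraction import normalize_proportion

        return normalize_proportion(value)
    return float(value)


def load_cmrt(path, schema_map: Optional[dict[str, str]] = None) -> LoadResult:
    """Load a CMRT-dialect CSV.

    ``schema_map`` maps canonical names to the file's headers.  Rows
    violating record invariants go to ``rejects`` with a reason instead
    of being silently dropped.
    """
    df = pd.read_csv(path, dtype={"pair_id": str, "source_id": str})
    if schema_map:
        df = df.rename(columns={v: k for k, v in schema_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[MoleculeRecord] = []
    reject_rows = []
    for idx, row in df.iterrows():
        try:
            records.append(
                MoleculeRecord(
                    smiles=str(row["smiles"]),
                    column_name=str(row["column_name"]),
                    elution_proportion=_normalize_proportion_cell(row["elution_proportion"]),
                    flow_rate=float(row["flow_rate"]),
                    rt=float(row["rt"]),
                    handedness_label=str(row.get("handedness_label", "unknown") or "unknown"),
                    pair_id=(None if pd.isna(row.get("pair_id")) else str(row.get("pair_id"))),
                    source_id=(None if pd.isna(row.get("source_id")) else str(row.get("source_id"))),
                )
            )
        except (ContractError, ValueError) as exc:
            reject_rows.append({**row.to_dict(), "row": idx, "reason": str(exc)})
    rejects = pd.DataFrame(reject_rows)
    return LoadResult(records, rejects)


def write_cmrt(records: Sequence[MoleculeRecord], path) -> None:
    """Write records in the canonical dialect (lossless round-trip)."""
    cols = [f.name for f in dc_fields(MoleculeRecord) if f.name != "unpaired"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    df.to_csv(path, index=False)


# -- filters ---------------------------------------------------------------


def count_assigned_stereocenters(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return -1
    return len(Chem.FindMolChiralCenters(mol, includeUnassigned=False))


@dataclass
class FilterResult:
    kept: list[MoleculeRecord]
    removed: list[tuple[MoleculeRecord, str]]

    @property
    def flagged_unpaired(self) -> list[MoleculeRecord]:
        return [r for r in self.kept if r.unpaired]


def filter_records(
    records: Sequence[MoleculeRecord],
    rtv_max: float = RTV_MAX,
    max_stereocenters: int = 1,
) -> FilterResult:
    """Apply the standard record filters.

    Removes records with RTv strictly greater than ``rtv_max`` and
    molecules with more than ``max_stereocenters`` assigned
    stereocenters (default 1, matching the two-reported-retention-times
    pairing assumption of auto-extracted data; raise to 2 for the looser
    reading).  When one member of an enantiomer pair is removed, the
    surviving partner is flagged ``unpaired`` rather than dropped.
    """
    kept, removed = [], []
    for rec in records:
        if rec.rtv > rtv_max:
            removed.append((rec, f"RTv {rec.rtv:.3g} > {rtv_max:g}"))
            continue
        n_centers = count_assigned_stereocenters(rec.smiles)
        if n_centers < 0:
            removed.append((rec, "unparseable SMILES"))
            continue
        if n_centers > max_stereocenters:
            removed.append((rec, f"{n_centers} stereocenters > bound {max_stereocenters}"))
            continue
        kept.append(rec)
    removed_pairs = {r.pair_id for r, _ in removed if r.pair_id is not None}
    for rec in kept:
        if rec.pair_id in removed_pairs:
            rec.unpaired = True
    return FilterResult(kept, removed)


# -- chromatographic-equation consistency ----------------------------------


@dataclass
class ChromEquationSummary:
    n_groups: int
    errors: np.ndarray   # all pairwise |RTv_i - RTv_j| across qualifying groups
    median: float


def chrom_equation_error(
    records: Sequence[MoleculeRecord],
    flow_range: tuple[float, float] = (0.3, 1.0),
    rt_range: tuple[float, float] = (3.5, 60.0),
) -> ChromEquationSummary:
    """RTv consistency across repeated measurements at different flow rates.

    Records are grouped by (canonical SMILES, column, proportion); a
    group qualifies if it contains at least two measurements at distinct
    flow rates, all within ``flow_range`` and ``rt_range``.  Within each
    qualifying group every pairwise absolute RTv difference is an error
    sample; the flow-invariance of RTv predicts zero.
    """
    groups: dict[tuple, list[MoleculeRecord]] = {}
    for rec in records:
        if not (flow_range[0] <= rec.flow_rate <= flow_range[1]):
            continue
        if not (rt_range[0] <= rec.rt <= rt_range[1]):
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        smi = Chem.MolToSmiles(mol) if mol is not None else rec.smiles
        key = (smi, rec.column_name, round(rec.elution_proportion, 6))
        groups.setdefault(key, []).append(rec)
    errors = []
    n_groups = 0
    for recs in groups.values():
        flows = {r.flow_rate for r in recs}
        if len(recs) < 2 or len(flows) < 2:
            continue
        n_groups += 1
        vals = [r.rtv for r in recs]
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                errors.append(abs(vals[i] - vals[j]))
    if not errors:
        warnings.warn("no qualifying repeated-measurement groups found")
        return ChromEquationSummary(0, np.array([]), float("nan"))
    arr = np.array(sorted(errors))
    return ChromEquationSummary(n_groups, arr, float(np.median(arr)))


# -- similarity grouping ---------------------------------------------------


def _fingerprints(smiles_list: Sequence[str], kind: str):
    if kind == "morgan":
        gen = GetMorganGenerator(radius=2, fpSize=2048)
        fn = gen.GetFingerprint
    elif kind == "maccs":
        fn = MACCSkeys.GenMACCSKeys
    else:
        raise ContractError(f"unknown fingerprint kind {kind!r}")
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ContractError(f"unparseable SMILES in similarity grouping: {smi!r}")
        fps.append(fn(mol))
    return fps


@dataclass
class SimilarityGroups:
    fingerprint: str
    thresholds: tuple[float, ...]
    # threshold -> indices of test records with >= 1 training neighbor at
    # that similarity level or above
    members: dict[float, list[int]] = field(default_factory=dict)

    def sizes(self) -> dict[float, int]:
        return {t: len(v) for t, v in self.members.items()}


def similarity_groups(
    test_records: Sequence[MoleculeRecord],
    train_records: Sequence[MoleculeRecord],
    thresholds: Sequence[float] = (95, 90, 80, 70, 60, 50),
    fingerprint: str = "morgan",
) -> SimilarityGroups:
    """Group test molecules by their maximum Tanimoto similarity to training.

    Thresholds are percentages.  Groups are nested: lowering the
    threshold never removes a member.
    """
    if not test_records or not train_records:
        raise ContractError("similarity grouping needs nonempty test and train sets")
    test_fps = _fingerprints([r.smiles for r in test_records], fingerprint)
    train_fps = _fingerprints([r.smiles for r in train_records], fingerprint)
    max_sim = np.array(
        [max(DataStructs.BulkTanimotoSimilarity(fp, train_fps)) for fp in test_fps]
    )
    out = SimilarityGroups(fingerprint, tuple(float(t) for t in thresholds))
    for t in out.thresholds:
        out.members[t] = list(np.nonzero(max_sim * 100.0 >= t)[0])
    return out
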