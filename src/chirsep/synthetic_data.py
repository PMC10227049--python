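"""Synthetic chiral retention datasets with known ground truth.

The generator emits CMRT-dialect records for enantiomer pairs drawn
from a shipped library of ~50 small chiral scaffolds (α-substituted
acids, alcohols and amines, each with exactly one assigned
stereocenter; the mirror image is obtained by inverting the chiral
tag).  The true target is constructed on the flow-invariant RTv scale:

    RTv = base(descriptors) + column_effect + proportion_effect + s·δ

where ``base`` is a fixed linear function of the five z-scored
molecular descriptors, ``column_effect`` depends on the column's
substrate, connection type and packing size, ``proportion_effect``
makes stronger eluents elute faster, and ``s = ±1`` by handedness with
chirality offset δ.  The truth is clipped at the dead-time bound of 2
min·mL/min, retention time is RT = RTv/v, and measurement noise enters
as ``ŷ = y + ε·std(y)·N(0, 1)``.

This emulates the statistical structure a retention model assumes —
flow-invariant RTv, an enantiomer-dependent offset, column- and
eluent-dependent retention — not the physics of real chromatography.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_graphs import ColumnSpec, compute_descriptors, load_column_registry
from .cmrt_data import MoleculeRecord
from .constants import DEADTIME_RTV
from .errors import ContractError

# base(.) coefficients on z-scored descriptors [tpsa, rpsa, rasa, medc, mats]
BASE_INTERCEPT = 22.0
BASE_COEFFS = np.array([3.0, 2.0, 2.0, -1.5, 1.0])
PROPORTION_SLOPE = -8.0    # RTv change per unit minor-component fraction, about 0.1
PROPORTION_CENTER = 0.1


@dataclass
class SynthConfig:
    n_pairs: int = 100
    columns: Sequence[str] = ("ADH", "ODH", "IC", "IA")
    seed: int = 0
    chirality_effect: float = 1.5          # δ, min·mL/min
    noise_eps: float = 0.1                 # ε of the noise model
    flow_rate_range: tuple[float, float] = (0.5, 1.0)
    proportion_range: tuple[float, float] = (0.02, 0.2)

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ContractError("n_pairs must be >= 1")
        if self.noise_eps < 0:
            raise ContractError("noise_eps must be >= 0")


@dataclass
class GroundTruth:
    """Per-record generating terms, aligned with the emitted records."""

    true_rtv: np.ndarray
    base_term: np.ndarray
    column_term: np.ndarray
    proportion_term: np.ndarray
    handedness_term: np.ndarray
    noise: np.ndarray            # observed RTv - true RTv
    noise_sd: float              # ε·std(true RTv); 10-90 band half-width / 1.2816

    def to_json(self, path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def load_scaffolds() -> list[tuple[str, str]]:
    """The shipped chiral scaffold library as (smiles, name) pairs."""
    ref = importlib.resources.files("chirsep") / "data" / "scaffolds.smi"
    out = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi, name = line.split()
        out.append((smi, name))
    if not out:
        raise ContractError("empty scaffold library")
    return out


def mirror_smiles(smiles: str) -> str:
    """Invert the single chiral tag, yielding the enantiomer."""
    if smiles.count("[C@H]") + smiles.count("[C@@H]") != 1:
        raise ContractError(f"scaffold must have exactly one chiral tag: {smiles!r}")
    if "[C@@H]" in smiles:
        return smiles.replace("[C@@H]", "[C@H]")
    return smiles.replace("[C@H]", "[C@@H]")


def add_noise(y, eps: float, seed: int) -> np.ndarray:
    """Measurement-noise model ``ŷ = y + ε·std(y)·N(0, 1)``."""
    y = np.asarray(y, float)
    if eps < 0:
        raise ContractError("eps must be >= 0")
    if y.size < 2:
        raise ContractError("need at least 2 values for std(y)")
    if eps == 0:
        return y.copy()
    rng = np.random.default_rng(seed)
    return y + eps * y.std() * rng.standard_normal(y.size)


def _column_effect(col: ColumnSpec) -> float:
    return (
        3.0 * col.substrate_code
        + 2.0 * col.connection_code
        + 0.5 * (col.packing_size - 5.0)
    )


class SyntheticGenerator:
    """Deterministic CMRT-dataset generator with analytic ground truth."""

    def __init__(self, config: SynthConfig, registry: Optional[dict] = None):
        self.config = config
        self.registry = registry or load_column_registry()
        for name in config.columns:
            if name not in self.registry:
                raise ContractError(f"unknown column {name!r} in SynthConfig")
        self.scaffolds = load_scaffolds()
        # z-score statistics of the descriptor matrix over the library
        desc = np.array([compute_descriptors(s).as_array() for s, _ in self.scaffolds])
        self._desc_mean = desc.mean(axis=0)
        self._desc_std = np.where(desc.std(axis=0) < 1e-8, 1.0, desc.std(axis=0))
        self._desc = {s: d for (s, _), d in zip(self.scaffolds, desc)}

    def base_rtv(self, smiles: str) -> float:
        """The descriptor-driven component of the true RTv."""
        d = self._desc.get(smiles)
        if d is None:
            d = compute_descriptors(smiles).as_array()
        z = (d - self._desc_mean) / self._desc_std
        return float(BASE_INTERCEPT + BASE_COEFFS @ z)

    def true_rtv(
        self, smiles: str, column: ColumnSpec, proportion: float, handedness_sign: int
    ) -> float:
        val = (
            self.base_rtv(smiles)
            + _column_effect(column)
            + PROPORTION_SLOPE * (proportion - PROPORTION_CENTER)
            + handedness_sign * self.config.chirality_effect
        )
        return max(val, DEADTIME_RTV)

    def generate(self) -> tuple[list[MoleculeRecord], GroundTruth]:
        """Emit ``2·n_pairs`` records (both enantiomers of every pair)."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        rows = []
        base_t, col_t, prop_t, hand_t, true_vals = [], [], [], [], []
        for i in range(cfg.n_pairs):
            smi_parent, _name = self.scaffolds[rng.integers(len(self.scaffolds))]
            column = self.registry[cfg.columns[rng.integers(len(cfg.columns))]]
            proportion = round(float(rng.uniform(*cfg.proportion_range)), 4)
            flow = round(float(rng.uniform(*cfg.flow_rate_range)), 2)
            for handedness, sign, smi in (
                ("major", +1, smi_parent),
                ("minor", -1, mirror_smiles(smi_parent)),
            ):
                base = self.base_rtv(smi_parent)
                ceff = _column_effect(column)
                peff = PROPORTION_SLOPE * (proportion - PROPORTION_CENTER)
                heff = sign * cfg.chirality_effect
                truth = max(base + ceff + peff + heff, DEADTIME_RTV)
                rows.append(
                    dict(
                        smiles=smi, column_name=column.name,
                        elution_proportion=proportion, flow_rate=flow,
                        handedness_label=handedness, pair_id=f"pair{i:05d}",
                        source_id="synthetic",
                    )
                )
                base_t.append(base)
                col_t.append(ceff)
                prop_t.append(peff)
                hand_t.append(heff)
                true_vals.append(truth)
        true_rtv = np.array(true_vals)
        observed_rtv = add_noise(true_rtv, cfg.noise_eps, seed=cfg.seed + 1)
        observed_rtv = np.maximum(observed_rtv, 0.1)  # keep rt > 0 under extreme noise
        records = [
            MoleculeRecord(rt=obs / row["flow_rate"], **row)
            for row, obs in zip(rows, observed_rtv)
        ]
        truth = GroundTruth(
            true_rtv=true_rtv,
            base_term=np.array(base_t),
            column_term=np.array(col_t),
            proportion_term=np.array(prop_t),
            handedness_term=np.array(hand_t),
            noise=observed_rtv - true_rtv,
            noise_sd=float(cfg.noise_eps * true_rtv.std()),
        )
        return records, truth


def generate(config: SynthConfig, registry: Optional[dict] = None):
    """Functional entry point: ``generate(config) -> (records, truth)``."""
    return SyntheticGenerator(config, registry).generate()
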