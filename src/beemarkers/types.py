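"""Core data containers shared across the pipeline.

The containers mirror the stages of a triplex (light/medium/heavy dimethyl
labeling) quantitative-proteomics experiment on honey-bee colonies scored
for hygienic behavior (HB): colony phenotype records, the incomplete block
design mapping colony replicates to labeled slots, the protein x (block,
label) quantification matrix, per-protein association results, marker
ranking scores, and fluorescence titration curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: The three isotopic labels of a triplex dimethyl block, in canonical order.
LABELS: tuple[str, str, str] = ("light", "medium", "heavy")

#: The four freeze-killed-brood field phenotypes (removed/uncapped at 24/48 h).
HB_VARIABLES: tuple[str, str, str, str] = ("r24", "r48", "u24", "u48")


@dataclass
class ColonyRecord:
    """One honey-bee colony with its field phenotypes and pedigree links.

    ``r24``/``r48`` are the proportions of freeze-killed brood cells removed
    at 24/48 h; ``u24``/``u48`` the proportions uncapped.  A cell must be
    uncapped before its pupa can be removed, so ``u24 >= r24`` and
    ``u48 >= r48``; removal only accumulates, so ``r48 >= r24``.
    ``hb_true`` is the latent hygienic propensity the phenotypes estimate.
    """

    colony_id: str
    site: str
    year: str
    population: str
    hb_true: float
    r24: float
    r48: float
    u24: float
    u48: float
    dam_id: Optional[str] = None
    sire_id: Optional[str] = None

    def validate(self) -> None:
        for name in HB_VARIABLES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.colony_id}: {name}={v} outside [0, 1]")
        if not 0.0 <= self.hb_true <= 1.0:
            raise ValueError(f"{self.colony_id}: hb_true outside [0, 1]")
        if self.u24 < self.r24 or self.u48 < self.r48:
            raise ValueError(
                f"{self.colony_id}: removed exceeds uncapped (u24={self.u24}, "
                f"r24={self.r24}, u48={self.u48}, r48={self.r48})"
            )
        if self.r48 < self.r24:
            raise ValueError(f"{self.colony_id}: r48={self.r48} < r24={self.r24}")


def colonies_to_frame(colonies: Sequence[ColonyRecord]) -> pd.DataFrame:
    """Tabulate colony records (one row per colony, colony_id index)."""
    rows = [
        {
            "colony_id": c.colony_id,
            "site": c.site,
            "year": c.year,
            "population": c.population,
            "hb_true": c.hb_true,
            "r24": c.r24,
            "r48": c.r48,
            "u24": c.u24,
            "u48": c.u48,
            "dam_id": c.dam_id,
            "sire_id": c.sire_id,
        }
        for c in colonies
    ]
    return pd.DataFrame(rows).set_index("colony_id", drop=False)


@dataclass(frozen=True)
class BlockSlot:
    """One labeled sample slot in a triplex block."""

    colony_id: str
    replicate: int  # 0, 1, 2
    label: str  # one of LABELS


@dataclass
class BlockAssignment:
    """Assignment of colony replicate samples to triplex blocks.

    Each block holds exactly three slots carrying the three distinct isotopic
    labels; each colony contributes three replicate samples, one per label,
    spread over three different blocks, and never shares a block with another
    colony from the same population.
    """

    blocks: list[list[BlockSlot]]
    objective_value: float = float("nan")
    seed: Optional[int] = None

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_ids(self) -> list[str]:
        return [f"B{i:03d}" for i in range(self.n_blocks)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, block in enumerate(self.blocks):
            for s, slot in enumerate(block):
                rows.append(
                    {
                        "block_id": f"B{b:03d}",
                        "slot": s,
                        "colony_id": slot.colony_id,
                        "replicate": slot.replicate,
                        "label": slot.label,
                    }
                )
        return pd.DataFrame(rows)

    def colony_of(self, block_id: str, label: str) -> str:
        """Colony occupying the (block, label) cell."""
        b = int(block_id[1:])
        for slot in self.blocks[b]:
            if slot.label == label:
                return slot.colony_id
        raise KeyError(f"no slot with label {label!r} in block {block_id}")


#: Allowed processing states of a QuantMatrix, in pipeline order.
QUANT_STATES = ("raw", "log", "block_centered", "standardized")


class QuantMatrixError(ValueError):
    pass


@dataclass
class QuantMatrix:
    """Protein x (block, label) intensity matrix with a processing state.

    ``values`` is indexed by protein-group id with a (block, label)
    MultiIndex over columns; NaN marks a missing cell.  ``state`` advances
    monotonically through ``raw -> log -> block_centered -> standardized``
    and ``provenance`` records every transformation applied.
    """

    values: pd.DataFrame
    state: str = "raw"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in QUANT_STATES:
            raise QuantMatrixError(f"unknown state {self.state!r}")
        if self.values.columns.nlevels != 2:
            raise QuantMatrixError("columns must be a (block, label) MultiIndex")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def blocks(self) -> list:
        return list(self.values.columns.get_level_values(0).unique())

    def advance_state(self, new_state: str) -> None:
        """Move to a later processing state; backwards moves are refused."""
        if QUANT_STATES.index(new_state) <= QUANT_STATES.index(self.state):
            raise QuantMatrixError(
                f"cannot move from state {self.state!r} to {new_state!r}"
            )
        self.state = new_state

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.state, list(self.provenance))

    def presence_by_block(self) -> pd.DataFrame:
        """Boolean protein x block table: any label observed in the block."""
        present = self.values.notna()
        return present.T.groupby(level=0).any().T

    def to_long(self) -> pd.DataFrame:
        """Long-format (protein, block, label, intensity) table, missing rows dropped."""
        long = self.values.stack([0, 1], future_stack=True).rename("intensity")
        long = long.dropna().reset_index()
        long.columns = ["protein", "block", "label", "intensity"]
        return long


@dataclass
class AssociationResult:
    """Per-protein slope of a colony-level predictor on standardized expression."""

    protein_id: str
    predictor: str
    effect: float
    se: float
    p_value: float
    q_value: float = float("nan")
    n_obs: int = 0
    converged: bool = False
    fit_notes: str = ""

    def validate(self) -> None:
        if self.converged and not (np.isnan(self.se) or self.se > 0):
            raise ValueError(f"{self.protein_id}: converged fit with se <= 0")
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"{self.protein_id}: p_value outside [0, 1]")


@dataclass
class HeritabilityFit:
    """Midparent regression of F1 daughter expression on dam and sire levels."""

    protein_id: str
    slope_dam: float
    slope_sire: float
    joint_p: float
    n_trios: int


@dataclass
class MarkerScore:
    """Cross-dataset HB correlation score for one protein."""

    protein_id: str
    per_dataset_factor: dict[str, float]
    n_datasets_quantified: int
    heritability_factor: float
    correlation_score: float
    selected: bool = False
    selection_rules_hit: list[str] = field(default_factory=list)


@dataclass
class TitrationCurve:
    """Fluorescence titration of a protein with a ligand.

    In ``saturation`` mode the titrated ligand is the fluorescent probe
    itself; in ``competition`` mode a fixed probe concentration is displaced
    by increasing competitor, and the first point should carry competitor 0.
    """

    protein_conc: float  # uM total
    points: list[tuple[float, float]]  # (ligand_total uM, fluorescence AU)
    mode: str = "saturation"  # "saturation" | "competition"
    probe_conc: float = float("nan")  # uM total probe, competition mode
    ligand_name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("saturation", "competition"):
            raise ValueError(f"unknown titration mode {self.mode!r}")
        concs = [c for c, _ in self.points]
        if any(c < 0 for c in concs):
            raise ValueError("negative ligand concentration")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("ligand concentrations must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def fluorescence(self) -> np.ndarray:
        return np.array([f for _, f in self.points], dtype=float)


@dataclass
class BindingResult:
    """Binding constants estimated from titration data."""

    k_probe: float = float("nan")  # uM, probe (1-NPN) dissociation constant
    ic50: float = float("nan")  # uM
    k_d: float = float("nan")  # uM, competitor dissociation constant
    fit_r2: float = float("nan")
    censored: bool = False  # IC50 not reached within tested range
    method_notes: str = ""
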