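"""Readers and writers for the pipeline's plain-text table formats.

Colony phenotypes travel as CSV; designs, PSMs, quantification matrices and
association results as TSV; titrations as CSV with a ``# key: value``
header block; ground-truth sidecars as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .synthetic_data import GroundTruth, MissingnessModel
from .types import (
    LABELS,
    BlockAssignment,
    BlockSlot,
    ColonyRecord,
    QuantMatrix,
    TitrationCurve,
    colonies_to_frame,
)

PathLike = Union[str, Path]

_COLONY_COLUMNS = [
    "colony_id", "site", "year", "population", "dam_id", "sire_id",
    "hb_true", "r24", "r48", "u24", "u48",
]


def write_colonies(colonies: Sequence[ColonyRecord], path: PathLike) -> None:
    df = colonies_to_frame(colonies)[_COLONY_COLUMNS]
    df.to_csv(path, index=False)


def read_colonies(path: PathLike) -> list[ColonyRecord]:
    df = pd.read_csv(path, dtype={"colony_id": str, "dam_id": str, "sire_id": str})
    out = []
    for _, r in df.iterrows():
        rec = ColonyRecord(
            colony_id=str(r["colony_id"]),
            site=str(r["site"]),
            year=str(r["year"]),
            population=str(r["population"]),
            hb_true=float(r.get("hb_true", np.nan)),
            r24=float(r["r24"]),
            r48=float(r["r48"]),
            u24=float(r["u24"]),
            u48=float(r["u48"]),
            dam_id=None if pd.isna(r.get("dam_id")) else str(r["dam_id"]),
            sire_id=None if pd.isna(r.get("sire_id")) else str(r["sire_id"]),
        )
        out.append(rec)
    return out


def write_design(assignment: BlockAssignment, path: PathLike) -> None:
    assignment.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: PathLike) -> BlockAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"colony_id": str})
    blocks: list[list[BlockSlot]] = []
    for _, grp in df.groupby("block_id", sort=True):
        grp = grp.sort_values("slot")
        blocks.append(
            [
                BlockSlot(str(r["colony_id"]), int(r["replicate"]), str(r["label"]))
                for _, r in grp.iterrows()
            ]
        )
    return BlockAssignment(blocks=blocks)


def write_quant_matrix(matrix: QuantMatrix, path: PathLike) -> None:
    """Long-format TSV: protein, block, label, intensity (missing cells omitted)."""
    matrix.to_long().to_csv(path, sep="\t", index=False)


def read_quant_matrix(path: PathLike, state: str = "raw") -> QuantMatrix:
    long = pd.read_csv(path, sep="\t", dtype={"protein": str, "block": str, "label": str})
    wide = long.pivot_table(
        index="protein", columns=["block", "label"], values="intensity", aggfunc="first"
    )
    # ensure every block carries all three label columns, missing as NaN
    blocks = sorted(wide.columns.get_level_values(0).unique())
    full = pd.MultiIndex.from_tuples(
        [(b, lab) for b in blocks for lab in LABELS], names=["block", "label"]
    )
    wide = wide.reindex(columns=full)
    wide.index.name = "protein"
    return QuantMatrix(values=wide, state=state, provenance=[f"read from {path}"])


def write_psms(psms: pd.DataFrame, path: PathLike) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psms(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protein_ids": str, "block": str})


def write_titration(curve: TitrationCurve, path: PathLike) -> None:
    """CSV with a '#'-prefixed header block followed by concentration/fluorescence."""
    with open(path, "w") as fh:
        fh.write(f"# mode: {curve.mode}\n")
        fh.write(f"# protein_conc_uM: {curve.protein_conc!r}\n")
        fh.write(f"# probe_conc_uM: {curve.probe_conc!r}\n")
        fh.write(f"# ligand: {curve.ligand_name}\n")
        fh.write("concentration_uM,fluorescence\n")
        for c, f in curve.points:
            fh.write(f"{c!r},{f!r}\n")


def read_titration(path: PathLike) -> TitrationCurve:
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            elif not line[0].isalpha():
                c, f = line.split(",")
                rows.append((float(c), float(f)))
    return TitrationCurve(
        protein_conc=float(meta.get("protein_conc_uM", "nan")),
        points=rows,
        mode=meta.get("mode", "saturation"),
        probe_conc=float(meta.get("probe_conc_uM", "nan")),
        ligand_name=meta.get("ligand", ""),
    )


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload = {
        "protein_ids": truth.protein_ids,
        "marker_ids": sorted(truth.marker_ids),
        "beta": truth.beta,
        "h2": truth.h2,
        "baselines": truth.baselines,
        "pop_effects": {f"{p}|{q}": v for (p, q), v in truth.pop_effects.items()},
        "sigma_colony": truth.sigma_colony,
        "sigma_resid": truth.sigma_resid,
        "sigma_block": truth.sigma_block,
        "sigma_label": truth.sigma_label,
        "missing_model": {
            "mnar_intercept": truth.missing_model.mnar_intercept,
            "mnar_slope": truth.missing_model.mnar_slope,
            "mcar_rate": truth.missing_model.mcar_rate,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: PathLike) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    mm = d["missing_model"]
    return GroundTruth(
        protein_ids=list(d["protein_ids"]),
        marker_ids=set(d["marker_ids"]),
        beta=d["beta"],
        h2=d["h2"],
        baselines=d["baselines"],
        pop_effects={
            (k.split("|")[0], k.split("|")[1]): v for k, v in d["pop_effects"].items()
        },
        sigma_colony=d["sigma_colony"],
        sigma_resid=d["sigma_resid"],
        sigma_block=d["sigma_block"],
        sigma_label=d["sigma_label"],
        missing_model=MissingnessModel(
            mnar_intercept=mm["mnar_intercept"],
            mnar_slope=mm["mnar_slope"],
            mcar_rate=mm["mcar_rate"],
        ),
    )


def write_association_results(results: pd.DataFrame, path: PathLike) -> None:
    results.to_csv(path, sep="\t")


def read_association_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein")
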