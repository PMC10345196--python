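"""Assemble the per-variant feature table for the classifier.

Ingests precomputed substitution score matrices:

* ddG — predicted change in folding stability (Rosetta-style; raw Rosetta
  energy units are divided by 2.9 to approximate kcal/mol and then clamped to
  [0, 5] kcal/mol),
* ddE — evolutionary conservation score from an MSA-based model (GEMME-style;
  0 = conservative substitution, -7 = incompatible with the family),

computes per-position residue averages, flanking-neighbour averages, joins the
target amino acid's hydrophobicity and the structural weighted contact number,
and emits one row per substitution carrying the eight classifier features.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy index (default hydrophobicity scale).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Classifier feature columns, in the fixed model order.
FEATURE_NAMES = (
    "ddG_variant",
    "ddE_variant",
    "ddG_residue_avg",
    "ddE_residue_avg",
    "ddG_neighbour_avg",
    "ddE_neighbour_avg",
    "hydrophobicity_target",
    "wcn",
)

_VARIANT_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


@dataclass
class ScoreMatrix:
    """Position x 20-amino-acid substitution score matrix.

    ``values`` is indexed by 1-based sequence position with one column per
    canonical amino acid (NaN = unavailable); ``wt`` maps position to the
    wild-type residue.  Wild-type self-substitutions are stored as NaN and
    excluded from averages.
    """

    kind: str                     # "ddG" or "ddE"
    values: pd.DataFrame
    wt: pd.Series
    provenance: str = "unknown"   # rosetta_raw | kcal_mol | rasp | gemme

    def __post_init__(self) -> None:
        if self.kind not in ("ddG", "ddE"):
            raise ValueError(f"kind must be 'ddG' or 'ddE', got {self.kind!r}")
        bad = [c for c in self.values.columns if c not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"non-canonical amino-acid columns: {bad}")
        self.values = self.values.reindex(columns=list(AMINO_ACIDS)).sort_index()
        self.values.index = self.values.index.astype(int)
        self.wt = self.wt.astype(str).sort_index()
        # blank out wild-type self-substitutions: no substitution signal
        for pos, aa in self.wt.items():
            if pos in self.values.index and aa in self.values.columns:
                self.values.loc[pos, aa] = np.nan
        if self.kind == "ddE":
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and ((finite > 0.05).any() or (finite < -7.05).any()):
                warnings.warn(
                    "ddE values outside the expected [-7, 0] range", stacklevel=2
                )

    @property
    def positions(self) -> list[int]:
        return [int(p) for p in self.values.index]

    def value(self, position: int, target_aa: str) -> float:
        try:
            return float(self.values.at[position, target_aa])
        except KeyError:
            return float("nan")

    def residue_average(self, position: int) -> float:
        """Mean over available substitution values at ``position``."""
        if position not in self.values.index:
            return float("nan")
        row = self.values.loc[position]
        return float(row.mean()) if row.notna().any() else float("nan")

    def neighbour_average(self, position: int) -> float:
        """Mean of substitution values pooled from positions i-1 and i+1.

        At a terminus the single existing neighbour is used; NaN when neither
        flanking position has values.
        """
        pool: list[np.ndarray] = []
        for nb in (position - 1, position + 1):
            if nb in self.values.index:
                vals = self.values.loc[nb].dropna().to_numpy()
                if vals.size:
                    pool.append(vals)
        if not pool:
            return float("nan")
        return float(np.concatenate(pool).mean())


def read_long_csv(path, kind: str, provenance: str = "unknown") -> ScoreMatrix:
    """Read a long-form CSV with header ``position,wt,mut,score``."""
    df = pd.read_csv(path, comment="#")
    required = {"position", "wt", "mut", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"long-form CSV needs columns {sorted(required)}")
    return _from_long(df, kind, provenance)


def _from_long(df: pd.DataFrame, kind: str, provenance: str) -> ScoreMatrix:
    wt = (
        df.drop_duplicates("position").set_index("position")["wt"].sort_index()
    )
    conflicts = df.groupby("position")["wt"].nunique()
    if (conflicts > 1).any():
        raise ValueError(
            f"conflicting wild-type annotations at positions "
            f"{conflicts[conflicts > 1].index.tolist()}"
        )
    values = df.pivot_table(
        index="position", columns="mut", values="score", aggfunc="mean"
    )
    return ScoreMatrix(kind=kind, values=values, wt=wt, provenance=provenance)


def read_matrix_tsv(
    path, kind: str, wt_sequence: str, provenance: str = "unknown"
) -> ScoreMatrix:
    """Read a GEMME-style matrix TSV (rows = amino acids, columns = positions).

    Orientation is auto-detected from the shape (the 20-long axis is the
    amino-acid axis) and the wild-type sequence is used to label positions
    1..L.
    """
    df = pd.read_csv(path, sep=r"\s+", index_col=0, comment="#")
    if df.shape[0] != 20 and df.shape[1] == 20:
        df = df.T
    if df.shape[0] != 20:
        raise ValueError(f"expected a 20-row amino-acid axis, got shape {df.shape}")
    df.index = [str(a).upper() for a in df.index]
    if sorted(df.index) != sorted(AMINO_ACIDS):
        raise ValueError("amino-acid axis does not contain the 20 canonical codes")
    if df.shape[1] != len(wt_sequence):
        raise ValueError(
            f"matrix has {df.shape[1]} positions but wt_sequence has "
            f"{len(wt_sequence)}"
        )
    values = df.T
    values.index = pd.Index(range(1, len(wt_sequence) + 1), name="position")
    wt = pd.Series(list(wt_sequence), index=values.index, name="wt")
    return ScoreMatrix(kind=kind, values=values, wt=wt, provenance=provenance)


def read_rosetta_csv(path, provenance: str = "rosetta_raw") -> ScoreMatrix:
    """Read a Rosetta ddG summary CSV with variant labels like ``A123G``.

    Expects columns ``variant`` and ``score`` (replicate averaging is done
    upstream).
    """
    df = pd.read_csv(path, comment="#")
    if not {"variant", "score"}.issubset(df.columns):
        raise ValueError("Rosetta summary CSV needs columns variant,score")
    parsed = []
    for label, score in zip(df["variant"], df["score"]):
        m = _VARIANT_RE.match(str(label).strip())
        if m is None:
            raise ValueError(f"unparseable variant label {label!r}")
        parsed.append((m.group(1), int(m.group(2)), m.group(3), float(score)))
    long = pd.DataFrame(parsed, columns=["wt", "position", "mut", "score"])
    return _from_long(long, kind="ddG", provenance=provenance)


def normalize_ddg(
    matrix: ScoreMatrix,
    rosetta_divisor: float = 2.9,
    clamp_low: float = 0.0,
    clamp_high: float = 5.0,
) -> ScoreMatrix:
    """Bring ddG onto the kcal/mol scale and clamp to [clamp_low, clamp_high].

    Raw Rosetta energy units (provenance ``rosetta_raw``) are first divided by
    ``rosetta_divisor``; values are then clamped.  Idempotent: already
    normalised input passes through the clamp unchanged.
    """
    if matrix.kind != "ddG":
        raise ValueError("normalize_ddg applies to ddG matrices only")
    values = matrix.values.copy()
    bad = values.apply(np.isinf).to_numpy()
    if bad.any():
        idx = np.argwhere(bad)[0]
        pos = values.index[idx[0]]
        aa = values.columns[idx[1]]
        raise ValueError(f"non-finite ddG value at position {pos}, target {aa}")
    if matrix.provenance == "rosetta_raw":
        values = values / rosetta_divisor
    values = values.clip(lower=clamp_low, upper=clamp_high)
    return replace(matrix, values=values, provenance="kcal_mol")


def load_hydrophobicity_scale(path=None) -> dict[str, float]:
    """Load a 20-row ``aa<TAB>value`` scale; default is Kyte-Doolittle."""
    if path is None:
        return dict(KYTE_DOOLITTLE)
    scale: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            scale[row[0].strip().upper()] = float(row[1])
    missing = [a for a in AMINO_ACIDS if a not in scale]
    if missing:
        raise ValueError(f"hydrophobicity scale missing amino acids {missing}")
    return scale


def assemble_features(
    ddg: ScoreMatrix,
    dde: ScoreMatrix,
    wcn: "pd.Series | Mapping[int, float]",
    wt_sequence: "str | Mapping[int, str] | None" = None,
    scale: "Mapping[str, float] | None" = None,
) -> pd.DataFrame:
    """Join the score matrices, WCN and hydrophobicity into the variant table.

    Returns one row per (position, target amino acid != wild type) with the
    eight classifier features plus identifiers and a ``complete`` flag; rows
    with any unavailable feature are flagged incomplete and must not enter
    training or prediction.

    ``wcn`` is a position-indexed series (see
    :func:`funcsites.structure.per_position_wcn`); ``wt_sequence`` (string
    indexed from position 1, or a position->aa mapping) is validated against
    the matrices' wild-type annotations.
    """
    if ddg.provenance not in ("kcal_mol", "rasp"):
        raise ValueError(
            "ddG matrix must be normalised (normalize_ddg) before assembly"
        )
    scale = dict(scale) if scale is not None else dict(KYTE_DOOLITTLE)
    wcn = pd.Series(wcn, dtype=float) if not isinstance(wcn, pd.Series) else wcn
    wcn.index = wcn.index.astype(int)

    wt_map: dict[int, str] = {}
    for matrix in (ddg, dde):
        for pos, aa in matrix.wt.items():
            wt_map.setdefault(int(pos), aa)
    if wt_sequence is not None:
        ref = (
            {i + 1: aa for i, aa in enumerate(wt_sequence)}
            if isinstance(wt_sequence, str)
            else {int(k): v for k, v in dict(wt_sequence).items()}
        )
        offending = sorted(
            {
                int(pos)
                for m in (ddg, dde)
                for pos, aa in m.wt.items()
                if int(pos) in ref and ref[int(pos)] != aa
            }
        )
        if offending:
            raise ValueError(
                f"wild-type disagreement with reference sequence at positions "
                f"{offending}"
            )
        for pos, aa in ref.items():
            wt_map.setdefault(pos, aa)

    positions = sorted(set(ddg.positions) | set(dde.positions))
    rows = []
    for pos in positions:
        wt_aa = wt_map.get(pos)
        if wt_aa is None:
            continue
        feats_pos = {
            "ddG_residue_avg": ddg.residue_average(pos),
            "ddE_residue_avg": dde.residue_average(pos),
            "ddG_neighbour_avg": ddg.neighbour_average(pos),
            "ddE_neighbour_avg": dde.neighbour_average(pos),
            "wcn": float(wcn.get(pos, np.nan)),
        }
        for target in AMINO_ACIDS:
            if target == wt_aa:
                continue
            row = {
                "position": pos,
                "wt_aa": wt_aa,
                "target_aa": target,
                "ddG_variant": ddg.value(pos, target),
                "ddE_variant": dde.value(pos, target),
                **feats_pos,
                "hydrophobicity_target": scale[target],
            }
            row["complete"] = bool(
                np.isfinite([row[f] for f in FEATURE_NAMES]).all()
            )
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["position", "wt_aa", "target_aa", *FEATURE_NAMES, "complete"],
    )
    return table


def coverage_report(table: pd.DataFrame, sequence_length: "int | None" = None) -> dict:
    """Counts of complete rows and covered positions (cf. 190/210-style reporting)."""
    complete = table[table["complete"]]
    covered = sorted(complete["position"].unique().tolist())
    report = {
        "n_rows": int(len(table)),
        "n_complete_rows": int(len(complete)),
        "n_positions_covered": len(covered),
    }
    if sequence_length is not None:
        report["sequence_length"] = int(sequence_length)
    return report


def write_variant_table(path, table: pd.DataFrame, config: "dict | None" = None) -> None:
    """Write the variant feature CSV with a provenance header."""
    with open(path, "w") as fh:
        if config:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in config.items()) + "\n")
        table.to_csv(fh, index=False)


def read_variant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
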