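"""Aggregate variant predictions into residue-level functional-site calls.

A position is assigned to a class when at least half of its classified
variants fall in that class; remaining positions stay unclassified.  A
position is a predicted functional site when >= 50% of its variants are
stable-but-inactive (SBI).  Also provides the 4->2 class projections used for
single-assay validation, and monomer-vs-oligomer run comparison to expose
candidate interface residues.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .mave import CLASS_ORDER, VariantClass
from .structure import StructureModel, min_distance_to_sites

UNCLASSIFIED = "unclassified"

#: 4-class -> binary projections for single-assay validation.
_FUNCTION_MODE = {
    VariantClass.WT_LIKE.value: "functional",
    VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY.value: "functional",
    VariantClass.SBI.value: "inactive",
    VariantClass.TOTAL_LOSS.value: "inactive",
}
_ABUNDANCE_MODE = {
    VariantClass.WT_LIKE.value: "high",
    VariantClass.SBI.value: "high",
    VariantClass.TOTAL_LOSS.value: "low",
    VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY.value: "low",
}


def assign_residues(
    predictions: pd.DataFrame, min_variants: int = 1, fraction: float = 0.5
) -> pd.DataFrame:
    """Per-position class call from per-variant predictions.

    ``predictions`` needs columns ``position`` and ``predicted_class``
    (rows with class ``unpredicted`` are ignored).  Per position, the class
    fraction denominator is the number of variants actually classified there.
    The class with fraction >= ``fraction`` (default 0.5) is assigned; no such
    class -> ``unclassified``; an exact two-way tie at the threshold ->
    ``unclassified`` with ``tie=True``.  ``functional_site`` is True iff the
    SBI fraction >= ``fraction``.
    """
    classified = predictions[predictions["predicted_class"] != "unpredicted"]
    rows = []
    for pos, group in classified.groupby("position"):
        n = len(group)
        if n < min_variants:
            continue
        counts = group["predicted_class"].value_counts()
        fractions = {c: float(counts.get(c, 0)) / n for c in CLASS_ORDER}
        top = max(fractions.values())
        winners = [c for c in CLASS_ORDER if fractions[c] == top]
        tie = False
        if top >= fraction:
            if len(winners) == 1:
                assigned = winners[0]
            else:
                assigned, tie = UNCLASSIFIED, True
        else:
            assigned = UNCLASSIFIED
        row = {"position": int(pos), "n_variants_classified": n}
        row.update({f"frac_{c}": fractions[c] for c in CLASS_ORDER})
        row["assigned_class"] = assigned
        row["functional_site"] = fractions[VariantClass.SBI.value] >= fraction
        row["tie"] = tie
        rows.append(row)
    return pd.DataFrame(rows).sort_values("position").reset_index(drop=True)


def binary_projection(classes, mode: str) -> np.ndarray:
    """Project 4-class calls to two classes for single-assay validation.

    ``mode='function'``: functional (WT-like, low-abundance/high-activity) vs
    inactive (SBI, total-loss) — abundance ignored.  ``mode='abundance'``:
    high (WT-like, SBI) vs low (total-loss, low-abundance/high-activity) —
    activity ignored.
    """
    if mode == "function":
        mapping = _FUNCTION_MODE
    elif mode == "abundance":
        mapping = _ABUNDANCE_MODE
    else:
        raise ValueError(f"mode must be 'function' or 'abundance', got {mode!r}")
    values = [getattr(c, "value", c) for c in np.asarray(classes, dtype=object)]
    return np.array([mapping[v] for v in values], dtype=object)


def compare_runs(run_a: pd.DataFrame, run_b: pd.DataFrame) -> dict:
    """Compare residue assignments from two runs (e.g. monomer vs oligomer).

    Positions are matched by reference-sequence numbering.  Returns the
    per-position transition table, counts per (class_a -> class_b) transition,
    and the positions moving functional-site -> total-loss — the signature of
    residues whose conservation is explained by oligomer-context stability,
    i.e. candidate interface residues.
    """
    merged = run_a[["position", "assigned_class", "functional_site"]].merge(
        run_b[["position", "assigned_class", "functional_site"]],
        on="position",
        suffixes=("_a", "_b"),
    )
    if merged.empty:
        raise ValueError("runs share no positions")
    merged["changed"] = merged["assigned_class_a"] != merged["assigned_class_b"]
    transitions = (
        merged.groupby(["assigned_class_a", "assigned_class_b"])
        .size()
        .to_dict()
    )
    candidates = merged[
        merged["functional_site_a"]
        & (merged["assigned_class_b"] == VariantClass.TOTAL_LOSS.value)
    ]["position"].tolist()
    return {
        "table": merged,
        "n_shared": int(len(merged)),
        "n_changed": int(merged["changed"].sum()),
        "transitions": {f"{a}->{b}": int(n) for (a, b), n in transitions.items()},
        "candidate_interface_positions": [int(p) for p in candidates],
    }


def functional_site_summary(
    assignments: pd.DataFrame,
    structure: "StructureModel | None" = None,
    catalytic_positions=None,
    distance_cutoff: float = 10.0,
) -> dict:
    """Class composition of the assigned residues, plus distance-to-catalytic-
    site statistics for the predicted functional sites when a reference set of
    catalytic positions (and the structure) is given.
    """
    n = len(assignments)
    counts = assignments["assigned_class"].value_counts()
    report: dict = {
        "n_positions": int(n),
        "class_counts": {
            c: int(counts.get(c, 0)) for c in (*CLASS_ORDER, UNCLASSIFIED)
        },
        "class_fractions": {
            c: float(counts.get(c, 0)) / n if n else 0.0
            for c in (*CLASS_ORDER, UNCLASSIFIED)
        },
        "n_functional_sites": int(assignments["functional_site"].sum()),
    }
    if catalytic_positions is not None:
        if structure is None:
            raise ValueError("structure required for catalytic-distance analysis")
        dist = min_distance_to_sites(structure, catalytic_positions)
        func_pos = assignments.loc[
            assignments["functional_site"], "position"
        ].tolist()
        distances = {int(p): dist[int(p)] for p in func_pos if int(p) in dist}
        report["functional_site_distances"] = distances
        report["distance_cutoff"] = float(distance_cutoff)
        report["fraction_within_cutoff"] = (
            float(np.mean([d <= distance_cutoff for d in distances.values()]))
            if distances
            else float("nan")
        )
    return report


#: Integer codes written to the B-factor column for molecular-viewer colouring.
CLASS_BFACTOR_CODES = {
    VariantClass.WT_LIKE.value: 1,
    VariantClass.TOTAL_LOSS.value: 2,
    VariantClass.SBI.value: 3,
    VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY.value: 4,
    UNCLASSIFIED: 0,
}


def write_class_pdb(structure: StructureModel, assignments: pd.DataFrame, path) -> None:
    """Write a PDB copy with the assigned class encoded in the B-factor column."""
    from biotite.structure.io.pdb import PDBFile

    if structure.atoms is None:
        raise ValueError("heavy-atom records unavailable")
    atoms = structure.atoms.copy()
    class_by_pos = dict(
        zip(assignments["position"].astype(int), assignments["assigned_class"])
    )
    b = np.zeros(len(atoms))
    for i, (ch, res_id) in enumerate(zip(atoms.chain_id, atoms.res_id)):
        pos = structure.position_map.get((str(ch), int(res_id)))
        b[i] = CLASS_BFACTOR_CODES.get(class_by_pos.get(pos, UNCLASSIFIED), 0)
    atoms.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def write_assignments(path, assignments: pd.DataFrame, summary: "dict | None" = None,
                      summary_path=None) -> None:
    assignments.to_csv(path, index=False)
    if summary is not None and summary_path is not None:
        clean = {k: v for k, v in summary.items() if k != "table"}
        with open(summary_path, "w") as fh:
            json.dump(clean, fh, indent=2, default=str)
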