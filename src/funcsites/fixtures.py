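"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates, as pure functions of a :class:`FixtureSpec` and its seed:

* an idealised helical Calpha trace (single helix or packed helix bundle) so
  buried (high-WCN) and exposed (low-WCN) positions exist by construction;
* ddG/ddE substitution matrices whose values are drawn from class-conditional
  distributions planted per variant.  The planted architecture mirrors the
  biology the classifier exploits: stable-but-inactive (SBI) variants are
  strongly conserved (ddE near -5) but not destabilising (ddG < 1), total-loss
  variants are destabilising (ddG near 4) and equally conserved — so neither
  score alone separates the four classes, only their combination does;
* trimodal abundance/activity MAVE scores whose component membership is
  dictated by the planted class, for exercising the mixture-threshold
  labelling.

These are statistical stand-ins, not physically realistic proteins.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AMINO_ACIDS, ScoreMatrix
from .mave import VariantClass
from .structure import StructureModel

#: Class-conditional feature distributions: (ddG mean, ddG sd, ddE mean, ddE sd).
#: ddG separates {WT-like, SBI} from {total-loss, low-abundance}; ddE separates
#: {WT-like, low-abundance} from {SBI, total-loss}.
DEFAULT_CLASS_PROFILES: dict[str, tuple[float, float, float, float]] = {
    VariantClass.WT_LIKE.value: (0.6, 0.4, -0.8, 0.5),
    VariantClass.TOTAL_LOSS.value: (4.0, 0.5, -5.0, 0.8),
    VariantClass.SBI.value: (0.6, 0.4, -5.0, 0.8),
    VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY.value: (4.0, 0.5, -0.8, 0.5),
}


@dataclass
class FixtureSpec:
    """Fully serialisable recipe for one synthetic dataset.

    ``class_fractions`` are per-position probabilities of the planted class;
    ``class_purity`` is the probability that a variant inherits its position's
    class (the remainder are wild-type-like, emulating tolerated
    substitutions).  MAVE scores come from three Gaussian components per assay
    at ``mave_means`` with sd ``mave_sd`` (default separation 6+ sd, the
    strong-separation regime); a small ``intermediate_fraction`` of score
    draws come from the middle component, giving it mass while keeping
    planted labels recoverable.
    """

    n_residues: int = 160
    n_helices: int = 2
    seed: int = 0
    class_fractions: dict = field(
        default_factory=lambda: {
            VariantClass.WT_LIKE.value: 0.52,
            VariantClass.TOTAL_LOSS.value: 0.25,
            VariantClass.SBI.value: 0.15,
            VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY.value: 0.08,
        }
    )
    class_profiles: dict = field(
        default_factory=lambda: {
            k: tuple(v) for k, v in DEFAULT_CLASS_PROFILES.items()
        }
    )
    class_purity: float = 0.9
    n_interface: int = 6
    mave_means: tuple = (0.0, 0.5, 1.0)
    mave_sd: float = 0.08
    intermediate_fraction: float = 0.02

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if not 0 <= self.class_purity <= 1:
            raise ValueError("class_purity must lie in [0, 1]")
        if self.mave_sd <= 0:
            raise ValueError("mave_sd must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        d["mave_means"] = tuple(d["mave_means"])
        d["class_profiles"] = {k: tuple(v) for k, v in d["class_profiles"].items()}
        return cls(**d)


# ------------------------------------------------------------------ structure

_HELIX_RADIUS = 2.3       # A, Calpha distance from helix axis
_HELIX_RISE = 1.5         # A per residue along the axis
_HELIX_TWIST = np.deg2rad(100.0)
_BUNDLE_SPACING = 10.0    # A between neighbouring helix axes


def make_structure(spec: FixtureSpec) -> tuple[StructureModel, str]:
    """Idealised helical Calpha trace; returns the model and its PDB text.

    ``n_helices=1`` gives a single straight alpha-helix (consecutive
    Calpha-Calpha distance ~3.8 A everywhere).  With more helices the chain
    folds into an antiparallel bundle on a square lattice, so residues facing
    bundle neighbours are packed (high WCN) while terminal and outward-facing
    residues stay exposed.  Deterministic per spec (the seed only selects the
    residue types).
    """
    if spec.n_residues < 2:
        raise ValueError("need at least two residues")
    rng = np.random.default_rng(spec.seed)
    n, h = spec.n_residues, max(1, spec.n_helices)
    per = n // h
    coords = []
    for i in range(n):
        arm, idx = min(i // per, h - 1), i
        if arm == h - 1:
            idx_in_arm = i - arm * per
        else:
            idx_in_arm = i % per
        length = per if arm < h - 1 else n - (h - 1) * per
        # antiparallel arms: odd arms run back down the bundle
        t = idx_in_arm if arm % 2 == 0 else length - 1 - idx_in_arm
        angle = _HELIX_TWIST * idx
        ax_x = _BUNDLE_SPACING * (arm % 2 + 2 * (arm // 4))
        ax_y = _BUNDLE_SPACING * ((arm // 2) % 2)
        coords.append(
            (
                ax_x + _HELIX_RADIUS * np.cos(angle),
                ax_y + _HELIX_RADIUS * np.sin(angle),
                _HELIX_RISE * t,
            )
        )
    coords = np.asarray(coords)
    residue_types = rng.choice(list(AMINO_ACIDS), size=n)
    model = StructureModel(
        chain_ids=np.array(["A"] * n),
        positions=np.arange(1, n + 1),
        residue_types=residue_types,
        ca_coords=coords,
        position_map={("A", i + 1): i + 1 for i in range(n)},
    )
    return model, _to_pdb_text(model)


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _to_pdb_text(model: StructureModel) -> str:
    lines = []
    for i, (ch, pos, aa, xyz) in enumerate(
        zip(model.chain_ids, model.positions, model.residue_types, model.ca_coords)
    ):
        lines.append(
            f"ATOM  {i + 1:>5}  CA  {_ONE_TO_THREE[aa]} {ch}{pos:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# -------------------------------------------------------------- score planting


def make_score_matrices(
    spec: FixtureSpec, structure: StructureModel
) -> tuple[ScoreMatrix, ScoreMatrix, pd.DataFrame]:
    """Plant per-position classes and draw class-conditional ddG/ddE values.

    Returns normalised (kcal/mol-scale, clamped) ddG and ddE matrices plus a
    truth table with columns ``position, wt, mut, true_class`` and per-position
    ``position_class``.  Interface positions (``n_interface`` of the planted
    SBI positions, used by the oligomer-comparison analysis) are marked in the
    truth table's attrs along with the planted functional positions.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = len(structure)
    positions = structure.positions
    seq = structure.sequence()
    classes = list(spec.class_fractions)
    probs = np.array([spec.class_fractions[c] for c in classes])
    position_class = rng.choice(classes, size=n, p=probs)

    sbi_positions = positions[position_class == VariantClass.SBI.value]
    n_int = min(spec.n_interface, len(sbi_positions))
    interface = np.sort(rng.choice(sbi_positions, size=n_int, replace=False))

    ddg_rows, dde_rows, truth_rows = [], [], []
    for pos, pos_class in zip(positions.tolist(), position_class.tolist()):
        wt = seq[pos]
        for mut in AMINO_ACIDS:
            if mut == wt:
                continue
            v_class = (
                pos_class
                if rng.random() < spec.class_purity
                else VariantClass.WT_LIKE.value
            )
            gm, gs, em, es = spec.class_profiles[v_class]
            ddg = float(np.clip(rng.normal(gm, gs), 0.0, 5.0))
            dde = float(np.clip(rng.normal(em, es), -7.0, 0.0))
            ddg_rows.append((pos, wt, mut, ddg))
            dde_rows.append((pos, wt, mut, dde))
            truth_rows.append((pos, wt, mut, v_class, pos_class))

    def _matrix(rows, kind, provenance):
        df = pd.DataFrame(rows, columns=["position", "wt", "mut", "score"])
        values = df.pivot(index="position", columns="mut", values="score")
        wt = df.drop_duplicates("position").set_index("position")["wt"]
        return ScoreMatrix(kind=kind, values=values, wt=wt, provenance=provenance)

    ddg = _matrix(ddg_rows, "ddG", "kcal_mol")
    dde = _matrix(dde_rows, "ddE", "gemme")
    truth = pd.DataFrame(
        truth_rows, columns=["position", "wt", "mut", "true_class", "position_class"]
    )
    truth.attrs["functional_positions"] = [int(p) for p in sbi_positions]
    truth.attrs["interface_positions"] = [int(p) for p in interface]
    return ddg, dde, truth


def make_oligomer_ddg(
    spec: FixtureSpec, ddg: ScoreMatrix, interface_positions
) -> ScoreMatrix:
    """Oligomer-context ddG: interface substitutions become destabilising.

    Re-draws every variant at the interface positions from the total-loss
    stability profile, floored above 3 kcal/mol (interface packing lost in the
    oligomer context); all other values are untouched.
    """
    rng = np.random.default_rng(spec.seed + 2)
    values = ddg.values.copy()
    gm, gs, _, _ = spec.class_profiles[VariantClass.TOTAL_LOSS.value]
    for pos in interface_positions:
        row = values.loc[pos]
        for aa in values.columns:
            if np.isfinite(row[aa]):
                values.loc[pos, aa] = float(
                    np.clip(rng.normal(gm, gs), 3.2, 5.0)
                )
    return ScoreMatrix(kind="ddG", values=values, wt=ddg.wt, provenance="kcal_mol")


# ----------------------------------------------------------------- MAVE scores

#: Which mixture component (low/mid/high index into mave_means) each class
#: draws its (abundance, activity) scores from.
_CLASS_COMPONENTS = {
    VariantClass.WT_LIKE.value: (2, 2),
    VariantClass.TOTAL_LOSS.value: (0, 0),
    VariantClass.SBI.value: (2, 0),
    VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY.value: (0, 2),
}


def make_mave_scores(spec: FixtureSpec, truth: pd.DataFrame) -> pd.DataFrame:
    """Trimodal abundance/activity scores dictated by the planted classes.

    Higher score = more abundant / more active.  A fraction
    ``intermediate_fraction`` of draws per assay comes from the middle
    component instead, so the fitted three-Gaussian mixture has genuine
    central mass.
    """
    rng = np.random.default_rng(spec.seed + 3)
    means = np.asarray(spec.mave_means, dtype=float)
    rows = []
    for rec in truth.itertuples(index=False):
        comp_ab, comp_ac = _CLASS_COMPONENTS[rec.true_class]
        if rng.random() < spec.intermediate_fraction:
            comp_ab = 1
        if rng.random() < spec.intermediate_fraction:
            comp_ac = 1
        rows.append(
            (
                rec.position,
                rec.wt,
                rec.mut,
                rng.normal(means[comp_ab], spec.mave_sd),
                rng.normal(means[comp_ac], spec.mave_sd),
            )
        )
    return pd.DataFrame(
        rows, columns=["position", "wt", "mut", "abundance_score", "activity_score"]
    )


# ------------------------------------------------------------------- bundling


def make_fixture(spec: FixtureSpec) -> dict:
    """Generate every artefact of one synthetic dataset."""
    structure, pdb_text = make_structure(spec)
    ddg, dde, truth = make_score_matrices(spec, structure)
    mave = make_mave_scores(spec, truth)
    ddg_oligomer = make_oligomer_ddg(spec, ddg, truth.attrs["interface_positions"])
    return {
        "spec": spec,
        "structure": structure,
        "pdb_text": pdb_text,
        "ddg": ddg,
        "dde": dde,
        "ddg_oligomer": ddg_oligomer,
        "mave": mave,
        "truth": truth,
    }


def _matrix_to_long(matrix: ScoreMatrix) -> pd.DataFrame:
    long = (
        matrix.values.stack()
        .rename("score")
        .reset_index()
        .rename(columns={"level_1": "mut", "mut_aa": "mut"})
    )
    long.columns = ["position", "mut", "score"]
    long["wt"] = long["position"].map(matrix.wt)
    return long[["position", "wt", "mut", "score"]]


def write_fixture(fixture: dict, out_dir) -> dict:
    """Write PDB, long-form score CSVs, MAVE CSV and truth.json; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "pdb": os.path.join(out_dir, "structure.pdb"),
        "ddg": os.path.join(out_dir, "ddg.csv"),
        "dde": os.path.join(out_dir, "dde.csv"),
        "ddg_oligomer": os.path.join(out_dir, "ddg_oligomer.csv"),
        "mave": os.path.join(out_dir, "mave.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
        "spec": os.path.join(out_dir, "fixture_spec.json"),
    }
    with open(paths["pdb"], "w") as fh:
        fh.write(fixture["pdb_text"])
    for key in ("ddg", "dde", "ddg_oligomer"):
        _matrix_to_long(fixture[key]).to_csv(paths[key], index=False)
    fixture["mave"].to_csv(paths["mave"], index=False)
    truth = fixture["truth"]
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "variants": truth.to_dict(orient="records"),
                "functional_positions": truth.attrs["functional_positions"],
                "interface_positions": truth.attrs["interface_positions"],
            },
            fh,
        )
    with open(paths["spec"], "w") as fh:
        fh.write(fixture["spec"].to_json())
    return paths
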