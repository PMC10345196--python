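"""Per-residue structural features from protein coordinates.

Reads PDB coordinates into a light :class:`StructureModel` and computes the
weighted contact number (WCN), a smooth, parameter-light proxy for residue
burial and packing density:

    WCN_i = sum_{j != i} s(r_ij),   s(r) = (1 - (r/r0)^6) / (1 - (r/r0)^12)

where r_ij is the Calpha-Calpha distance between residues i and j and r0 is a
switching distance (default 7.0 A).  The rational switching function is
evaluated in its factored form 1 / (1 + (r/r0)^6), which is identical
everywhere except at the removable singularity r = r0 (where the factored form
gives the correct limit 1/2).

Also provides relative solvent accessibility (Shrake-Rupley, normalised by
per-residue-type theoretical maxima) and minimum Calpha distances to a set of
reference sites (e.g. catalytic residues).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "read_structure",
    "switching_function",
    "weighted_contact_number",
    "relative_exposure",
    "min_distance_to_sites",
    "MAX_ASA",
]

# Theoretical maximum accessible surface areas per residue type (A^2),
# Tien et al. 2013 ("theoretical" column); used to normalise raw SASA.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class StructureModel:
    """Calpha-level model of one or more protein chains.

    Positions are 1-based and refer to the reference (e.g. UniProt) sequence;
    in a homo-oligomer the same position appears once per chain.
    """

    chain_ids: np.ndarray        # (n,) chain id per residue
    positions: np.ndarray        # (n,) 1-based sequence position per residue
    residue_types: np.ndarray    # (n,) one-letter amino-acid codes
    ca_coords: np.ndarray        # (n, 3) Calpha coordinates in Angstrom
    atoms: "struc.AtomArray | None" = None   # heavy atoms, for SASA
    position_map: dict = field(default_factory=dict)  # author numbering -> position

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids)
        self.residue_types = np.asarray(self.residue_types)
        if not np.isfinite(self.ca_coords).all():
            raise ValueError("non-finite Calpha coordinates")
        for ch in np.unique(self.chain_ids):
            pos = self.positions[self.chain_ids == ch]
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing in chain {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def chains(self) -> list:
        return list(dict.fromkeys(self.chain_ids.tolist()))

    def sequence(self) -> dict[int, str]:
        """Position -> one-letter residue type (first chain wins)."""
        seq: dict[int, str] = {}
        for pos, aa in zip(self.positions.tolist(), self.residue_types.tolist()):
            seq.setdefault(int(pos), aa)
        return seq


def _one_letter(res_name: str) -> str | None:
    try:
        code = ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return None
    return code if code != "X" else None


def read_structure(
    pdb_source: "str | IO[str]",
    chain: "str | Iterable[str] | None" = None,
    include_hetero: bool = False,
    renumber: bool = False,
) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, or a text stream / raw PDB string.
    chain
        Chain id (or iterable of ids) to keep; ``None`` keeps all chains.
    include_hetero
        Keep HETATM residues that map to a canonical amino acid.
    renumber
        Remap author residue numbering to 1..N per chain (in order of
        appearance); the author->position mapping is logged and stored in
        ``position_map``.

    Multi-model files use the first model only.  Residues without a Calpha
    atom are excluded with a warning.
    """
    if isinstance(pdb_source, str) and "\n" in pdb_source:
        pdb_source = io.StringIO(pdb_source)
    pdb_file = PDBFile.read(pdb_source)
    atoms = pdb_file.get_structure(model=1, extra_fields=["b_factor"])
    if not include_hetero:
        atoms = atoms[~atoms.hetero]
    atoms = atoms[atoms.element != "H"]

    available = list(dict.fromkeys(atoms.chain_id.tolist()))
    if chain is not None:
        wanted = [chain] if isinstance(chain, str) else list(chain)
        missing = [c for c in wanted if c not in available]
        if missing:
            raise ValueError(
                f"chain(s) {missing} not found; available chains: {available}"
            )
        atoms = atoms[np.isin(atoms.chain_id, wanted)]

    chain_ids, positions, res_types, ca_coords = [], [], [], []
    position_map: dict[tuple, int] = {}
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    counter: dict[str, int] = {}
    for i in range(len(starts) - 1):
        res = atoms[starts[i]:starts[i + 1]]
        ch = res.chain_id[0]
        author_id = int(res.res_id[0])
        aa = _one_letter(res.res_name[0])
        if aa is None:
            continue
        ca = res[res.atom_name == "CA"]
        if len(ca) == 0:
            warnings.warn(
                f"residue {res.res_name[0]} {ch}{author_id} has no Calpha; excluded",
                stacklevel=2,
            )
            continue
        if renumber:
            counter[ch] = counter.get(ch, 0) + 1
            pos = counter[ch]
        else:
            pos = author_id
        position_map[(str(ch), author_id)] = pos
        chain_ids.append(ch)
        positions.append(pos)
        res_types.append(aa)
        ca_coords.append(ca.coord[0])
    if not positions:
        raise ValueError("no amino-acid residues with Calpha atoms found")
    if renumber:
        logger.info("renumbered %d residues: %s", len(position_map), position_map)
    return StructureModel(
        chain_ids=np.array(chain_ids),
        positions=np.array(positions),
        residue_types=np.array(res_types),
        ca_coords=np.array(ca_coords),
        atoms=atoms,
        position_map=position_map,
    )


def switching_function(r, r0: float = 7.0):
    """Smooth contact weight s(r) = 1 / (1 + (r/r0)^6), in (0, 1].

    The factored form of (1-(r/r0)^6)/(1-(r/r0)^12); identical everywhere
    except at r = r0, where it takes the removable-singularity limit 1/2.
    Monotonically decreasing in r.
    """
    if r0 <= 0:
        raise ValueError(f"r0 must be positive, got {r0}")
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distances must be non-negative")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return out if out.ndim else float(out)


def weighted_contact_number(model: StructureModel, r0: float = 7.0) -> pd.DataFrame:
    """Per-residue WCN over all chains in the model.

    Oligomeric input therefore yields oligomer-context WCN.  Returns a frame
    with columns ``chain``, ``position``, ``aa``, ``wcn``.
    """
    n = len(model)
    if n < 2:
        raise ValueError("WCN requires at least two residues")
    dist = cdist(model.ca_coords, model.ca_coords)
    s = switching_function(dist, r0=r0)
    np.fill_diagonal(s, 0.0)
    return pd.DataFrame(
        {
            "chain": model.chain_ids,
            "position": model.positions,
            "aa": model.residue_types,
            "wcn": s.sum(axis=1),
        }
    )


def per_position_wcn(model: StructureModel, r0: float = 7.0) -> pd.Series:
    """WCN indexed by sequence position, averaged over chains (homo-oligomers)."""
    wcn = weighted_contact_number(model, r0=r0)
    return wcn.groupby("position")["wcn"].mean()


def relative_exposure(
    model: StructureModel,
    threshold: float = 0.20,
    point_number: int = 200,
) -> pd.DataFrame:
    """Relative solvent accessibility and buried/exposed calls.

    Shrake-Rupley SASA over heavy atoms, summed per residue and normalised by
    the per-residue-type theoretical maximum (``MAX_ASA``).  A residue is
    flagged buried when rel_sasa < ``threshold`` (default 20%).  Intended for
    stratified analyses only; not a classifier feature.
    """
    if model.atoms is None:
        raise ValueError("heavy-atom records unavailable; re-read the structure")
    atoms = model.atoms
    atom_sasa = struc.sasa(atoms, vdw_radii="Single", point_number=point_number)
    rows = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for i in range(len(starts) - 1):
        res = atoms[starts[i]:starts[i + 1]]
        sasa_vals = atom_sasa[starts[i]:starts[i + 1]]
        ch, author_id = str(res.chain_id[0]), int(res.res_id[0])
        if (ch, author_id) not in model.position_map:
            continue
        pos = model.position_map[(ch, author_id)]
        aa = _one_letter(res.res_name[0])
        if np.isnan(sasa_vals).all() or aa not in MAX_ASA:
            rel = np.nan
        else:
            rel = float(np.nansum(sasa_vals)) / MAX_ASA[aa]
        rows.append(
            {
                "chain": ch,
                "position": pos,
                "aa": aa,
                "rel_sasa": rel,
                "buried": bool(rel < threshold) if np.isfinite(rel) else False,
            }
        )
    return pd.DataFrame(rows)


def min_distance_to_sites(
    model: StructureModel, site_positions: Iterable[int]
) -> dict[int, float]:
    """Minimum Calpha-Calpha distance from every residue to a set of sites.

    ``site_positions`` are sequence positions (e.g. catalytic residues); a
    site's distance to itself is 0.  Returns position -> distance (A),
    minimised over chains.
    """
    sites = set(int(p) for p in site_positions)
    if not sites:
        raise ValueError("site set is empty")
    present = set(model.positions.tolist())
    absent = sites - present
    if absent:
        raise ValueError(f"site positions {sorted(absent)} not in structure")
    site_mask = np.isin(model.positions, list(sites))
    dist = cdist(model.ca_coords, model.ca_coords[site_mask]).min(axis=1)
    out: dict[int, float] = {}
    for pos, d in zip(model.positions.tolist(), dist.tolist()):
        out[int(pos)] = min(out.get(int(pos), np.inf), float(d))
    return out


def write_feature_table(
    path: str,
    wcn: pd.DataFrame,
    exposure: "pd.DataFrame | None" = None,
    r0: float = 7.0,
    threshold: float = 0.20,
) -> None:
    """Write the per-residue structural feature TSV with a provenance header."""
    table = wcn
    if exposure is not None:
        table = wcn.merge(
            exposure[["chain", "position", "rel_sasa", "buried"]],
            on=["chain", "position"],
            how="left",
        )
    with open(path, "w") as fh:
        fh.write(f"# r0={r0} exposure_threshold={threshold}\n")
        table.to_csv(fh, sep="\t", index=False)
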