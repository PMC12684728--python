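"""Reading structures and ligands into the pipeline's internal types.

Proteins come in as PDB/mmCIF (parsed with gemmi), ligands as SMILES or
SDF/MOL (parsed with RDKit).  Surface point clouds are persisted to a single
HDF5 container.  Only atoms of the six elements {C, H, O, N, S, Se} enter the
protein point cloud; everything else is dropped before centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import h5py
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: supported protein elements, in one-hot order
ELEMENTS = ("C", "H", "O", "N", "S", "Se")

#: fixed van der Waals radii, Å
VDW_RADII = {"C": 1.70, "H": 1.10, "O": 1.52, "N": 1.55, "S": 1.80, "Se": 1.90}

AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
AA_INDEX = {a: i for i, a in enumerate(AA3)}
AA_INDEX["MSE"] = AA_INDEX["MET"]  # selenomethionine

LIGAND_ELEMENTS = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")
BOND_TYPES = (
    Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE, Chem.BondType.AROMATIC,
)


class FormatError(ValueError):
    """Unparseable or structurally empty input file."""


@dataclass
class AtomCloud:
    """Centered heavy+light atom cloud of one protein."""

    coords: np.ndarray      # (M, 3) Å, centroid at origin
    elements: np.ndarray    # (M, 6) one-hot over ELEMENTS
    vdw_radii: np.ndarray   # (M,) Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if len(self.coords) < 1:
            raise FormatError("empty atom cloud")
        rows = self.elements.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("element rows must be one-hot")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("radii must be positive")

    @classmethod
    def from_symbols(cls, coords: np.ndarray, symbols: list[str]) -> "AtomCloud":
        """Filter to supported elements, center, assign radii."""
        coords = np.asarray(coords, dtype=np.float64)
        keep = [i for i, s in enumerate(symbols) if s in VDW_RADII]
        if not keep:
            raise FormatError("no atoms of supported elements")
        coords = coords[keep]
        syms = [symbols[i] for i in keep]
        onehot = np.zeros((len(syms), len(ELEMENTS)))
        for i, s in enumerate(syms):
            onehot[i, ELEMENTS.index(s)] = 1.0
        radii = np.array([VDW_RADII[s] for s in syms])
        return cls(coords - coords.mean(axis=0), onehot, radii)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class ResidueBackbone:
    """Backbone geometry of one chain: N, Cα, C, O and Cβ per residue."""

    aa_index: np.ndarray   # (V,) 0..19, or -1 for non-canonical
    n: np.ndarray          # (V, 3)
    ca: np.ndarray         # (V, 3)
    c: np.ndarray          # (V, 3)
    o: np.ndarray          # (V, 3), NaN where missing
    cb: np.ndarray         # (V, 3), NaN for glycine / missing
    resnames: list[str] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.aa_index)


@dataclass
class LigandGraph:
    """Small-molecule graph: typed atoms, both-direction bond list."""

    node_feat: np.ndarray   # (n_atoms, node_dim)
    edge_index: np.ndarray  # (2, n_edges) directed, both directions present
    edge_feat: np.ndarray   # (n_edges, edge_dim)
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.node_feat)

    node_dim: int = 0
    edge_dim: int = 0

    def __post_init__(self):
        self.node_dim = self.node_feat.shape[1]
        self.edge_dim = self.edge_feat.shape[1] if len(self.edge_feat) else 4


# --------------------------------------------------------------------------
# protein reading


def read_protein(path: str, dialect: str | None = None) -> tuple[AtomCloud, ResidueBackbone]:
    """Parse a PDB/mmCIF file into an (AtomCloud, ResidueBackbone) pair.

    Alternate locations resolve to the highest-occupancy conformer (first one
    on ties).  HETATM records are skipped except selenium-containing residues
    such as MSE.  Only the first model is read.
    """
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError("structure has no models")

    coords, symbols = [], []
    aa, n_, ca_, c_, o_, cb_, names = [], [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            has_se = any(at.element.name == "Se" for at in res)
            if is_het and not has_se:
                continue
            # altloc resolution: best occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                coords.append([at.pos.x, at.pos.y, at.pos.z])
                symbols.append(at.element.name)
            bb = {k: best.get(k) for k in ("N", "CA", "C", "O", "CB")}
            if bb["N"] and bb["CA"] and bb["C"]:
                aa.append(AA_INDEX.get(res.name, -1))
                names.append(res.name)
                for lst, key in ((n_, "N"), (ca_, "CA"), (c_, "C"), (o_, "O"), (cb_, "CB")):
                    at = bb[key]
                    lst.append([at.pos.x, at.pos.y, at.pos.z] if at else [np.nan] * 3)

    cloud = AtomCloud.from_symbols(np.array(coords, dtype=np.float64).reshape(-1, 3), symbols)
    backbone = ResidueBackbone(
        np.array(aa, dtype=int),
        np.array(n_, dtype=np.float64).reshape(-1, 3),
        np.array(ca_, dtype=np.float64).reshape(-1, 3),
        np.array(c_, dtype=np.float64).reshape(-1, 3),
        np.array(o_, dtype=np.float64).reshape(-1, 3),
        np.array(cb_, dtype=np.float64).reshape(-1, 3),
        names,
    )
    return cloud, backbone


# --------------------------------------------------------------------------
# ligand reading


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    el = np.zeros(len(LIGAND_ELEMENTS) + 1)
    sym = atom.GetSymbol()
    el[LIGAND_ELEMENTS.index(sym) if sym in LIGAND_ELEMENTS else -1] = 1.0
    deg = np.zeros(6)
    deg[min(atom.GetDegree(), 5)] = 1.0
    return np.concatenate(
        [el, deg, [atom.GetFormalCharge(), float(atom.GetIsAromatic())]]
    )


def read_ligand(source: str) -> LigandGraph:
    """Build a LigandGraph from a SMILES string or an SDF/MOL file path."""
    if str(source).endswith((".sdf", ".mol")):
        mol = Chem.MolFromMolFile(str(source))
    else:
        mol = Chem.MolFromSmiles(source)
    if mol is None:
        raise FormatError(f"cannot parse ligand: {source!r}")
    nodes = np.array([_atom_features(a) for a in mol.GetAtoms()])
    src, dst, efeat = [], [], []
    for b in mol.GetBonds():
        bt = np.zeros(len(BOND_TYPES))
        if b.GetBondType() in BOND_TYPES:
            bt[BOND_TYPES.index(b.GetBondType())] = 1.0
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
        efeat += [bt, bt]
    edge_index = np.array([src, dst], dtype=int).reshape(2, -1)
    edge_feat = np.array(efeat).reshape(-1, len(BOND_TYPES))
    return LigandGraph(nodes, edge_index, edge_feat, Chem.MolToSmiles(mol))


# --------------------------------------------------------------------------
# surface artifact container


def write_surface(cloud, path: str) -> None:
    """Persist a SurfaceCloud to a single HDF5 file (lossless float64)."""
    if len(cloud.points) == 0:
        raise ValueError("refusing to serialize an empty surface")
    with h5py.File(path, "w") as f:
        for name in ("points", "normals", "geom", "chem_idx", "chem_dist"):
            f.create_dataset(name, data=getattr(cloud, name))
        f.attrs["level_radius"] = cloud.level_radius


def read_surface(path: str):
    from .surface_gen import SurfaceCloud  # avoid import cycle

    with h5py.File(path, "r") as f:
        return SurfaceCloud(
            points=f["points"][:],
            normals=f["normals"][:],
            geom=f["geom"][:],
            chem_idx=f["chem_idx"][:].astype(int),
            chem_dist=f["chem_dist"][:],
            level_radius=float(f.attrs["level_radius"]),
        )
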