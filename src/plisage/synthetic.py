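"""Seeded generators for toy proteins, ligands and labeled complex datasets.

Proteins are single chains built from ideal backbone geometry (N-CA 1.46 Å,
CA-C 1.52 Å, C-N 1.33 Å, trans peptide bonds) by natural-extension-of-
reference-frame placement, with helix (phi=-57, psi=-47), extended zigzag
(phi=psi=180) or random-walk dihedrals, plus carbonyl O and ideal C-beta
(absent for glycine).  Ligands are small random C/N chains; "binders" carry a
planted carboxylate motif C(=O)O.

Labels are functions of geometry the model can see.  Interaction: a pair is
positive when a motif ligand meets a helix protein (the planted pocket);
negatives are random protein-ligand re-pairings excluding positives at an
exact 1:1 ratio.  Affinity: a smooth logistic function of the surface point
count near a designated pocket (the first residue's C-alpha), plus Gaussian
noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion_predict import ComplexRecord
from .io_formats import AA3, AtomCloud, ResidueBackbone, read_ligand
from .patch_tokenizer import build_patches
from .protein_graph import build_graph
from .surface_gen import generate_surface

GEOMETRIES = ("helix", "zigzag", "random-walk")
MOTIF_SMILES = "C(=O)O"          # carboxylate planted on positive ligands


@dataclass
class SyntheticSpec:
    n_residues: int = 16
    geometry: str = "helix"
    n_complexes: int = 16
    n_proteins: int = 8
    label_rule: str = "motif"          # "motif" (interaction) | "pocket" (affinity)
    noise_sd: float = 0.1
    seed: int = 0
    # desk-scale pipeline parameters used when building records
    level_radius: float = 1.0
    n_init: int = 8
    knn_k: int = 10
    n_patches: int = 32
    points_per_patch: int = 16

    def __post_init__(self):
        if self.n_residues < 1 or self.n_complexes < 1 or self.noise_sd < 0:
            raise ValueError("counts must be positive and noise sd >= 0")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")


# --------------------------------------------------------------------------
# backbone construction


def _place(a, b, c, bond, angle, torsion):
    """NeRF placement: new atom at distance `bond` from c, angle at c, dihedral a-b-c-new."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    d = bond * np.array([
        -np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)
    ])
    return c + m @ d


_DIHEDRALS = {
    "helix": (np.deg2rad(-57.0), np.deg2rad(-47.0)),
    "zigzag": (np.pi, np.pi),
}


def build_backbone(n_residues: int, geometry: str, seed: int = 0) -> ResidueBackbone:
    """Ideal-geometry single chain with the requested dihedral pattern."""
    rng = np.random.default_rng(seed)
    b_nca, b_cac, b_cn = 1.46, 1.52, 1.33
    ang_ncac, ang_cacn, ang_cnca = np.deg2rad(110.0), np.deg2rad(116.0), np.deg2rad(121.0)
    omega = np.pi

    if geometry == "random-walk":
        phis = rng.uniform(-np.pi, np.pi, n_residues)
        psis = rng.uniform(-np.pi, np.pi, n_residues)
    else:
        phi0, psi0 = _DIHEDRALS[geometry]
        phis = np.full(n_residues, phi0)
        psis = np.full(n_residues, psi0)

    N = [np.zeros(3)]
    CA = [np.array([b_nca, 0.0, 0.0])]
    C = [CA[0] + b_cac * np.array([-np.cos(ang_ncac), np.sin(ang_ncac), 0.0])]
    for i in range(1, n_residues):
        N.append(_place(N[-1], CA[-1], C[-1], b_cn, ang_cacn, psis[i - 1]))
        CA.append(_place(CA[-1], C[-1], N[-1], b_nca, ang_cnca, omega))
        C.append(_place(C[-1], N[-1], CA[-1], b_cac, ang_ncac, phis[i]))
    N, CA, C = map(np.array, (N, CA, C))

    aa = rng.integers(0, 20, n_residues)
    O = np.full((n_residues, 3), np.nan)
    CB = np.full((n_residues, 3), np.nan)
    for i in range(n_residues):
        psi_ref = psis[i] if i < n_residues - 1 else 0.0
        O[i] = _place(N[i], CA[i], C[i], 1.23, np.deg2rad(121.0), psi_ref + np.pi)
        if AA3[aa[i]] != "GLY":
            CB[i] = _place(C[i], N[i], CA[i], 1.53, np.deg2rad(110.5), np.deg2rad(122.6))
    return ResidueBackbone(aa, N, CA, C, O, CB, [AA3[a] for a in aa])


def backbone_to_pdb(bb: ResidueBackbone) -> str:
    """Serialize a backbone as PDB text (3-decimal coordinates)."""
    lines, serial = [], 1
    for i in range(bb.n_residues):
        res = bb.resnames[i] if bb.resnames else "ALA"
        for name, pos, elem in (("N", bb.n[i], "N"), ("CA", bb.ca[i], "C"),
                                ("C", bb.c[i], "C"), ("O", bb.o[i], "O"),
                                ("CB", bb.cb[i], "C")):
            if not np.all(np.isfinite(pos)):
                continue
            namef = f" {name:<3s}"       # short names start in column 14
            lines.append(
                f"ATOM  {serial:5d} {namef:4s} {res:3s} A{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}")
            serial += 1
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def make_protein(spec: SyntheticSpec, path: str | None = None):
    """(pdb_text, ResidueBackbone, AtomCloud) for one synthetic chain.

    Coordinates are rounded to PDB precision (3 decimals) before building the
    returned objects, so parsing the written file round-trips exactly.
    """
    bb = build_backbone(spec.n_residues, spec.geometry, spec.seed)
    for arr in (bb.n, bb.ca, bb.c, bb.o, bb.cb):
        np.round(arr, 3, out=arr)
    pdb_text = backbone_to_pdb(bb)
    coords, symbols = [], []
    for i in range(bb.n_residues):
        for pos, elem in ((bb.n[i], "N"), (bb.ca[i], "C"), (bb.c[i], "C"),
                          (bb.o[i], "O"), (bb.cb[i], "C")):
            if np.all(np.isfinite(pos)):
                coords.append(pos)
                symbols.append(elem)
    cloud = AtomCloud.from_symbols(np.array(coords), symbols)
    if path:
        with open(path, "w") as f:
            f.write(pdb_text)
    return pdb_text, bb, cloud


# --------------------------------------------------------------------------
# ligands


def make_ligand_smiles(rng: np.random.Generator, motif: bool) -> str:
    """Random short C/N chain, optionally ending in the carboxylate motif."""
    length = int(rng.integers(2, 6))
    chain = "".join(rng.choice(list("CCCN"), size=length))
    return chain + (MOTIF_SMILES if motif else "")


# --------------------------------------------------------------------------
# labeled datasets


def _build_protein_inputs(spec: SyntheticSpec, geometry: str, n_res: int, seed: int):
    sub = SyntheticSpec(n_residues=n_res, geometry=geometry, seed=seed,
                        level_radius=spec.level_radius, n_init=spec.n_init)
    _, bb, cloud = make_protein(sub)
    surface = generate_surface(cloud, r=spec.level_radius, n_init=spec.n_init, seed=seed)
    patchset = build_patches(surface, spec.n_patches, spec.points_per_patch, seed=seed)
    graph = build_graph(bb, k=spec.knn_k)
    return bb, cloud, surface, patchset, graph


def pocket_size(surface, bb: ResidueBackbone, radius: float = 8.0) -> int:
    """Geometric label summary: surface points near the designated pocket.

    The pocket is anchored at the first residue's C-alpha (in the centered
    atom frame the surface lives in).
    """
    all_atoms = []
    for i in range(bb.n_residues):
        for pos in (bb.n[i], bb.ca[i], bb.c[i], bb.o[i], bb.cb[i]):
            if np.all(np.isfinite(pos)):
                all_atoms.append(pos)
    centroid = np.mean(all_atoms, axis=0)
    anchor = bb.ca[0] - centroid
    return int((np.linalg.norm(surface.points - anchor, axis=1) < radius).sum())


def make_dataset(spec: SyntheticSpec, n_proteins: int | None = None,
                 out_dir: str | None = None):
    """ComplexRecord list + manifest with disjoint train/val/test splits.

    Interaction ('motif' rule): positives pair helix proteins with motif
    ligands; negatives are random re-pairings excluding positives, exactly
    1:1.  Affinity ('pocket' rule): label = 4 + 4/(1 + exp(-(P - 60)/20)) +
    noise, with P the pocket surface-point count.
    """
    if spec.n_complexes < 2:
        raise ValueError("need at least 2 complexes")
    if n_proteins is None:
        n_proteins = spec.n_proteins
    rng = np.random.default_rng(spec.seed)
    proteins = []
    for p in range(n_proteins):
        geometry = "helix" if p % 2 == 0 else "zigzag"
        n_res = int(rng.integers(max(6, spec.n_residues - 4), spec.n_residues + 5))
        seed = spec.seed * 1009 + p
        bb, cloud, surface, patchset, graph = _build_protein_inputs(
            spec, geometry, n_res, seed)
        proteins.append(dict(pid=f"prot{p}", geometry=geometry, bb=bb, cloud=cloud,
                             surface=surface, patchset=patchset, graph=graph))
        if out_dir:
            make_protein(SyntheticSpec(n_residues=n_res, geometry=geometry, seed=seed),
                         path=os.path.join(out_dir, f"prot{p}.pdb"))

    records, rows = [], []

    def add_record(prot, smiles, label, task):
        records.append(ComplexRecord(
            ligand=read_ligand(smiles), label=float(label), task=task,
            surface=prot["surface"], patchset=prot["patchset"], graph=prot["graph"],
            atoms=prot["cloud"], protein_id=prot["pid"]))
        rows.append({"protein": prot["pid"], "ligand": smiles, "label": float(label)})

    if spec.label_rule == "motif":
        n_pos = spec.n_complexes // 2
        helix = [p for p in proteins if p["geometry"] == "helix"]
        positives = set()
        for _ in range(n_pos):
            prot = helix[int(rng.integers(len(helix)))]
            smiles = make_ligand_smiles(rng, motif=True)
            positives.add((prot["pid"], smiles))
            add_record(prot, smiles, 1.0, "interaction")
        n_neg = spec.n_complexes - n_pos
        made = 0
        while made < n_neg:
            prot = proteins[int(rng.integers(len(proteins)))]
            motif = bool(rng.integers(2))
            smiles = make_ligand_smiles(rng, motif=motif)
            pair_is_positive = prot["geometry"] == "helix" and motif
            if pair_is_positive or (prot["pid"], smiles) in positives:
                continue
            add_record(prot, smiles, 0.0, "interaction")
            made += 1
    elif spec.label_rule == "pocket":
        for _ in range(spec.n_complexes):
            prot = proteins[int(rng.integers(len(proteins)))]
            p_size = pocket_size(prot["surface"], prot["bb"])
            label = 4.0 + 4.0 / (1.0 + np.exp(-(p_size - 60.0) / 20.0))
            label += rng.normal(scale=spec.noise_sd)
            smiles = make_ligand_smiles(rng, motif=bool(rng.integers(2)))
            add_record(prot, smiles, label, "affinity")
    else:
        raise ValueError(f"unknown label rule {spec.label_rule!r}")

    # disjoint splits: 60/20/20 over a seeded permutation
    n = len(records)
    perm = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[: int(0.6 * n)]] = "train"
    split[perm[int(0.6 * n): int(0.8 * n)]] = "val"
    split[perm[int(0.8 * n):]] = "test"
    manifest = pd.DataFrame(rows)
    manifest["split"] = split
    manifest["task"] = "interaction" if spec.label_rule == "motif" else "affinity"
    if out_dir:
        manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "ligands.smi"), "w") as f:
            f.write("\n".join(dict.fromkeys(manifest["ligand"])) + "\n")
    return records, manifest
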