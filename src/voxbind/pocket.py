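"""Binding-pocket extraction and ligand-centred coordinate frames.

The pocket is the set of receptor heavy atoms within a query radius of any
ligand atom (an open ball: strictly closer than the radius).  Membership is
decided per atom through a k-d tree nearest-neighbour query; whole residues
are never completed.  After extraction all coordinates are translated so
the unweighted ligand centroid sits at the origin, which is the frame the
voxel grid is built in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, ComplexPair

__all__ = ["Pocket", "EmptyPocketError", "extract_pocket", "center_on_ligand"]


class EmptyPocketError(ValueError):
    """No receptor atom falls within the query radius of the ligand."""


def _shift_atoms(atoms: list[Atom], delta: np.ndarray) -> list[Atom]:
    return [replace(a, coords=a.coords + delta) for a in atoms]


@dataclass
class Pocket:
    """Receptor pocket subset plus ligand, optionally ligand-centred."""

    rna_atoms: list[Atom]
    ligand_atoms: list[Atom]
    radius: float
    center: np.ndarray  # ligand centroid in the original frame
    centered: bool = False
    source_id: str = ""

    def rna_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.rna_atoms], dtype=float)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float)

    def all_atoms(self) -> list[Atom]:
        return self.rna_atoms + self.ligand_atoms

    def to_pdb_fragment(self) -> str:
        """Debug dump of pocket atoms as minimal PDB-style lines."""
        lines = []
        for rec, atoms in (("ATOM", self.rna_atoms), ("HETATM", self.ligand_atoms)):
            for a in atoms:
                x, y, z = a.coords
                lines.append(
                    f"{rec:<6}{a.serial:>5} {a.name:<4} {a.residue_name:<3} "
                    f"{a.chain_id}{a.residue_index:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                )
        return "\n".join(lines) + "\n"


def extract_pocket(c: ComplexPair, radius: float) -> Pocket:
    """Keep receptor heavy atoms strictly within ``radius`` of the ligand.

    Uses a k-d tree over the ligand atoms; each receptor atom is tested via
    its nearest-neighbour distance, which matches the brute-force all-pairs
    minimum exactly.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not c.ligand_atoms:
        raise ValueError("ligand is empty")
    lig = c.ligand_coords()
    tree = cKDTree(lig)
    dists, _ = tree.query(c.rna_coords(), k=1)
    keep = dists < radius
    if not np.any(keep):
        raise EmptyPocketError(
            f"{c.source_id}: empty pocket (no receptor atom within {radius} A)"
        )
    rna = [a for a, k in zip(c.rna_atoms, keep) if k]
    return Pocket(
        rna_atoms=rna,
        ligand_atoms=list(c.ligand_atoms),
        radius=float(radius),
        center=lig.mean(axis=0),
        centered=False,
        source_id=c.source_id,
    )


def center_on_ligand(p: Pocket) -> Pocket:
    """Translate every atom so the unweighted ligand centroid is the origin.

    Centring an already-centred pocket is the identity (the centroid is
    already zero), so the operation is idempotent.
    """
    centroid = p.ligand_coords().mean(axis=0)
    return Pocket(
        rna_atoms=_shift_atoms(p.rna_atoms, -centroid),
        ligand_atoms=_shift_atoms(p.ligand_atoms, -centroid),
        radius=p.radius,
        center=p.center if p.centered else centroid,
        centered=True,
        source_id=p.source_id,
    )
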