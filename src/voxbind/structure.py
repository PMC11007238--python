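"""Parsing of RNA-ligand complex structures and curation rules.

Complexes arrive as single PDB files holding the receptor RNA as polymer
``ATOM`` records and the bound small molecule as ``HETATM`` records.  Only
heavy atoms matter downstream (the grid featurization is element-based), so
hydrogens and deuteriums are stripped at partition time.  Curation mirrors
the filters applied to the labelled corpus: no protein chains, RNA of at
least 10 nucleotides, no ion-only or crystallization-artifact ligands, and a
genuine contact (minimum heavy-atom distance below 4 A) between receptor
and ligand.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure.io.pdb as _pdb

logger = logging.getLogger("voxbind")

__all__ = [
    "Atom",
    "Structure",
    "ComplexPair",
    "CurationConfig",
    "ParseError",
    "parse_pdb",
    "partition_complex",
    "passes_curation",
    "min_contact_distance",
]

#: Canonical RNA nucleotides; extended per-config with modified residues.
RNA_RESIDUES = {"A", "C", "G", "U"}

#: Three-letter codes of the 20 standard amino acids, used to detect
#: protein chains during curation.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_RESIDUES = {"HOH", "DOD", "WAT"}

#: Elements recognised during element inference from atom names.  Two-letter
#: symbols are matched before one-letter ones (longest prefix wins).
_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "MG", "MN", "ZN", "FE", "NA", "CA", "SE", "SI", "AL", "CU",
    "NI", "CO", "CD", "HG", "PB", "PT", "AU", "AG", "SR", "BA", "RB", "CS",
    "LI", "BE",
}
_ONE_LETTER_ELEMENTS = {"C", "N", "O", "P", "S", "F", "H", "K", "I", "B", "D"}

HYDROGEN_ELEMENTS = {"H", "D"}


class ParseError(ValueError):
    """Raised when PDB text cannot be converted to a Structure."""


@dataclass(frozen=True)
class Atom:
    """One heavy or light atom from a coordinate record."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    coords: np.ndarray  # shape (3,), Angstrom
    is_hetero: bool

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")


@dataclass
class Structure:
    """Ordered atom list parsed from one PDB file."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ParseError(f"{self.source_id or 'structure'}: no atoms")


@dataclass
class ComplexPair:
    """Heavy-atom receptor/ligand partition of one complex."""

    rna_atoms: list[Atom]
    ligand_atoms: list[Atom]
    ligand_id: str
    source_id: str = ""

    def rna_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.rna_atoms], dtype=float)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float)


@dataclass
class CurationConfig:
    """Filter thresholds for admitting a complex into a dataset.

    ``artifact_ligands`` defaults to common crystallization additives;
    single-heavy-atom hetero residues are treated as ions regardless of code.
    """

    min_rna_length: int = 10
    contact_cutoff: float = 4.0
    artifact_ligands: frozenset[str] = frozenset(
        {"GOL", "EDO", "SO4", "PO4", "MPD", "PEG", "ACT", "DMS", "FMT", "TRS"}
    )
    treat_single_atom_hetero_as_ion: bool = True
    modified_nucleotides: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")
        if self.min_rna_length < 1:
            raise ValueError("min_rna_length must be >= 1")

    def nucleotide_vocab(self) -> set[str]:
        return RNA_RESIDUES | set(self.modified_nucleotides)


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Digits, primes and asterisks are stripped, then the longest prefix that
    is a known element symbol wins (so ``CL1`` -> Cl but ``C1'`` -> C).
    """
    stripped = "".join(
        ch for ch in atom_name.strip().upper() if ch not in "0123456789'*\""
    )
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        sym = stripped[:2]
        return sym[0] + sym[1].lower()
    if stripped[0] in _ONE_LETTER_ELEMENTS:
        return stripped[0]
    raise ParseError(f"cannot infer element from atom name {atom_name!r}")


def _validate_coordinate_fields(text: str) -> int:
    """Pre-scan coordinate records; returns their count.

    Biotite's error messages do not name the offending line, so badly formed
    x/y/z fields are caught here first.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi]
            try:
                float(fieldtxt)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: unparseable {label} coordinate {fieldtxt!r}"
                ) from None
    return n


def parse_pdb(text: str, source_id: str = "") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Model 1 only; alternate locations other than ``' '``/``'A'`` are
    dropped.  The element comes from columns 77-78 when present, otherwise
    it is inferred from the atom name.
    """
    if _validate_coordinate_fields(text) == 0:
        raise ParseError(f"{source_id or 'input'}: no ATOM/HETATM records")
    try:
        with warnings.catch_warnings():
            # biotite warns when it guesses elements; we re-infer below.
            warnings.simplefilter("ignore")
            pdb_file = _pdb.PDBFile.read(io.StringIO(text))
            arr = pdb_file.get_structure(
                model=1, altloc="all", extra_fields=["atom_id"]
            )
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various error types
        raise ParseError(f"{source_id or 'input'}: {exc}") from exc

    keep = np.isin(arr.altloc_id, (" ", "", "A"))
    arr = arr[keep]
    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip()
        if not element:
            element = infer_element(str(arr.atom_name[i]))
        else:
            element = element[0].upper() + element[1:].lower()
        atoms.append(
            Atom(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=element,
                residue_name=str(arr.res_name[i]).strip(),
                residue_index=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                coords=arr.coord[i].astype(float),
                is_hetero=bool(arr.hetero[i]),
            )
        )
    if not atoms:
        raise ParseError(f"{source_id or 'input'}: no usable coordinate records")
    return Structure(atoms=atoms, source_id=source_id)


def _is_heavy(atom: Atom) -> bool:
    return atom.element not in HYDROGEN_ELEMENTS


def hetero_residue_codes(s: Structure) -> set[str]:
    """Residue codes appearing on HETATM records, waters excluded."""
    return {
        a.residue_name
        for a in s.atoms
        if a.is_hetero and a.residue_name not in WATER_RESIDUES
    }


def partition_complex(
    s: Structure,
    ligand_id: str,
    nucleotide_vocab: set[str] | None = None,
) -> ComplexPair:
    """Split a structure into heavy RNA receptor atoms and heavy ligand atoms.

    The ligand is the first (chain, residue) occurrence of ``ligand_id``
    among hetero records; waters and other hetero residues are discarded.
    """
    vocab = nucleotide_vocab if nucleotide_vocab is not None else RNA_RESIDUES
    rna = [
        a
        for a in s.atoms
        if not a.is_hetero and a.residue_name in vocab and _is_heavy(a)
    ]
    lig_instances: dict[tuple[str, int], list[Atom]] = {}
    for a in s.atoms:
        if a.is_hetero and a.residue_name == ligand_id and _is_heavy(a):
            lig_instances.setdefault((a.chain_id, a.residue_index), []).append(a)
    if not lig_instances:
        raise ValueError(f"{s.source_id}: ligand {ligand_id!r} not found among hetero residues")
    first_key = next(iter(lig_instances))
    ligand = lig_instances[first_key]
    if len(lig_instances) > 1:
        logger.debug(
            "%s: ligand %s has %d copies; using chain %s residue %d",
            s.source_id, ligand_id, len(lig_instances), *first_key,
        )
    if not rna:
        raise ValueError(f"{s.source_id}: zero RNA heavy atoms")
    return ComplexPair(
        rna_atoms=rna, ligand_atoms=ligand, ligand_id=ligand_id,
        source_id=s.source_id,
    )


def _longest_rna_chain_length(s: Structure, vocab: set[str]) -> int:
    per_chain: dict[str, set[int]] = {}
    for a in s.atoms:
        if not a.is_hetero and a.residue_name in vocab:
            per_chain.setdefault(a.chain_id, set()).add(a.residue_index)
    if not per_chain:
        return 0
    return max(len(v) for v in per_chain.values())


def min_contact_distance(c: ComplexPair) -> float:
    """Minimum heavy-atom distance between receptor and ligand, in Angstrom."""
    return float(cdist(c.rna_coords(), c.ligand_coords()).min())


def passes_curation(
    c: ComplexPair, s: Structure, cfg: CurationConfig | None = None
) -> tuple[bool, str]:
    """Apply the dataset admission rules; returns (ok, reason).

    Rules, in order: no protein residues on polymer records; longest RNA
    chain at least ``min_rna_length`` nucleotides; ligand neither a
    single-atom ion nor a listed artifact; minimum receptor-ligand
    heavy-atom distance strictly below ``contact_cutoff``.
    """
    cfg = cfg or CurationConfig()
    has_protein = any(
        not a.is_hetero and a.residue_name in AMINO_ACIDS for a in s.atoms
    )
    if has_protein:
        return False, "protein"
    length = _longest_rna_chain_length(s, cfg.nucleotide_vocab())
    if length < cfg.min_rna_length:
        return False, "min_rna_length"
    if cfg.treat_single_atom_hetero_as_ion and len(c.ligand_atoms) == 1:
        return False, "ion"
    if c.ligand_id in cfg.artifact_ligands:
        return False, "artifact"
    if min_contact_distance(c) >= cfg.contact_cutoff:
        return False, "contact"
    return True, "ok"
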