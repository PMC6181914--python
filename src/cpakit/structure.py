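"""Mapping motif positions onto 3D structures.

Residue-residue distances (CA, charged side-chain atoms, or all-atom
minimum), salt-bridge detection by the strict 4 Å cross-class criterion, and
the spatial extent of a residue set (the motif positions cluster around the
ion-binding site, so their maximal pairwise CA distance is a useful
diagnostic).  Author residue numbering is used verbatim — K300, D163, E215,
R432, K305, E333 as printed in structural work on EcNhaA/TtNapA/HsNHA2.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.Atom import Atom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure

log = logging.getLogger(__name__)

BASIC_ATOMS = frozenset({"NZ", "NH1", "NH2", "NE", "ND1", "NE2"})
ACIDIC_ATOMS = frozenset({"OD1", "OD2", "OE1", "OE2"})
ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"LYS", "ARG", "HIS"})  # His counted as basic (configurable)
SALT_BRIDGE_CUTOFF = 4.0  # Å, strict inequality


class PDBParseError(ValueError):
    """Malformed PDB input."""


@dataclass
class StructureModel:
    """First model of a PDB entry: chains -> residues -> atom coordinates."""

    name: str
    chains: dict  # chain id -> {(resnum, icode): {"resname": str, "atoms": {name: xyz}}}

    def residue(self, chain_id: str, resnum: int, icode: str = " ") -> dict:
        try:
            return self.chains[chain_id][(resnum, icode)]
        except KeyError:
            raise KeyError(f"residue {chain_id}:{resnum}{icode.strip()} not in structure") from None

    def residue_ids(self, chain_id: str) -> list:
        return sorted(self.chains[chain_id].keys())


def parse_pdb(text: str, name: str = "structure") -> StructureModel:
    """Parse legacy PDB text: first model only, altloc A preferred."""
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(name, io.StringIO(text))
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB record: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise PDBParseError("no MODEL/ATOM records found")
    model = models[0]
    chains: dict = {}
    for chain in model:
        residues = {}
        for res in chain:
            hetflag, resnum, icode = res.id
            atoms = {}
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if atoms:
                residues[(resnum, icode)] = {"resname": res.get_resname(), "atoms": atoms}
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise PDBParseError("structure contains no atoms")
    return StructureModel(name, chains)


def read_pdb(path) -> StructureModel:
    with open(path) as fh:
        return parse_pdb(fh.read(), name=str(path))


def write_pdb(model: StructureModel, path) -> None:
    """Serialise a StructureModel back to legacy PDB (3-decimal coordinates)."""
    structure = Structure(model.name)
    md = Model(0)
    structure.add(md)
    serial = 1
    for chain_id, residues in model.chains.items():
        chain = Chain(chain_id)
        md.add(chain)
        for (resnum, icode), res in sorted(residues.items()):
            residue = Residue((" ", resnum, icode), res["resname"], "")
            for atom_name, coord in res["atoms"].items():
                element = atom_name.strip()[0]
                residue.add(Atom(atom_name, np.asarray(coord, dtype=float), 0.0, 1.0,
                                 " ", atom_name.ljust(4), serial, element=element))
                serial += 1
            chain.add(residue)
    pdb_io = PDBIO()
    pdb_io.set_structure(structure)
    pdb_io.save(str(path))


# -- geometry -----------------------------------------------------------------------


def _charged_atoms(res: dict, label: str) -> dict:
    resname = res["resname"]
    if resname in ACIDIC_RESIDUES:
        pool = ACIDIC_ATOMS
    elif resname in BASIC_RESIDUES:
        pool = BASIC_ATOMS
    else:
        raise ValueError(f"residue {label} ({resname}) carries no charged side chain")
    atoms = {n: c for n, c in res["atoms"].items() if n in pool}
    if not atoms:
        raise ValueError(f"residue {label} ({resname}) lacks charged side-chain atoms")
    return atoms


def residue_distance(
    model: StructureModel,
    a: tuple,
    b: tuple,
    atom_selection: str = "all-atom-min",
) -> float:
    """Distance in Å between residues ``a`` and ``b`` = (chain, resnum[, icode]).

    ``atom_selection``: "CA" (alpha carbons), "side-chain-charged" (minimum
    over charged side-chain atom pairs) or "all-atom-min".
    """
    ra = model.residue(*a)
    rb = model.residue(*b)
    la = f"{a[0]}:{a[1]}"
    lb = f"{b[0]}:{b[1]}"
    if atom_selection == "CA":
        for res, lab in ((ra, la), (rb, lb)):
            if "CA" not in res["atoms"]:
                raise ValueError(f"residue {lab} has no CA atom")
        pa = {"CA": ra["atoms"]["CA"]}
        pb = {"CA": rb["atoms"]["CA"]}
    elif atom_selection == "side-chain-charged":
        pa = _charged_atoms(ra, la)
        pb = _charged_atoms(rb, lb)
    elif atom_selection == "all-atom-min":
        pa, pb = ra["atoms"], rb["atoms"]
    else:
        raise ValueError(f"unknown atom selection {atom_selection!r}")
    return min(
        float(np.linalg.norm(ca - cb)) for ca in pa.values() for cb in pb.values()
    )


@dataclass(frozen=True)
class ContactReport:
    residue_a: tuple
    residue_b: tuple
    atom_a: str
    atom_b: str
    distance: float
    is_bridge: bool


def detect_salt_bridges(
    model: StructureModel,
    pairs,
    cutoff: float = SALT_BRIDGE_CUTOFF,
    histidine_basic: bool = True,
) -> list[ContactReport]:
    """Salt bridges among (acidic, basic) residue pairs.

    A bridge requires the minimum basic-N to acidic-O distance to be strictly
    below ``cutoff`` (the "lower than 4 Å" convention).  Passing a pair whose
    residues are not one acidic + one basic raises an error.
    """
    basic_set = BASIC_RESIDUES if histidine_basic else BASIC_RESIDUES - {"HIS"}
    reports = []
    for a, b in pairs:
        ra, rb = model.residue(*a), model.residue(*b)
        names = {ra["resname"], rb["resname"]}
        if ra["resname"] in ACIDIC_RESIDUES and rb["resname"] in basic_set:
            acid, base, la, lb = ra, rb, a, b
        elif rb["resname"] in ACIDIC_RESIDUES and ra["resname"] in basic_set:
            acid, base, la, lb = rb, ra, b, a
        else:
            raise ValueError(f"pair {a}/{b} ({sorted(names)}) is not acidic+basic")
        acid_atoms = {n: c for n, c in acid["atoms"].items() if n in ACIDIC_ATOMS}
        base_atoms = {n: c for n, c in base["atoms"].items() if n in BASIC_ATOMS}
        if not acid_atoms or not base_atoms:
            raise ValueError(f"pair {a}/{b} lacks charged side-chain atoms")
        best = min(
            ((float(np.linalg.norm(ca - cb)), na, nb)
             for na, ca in acid_atoms.items() for nb, cb in base_atoms.items()),
        )
        dist, atom_acid, atom_base = best
        reports.append(ContactReport(la, lb, atom_acid, atom_base, dist,
                                     dist < cutoff))
    return reports


def motif_spatial_extent(model: StructureModel, residues) -> float:
    """Maximum pairwise CA distance (Å) over the given residues.

    Residues missing from the structure (or lacking CA) are skipped with a
    warning; a single resolved residue gives extent 0.
    """
    coords = []
    for spec in residues:
        try:
            res = model.residue(*spec)
            coords.append(res["atoms"]["CA"])
        except KeyError:
            log.warning("residue %s unresolved or lacking CA: skipped", (spec,))
    if len(coords) < 2:
        return 0.0
    coords = np.asarray(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def contact_report_tsv(reports: list[ContactReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("residue_a\tresidue_b\tatom_a\tatom_b\tdistance_A\tsalt_bridge\n")
        for r in reports:
            fh.write(f"{r.residue_a[0]}:{r.residue_a[1]}\t{r.residue_b[0]}:{r.residue_b[1]}"
                     f"\t{r.atom_a}\t{r.atom_b}\t{r.distance:.3f}\t{int(r.is_bridge)}\n")
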