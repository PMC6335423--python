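"""Map mutated residues onto 3D structures: distances, interfaces, contacts.

Structures are read from PDB-format files into a light coordinate
container (chains -> residues -> heavy atoms).  Distance queries use
minimum heavy-atom distances: a residue belongs to a chain-chain interface
when its minimum distance to any residue of the partner chain falls below
a cutoff (default 5.0 A), and intra-chain contact partners are residues
within 4.5 A at sequence separation >= 3.  The cutoffs are conventions,
exposed as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .variants import IsoformMap, ProteinChange, harmonize_isoform, UnmappableChange

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResidueContact",
    "InterfaceReport",
    "FormatError",
    "LookupErrorStruct",
    "read_structure",
    "residue_min_distance",
    "interface_residues",
    "contact_partners",
    "map_mutations_to_structure",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    pass


class LookupErrorStruct(KeyError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    coord: tuple  # (x, y, z) in Angstrom


@dataclass(frozen=True)
class Residue:
    res_seq: str  # residue number, insertion code appended if present
    name: str
    atoms: tuple  # of Atom

    @property
    def number(self) -> int:
        digits = "".join(ch for ch in self.res_seq if ch.isdigit() or ch == "-")
        return int(digits)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Polymer chains plus a separate ligand namespace (HETATM groups).

    Hydrogens and waters are dropped at load time; ligands are kept but
    excluded from residue distance queries unless addressed explicitly.
    """

    chains: dict = field(default_factory=dict)  # chain_id -> list[Residue]
    ligands: dict = field(default_factory=dict)  # chain_id -> list[Residue]

    def residue(self, chain_id: str, res_seq) -> Residue:
        key = str(res_seq)
        try:
            chain = self.chains[chain_id]
        except KeyError:
            raise LookupErrorStruct(f"chain {chain_id!r} not in model") from None
        for r in chain:
            if r.res_seq == key:
                return r
        raise LookupErrorStruct(
            f"residue {key} not found in chain {chain_id!r}"
        )

    def has_residue(self, chain_id: str, res_seq) -> bool:
        try:
            self.residue(chain_id, res_seq)
            return True
        except LookupErrorStruct:
            return False


def _pick_altloc(atom):
    """Resolve disordered atoms: highest occupancy, tie -> altloc 'A'."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    return max(children, key=lambda a: (a.get_occupancy() or 0.0,
                                        a.get_altloc() == "A"))


def read_structure(path, model_index: int = 0) -> StructureModel:
    """Load one model from a PDB-format file.

    ``model_index`` selects among MODEL records (0 = first).  Raises
    :class:`FormatError` for unreadable files, a missing model index, or a
    file with no polymer residues.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("model", str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise FormatError(f"no models in {path}")
    if model_index >= len(models):
        raise FormatError(
            f"model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]
    out = StructureModel()
    n_polymer = 0
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            if resname in _WATER_NAMES or hetflag == "W":
                continue
            atoms = []
            for atom in res.get_atoms():
                atom = _pick_altloc(atom)
                element = (atom.element or "").strip().upper()
                if element == "H" or element == "D":
                    continue
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(Atom(atom.get_name(), (x, y, z)))
            if not atoms:
                continue
            key = f"{resseq}{icode.strip()}"
            residue = Residue(key, resname, tuple(atoms))
            if hetflag.strip():  # HETATM ligand
                out.ligands.setdefault(chain.id, []).append(residue)
            else:
                out.chains.setdefault(chain.id, []).append(residue)
                n_polymer += 1
    if n_polymer == 0:
        raise FormatError(f"no polymer residues in {path}")
    return out


def residue_min_distance(
    model: StructureModel, chain_a: str, res_a, chain_b: str, res_b
) -> float:
    """Minimum heavy-atom distance between two residues, in Angstrom.

    A residue against itself returns 0.0 by convention.
    """
    ra = model.residue(chain_a, res_a)
    rb = model.residue(chain_b, res_b)
    if chain_a == chain_b and ra.res_seq == rb.res_seq:
        return 0.0
    return float(cdist(ra.coords(), rb.coords()).min())


@dataclass(frozen=True)
class ResidueContact:
    chain_a: str
    res_a: str
    chain_b: str
    res_b: str
    min_distance: float


@dataclass(frozen=True)
class InterfaceReport:
    pair: tuple
    cutoff: float
    interface_residues_a: frozenset
    interface_residues_b: frozenset
    flagged_mutations: tuple = ()


def _chain_residue_distances(ra_list, rb_list) -> np.ndarray:
    """Matrix of residue-residue minimum heavy-atom distances."""
    coords_a = [r.coords() for r in ra_list]
    coords_b = [r.coords() for r in rb_list]
    d = cdist(np.concatenate(coords_a), np.concatenate(coords_b))
    ends_a = np.cumsum([len(c) for c in coords_a])
    ends_b = np.cumsum([len(c) for c in coords_b])
    starts_a = np.concatenate(([0], ends_a[:-1]))
    starts_b = np.concatenate(([0], ends_b[:-1]))
    out = np.empty((len(ra_list), len(rb_list)))
    for i, (sa, ea) in enumerate(zip(starts_a, ends_a)):
        for j, (sb, eb) in enumerate(zip(starts_b, ends_b)):
            out[i, j] = d[sa:ea, sb:eb].min()
    return out


def interface_residues(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 5.0
) -> InterfaceReport:
    """Residues of each chain within ``cutoff`` of the partner chain."""
    for cid in (chain_a, chain_b):
        if cid not in model.chains or not model.chains[cid]:
            raise LookupErrorStruct(f"chain {cid!r} absent or empty")
    ra_list = model.chains[chain_a]
    rb_list = model.chains[chain_b]
    dmat = _chain_residue_distances(ra_list, rb_list)
    mask = dmat <= cutoff
    set_a = frozenset(r.res_seq for r, hit in zip(ra_list, mask.any(axis=1)) if hit)
    set_b = frozenset(r.res_seq for r, hit in zip(rb_list, mask.any(axis=0)) if hit)
    return InterfaceReport(
        pair=(chain_a, chain_b),
        cutoff=cutoff,
        interface_residues_a=set_a,
        interface_residues_b=set_b,
    )


def contact_partners(
    model: StructureModel,
    chain: str,
    res,
    cutoff: float = 4.5,
    min_seq_sep: int = 3,
) -> list[ResidueContact]:
    """Intra-chain contacts of one residue, sorted by distance.

    Sequence separation below ``min_seq_sep`` is excluded to suppress
    trivial backbone neighbors.
    """
    target = model.residue(chain, res)
    contacts = []
    for other in model.chains[chain]:
        if other.res_seq == target.res_seq:
            continue
        if abs(other.number - target.number) < min_seq_sep:
            continue
        d = float(cdist(target.coords(), other.coords()).min())
        if d <= cutoff:
            contacts.append(
                ResidueContact(chain, target.res_seq, chain, other.res_seq, d)
            )
    contacts.sort(key=lambda c: (c.min_distance, c.res_b))
    return contacts


@dataclass(frozen=True)
class MutationStructureAnnotation:
    gene: str
    change: ProteinChange
    chain: str | None
    structure_position: int | None
    resolved: bool
    in_interface: bool | None = None
    partners: tuple = ()


def map_mutations_to_structure(
    mutations: Sequence[tuple],
    model: StructureModel,
    chain_of_gene: Mapping[str, str],
    partner_of_chain: Mapping[str, str] | None = None,
    numbering_offset: Mapping[str, IsoformMap] | None = None,
    interface_cutoff: float = 5.0,
    contact_cutoff: float = 4.5,
    min_seq_sep: int = 3,
) -> list[MutationStructureAnnotation]:
    """Annotate (gene, change) pairs with structural context.

    A mutation whose position is absent from the model (disordered or
    outside the crystallized construct, e.g. outside an LBD-only 231-505
    construct) is flagged unresolved, never dropped.  ``numbering_offset``
    optionally renumbers each gene's mutations into the model's frame.
    ``partner_of_chain`` names the chain against which interface membership
    is evaluated.
    """
    partner_of_chain = partner_of_chain or {}
    numbering_offset = numbering_offset or {}
    iface_cache: dict = {}
    annotations = []
    for gene, change in mutations:
        if gene not in chain_of_gene:
            raise KeyError(f"gene {gene!r} has no chain mapping")
        chain = chain_of_gene[gene]
        if gene in numbering_offset:
            mapped = harmonize_isoform(change, numbering_offset[gene])
            if isinstance(mapped, UnmappableChange):
                annotations.append(
                    MutationStructureAnnotation(gene, change, chain, None, False)
                )
                continue
            pos = mapped.position
        else:
            pos = change.position
        if not model.has_residue(chain, pos):
            annotations.append(
                MutationStructureAnnotation(gene, change, chain, pos, False)
            )
            continue
        in_iface = None
        partner = partner_of_chain.get(chain)
        if partner is not None:
            key = (chain, partner)
            if key not in iface_cache:
                iface_cache[key] = interface_residues(
                    model, chain, partner, cutoff=interface_cutoff
                )
            in_iface = str(pos) in iface_cache[key].interface_residues_a
        partners = tuple(
            contact_partners(model, chain, pos, cutoff=contact_cutoff,
                             min_seq_sep=min_seq_sep)
        )
        annotations.append(
            MutationStructureAnnotation(
                gene, change, chain, pos, True, in_iface, partners
            )
        )
    return annotations
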