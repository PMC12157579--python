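"""Read PDB/mmCIF models into a light internal representation.

pLDDT is taken from the B-factor column of the CA atom, following the
AlphaFold convention. Hydrogens, waters and non-polymer entities are
dropped on input; only the first model of multi-model files is read.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureFormatError",
    "PlddtRangeError",
    "read_structure",
    "segment_chain",
    "write_structure_subset",
]

_BACKBONE = ("N", "CA", "C")


class StructureFormatError(ValueError):
    """Raised when the input cannot be parsed as the named format."""


class PlddtRangeError(ValueError):
    """Raised when a CA B-value falls outside the pLDDT range [0, 100]."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Angstroms
    b_value: float
    serial: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name!r} has empty element")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: list[Atom]
    plddt: float | None = None

    @property
    def rid(self) -> str:
        """Canonical residue identifier, e.g. 'A 15' or 'A 15B'."""
        return f"{self.chain_id} {self.seq_number}{self.insertion_code}".rstrip()

    @property
    def eligible(self) -> bool:
        """Classification-eligible residues carry a full N/CA/C backbone."""
        names = {a.name for a in self.atoms}
        return all(n in names for n in _BACKBONE) and self.plddt is not None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.position


@dataclasses.dataclass
class StructureModel:
    """Residues in file order, grouped by chain, plus peptide segments.

    ``segments`` holds lists of residue indices (into ``residues``), each a
    maximal peptide-bonded run within one chain; populated by
    :func:`segment_chain`.
    """

    residues: list[Residue]
    segments: list[list[int]] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def chains(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, res in enumerate(self.residues):
            out.setdefault(res.chain_id, []).append(i)
        return out

    def segment_of(self) -> list[int]:
        """Per-residue segment index (requires segments populated)."""
        seg_of = [-1] * len(self.residues)
        for s, seg in enumerate(self.segments):
            for i in seg:
                seg_of[i] = s
        return seg_of

    def index_of(self) -> dict[str, int]:
        return {r.rid: i for i, r in enumerate(self.residues)}


def _sniff_format(text: str) -> str:
    head = text.lstrip()[:2048]
    if head.startswith("data_") or "\nloop_" in head or head.startswith("#"):
        return "mmcif"
    return "pdb"


def _as_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if "\n" not in source and len(source) < 4096:
        p = Path(source)
        if p.exists():
            return p.read_text()
    return str(source)


def _guess_format(source: str | Path, text: str) -> str:
    name = str(source).lower()
    if name.endswith((".cif", ".mmcif")):
        return "mmcif"
    if name.endswith((".pdb", ".ent")):
        return "pdb"
    return _sniff_format(text)


def read_structure(source: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF model; pLDDT is read from each CA B-value.

    Residues lacking a CA are retained but ineligible for classification.
    A CA B-value outside [0, 100] raises :class:`PlddtRangeError`.
    """
    text = _as_text(source)
    fmt = format if format in ("pdb", "mmcif") else _guess_format(source, text)
    parser = PDBParser(QUIET=True) if fmt == "pdb" else MMCIFParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("model", io.StringIO(text))
    except Exception as exc:  # Bio raises assorted exception types
        raise StructureFormatError(f"could not parse input as {fmt}: {exc}") from exc

    try:
        biomodel = next(structure.get_models())
    except StopIteration:
        raise StructureFormatError("input contains no models")

    residues: list[Residue] = []
    for chain in biomodel:
        for res in chain:
            het, seq, icode = res.get_id()
            if het.strip():  # waters, ligands, other non-polymer entities
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                name = atom.get_name().strip()
                if name in seen:
                    continue
                seen.add(name)
                atoms.append(
                    Atom(
                        name=name,
                        element=element or name[:1],
                        position=np.array(atom.get_coord(), dtype=float),
                        b_value=float(atom.get_bfactor()),
                        serial=int(atom.get_serial_number() or 0),
                    )
                )
            if not atoms:
                continue
            residue = Residue(
                chain_id=chain.get_id().strip() or "A",
                seq_number=int(seq),
                insertion_code=icode.strip(),
                name=res.get_resname().strip(),
                atoms=atoms,
            )
            ca = residue.atom("CA")
            if ca is not None:
                if not 0.0 <= ca.b_value <= 100.0:
                    raise PlddtRangeError(
                        f"residue {residue.rid}: CA B-value {ca.b_value} "
                        "outside pLDDT range [0, 100]"
                    )
                residue.plddt = ca.b_value
                if any(abs(a.b_value - ca.b_value) > 1e-6 for a in atoms):
                    warnings.warn(
                        f"residue {residue.rid}: heterogeneous B-values; "
                        "pLDDT taken from CA",
                        stacklevel=2,
                    )
            residues.append(residue)

    if not residues:
        raise StructureFormatError("no polymer residues found in input")
    return segment_chain(StructureModel(residues=residues))


def segment_chain(model: StructureModel, peptide_bond_max: float = 2.5) -> StructureModel:
    """Partition residues into maximal peptide-bonded runs per chain.

    Residues i and i+1 share a segment iff they are in the same chain and
    d(C_i, N_{i+1}) <= ``peptide_bond_max``. Missing atoms end a segment.
    """
    segments: list[list[int]] = []
    current: list[int] = []
    for i, res in enumerate(model.residues):
        if not current:
            current = [i]
            continue
        prev = model.residues[current[-1]]
        bonded = False
        if prev.chain_id == res.chain_id:
            c = prev.coord("C")
            n = res.coord("N")
            if c is not None and n is not None:
                bonded = float(np.linalg.norm(c - n)) <= peptide_bond_max
        if bonded:
            current.append(i)
        else:
            segments.append(current)
            current = [i]
    if current:
        segments.append(current)
    model.segments = segments
    return model


def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB: element right-aligned in columns 13-14 for 1-2 char
    # elements; 4-char names fill the whole field.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure_subset(model: StructureModel, keep) -> str:
    """Render the kept residues as PDB ATOM records, order preserved.

    ``keep`` is a set of residue identifiers (``Residue.rid`` strings).
    Raises ``ValueError`` on an empty selection.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("refusing to write an empty model (no residues kept)")
    known = {r.rid for r in model.residues}
    missing = keep - known
    if missing:
        raise ValueError(f"unknown residue identifiers: {sorted(missing)[:5]}")

    lines: list[str] = []
    serial = 0
    last_chain: str | None = None
    last_res: Residue | None = None
    for res in model.residues:
        if res.rid not in keep:
            continue
        if last_chain is not None and res.chain_id != last_chain:
            serial += 1
            lines.append(_ter_record(serial, last_res))
        for atom in res.atoms:
            serial += 1
            lines.append(
                "ATOM  {serial:>5d} {name}{alt}{res:<3s} {chain}{seq:>4d}{icode}"
                "   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
                "          {elem:>2s}".format(
                    serial=serial,
                    name=_format_atom_name(atom.name, atom.element),
                    alt=" ",
                    res=res.name,
                    chain=(res.chain_id or "A")[:1],
                    seq=res.seq_number,
                    icode=res.insertion_code[:1] or " ",
                    x=atom.position[0],
                    y=atom.position[1],
                    z=atom.position[2],
                    occ=1.0,
                    b=atom.b_value,
                    elem=atom.element[:2],
                )
            )
        last_chain = res.chain_id
        last_res = res
    serial += 1
    lines.append(_ter_record(serial, last_res))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _ter_record(serial: int, res: Residue | None) -> str:
    if res is None:
        return "TER"
    return "TER   {serial:>5d}      {res:<3s} {chain}{seq:>4d}{icode}".format(
        serial=serial,
        res=res.name,
        chain=(res.chain_id or "A")[:1],
        seq=res.seq_number,
        icode=res.insertion_code[:1] or " ",
    )
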