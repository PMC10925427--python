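"""Reading and writing of macromolecular coordinate files.

Thin domain model (:class:`AtomRecord` / :class:`Residue` / :class:`Chain` /
:class:`Structure`) backed by gemmi for parsing PDB and mmCIF.  Predicted
zinc sites are written back as HETATM/LINK records (PDB) or
atom_site/struct_conn (mmCIF), with the per-site certainty score stored in
the occupancy field of the zinc record.

Hydrogens are read and retained in the record lists but every downstream
module ignores them: metals coordinate heavy atoms only.  Waters are kept
as ordinary residues; they never seed a candidate site but may appear as
first/second-sphere auxiliary ligands.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "ParseError",
    "FormatError",
    "read_structure",
    "primary_conformer",
    "write_predictions",
    "structure_to_text",
]

#: chain identifier given to predicted zinc ions in output files; a distinct
#: segment marks predictions apart from experimental records.
PREDICTED_CHAIN_ID = "Z"

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# elements treated as (potential) coordination metals by downstream modules
METAL_ELEMENTS = {
    "ZN", "CU", "FE", "MN", "CO", "NI", "CD", "MG", "CA", "NA", "K",
    "HG", "PB", "PT", "AU", "AG", "MO", "W", "V", "CR",
}


class ParseError(ValueError):
    """A coordinate file failed to parse under the named standard."""


class FormatError(ValueError):
    """Unknown or unsupported coordinate format."""


@dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``occupancy`` must lie in [0, 1] and ``b_factor`` must be non-negative;
    positions are finite 3-vectors in Å.
    """

    serial: int
    name: str
    altloc: str          # '' when blank
    res_name: str
    chain_id: str
    resseq: int
    icode: str           # '' when blank
    position: np.ndarray
    occupancy: float
    b_factor: float
    element: str
    is_hetero: bool

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_metal(self) -> bool:
        return self.element.upper() in METAL_ELEMENTS

    def key(self) -> tuple:
        return (self.chain_id, self.resseq, self.icode, self.name, self.altloc)


@dataclass
class Residue:
    res_name: str
    resseq: int
    icode: str
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    #: set by :func:`primary_conformer` when alternate conformations were pruned
    multi_conformer: bool = False

    def key(self) -> tuple:
        """Residue identity: (chain, resseq, icode)."""
        return (self.chain_id, self.resseq, self.icode)

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: Optional[float] = None
    method: Optional[str] = None

    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def atoms(self) -> Iterator[AtomRecord]:
        for res in self.residues():
            yield from res.atoms

    def heavy_atoms(self) -> Iterator[AtomRecord]:
        return (a for a in self.atoms() if not a.is_hydrogen)

    def find_residue(self, key: tuple) -> Optional[Residue]:
        for res in self.residues():
            if res.key() == key:
                return res
        return None

    def metal_atoms(self) -> list[AtomRecord]:
        """Modelled metal ions (single-atom metallic HETATM records)."""
        return [a for a in self.atoms() if a.is_hetero and a.is_metal]


# ---------------------------------------------------------------------------
# reading

def _sniff_format(text: str) -> str:
    head = text.lstrip()[:4096]
    if head.startswith("data_") or "_atom_site." in head or head.startswith("#"):
        return "mmcif"
    return "pdb"


def _from_gemmi(st: gemmi.Structure, sid: str) -> Structure:
    if len(st) == 0:
        return Structure(id=sid)
    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        chain = Chain(chain_id=gch.name)
        for gres in gch:
            res = Residue(
                res_name=gres.name,
                resseq=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                chain_id=gch.name,
            )
            for ga in gres:
                altloc = "" if ga.altloc in ("\0", " ", "") else ga.altloc
                element = ga.element.name.upper()
                if not element or element == "X":
                    element = _element_from_name(ga.name)
                res.atoms.append(AtomRecord(
                    serial=ga.serial,
                    name=ga.name,
                    altloc=altloc,
                    res_name=gres.name,
                    chain_id=gch.name,
                    resseq=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=max(ga.b_iso, 0.0),
                    element=element,
                    is_hetero=(gres.het_flag == "H"),
                ))
            chain.residues.append(res)
        chains.append(chain)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    try:
        method = st.info["_exptl.method"] or None
    except KeyError:
        method = None
    return Structure(id=sid or st.name, chains=chains, resolution=resolution, method=method)


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in METAL_ELEMENTS or two in ("CL", "BR", "SE"):
        return two
    return stripped[0].upper()


def read_structure(source: str | Path, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF coordinate file (path or raw text).

    ``source`` may be a filesystem path or the file content itself.  With
    ``format='auto'`` the format is sniffed from the content (``data_`` /
    ``_atom_site.`` marks mmCIF).  All ATOM/HETATM records are represented;
    alternate-conformation indicators are preserved.
    """
    if format not in ("pdb", "mmcif", "auto"):
        raise FormatError(f"unknown format {format!r}")
    is_path = isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    )
    if is_path:
        path = Path(source)
        text = path.read_text()
        sid = path.stem
        if format == "auto":
            suffix = path.suffix.lower()
            if suffix in (".cif", ".mmcif"):
                format = "mmcif"
            elif suffix in (".pdb", ".ent"):
                format = "pdb"
    else:
        text = str(source)
        sid = "structure"
    if format == "auto":
        format = _sniff_format(text)
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {format} input: {exc}") from exc
    return _from_gemmi(st, sid)


# ---------------------------------------------------------------------------
# alternate conformations

def primary_conformer(structure: Structure) -> Structure:
    """Collapse alternate conformations onto the primary one.

    For every atom with alternates, keeps the highest-occupancy conformer
    (ties broken by the lowest altloc character) and flags the residue as
    multi-conformational so training-set construction can exclude it.
    Returns a new Structure; the input is not modified.
    """
    out = Structure(id=structure.id, resolution=structure.resolution,
                    method=structure.method)
    for ch in structure.chains:
        new_chain = Chain(chain_id=ch.chain_id)
        for res in ch.residues:
            new_res = Residue(res_name=res.res_name, resseq=res.resseq,
                              icode=res.icode, chain_id=res.chain_id,
                              multi_conformer=res.multi_conformer)
            by_name: dict[str, list[AtomRecord]] = {}
            order: list[str] = []
            for a in res.atoms:
                if a.name not in by_name:
                    by_name[a.name] = []
                    order.append(a.name)
                by_name[a.name].append(a)
            for name in order:
                group = by_name[name]
                if len(group) > 1:
                    new_res.multi_conformer = True
                best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
                new_res.atoms.append(best)
            new_chain.residues.append(new_res)
        out.chains.append(new_chain)
    return out


# ---------------------------------------------------------------------------
# writing

def _pdb_atom_name_field(name: str, element: str) -> str:
    # columns 13-16: 1-2 letter elements start in column 14 unless the name
    # is four characters long
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def _format_pdb_atom(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = _pdb_atom_name_field(a.name, a.element)
    alt = a.altloc if a.altloc else " "
    icode = a.icode if a.icode else " "
    x, y, z = a.position
    return (
        f"{record}{serial:5d} {name}{alt}{a.res_name:>3s} {a.chain_id[:1]}"
        f"{a.resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
        f"{a.element:>2s}"
    )


def _format_link(zn: AtomRecord, donor: AtomRecord, distance: float) -> str:
    n1 = _pdb_atom_name_field(zn.name, zn.element)
    n2 = _pdb_atom_name_field(donor.name, donor.element)
    i1 = zn.icode if zn.icode else " "
    i2 = donor.icode if donor.icode else " "
    a1 = zn.altloc if zn.altloc else " "
    a2 = donor.altloc if donor.altloc else " "
    return (
        f"LINK        {n1}{a1}{zn.res_name:>3s} {zn.chain_id[:1]}{zn.resseq:4d}{i1}"
        f"               {n2}{a2}{donor.res_name:>3s} {donor.chain_id[:1]}"
        f"{donor.resseq:4d}{i2}  1555   1555 {distance:5.2f}"
    )


def _zinc_records(sites: Sequence) -> list[tuple[AtomRecord, list[AtomRecord]]]:
    """Build one ZN HETATM per placed site plus its coordinating partners."""
    out = []
    for i, site in enumerate(sites):
        certainty = getattr(site, "certainty", None)
        if certainty is None:
            certainty = 0.0
        if not (0.0 <= certainty <= 1.0):
            raise ValueError(f"site certainty {certainty} outside [0, 1]")
        zn = AtomRecord(
            serial=0,
            name="ZN",
            altloc="",
            res_name="ZN",
            chain_id=PREDICTED_CHAIN_ID,
            resseq=i + 1,
            icode="",
            position=np.asarray(site.zinc_position, dtype=float),
            occupancy=round(certainty, 2),
            b_factor=0.0,
            element="ZN",
            is_hetero=True,
        )
        partners = [ca.atom for ca in site.site.chosen_atoms]
        out.append((zn, partners))
    return out


def write_predictions(structure: Structure, sites: Sequence, format: str = "pdb") -> str:
    """Render the structure plus predicted zinc sites as PDB or mmCIF text.

    Each site becomes one hetero ZN record whose occupancy field carries the
    certainty (rounded to 2 decimals) and one LINK / struct_conn entry per
    coordination bond.  Pre-existing atoms are written unmodified and in
    their original order.
    """
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown output format {format!r}")
    zincs = _zinc_records(sites)
    if format == "pdb":
        lines = []
        for zn, partners in zincs:
            for donor in partners:
                d = float(np.linalg.norm(zn.position - donor.position))
                lines.append(_format_link(zn, donor, d))
        serial = 0
        for a in structure.atoms():
            serial += 1
            lines.append(_format_pdb_atom(a, serial))
        for zn, _ in zincs:
            serial += 1
            lines.append(_format_pdb_atom(zn, serial))
        lines.append("END")
        return "\n".join(lines) + "\n"
    # mmCIF via gemmi, connections through struct_conn
    st = _to_gemmi(structure, zincs)
    return st.make_mmcif_document().as_string()


def structure_to_text(structure: Structure, format: str = "pdb") -> str:
    """Write a structure with no predicted sites (plain serialization)."""
    return write_predictions(structure, [], format=format)


def _to_gemmi(structure: Structure, zincs) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    serial = 0
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.resseq, res.icode or " ")
            gres.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            for a in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = a.name
                ga.altloc = a.altloc if a.altloc else "\0"
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.element = gemmi.Element(a.element.capitalize())
                ga.serial = serial
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    if zincs:
        gch = gemmi.Chain(PREDICTED_CHAIN_ID)
        for zn, _ in zincs:
            serial += 1
            gres = gemmi.Residue()
            gres.name = "ZN"
            gres.seqid = gemmi.SeqId(zn.resseq, " ")
            gres.het_flag = "H"
            ga = gemmi.Atom()
            ga.name = "ZN"
            ga.pos = gemmi.Position(*zn.position)
            ga.occ = zn.occupancy
            ga.b_iso = 0.0
            ga.element = gemmi.Element("Zn")
            ga.serial = serial
            gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    for zn, partners in zincs:
        for k, donor in enumerate(partners):
            con = gemmi.Connection()
            con.name = f"znlink{zn.resseq}_{k}"
            con.type = gemmi.ConnectionType.MetalC
            con.partner1 = gemmi.AtomAddress(
                PREDICTED_CHAIN_ID, gemmi.SeqId(zn.resseq, " "), "ZN", "ZN")
            con.partner2 = gemmi.AtomAddress(
                donor.chain_id, gemmi.SeqId(donor.resseq, donor.icode or " "),
                donor.res_name, donor.name)
            con.reported_distance = float(
                np.linalg.norm(zn.position - donor.position))
            st.connections.append(con)
    return st
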