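"""Coordinate I/O and atom selection.

Structures are held as flat, ordered lists of atom records in full-length
residue numbering (the deposited transporter models keep UniProt numbering
even for truncated constructs, so W84 is always resseq 84).  Trajectories
pair one topology with a stack of per-frame coordinate arrays in Å.

PDB parsing and writing are delegated to :mod:`gemmi`; a plain per-frame
XYZ dialect (count line, comment line, ``element x y z`` rows, with an
optional ``box a b c`` token on the comment line) is supported for
trajectories because engine-native binary formats are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "select_atoms",
    "atomic_mass",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a coordinate model (PDB conventions, Å)."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    position: tuple[float, float, float]
    element: str
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            object.__setattr__(
                self, "element", _element_from_name(self.name, self.resname)
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """Ordered collection of atoms, heteroatoms (ions, ligands) included."""

    atoms: list[AtomRecord]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with positions replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected {(len(self.atoms), 3)} array, got {coords.shape}")
        atoms = [
            replace(a, position=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms=atoms, id=self.id)

    def find_atom(
        self, chain: str, resseq: int, name: str, icode: str = ""
    ) -> AtomRecord | None:
        for a in self.atoms:
            if (
                a.chain == chain
                and a.resseq == resseq
                and a.name == name
                and a.icode == icode
            ):
                return a
        return None


@dataclass
class Trajectory:
    """Fixed topology plus per-frame coordinates.

    ``box`` holds orthorhombic box edge lengths in Å where periodic
    normalisation (solvent RDF) needs them; ``frame_spacing`` is metadata
    only and carries no unit enforcement.
    """

    topology: Structure
    frames: list[np.ndarray]
    frame_spacing: float = 1.0
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory must contain at least one frame")
        n = len(self.topology)
        converted = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )
            converted.append(f)
        self.frames = converted

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter resolved against a Structure.

    All criteria are conjunctive; ``None`` means "no constraint".
    Residue ranges are inclusive and use the structure's own numbering.
    """

    chain: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    resnames: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False

    @classmethod
    def make(
        cls,
        chain: str | None = None,
        residues: Iterable[int] | Iterable[tuple[int, int]] | None = None,
        resnames: Iterable[str] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> "Selection":
        """Convenience constructor accepting residue numbers or (lo, hi) pairs."""
        ranges: tuple[tuple[int, int], ...] | None = None
        if residues is not None:
            out = []
            for r in residues:
                if isinstance(r, tuple):
                    lo, hi = r
                else:
                    lo = hi = int(r)
                out.append((int(lo), int(hi)))
            ranges = tuple(out)
        return cls(
            chain=chain,
            residue_ranges=ranges,
            resnames=frozenset(resnames) if resnames is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            heavy_only=heavy_only,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.resseq <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.resnames is not None and atom.resname not in self.resnames:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.heavy_only and atom.is_hydrogen:
            return False
        return True


def select_atoms(structure: Structure, sel: Selection) -> list[int]:
    """Indices of atoms matching ``sel``, in file order (possibly empty)."""
    return [i for i, a in enumerate(structure.atoms) if sel.matches(a)]


_DIGITS = set("0123456789")


def _element_from_name(name: str, resname: str = "") -> str:
    """Infer the element from a PDB atom name when the element column is absent.

    Monatomic ions are recognised by the PDB convention that the residue
    name equals the atom name (e.g. ZN, NA, CA as calcium); otherwise the
    first letter governs, with names starting in H/D or a digit read as
    hydrogens (e.g. "1HB").
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if (
        two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA", "K", "CU")
        and name.strip().upper() == resname.strip().upper()
    ):
        return two.capitalize()
    if stripped[0] in ("H", "D") or name.strip()[0] in _DIGITS:
        return "H"
    return stripped[0].upper()


def atomic_mass(element: str) -> float:
    """Standard atomic weight in Da (gemmi periodic table)."""
    el = gemmi.Element(element.capitalize() if len(element) > 1 else element.upper())
    if el.name == "X":
        raise ValueError(f"unknown element {element!r}")
    return float(el.weight)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _atoms_from_gemmi_model(model: "gemmi.Model") -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                altloc = atom.altloc if atom.altloc not in ("\0", " ", "") else ""
                if altloc not in ("", "A"):
                    continue  # keep-first altloc policy
                serial += 1
                element = atom.element.name if atom.element.name != "X" else ""
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        altloc=altloc,
                        resname=residue.name,
                        chain=chain.name,
                        resseq=residue.seqid.num,
                        icode=residue.seqid.icode.strip(),
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        element=element,
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                    )
                )
    return atoms


def read_structure(path: str | Path, label: str | None = None) -> Structure:
    """Parse a fixed-column PDB file into a Structure.

    All ATOM and HETATM records are kept; where an atom carries alternate
    locations only the blank or 'A' conformer is retained.  Raises
    ``ValueError`` if no atoms parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    atoms = _atoms_from_gemmi_model(st[0])
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return Structure(atoms=atoms, id=label if label is not None else st.name or path.stem)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    # gemmi add_* methods copy their argument, so build bottom-up:
    # group atoms into residues, residues into chains, then assemble.
    for a in structure.atoms:
        if len(a.name) > 4:
            raise ValueError(
                f"atom name {a.name!r} exceeds the 4-character PDB field"
            )
        if len(a.resname) > 3:
            raise ValueError(
                f"residue name {a.resname!r} exceeds the 3-character PDB field"
            )

    chain_order: list[str] = []
    residues: dict[str, list[tuple[tuple, list[AtomRecord]]]] = {}
    for a in structure.atoms:
        if a.chain not in residues:
            residues[a.chain] = []
            chain_order.append(a.chain)
        key = (a.resseq, a.icode, a.resname)
        if not residues[a.chain] or residues[a.chain][-1][0] != key:
            residues[a.chain].append((key, []))
        residues[a.chain][-1][1].append(a)

    st = gemmi.Structure()
    st.name = structure.id or "MODEL"
    model = gemmi.Model("1")
    for chain_name in chain_order:
        chain = gemmi.Chain(chain_name)
        for (resseq, icode, resname), recs in residues[chain_name]:
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(resseq, icode if icode else " ")
            residue.het_flag = "A"
            for a in recs:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.altloc = a.altloc if a.altloc else "\0"
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.bfactor
                atom.element = gemmi.Element(a.element)
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-format PDB (coordinates kept to 0.001 Å)."""
    st = _to_gemmi(structure)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    topology: Structure,
    stride: int = 1,
    frame_spacing: float = 1.0,
) -> Trajectory:
    """Load a multi-model PDB or XYZ-frames file against a known topology.

    Every frame must carry exactly the topology's atom count; stride ``k``
    keeps frames 0, k, 2k, ...  Frames are returned in file order.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    path = Path(path)
    text_head = path.open().readline()
    if text_head.strip().split() and text_head.strip().split()[0].isdigit():
        frames, box = _read_xyz_frames(path, len(topology))
    else:
        frames, box = _read_multimodel_pdb(path, len(topology)), None
    if not frames:
        raise ValueError(f"no frames read from {path}")
    return Trajectory(
        topology=topology,
        frames=frames[::stride],
        frame_spacing=frame_spacing * stride,
        box=box,
    )


def _read_multimodel_pdb(path: Path, n_atoms: int) -> list[np.ndarray]:
    st = gemmi.read_pdb(str(path))
    frames = []
    for i, model in enumerate(st):
        atoms = _atoms_from_gemmi_model(model)
        if len(atoms) != n_atoms:
            raise ValueError(
                f"frame {i} has {len(atoms)} atoms, topology has {n_atoms}"
            )
        frames.append(np.array([a.position for a in atoms], dtype=float))
    return frames


def _read_xyz_frames(
    path: Path, n_atoms: int
) -> tuple[list[np.ndarray], tuple[float, float, float] | None]:
    frames: list[np.ndarray] = []
    box: tuple[float, float, float] | None = None
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        count = int(lines[i].split()[0])
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        tokens = comment.split()
        if "box" in tokens:
            j = tokens.index("box")
            box = tuple(float(t) for t in tokens[j + 1 : j + 4])  # type: ignore[assignment]
        if count != n_atoms:
            raise ValueError(
                f"frame {frame_idx} has {count} atoms, topology has {n_atoms}"
            )
        rows = lines[i + 2 : i + 2 + count]
        if len(rows) < count:
            raise ValueError(f"frame {frame_idx} is truncated")
        coords = np.array(
            [[float(x) for x in r.split()[1:4]] for r in rows], dtype=float
        )
        frames.append(coords)
        i += 2 + count
        frame_idx += 1
    return frames, box


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the per-frame XYZ dialect read by read_trajectory."""
    elements = [a.element for a in traj.topology.atoms]
    box_str = ""
    if traj.box is not None:
        box_str = " box " + " ".join(f"{b:.4f}" for b in traj.box)
    with Path(path).open("w") as fh:
        for k, frame in enumerate(traj.frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {k}{box_str}\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
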