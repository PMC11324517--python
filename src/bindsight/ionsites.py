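"""Metal/ion coordination-shell detection and geometry validation.

Finds the ligand shell of a bound ion (e.g. the Zn²⁺ bridging the
extracellular loops, or the Na⁺ at the Na2 site) by an element-resolved
distance window over N/O/S donor atoms, and scores the shell against
ideal coordination polyhedra (trigonal planar, tetrahedral, square
planar, trigonal bipyramidal, octahedral) by exhaustive assignment of
ligands to template vertices.

Distance windows default to Zn 1.9–2.6 Å and Na 2.2–2.9 Å — standard
coordination-chemistry brackets, configurable per element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .structio import AtomRecord, Structure

__all__ = [
    "CoordinationConfig",
    "CoordinationLigand",
    "CoordinationSite",
    "find_coordination_shell",
    "coordination_summary",
    "geometry_deviation",
    "IDEAL_GEOMETRIES",
]

DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "ZN": (1.9, 2.6),
    "NA": (2.2, 2.9),
}
DONOR_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class CoordinationConfig:
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    donor_elements: frozenset[str] = DONOR_ELEMENTS

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ValueError(f"window for {el} must have min < max")

    def window_for(self, element: str) -> tuple[float, float]:
        key = element.upper()
        if key not in self.windows:
            raise KeyError(f"no distance window configured for element {element}")
        return self.windows[key]


@dataclass(frozen=True)
class CoordinationLigand:
    atom_index: int
    atom: AtomRecord
    distance: float


@dataclass
class CoordinationSite:
    ion_index: int
    ion: AtomRecord
    ligands: list[CoordinationLigand]

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def mean_distance(self) -> float:
        if not self.ligands:
            raise ValueError("empty coordination shell")
        return float(np.mean([l.distance for l in self.ligands]))


def find_coordination_shell(
    structure: Structure,
    ion: tuple[str | None, int, str] | int,
    cfg: CoordinationConfig | None = None,
) -> CoordinationSite:
    """All donor atoms (N/O/S) inside the ion's element distance window.

    ``ion`` is either an atom index or a (chain, resseq, atom name)
    spec.  Ligands are returned sorted by ascending distance; an empty
    shell is a valid result (coordination_number 0).
    """
    cfg = cfg or CoordinationConfig()
    if isinstance(ion, int):
        ion_idx = ion
    else:
        chain, resseq, name = ion
        matches = [
            i
            for i, a in enumerate(structure.atoms)
            if a.resseq == resseq
            and a.name == name
            and (chain is None or a.chain == chain)
        ]
        if not matches:
            raise ValueError(f"ion atom {ion} not found")
        ion_idx = matches[0]
    ion_atom = structure.atoms[ion_idx]
    lo, hi = cfg.window_for(ion_atom.element)
    coords = structure.coords
    ipos = coords[ion_idx]
    ligands = []
    for i, a in enumerate(structure.atoms):
        if i == ion_idx or a.element.upper() not in cfg.donor_elements:
            continue
        d = float(np.linalg.norm(coords[i] - ipos))
        if lo <= d <= hi:
            ligands.append(CoordinationLigand(atom_index=i, atom=a, distance=d))
    ligands.sort(key=lambda l: l.distance)
    return CoordinationSite(ion_index=ion_idx, ion=ion_atom, ligands=ligands)


def coordination_summary(site: CoordinationSite) -> dict:
    """Mean/min/max distances and donor residue list for a non-empty shell."""
    if site.coordination_number < 1:
        raise ValueError("cannot summarise an empty coordination shell")
    distances = [l.distance for l in site.ligands]
    return {
        "ion": f"{site.ion.element}{site.ion.resseq}",
        "coordination_number": site.coordination_number,
        "mean_distance": float(np.mean(distances)),
        "min_distance": float(np.min(distances)),
        "max_distance": float(np.max(distances)),
        "donors": [
            f"{l.atom.chain}/{l.atom.resname}{l.atom.resseq}:{l.atom.name}"
            for l in site.ligands
        ],
    }


def _unit_vectors(vertices: np.ndarray) -> np.ndarray:
    return vertices / np.linalg.norm(vertices, axis=1, keepdims=True)


_SQRT3 = np.sqrt(3.0)

IDEAL_GEOMETRIES: dict[str, np.ndarray] = {
    "trigonal_planar": _unit_vectors(
        np.array(
            [
                [1.0, 0.0, 0.0],
                [-0.5, _SQRT3 / 2, 0.0],
                [-0.5, -_SQRT3 / 2, 0.0],
            ]
        )
    ),
    "tetrahedral": _unit_vectors(
        np.array(
            [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
        )
    ),
    "square_planar": _unit_vectors(
        np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
    ),
    "trigonal_bipyramidal": _unit_vectors(
        np.array(
            [
                [1.0, 0, 0],
                [-0.5, _SQRT3 / 2, 0],
                [-0.5, -_SQRT3 / 2, 0],
                [0, 0, 1.0],
                [0, 0, -1.0],
            ]
        )
    ),
    "octahedral": _unit_vectors(
        np.array(
            [
                [1.0, 0, 0],
                [-1.0, 0, 0],
                [0, 1.0, 0],
                [0, -1.0, 0],
                [0, 0, 1.0],
                [0, 0, -1.0],
            ]
        )
    ),
}


def _pair_angles(unit: np.ndarray) -> np.ndarray:
    """Upper-triangle vertex–centre–vertex angles in degrees."""
    n = unit.shape[0]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    iu = np.triu_indices(n, k=1)
    return np.degrees(np.arccos(cos[iu]))


def template_deviation(
    site: CoordinationSite, structure: Structure, template: str
) -> float:
    """Minimal angle RMS deviation (degrees) from one ideal template.

    Exhaustive over all ligand-to-vertex assignments, so the result is
    invariant to ligand input order.
    """
    verts = IDEAL_GEOMETRIES[template]
    n = site.coordination_number
    if verts.shape[0] != n:
        raise ValueError(
            f"template {template} has {verts.shape[0]} vertices, shell has {n}"
        )
    coords = structure.coords
    vecs = coords[[l.atom_index for l in site.ligands]] - coords[site.ion_index]
    unit = _unit_vectors(vecs)
    best = np.inf
    for perm in permutations(range(n)):
        obs = _pair_angles(unit[list(perm)])
        ideal = _pair_angles(verts)
        rms = float(np.sqrt(np.mean((obs - ideal) ** 2)))
        best = min(best, rms)
    return best


def geometry_deviation(
    site: CoordinationSite, structure: Structure
) -> tuple[str, float]:
    """Best-matching ideal coordination geometry and its angle RMS deviation.

    Supported coordination numbers 3–6; every template with the shell's
    vertex count is tried and the minimal-RMS label returned.
    """
    n = site.coordination_number
    if n not in (3, 4, 5, 6):
        raise ValueError(f"unsupported coordination number {n}")
    candidates = [
        name for name, verts in IDEAL_GEOMETRIES.items() if verts.shape[0] == n
    ]
    results = {
        name: template_deviation(site, structure, name) for name in candidates
    }
    best = min(results, key=results.get)
    return best, results[best]
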