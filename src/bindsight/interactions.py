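"""Trajectory interaction statistics for protein–ligand complexes.

The analyses mirror standard MD interaction fingerprints with the exact
criteria used in the transporter study:

* a residue is *in contact* with the ligand in a frame when any heavy-atom
  pair is within 4.0 Å, and the contact is *stable* when the per-frame
  contact probability exceeds 0.40 (strictly "more than 40% of the time");
* two aromatic rings are *stacked* in a frame when the distance between
  their heavy-atom centres of mass is ≤ 5 Å and the acute angle between
  their least-squares plane normals is ≤ 45°;
* hydrogen bonds use a geometric donor–acceptor distance / D–H–A angle
  criterion (cutoffs configurable; the defaults D–A ≤ 3.5 Å, angle ≥ 120°
  are a common convention, not a value taken from any one study);
* the radial distribution function g(r) normalises a minimum-image
  distance histogram by shell volume and bulk probe density so that an
  ideal gas gives g(r) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structio import (
    Selection,
    Structure,
    Trajectory,
    atomic_mass,
    select_atoms,
)
from .geometry import rmsf_per_atom

__all__ = [
    "ContactProfile",
    "ContactRow",
    "RingSpec",
    "StackingSeries",
    "HBondSeries",
    "RDFResult",
    "contact_profile",
    "top_coordinating_residues",
    "ring_geometry",
    "stacking_series",
    "hbond_series",
    "moiety_rmsf",
    "radial_distribution",
]

CONTACT_CUTOFF = 4.0          # Å, heavy-atom pair distance
STABLE_THRESHOLD = 0.40       # strict: stable iff probability > threshold
STACK_DMAX = 5.0              # Å, ring COM distance
STACK_AMAX = 45.0             # degrees, acute inter-normal angle


@dataclass(frozen=True)
class ContactRow:
    chain: str
    resseq: int
    resname: str
    contact_probability: float
    stable: bool


@dataclass
class ContactProfile:
    rows: list[ContactRow]
    n_frames: int
    cutoff: float
    stable_threshold: float

    def probability(self, chain: str, resseq: int) -> float:
        for r in self.rows:
            if r.chain == chain and r.resseq == resseq:
                return r.contact_probability
        raise KeyError((chain, resseq))


def contact_profile(
    traj: Trajectory,
    ligand_sel: Selection,
    residues: Sequence[tuple[str, int]] | None = None,
    cutoff: float = CONTACT_CUTOFF,
    stable_threshold: float = STABLE_THRESHOLD,
) -> ContactProfile:
    """Per-residue ligand contact probabilities over a trajectory.

    In every frame a residue counts as in contact when *any* of its heavy
    atoms lies within ``cutoff`` of any ligand heavy atom.  ``residues``
    restricts the profile; by default all residues outside the ligand
    selection are profiled.  The stable flag applies the strict
    ``probability > stable_threshold`` rule.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    lig_idx = [
        i for i in select_atoms(top, ligand_sel) if not top.atoms[i].is_hydrogen
    ]
    if not lig_idx:
        raise ValueError("ligand selection resolves no heavy atoms")
    lig_set = set(lig_idx)

    groups: dict[tuple[str, int], list[int]] = {}
    resnames: dict[tuple[str, int], str] = {}
    wanted = set((c, int(r)) for c, r in residues) if residues is not None else None
    for i, a in enumerate(top.atoms):
        if i in lig_set or a.is_hydrogen:
            continue
        key = (a.chain, a.resseq)
        if wanted is not None and key not in wanted:
            continue
        groups.setdefault(key, []).append(i)
        resnames.setdefault(key, a.resname)

    counts = {key: 0 for key in groups}
    for frame in traj.frames:
        lig = frame[lig_idx]
        for key, idx in groups.items():
            d2 = ((frame[idx][:, None, :] - lig[None, :, :]) ** 2).sum(axis=-1)
            if (d2 <= cutoff * cutoff).any():
                counts[key] += 1

    rows = []
    for key in sorted(groups):
        p = counts[key] / traj.n_frames
        rows.append(
            ContactRow(
                chain=key[0],
                resseq=key[1],
                resname=resnames[key],
                contact_probability=p,
                stable=p > stable_threshold,
            )
        )
    return ContactProfile(
        rows=rows,
        n_frames=traj.n_frames,
        cutoff=cutoff,
        stable_threshold=stable_threshold,
    )


def top_coordinating_residues(profile: ContactProfile, k: int = 15) -> list[ContactRow]:
    """The ``k`` residues with highest contact probability.

    Ties are broken by (chain, resseq) ascending so the ranking is
    deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        profile.rows,
        key=lambda r: (-r.contact_probability, r.chain, r.resseq),
    )
    return ranked[:k]


@dataclass(frozen=True)
class RingSpec:
    """An aromatic ring named by residue and an explicit ordered atom list.

    The atom list convention follows the study's definitions, e.g. the
    tryptophan indole (CG, CD1, NE1, CE2, CZ2, CH2, CZ3, CE3, CD2) and the
    ligand adenine ring (N3, C4, N1, C3, C5, N4, C6, N5, C2).
    """

    chain: str | None
    resseq: int
    atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.atom_names) < 5:
            raise ValueError("a ring needs at least 5 atoms")

    def resolve(self, structure: Structure) -> list[int]:
        by_name = {}
        for i, a in enumerate(structure.atoms):
            if a.resseq == self.resseq and (
                self.chain is None or a.chain == self.chain
            ):
                by_name[a.name] = i
        idx = []
        for name in self.atom_names:
            if name not in by_name:
                raise ValueError(
                    f"ring atom {name} missing from residue {self.chain}/{self.resseq}"
                )
            idx.append(by_name[name])
        return idx


def ring_geometry(
    coords: np.ndarray, elements: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted centre of mass and unit plane normal of a ring.

    The normal is the smallest principal component of the centered atom
    cloud; its sign is arbitrary (callers fold angles to [0°, 90°]).
    Raises on (near-)collinear input.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.array([atomic_mass(e) for e in elements])
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("ring atoms are collinear; plane undefined")
    normal = vt[2]
    return com, normal / np.linalg.norm(normal)


@dataclass
class StackingSeries:
    com_distance: np.ndarray     # Å per frame
    normal_angle: np.ndarray     # degrees in [0, 90] per frame
    stacked: np.ndarray          # bool per frame
    occupancy: float
    d_max: float
    a_max: float


def stacking_series(
    traj: Trajectory,
    ring_a: RingSpec,
    ring_b: RingSpec,
    d_max: float = STACK_DMAX,
    a_max: float = STACK_AMAX,
) -> StackingSeries:
    """Per-frame π-stacking evaluation of two rings.

    A frame is stacked when the ring COM distance is ≤ ``d_max`` and the
    acute angle between ring normals is ≤ ``a_max``; occupancy is the
    stacked-frame fraction.
    """
    top = traj.topology
    idx_a = ring_a.resolve(top)
    idx_b = ring_b.resolve(top)
    el_a = [top.atoms[i].element for i in idx_a]
    el_b = [top.atoms[i].element for i in idx_b]
    n = traj.n_frames
    dist = np.empty(n)
    ang = np.empty(n)
    for k, frame in enumerate(traj.frames):
        com_a, n_a = ring_geometry(frame[idx_a], el_a)
        com_b, n_b = ring_geometry(frame[idx_b], el_b)
        dist[k] = np.linalg.norm(com_a - com_b)
        c = abs(float(np.clip(n_a @ n_b, -1.0, 1.0)))
        ang[k] = np.degrees(np.arccos(c))
    stacked = (dist <= d_max) & (ang <= a_max)
    return StackingSeries(
        com_distance=dist,
        normal_angle=ang,
        stacked=stacked,
        occupancy=float(stacked.mean()),
        d_max=d_max,
        a_max=a_max,
    )


@dataclass
class HBondSeries:
    donor: tuple[str | None, int, str]
    hydrogen: tuple[str | None, int, str] | None
    acceptor: tuple[str | None, int, str]
    da_distance: np.ndarray      # Å per frame
    dha_angle: np.ndarray | None  # degrees per frame, None if no hydrogen
    present: np.ndarray
    occupancy: float


def _resolve_atom(structure: Structure, spec: tuple[str | None, int, str]) -> int:
    chain, resseq, name = spec
    for i, a in enumerate(structure.atoms):
        if (
            a.resseq == resseq
            and a.name == name
            and (chain is None or a.chain == chain)
        ):
            return i
    raise ValueError(f"atom {spec} not found")


def hbond_series(
    traj: Trajectory,
    donor: tuple[str | None, int, str],
    acceptor: tuple[str | None, int, str],
    hydrogen: tuple[str | None, int, str] | None = None,
    d_cut: float = 3.5,
    a_cut: float = 120.0,
) -> HBondSeries:
    """Geometric hydrogen-bond occupancy for one donor/acceptor pair.

    Present in a frame iff donor–acceptor distance ≤ ``d_cut`` and, when a
    hydrogen atom is given, the D–H–A angle is ≥ ``a_cut``.  Omitting the
    hydrogen disables the angle criterion (distance-only evaluation, for
    heavy-atom-only topologies).
    """
    top = traj.topology
    di = _resolve_atom(top, donor)
    ai = _resolve_atom(top, acceptor)
    hi = _resolve_atom(top, hydrogen) if hydrogen is not None else None
    n = traj.n_frames
    da = np.empty(n)
    ang = np.empty(n) if hi is not None else None
    for k, frame in enumerate(traj.frames):
        da[k] = np.linalg.norm(frame[di] - frame[ai])
        if hi is not None:
            v1 = frame[di] - frame[hi]
            v2 = frame[ai] - frame[hi]
            c = float(
                np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
                )
            )
            ang[k] = np.degrees(np.arccos(c))
    present = da <= d_cut
    if ang is not None:
        present = present & (ang >= a_cut)
    return HBondSeries(
        donor=donor,
        hydrogen=hydrogen,
        acceptor=acceptor,
        da_distance=da,
        dha_angle=ang,
        present=present,
        occupancy=float(present.mean()),
    )


def moiety_rmsf(
    traj: Trajectory,
    fit_sel: Selection,
    moieties: Mapping[str, Selection],
) -> dict[str, float]:
    """Mean per-atom RMSF (Å) within each named atom group.

    Used to compare the mobility of chemically distinct ligand moieties
    (e.g. tropane vs carbomethoxy vs fluorophenyl) over aligned frames.
    """
    out = {}
    for name, sel in moieties.items():
        idx = select_atoms(traj.topology, sel)
        if not idx:
            raise ValueError(f"moiety {name!r} selects no atoms")
        rmsf = rmsf_per_atom(traj, fit_sel, sel)
        out[name] = float(rmsf.mean())
    return out


@dataclass
class RDFResult:
    r: np.ndarray          # bin centres, Å
    g: np.ndarray          # g(r)
    dr: float
    n_frames: int
    reference: str = ""


def radial_distribution(
    traj: Trajectory,
    ref_sel: Selection,
    probe_sel: Selection,
    r_max: float,
    dr: float,
) -> RDFResult:
    """Radial distribution function g(r) of probe atoms around a reference.

    Minimum-image distances in an orthorhombic box; the histogram is
    normalised by shell volume 4πr²dr, bulk probe density N_probe/V, the
    reference count and the frame count, so that uniformly distributed
    probes give g(r) = 1.
    """
    if not (r_max > dr > 0):
        raise ValueError("require r_max > dr > 0")
    if traj.box is None:
        raise ValueError("RDF requires trajectory box dimensions")
    box = np.asarray(traj.box, dtype=float)
    ref_idx = select_atoms(traj.topology, ref_sel)
    probe_idx = select_atoms(traj.topology, probe_sel)
    if not ref_idx or not probe_idx:
        raise ValueError("empty reference or probe selection")
    edges = np.arange(0.0, r_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        ref = frame[ref_idx]
        probe = frame[probe_idx]
        delta = probe[None, :, :] - ref[:, None, :]
        delta -= box * np.round(delta / box)
        d = np.sqrt((delta**2).sum(axis=-1)).ravel()
        h, _ = np.histogram(d, bins=edges)
        hist += h
    volume = float(np.prod(box))
    rho = len(probe_idx) / volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * dr
    norm = rho * shell * len(ref_idx) * traj.n_frames
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    return RDFResult(r=centers, g=g, dr=dr, n_frames=traj.n_frames)
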