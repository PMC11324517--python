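"""Seeded synthetic fixtures with exactly known ground truth.

Each generator emulates one class of input consumed by the analysis
modules — ideal α-helices for axis fitting, trajectories with planted
contact fractions and stacking geometries, toy metal coordination sites,
uniform "ideal-gas" solvent boxes for the RDF null model, and noisy
dose-response curves at the published assay parameters.  Constructions
are threshold-exact: a planted contact fraction of 0.5 over 100 frames
yields a measured probability of exactly 0.50, because atoms are placed
1 Å inside or 2 Å outside the contact cutoff rather than on it.

All generators consume an integer seed through ``numpy.random.default_rng``
and are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .structio import AtomRecord, Structure, Trajectory
from .pharmacology import (
    DoseResponseDataset,
    hill_normalized,
    hill_variable,
    michaelis_menten,
    single_site_binding,
)

__all__ = [
    "build_ideal_helix",
    "make_fold_pair",
    "make_helix_shift_pair",
    "make_planted_contact_trajectory",
    "make_stacked_rings_trajectory",
    "make_metal_site",
    "make_ideal_gas_box",
    "simulate_dose_response",
    "DOSE_RESPONSE_PRESETS",
    "default_concentration_grid",
    "INDOLE_ATOMS",
    "ADENINE_ATOMS",
]

# ring atom-name conventions used by the stacking analysis
INDOLE_ATOMS = ("CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2")
ADENINE_ATOMS = ("N3", "C4", "N1", "C3", "C5", "N4", "C6", "N5", "C2")


def _atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    pos: Sequence[float],
    element: str,
) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name,
        altloc="",
        resname=resname,
        chain=chain,
        resseq=resseq,
        icode="",
        position=(float(pos[0]), float(pos[1]), float(pos[2])),
        element=element,
    )


# ---------------------------------------------------------------------------
# ideal helix
# ---------------------------------------------------------------------------

def build_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    orientation: np.ndarray | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    chain: str = "A",
    start_resseq: int = 1,
) -> Structure:
    """Cα trace of an ideal α-helix built along z, then rigidly placed.

    Cα_i = orientation · (radius·cos θ_i, radius·sin θ_i, i·rise) + origin
    with θ_i = i·twist.  Defaults (1.5 Å rise, 100° twist, 2.3 Å radius)
    are the canonical α-helix parameters.
    """
    if n_res < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    R = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    origin = np.asarray(origin, dtype=float)
    atoms = []
    for i in range(n_res):
        theta = np.radians(i * twist)
        local = np.array([radius * np.cos(theta), radius * np.sin(theta), i * rise])
        pos = R @ local + origin
        atoms.append(
            _atom(i + 1, "CA", "ALA", chain, start_resseq + i, pos, "C")
        )
    return Structure(atoms=atoms, id=f"ideal_helix_{n_res}")


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # uniform random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20.0, 20.0, size=3)


def make_fold_pair(
    target_rmsd: float,
    n_per_helix: int = 24,
    n_helices: int = 3,
    seed: int = 0,
) -> tuple[Structure, Structure, list[tuple[str, int, str, int]]]:
    """Synthetic orthologue-style Cα pair with an exactly planted RMSD.

    Builds a small helical-bundle Cα fold, adds a seeded random
    displacement field to the copy, rescales the field iteratively so
    that the optimal (Kabsch) superposition RMSD equals ``target_rmsd``,
    then hides the correspondence behind a random global rigid motion.
    Returns (reference, target, identity residue mapping).
    """
    from .geometry import kabsch_superpose

    rng = np.random.default_rng(seed)
    pieces = []
    for h in range(n_helices):
        pieces.append(
            build_ideal_helix(
                n_per_helix,
                origin=(10.0 * h, 0.0, 0.0),
                chain="A",
                start_resseq=1 + 100 * h,
            )
        )
    atoms = [a for p in pieces for a in p.atoms]
    ref = Structure(atoms=atoms, id="fold_ref")
    coords = ref.coords
    delta = rng.normal(size=coords.shape)
    tgt = coords + delta * target_rmsd / np.sqrt((delta**2).sum(axis=1).mean())
    for _ in range(8):
        sup = kabsch_superpose(coords, tgt)
        aligned = sup.transform.apply(tgt)
        resid = aligned - coords
        if abs(sup.rmsd - target_rmsd) < 1e-12:
            tgt = aligned
            break
        tgt = coords + resid * (target_rmsd / sup.rmsd)
    R, t = _random_rigid(rng)
    target = ref.with_coords(tgt @ R.T + t)
    mapping = [("A", a.resseq, "A", a.resseq) for a in ref.atoms]
    return ref, target, mapping


def make_helix_shift_pair(
    displacement: float = 1.9,
    reorientation: float = 3.1,
    seed: int = 0,
    target_offsets: Mapping[str, int] | None = None,
) -> tuple[Structure, Structure]:
    """Two-species-style structures with one helix shifted by known amounts.

    The reference carries TM3 (140–170), TM8 (400–430) and TM1b (77–90)
    ideal helices in transporter numbering; the target duplicates the
    fold under orthologue numbering offsets (defaults follow the
    packaged cross-species mapping table) with TM1b rotated by
    ``reorientation``° about its Cα centroid and translated by
    ``displacement`` Å perpendicular to its axis, all behind a random
    global rigid motion.
    """
    if target_offsets is None:
        target_offsets = {"TM3": 20, "TM8": 16, "TM1b": 19}
    rng = np.random.default_rng(seed)
    layout = {
        "TM3": ((140, 170), (0.0, 0.0, 0.0)),
        "TM8": ((400, 430), (12.0, 0.0, 0.0)),
        "TM1b": ((77, 90), (6.0, 9.0, 0.0)),
    }

    def build(offsets: Mapping[str, int], shift: bool) -> Structure:
        parts = []
        for name, ((lo, hi), origin) in layout.items():
            h = build_ideal_helix(
                hi - lo + 1,
                origin=origin,
                chain="A",
                start_resseq=lo + offsets.get(name, 0),
            )
            if shift and name == "TM1b":
                coords = h.coords
                centroid = coords.mean(axis=0)
                a = np.radians(reorientation)
                rot = np.array(
                    [
                        [np.cos(a), 0.0, np.sin(a)],
                        [0.0, 1.0, 0.0],
                        [-np.sin(a), 0.0, np.cos(a)],
                    ]
                )
                coords = (coords - centroid) @ rot.T + centroid
                coords += np.array([0.0, displacement, 0.0])
                h = h.with_coords(coords)
            parts.append(h)
        atoms = [a for p in parts for a in p.atoms]
        return Structure(atoms=atoms)

    ref = build({}, shift=False)
    target = build(dict(target_offsets), shift=True)
    R, t = _random_rigid(rng)
    target = target.with_coords(target.coords @ R.T + t)
    return ref, target


# ---------------------------------------------------------------------------
# planted-contact trajectory
# ---------------------------------------------------------------------------

def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic well-spread unit vectors (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_planted_contact_trajectory(
    n_frames: int,
    contact_fractions: Mapping[int, float],
    cutoff: float = 4.0,
    seed: int = 0,
) -> Trajectory:
    """Trajectory where each residue's ligand-contact fraction is planted.

    The topology is a one-atom ligand at the origin plus one heavy atom
    per listed residue number (chain "A").  For residue fraction ``f``,
    exactly ``round(f · n_frames)`` seeded-random frames place the residue
    atom at ``cutoff − 1`` Å from the ligand; all other frames place it at
    ``cutoff + 2`` Å, so the measured contact probability equals the
    planted fraction exactly.
    """
    for resseq, f in contact_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction for residue {resseq} outside [0, 1]")
    rng = np.random.default_rng(seed)
    resseqs = sorted(contact_fractions)
    dirs = _sphere_directions(max(len(resseqs), 4))[: len(resseqs)]

    atoms = [_atom(1, "C1", "LIG", "L", 900, (0.0, 0.0, 0.0), "C")]
    for j, resseq in enumerate(resseqs):
        atoms.append(
            _atom(j + 2, "CB", "ALA", "A", resseq, dirs[j] * (cutoff + 2.0), "C")
        )
    topology = Structure(atoms=atoms, id="planted_contacts")

    frames = []
    in_contact = np.zeros((len(resseqs), n_frames), dtype=bool)
    for j, resseq in enumerate(resseqs):
        m = int(round(contact_fractions[resseq] * n_frames))
        if m > 0:
            chosen = rng.choice(n_frames, size=m, replace=False)
            in_contact[j, chosen] = True
    for k in range(n_frames):
        coords = np.zeros((len(atoms), 3))
        for j in range(len(resseqs)):
            r = cutoff - 1.0 if in_contact[j, k] else cutoff + 2.0
            coords[j + 1] = dirs[j] * r
        frames.append(coords)
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# stacked-rings trajectory
# ---------------------------------------------------------------------------

# planar fused-ring template (arbitrary but non-degenerate 9-atom layout, Å)
_RING_TEMPLATE = np.array(
    [
        [1.40, 0.00, 0.0],
        [0.70, 1.21, 0.0],
        [-0.70, 1.21, 0.0],
        [-1.40, 0.00, 0.0],
        [-0.70, -1.21, 0.0],
        [0.70, -1.21, 0.0],
        [2.73, 0.43, 0.0],
        [3.55, -0.70, 0.0],
        [2.73, -1.83, 0.0],
    ]
)

_INDOLE_ELEMENTS = ("C", "C", "N", "C", "C", "C", "C", "C", "C")
_ADENINE_ELEMENTS = ("N", "C", "N", "C", "C", "N", "C", "N", "C")


def _mass_center(coords: np.ndarray, elements: Sequence[str]) -> np.ndarray:
    from .structio import atomic_mass

    m = np.array([atomic_mass(e) for e in elements])
    return (coords * m[:, None]).sum(axis=0) / m.sum()


def _rot_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def make_stacked_rings_trajectory(
    n_frames: int,
    stacked_fraction: float,
    distance_when_stacked: float = 3.8,
    angle_when_stacked: float = 10.0,
    unstacked_distance: float = 9.0,
    seed: int = 0,
) -> Trajectory:
    """Two aromatic rings with a planted per-frame stacking fraction.

    Ring A is a tryptophan indole (residue 84) fixed in the xy-plane;
    ring B carries the adenine atom names of the allosteric ligand.  In
    stacked frames ring B sits with its centre of mass exactly
    ``distance_when_stacked`` Å above ring A's and its plane tilted by
    exactly ``angle_when_stacked``°; in unstacked frames the COM distance
    is ``unstacked_distance`` Å (violating the distance criterion).
    """
    if not 0.0 <= stacked_fraction <= 1.0:
        raise ValueError("stacked_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)

    com_a = _mass_center(_RING_TEMPLATE, _INDOLE_ELEMENTS)
    ring_a = _RING_TEMPLATE - com_a  # COM at origin
    com_b0 = _mass_center(_RING_TEMPLATE, _ADENINE_ELEMENTS)
    ring_b_local = _RING_TEMPLATE - com_b0

    atoms = []
    serial = 1
    for name, el, pos in zip(INDOLE_ATOMS, _INDOLE_ELEMENTS, ring_a):
        atoms.append(_atom(serial, name, "TRP", "A", 84, pos, el))
        serial += 1
    for name, el, pos in zip(ADENINE_ATOMS, _ADENINE_ELEMENTS, ring_b_local):
        atoms.append(
            _atom(serial, name, "MRS", "L", 901, pos + np.array([0, 0, unstacked_distance]), el)
        )
        serial += 1
    topology = Structure(atoms=atoms, id="stacked_rings")

    m = int(round(stacked_fraction * n_frames))
    stacked_frames = np.zeros(n_frames, dtype=bool)
    if m > 0:
        stacked_frames[rng.choice(n_frames, size=m, replace=False)] = True

    tilt = _rot_x(angle_when_stacked)
    frames = []
    for k in range(n_frames):
        coords = np.zeros((18, 3))
        coords[:9] = ring_a
        if stacked_frames[k]:
            b = ring_b_local @ tilt.T + np.array([0, 0, distance_when_stacked])
        else:
            b = ring_b_local + np.array([0, 0, unstacked_distance])
        coords[9:] = b
        frames.append(coords)
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# toy metal site
# ---------------------------------------------------------------------------

_GEOMETRY_VERTICES: dict[str, np.ndarray] = {
    "tetrahedral": np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    / np.sqrt(3.0),
    "octahedral": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    ),
    "square_planar": np.array(
        [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float
    ),
}


def make_metal_site(
    geometry: str,
    distances: Sequence[float],
    jitter: float = 0.0,
    seed: int = 0,
    ion: str = "ZN",
    ligand_elements: Sequence[str] | None = None,
) -> Structure:
    """Toy coordination site: an ion at the origin with ideal-polyhedron ligands.

    ``distances`` gives one ion–ligand distance per vertex of the chosen
    geometry; optional isotropic Gaussian ``jitter`` (Å per coordinate) is
    applied to the ligand positions with the given seed.
    """
    if geometry not in _GEOMETRY_VERTICES:
        raise ValueError(f"unknown geometry {geometry!r}")
    verts = _GEOMETRY_VERTICES[geometry]
    if len(distances) != verts.shape[0]:
        raise ValueError(
            f"{geometry} needs {verts.shape[0]} distances, got {len(distances)}"
        )
    if ligand_elements is None:
        ligand_elements = ["O"] * len(distances)
    rng = np.random.default_rng(seed)
    atoms = [_atom(1, ion.upper(), ion.upper(), "M", 500, (0, 0, 0), ion.upper())]
    for i, (v, d, el) in enumerate(zip(verts, distances, ligand_elements)):
        pos = v * d + rng.normal(0.0, jitter, size=3)
        name = el.upper() if el.upper() != "O" else "O"
        atoms.append(_atom(i + 2, name, "HOH", "W", 600 + i, pos, el))
    return Structure(atoms=atoms, id=f"{ion.lower()}_{geometry}_site")


# ---------------------------------------------------------------------------
# ideal-gas solvent box
# ---------------------------------------------------------------------------

def make_ideal_gas_box(
    n_points: int,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    n_frames: int = 10,
    exclusion_radius: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Uniform random probe atoms around a fixed reference (RDF null model).

    Probes are redrawn uniformly every frame, rejecting points whose
    minimum-image distance to the reference (at the box centre) is below
    ``exclusion_radius``.  The orthorhombic box is recorded on the
    trajectory for periodic normalisation.
    """
    if n_points < 100:
        raise ValueError("need at least 100 probe points")
    box = np.asarray(box, dtype=float)
    if exclusion_radius > 0 and np.any(box < 2 * exclusion_radius):
        raise ValueError("box must be at least twice the exclusion radius")
    rng = np.random.default_rng(seed)
    center = box / 2.0

    atoms = [_atom(1, "C1", "REF", "R", 1, center, "C")]
    for i in range(n_points):
        atoms.append(_atom(i + 2, "O", "SOL", "S", i + 2, center, "O"))
    topology = Structure(atoms=atoms, id="ideal_gas_box")

    frames = []
    for _ in range(n_frames):
        pts = np.empty((n_points, 3))
        filled = 0
        while filled < n_points:
            cand = rng.uniform(0.0, box, size=(n_points - filled, 3))
            if exclusion_radius > 0:
                delta = cand - center
                delta -= box * np.round(delta / box)
                keep = np.sqrt((delta**2).sum(axis=1)) >= exclusion_radius
                cand = cand[keep]
            pts[filled : filled + len(cand)] = cand
            filled += len(cand)
        coords = np.vstack([center[None, :], pts])
        frames.append(coords)
    return Trajectory(topology=topology, frames=frames, box=tuple(box))


# ---------------------------------------------------------------------------
# dose-response simulator
# ---------------------------------------------------------------------------

# parameter presets at the published assay values
DOSE_RESPONSE_PRESETS: dict[str, dict] = {
    # [3H]dopamine uptake kinetics, truncated construct: Km 0.55 µM, Vmax 342.8
    "uptake_delta_hdat": {"model": "mm", "km": 0.55, "vmax": 342.8, "unit": "uM"},
    # full-length transporter: Km 0.56 µM, Vmax 190.9
    "uptake_full_length_hdat": {"model": "mm", "km": 0.56, "vmax": 190.9, "unit": "uM"},
    # [3H]WIN35428 scintillation-proximity binding: Kd 6.5 nM
    "win35428_binding": {"model": "binding", "kd": 6.5, "bmax": 1000.0, "unit": "nM"},
}


def default_concentration_grid(model: str) -> np.ndarray:
    """Assay-style concentration grids (3-fold dilution series)."""
    if model == "mm":
        # 30 µM down to 0.0137 µM
        return 30.0 / 3.0 ** np.arange(8)
    if model == "binding":
        # 0–150 nM saturation series
        return np.array([0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 150.0])
    if model in ("hill_normalized", "hill_variable"):
        # 30 µM down to 0.0411 µM plus a vanishing control dose
        return np.concatenate([[1e-6], 30.0 / 3.0 ** np.arange(7)[::-1]])
    raise ValueError(f"unknown model {model!r}")


def _model_curve(model: str, params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    if model == "mm":
        return michaelis_menten(x, params["km"], params["vmax"])
    if model == "binding":
        return single_site_binding(x, params["kd"], params["bmax"])
    if model == "hill_normalized":
        return hill_normalized(x, params["ic50"], params.get("hill", 1.0))
    if model == "hill_variable":
        return hill_variable(
            x,
            params["ic50"],
            params.get("hill", 1.0),
            params.get("top", 100.0),
            params.get("bottom", 0.0),
        )
    raise ValueError(f"unknown model {model!r}")


def simulate_dose_response(
    model: str,
    params: Mapping[str, float] | str,
    x: np.ndarray | None = None,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    background_mean: float = 0.0,
    n_background: int = 3,
) -> DoseResponseDataset:
    """Noisy replicate dose-response data from a named model.

    ``params`` may be a preset name from ``DOSE_RESPONSE_PRESETS``.  Noise
    is multiplicative Gaussian with constant coefficient of variation
    ``cv`` (the assay reports mean ± s.d. only, so constant-CV noise is
    the simulator's model); ``cv = 0`` reproduces the curve exactly.
    Background replicates are drawn around ``background_mean`` with the
    same CV.
    """
    unit = "uM"
    if isinstance(params, str):
        preset = DOSE_RESPONSE_PRESETS[params]
        model = preset["model"]
        unit = preset.get("unit", "uM")
        params = {k: v for k, v in preset.items() if k not in ("model", "unit")}
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if x is None:
        x = default_concentration_grid(model)
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    curve = _model_curve(model, params, x)
    noise = rng.normal(0.0, cv, size=(len(x), n_replicates)) if cv > 0 else np.zeros(
        (len(x), n_replicates)
    )
    y = curve[:, None] * (1.0 + noise) + background_mean
    if background_mean > 0:
        bg = background_mean * (
            1.0 + (rng.normal(0.0, cv, size=n_background) if cv > 0 else 0.0)
        )
    else:
        bg = np.zeros(n_background)
    return DoseResponseDataset(x=x, y=y, background=bg, unit=unit, condition=model)
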