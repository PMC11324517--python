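"""Rigid-body superposition and helix-geometry measurements.

Implements the structural comparisons used throughout the transporter
analysis: least-squares (Kabsch) superposition with Cα pairing across
orthologues, principal-axis fits to transmembrane helices, the helix
displacement/reorientation metrics, residue-pair distances under several
atom rules, and per-atom RMSF over aligned trajectory frames.

Conventions adopted here (the source measurements leave them open):

* helix *displacement* is the distance between helix Cα centroids after
  the alignment transform has been applied to the mobile structure;
* helix *reorientation* is the acute angle between principal axes,
  folded to [0°, 90°] because an axis has no intrinsic sign;
* helix axes are principal components of the centered Cα cloud, with the
  sign fixed to point from the first toward the last residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Selection, Structure, Trajectory, select_atoms

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "HelixAxis",
    "HelixComparison",
    "kabsch_superpose",
    "pair_calpha",
    "fit_helix_axis",
    "compare_helix",
    "residue_distance",
    "rmsf_per_atom",
]

# side-chain ring atoms for the ring-centroid distance rule
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    pairing: tuple[tuple[int, int], ...] = ()


def kabsch_superpose(
    ref: np.ndarray, mob: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mob`` onto ``ref``.

    Returns the optimal proper rotation + translation and the post-fit
    RMSD.  Requires at least three non-collinear point pairs.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError(f"point sets differ in shape: {ref.shape} vs {mob.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    # collinearity check: rank of either centered cloud < 2
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(ref.shape[0]))
    return SuperpositionResult(
        transform=RigidTransform(R, t), rmsd=rmsd, n_pairs=ref.shape[0]
    )


def pair_calpha(
    ref: Structure,
    target: Structure,
    mapping: Sequence[tuple[str, int, str, int]],
) -> list[tuple[int, int]]:
    """Pair Cα atom indices across two structures via an explicit residue map.

    ``mapping`` rows are (ref_chain, ref_resseq, target_chain, target_resseq).
    Rows where either Cα is missing are dropped; an empty result raises.
    """
    ref_ca = {
        (a.chain, a.resseq): i
        for i, a in enumerate(ref.atoms)
        if a.name == "CA" and not a.icode
    }
    tgt_ca = {
        (a.chain, a.resseq): i
        for i, a in enumerate(target.atoms)
        if a.name == "CA" and not a.icode
    }
    pairs = []
    for rc, rr, tc, tr in mapping:
        i = ref_ca.get((rc, int(rr)))
        j = tgt_ca.get((tc, int(tr)))
        if i is not None and j is not None:
            pairs.append((i, j))
    if not pairs:
        raise ValueError("no Cα pairs could be formed from the mapping")
    return pairs


def superpose_structures(
    ref: Structure,
    target: Structure,
    mapping: Sequence[tuple[str, int, str, int]],
) -> SuperpositionResult:
    """Kabsch fit of ``target`` onto ``ref`` over a Cα residue mapping."""
    pairs = pair_calpha(ref, target, mapping)
    rc = ref.coords[[i for i, _ in pairs]]
    tc = target.coords[[j for _, j in pairs]]
    res = kabsch_superpose(rc, tc)
    return SuperpositionResult(
        transform=res.transform,
        rmsd=res.rmsd,
        n_pairs=res.n_pairs,
        pairing=tuple(pairs),
    )


@dataclass(frozen=True)
class HelixAxis:
    centroid: np.ndarray
    direction: np.ndarray
    residue_range: tuple[int, int]
    n_calpha: int


def fit_helix_axis(
    calpha: np.ndarray, residue_range: tuple[int, int] = (0, 0)
) -> HelixAxis:
    """Principal-component axis of a helix Cα trace.

    The direction is the first principal component of sliding 4-residue
    Cα centroids (one helical turn ≈ 3.6 residues, so the window largely
    cancels the radial winding and the centroids track the local helix
    axis), with sign fixed to point from the first to the last residue.
    Needs at least 4 points with non-zero variance.
    """
    calpha = np.asarray(calpha, dtype=float)
    if calpha.ndim != 2 or calpha.shape[1] != 3 or calpha.shape[0] < 4:
        raise ValueError("helix axis fit needs at least 4 Cα points")
    centroid = calpha.mean(axis=0)
    if calpha.shape[0] >= 7:
        window = 4
        kernel = np.ones(window) / window
        smoothed = np.stack(
            [np.convolve(calpha[:, d], kernel, mode="valid") for d in range(3)],
            axis=1,
        )
    else:
        smoothed = calpha
    centered = smoothed - smoothed.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-12):
        raise ValueError("zero-variance Cα input")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ (calpha[-1] - calpha[0]) < 0:
        direction = -direction
    return HelixAxis(
        centroid=centroid,
        direction=direction / np.linalg.norm(direction),
        residue_range=residue_range,
        n_calpha=calpha.shape[0],
    )


@dataclass(frozen=True)
class HelixComparison:
    displacement: float
    reorientation: float
    alignment_rmsd: float


def _calpha_coords(
    s: Structure, chain: str | None, residue_range: tuple[int, int]
) -> np.ndarray:
    sel = Selection.make(chain=chain, residues=[residue_range], atom_names=["CA"])
    idx = select_atoms(s, sel)
    if len(idx) < 4:
        raise ValueError(
            f"helix range {residue_range} resolves only {len(idx)} Cα atoms"
        )
    return s.coords[idx]


def compare_helix(
    ref: Structure,
    target: Structure,
    align_mapping: Sequence[tuple[str, int, str, int]],
    ref_helix: tuple[str | None, tuple[int, int]],
    target_helix: tuple[str | None, tuple[int, int]],
) -> HelixComparison:
    """Displacement and reorientation of one helix after a shared-frame alignment.

    The rigid transform is fit on the ``align_mapping`` Cα pairs only
    (for the transporter comparisons that is the TM3/TM8 core), applied to
    all of ``target``, and the two helix axes compared: displacement is the
    distance between helix Cα centroids, reorientation the acute angle
    between axis directions.
    """
    sup = superpose_structures(ref, target, align_mapping)
    ref_ca = _calpha_coords(ref, ref_helix[0], ref_helix[1])
    tgt_ca = sup.transform.apply(_calpha_coords(target, target_helix[0], target_helix[1]))
    axis_ref = fit_helix_axis(ref_ca, ref_helix[1])
    axis_tgt = fit_helix_axis(tgt_ca, target_helix[1])
    displacement = float(np.linalg.norm(axis_ref.centroid - axis_tgt.centroid))
    cosang = abs(float(np.clip(axis_ref.direction @ axis_tgt.direction, -1.0, 1.0)))
    reorientation = float(np.degrees(np.arccos(cosang)))
    return HelixComparison(
        displacement=displacement,
        reorientation=reorientation,
        alignment_rmsd=sup.rmsd,
    )


def residue_distance(
    s: Structure,
    a: tuple[str | None, int],
    b: tuple[str | None, int],
    rule: str = "ca",
    atom_a: str | None = None,
    atom_b: str | None = None,
) -> float:
    """Distance in Å between two residues under a named atom rule.

    Rules: ``"ca"`` (Cα–Cα), ``"atom"`` (named atoms ``atom_a``/``atom_b``),
    ``"ring_centroid"`` (centroids of the side-chain rings), and
    ``"min_heavy"`` (minimum over heavy-atom pairs).
    """
    pa = _residue_point(s, a, rule, atom_a)
    pb = _residue_point(s, b, rule, atom_b)
    if rule == "min_heavy":
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        return float(d.min())
    return float(np.linalg.norm(pa - pb))


def _residue_atoms(s: Structure, spec: tuple[str | None, int]) -> list[int]:
    chain, resseq = spec
    idx = [
        i
        for i, at in enumerate(s.atoms)
        if at.resseq == resseq and (chain is None or at.chain == chain)
    ]
    if not idx:
        raise ValueError(f"residue {spec} not found")
    return idx


def _residue_point(
    s: Structure, spec: tuple[str | None, int], rule: str, atom_name: str | None
) -> np.ndarray:
    idx = _residue_atoms(s, spec)
    atoms = [s.atoms[i] for i in idx]
    coords = s.coords[idx]
    if rule == "ca":
        for at, xyz in zip(atoms, coords):
            if at.name == "CA":
                return xyz
        raise ValueError(f"residue {spec} has no Cα atom")
    if rule == "atom":
        if atom_name is None:
            raise ValueError("rule 'atom' requires an atom name")
        for at, xyz in zip(atoms, coords):
            if at.name == atom_name:
                return xyz
        raise ValueError(f"atom {atom_name} absent from residue {spec}")
    if rule == "ring_centroid":
        resname = atoms[0].resname
        ring = RING_ATOMS.get(resname)
        if ring is None:
            raise ValueError(f"no ring definition for residue type {resname}")
        sel = [xyz for at, xyz in zip(atoms, coords) if at.name in ring]
        if len(sel) < len(ring):
            raise ValueError(f"ring atoms incomplete for residue {spec}")
        return np.mean(sel, axis=0)
    if rule == "min_heavy":
        heavy = np.array(
            [xyz for at, xyz in zip(atoms, coords) if not at.is_hydrogen]
        )
        if heavy.size == 0:
            raise ValueError(f"no heavy atoms in residue {spec}")
        return heavy
    raise ValueError(f"unknown distance rule {rule!r}")


def rmsf_per_atom(
    traj: Trajectory,
    fit_sel: Selection,
    measure_sel: Selection,
) -> np.ndarray:
    """Per-atom RMSF (Å) of ``measure_sel`` atoms over alignment-corrected frames.

    Each frame is rigidly superposed onto frame 0 using the ``fit_sel``
    atoms, then the fluctuation of every measured atom about its mean
    position is computed: RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_idx = select_atoms(traj.topology, fit_sel)
    meas_idx = select_atoms(traj.topology, measure_sel)
    if not fit_idx or not meas_idx:
        raise ValueError("empty fit or measure selection")
    ref = traj.frames[0][fit_idx]
    aligned = np.empty((traj.n_frames, len(meas_idx), 3))
    for k, frame in enumerate(traj.frames):
        sup = kabsch_superpose(ref, frame[fit_idx])
        aligned[k] = sup.transform.apply(frame[meas_idx])
    mean_pos = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))
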