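"""Coarse comparative model construction, the surrogate energy, the
CP-site-hinged rigid-body refinement, and structural evaluation.

The coarse model copies template Cα coordinates onto aligned target residues
and threads unaligned residues (typically the designed linker) onto a
circular arc between their flanking anchors at near-ideal 3.8 Å spacing.
Models are scored by a simple Cα pseudo-energy — a harmonic term on
consecutive Cα spacing plus a hard-sphere clash count — that is cheap,
deterministic and rigid-motion invariant; any callable with the same
signature (for instance an adapter around an external statistical potential)
can replace it through the backend contract.

Refinement treats the CP junction as a hinge.  The model's native-protein
residues fall into two proportions separated by the linker midpoint; the
smaller proportion is swept through a rigid-body grid — 9 in-plane pause
angles (20° steps over 180°) times 18 axial snapshot angles (20° steps over
360°), 162 poses — and the lowest-energy snapshot wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .seqalign import Alignment
from .structure import Structure, StructureError, structure_from_ca

#: Ideal consecutive Cα–Cα distance (Å) for chain geometry.
IDEAL_CA_SPACING = 3.8
#: Cα pairs at sequence separation ≥ 3 closer than this are clashes.
CLASH_DISTANCE = 4.0
CLASH_PENALTY = 10.0

#: Hinge-refinement grid: 180°/20° in-plane pauses × 360°/20° axial snapshots.
PLANE_ANGLES = tuple(range(0, 180, 20))   # 9 values
AXIAL_ANGLES = tuple(range(0, 360, 20))   # 18 values


def surrogate_energy(s: Structure) -> float:
    """Cα pseudo-energy: Σ (d_consec − 3.8)² + 10 · #clashes.

    A clash is a residue pair at sequence separation ≥ 3 with Cα distance
    below 4.0 Å.  Zero for an ideally spaced clash-free chain; invariant to
    rigid motion; lower is better.
    """
    coords = s.ca_coords()
    diffs = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    bond = float(np.sum((diffs - IDEAL_CA_SPACING) ** 2))
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    n = len(coords)
    i, j = np.triu_indices(n, k=3)
    clashes = int(np.sum(d[i, j] < CLASH_DISTANCE))
    return bond + CLASH_PENALTY * clashes


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to v: the one with the
    largest global-z component, tie-broken toward +x."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    w = z - np.dot(z, v) * v
    if np.linalg.norm(w) < 1e-8:
        x = np.array([1.0, 0.0, 0.0])
        w = x - np.dot(x, v) * v
    return w / np.linalg.norm(w)


def _arc_points(a: np.ndarray, b: np.ndarray, k: int,
                spacing: float = IDEAL_CA_SPACING) -> np.ndarray:
    """Place k points between anchors a and b on a circular arc with
    consecutive spacing ≈ ``spacing``.

    If the straight path already needs stretched steps the points are evenly
    spaced on the segment; otherwise the arc radius is solved so that every
    chord equals ``spacing``.  The arc plane is chosen deterministically.
    """
    if k <= 0:
        return np.empty((0, 3))
    D = float(np.linalg.norm(b - a))
    nseg = k + 1
    if D < 1e-9:
        # Coincident anchors: loop out along a deterministic direction.
        w = np.array([0.0, 0.0, 1.0])
        gamma = 2 * np.pi / nseg
        R = spacing / (2 * np.sin(gamma / 2))
        center = a + R * w
        u1 = -w
        u2 = np.array([1.0, 0.0, 0.0])
        angles = [2 * np.pi * j / nseg for j in range(1, k + 1)]
        return np.array([center + R * (np.cos(t) * u1 + np.sin(t) * u2)
                         for t in angles])
    u = (b - a) / D
    if nseg * spacing <= D:
        step = D / nseg
        return np.array([a + u * step * j for j in range(1, k + 1)])
    # Solve 2R·sin(γ/2) = spacing and 2R·sin(nseg·γ/2) = D by bisection on γ.
    lo, hi = 1e-9, 2 * np.pi / nseg - 1e-9

    def gap(gamma: float) -> float:
        R = spacing / (2 * np.sin(gamma / 2))
        return 2 * R * np.sin(nseg * gamma / 2) - D

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    gamma = 0.5 * (lo + hi)
    R = spacing / (2 * np.sin(gamma / 2))
    theta = nseg * gamma  # total arc angle
    w = _perpendicular(u)
    h = R * np.cos(theta / 2)
    center = 0.5 * (a + b) + h * w
    e1 = -w
    angles = [-theta / 2 + gamma * j for j in range(1, k + 1)]
    return np.array([center + R * (np.cos(t) * e1 + np.sin(t) * u)
                     for t in angles])


def build_coarse_model(aln: Alignment, template: Structure,
                       linker: str = "",
                       energy_fn=surrogate_energy
                       ) -> tuple[Structure, float]:
    """Build a Cα coarse model of the target from a target–template alignment.

    Aligned target residues inherit the template Cα coordinate; unaligned
    runs (linker residues and insertions) are threaded on a circular arc
    between the flanking anchors; unaligned termini are extrapolated along
    the terminal chain direction.  Returns the model and its energy.
    """
    target_seq, template_seq = aln.degapped()
    if template_seq != template.sequence:
        raise StructureError(
            "alignment/template mismatch: second alignment row does not "
            "degap to the template sequence")
    if linker and linker not in target_seq:
        raise StructureError("linker sequence absent from the aligned target")
    tpl_ca = template.ca_coords()
    n_target = len(target_seq)
    coords = np.full((n_target, 3), np.nan)
    anchored = np.zeros(n_target, dtype=bool)
    for ti, pi in aln.column_pairs():
        if ti is not None and pi is not None:
            coords[ti - 1] = tpl_ca[pi - 1]
            anchored[ti - 1] = True
    if not anchored.any():
        raise StructureError("alignment/template mismatch: no aligned columns")
    idx_anchor = np.flatnonzero(anchored)
    # Interior gaps: arc between flanking anchors.
    for left, right in zip(idx_anchor, idx_anchor[1:]):
        k = right - left - 1
        if k > 0:
            coords[left + 1:right] = _arc_points(coords[left], coords[right], k)
    # Terminal overhangs: extrapolate along the nearest anchored direction.
    first, last = idx_anchor[0], idx_anchor[-1]
    if first > 0:
        direction = _terminal_direction(coords, idx_anchor, head=True)
        for j in range(first - 1, -1, -1):
            coords[j] = coords[j + 1] + direction * IDEAL_CA_SPACING
    if last < n_target - 1:
        direction = _terminal_direction(coords, idx_anchor, head=False)
        for j in range(last + 1, n_target):
            coords[j] = coords[j - 1] + direction * IDEAL_CA_SPACING
    model = structure_from_ca(target_seq, coords)
    return model, float(energy_fn(model))


def _terminal_direction(coords: np.ndarray, idx_anchor: np.ndarray,
                        head: bool) -> np.ndarray:
    if len(idx_anchor) >= 2:
        if head:
            v = coords[idx_anchor[0]] - coords[idx_anchor[1]]
        else:
            v = coords[idx_anchor[-1]] - coords[idx_anchor[-2]]
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            return v / norm
    return np.array([1.0, 0.0, 0.0]) * (-1.0 if head else 1.0)


@dataclass
class Junction:
    """Where the native termini meet inside a CPM model.

    ``linker_span`` is the inclusive (start, end) serial range of linker
    residues on the model, or None when the termini are joined directly, in
    which case ``joined_at`` is the serial of the last residue of the
    N-terminal proportion (the junction lies between it and the next one).
    """

    linker_span: tuple[int, int] | None = None
    joined_at: int | None = None


@dataclass
class HingeFrame:
    """Geometry of the CP-site hinge used by the rigid-body refinement."""

    hinge: np.ndarray
    com_small: np.ndarray
    com_large: np.ndarray
    axis_r: np.ndarray
    plane_normal: np.ndarray
    small_serials: list[int]
    small_is_cterm: bool


def split_by_hinge(model: Structure, junction: Junction) -> HingeFrame:
    """Divide a CPM model at the CP junction and set up the hinge frame.

    The hinge is the Cα of the middle linker residue (⌈l/2⌉) when a linker
    is present, otherwise the midpoint of the two directly joined
    native-termini Cαs.  The two native-protein proportions are compared by
    residue count; the smaller one will be moved (ties take the C-terminal
    proportion).  Axis r runs from the hinge to the small proportion's
    Cα centroid; plane P contains the hinge and both centroids, its normal
    chosen deterministically when the three points are collinear.
    """
    L = len(model)
    coords = model.ca_coords()
    if junction.linker_span is not None:
        start, end = junction.linker_span
        if not 1 <= start <= end <= L:
            raise StructureError("linker span out of bounds")
        l = end - start + 1
        hinge = coords[start + (l + 1) // 2 - 2].copy()
        seg1 = list(range(1, start))
        seg2 = list(range(end + 1, L + 1))
    else:
        j = junction.joined_at
        if j is None or not 1 <= j < L:
            raise StructureError("junction position out of bounds")
        hinge = 0.5 * (coords[j - 1] + coords[j])
        seg1 = list(range(1, j + 1))
        seg2 = list(range(j + 1, L + 1))
    if not seg1 or not seg2:
        raise StructureError("hinge does not separate two proportions")
    small_is_cterm = len(seg2) <= len(seg1)
    small = seg2 if small_is_cterm else seg1
    large = seg1 if small_is_cterm else seg2
    com_small = coords[[i - 1 for i in small]].mean(axis=0)
    com_large = coords[[i - 1 for i in large]].mean(axis=0)
    v_small = com_small - hinge
    if np.linalg.norm(v_small) < 1e-9:
        raise StructureError("degenerate hinge: small proportion centroid "
                             "coincides with the hinge")
    axis_r = v_small / np.linalg.norm(v_small)
    normal = np.cross(v_small, com_large - hinge)
    if np.linalg.norm(normal) < 1e-8:
        normal = _perpendicular(axis_r)
    else:
        normal = normal / np.linalg.norm(normal)
    return HingeFrame(hinge, com_small, com_large, axis_r, normal,
                      small, small_is_cterm)


@dataclass
class RefinementResult:
    """Outcome of the 162-snapshot hinge search."""

    structure: Structure
    best_pose: tuple[int, int]          # (plane angle θ, axial angle φ)
    best_energy: float
    energies: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return len(self.energies)


def _pose_structure(model: Structure, frame: HingeFrame,
                    theta_deg: float, phi_deg: float) -> Structure:
    if theta_deg == 0 and phi_deg == 0:
        return model.copy()  # exact identity: keep the input bit-for-bit
    rot = (Rotation.from_rotvec(np.deg2rad(phi_deg) * frame.axis_r) *
           Rotation.from_rotvec(np.deg2rad(theta_deg) * frame.plane_normal))
    out = model.copy()
    for serial in frame.small_serials:
        res = out.residues[serial - 1]
        for name, xyz in res.atoms.items():
            res.atoms[name] = rot.apply(xyz - frame.hinge) + frame.hinge
    return out


def hinge_refine(model: Structure, frame: HingeFrame,
                 energy_fn=surrogate_energy) -> RefinementResult:
    """Sweep the small proportion over the 162-pose grid; keep the best.

    Each pose rigidly rotates the small proportion about the hinge: first
    in plane P (about the plane normal) by θ ∈ {0°, 20°, …, 160°}, then
    about axis r by φ ∈ {0°, 20°, …, 340°}.  The linker and the large
    proportion never move.  Pose (0°, 0°) is the identity, so the refined
    energy never exceeds the input energy.  Ties go to the lexicographically
    smallest (θ, φ).
    """
    best: tuple[float, tuple[int, int], Structure] | None = None
    energies: list[tuple[int, int, float]] = []
    for theta in PLANE_ANGLES:
        for phi in AXIAL_ANGLES:
            posed = _pose_structure(model, frame, theta, phi)
            e = float(energy_fn(posed))
            energies.append((theta, phi, e))
            if best is None or e < best[0]:
                best = (e, (theta, phi), posed)
    assert best is not None
    return RefinementResult(best[2], best[1], best[0], energies)


def kabsch_rmsd(A: np.ndarray, B: np.ndarray
                ) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Least-squares rigid superposition of matched point sets.

    Finds the proper rotation R and translation t minimising
    ‖(A − ā)·Rᵀ + t̄ − B‖ and returns the post-fit RMSD together with
    (R, t) such that A is mapped onto B by ``A @ R.T + t``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if len(A) < 3:
        raise ValueError("at least 3 point pairs are required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return rmsd, (R, t)


def alignment_ratio(n_aligned: int, target_size: int) -> float:
    """Percent of the target's residues that are aligned."""
    if target_size <= 0:
        raise ValueError("target size must be positive")
    if not 0 <= n_aligned <= target_size:
        raise ValueError("aligned count must lie in 0..target_size")
    return 100.0 * n_aligned / target_size


class SurrogateBackend:
    """Default modeling/energy backend: arc-threaded Cα models scored by the
    surrogate energy.  Deterministic; lower energy is better."""

    name = "surrogate"
    deterministic = True

    def __init__(self, energy_fn=surrogate_energy):
        self.energy_fn = energy_fn

    def build_model(self, aln: Alignment, template: Structure,
                    linker: str = "") -> tuple[Structure, float]:
        return build_coarse_model(aln, template, linker,
                                  energy_fn=self.energy_fn)

    def energy(self, s: Structure) -> float:
        return float(self.energy_fn(s))


def get_backend(name: str = "surrogate"):
    """Resolve a backend by name.  Only the surrogate ships; external
    modeling/energy programs can be plugged in by passing a backend object
    with the same ``build_model``/``energy`` surface."""
    if name == "surrogate":
        return SurrogateBackend()
    raise ValueError(f"unknown backend {name!r}")
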