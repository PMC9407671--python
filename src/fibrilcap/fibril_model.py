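"""Fibril assembly model: layers, screw symmetry, tips, secondary structure.

An amyloid fibril is represented as one or two protofilaments, each an
ordered stack of identical layers (chains) related by a screw operator:
an axial rise (Angstrom) plus a twist (degrees) about the fibril axis.
The module infers that operator from coordinates, orders layers along the
axis, and generates the virtual "next layer" at either fibril end — the
position a new monomer, or a capping inhibitor's grafted strand, would
occupy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import backbone_dihedrals
from .errors import SymmetryError
from .geometry import RigidTransform, kabsch_superpose
from .structure_io import Chain, StructureModel

__all__ = [
    "ScrewSymmetry",
    "FibrilAssembly",
    "group_layers",
    "fit_screw_symmetry",
    "virtual_next_layer",
    "assign_secondary_structure",
]

#: Twist below which rotation-axis extraction is numerically unstable and
#: the operator is treated as a pure translation (degrees).
PURE_TRANSLATION_TWIST = 0.1

#: Below this twist the rotation axis of the fitted matrix is too noisy
#: to trust (sin(theta) ~ 0), so the axis is taken from the translation
#: direction instead — for cross-beta fibrils the perpendicular component
#: of the layer-to-layer translation is tiny compared with the rise.
AXIS_FROM_TRANSLATION_TWIST = 5.0

#: Post-superposition rmsd (Angstrom) below which two chains are considered
#: copies of the same layer.
LAYER_RMSD_THRESHOLD = 0.5

#: Rotation angle (degrees) separating within-protofilament screw steps
#: (small multiples of the twist) from cross-protofilament symmetry
#: operations such as the C2 of a two-protofilament fibril (~180 deg).
PROTOFILAMENT_ANGLE_CUTOFF = 90.0


@dataclass(frozen=True)
class ScrewSymmetry:
    """Layer-to-layer screw operator of one protofilament.

    ``transform(n)`` maps layer k onto layer k+n (bottom -> top along
    ``axis_dir``); ``rise`` is therefore non-negative by convention and
    the twist sign carries the handedness.
    """

    rise: float
    twist: float
    axis_point: np.ndarray
    axis_dir: np.ndarray
    rmsd: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_dir, dtype=float).reshape(3)
        norm = np.linalg.norm(d)
        if not np.isfinite(norm) or norm == 0:
            raise SymmetryError("axis direction must be a finite non-zero vector")
        object.__setattr__(self, "axis_dir", d / norm)
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3))
        t = float(self.twist)
        if not -180.0 < t <= 180.0:
            t = ((t + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "twist", t)

    def transform(self, n: int = 1) -> RigidTransform:
        """Rigid transform of the operator applied ``n`` times (n may be negative)."""
        theta = np.radians(self.twist * n)
        a = self.axis_dir
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        t = self.axis_point - R @ self.axis_point + n * self.rise * a
        return RigidTransform(R, t)


@dataclass
class FibrilAssembly:
    """Chains of a StructureModel grouped into ordered protofilament stacks."""

    model: StructureModel
    protofilaments: list[list[str]]
    symmetry: list[ScrewSymmetry]

    def layers(self, protofilament: int) -> list[Chain]:
        try:
            ids = self.protofilaments[protofilament]
        except IndexError:
            raise SymmetryError(f"no protofilament {protofilament}") from None
        return [self.model.chain(cid) for cid in ids]

    def tip_layer(self, protofilament: int, end: str) -> Chain:
        chains = self.layers(protofilament)
        if end == "plus":
            return chains[-1]
        if end == "minus":
            return chains[0]
        raise ValueError(f"end must be 'plus' or 'minus', got {end!r}")


def _rotation_angle(R: np.ndarray) -> float:
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _twist_about(R: np.ndarray, axis: np.ndarray) -> float:
    """Signed rotation angle of R about a given unit axis (degrees)."""
    u = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    Ru = R @ u
    return float(np.degrees(np.arctan2(Ru @ w, Ru @ u)))


def fit_screw_symmetry(layer_i: Chain, layer_j: Chain) -> ScrewSymmetry:
    """Fit the screw operator mapping ``layer_i`` onto ``layer_j``.

    The rigid transform is obtained by least-squares superposition of the
    backbone (N, CA, C, O) atoms, then decomposed into a rotation axis,
    twist, and axial rise. The returned operator is oriented so that the
    rise is non-negative (axis points from layer_i toward layer_j).

    Raises
    ------
    SymmetryError
        If the layers have mismatched residue counts or incomplete
        backbones.
    """
    if len(layer_i) != len(layer_j):
        raise SymmetryError(
            f"layer residue counts differ ({len(layer_i)} vs {len(layer_j)})"
        )
    P = layer_i.backbone_coords().reshape(-1, 3)
    Q = layer_j.backbone_coords().reshape(-1, 3)
    transform, rmsd = kabsch_superpose(P, Q)
    R, t = transform.rotation, transform.translation
    theta = _rotation_angle(R)

    if theta < PURE_TRANSLATION_TWIST:
        # Near-pure translation: the rotation axis is ill-conditioned, take
        # the translation direction as the fibril axis.
        norm = np.linalg.norm(t)
        if norm < 1e-9:
            raise SymmetryError("layers are coincident; no screw operator")
        axis = t / norm
        return ScrewSymmetry(norm, 0.0, P.mean(axis=0), axis, rmsd)

    if theta < AXIS_FROM_TRANSLATION_TWIST:
        # Small twist: the rotation axis of a noisy R tilts badly (error
        # scales with 1/sin(theta)) and biases the rise low. The axial
        # component dominates the translation at cross-beta twists, so the
        # translation direction is the far more stable axis estimate; the
        # twist is then the rotation of R projected about that axis.
        norm = np.linalg.norm(t)
        if norm < 1e-9:
            raise SymmetryError("layers are coincident; no screw operator")
        axis = t / norm
        twist = _twist_about(R, axis)
        rise = float(axis @ t)
    else:
        axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis /= 2.0 * np.sin(np.radians(theta))
        twist = theta
        rise = float(axis @ t)
        if rise < 0:
            axis, twist, rise = -axis, -twist, -rise
    # Point on the axis: solve (I - R) p = t_perp in least squares; the
    # component along the axis is unconstrained, lstsq gives min-norm.
    t_perp = t - rise * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return ScrewSymmetry(rise, twist, p, axis, rmsd)


def group_layers(
    model: StructureModel,
    chain_groups: list[list[str]] | None = None,
    rmsd_threshold: float = LAYER_RMSD_THRESHOLD,
) -> FibrilAssembly:
    """Cluster a model's chains into protofilaments of stacked layers.

    Chains with identical sequences are superposed pairwise; two chains
    belong to the same protofilament when they superpose below
    ``rmsd_threshold`` through a small rotation (a few screw steps), as
    opposed to the large rotation (~180 deg) relating distinct
    protofilaments of, e.g., a two-protofilament fibril. Each
    protofilament is ordered bottom -> top along the fitted axis and its
    screw operator is averaged over all consecutive layer pairs.

    ``chain_groups`` overrides the clustering with an explicit grouping
    (lists of chain ids, each ordered or unordered).
    """
    if chain_groups is None:
        chain_groups = _cluster_chains(model, rmsd_threshold)

    protofilaments: list[list[str]] = []
    symmetries: list[ScrewSymmetry] = []
    for group in chain_groups:
        if len(group) < 2:
            raise SymmetryError(
                f"protofilament {group} has fewer than 2 layers; cannot infer symmetry"
            )
        ordered = _order_group(model, list(group))
        sym = _average_symmetry(model, ordered)
        protofilaments.append(ordered)
        symmetries.append(sym)
    # Deterministic protofilament order regardless of input chain order.
    order = np.argsort([pf[0] for pf in protofilaments])
    protofilaments = [protofilaments[i] for i in order]
    symmetries = [symmetries[i] for i in order]
    return FibrilAssembly(model, protofilaments, symmetries)


def _cluster_chains(model: StructureModel, rmsd_threshold: float) -> list[list[str]]:
    chains = model.chains
    if len(chains) < 2:
        raise SymmetryError("need at least 2 chains to infer fibril layers")
    n = len(chains)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    seqs = [c.sequence() for c in chains]
    coords = [c.backbone_coords().reshape(-1, 3) for c in chains]
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i] != seqs[j] or len(chains[i]) != len(chains[j]):
                continue
            transform, rmsd = kabsch_superpose(coords[i], coords[j])
            if rmsd < rmsd_threshold and _rotation_angle(transform.rotation) < PROTOFILAMENT_ANGLE_CUTOFF:
                union(i, j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(chains[i].chain_id)
    result = [g for g in groups.values()]
    if all(len(g) < 2 for g in result):
        raise SymmetryError("no stackable chains found; cannot infer fibril layers")
    return result


def _order_group(model: StructureModel, group: list[str]) -> list[str]:
    centroids = np.array([model.chain(cid).ca_coords().mean(axis=0) for cid in group])
    if len(group) == 2:
        v = centroids[1] - centroids[0]
    else:
        centered = centroids - centroids.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered)
        v = Vt[0]
    # Deterministic sign: largest-magnitude component positive.
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    proj = centroids @ v
    order = np.argsort(proj, kind="stable")
    return [group[i] for i in order]


def _average_symmetry(model: StructureModel, ordered: list[str]) -> ScrewSymmetry:
    fits = [
        fit_screw_symmetry(model.chain(ordered[k]), model.chain(ordered[k + 1]))
        for k in range(len(ordered) - 1)
    ]
    rise = float(np.mean([f.rise for f in fits]))
    twist = float(np.mean([f.twist for f in fits]))
    axis = np.mean([f.axis_dir for f in fits], axis=0)
    point = np.mean([f.axis_point for f in fits], axis=0)
    rmsd = float(np.mean([f.rmsd for f in fits]))
    return ScrewSymmetry(rise, twist, point, axis, rmsd)


def virtual_next_layer(assembly: FibrilAssembly, protofilament: int, end: str) -> Chain:
    """Coordinates of the ideal next layer beyond a protofilament tip.

    For the plus end the screw operator is applied to the top layer; for
    the minus end its inverse is applied to the bottom layer. The result
    is where a new monomer — or the grafted strand of a capping design —
    would sit.
    """
    if not 0 <= protofilament < len(assembly.protofilaments):
        raise SymmetryError(f"unknown protofilament {protofilament}")
    sym = assembly.symmetry[protofilament]
    tip = assembly.tip_layer(protofilament, end)
    n = 1 if end == "plus" else -1
    virtual = tip.transformed(sym.transform(n))
    virtual.chain_id = "V"
    return virtual


# --- secondary structure ---------------------------------------------------

# Dihedral basins (degrees). Deliberately simple rectangular bins; an
# H-bond-pattern (DSSP-style) assignment is out of scope.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -90.0)
STRAND_PSI_HI = (90.0, 180.0)
STRAND_PSI_LO = (-180.0, -170.0)

MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3


def _label(phi: float, psi: float) -> str:
    if np.isnan(phi) or np.isnan(psi):
        return "L"
    if HELIX_PHI[0] < phi < HELIX_PHI[1] and HELIX_PSI[0] < psi < HELIX_PSI[1]:
        return "H"
    if STRAND_PHI[0] <= phi < STRAND_PHI[1] and (
        STRAND_PSI_HI[0] < psi <= STRAND_PSI_HI[1]
        or STRAND_PSI_LO[0] <= psi < STRAND_PSI_LO[1]
    ):
        return "E"
    return "L"


def _smooth(labels: list[str]) -> str:
    out = labels[:]
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        run = j - i
        kind = out[i]
        if (kind == "H" and run < MIN_HELIX_RUN) or (kind == "E" and run < MIN_STRAND_RUN):
            for k in range(i, j):
                out[k] = "L"
        i = j
    return "".join(out)


def assign_secondary_structure(chain: Chain) -> str:
    """Per-residue H/E/L labels from backbone dihedral basins.

    Runs shorter than the minimum element length (H >= 4, E >= 3) are
    relabeled L; chains of fewer than 3 residues are all-L.
    """
    if len(chain) < 3:
        return "L" * len(chain)
    coords = chain.backbone_coords()
    pp = backbone_dihedrals(coords)
    labels = [_label(phi, psi) for phi, psi in pp]
    return _smooth(labels)
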