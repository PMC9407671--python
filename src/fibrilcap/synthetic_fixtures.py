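"""Ground-truth synthetic fibrils, perfect cappers, and kinetic datasets.

Every downstream stage is testable without downloading real structures:
the generator emits an idealized cross-beta fibril with a known screw
operator (default rise 4.75 A, twist -1.2 deg — inside the cross-beta
stacking regime), known strand layout, and the coordinates of the
held-out next layer at either end. A "perfect capper" scaffold whose
graft strand is an exact copy of that next layer gives the zero of the
graft-rmsd scale and satisfies the dangling tip H-bonds by construction.

These fixtures are idealized: layers are exactly identical, loops are a
fixed turn, and residues alternate Ala/Val so sequence-dependent scores
are well defined. They are not a physical fibril simulator and do not
mimic real tau / alpha-synuclein / amyloid-beta sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import STRAND_PHI_PSI, HELIX_PHI_PSI, build_from_dihedrals
from .errors import BuildError
from .fibril_model import ScrewSymmetry
from .geometry import RigidTransform
from .kinetics import KineticTrace
from .scaffold_builder import Scaffold, TopologyClass
from .structure_io import Atom, Chain, Residue, StructureModel, PDB_CHAIN_IDS

__all__ = [
    "FibrilSpec",
    "GroundTruth",
    "make_ideal_fibril",
    "make_complementary_capper",
    "make_tht_dataset",
    "make_binding_dataset",
]

#: Turn dihedrals joining two strands of a layer into a beta-arch-like
#: motif: strands roughly antiparallel, laterally separated so they do
#: not hydrogen-bond to each other, layer flat enough to stack at the
#: cross-beta rise without steric clashes. Chosen once by geometric
#: screening; treat as part of the fixture definition.
TURN_DIHEDRALS: tuple[tuple[float, float], ...] = (
    (-62.21, -110.34),
    (-76.68, 13.41),
    (-24.54, 117.51),
)

#: Radial offset of the layer centroid from the fibril axis (Angstrom).
AXIS_OFFSET = 12.0

LAYER_SEQ = "AV"  # alternating Ala/Val
_RES3 = {"A": "ALA", "V": "VAL", "L": "LEU", "G": "GLY"}


@dataclass(frozen=True)
class FibrilSpec:
    """Parameters of an idealized synthetic fibril."""

    n_layers: int = 6
    strands: tuple[int, ...] = (8, 7)
    loop_len: int = 3
    rise: float = 4.75
    twist: float = -1.2
    n_protofilaments: int = 1
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 3:
            raise BuildError("fibril needs >= 3 layers")
        if not 4.0 <= self.rise <= 5.5:
            raise BuildError("rise outside the cross-beta regime [4.0, 5.5] A")
        if any(s < 4 for s in self.strands) or not self.strands:
            raise BuildError("strand lengths must be >= 4")
        if self.n_protofilaments not in (1, 2):
            raise BuildError("n_protofilaments must be 1 or 2")


@dataclass
class GroundTruth:
    """Machine-readable truth accompanying a synthetic fibril."""

    spec: FibrilSpec
    symmetry: ScrewSymmetry
    ss: str
    strand_windows: list[tuple[int, int]]
    next_layer_plus: Chain
    next_layer_minus: Chain
    model: StructureModel


def _layer_dihedrals(spec: FibrilSpec) -> tuple[np.ndarray, str]:
    pp: list[tuple[float, float]] = []
    ss: list[str] = []
    for k, slen in enumerate(spec.strands):
        if k > 0:
            for t in range(spec.loop_len):
                pp.append(TURN_DIHEDRALS[t % len(TURN_DIHEDRALS)])
                ss.append("L")
        pp.extend([STRAND_PHI_PSI] * slen)
        ss.extend("E" * slen)
    return np.asarray(pp), "".join(ss)


def _orient_layer(coords: np.ndarray, first_strand: int) -> np.ndarray:
    """Rotate/translate a built layer into the cross-beta stacking frame.

    The first strand runs along +x and its carbonyl direction — the
    direction backbone H-bonds form in a beta-sheet — along +z, which is
    the stacking axis. The centroid sits at (AXIS_OFFSET, 0, 0) so the
    fibril axis is the z-axis through the origin.
    """
    ca = coords[:, 1, :]
    u = ca[first_strand - 1] - ca[0]
    u /= np.linalg.norm(u)
    co = coords[0, 3] - coords[0, 2]  # first carbonyl C -> O
    w = co - (co @ u) * u
    w /= np.linalg.norm(w)
    v = np.cross(w, u)
    R = np.stack([u, v, w])  # world -> layer frame (right-handed)
    flat = coords.reshape(-1, 3)
    X = flat - flat.mean(axis=0)
    out = (X @ R.T).reshape(coords.shape)
    out = out + np.array([AXIS_OFFSET, 0.0, 0.0])
    return out


def _layer_to_chain(coords: np.ndarray, chain_id: str) -> Chain:
    chain = Chain(chain_id)
    elements = ("N", "C", "C", "O")
    names = ("N", "CA", "C", "O")
    for i in range(coords.shape[0]):
        aa = LAYER_SEQ[i % len(LAYER_SEQ)]
        res = Residue(_RES3[aa], i + 1)
        for j in range(4):
            res.atoms.append(Atom(names[j], elements[j], coords[i, j], 0))
        chain.residues.append(res)
    return chain


def make_ideal_fibril(spec: FibrilSpec) -> tuple[StructureModel, GroundTruth]:
    """Build an idealized fibril with known screw symmetry.

    Layer 0 is an ideal-strand layer (strands joined by a fixed turn);
    layer k is layer 0 transformed by the screw operator applied k times.
    A two-protofilament fibril relates the filaments by a 2-fold rotation
    about the axis. Optional Gaussian coordinate noise is applied last
    (the ground truth keeps the noiseless held-out layers).
    """
    pp, ss = _layer_dihedrals(spec)
    base = build_from_dihedrals(pp)
    base = _orient_layer(base, spec.strands[0])

    # self-consistency: strands must not overlap after the turn
    flat = base.reshape(-1, 3)
    d = np.sqrt(((flat[:, None] - flat[None, :]) ** 2).sum(-1))
    res_idx = np.repeat(np.arange(base.shape[0]), 4)
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    if np.any(d[sep >= 2] < 2.0):
        raise BuildError("strand layout overlaps; adjust strands/loop_len")

    sym = ScrewSymmetry(spec.rise, spec.twist, np.zeros(3), np.array([0.0, 0.0, 1.0]))
    c2 = RigidTransform(
        np.diag([-1.0, -1.0, 1.0]), np.zeros(3)
    )  # 2-fold about the fibril axis

    rng = np.random.default_rng(spec.seed)
    chains: list[Chain] = []
    strand_windows = _ss_windows(ss)
    chain_idx = 0
    for pf in range(spec.n_protofilaments):
        for k in range(spec.n_layers):
            coords = sym.transform(k).apply(base.reshape(-1, 3)).reshape(base.shape)
            if pf == 1:
                coords = c2.apply(coords.reshape(-1, 3)).reshape(base.shape)
            if spec.noise_sigma > 0:
                coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
            chains.append(_layer_to_chain(coords, PDB_CHAIN_IDS[chain_idx]))
            chain_idx += 1
    model = StructureModel(chains, source=f"synthetic fibril seed={spec.seed}")

    plus = sym.transform(spec.n_layers).apply(base.reshape(-1, 3)).reshape(base.shape)
    minus = sym.transform(-1).apply(base.reshape(-1, 3)).reshape(base.shape)
    truth = GroundTruth(
        spec=spec,
        symmetry=sym,
        ss=ss,
        strand_windows=strand_windows,
        next_layer_plus=_layer_to_chain(plus, "V"),
        next_layer_minus=_layer_to_chain(minus, "V"),
        model=model,
    )
    return model, truth


def _ss_windows(ss: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(ss):
        j = i
        while j < len(ss) and ss[j] == ss[i]:
            j += 1
        if ss[i] == "E":
            runs.append((i, j))
        i = j
    return runs


# --- perfect capper --------------------------------------------------------

CAPPER_LOOP = 4
CAPPER_HELIX = 14
CAPPER_STRAND2 = 7


def make_complementary_capper(
    site,
    truth: GroundTruth,
    body: TopologyClass = TopologyClass("EHE"),
    seed: int = 0,
    max_tries: int = 1000,
    flank: int = 1,
) -> Scaffold:
    """Scaffold whose graft strand exactly copies the held-out next layer.

    The strand backbone is copied from the next layer restricted to the
    site window (extended by ``flank`` residues on each side where the
    layer has them, so edge H-bond partners are covered); an idealized
    clash-free body — the remaining elements of ``body`` joined by loops —
    is grown from its C-terminus, resampling loop dihedrals until the
    body neither clashes with the fibril nor with itself.

    Raises
    ------
    BuildError
        If no clash-free body placement is found within ``max_tries``.
    """
    next_layer = truth.next_layer_plus if site.end == "plus" else truth.next_layer_minus
    # The N-side flank may reach into the preceding turn (its carbonyl can
    # be an edge H-bond partner), but the C-side flank stays inside the
    # strand run so the junction where the body grows keeps ideal strand
    # geometry.
    run_stop = len(next_layer)
    for s, e in truth.strand_windows:
        if s <= site.window[0] and site.window[1] <= e:
            run_stop = e
            break
    start = max(0, site.window[0] - flank)
    stop = min(run_stop, site.window[1] + flank)
    seg = np.stack([next_layer.residues[i].backbone_coords() for i in range(start, stop)])
    seg_len = stop - start

    # the graft strand stands in for the first strand (E) of the class;
    # the remaining elements are grown after it in class order
    letters = list(body.ss_string)
    first_e = letters.index("E")
    tail_elements = letters[:first_e] + letters[first_e + 1 :]
    plan: list[tuple[str, int]] = []
    for k in tail_elements:
        plan.append(("L", CAPPER_LOOP))
        plan.append((k, CAPPER_HELIX if k == "H" else CAPPER_STRAND2))

    fib_coords, _ = truth.model.heavy_coords_and_elements()
    rng = np.random.default_rng(np.random.SeedSequence([seed, site.site_index, 7]))
    for _ in range(max_tries):
        ss = ["E"] * seg_len
        dihed: list[tuple[float, float]] = []
        for kind, ln in plan:
            for _i in range(ln):
                if kind == "H":
                    dihed.append(HELIX_PHI_PSI)
                elif kind == "E":
                    dihed.append(STRAND_PHI_PSI)
                else:
                    dihed.append((float(rng.uniform(-160, -40)), float(rng.uniform(-60, 180))))
                ss.append(kind)
        coords = _extend_backbone(seg, dihed)
        body_flat = coords[seg_len:].reshape(-1, 3)
        if _min_dist(body_flat, fib_coords) < 2.8:
            continue
        if _self_clash(coords):
            continue
        n_total = coords.shape[0]
        seq = "".join(LAYER_SEQ[i % len(LAYER_SEQ)] for i in range(n_total))
        return Scaffold(coords, "".join(ss), seq, seed, body)
    raise BuildError("could not place a clash-free capper body; increase max_tries")


def _extend_backbone(seg: np.ndarray, dihedrals: list[tuple[float, float]]) -> np.ndarray:
    """Grow residues past a copied backbone segment with NeRF steps."""
    from .backbone import (
        ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C, ANGLE_CA_C_O,
        BOND_CA_C, BOND_C_N, BOND_C_O, BOND_N_CA, OMEGA_TRANS,
    )
    from .geometry import place_atom

    coords = [seg[i] for i in range(seg.shape[0])]
    for i, (phi, psi) in enumerate(dihedrals):
        Np, CAp, Cp = coords[-1][0], coords[-1][1], coords[-1][2]
        # psi of the previous residue: extended-ish for the junction, then
        # the previous residue's own psi once we are growing de novo
        psi_prev = 135.0 if i == 0 else dihedrals[i - 1][1]
        N = place_atom(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA = place_atom(CAp, Cp, N, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C = place_atom(Cp, N, CA, BOND_CA_C, ANGLE_N_CA_C, phi)
        O = place_atom(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        coords.append(np.stack([N, CA, C, O]))
    return np.stack(coords)


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(b).query(a)
    return float(d.min())


def _self_clash(coords: np.ndarray) -> bool:
    flat = coords.reshape(-1, 3)
    res_idx = np.repeat(np.arange(coords.shape[0]), 4)
    d = np.sqrt(((flat[:, None] - flat[None, :]) ** 2).sum(-1))
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    return bool(np.any(d[sep >= 2] < 2.0))


# --- kinetic fixtures ------------------------------------------------------

def make_tht_dataset(
    baseline: float = 0.1,
    amplitude: float = 1.0,
    t50: float = 20.0,
    rate: float = 0.5,
    t_max: float = 48.0,
    n_points: int = 97,
    noise_sigma: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[KineticTrace], dict]:
    """Seeded logistic ThT traces with recorded ground truth.

    Defaults mirror a bench-scale aggregation assay: ~50 h at 30-min
    reads, n = 3 replicates, a few percent measurement noise. The truth
    dict records the generating parameters and the analytic lag time
    t50 - 2/rate.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    clean = baseline + amplitude / (1.0 + np.exp(-rate * (t - t50)))
    traces = [
        KineticTrace(t, clean + rng.normal(0.0, noise_sigma, t.size), f"r{i + 1}")
        for i in range(n_replicates)
    ]
    truth = {
        "baseline": baseline, "amplitude": amplitude, "t50": t50, "rate": rate,
        "lag_time": t50 - 2.0 / rate,
    }
    return traces, truth


def make_binding_dataset(
    bmax: float = 1.0,
    half_saturation: float = 150.0,
    conc: np.ndarray | None = None,
    noise_sigma: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Seeded one-site saturation binding curve (concentrations in nM)."""
    rng = np.random.default_rng(seed)
    if conc is None:
        # 12-point dilution series bracketing the low-hundreds-nM regime
        conc = np.array([5, 10, 20, 40, 75, 150, 300, 600, 1200, 2500, 5000, 10000.0])
    signal = bmax * conc / (half_saturation + conc)
    signal = signal + rng.normal(0.0, noise_sigma, conc.size)
    return conc, signal, {"bmax": bmax, "half_saturation": half_saturation}
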