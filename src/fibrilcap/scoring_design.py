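"""Interface scoring, greedy sequence design, and funnel ranking.

The funnel metrics mirror what is known to discriminate good capping
designs: satisfaction of the backbone hydrogen bonds left dangling at the
fibril tip, the number of atoms buried in the interface, a residue-level
contact-potential surrogate for binding energy (lower is better), and a
backbone-dihedral amino-acid propensity score for the scaffold itself
(higher is better). Side chains are modeled as single centroid
pseudo-atoms so that steric negative controls (e.g. an A -> R mutation at
a buried interface position) are expressible without rotamers.

Amide hydrogens are rebuilt geometrically here — this module is the
single source of truth for them; hydrogens in input files are ignored.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .backbone import backbone_dihedrals, virtual_cbeta
from .capping_dock import (
    HARD_CLASH_CUTOFF,
    SOFT_FACTOR,
    VDW_RADII,
    DockedPose,
    clash_counts,
)
from .errors import ScoreError
from .fibril_model import FibrilAssembly
from .scaffold_builder import Scaffold
from .structure_io import AA3_TO_1, Chain

__all__ = [
    "HBond",
    "InterfaceScore",
    "FunnelConfig",
    "load_contact_table",
    "load_rama_propensities",
    "load_centroid_radii",
    "rebuild_amide_hydrogens",
    "detect_backbone_hbonds",
    "tip_hbond_satisfaction",
    "interface_atom_count",
    "ddg_surrogate",
    "paap_score",
    "optimize_interface_sequence",
    "mutate_and_rescore",
    "score_pose",
    "rank_designs",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DESIGN_AA = [a for a in AA20 if a != "C"]  # no cysteine, ever

HBOND_DIST_CUTOFF = 3.5   # N...O, Angstrom
HBOND_ANGLE_CUTOFF = 120.0  # N-H...O angle at H, degrees
CONTACT_CB_CUTOFF = 8.0   # Cbeta-Cbeta, Angstrom
INTERFACE_CUTOFF = 5.0    # heavy-atom interface distance, Angstrom
CENTROID_DISTANCE = 1.53  # pseudo-atom offset from CA along CA->CB (the
                          # C-beta bond length; side-chain size lives in the
                          # residue-specific radius, not the offset)

#: A centroid is a coarse pseudo-atom, not a nucleus: cross-beta stacking
#: legitimately brings C-beta within ~1.5 A of the facing layer's carbonyl
#: oxygens, so only genuine overlap below this distance counts as a hard
#: centroid clash. Steric strain from oversized side chains is captured by
#: the radius-dependent soft count instead.
CENTROID_HARD_CUTOFF = 1.2
AMIDE_NH = 1.01           # N-H bond length, Angstrom


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds of the filter-then-sort ranking funnel."""

    hb_unsat_max: int = 2
    interface_atoms_min: int = 40
    hbond_dist: float = HBOND_DIST_CUTOFF
    hbond_angle: float = HBOND_ANGLE_CUTOFF


@dataclass(frozen=True)
class HBond:
    donor: tuple  # (chain tag, residue index)
    acceptor: tuple
    distance: float
    angle: float


@dataclass
class InterfaceScore:
    design_id: str
    hb_satisfied: int
    hb_unsat: int
    interface_atoms: int
    ddg_surrogate: float
    paap: float
    soft_clashes: int
    hard_clashes: int
    composite_rank: int | None = None


# --- packaged tables -------------------------------------------------------

def _read_csv_rows(name: str) -> list[list[str]]:
    text = resources.files("fibrilcap.data").joinpath(name).read_text()
    rows = [r for r in csv.reader(text.splitlines()) if r and not r[0].startswith("#")]
    return rows


_TABLES: dict[str, object] = {}


def load_contact_table(version: str = "v1") -> dict[tuple[str, str], float]:
    """20x20 symmetric residue-pair contact energies (dimensionless)."""
    key = f"contact_{version}"
    if key not in _TABLES:
        rows = _read_csv_rows(f"contact_table_{version}.csv")
        header = rows[0][1:]
        table: dict[tuple[str, str], float] = {}
        for row in rows[1:]:
            a = row[0]
            for b, v in zip(header, row[1:]):
                table[(a, b)] = float(v)
        _TABLES[key] = table
    return _TABLES[key]


def load_rama_propensities(version: str = "v1") -> dict[str, dict[str, float]]:
    """P(amino acid | coarse Ramachandran bin), per bin."""
    key = f"rama_{version}"
    if key not in _TABLES:
        rows = _read_csv_rows(f"rama_propensity_{version}.csv")
        bins = rows[0][1:]
        table = {row[0]: dict(zip(bins, map(float, row[1:]))) for row in rows[1:]}
        _TABLES[key] = table
    return _TABLES[key]


def load_centroid_radii(version: str = "v1") -> dict[str, float]:
    key = f"centroid_{version}"
    if key not in _TABLES:
        rows = _read_csv_rows(f"centroid_radii_{version}.csv")
        _TABLES[key] = {row[0]: float(row[1]) for row in rows[1:]}
    return _TABLES[key]


# --- hydrogen bonds --------------------------------------------------------

def rebuild_amide_hydrogens(backbone: np.ndarray) -> np.ndarray:
    """Amide H positions for residues 1..n-1 of an (n, 4, 3) backbone.

    H sits in the peptide plane, 1.01 A from N, anti to the preceding
    carbonyl carbon (bisector construction). Row 0 is NaN: the first
    residue has no preceding C' and donates no backbone H-bond.
    """
    bb = np.asarray(backbone, dtype=float)
    n = bb.shape[0]
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        N = bb[i, 0]
        u1 = N - bb[i - 1, 2]  # from previous C'
        u2 = N - bb[i, 1]      # from own CA
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        d = u1 + u2
        H[i] = N + AMIDE_NH * d / np.linalg.norm(d)
    return H


def _participants_from_chain(tag: str, chain: Chain):
    """Backbone donors (N with rebuilt H, non-proline, i >= 1) and acceptors (O)."""
    bb = chain.backbone_coords()
    H = rebuild_amide_hydrogens(bb)
    donors, acceptors = [], []
    for i, res in enumerate(chain.residues):
        acceptors.append(((tag, i), bb[i, 3]))
        if i == 0 or res.name == "PRO":
            continue
        donors.append(((tag, i), bb[i, 0], H[i]))
    return donors, acceptors


def detect_backbone_hbonds(donors, acceptors, dist_cutoff: float = HBOND_DIST_CUTOFF,
                           angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> list[HBond]:
    """Geometric backbone H-bond detection.

    A bond is reported when N...O <= ``dist_cutoff`` and the N-H...O angle
    at H is >= ``angle_cutoff``. Each donor gets at most one acceptor (the
    shortest admissible N...O; ties broken by lower residue index). Donors
    are (key, N, H) triples; acceptors are (key, O) pairs. Self-pairs
    (donor and acceptor of the same residue) and adjacent in-chain pairs
    are excluded.
    """
    bonds: list[HBond] = []
    if not donors or not acceptors:
        return bonds
    O = np.asarray([a[1] for a in acceptors])
    tree = cKDTree(O)
    for key_d, N, Hpos in donors:
        idxs = tree.query_ball_point(N, r=dist_cutoff)
        best = None
        for j in idxs:
            key_a = acceptors[j][0]
            if key_a[0] == key_d[0] and abs(key_a[1] - key_d[1]) <= 1:
                continue  # same or adjacent residue in the same chain
            Opos = acceptors[j][1]
            d = float(np.linalg.norm(Opos - N))
            hn = N - Hpos
            ho = Opos - Hpos
            cosang = float(hn @ ho) / (np.linalg.norm(hn) * np.linalg.norm(ho))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang < angle_cutoff:
                continue
            cand = (d, key_a[1], key_a[0])
            if best is None or cand < best[0]:
                best = (cand, HBond(key_d, key_a, d, ang))
        if best is not None:
            bonds.append(best[1])
    return bonds


def _fibril_participants(assembly: FibrilAssembly):
    donors, acceptors = [], []
    for chain in assembly.model.chains:
        d, a = _participants_from_chain(chain.chain_id, chain)
        donors.extend(d)
        acceptors.extend(a)
    return donors, acceptors


def _unsatisfied_inventory(donors, acceptors, bonds):
    bonded_donors = {b.donor for b in bonds}
    bonded_acceptors = {b.acceptor for b in bonds}
    unsat_d = {d[0] for d in donors} - bonded_donors
    unsat_a = {a[0] for a in acceptors} - bonded_acceptors
    return unsat_d, unsat_a


def tip_hbond_satisfaction(assembly: FibrilAssembly, pose: DockedPose) -> tuple[int, int]:
    """Count tip-window H-bond partners newly satisfied by a capping pose.

    The dangling inventory is the set of tip-layer donors/acceptors in
    the site window that are unsatisfied in the bare fibril but would be
    satisfied by the arrival of the ideal next layer (the virtual layer
    generated from the fitted screw operator). The posed scaffold is then
    added and the H-bond network recounted. Returns ``(hb_satisfied,
    hb_unsat)``; their sum equals the dangling inventory of the window.
    """
    from .fibril_model import virtual_next_layer

    site = pose.site
    tip = assembly.tip_layer(site.protofilament, site.end)
    tip_tag = tip.chain_id
    window_keys = {(tip_tag, i) for i in range(*site.window)}

    donors, acceptors = _fibril_participants(assembly)
    bonds_before = detect_backbone_hbonds(donors, acceptors)
    unsat_d, unsat_a = _unsatisfied_inventory(donors, acceptors, bonds_before)

    # A tip partner counts as dangling only if fibril growth would satisfy
    # it: recount with the ideal next layer present. (A strand-terminal
    # carbonyl that even the next monomer could not reach is not held
    # against the capper.)
    vlayer = virtual_next_layer(assembly, site.protofilament, site.end)
    dv, av = _participants_from_chain("__virtual__", vlayer)
    bonds_grown = detect_backbone_hbonds(donors + dv, acceptors + av)
    grown_d = {b.donor for b in bonds_grown}
    grown_a = {b.acceptor for b in bonds_grown}
    inv_d = unsat_d & window_keys & grown_d
    inv_a = unsat_a & window_keys & grown_a

    posed = pose.posed_chain("Z")
    d2, a2 = _participants_from_chain("Z", posed)
    bonds_after = detect_backbone_hbonds(donors + d2, acceptors + a2)
    sat_d = {b.donor for b in bonds_after if b.donor in inv_d}
    sat_a = {b.acceptor for b in bonds_after if b.acceptor in inv_a}
    satisfied = len(sat_d) + len(sat_a)
    total = len(inv_d) + len(inv_a)
    return satisfied, total - satisfied


# --- interface metrics -----------------------------------------------------

def interface_atom_count(pose: DockedPose, assembly: FibrilAssembly,
                         cutoff: float = INTERFACE_CUTOFF) -> int:
    """Scaffold heavy atoms within ``cutoff`` (closed bound) of any fibril heavy atom."""
    posed = pose.posed_backbone().reshape(-1, 3)
    fib, _ = assembly.model.heavy_coords_and_elements()
    tree = cKDTree(fib)
    d, _ = tree.query(posed)
    return int((d <= cutoff).sum())


def _scaffold_cbetas(backbone: np.ndarray, sequence: str) -> np.ndarray:
    out = np.empty((backbone.shape[0], 3))
    for i in range(backbone.shape[0]):
        if sequence[i] == "G":
            out[i] = backbone[i, 1]
        else:
            out[i] = virtual_cbeta(backbone[i, 0], backbone[i, 1], backbone[i, 2])
    return out


def _chain_cbetas(chain: Chain) -> tuple[np.ndarray, list[str]]:
    coords, seq = [], []
    for res in chain.residues:
        aa = AA3_TO_1.get(res.name)
        if aa is None:
            raise ScoreError(f"unknown residue type {res.name}")
        cb = res.atom("CB")
        bb = res.backbone_coords()
        if aa == "G":
            coords.append(bb[1])
        elif cb is not None:
            coords.append(cb.pos)
        else:
            coords.append(virtual_cbeta(bb[0], bb[1], bb[2]))
        seq.append(aa)
    return np.asarray(coords), seq


def ddg_surrogate(pose: DockedPose, assembly: FibrilAssembly,
                  table: dict | None = None,
                  sequence: str | None = None) -> float:
    """Contact-potential surrogate for the binding energy of a pose.

    Sum of packaged table entries over intermolecular residue pairs whose
    Cbeta-Cbeta distance (CA for glycine) is within 8 A. Dimensionless;
    lower is better. ``sequence`` overrides the scaffold sequence (used
    during greedy design).
    """
    if table is None:
        table = load_contact_table()
    seq = sequence if sequence is not None else pose.scaffold.sequence
    if not seq:
        raise ScoreError("pose scaffold has no sequence assigned")
    for aa in seq:
        if aa not in AA20:
            raise ScoreError(f"unknown residue type {aa!r} in scaffold sequence")
    scb = _scaffold_cbetas(pose.posed_backbone(), seq)
    total = 0.0
    for chain in assembly.model.chains:
        fcb, fseq = _chain_cbetas(chain)
        d = np.sqrt(((scb[:, None, :] - fcb[None, :, :]) ** 2).sum(axis=-1))
        ii, jj = np.nonzero(d <= CONTACT_CB_CUTOFF)
        for i, j in zip(ii, jj):
            total += table[(seq[i], fseq[j])]
    return float(total)


# --- dihedral propensity ---------------------------------------------------

def _rama_bin(phi: float, psi: float) -> str:
    if -100 < phi < -30 and -80 < psi < -5:
        return "alphaR"
    if -180 <= phi < -90 and (90 < psi <= 180 or -180 <= psi < -170):
        return "beta"
    if 30 < phi < 100 and -5 < psi < 80:
        return "alphaL"
    if -90 <= phi < -50 and 120 < psi <= 180:
        return "ppii"
    return "other"


def paap_score(scaffold: Scaffold) -> float:
    """Mean log-propensity of the sequence given its backbone dihedrals.

    Each residue's (phi, psi) is mapped to one of five coarse Ramachandran
    bins and scored as log P(aa | bin) from the packaged table; the mean
    over residues with defined dihedrals is returned (higher is better).
    Returns NaN if no residue has defined dihedrals (e.g. a single-residue
    chain).
    """
    table = load_rama_propensities()
    pp = backbone_dihedrals(scaffold.backbone)
    vals = []
    for i, (phi, psi) in enumerate(pp):
        if np.isnan(phi) or np.isnan(psi):
            continue
        aa = scaffold.sequence[i]
        vals.append(np.log(table[aa][_rama_bin(phi, psi)]))
    return float(np.mean(vals)) if vals else float("nan")


# --- centroid side-chain model ---------------------------------------------

def _centroid_positions(backbone: np.ndarray, sequence: str) -> np.ndarray:
    """Pseudo-atom per residue at fixed distance from CA along CA->CB."""
    cb = _scaffold_cbetas(backbone, sequence)
    ca = backbone[:, 1, :]
    out = np.empty_like(cb)
    for i in range(len(sequence)):
        v = cb[i] - ca[i]
        norm = np.linalg.norm(v)
        if norm < 1e-9:  # glycine: CB falls on CA; use a virtual direction
            v = virtual_cbeta(backbone[i, 0], ca[i], backbone[i, 2]) - ca[i]
            norm = np.linalg.norm(v)
        out[i] = ca[i] + CENTROID_DISTANCE * v / norm
    return out


def _centroid_clashes(backbone: np.ndarray, sequence: str,
                      fib_coords: np.ndarray, fib_elements: list[str],
                      radii: dict[str, float]) -> tuple[int, int]:
    """(hard, soft) clash counts of side-chain centroids against the fibril."""
    cen = _centroid_positions(backbone, sequence)
    rvdw = np.array([VDW_RADII.get(e, 1.7) for e in fib_elements])
    tree = cKDTree(fib_coords)
    hard = soft = 0
    for i, aa in enumerate(sequence):
        rc = radii[aa]
        rmax = SOFT_FACTOR * (rc + rvdw.max())
        idxs = tree.query_ball_point(cen[i], r=max(rmax, CENTROID_HARD_CUTOFF))
        if not idxs:
            continue
        d = np.linalg.norm(fib_coords[idxs] - cen[i], axis=1)
        cut = SOFT_FACTOR * (rc + rvdw[idxs])
        hard += int((d < CENTROID_HARD_CUTOFF).sum())
        soft += int(((d >= CENTROID_HARD_CUTOFF) & (d < cut)).sum())
    return hard, soft


def _pose_clashes(pose: DockedPose, assembly: FibrilAssembly,
                  sequence: str | None = None) -> tuple[int, int]:
    """Backbone + centroid (hard, soft) clash counts for a scored pose."""
    seq = sequence if sequence is not None else pose.scaffold.sequence
    posed = pose.posed_backbone()
    fib, fel = assembly.model.heavy_coords_and_elements()
    hard_bb, soft_bb = clash_counts(
        posed.reshape(-1, 3), ["N", "C", "C", "O"] * len(seq), fib, fel
    )
    hard_c, soft_c = _centroid_clashes(posed, seq, fib, fel, load_centroid_radii())
    return hard_bb + hard_c, soft_bb + soft_c


# --- greedy interface design ----------------------------------------------

def interface_positions(pose: DockedPose, assembly: FibrilAssembly,
                        cutoff: float = INTERFACE_CUTOFF) -> list[int]:
    """Scaffold residue indices with at least one backbone atom in the interface."""
    posed = pose.posed_backbone()
    fib, _ = assembly.model.heavy_coords_and_elements()
    tree = cKDTree(fib)
    out = []
    for i in range(posed.shape[0]):
        d, _ = tree.query(posed[i])
        if np.min(d) <= cutoff:
            out.append(i)
    return out


def optimize_interface_sequence(
    pose: DockedPose,
    assembly: FibrilAssembly,
    mutable: list[int] | None = None,
    max_sweeps: int = 10,
) -> tuple[DockedPose, list[float]]:
    """Greedy per-position optimization of the interface sequence.

    Sweeps over mutable positions in ascending index order; at each
    position all 19 non-cysteine amino acids are tried and the best
    contact-energy improvement that introduces no hard clash under the
    centroid side-chain model is accepted. Stops when a full sweep makes
    no change. Returns the redesigned pose and the score trajectory
    (monotone non-increasing by construction).
    """
    if mutable is None:
        mutable = interface_positions(pose, assembly)
    mutable = sorted(mutable)
    table = load_contact_table()
    radii = load_centroid_radii()
    fib, fel = assembly.model.heavy_coords_and_elements()
    posed = pose.posed_backbone()

    seq = list(pose.scaffold.sequence)
    current = ddg_surrogate(pose, assembly, table)
    trajectory = [current]
    if not mutable:
        return pose, trajectory

    # The docked geometry is fixed during sequence design except for the
    # glycine CA-for-CB convention, so the contact partners of every
    # non-glycine candidate can be tabulated once and each trial scored
    # incrementally. Glycine trials fall back to the full evaluation.
    partners: dict[int, list[str]] = {}
    scb = _scaffold_cbetas(posed, "A" * len(seq))  # virtual CB everywhere
    for chain in assembly.model.chains:
        fcb, fseq = _chain_cbetas(chain)
        d = np.sqrt(((scb[:, None, :] - fcb[None, :, :]) ** 2).sum(axis=-1))
        ii, jj = np.nonzero(d <= CONTACT_CB_CUTOFF)
        for i, j in zip(ii, jj):
            partners.setdefault(int(i), []).append(fseq[j])

    def trial_score(i: int, aa: str) -> float:
        if aa == "G" or seq[i] == "G":
            saved = seq[i]
            seq[i] = aa
            s = ddg_surrogate(pose, assembly, table, sequence="".join(seq))
            seq[i] = saved
            return s
        delta = sum(table[(aa, fj)] - table[(seq[i], fj)] for fj in partners.get(i, ()))
        return current + delta

    for _ in range(max_sweeps):
        changed = False
        for i in mutable:
            best_aa, best_score = seq[i], current
            for aa in DESIGN_AA:
                if aa == seq[i]:
                    continue
                hard, _ = _centroid_clashes(
                    posed[i : i + 1], aa, fib, fel, radii
                )
                if hard > 0:
                    continue
                s = trial_score(i, aa)
                if s < best_score - 1e-12:
                    best_aa, best_score = aa, s
            if best_aa != seq[i]:
                seq[i] = best_aa
                # re-anchor on the exact evaluator so incremental drift
                # cannot accumulate
                current = ddg_surrogate(pose, assembly, table, sequence="".join(seq))
                trajectory.append(current)
                changed = True
        if not changed:
            break
    new_scaffold = replace_sequence(pose.scaffold, "".join(seq))
    new_pose = DockedPose(
        pose.scaffold_id, new_scaffold, pose.site, pose.strand_choice,
        pose.transform, pose.graft_rmsd, pose.hard_clashes, pose.soft_clashes,
        pose.orientation,
    )
    return new_pose, trajectory


def replace_sequence(scaffold: Scaffold, sequence: str) -> Scaffold:
    if len(sequence) != len(scaffold):
        raise ScoreError("sequence length mismatch")
    return Scaffold(scaffold.backbone, scaffold.ss, sequence, scaffold.seed, scaffold.class_id)


# --- mutation rescoring ----------------------------------------------------

def parse_mutation(mut: str) -> tuple[str, int, str]:
    if len(mut) < 3 or mut[0] not in AA20 or mut[-1] not in AA20:
        raise ScoreError(f"malformed mutation string {mut!r}")
    try:
        pos = int(mut[1:-1])
    except ValueError:
        raise ScoreError(f"malformed mutation string {mut!r}") from None
    return mut[0], pos, mut[-1]


def score_pose(pose: DockedPose, assembly: FibrilAssembly,
               config: FunnelConfig = FunnelConfig()) -> InterfaceScore:
    """Compute the full funnel metric set for one pose."""
    sat, unsat = tip_hbond_satisfaction(assembly, pose)
    n_iface = interface_atom_count(pose, assembly)
    ddg = ddg_surrogate(pose, assembly)
    paap = paap_score(pose.scaffold)
    hard, soft = _pose_clashes(pose, assembly)
    return InterfaceScore(
        design_id=pose.scaffold_id,
        hb_satisfied=sat,
        hb_unsat=unsat,
        interface_atoms=n_iface,
        ddg_surrogate=ddg,
        paap=paap,
        soft_clashes=soft,
        hard_clashes=hard,
    )


def mutate_and_rescore(pose: DockedPose, assembly: FibrilAssembly,
                       mutations: list[str]) -> dict[str, float]:
    """Apply point mutations (author numbering, e.g. "A42R") and rescore.

    Side chains are the centroid pseudo-atoms; a mutation swaps the
    centroid radius and residue type, all funnel metrics are recomputed,
    and the deltas (mutant - reference) are returned.

    Raises
    ------
    ScoreError
        If the reference residue does not match (e.g. "A42R" where
        position 42 is not alanine).
    """
    seq = list(pose.scaffold.sequence)
    for mut in mutations:
        ref, pos, new = parse_mutation(mut)
        idx = pos - 1  # author numbering of the scaffold starts at 1
        if not 0 <= idx < len(seq):
            raise ScoreError(f"mutation {mut}: position {pos} outside scaffold")
        if seq[idx] != ref:
            raise ScoreError(
                f"mutation {mut}: position {pos} is {seq[idx]}, not {ref}"
            )
        seq[idx] = new
    before = score_pose(pose, assembly)
    mutant_pose = DockedPose(
        pose.scaffold_id + "+" + ",".join(mutations),
        replace_sequence(pose.scaffold, "".join(seq)),
        pose.site, pose.strand_choice, pose.transform, pose.graft_rmsd,
        pose.hard_clashes, pose.soft_clashes, pose.orientation,
    )
    after = score_pose(mutant_pose, assembly)
    return {
        "d_hb_satisfied": after.hb_satisfied - before.hb_satisfied,
        "d_hb_unsat": after.hb_unsat - before.hb_unsat,
        "d_interface_atoms": after.interface_atoms - before.interface_atoms,
        "d_ddg_surrogate": after.ddg_surrogate - before.ddg_surrogate,
        "d_paap": after.paap - before.paap,
        "d_soft_clashes": after.soft_clashes - before.soft_clashes,
        "d_hard_clashes": after.hard_clashes - before.hard_clashes,
    }


# --- ranking ---------------------------------------------------------------

def rank_designs(scores: list[InterfaceScore],
                 config: FunnelConfig = FunnelConfig()) -> pd.DataFrame:
    """Filter-then-sort funnel ranking of scored poses.

    Hard filters first (no hard clashes, unsatisfied H-bonds and
    interface-atom thresholds), then sort by the binding-energy surrogate
    ascending, ties by satisfied H-bonds descending, then design id: a
    deterministic total order invariant to input permutation.
    """
    rows = [
        s for s in scores
        if s.hard_clashes == 0
        and s.hb_unsat <= config.hb_unsat_max
        and s.interface_atoms >= config.interface_atoms_min
    ]
    rows.sort(key=lambda s: (s.ddg_surrogate, -s.hb_satisfied, s.design_id))
    records = []
    for rank, s in enumerate(rows, start=1):
        s.composite_rank = rank
        records.append({
            "rank": rank,
            "design_id": s.design_id,
            "ddg_surrogate": s.ddg_surrogate,
            "hb_satisfied": s.hb_satisfied,
            "hb_unsat": s.hb_unsat,
            "interface_atoms": s.interface_atoms,
            "paap": s.paap,
            "soft_clashes": s.soft_clashes,
        })
    return pd.DataFrame.from_records(
        records,
        columns=["rank", "design_id", "ddg_surrogate", "hb_satisfied",
                 "hb_unsat", "interface_atoms", "paap", "soft_clashes"],
    )
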