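"""Miniprotein scaffold generation.

Enumerates the topology classes (one alpha-helix plus two or three
beta-strands, e.g. HEE), builds idealized 35-50 residue backbones from
blueprints, and assigns a burial-based starting sequence: hydrophobic
core, charged/polar exterior, never cysteine (the designs must survive
the reducing cytoplasm, so disulfides are excluded by construction).

Backbones are built residue-by-residue with ideal bond geometry: helix
and strand elements use ideal dihedrals, loop dihedrals are drawn from
allowed Ramachandran bins with a seeded generator. A candidate is
accepted when it is clash-free and compact; generation is deterministic
given (blueprint, seed).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .backbone import HELIX_PHI_PSI, STRAND_PHI_PSI, build_from_dihedrals
from .errors import BuildError

__all__ = [
    "TopologyClass",
    "Blueprint",
    "Scaffold",
    "enumerate_topology_classes",
    "build_backbone",
    "assign_initial_sequence",
    "sample_blueprint",
]

MIN_LENGTH = 35
MAX_LENGTH = 50

#: Self-clash threshold between heavy atoms of non-adjacent residues.
SELF_CLASH_CUTOFF = 2.0

#: Compactness: accepted scaffolds satisfy Rg <= RG_COEFF * N**RG_EXP.
RG_COEFF = 3.0
RG_EXP = 0.34

HYDROPHOBIC = "AVLIFMW"
POLAR = "DEKRNQST"
BURIAL_RADIUS = 10.0
BURIAL_THRESHOLD = 12

# Loop Ramachandran bins: (phi range, psi range), sampling weight.
LOOP_BINS = (
    ((-100.0, -30.0), (-80.0, -5.0), 0.35),   # broad alpha
    ((-180.0, -90.0), (90.0, 180.0), 0.50),   # broad beta / extended
    ((30.0, 100.0), (-5.0, 80.0), 0.15),      # left-handed alpha
)


@dataclass(frozen=True)
class TopologyClass:
    """Ordered arrangement of helix (H) and strand (E) elements."""

    ss_string: str

    def __post_init__(self) -> None:
        s = self.ss_string
        if set(s) - {"H", "E"}:
            raise ValueError(f"topology may contain only H and E: {s!r}")
        if s.count("H") != 1 or s.count("E") < 1:
            raise ValueError(
                f"topology must have exactly one helix and at least one strand: {s!r}"
            )

    def __str__(self) -> str:
        return self.ss_string


@dataclass(frozen=True)
class Blueprint:
    """Ordered (kind, length) elements, kinds in {H, E, L}."""

    elements: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple((k, int(n)) for k, n in self.elements))
        for kind, n in self.elements:
            if kind not in "HEL":
                raise ValueError(f"unknown element kind {kind!r}")
            if n < 1:
                raise ValueError("element lengths must be positive")
        if not MIN_LENGTH <= self.total_length <= MAX_LENGTH:
            raise BuildError(
                f"blueprint length {self.total_length} outside [{MIN_LENGTH}, {MAX_LENGTH}]"
            )
        core = "".join(k for k, _ in self.elements if k != "L")
        TopologyClass(core)  # validates the topology pattern

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.elements)

    @property
    def ss(self) -> str:
        return "".join(k * n for k, n in self.elements)

    @property
    def topology(self) -> TopologyClass:
        return TopologyClass("".join(k for k, _ in self.elements if k != "L"))


@dataclass
class Scaffold:
    """An idealized miniprotein backbone with sequence and provenance."""

    backbone: np.ndarray  # (n, 4, 3): N, CA, C, O
    ss: str
    sequence: str
    seed: int
    class_id: TopologyClass

    def __len__(self) -> int:
        return self.backbone.shape[0]

    def strand_elements(self) -> list[tuple[int, int]]:
        """(start, stop) index ranges of the E elements, in order."""
        runs = []
        i = 0
        n = len(self.ss)
        while i < n:
            j = i
            while j < n and self.ss[j] == self.ss[i]:
                j += 1
            if self.ss[i] == "E":
                runs.append((i, j))
            i = j
        return runs

    def ca_coords(self) -> np.ndarray:
        return self.backbone[:, 1, :]

    def to_chain(self, chain_id: str = "Z"):
        """Export as a structure_io Chain (backbone atoms only)."""
        from .structure_io import AA1_TO_3, Atom, Chain, Residue

        chain = Chain(chain_id)
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        for i in range(len(self)):
            aa = self.sequence[i] if self.sequence else "A"
            res = Residue(AA1_TO_3.get(aa, "ALA"), i + 1)
            for j, name in enumerate(("N", "CA", "C", "O")):
                res.atoms.append(Atom(name, elements[name], self.backbone[i, j], 0))
            chain.residues.append(res)
        return chain


def enumerate_topology_classes(
    n_helix: set[int] = frozenset({1}), n_strand: set[int] = frozenset({2, 3})
) -> list[TopologyClass]:
    """All distinct H/E arrangements for the given element counts.

    With one helix and two or three strands this yields the seven classes
    HEE, EHE, EEH, HEEE, EHEE, EEHE, EEEH (returned lexicographically).
    """
    if not n_helix or not n_strand:
        raise ValueError("element count sets must be non-empty")
    seen = set()
    for h in sorted(n_helix):
        for e in sorted(n_strand):
            for perm in set(itertools.permutations("H" * h + "E" * e)):
                seen.add("".join(perm))
    return [TopologyClass(s) for s in sorted(seen)]


def _self_clash_pairs(coords_flat: np.ndarray) -> int:
    """Heavy-atom pairs from non-adjacent residues closer than the cutoff."""
    from scipy.spatial import cKDTree

    pairs = cKDTree(coords_flat).query_pairs(SELF_CLASH_CUTOFF, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    res = pairs // 4
    return int((np.abs(res[:, 0] - res[:, 1]) >= 2).sum())


def _self_clashes(coords_flat: np.ndarray, n_res: int) -> bool:
    return _self_clash_pairs(coords_flat) > 0


def _radius_of_gyration(ca: np.ndarray) -> float:
    centered = ca - ca.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def _sample_loop(rng: np.random.Generator) -> tuple[float, float]:
    weights = np.array([w for _, _, w in LOOP_BINS])
    k = rng.choice(len(LOOP_BINS), p=weights / weights.sum())
    (plo, phi_), (qlo, qhi), _ = LOOP_BINS[k]
    return float(rng.uniform(plo, phi_)), float(rng.uniform(qlo, qhi))


def _loop_ranges(blueprint: Blueprint) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for kind, n in blueprint.elements:
        if kind == "L":
            out.append((pos, pos + n))
        pos += n
    return out


def build_backbone(
    blueprint: Blueprint,
    seed: int,
    max_tries: int = 12,
    greedy_draws: int = 12,
    refine_steps: int = 500,
    patience: int = 80,
) -> Scaffold:
    """Build an idealized backbone for a blueprint.

    Helix and strand elements take ideal dihedrals; loop dihedrals are
    drawn from allowed Ramachandran bins with a seeded generator. An
    independently sampled chain is almost never globular, so each attempt
    folds the chain in two stages: loops are first chosen greedily —
    ``greedy_draws`` candidates per loop, keeping the one that most
    compacts the partial chain — and the result is then refined by
    stochastic descent on (clashing pairs, radius-of-gyration excess),
    resampling one loop element per proposal. A candidate is accepted
    once it is self-clash-free and compact (Rg <= RG_COEFF * N**RG_EXP);
    up to ``max_tries`` attempts are made. The whole procedure uses one
    seeded stream, so the result is bit-identical given
    (blueprint, seed).

    Raises
    ------
    BuildError
        If no attempt converges; the caller may retry with another seed.
    """
    rng = np.random.default_rng(seed)
    n = blueprint.total_length
    ss = blueprint.ss
    rg_limit = RG_COEFF * n**RG_EXP
    loops = _loop_ranges(blueprint)

    base = np.empty((n, 2))
    for i, kind in enumerate(ss):
        if kind == "H":
            base[i] = HELIX_PHI_PSI
        elif kind == "E":
            base[i] = STRAND_PHI_PSI
        else:
            base[i] = (0.0, 0.0)  # filled per attempt

    def key_of(pp: np.ndarray) -> tuple[tuple[int, float], np.ndarray]:
        c = build_from_dihedrals(pp)
        clashes = _self_clash_pairs(c.reshape(-1, 3))
        excess = max(_radius_of_gyration(c[:, 1, :]) - rg_limit, 0.0)
        return (clashes, excess), c

    for _attempt in range(max_tries):
        pp = base.copy()
        # stage 1: greedy loop-by-loop compaction of the partial chain
        for li, (lo, hi) in enumerate(loops):
            prefix_end = loops[li + 1][0] if li + 1 < len(loops) else n
            best = None
            for _ in range(greedy_draws):
                for i in range(lo, hi):
                    pp[i] = _sample_loop(rng)
                partial = build_from_dihedrals(pp[:prefix_end])
                rg = _radius_of_gyration(partial[:, 1, :])
                if best is None or rg < best[0]:
                    best = (rg, pp[lo:hi].copy())
            pp[lo:hi] = best[1]
        cur, coords = key_of(pp)
        if cur[1] > 2.5:  # hopeless attempt, redraw from scratch
            continue
        # stage 2: stochastic descent to clash-free compactness
        stalled = 0
        for _ in range(refine_steps):
            if cur == (0, 0.0):
                break
            if stalled >= patience:
                break
            lo, hi = loops[rng.integers(len(loops))]
            cand = pp.copy()
            if rng.random() < 0.5:
                idxs = range(lo, hi)
            else:
                idxs = [int(rng.integers(lo, hi))]
            for i in idxs:
                cand[i] = _sample_loop(rng)
            ck, cc = key_of(cand)
            stalled += 1
            if ck < cur:
                pp, cur, coords, stalled = cand, ck, cc, 0
        if cur == (0, 0.0):
            return Scaffold(coords, ss, "", seed, blueprint.topology)
    raise BuildError(
        f"no clash-free compact backbone for {blueprint.topology} "
        f"(N={n}) within {max_tries} attempts; reseed and retry"
    )


def assign_initial_sequence(scaffold: Scaffold) -> Scaffold:
    """Fill the scaffold sequence from per-residue burial.

    Burial of residue i is the count of CA atoms within BURIAL_RADIUS,
    excluding chain neighbors i-2..i+2. Buried positions draw from the
    hydrophobic set, exposed ones from the charged/polar set; loop
    positions with positive phi get glycine. Cysteine is never assigned.
    The draw uses a stream seeded from the scaffold seed, so sequences
    are reproducible.
    """
    from .backbone import backbone_dihedrals

    n = len(scaffold)
    ca = scaffold.ca_coords()
    d = np.sqrt(((ca[:, None, :] - ca[None, :, :]) ** 2).sum(axis=-1))
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    burial = ((d <= BURIAL_RADIUS) & (sep > 2)).sum(axis=1)

    pp = backbone_dihedrals(scaffold.backbone)
    rng = np.random.default_rng(np.random.SeedSequence([scaffold.seed, 1]))
    seq = []
    for i in range(n):
        phi = pp[i, 0]
        if scaffold.ss[i] == "L" and np.isfinite(phi) and phi > 0:
            seq.append("G")
        elif burial[i] >= BURIAL_THRESHOLD:
            seq.append(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))])
        else:
            seq.append(POLAR[rng.integers(len(POLAR))])
    return Scaffold(scaffold.backbone, scaffold.ss, "".join(seq), scaffold.seed, scaffold.class_id)


def sample_blueprint(topology: TopologyClass, rng: np.random.Generator) -> Blueprint:
    """Draw a random blueprint for a topology with total length in [35, 50].

    Helix 10-14 residues, strands 5-8, loops 3-5 between elements plus
    short 1-2 residue termini; resampled until the total fits the length
    window.
    """
    for _ in range(200):
        elements: list[tuple[str, int]] = []
        elements.append(("L", int(rng.integers(1, 3))))
        for k, kind in enumerate(topology.ss_string):
            if k > 0:
                elements.append(("L", int(rng.integers(3, 6))))
            if kind == "H":
                elements.append(("H", int(rng.integers(10, 15))))
            else:
                elements.append(("E", int(rng.integers(5, 9))))
        elements.append(("L", int(rng.integers(1, 3))))
        total = sum(nl for _, nl in elements)
        if MIN_LENGTH <= total <= MAX_LENGTH:
            return Blueprint(tuple(elements))
    raise BuildError(f"could not sample a blueprint in length window for {topology}")
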