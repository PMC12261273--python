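"""Synthetic study systems with known ground truth.

Everything downstream is exercised against systems built here: a coarse
hairpin-plus-tail ssDNA model (≈15 atoms per residue: phosphate, sugar
skeleton, base-ring hexagon and Watson–Crick edge atoms), Gaussian-
fluctuation trajectories with planted conformers and contacts, and boosted
collective-variable samples whose canonical free-energy surface is known in
closed form.  Fixtures ship their ground truth (pair lists, segment sigmas,
conformer counts, analytic PMFs) so tests assert against construction.

The default spec represents the study conditions used throughout the test
suite: a 4-bp stem closed by a 4-nt loop with a 10-nt single-stranded 3'
tail, 1000 frames, a rigid core (σ = 0.2 Å) and a floppy tail (σ = 2.0 Å
plus rigid reorientation about the junction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Atom, Sequence, Topology, Trajectory, write_pdb_models, write_topology
from .reweight import KB, BoostSeries
from .secondary import SecondaryStructure

__all__ = [
    "FixtureSpec",
    "HairpinSystem",
    "make_hairpin_system",
    "simulate_trajectory",
    "simulate_boosted_cv",
    "write_fixture_bundle",
]

_RISE = 3.4  # Å stacking rise in the stem
_BACKBONE_X = 8.0  # |x| of the backbone anchor in the stem
_WC_X = 1.45  # |x| of Watson-Crick edge atoms: gap = 2.9 Å

# Local template offsets (e1 = toward partner, e2 = in-plane, e3 = normal).
# The backbone positions were optimized once, offline, so that within a
# stem every nonbonded (and 1-4) pair of the residue, its stacked
# neighbors and the paired strand stays outside the steep Lennard-Jones
# wall; the values are frozen here as the fixture geometry.
_BACKBONE_TEMPLATE = {
    "P": (-0.95, 0.81, 0.58),
    "O5'": (-0.84, -0.45, 0.28),
    "C5'": (0.54, 0.41, -0.02),
    "C4'": (1.69, 0.00, -0.46),
    "O4'": (1.96, 2.79, 0.98),
    "C3'": (1.37, -1.74, -1.19),
    "O3'": (1.99, -2.79, -1.63),
    "C1'": (2.86, 1.32, 0.28),
}
_RING_CENTER = 5.05  # along e1
_RING_RADIUS = 1.5
# hexagon vertex order, WC-edge vertex first (position 6.55 e1)
_RING_ORDER = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N3", "C4", "C5", "C6", "N1", "C2"),
    "T": ("N3", "C4", "C5", "C6", "N1", "C2"),
}
#: exocyclic WC atoms: name -> in-plane offset dy from the edge vertex.
#: The 2.2 Å spacing is wider than chemistry would place them; it keeps the
#: diagonal (non-Watson-Crick) donor/acceptor combinations outside the
#: hydrogen-bond cutoff so the planted pairs are recovered as exactly the
#: canonical bond set.
_WC_EXTRA = {
    "G": (("O6", 2.2), ("N2", -2.2)),
    "C": (("N4", 2.2), ("O2", -2.2)),
    "A": (("N6", 2.2),),
    "T": (("O4", 2.2), ("O2", -2.2)),
}
_CHARGES = {
    "P": 1.17, "O5'": -0.50, "C5'": 0.05, "C4'": 0.10, "O4'": -0.37,
    "C3'": 0.07, "O3'": -0.52, "C1'": 0.13,
    "O6": -0.225, "O4": -0.225, "O2": -0.225,
    "N2": 0.15, "N4": 0.15, "N6": 0.15,
}
_RING_CHARGE = {"N": -0.20, "C": 0.10}
#: ring nitrogens that carry the Watson-Crick proton get a positive charge
#: so planted hydrogen bonds are electrostatically favorable; the moderate
#: magnitudes keep the generalized-Born desolvation cost of burying the
#: edge below the contact attraction, so a formed pair is a real minimum
_RING_CHARGE_OVERRIDE = {("G", "N1"): 0.12, ("T", "N3"): 0.12}
_LJ = {"C": (3.40, 0.086), "N": (3.25, 0.17), "O": (2.96, 0.21), "P": (3.74, 0.20)}
#: Watson-Crick edge atoms carry implicit hydrogens, so their effective LJ
#: radius is reduced: the 2.9 Å donor-acceptor geometry then sits at the
#: pair minimum instead of inside the repulsive wall, making a planted
#: base pair a genuine energy well for the end-point scorer.
_WC_LJ = (2.55, 0.8)
_WC_EDGE_ATOMS = {"O6", "N2", "N4", "O2", "O4", "N6",
                  ("G", "N1"), ("T", "N3"), ("C", "N3"), ("A", "N1")}
_GB_RADIUS = {"C": 1.7, "N": 1.55, "O": 1.5, "P": 1.85, "H": 1.2}
_GB_SCREEN = {"C": 0.72, "N": 0.79, "O": 0.85, "P": 0.86, "H": 0.85}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class FixtureSpec:
    """Ground-truth parameters of a synthetic hairpin-plus-tail system."""

    n_stem: int = 4  # base pairs
    n_loop: int = 4  # unpaired loop residues (>= 3)
    n_tail: int = 10  # single-stranded tail residues
    tail_end: str = "3p"  # "5p" | "3p"
    tail_base: str = "T"
    stem_seq: str | None = None  # 5' strand of the stem; default alternating G/C
    sigma_stem: float = 0.2  # Å isotropic jitter of the structured core
    sigma_tail: float = 2.0  # Å isotropic jitter of the tail
    tail_reorient_deg: float = 25.0  # per-frame rigid tail swing (std of rotvec)
    n_frames: int = 1000
    dt_ns: float = 0.1
    conformer_populations: tuple[float, ...] | None = None
    planted_contact_pair: tuple[int, int] | None = None
    planted_contact_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stem < 2:
            raise ValueError("a stem needs at least 2 base pairs")
        if self.n_loop < 3:
            raise ValueError("hairpin loops need at least 3 residues")
        if self.n_tail < 0:
            raise ValueError("n_tail must be >= 0")
        if self.tail_end not in ("5p", "3p"):
            raise ValueError("tail_end must be '5p' or '3p'")
        if self.conformer_populations is not None:
            if abs(sum(self.conformer_populations) - 1.0) > 1e-9:
                raise ValueError("conformer populations must sum to 1")
        if self.sigma_stem <= 0 or self.sigma_tail <= 0:
            raise ValueError("fluctuation sigmas must be positive")


@dataclass
class HairpinSystem:
    topology: Topology
    reference: np.ndarray  # (n_atoms, 3)
    secondary: SecondaryStructure
    sequence: Sequence
    ground_truth: dict = field(default_factory=dict)
    spec: FixtureSpec | None = None


def _residue_atoms(base: str, origin, e1, e2, e3, start_id: int, res_idx: int):
    """Place one coarse residue; returns (atoms, coords, bonds, name->id)."""
    atoms, coords, bonds = [], [], []
    name_to_id = {}
    aid = start_id

    def add(name, pos, charge):
        nonlocal aid
        element = name[0]
        if name in _WC_EDGE_ATOMS or (base, name) in _WC_EDGE_ATOMS:
            sig, eps = _WC_LJ
        else:
            sig, eps = _LJ[element]
        atoms.append(
            Atom(
                atom_id=aid, name=name, element=element, residue_index=res_idx,
                charge=charge, lj_sigma=sig, lj_epsilon=eps,
                gb_radius=_GB_RADIUS[element], gb_screen=_GB_SCREEN[element],
            )
        )
        coords.append(pos)
        name_to_id[name] = aid
        aid += 1

    o = np.asarray(origin, float)
    for name, (a, b_, c) in _BACKBONE_TEMPLATE.items():
        add(name, o + a * e1 + b_ * e2 + c * e3, _CHARGES[name])
    center = o + _RING_CENTER * e1
    ring = _RING_ORDER[base]
    for k, name in enumerate(ring):
        ang = 2.0 * np.pi * k / 6.0
        pos = center + _RING_RADIUS * (np.cos(ang) * e1 + np.sin(ang) * e2)
        charge = _RING_CHARGE_OVERRIDE.get((base, name), _RING_CHARGE[name[0]])
        add(name, pos, charge)
    edge = o + (_RING_CENTER + _RING_RADIUS) * e1  # the WC-edge vertex position
    for name, dy in _WC_EXTRA[base]:
        add(name, edge + dy * e2, _CHARGES[name])

    chain = ["P", "O5'", "C5'", "C4'", "C3'", "O3'"]
    for a, b_ in zip(chain, chain[1:]):
        bonds.append((name_to_id[a], name_to_id[b_]))
    # compressed furanose: C4'-C1' closes the sugar, O4' hangs off C1'
    bonds.append((name_to_id["C4'"], name_to_id["C1'"]))
    bonds.append((name_to_id["C1'"], name_to_id["O4'"]))
    bonds.append((name_to_id["C1'"], name_to_id[ring[3]]))
    for k in range(6):
        bonds.append((name_to_id[ring[k]], name_to_id[ring[(k + 1) % 6]]))
    for name, dy in _WC_EXTRA[base]:
        # the coarse edge atom bridges the WC vertex and its neighbor on
        # the same side, so no stretched 1-4 contact remains inside a base
        bonds.append((name_to_id[name], name_to_id[ring[0]]))
        bonds.append((name_to_id[name], name_to_id[ring[1 if dy > 0 else 5]]))
    return atoms, coords, bonds, name_to_id


def make_hairpin_system(spec: FixtureSpec | None = None) -> HairpinSystem:
    """Build the coarse hairpin(+tail) topology, reference geometry and fold.

    Stem pairs are placed with their Watson–Crick edge atoms exactly 2.9 Å
    apart and consecutive stem bases stacked at a 3.4 Å rise, so the
    default contact criteria recover the planted pairs and stacks; loop and
    tail bases point away from the core and make no contacts.
    """
    spec = spec or FixtureSpec()
    n_stem, n_loop, n_tail = spec.n_stem, spec.n_loop, spec.n_tail
    stem_seq = spec.stem_seq or "".join("GC"[i % 2] for i in range(n_stem))
    if len(stem_seq) != n_stem:
        raise ValueError("stem_seq length must equal n_stem")
    core_len = 2 * n_stem + n_loop
    n_res = core_len + n_tail
    off = n_tail if spec.tail_end == "5p" else 0  # residues before the core

    seq = [""] * n_res
    kind = [""] * n_res  # stem5 | loop | stem3 | tail
    for t in range(n_tail):
        pos = t if spec.tail_end == "5p" else core_len + t
        seq[pos] = spec.tail_base
        kind[pos] = "tail"
    for i in range(n_stem):
        seq[off + i] = stem_seq[i]
        kind[off + i] = "stem5"
        seq[off + core_len - 1 - i] = _COMPLEMENT[stem_seq[i]]
        kind[off + core_len - 1 - i] = "stem3"
    for m in range(n_loop):
        seq[off + n_stem + m] = "T"
        kind[off + n_stem + m] = "loop"

    pairing: dict[int, int] = {}
    pairs = []
    for i in range(n_stem):
        a = off + i + 1
        b = off + core_len - i
        pairing[a] = b
        pairing[b] = a
        pairs.append((a, b))

    ez = np.array([0.0, 0.0, 1.0])
    ey = np.array([0.0, 1.0, 0.0])
    origins: list[np.ndarray] = [None] * n_res
    frames_e: list[tuple] = [None] * n_res
    z_top = _RISE * n_stem
    for i in range(n_stem):  # 5' strand, pair i+1 at z = (i+1) * rise
        r = off + i
        origins[r] = np.array([-_BACKBONE_X, 0.0, _RISE * (i + 1)])
        frames_e[r] = (np.array([1.0, 0.0, 0.0]), ey, ez)
        r2 = off + core_len - 1 - i
        origins[r2] = np.array([_BACKBONE_X, 0.0, _RISE * (i + 1)])
        frames_e[r2] = (np.array([-1.0, 0.0, 0.0]), ey, ez)
    for m in range(n_loop):  # arc over the top, bases pointing outward
        r = off + n_stem + m
        t = np.pi * (m + 1) / (n_loop + 1)
        radial = np.array([-np.cos(t), np.sin(t), 0.0])
        origins[r] = _BACKBONE_X * radial + np.array([0.0, 0.0, z_top + 3.0])
        e1 = radial  # base points away from the hairpin axis
        e3 = ez
        e2 = np.cross(e3, e1)
        frames_e[r] = (e1, e2, e3)
    if n_tail:
        step = np.array([5.0, 0.0, -3.5])
        step = 6.0 * step / np.linalg.norm(step)
        if spec.tail_end == "3p":
            anchor = np.array([_BACKBONE_X, 0.0, _RISE])  # 3' stem strand bottom
            order = range(core_len, n_res)
        else:
            anchor = np.array([-_BACKBONE_X, 0.0, _RISE])
            step = step * np.array([-1.0, 1.0, 1.0])
            order = range(n_tail - 1, -1, -1)  # 5' terminus farthest out
        # bases point +y, ring planes perpendicular to the chain direction:
        # neighboring residues are then separated by the full 6 Å step in
        # every atom, leaving the extended tail free of self-contacts
        e1 = np.array([0.0, 1.0, 0.0])
        e3 = step / np.linalg.norm(step)
        e2 = np.cross(e3, e1)
        for k, r in enumerate(order):
            origins[r] = anchor + (k + 1) * step
            frames_e[r] = (e1, e2, e3)
        tail_pivot = anchor.copy()
    else:
        tail_pivot = None

    atoms: list[Atom] = []
    coords: list = []
    bonds: list[tuple[int, int]] = []
    residue_bases: dict[int, str] = {}
    last_o3: int | None = None
    next_id = 1
    for r in range(n_res):
        res_idx = r + 1
        residue_bases[res_idx] = seq[r]
        a, c, b, names = _residue_atoms(
            seq[r], origins[r], *frames_e[r], next_id, res_idx
        )
        atoms += a
        coords += c
        bonds += b
        if last_o3 is not None:
            bonds.append((last_o3, names["P"]))
        last_o3 = names["O3'"]
        next_id += len(a)

    topo = Topology(atoms=atoms, bonds=bonds, residue_bases=residue_bases)
    ref = np.array(coords)
    sequence = Sequence(id="fixture", residues="".join(seq))
    db = "".join(
        "(" if i + 1 in pairing and pairing[i + 1] > i + 1
        else ")" if i + 1 in pairing else "."
        for i in range(n_res)
    )
    ss = SecondaryStructure(pairing=pairing, dot_bracket=db, source="dotbracket")
    tail_residues = [r + 1 for r in range(n_res) if kind[r] == "tail"]
    ground_truth = {
        "pairs": pairs,
        "stem_residues": [r + 1 for r in range(n_res) if kind[r] in ("stem5", "stem3")],
        "loop_residues": [r + 1 for r in range(n_res) if kind[r] == "loop"],
        "tail_residues": tail_residues,
        "tail_pivot": None if tail_pivot is None else tail_pivot.tolist(),
        "sigma_stem": spec.sigma_stem,
        "sigma_tail": spec.sigma_tail,
    }
    return HairpinSystem(
        topology=topo, reference=ref, secondary=ss, sequence=sequence,
        ground_truth=ground_truth, spec=spec,
    )


def _conformer_counts(populations: tuple[float, ...], n_frames: int) -> list[int]:
    """Deterministic largest-remainder allocation of frames to conformers."""
    raw = [p * n_frames for p in populations]
    counts = [int(np.floor(x)) for x in raw]
    rem = n_frames - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: -(raw[i] - counts[i]))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def simulate_trajectory(system: HairpinSystem, spec: FixtureSpec | None = None) -> Trajectory:
    """Gaussian-fluctuation trajectory with the spec's planted features.

    Core atoms are jittered isotropically with σ_stem; tail atoms undergo a
    per-frame rigid reorientation about the stem–tail junction plus σ_tail
    jitter.  Discrete conformers (rigid tail swings of 0°, 120°, 240°, …
    about the helix axis) occupy exactly their allotted frame counts in
    contiguous blocks, and a planted contact, when requested, is present in
    exactly ``round(fraction · n_frames)`` leading frames (the partner's
    Watson–Crick atoms are displaced 5 Å in the remaining frames).
    """
    spec = spec or system.spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    topo = system.topology
    ref = system.reference
    n_atoms = ref.shape[0]
    tail_res = set(system.ground_truth["tail_residues"])
    tail_atoms = np.array(
        [k for k, a in enumerate(topo.atoms) if a.residue_index in tail_res], dtype=int
    )
    core_atoms = np.array(
        [k for k in range(n_atoms) if k not in set(tail_atoms.tolist())], dtype=int
    )
    pivot = system.ground_truth["tail_pivot"]
    pivot = np.zeros(3) if pivot is None else np.asarray(pivot)

    if spec.conformer_populations is not None:
        counts = _conformer_counts(spec.conformer_populations, spec.n_frames)
    else:
        counts = [spec.n_frames]
    conf_of_frame = np.repeat(np.arange(len(counts)), counts)

    if tail_atoms.size:
        moving = tail_atoms
    else:
        # no tail: conformers swing the loop + 3' strand about the helix axis
        half_res = set(
            system.ground_truth["loop_residues"]
        ) | {r for r in system.ground_truth["stem_residues"]
             if r > max(system.ground_truth["loop_residues"])}
        moving = np.array(
            [k for k, a in enumerate(topo.atoms) if a.residue_index in half_res],
            dtype=int,
        )
    conf_rots = [
        Rotation.from_rotvec([0.0, 0.0, np.deg2rad(360.0 * c / max(len(counts), 1))])
        for c in range(len(counts))
    ]

    broken_atoms = np.array([], dtype=int)
    n_contact_frames = spec.n_frames
    if spec.planted_contact_fraction is not None:
        pair = spec.planted_contact_pair or system.ground_truth["pairs"][0]
        j = pair[1]
        base = topo.residue_base(j)
        wc_names = {name for name, _ in _WC_EXTRA[base]} | {_RING_ORDER[base][0]}
        broken_atoms = np.array(
            [k for k, a in enumerate(topo.atoms)
             if a.residue_index == j and a.name in wc_names],
            dtype=int,
        )
        n_contact_frames = int(round(spec.planted_contact_fraction * spec.n_frames))

    frames = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        x = ref.copy()
        c = conf_of_frame[f]
        if len(counts) > 1:
            x[moving] = conf_rots[c].apply(x[moving] - pivot) + pivot
        if tail_atoms.size:
            # The tail moves as a floppy rigid body: a random swing about
            # the junction plus a bulk translation of amplitude sigma_tail.
            # Keeping the tail internally rigid (up to the small per-atom
            # jitter below) avoids the sterically impossible atom overlaps
            # that independent per-atom displacements of this size produce;
            # excluded volume is honored by redrawing moves that would park
            # the tail inside the core.
            base_tail = x[tail_atoms]
            core_x = x[core_atoms]
            for _attempt in range(20):
                rotvec = rng.normal(0.0, np.deg2rad(spec.tail_reorient_deg), 3)
                shift = rng.normal(0.0, spec.sigma_tail, 3)
                cand = Rotation.from_rotvec(rotvec).apply(base_tail - pivot) + pivot + shift
                dmin = np.sqrt(
                    ((cand[:, None, :] - core_x[None, :, :]) ** 2).sum(axis=2).min()
                )
                if dmin >= 2.5:
                    break
            x[tail_atoms] = cand
        x += rng.normal(0.0, spec.sigma_stem, (n_atoms, 3))
        if broken_atoms.size and f >= n_contact_frames:
            x[broken_atoms] += np.array([0.0, 8.0, 0.0])
        frames[f] = x
    times = np.arange(spec.n_frames) * spec.dt_ns
    return Trajectory(coordinates=frames, times=times)


def simulate_boosted_cv(
    k: float,
    x0: float,
    a: float,
    x1: float,
    n: int,
    temperature: float = 300.0,
    seed: int = 0,
):
    """Boosted samples of a quadratic landscape with analytic ground truth.

    Draws x from the density ∝ exp(-β[U(x) + ΔV(x)]) with
    U = ½k(x-x0)² and the non-negative boost ΔV = a(x-x1)²; the sum is a
    Gaussian with mean (k·x0 + 2a·x1)/(k + 2a) and variance kT/(k + 2a).
    Returns (cv series, BoostSeries, analytic U callable).
    """
    if k + 2.0 * a <= 0:
        raise ValueError("k + 2a must be positive for an integrable landscape")
    if a < 0:
        raise ValueError("boost curvature must be non-negative")
    kt = KB * temperature
    mean = (k * x0 + 2.0 * a * x1) / (k + 2.0 * a)
    var = kt / (k + 2.0 * a)
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, np.sqrt(var), n)
    boost = BoostSeries(delta_v=a * (x - x1) ** 2, temperature=temperature)
    return x, boost, (lambda xx: 0.5 * k * (np.asarray(xx) - x0) ** 2)


def write_fixture_bundle(
    system: HairpinSystem, traj: Trajectory, out_dir, stem: str = "fixture"
) -> dict:
    """Write PDB + topology + JSON ground-truth sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = write_pdb_models(system.topology, traj, out_dir / f"{stem}.pdb")
    top = write_topology(system.topology, out_dir / f"{stem}.top")
    gt = dict(system.ground_truth)
    gt["sequence"] = system.sequence.residues
    gt["dot_bracket"] = system.secondary.dot_bracket
    gt_path = out_dir / f"{stem}_ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=2, sort_keys=True) + "\n")
    return {"pdb": str(pdb), "topology": str(top), "ground_truth": str(gt_path)}
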