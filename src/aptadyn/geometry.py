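"""Superposition, RMSD/RMSF profiles and contact annotation.

All fits are least-squares optimal rigid-body superpositions (Kabsch, via
SVD).  Segment RMSD profiles fit *on the segment* so that a rigid internal
motif shows a flat profile even when the molecule tumbles or hinges around
it.  Contact detection annotates hydrogen bonds, Watson–Crick base pairs
and base stacking, each with an abundance: the exact percentage of frames
in which the geometric criteria hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, GeometryError
from .io import AtomMask, Topology, Trajectory, select_atoms, BACKBONE_ATOM_NAMES

__all__ = [
    "SuperpositionResult",
    "ContactRecord",
    "ContactParams",
    "kabsch",
    "pair_rmsd",
    "superpose",
    "rmsd_profile",
    "rmsf",
    "detect_contacts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float  # Å


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise GeometryError(f"superposition needs >= 3 atoms, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("fit atoms are collinear")


def kabsch(mobile: np.ndarray, ref: np.ndarray) -> SuperpositionResult:
    """Optimal rotation + translation mapping ``mobile`` onto ``ref``.

    Returns the transform ``x' = x @ R.T + t`` together with the residual
    RMSD over the input points.
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    _check_fit_atoms(mobile)
    _check_fit_atoms(ref)
    cm, cr = mobile.mean(axis=0), ref.mean(axis=0)
    P, Q = mobile - cm, ref - cr
    C = P.T @ Q
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt  # row-vector convention: aligned = P @ R
    # residual computed explicitly: the singular-value shortcut loses ~8
    # digits to cancellation when the fit is near-perfect
    rmsd = float(np.sqrt(((P @ R - Q) ** 2).sum() / mobile.shape[0]))
    rot = R.T  # column-vector convention for the public result
    t = cr - cm @ R
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd)


def pair_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations under optimal superposition."""
    return kabsch(a, b).rmsd


def superpose(
    traj: Trajectory,
    ref_frame: int | np.ndarray,
    mask: np.ndarray | AtomMask | str,
    topology: Topology | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Superpose every frame onto a reference on the mask atoms.

    The optimal transform is computed on the mask but applied to all atoms.
    Returns the aligned trajectory and the per-frame RMSD series over the
    mask.
    """
    idx = _resolve_mask(mask, topology)
    ref = traj.frame(ref_frame) if isinstance(ref_frame, (int, np.integer)) else np.asarray(ref_frame, float)
    ref_sel = ref[idx]
    _check_fit_atoms(ref_sel)
    aligned = np.empty_like(traj.coordinates)
    series = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        res = kabsch(traj.coordinates[f][idx], ref_sel)
        aligned[f] = traj.coordinates[f] @ res.rotation.T + res.translation
        series[f] = res.rmsd
    return Trajectory(coordinates=aligned, times=traj.times.copy()), series


def _resolve_mask(mask, topology: Topology | None) -> np.ndarray:
    if isinstance(mask, (AtomMask, str)):
        if topology is None:
            raise ValueError("textual masks need a topology")
        return select_atoms(topology, mask)
    return np.asarray(mask, dtype=int)


def rmsd_profile(
    traj: Trajectory,
    ref_frame: int | np.ndarray,
    masks: list[AtomMask | str | np.ndarray],
    topology: Topology | None = None,
) -> dict[str, np.ndarray]:
    """Per-mask RMSD series with segment-local superposition.

    Each mask is fitted and measured on itself, which separates internal
    deformation of a segment from its overall motion — the global series and
    a segment series answer different questions.
    """
    out: dict[str, np.ndarray] = {}
    ref = traj.frame(ref_frame) if isinstance(ref_frame, (int, np.integer)) else np.asarray(ref_frame, float)
    for m, mask in enumerate(masks):
        idx = _resolve_mask(mask, topology)
        ref_sel = ref[idx]
        _check_fit_atoms(ref_sel)
        series = np.array(
            [kabsch(traj.coordinates[f][idx], ref_sel).rmsd for f in range(traj.n_frames)]
        )
        name = mask.expression if isinstance(mask, AtomMask) else (mask if isinstance(mask, str) else f"mask_{m}")
        out[name] = series
    return out


def rmsf(
    traj: Trajectory,
    topology: Topology,
    mask: AtomMask | str | np.ndarray = "heavy",
) -> dict[int, float]:
    """Per-residue RMSF (Å) about the mean structure.

    The trajectory is assumed pre-aligned on a stated core mask.  Each
    atom's root-mean-square fluctuation is computed about its time-averaged
    position and then averaged over the residue's mask atoms.
    """
    if traj.n_frames < 2:
        raise DegenerateInputError("RMSF needs at least 2 frames")
    idx = _resolve_mask(mask, topology)
    coords = traj.coordinates[:, idx, :]
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    out: dict[int, float] = {}
    residues = np.array([topology.atoms[k].residue_index for k in idx])
    for r in sorted(set(residues.tolist())):
        out[r] = float(per_atom[residues == r].mean())
    return out


def distance_fluctuation_score(traj: Trajectory, topology: Topology) -> dict[int, float]:
    """Alignment-free per-residue rigidity score (Å).

    For each residue pair the standard deviation of the C1'–C1' distance is
    computed over the trajectory; a residue's score is the median over its
    partners.  Residues embedded in a rigid core score low; residues that
    move relative to most of the molecule score high — and, unlike an
    RMSF after a global fit, the measure cannot be fooled by a floppy
    terminus that happens to dominate the superposition.
    """
    residues = topology.residue_indices
    anchors = []
    for r in residues:
        k = topology.index_of(r, "C1'")
        anchors.append(k if k is not None else int(topology.residue_atoms(r)[0]))
    pts = traj.coordinates[:, anchors, :]  # (frames, residues, 3)
    d = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=3)
    sd = d.std(axis=0)  # (residues, residues)
    out = {}
    n = len(residues)
    for a, r in enumerate(residues):
        others = np.delete(sd[a], a) if n > 1 else np.array([0.0])
        out[r] = float(np.median(others))
    return out


def align_on_rigid_core(
    traj: Trajectory,
    topology: Topology,
    fraction: float = 0.5,
) -> tuple[Trajectory, list[int], dict[int, float]]:
    """Align on the least-mobile residues and return per-residue RMSF.

    A single global fit lets a floppy terminus drag the rigid core during
    superposition and inflate its apparent fluctuation, so the fit residues
    are chosen first by the alignment-free distance-fluctuation score: the
    ``fraction`` most rigid residues form the core, the trajectory is
    superposed on their backbone, and the heavy-atom RMSF is reported for
    every residue.
    """
    score = distance_fluctuation_score(traj, topology)
    ranked = sorted(score, key=lambda r: score[r])
    n_core = max(int(np.ceil(fraction * len(ranked))), 3)
    core = sorted(ranked[:n_core])
    mask = "res " + ",".join(str(r) for r in core) + " backbone"
    aligned, _ = superpose(traj, 0, mask, topology)
    rmsf_map = rmsf(aligned, topology, "heavy")
    return aligned, core, rmsf_map


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

#: Base-edge hydrogen-bond donors/acceptors by base letter (heavy atoms).
HB_DONORS = {"A": ("N6",), "T": ("N3",), "G": ("N1", "N2"), "C": ("N4",)}
HB_ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "T": ("O2", "O4"),
    "G": ("O6", "N3", "N7"),
    "C": ("N3", "O2"),
}
#: Watson–Crick hydrogen-bond patterns: (donor base, donor atom, acceptor atom).
WC_PATTERNS = {
    frozenset(("G", "C")): [("G", "O6", "N4"), ("C", "N3", "N1"), ("G", "N2", "O2")],
    frozenset(("A", "T")): [("A", "N6", "O4"), ("T", "N3", "N1")],
}
RING_ATOM_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class ContactParams:
    """Geometric criteria for contact annotation.

    Hydrogen bonds use a donor–acceptor heavy-atom cutoff of 3.5 Å together
    with a D–H···A angle >= 135° when hydrogens are present, or a
    distance-only cutoff of 3.4 Å for heavy-atom-only inputs.  Stacking
    requires ring-centroid distance <= 4.5 Å, interplanar angle <= 30° and
    lateral centroid offset <= 2.5 Å.  Records below ``report_floor`` %
    abundance are omitted.
    """

    hbond_distance: float = 3.5  # Å, with explicit hydrogens
    hbond_angle: float = 135.0  # deg, D-H...A
    hbond_distance_heavy: float = 3.4  # Å, heavy-atom-only criterion
    stack_distance: float = 4.5  # Å centroid-centroid
    stack_angle: float = 30.0  # deg interplanar
    stack_offset: float = 2.5  # Å lateral
    min_separation: int = 2  # |i - j| below this is skipped for H-bonds
    report_floor: float = 5.0  # % abundance


@dataclass
class ContactRecord:
    kind: str  # hbond | basepair | stack
    i: int
    j: int
    atoms: str
    mean_distance: float  # Å over satisfying frames
    mean_angle: float  # deg (0 when not applicable)
    abundance: float  # % of frames
    canonical: bool = True
    per_frame: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "i": self.i,
            "j": self.j,
            "atoms": self.atoms,
            "mean_distance": self.mean_distance,
            "mean_angle": self.mean_angle,
            "abundance": self.abundance,
            "canonical": self.canonical,
        }


def _residue_atom_map(topology: Topology) -> dict[int, dict[str, int]]:
    out: dict[int, dict[str, int]] = {}
    for k, a in enumerate(topology.atoms):
        out.setdefault(a.residue_index, {})[a.name] = k
    return out


def _hbond_candidates(topology: Topology, params: ContactParams):
    """Yield (i, j, donor_idx, acceptor_idx, label) over residue pairs."""
    amap = _residue_atom_map(topology)
    residues = topology.residue_indices
    for a_pos, ri in enumerate(residues):
        for rj in residues[a_pos + 1:]:
            if rj - ri < params.min_separation:
                continue
            bi, bj = topology.residue_base(ri), topology.residue_base(rj)
            seen = set()
            for (rd, rb, ra_, ab) in (
                (ri, bi, rj, bj),  # donor in ri
                (rj, bj, ri, bi),  # donor in rj
            ):
                for dn in HB_DONORS.get(rb, ()):
                    d_idx = amap.get(rd, {}).get(dn)
                    if d_idx is None:
                        continue
                    for an in HB_ACCEPTORS.get(ab, ()):
                        a_idx = amap.get(ra_, {}).get(an)
                        if a_idx is None:
                            continue
                        key = frozenset((d_idx, a_idx))
                        if key in seen:
                            continue
                        seen.add(key)
                        if rd == ri:
                            label = f"{dn}-{an}"
                        else:
                            label = f"{an}-{dn}"
                        yield ri, rj, d_idx, a_idx, label


def _donor_hydrogen(topology: Topology, donor_idx: int) -> int | None:
    adj = topology.bonded_adjacency()
    for nb in adj[donor_idx]:
        if topology.atoms[nb].element == "H":
            return nb
    return None


def detect_contacts(
    traj: Trajectory,
    topology: Topology,
    kind: str = "hbond",
    params: ContactParams | None = None,
) -> list[ContactRecord]:
    """Annotate contacts of one kind over a trajectory.

    ``kind``: ``hbond`` (per donor/acceptor atom pair), ``basepair``
    (residue-pair records where all Watson–Crick bonds of the complementary
    pattern co-occur; incomplete or noncomplementary patterns with >= 2
    bonds are reported as noncanonical), or ``stack`` (ring geometry of
    residue pairs).  Abundance is an exact frame count in percent.
    """
    if params is None:
        params = ContactParams()
    if kind == "hbond":
        return _detect_hbonds(traj, topology, params)
    if kind == "basepair":
        return _detect_basepairs(traj, topology, params)
    if kind == "stack":
        return _detect_stacks(traj, topology, params)
    raise ValueError(f"unknown contact kind {kind!r}")


def _detect_hbonds(traj, topology, params, keep_all=False) -> list[ContactRecord]:
    coords = traj.coordinates
    n_frames = traj.n_frames
    records = []
    have_h = any(a.element == "H" for a in topology.atoms)
    for ri, rj, d_idx, a_idx, label in _hbond_candidates(topology, params):
        vec = coords[:, d_idx, :] - coords[:, a_idx, :]
        dist = np.linalg.norm(vec, axis=1)
        h_idx = _donor_hydrogen(topology, d_idx) if have_h else None
        if h_idx is not None:
            dh = coords[:, d_idx, :] - coords[:, h_idx, :]
            ah = coords[:, a_idx, :] - coords[:, h_idx, :]
            cosang = (dh * ah).sum(axis=1) / (
                np.linalg.norm(dh, axis=1) * np.linalg.norm(ah, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok = (dist <= params.hbond_distance) & (ang >= params.hbond_angle)
            mean_angle = float(ang[ok].mean()) if ok.any() else 0.0
        else:
            ok = dist <= params.hbond_distance_heavy
            mean_angle = 0.0
        abundance = 100.0 * int(ok.sum()) / n_frames
        if abundance <= 0.0 or (abundance < params.report_floor and not keep_all):
            continue
        records.append(
            ContactRecord(
                kind="hbond",
                i=ri,
                j=rj,
                atoms=label,
                mean_distance=float(dist[ok].mean()),
                mean_angle=mean_angle,
                abundance=abundance,
                canonical=_COMPLEMENT.get(topology.residue_base(ri))
                == topology.residue_base(rj),
                per_frame=ok,
            )
        )
    return records


def _detect_basepairs(traj, topology, params) -> list[ContactRecord]:
    hbonds = _detect_hbonds(traj, topology, params, keep_all=True)
    by_pair: dict[tuple[int, int], list[ContactRecord]] = {}
    for rec in hbonds:
        by_pair.setdefault((rec.i, rec.j), []).append(rec)
    records = []
    n_frames = traj.n_frames
    for (ri, rj), members in sorted(by_pair.items()):
        bi, bj = topology.residue_base(ri), topology.residue_base(rj)
        pattern = WC_PATTERNS.get(frozenset((bi, bj))) if bi != bj else None
        complementary = _COMPLEMENT.get(bi) == bj
        if complementary and pattern is not None:
            wanted = set()
            for donor_base, dn, an in pattern:
                if donor_base == bi:
                    wanted.add(f"{dn}-{an}")
                else:
                    wanted.add(f"{an}-{dn}")
            present = {m.atoms: m for m in members}
            canonical = wanted <= set(present)
            used = [present[w] for w in sorted(wanted) if w in present]
        else:
            canonical = False
            used = members
        if not used or (not canonical and len(used) < 2):
            continue
        joint = np.ones(n_frames, dtype=bool)
        for m in used:
            joint &= m.per_frame
        abundance = 100.0 * int(joint.sum()) / n_frames
        if abundance < params.report_floor:
            continue
        records.append(
            ContactRecord(
                kind="basepair",
                i=ri,
                j=rj,
                atoms="+".join(m.atoms for m in used),
                mean_distance=float(np.mean([m.mean_distance for m in used])),
                mean_angle=0.0,
                abundance=abundance,
                canonical=canonical,
                per_frame=joint,
            )
        )
    return records


def _ring_indices(topology: Topology) -> dict[int, np.ndarray]:
    amap = _residue_atom_map(topology)
    out = {}
    for r, names in amap.items():
        idx = [names[n] for n in RING_ATOM_NAMES if n in names and n not in BACKBONE_ATOM_NAMES]
        if len(idx) >= 3:
            out[r] = np.array(idx, dtype=int)
        else:
            logger.warning("residue %d lacks base-ring atoms; skipped for stacking", r)
    return out


def _detect_stacks(traj, topology, params) -> list[ContactRecord]:
    rings = _ring_indices(topology)
    residues = [r for r in topology.residue_indices if r in rings]
    coords = traj.coordinates
    n_frames = traj.n_frames
    # per-residue centroids and normals for every frame
    centroids: dict[int, np.ndarray] = {}
    normals: dict[int, np.ndarray] = {}
    for r in residues:
        ring = coords[:, rings[r], :]
        c = ring.mean(axis=1)
        centered = ring - c[:, None, :]
        # plane normal = singular vector of the smallest singular value
        _, _, vt = np.linalg.svd(centered)
        normals[r] = vt[:, 2, :]
        centroids[r] = c
    records = []
    for a_pos, ri in enumerate(residues):
        for rj in residues[a_pos + 1:]:
            d = centroids[rj] - centroids[ri]
            dist = np.linalg.norm(d, axis=1)
            cosang = np.abs((normals[ri] * normals[rj]).sum(axis=1))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            # lateral offset w.r.t. the first ring's normal
            vertical = np.abs((d * normals[ri]).sum(axis=1))
            lateral = np.sqrt(np.maximum(dist**2 - vertical**2, 0.0))
            ok = (
                (dist <= params.stack_distance)
                & (ang <= params.stack_angle)
                & (lateral <= params.stack_offset)
            )
            abundance = 100.0 * int(ok.sum()) / n_frames
            if abundance < params.report_floor or abundance <= 0:
                continue
            records.append(
                ContactRecord(
                    kind="stack",
                    i=ri,
                    j=rj,
                    atoms="ring-ring",
                    mean_distance=float(dist[ok].mean()),
                    mean_angle=float(ang[ok].mean()),
                    abundance=abundance,
                    canonical=True,
                    per_frame=ok,
                )
            )
    return records
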