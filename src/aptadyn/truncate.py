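"""Truncation proposals and spacer-effect comparison.

The evidence model is deliberately simple and auditable: a residue is
*essential* when it participates in (or partners into) a sufficiently
abundant polar contact, and *mobile* according to a normalized combination
of its RMSF and its displacement across cluster representatives.  Only
terminal segments are ever proposed for removal — the successful
truncations this strategy is modeled on all trim an end while preserving
the structured core, and internal excision can silently re-fold what
remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .cluster import ClusterSet
from .geometry import ContactRecord, kabsch
from .io import Topology, Trajectory

__all__ = [
    "TruncationReport",
    "SpacerComparison",
    "mobility_profile",
    "intercluster_displacement",
    "essentiality_map",
    "propose_truncations",
    "compare_variants",
]

#: Ranges smaller than this (Å) are treated as insignificant when profiles
#: are rescaled to [0, 1], so a uniformly rigid molecule does not have its
#: noise amplified into fake mobility.
NORMALIZATION_FLOOR = 2.0


@dataclass
class TruncationReport:
    variant: str
    n_residues: int
    mobility: np.ndarray  # per residue, 0-1
    essential: np.ndarray  # per residue, bool
    kept: list[tuple[int, int]]  # inclusive residue intervals
    removed: list[dict]  # {"start", "end", "end_label", "rationale"}
    reason: str = ""  # set when no proposal could be made

    @property
    def n_removed(self) -> int:
        return sum(seg["end"] - seg["start"] + 1 for seg in self.removed)

    def removed_residues(self) -> set[int]:
        out: set[int] = set()
        for seg in self.removed:
            out |= set(range(seg["start"], seg["end"] + 1))
        return out

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_residues": self.n_residues,
            "mobility": [round(float(v), 12) for v in self.mobility],
            "essential": [bool(v) for v in self.essential],
            "kept": [list(iv) for iv in self.kept],
            "removed": self.removed,
            "reason": self.reason,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _normalize(values: np.ndarray, floor: float) -> np.ndarray:
    values = np.asarray(values, float)
    spread = values.max() - values.min()
    if spread == 0.0:
        return np.full_like(values, 0.5)
    return (values - values.min()) / max(spread, floor)


def mobility_profile(
    rmsf_per_residue: np.ndarray,
    intercluster: np.ndarray | None = None,
    floor: float = NORMALIZATION_FLOOR,
    weights: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Per-residue mobility score in [0, 1].

    Equal-weight mean of the normalized RMSF and (when available) the
    normalized inter-cluster displacement.  Each component is min-shifted
    and divided by ``max(range, floor)``: an exactly constant profile maps
    to 0.5 everywhere (no information), while a small-range profile stays
    near zero instead of being stretched to full scale.
    """
    comp = [_normalize(np.asarray(rmsf_per_residue, float), floor)]
    w = [weights[0]]
    if intercluster is not None:
        inter = np.asarray(intercluster, float)
        if inter.shape != comp[0].shape:
            raise ValueError("rmsf and inter-cluster profiles differ in length")
        comp.append(_normalize(inter, floor))
        w.append(weights[1])
    w_arr = np.asarray(w) / np.sum(w)
    return np.clip(sum(wi * ci for wi, ci in zip(w_arr, comp)), 0.0, 1.0)


def intercluster_displacement(
    traj: Trajectory,
    topology: Topology,
    clusterset: ClusterSet,
    fit_mask: np.ndarray | str = "backbone",
    measure_mask: np.ndarray | str = "heavy",
) -> np.ndarray:
    """Per-residue spread (Å) across cluster representative structures.

    Representatives are superposed onto the top cluster's representative on
    ``fit_mask`` (pass the rigid core so a floppy terminus cannot smear the
    fit); the per-atom standard deviation across representatives is then
    averaged within each residue over ``measure_mask``.  A single cluster
    yields zeros.
    """
    from .geometry import _resolve_mask

    fit_idx = _resolve_mask(fit_mask, topology)
    meas_idx = _resolve_mask(measure_mask, topology)
    reps = [clusterset.representatives[c] for c in sorted(clusterset.representatives)]
    residues = topology.residue_indices
    if len(reps) < 2:
        return np.zeros(len(residues))
    ref = traj.coordinates[reps[0]]
    stackd = [ref[meas_idx]]
    for r in reps[1:]:
        res = kabsch(traj.coordinates[r][fit_idx], ref[fit_idx])
        moved = traj.coordinates[r] @ res.rotation.T + res.translation
        stackd.append(moved[meas_idx])
    arr = np.stack(stackd)  # (reps, atoms, 3)
    per_atom = np.sqrt(((arr - arr.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0))
    res_of = np.array([topology.atoms[k].residue_index for k in meas_idx])
    return np.array(
        [per_atom[res_of == r].mean() if (res_of == r).any() else 0.0 for r in residues]
    )


def essentiality_map(
    contacts: list[ContactRecord],
    n_residues: int,
    abundance_threshold: float = 50.0,
    include_stacking: bool = False,
) -> np.ndarray:
    """Boolean flags (index 0 → residue 1): residue takes part in, or
    partners into, a sufficiently abundant polar contact.

    Stacking alone does not confer essentiality unless requested — a stack
    constrains geometry far less than a persistent hydrogen bond.
    """
    flags = np.zeros(n_residues, dtype=bool)
    for rec in contacts:
        if rec.kind == "stack" and not include_stacking:
            continue
        if rec.abundance < abundance_threshold:
            continue
        for r in (rec.i, rec.j):
            if 1 <= r <= n_residues:
                flags[r - 1] = True
    return flags


def propose_truncations(
    mobility: np.ndarray,
    essential: np.ndarray,
    min_length: int = 15,
    mobility_cut: float = 0.5,
    max_segments: int = 2,
    variant: str = "truncated",
) -> TruncationReport:
    """Rank terminal removals supported by the mobility/essentiality evidence.

    For each end, the candidate is the largest terminal run of
    non-essential residues whose mean mobility clears ``mobility_cut``;
    proposals are ranked by removed length, internal residues are never
    touched, and the kept region keeps at least ``min_length`` residues.
    """
    mobility = np.asarray(mobility, float)
    essential = np.asarray(essential, bool)
    if mobility.shape != essential.shape:
        raise ValueError("mobility and essentiality profiles differ in length")
    n = mobility.size

    def candidate(end: str) -> dict | None:
        if end == "5p":
            run = 0
            while run < n and not essential[run]:
                run += 1
            values = mobility[:run]
        else:
            run = 0
            while run < n and not essential[n - 1 - run]:
                run += 1
            values = mobility[n - run:]
        for k in range(run, 0, -1):
            seg = values[:k] if end == "5p" else values[-k:]
            if seg.mean() >= mobility_cut:
                if end == "5p":
                    return {"start": 1, "end": k, "end_label": "5p",
                            "rationale": f"non-essential 5' run of {k} nt, "
                                         f"mean mobility {seg.mean():.2f} >= {mobility_cut}"}
                return {"start": n - k + 1, "end": n, "end_label": "3p",
                        "rationale": f"non-essential 3' run of {k} nt, "
                                     f"mean mobility {seg.mean():.2f} >= {mobility_cut}"}
        return None

    proposals = [c for c in (candidate("5p"), candidate("3p")) if c is not None]
    proposals.sort(key=lambda s: -(s["end"] - s["start"] + 1))
    proposals = proposals[:max_segments]

    # enforce the minimum kept length, trimming the lesser proposal first
    def kept_length(props):
        return n - sum(p["end"] - p["start"] + 1 for p in props)

    while proposals and kept_length(proposals) < min_length:
        deficit = min_length - kept_length(proposals)
        last = proposals[-1]
        length = last["end"] - last["start"] + 1
        if length <= deficit:
            proposals.pop()
            continue
        if last["end_label"] == "5p":
            last["end"] -= deficit
        else:
            last["start"] += deficit
        last["rationale"] += f" (trimmed to respect min kept length {min_length})"

    if not proposals:
        reason = (
            "no non-essential terminal segment"
            if essential[0] and essential[-1]
            else "terminal segments do not clear the mobility cutoff"
        )
        return TruncationReport(
            variant=variant, n_residues=n, mobility=mobility,
            essential=essential, kept=[(1, n)], removed=[], reason=reason,
        )

    removed = sorted(proposals, key=lambda s: s["start"])
    start_keep = 1
    end_keep = n
    for seg in removed:
        if seg["end_label"] == "5p":
            start_keep = seg["end"] + 1
        else:
            end_keep = seg["start"] - 1
    report = TruncationReport(
        variant=variant, n_residues=n, mobility=mobility, essential=essential,
        kept=[(start_keep, end_keep)],
        removed=sorted(proposals, key=lambda s: -(s["end"] - s["start"] + 1)),
    )
    # soundness: a removal must never contain an essential residue
    assert not any(essential[r - 1] for r in report.removed_residues())
    return report


@dataclass
class SpacerComparison:
    classification: str  # "inert spacer" | "structure-altering"
    spacer_core_pairs: list[tuple[int, int]]  # in variant-B numbering
    gained: list[dict] = field(default_factory=list)  # core contacts new in B
    lost: list[dict] = field(default_factory=list)  # core contacts absent in B

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "spacer_core_pairs": [list(p) for p in self.spacer_core_pairs],
            "gained": self.gained,
            "lost": self.lost,
        }


def compare_variants(
    report_a: TruncationReport,
    contacts_a: list[ContactRecord],
    report_b: TruncationReport,
    contacts_b: list[ContactRecord],
    spacer_end: str = "5p",
    abundance_threshold: float = 50.0,
) -> SpacerComparison:
    """Spacer-effect summary for variant B = variant A + terminal spacer.

    Core residues of B are index-aligned onto A; the comparison reports
    core contacts gained/lost and flags a *structure-altering* spacer when
    any spacer residue acquires a high-abundance base-pair contact with a
    core residue — the signature of a spacer folding into the stem instead
    of dangling free.
    """
    la, lb = report_a.n_residues, report_b.n_residues
    spacer_len = lb - la
    if spacer_len < 0:
        raise AlignmentError("variant B must be variant A plus a terminal spacer")
    if spacer_end == "5p":
        spacer = set(range(1, spacer_len + 1))
        to_a = lambda r: r - spacer_len
    elif spacer_end == "3p":
        spacer = set(range(la + 1, lb + 1))
        to_a = lambda r: r
    else:
        raise ValueError("spacer_end must be '5p' or '3p'")

    def key(rec: ContactRecord, mapped: bool) -> tuple:
        i, j = (to_a(rec.i), to_a(rec.j)) if mapped else (rec.i, rec.j)
        return (rec.kind, min(i, j), max(i, j), rec.atoms)

    core_b = {
        key(r, True): r
        for r in contacts_b
        if r.i not in spacer and r.j not in spacer and r.abundance >= abundance_threshold
    }
    core_a = {
        key(r, False): r for r in contacts_a if r.abundance >= abundance_threshold
    }
    gained = [core_b[k].to_dict() for k in sorted(set(core_b) - set(core_a))]
    lost = [core_a[k].to_dict() for k in sorted(set(core_a) - set(core_b))]

    spacer_pairs = sorted(
        {
            (rec.i, rec.j)
            for rec in contacts_b
            if rec.kind in ("basepair", "hbond")
            and rec.abundance >= abundance_threshold
            and ((rec.i in spacer) != (rec.j in spacer))
        }
    )
    classification = "structure-altering" if spacer_pairs else "inert spacer"
    return SpacerComparison(
        classification=classification,
        spacer_core_pairs=spacer_pairs,
        gained=gained,
        lost=lost,
    )
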