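"""Input/output layer: sequences, topologies, trajectories, masks, reports.

Conventions used throughout the package
---------------------------------------
* coordinates in Å, times in ns, energies in kcal/mol,
* residues numbered 1-based along the strand, 5'→3',
* atom indices used by masks and geometry code are 0-based positions into
  ``Topology.atoms`` (the ``atom_id`` field is a stable identifier and need
  not be contiguous).

The topology file format is a small plain-text dialect of our own with
``[sequence]``, ``[atoms]`` and ``[bonds]`` sections (see
:func:`read_topology`); multi-model PDB files are read and written through
:mod:`biotite`.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    SelectionError,
    TopologyValidationError,
)

__all__ = [
    "Sequence",
    "Atom",
    "Topology",
    "Trajectory",
    "AtomMask",
    "BACKBONE_ATOM_NAMES",
    "read_pdb_models",
    "write_pdb_models",
    "read_topology",
    "write_topology",
    "select_atoms",
    "write_report",
    "read_report",
]

_VALID_BASES = set("ACGT")

#: Heavy/H-inclusive atom names belonging to the sugar-phosphate backbone of
#: a deoxyribonucleotide.  "backbone" masks select the heavy subset of these.
BACKBONE_ATOM_NAMES = frozenset(
    {
        "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
        "C2'", "C1'", "HO5'", "HO3'",
    }
)


@dataclass(frozen=True)
class Sequence:
    """A single-stranded DNA sequence, 1-based, 5'→3'."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise EmptyInputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-DNA letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, residue_index: int) -> str:
        """Base letter at a 1-based residue index."""
        return self.residues[residue_index - 1]


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    residue_index: int
    charge: float  # e
    lj_sigma: float  # Å
    lj_epsilon: float  # kcal/mol
    gb_radius: float  # Å
    gb_screen: float  # unitless HCT screening factor


@dataclass
class Topology:
    """Solute description: atoms with nonbonded parameters, bonds, residues."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]]  # pairs of atom_ids
    residue_bases: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not self.atoms:
            raise EmptyInputError("topology has no atoms")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TopologyValidationError(f"duplicate atom_ids: {dupes}")
        known = set(ids)
        for i, j in self.bonds:
            if i not in known or j not in known:
                raise TopologyValidationError(f"bond ({i},{j}) references unknown atom")
        bad = [a.atom_id for a in self.atoms if not math.isfinite(a.charge)]
        if bad:
            raise TopologyValidationError(f"non-finite charge on atoms {bad}")
        bad = [a.atom_id for a in self.atoms if not (a.gb_radius > 0)]
        if bad:
            raise TopologyValidationError(f"missing/nonpositive GB radius on atoms {bad}")

    # -- derived views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        """0-based atom positions belonging to one residue."""
        return np.array(
            [k for k, a in enumerate(self.atoms) if a.residue_index == residue_index],
            dtype=int,
        )

    def residue_base(self, residue_index: int) -> str:
        return self.residue_bases.get(residue_index, "N")

    def index_of(self, residue_index: int, name: str) -> int | None:
        for k, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return k
        return None

    def id_to_index(self) -> dict[int, int]:
        return {a.atom_id: k for k, a in enumerate(self.atoms)}

    def bonded_adjacency(self) -> dict[int, set[int]]:
        """0-based adjacency sets from the bond list."""
        idx = self.id_to_index()
        adj: dict[int, set[int]] = {k: set() for k in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[idx[i]].add(idx[j])
            adj[idx[j]].add(idx[i])
        return adj


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) with per-frame times (ns)."""

    coordinates: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] == 0:
            raise EmptyInputError("trajectory has zero frames")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("trajectory contains non-finite coordinates")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise FormatError("times length must equal frame count")
            if np.any(np.diff(self.times) < 0):
                raise FormatError("times must be nondecreasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]


# ---------------------------------------------------------------------------
# Atom masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomMask:
    """Textual atom selection.

    Grammar (whitespace-separated tokens, all constraints intersected):

    * ``all`` — every atom (default when no class token given),
    * ``heavy`` — exclude hydrogens,
    * ``backbone`` — sugar+phosphate heavy atoms only,
    * ``base`` — heavy atoms not in the backbone,
    * ``res A-B[,C-D,...]`` — 1-based residue ranges (``res 7`` also allowed),
    * ``names N1,O6,...`` — explicit atom-name list.

    Example: ``"res 1-20 backbone"`` selects the backbone heavy atoms of
    residues 1–20.
    """

    expression: str

    def resolve(self, topology: Topology) -> np.ndarray:
        return select_atoms(topology, self)


def _parse_ranges(token: str) -> list[tuple[int, int]]:
    ranges = []
    for part in token.split(","):
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", part.strip())
        if not m:
            raise SelectionError(f"bad residue range {part!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise SelectionError(f"inverted residue range {part!r}")
        ranges.append((lo, hi))
    return ranges


def select_atoms(topology: Topology, mask: AtomMask | str) -> np.ndarray:
    """Resolve a mask to sorted, duplicate-free 0-based atom indices."""
    expr = mask.expression if isinstance(mask, AtomMask) else mask
    tokens = expr.split()
    if not tokens:
        raise SelectionError("empty mask expression")

    residues: set[int] | None = None
    names: set[str] | None = None
    klass = "all"
    it = iter(tokens)
    for tok in it:
        low = tok.lower()
        if low in ("all", "heavy", "backbone", "base"):
            klass = low
        elif low == "res":
            try:
                arg = next(it)
            except StopIteration:
                raise SelectionError("'res' requires a range argument") from None
            residues = set()
            avail = set(topology.residue_indices)
            for lo, hi in _parse_ranges(arg):
                span = set(range(lo, hi + 1))
                if not span & avail:
                    raise SelectionError(f"residue range {lo}-{hi} not in topology")
                residues |= span
        elif low == "names":
            try:
                arg = next(it)
            except StopIteration:
                raise SelectionError("'names' requires a name list") from None
            names = {n.strip() for n in arg.split(",") if n.strip()}
        else:
            raise SelectionError(f"unknown mask token {tok!r}")

    out = []
    for k, a in enumerate(topology.atoms):
        if residues is not None and a.residue_index not in residues:
            continue
        if names is not None and a.name not in names:
            continue
        if klass == "heavy" and a.element == "H":
            continue
        if klass == "backbone" and (a.element == "H" or a.name not in BACKBONE_ATOM_NAMES):
            continue
        if klass == "base" and (a.element == "H" or a.name in BACKBONE_ATOM_NAMES):
            continue
        out.append(k)
    if not out:
        raise SelectionError(f"mask {expr!r} selects no atoms")
    return np.array(sorted(out), dtype=int)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

_RES_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "N": "UNK"}
_BASE_FROM_RES = {v: k for k, v in _RES_NAME.items()}


def _prescan_models(path: Path) -> None:
    """Raise a FormatError naming the offending MODEL on atom-count mismatch."""
    counts: list[int] = []
    model_ids: list[int] = []
    current: int | None = None
    in_model = False
    loose = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                model_ids.append(int(line.split()[1]) if len(line.split()) > 1 else len(counts) + 1)
                current = 0
            elif rec == "ENDMDL":
                counts.append(current or 0)
                in_model = False
                current = None
            elif rec in ("ATOM", "HETATM"):
                if in_model:
                    current = (current or 0) + 1
                else:
                    loose += 1
    if current is not None:  # MODEL without ENDMDL
        counts.append(current)
    if counts and len(set(counts)) > 1:
        ref = counts[0]
        for mid, c in zip(model_ids, counts):
            if c != ref:
                raise FormatError(
                    f"MODEL {mid} has {c} atoms but MODEL {model_ids[0]} has {ref}"
                )
    if not counts and loose == 0:
        raise EmptyInputError(f"no models / atom records in {path}")


def read_pdb_models(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a multi-model PDB into a topology-lite and a trajectory.

    One frame per MODEL record (a plain single-structure file yields one
    frame).  The returned topology carries names/elements/residues but dummy
    energy parameters — pair it with :func:`read_topology` output for scoring.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_models(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite InvalidFileError
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise EmptyInputError(f"no models / atom records in {path}")

    atoms: list[Atom] = []
    residue_bases: dict[int, str] = {}
    for k in range(stack.array_length()):
        name = stack.atom_name[k]
        element = stack.element[k] or _infer_element(name)
        res_idx = int(stack.res_id[k])
        atoms.append(
            Atom(
                atom_id=k + 1,
                name=name,
                element=element,
                residue_index=res_idx,
                charge=0.0,
                lj_sigma=0.0,
                lj_epsilon=0.0,
                gb_radius=1.5,  # placeholder; real radii come from the topology file
                gb_screen=0.8,
            )
        )
        residue_bases.setdefault(res_idx, _BASE_FROM_RES.get(stack.res_name[k], "N"))
    topo = Topology(atoms=atoms, bonds=[], residue_bases=residue_bases)
    traj = Trajectory(coordinates=np.asarray(stack.coord, dtype=float))
    return topo, traj


def _infer_element(name: str) -> str:
    stripped = name.strip("0123456789'\"*")
    if not stripped:
        return "X"
    if stripped[0] in "HCNOPS":
        return stripped[0]
    return stripped[:1].upper()


def write_pdb_models(
    topology: Topology, traj: Trajectory, path: str | Path
) -> Path:
    """Write a trajectory as a multi-model PDB (coordinates at 1e-3 Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_atoms
    if traj.n_atoms != n:
        raise FormatError("trajectory/topology atom counts differ")
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coordinates[f]
        arr.chain_id = np.full(n, "A")
        arr.res_id = np.array([a.residue_index for a in topology.atoms])
        arr.res_name = np.array(
            [_RES_NAME.get(topology.residue_base(a.residue_index), "UNK")
             for a in topology.atoms]
        )
        arr.atom_name = np.array([a.name for a in topology.atoms])
        arr.element = np.array([a.element for a in topology.atoms])
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    path = Path(path)
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Topology dialect
# ---------------------------------------------------------------------------

_ATOM_COLUMNS = (
    "atom_id name element residue charge lj_sigma lj_epsilon gb_radius gb_screen"
).split()


def read_topology(path: str | Path) -> Topology:
    """Parse the plain-text topology dialect.

    Format::

        [sequence]
        1 G
        2 C
        ...
        [atoms]
        # atom_id name element residue charge lj_sigma lj_epsilon gb_radius gb_screen
        1 P P 1 1.1662 3.74 0.20 1.85 0.86
        ...
        [bonds]
        1 2
        ...

    Missing charge or GB radius raises a validation error listing the
    offending atom ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"topology file {path} is empty")

    section = None
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    residue_bases: dict[int, str] = {}
    missing: list[int] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        cols = line.split()
        if section == "sequence":
            if len(cols) != 2:
                raise FormatError(f"{path}:{ln}: sequence lines are 'index base'")
            residue_bases[int(cols[0])] = cols[1].upper()
        elif section == "atoms":
            if len(cols) != len(_ATOM_COLUMNS):
                raise FormatError(
                    f"{path}:{ln}: expected {len(_ATOM_COLUMNS)} columns "
                    f"({' '.join(_ATOM_COLUMNS)}), got {len(cols)}"
                )
            aid = int(cols[0])
            vals = {}
            for key, col in zip(_ATOM_COLUMNS[4:], cols[4:]):
                vals[key] = math.nan if col.lower() in ("nan", "na", "-") else float(col)
            if math.isnan(vals["charge"]) or math.isnan(vals["gb_radius"]):
                missing.append(aid)
                continue
            atoms.append(
                Atom(
                    atom_id=aid,
                    name=cols[1],
                    element=cols[2],
                    residue_index=int(cols[3]),
                    charge=vals["charge"],
                    lj_sigma=vals["lj_sigma"],
                    lj_epsilon=vals["lj_epsilon"],
                    gb_radius=vals["gb_radius"],
                    gb_screen=vals["gb_screen"],
                )
            )
        elif section == "bonds":
            if len(cols) != 2:
                raise FormatError(f"{path}:{ln}: bond lines are 'i j'")
            bonds.append((int(cols[0]), int(cols[1])))
        else:
            raise FormatError(f"{path}:{ln}: data outside any [section]")
    if missing:
        raise TopologyValidationError(
            f"atoms missing charge or GB radius: {sorted(missing)}"
        )
    if not atoms:
        raise EmptyInputError(f"topology file {path} defines no atoms")
    return Topology(atoms=atoms, bonds=bonds, residue_bases=residue_bases)


def write_topology(topology: Topology, path: str | Path) -> Path:
    path = Path(path)
    lines = ["[sequence]"]
    for r in topology.residue_indices:
        lines.append(f"{r} {topology.residue_base(r)}")
    lines.append("[atoms]")
    lines.append("# " + " ".join(_ATOM_COLUMNS))
    for a in topology.atoms:
        lines.append(
            f"{a.atom_id} {a.name} {a.element} {a.residue_index} "
            f"{a.charge:.6f} {a.lj_sigma:.6f} {a.lj_epsilon:.6f} "
            f"{a.gb_radius:.6f} {a.gb_screen:.6f}"
        )
    lines.append("[bonds]")
    for i, j in topology.bonds:
        lines.append(f"{i} {j}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(results, path: str | Path, format: str = "json") -> Path:
    """Serialize results (dataclasses / dicts / lists) to JSON or CSV.

    Numeric fields survive a round trip at full double precision (JSON uses
    repr; CSV uses 17 significant digits).
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(results), indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        rows = results if isinstance(results, (list, tuple)) else [results]
        df = pd.DataFrame([_to_jsonable(r) for r in rows])
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path):
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    return json.loads(path.read_text())
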