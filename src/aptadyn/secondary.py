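"""Secondary-structure parsing and nearest-neighbor free-energy scoring.

This module evaluates a *given* fold of a DNA strand with a standard
nearest-neighbor (NN) model: Watson–Crick stack increments plus
length-dependent hairpin/bulge/internal-loop penalties, a terminal A·T
correction and an entropic monovalent-salt term.  It deliberately does not
predict the minimum-free-energy fold — candidate structures come from an
external folding server (dot-bracket or CT files) and the job here is to
score and *rank* them consistently.

The bundled parameter table is a unified DNA NN set referenced to 37 °C and
1 M Na+; alternative tables with the same CSV layout can be loaded with
:func:`load_nn_parameters`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import (
    ParameterCoverageError,
    ParseError,
    StructureValidationError,
)
from .io import Sequence

__all__ = [
    "SecondaryStructure",
    "NNParameterSet",
    "load_nn_parameters",
    "parse_secondary",
    "evaluate_nn_energy",
    "rank_models",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Gas constant in kcal/(mol K) for loop-entropy extrapolation.
_R_KCAL = 0.0019872041
_T37 = 310.15


@dataclass
class SecondaryStructure:
    """A pseudoknot-free pairing of one strand.

    ``pairing`` maps 1-based residue index → partner index (symmetric);
    ``noncanonical`` lists pairs that are not A·T or G·C.
    """

    pairing: dict[int, int]
    dot_bracket: str
    source: str = "dotbracket"
    noncanonical: set[tuple[int, int]] = field(default_factory=set)

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted unique (i, j) pairs with i < j."""
        return sorted({(min(i, j), max(i, j)) for i, j in self.pairing.items()})

    def partner(self, i: int) -> int | None:
        return self.pairing.get(i)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs())


def _validate_structure(pairing: dict[int, int], sequence: Sequence) -> set[tuple[int, int]]:
    n = len(sequence)
    for i, j in pairing.items():
        if not (1 <= i <= n and 1 <= j <= n):
            raise StructureValidationError(f"pair ({i},{j}) outside sequence 1..{n}")
        if i == j:
            raise StructureValidationError(f"residue {i} paired with itself")
        if pairing.get(j) != i:
            raise StructureValidationError(f"pairing not symmetric at ({i},{j})")
    pairs = sorted({(min(i, j), max(i, j)) for i, j in pairing.items()})
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            i, j = pairs[a]
            k, l = pairs[b]
            if i < k < j < l:
                raise StructureValidationError(
                    f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross"
                )
    noncanonical = set()
    for i, j in pairs:
        if _COMPLEMENT[sequence.base(i)] != sequence.base(j):
            noncanonical.add((i, j))
            logger.warning(
                "noncanonical pair %s%d-%s%d accepted (contributes no stack energy)",
                sequence.base(i), i, sequence.base(j), j,
            )
    return noncanonical


def parse_secondary(
    text: str, format: str = "dotbracket", sequence: Sequence | None = None
) -> SecondaryStructure:
    """Parse dot-bracket or mfold-style CT text into a SecondaryStructure.

    CT dialect: optional header line, then six whitespace-separated columns
    per residue with the pairing partner in column 5 (0 = unpaired).
    """
    if format == "dotbracket":
        db = text.strip()
        if sequence is not None and len(db) != len(sequence):
            raise ParseError(
                f"dot-bracket length {len(db)} != sequence length {len(sequence)}"
            )
        pairing: dict[int, int] = {}
        stack: list[int] = []
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ParseError(f"unbalanced ')' at position {pos}")
                i = stack.pop()
                pairing[i] = pos
                pairing[pos] = i
            elif ch != ".":
                raise ParseError(f"unexpected character {ch!r} at position {pos}")
        if stack:
            raise ParseError(f"unbalanced '(' at position {stack[-1]}")
        src = "dotbracket"
    elif format == "ct":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ParseError("empty CT input")
        first = lines[0].split()
        try:
            n_declared = int(first[0])
            body = lines[1:]
        except ValueError:
            n_declared = None
            body = lines
        pairing = {}
        seen = set()
        for ln in body:
            cols = ln.split()
            if len(cols) < 6:
                raise ParseError(f"CT line has {len(cols)} columns, expected >= 6")
            idx, partner = int(cols[0]), int(cols[4])
            seen.add(idx)
            if partner:
                if idx in pairing and pairing[idx] != partner:
                    raise StructureValidationError(f"conflicting partners for residue {idx}")
                pairing[idx] = partner
        if n_declared is not None and len(seen) != n_declared:
            raise ParseError(f"CT declares {n_declared} residues, found {len(seen)}")
        if sequence is not None and len(seen) != len(sequence):
            raise ParseError(
                f"CT has {len(seen)} residues, sequence has {len(sequence)}"
            )
        n = max(seen) if seen else 0
        db = "".join(
            "(" if i in pairing and pairing[i] > i
            else ")" if i in pairing else "."
            for i in range(1, n + 1)
        )
        src = "ct"
    else:
        raise ValueError(f"unknown secondary-structure format {format!r}")

    noncanonical = set()
    if sequence is not None:
        noncanonical = _validate_structure(pairing, sequence)
    else:
        # still check symmetry / nesting with a dummy complement-free pass
        for i, j in pairing.items():
            if pairing.get(j) != i:
                raise StructureValidationError(f"pairing not symmetric at ({i},{j})")
    return SecondaryStructure(
        pairing=pairing, dot_bracket=db, source=src, noncanonical=noncanonical
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class NNParameterSet:
    """Stack increments (ΔG°37/ΔH/ΔS), loop penalties and corrections.

    ``stacks`` is keyed by canonicalized ``5'XY3'/3'WZ5'`` motifs;
    ``loops[kind]`` maps loop size → ΔG°37 (kcal/mol, treated as entropic
    when rescaled to other temperatures).  ``na_molar`` applies a standard
    per-stack entropic salt correction of ``0.368·ln[Na+]`` cal/(mol K);
    the bundled reference state is 1 M (zero correction).
    """

    stacks: dict[str, tuple[float, float, float]]
    loops: dict[str, dict[int, float]]
    terminal_at: tuple[float, float, float]
    multiloop: tuple[float, float, float]  # (a, b per branch, c per unpaired nt)
    temperature: float = 310.15  # K
    na_molar: float = 1.0

    MIN_HAIRPIN = 3

    def __post_init__(self) -> None:
        for a in "ACGT":
            for b in "ACGT":
                self.stack_dg37(a + b)  # raises if any WC/WC step is uncovered
        for kind, table in self.loops.items():
            sizes = sorted(table)
            start = 2 if kind == "bulge" else sizes[0]
            prev = None
            for s in sizes:
                if s < start:
                    continue
                if prev is not None and table[s] < prev - 1e-9:
                    raise ParameterCoverageError(
                        f"{kind} loop penalty decreases at size {s}"
                    )
                prev = table[s]
        if min(self.loops["hairpin"]) > self.MIN_HAIRPIN:
            raise ParameterCoverageError("hairpin table must start at size 3")

    @staticmethod
    def canonical_stack_key(key: str) -> str:
        """Canonical label of a WC/WC stack.

        A step is identified by its top-strand dinucleotide (5'→3'); read
        from the opposite strand the same duplex step appears as the
        reverse complement, so ``min(top, revcomp(top))`` is canonical.
        Accepts either ``XY`` or the two-strand ``XY/WZ`` spelling.
        """
        top = key.split("/")[0]
        alt = _COMPLEMENT[top[1]] + _COMPLEMENT[top[0]]
        return min(top, alt)

    def stack_dg37(self, key: str) -> tuple[float, float, float]:
        canon = self.canonical_stack_key(key)
        if canon not in self.stacks:
            raise ParameterCoverageError(f"no stack parameters for motif {key}")
        return self.stacks[canon]

    def stack_energy(self, key: str) -> float:
        _, dh, ds = self.stack_dg37(key)
        ds_eff = ds + 0.368 * math.log(self.na_molar)
        return dh - self.temperature * ds_eff / 1000.0

    def terminal_at_energy(self) -> float:
        _, dh, ds = self.terminal_at
        return dh - self.temperature * ds / 1000.0

    def loop_energy(self, kind: str, size: int) -> float:
        table = self.loops[kind]
        if size in table:
            dg37 = table[size]
        else:
            sizes = sorted(table)
            if size < sizes[0]:
                raise ParameterCoverageError(f"{kind} loop of size {size} below table minimum")
            if size > sizes[-1]:
                # Jacobson–Stockmayer extrapolation
                dg37 = table[sizes[-1]] + 2.44 * _R_KCAL * _T37 * math.log(size / sizes[-1])
            else:
                lo = max(s for s in sizes if s < size)
                hi = min(s for s in sizes if s > size)
                w = (math.log(size) - math.log(lo)) / (math.log(hi) - math.log(lo))
                dg37 = table[lo] * (1 - w) + table[hi] * w
        # loop penalties are treated as purely entropic
        return dg37 * self.temperature / _T37


def load_nn_parameters(
    path: str | Path | None = None,
    temperature: float = 310.15,
    na_molar: float = 1.0,
) -> NNParameterSet:
    """Load an NN parameter table (bundled unified DNA set by default)."""
    if path is None:
        source = resources.files("aptadyn.data").joinpath("dna_nn_unified.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    stacks: dict[str, tuple[float, float, float]] = {}
    loops: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    terminal_at = (0.0, 0.0, 0.0)
    multi = {"multi_a": 0.0, "multi_b": 0.0, "multi_c": 0.0}
    for row in csv.DictReader(text.splitlines()):
        kind = row["kind"]
        dg37 = float(row["dg37"])
        dh = float(row["dh"]) if row.get("dh") else 0.0
        ds = float(row["ds"]) if row.get("ds") else 0.0
        if kind == "stack":
            stacks[NNParameterSet.canonical_stack_key(row["key"])] = (dg37, dh, ds)
        elif kind == "terminal_at":
            terminal_at = (dg37, dh, ds)
        elif kind in loops:
            loops[kind][int(row["key"])] = dg37
        elif kind in multi:
            multi[kind] = dg37
        else:
            raise ParameterCoverageError(f"unknown parameter kind {kind!r}")
    return NNParameterSet(
        stacks=stacks,
        loops=loops,
        terminal_at=terminal_at,
        multiloop=(multi["multi_a"], multi["multi_b"], multi["multi_c"]),
        temperature=temperature,
        na_molar=na_molar,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _children_of(pairs: list[tuple[int, int]], i: int, j: int) -> list[tuple[int, int]]:
    """Pairs directly nested inside (i, j) (not inside a sibling)."""
    inside = [(k, l) for k, l in pairs if i < k < l < j]
    out = []
    for k, l in inside:
        if not any(k2 < k and l < l2 for k2, l2 in inside if (k2, l2) != (k, l)):
            out.append((k, l))
    return sorted(out)


def evaluate_nn_energy(
    sequence: Sequence,
    ss: SecondaryStructure,
    params: NNParameterSet | None = None,
) -> float:
    """ΔG of a given fold in kcal/mol at ``params.temperature``.

    Decomposition: one stack increment per adjacent canonical pair step,
    hairpin/bulge/internal penalties by loop size, a multiloop term
    ``a + b·branches + c·unpaired``, and the terminal A·T correction at each
    exterior-facing helix end.  Noncanonical pairs contribute no stack energy
    (a warning is logged at parse time); a fully unpaired strand scores 0.
    """
    if params is None:
        params = load_nn_parameters()
    pairs = ss.pairs()
    if not pairs:
        return 0.0
    nonc = ss.noncanonical
    total = 0.0

    def is_at(pair: tuple[int, int]) -> bool:
        bases = {sequence.base(pair[0]), sequence.base(pair[1])}
        return bases == {"A", "T"}

    for (i, j) in pairs:
        children = _children_of(pairs, i, j)
        if not children:
            total += params.loop_energy("hairpin", j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                if (i, j) in nonc or (k, l) in nonc:
                    pass  # noncanonical step: no stack increment
                else:
                    key = (
                        f"{sequence.base(i)}{sequence.base(k)}/"
                        f"{sequence.base(j)}{sequence.base(l)}"
                    )
                    total += params.stack_energy(key)
            elif s1 == 0 or s2 == 0:
                total += params.loop_energy("bulge", s1 + s2)
            else:
                total += params.loop_energy("internal", s1 + s2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            a, b, c = params.multiloop
            branches = len(children) + 1
            total += a + b * branches + c * unpaired

    # terminal A·T corrections at exterior-facing helix ends
    exterior = _children_of([(0, len(sequence) + 1)] + pairs, 0, len(sequence) + 1)
    for pair in exterior:
        if is_at(pair):
            total += params.terminal_at_energy()
    return total


def rank_models(models: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Order candidate models by ascending ΔG; ties break lexicographically."""
    if not models:
        raise ValueError("need at least one model to rank")
    return sorted(models, key=lambda m: (m[1], m[0]))
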