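"""Pairwise alignment of the two parent enzymes plus 3-state secondary structure.

The demarcation step needs the two parents as a single aligned, annotated
object: every alignment column paired with the H/E/C state of the residues
it covers.  Secondary structure can either be supplied by the user (the
preferred path when a reference assignment exists) or derived here from
backbone dihedrals of a coordinate model.

Structural superposition is deliberately not implemented; an SS-annotated
global sequence alignment stands in for a structure alignment of two
homologs in the ~50% identity regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError
from .formats_io import SeqRecord, StructureModel

# phi/psi windows (degrees) used for 3-state assignment.  A simple,
# testable dihedral-region proxy: not a hydrogen-bond-energy method.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -60.0)
STRAND_PSI_A = (60.0, 180.0)
STRAND_PSI_B = (-180.0, -150.0)
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3


@dataclass(frozen=True)
class SecondaryStructureString:
    """Per-residue 3-state (H/E/C) annotation for one parent sequence."""

    states: str
    source: Literal["provided", "computed"] = "provided"

    def __post_init__(self):
        if not self.states:
            raise InputError("empty secondary-structure string")
        bad = set(self.states) - set("HEC")
        if bad:
            raise InputError(f"secondary-structure states must be H/E/C, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


def read_ss(path: str | Path, source: Literal["provided", "computed"] = "provided") -> SecondaryStructureString:
    """Read an SS string from a one-line text file or a FASTA-like record."""
    text = Path(path).read_text().strip()
    lines = [l.strip() for l in text.splitlines() if l.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    return SecondaryStructureString("".join(lines).upper(), source=source)


@dataclass
class AlignedParents:
    """Two parents with alignment columns and per-residue SS states.

    ``columns`` lists, per alignment column, the 1-based residue position
    on each parent or ``None`` for a gap; together they cover every
    residue of both parents exactly once, in order.
    """

    parent_a: SeqRecord
    parent_b: SeqRecord
    ss_a: SecondaryStructureString
    ss_b: SecondaryStructureString
    columns: list[tuple[int | None, int | None]]
    identity_pct: float
    score: float

    def __post_init__(self):
        if len(self.ss_a) != len(self.parent_a.seq) or len(self.ss_b) != len(self.parent_b.seq):
            raise InputError("secondary-structure strings must match their sequence lengths")
        a_seen = [p for p, _ in self.columns if p is not None]
        b_seen = [p for _, p in self.columns if p is not None]
        if a_seen != list(range(1, len(self.parent_a.seq) + 1)) or b_seen != list(
            range(1, len(self.parent_b.seq) + 1)
        ):
            raise InputError("alignment columns must cover both parents exactly once, in order")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise InputError("identity_pct out of [0, 100]")

    def column_states(self, col: int) -> tuple[str | None, str | None]:
        """H/E/C state of each parent at 1-based alignment column ``col``."""
        a_pos, b_pos = self.columns[col - 1]
        sa = self.ss_a[a_pos - 1] if a_pos is not None else None
        sb = self.ss_b[b_pos - 1] if b_pos is not None else None
        return sa, sb

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # affine convention: a gap run of length L scores open + extend*(L-1)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_parents(
    a: SeqRecord,
    b: SeqRecord,
    ss_a: SecondaryStructureString,
    ss_b: SecondaryStructureString,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignedParents:
    """Globally align two parents (Needleman–Wunsch, affine gaps).

    Identity is computed over aligned residue pairs only:
    identical pairs / aligned pairs x 100.  The traceback is
    deterministic for fixed parameters (first-ranked alignment of the
    dynamic program).
    """
    if not a.seq or not b.seq:
        raise InputError("cannot align an empty sequence")
    if a.moltype != "protein" or b.moltype != "protein":
        raise InputError("parents must be amino-acid sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a.seq, b.seq)[0]
    indices = alignment.indices  # 2 x n_columns, -1 marks gaps
    columns: list[tuple[int | None, int | None]] = []
    matches = aligned_pairs = 0
    for k in range(indices.shape[1]):
        ia, ib = int(indices[0, k]), int(indices[1, k])
        a_pos = ia + 1 if ia >= 0 else None
        b_pos = ib + 1 if ib >= 0 else None
        columns.append((a_pos, b_pos))
        if a_pos is not None and b_pos is not None:
            aligned_pairs += 1
            if a.seq[ia] == b.seq[ib]:
                matches += 1
    identity = 100.0 * matches / aligned_pairs if aligned_pairs else 0.0
    return AlignedParents(
        parent_a=a,
        parent_b=b,
        ss_a=ss_a,
        ss_b=ss_b,
        columns=columns,
        identity_pct=identity,
        score=float(alignment.score),
    )


def score_columns(
    columns: list[tuple[int | None, int | None]],
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Recompute an alignment score directly from a column list.

    Used as a self-consistency check against the dynamic program's own
    score; gap runs on either parent cost ``open + extend*(L-1)``.
    """
    sub = substitution_matrices.load(matrix)
    total = 0.0
    prev_gap_a = prev_gap_b = False
    for a_pos, b_pos in columns:
        if a_pos is not None and b_pos is not None:
            total += float(sub[seq_a[a_pos - 1], seq_b[b_pos - 1]])
            prev_gap_a = prev_gap_b = False
        elif a_pos is None:  # gap in A
            total -= gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        else:  # gap in B
            total -= gap_extend if prev_gap_b else gap_open
            prev_gap_b, prev_gap_a = True, False
    return total


# ---------------------------------------------------------------------------
# secondary-structure assignment from coordinates


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def _in_range(value: float, lo_hi: tuple[float, float]) -> bool:
    return lo_hi[0] <= value <= lo_hi[1]


def assign_secondary_structure(model: StructureModel, chain: str = "A") -> SecondaryStructureString:
    """3-state SS from backbone (phi, psi) windows.

    A residue counts as helical/extended only when both dihedrals fall in
    the corresponding region; runs shorter than 4 (helix) or 3 (strand)
    smooth to coil, as do residues missing backbone atoms or terminal
    residues lacking a dihedral.  Invariant under rigid-body motion.
    """
    residues = model.chain_residues(chain)  # raises LookupFailure if absent
    if len(residues) < 3:
        raise InputError(f"chain {chain!r} has fewer than 3 residues")
    keys = list(residues)
    n = len(keys)
    helical = [False] * n
    extended = [False] * n
    for i in range(n):
        prev = residues[keys[i - 1]] if i > 0 else None
        curr = residues[keys[i]]
        nxt = residues[keys[i + 1]] if i < n - 1 else None
        needed = all(name in curr for name in ("N", "CA", "C"))
        if not needed or prev is None or nxt is None or "C" not in prev or "N" not in nxt:
            continue
        phi = _dihedral(prev["C"].coords, curr["N"].coords, curr["CA"].coords, curr["C"].coords)
        psi = _dihedral(curr["N"].coords, curr["CA"].coords, curr["C"].coords, nxt["N"].coords)
        if _in_range(phi, HELIX_PHI) and _in_range(psi, HELIX_PSI):
            helical[i] = True
        elif _in_range(phi, STRAND_PHI) and (_in_range(psi, STRAND_PSI_A) or _in_range(psi, STRAND_PSI_B)):
            extended[i] = True
    states = ["C"] * n
    _mark_runs(helical, MIN_HELIX_RUN, "H", states)
    _mark_runs(extended, MIN_STRAND_RUN, "E", states)
    return SecondaryStructureString("".join(states), source="computed")


def _mark_runs(flags: list[bool], min_run: int, symbol: str, states: list[str]) -> None:
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    states[k] = symbol
            i = j
        else:
            i += 1
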