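"""Fragment demarcation of an aligned parent pair.

Two hard constraints define a valid swap scheme for a pair of homologous
enzymes: (1) no fragment boundary may interrupt a local secondary-structure
element (helix or strand run) on either parent, and (2) every internal
fragment — everything except the N- and C-terminal fragments — must be
shorter than 20 residues on both parents.  Within those constraints the
choice of boundaries is configuration: the solver either maximizes the
number of internal fragments or hits a requested fragment count exactly,
breaking ties toward the most even internal lengths and then toward the
leftmost cuts.  Output is deterministic for fixed input and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Literal

from .align_ss import AlignedParents
from .errors import FeasibilityError, InputError

Objective = Literal["max_internal_count"]  # or ("target_count", k)


@dataclass(frozen=True)
class DemarcationParams:
    """Knobs of the demarcation solver.

    ``max_internal_len`` encodes the "shorter than 20 residues" rule as
    <= 19; ``min_fragment_len`` keeps fragments from degenerating into
    point mutations; ``eligibility_window`` is how many gap-free columns
    are required on each side of a junction.
    """

    max_internal_len: int = 19
    min_fragment_len: int = 5
    eligibility_window: int = 1
    objective: str | tuple[str, int] = "max_internal_count"

    def __post_init__(self):
        if not 1 <= self.min_fragment_len <= self.max_internal_len:
            raise InputError("need 1 <= min_fragment_len <= max_internal_len")
        if self.eligibility_window < 0:
            raise InputError("eligibility_window must be >= 0")
        obj = self.objective
        if obj != "max_internal_count" and not (
            isinstance(obj, tuple) and len(obj) == 2 and obj[0] == "target_count" and obj[1] >= 1
        ):
            raise InputError(f"unknown objective {obj!r}")


@dataclass(frozen=True)
class CutSite:
    """A junction after alignment column ``column`` (1-based).

    ``a_pos``/``b_pos`` are the residue positions after which the cut
    falls on each parent.
    """

    column: int
    a_pos: int
    b_pos: int


@dataclass(frozen=True)
class Fragment:
    name: str
    a_interval: tuple[int, int]  # closed, 1-based on parent A
    b_interval: tuple[int, int]
    terminal: bool

    def length_a(self) -> int:
        return self.a_interval[1] - self.a_interval[0] + 1

    def length_b(self) -> int:
        return self.b_interval[1] - self.b_interval[0] + 1


@dataclass
class FragmentScheme:
    """An ordered tiling of both parents into swap-compatible fragments M1..Mn."""

    fragments: list[Fragment]
    params: DemarcationParams

    def __getitem__(self, name: str) -> Fragment:
        for frag in self.fragments:
            if frag.name == name:
                return frag
        from .errors import LookupFailure

        raise LookupFailure(f"no fragment named {name!r}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class Violation:
    kind: Literal["tiling", "length", "ss", "terminal"]
    fragment: str
    message: str


# ---------------------------------------------------------------------------
# candidate cuts


def find_cut_candidates(ap: AlignedParents, params: DemarcationParams | None = None) -> list[CutSite]:
    """All alignment columns after which a cut is legal.

    A junction after column c is eligible when (i) the 2*(window+1)
    columns flanking the junction (c-window .. c+1+window) exist and are
    gap-free on both parents, (ii) both residues at column c are coil,
    and (iii) the cut splits no helix/strand run on either parent.
    """
    params = params or DemarcationParams()
    w = params.eligibility_window
    n = ap.n_columns
    out: list[CutSite] = []
    for c in range(1, n + 1):
        lo, hi = c - w, c + 1 + w
        if lo < 1 or hi > n:
            continue
        window_cols = [ap.columns[k - 1] for k in range(lo, hi + 1)]
        if any(a is None or b is None for a, b in window_cols):
            continue
        sa, sb = ap.column_states(c)
        if sa != "C" or sb != "C":
            continue
        a_pos, b_pos = ap.columns[c - 1]
        if _splits_run(ap.ss_a.states, a_pos) or _splits_run(ap.ss_b.states, b_pos):
            continue
        out.append(CutSite(column=c, a_pos=a_pos, b_pos=b_pos))
    return out


def _splits_run(ss: str, pos: int) -> bool:
    """True if cutting after 1-based residue ``pos`` interrupts an H/E run."""
    if pos >= len(ss):
        return False
    left, right = ss[pos - 1], ss[pos]
    return left != "C" and left == right


# ---------------------------------------------------------------------------
# partitioning


def partition_fragments(ap: AlignedParents, params: DemarcationParams | None = None) -> FragmentScheme:
    """Select cuts by dynamic programming under the configured objective.

    ``max_internal_count`` maximizes the number of fragments (ties:
    leftmost cuts); ``("target_count", k)`` returns a scheme with exactly
    k fragments, most-even internal lengths first, then leftmost.
    """
    params = params or DemarcationParams()
    candidates = find_cut_candidates(ap, params)
    a_len, b_len = len(ap.parent_a.seq), len(ap.parent_b.seq)

    if params.objective == "max_internal_count":
        cuts = _solve_max_count(candidates, a_len, b_len, params)
    else:
        _, k = params.objective
        cuts = _solve_target_count(candidates, a_len, b_len, params, k)
    return _build_scheme(cuts, a_len, b_len, params)


def _first_ok(c: CutSite, p: DemarcationParams) -> bool:
    return c.a_pos >= p.min_fragment_len and c.b_pos >= p.min_fragment_len


def _last_ok(c: CutSite, a_len: int, b_len: int, p: DemarcationParams) -> bool:
    return a_len - c.a_pos >= p.min_fragment_len and b_len - c.b_pos >= p.min_fragment_len


def _internal_ok(cj: CutSite, ci: CutSite, p: DemarcationParams) -> bool:
    la, lb = ci.a_pos - cj.a_pos, ci.b_pos - cj.b_pos
    return (
        p.min_fragment_len <= la <= p.max_internal_len
        and p.min_fragment_len <= lb <= p.max_internal_len
    )


def _whole_protein_ok(a_len: int, b_len: int, p: DemarcationParams) -> bool:
    return a_len >= p.min_fragment_len and b_len >= p.min_fragment_len


def _solve_max_count(candidates, a_len, b_len, params) -> list[CutSite]:
    n = len(candidates)
    # suffix[i]: max number of cuts in a valid completion that uses cut i
    # as its leftmost member, or None if cut i cannot start a completion.
    suffix: list[int | None] = [None] * n
    for i in range(n - 1, -1, -1):
        best = 1 if _last_ok(candidates[i], a_len, b_len, params) else None
        for k in range(i + 1, n):
            if suffix[k] is not None and _internal_ok(candidates[i], candidates[k], params):
                cand = 1 + suffix[k]
                if best is None or cand > best:
                    best = cand
        suffix[i] = best
    total = 0
    for i in range(n):
        if suffix[i] is not None and _first_ok(candidates[i], params):
            total = max(total, suffix[i])
    if total == 0:
        if not _whole_protein_ok(a_len, b_len, params):
            raise FeasibilityError("no valid scheme: parents shorter than min_fragment_len", 0)
        return []
    # leftmost-lexicographic reconstruction of an optimal cut set
    cuts: list[CutSite] = []
    remaining = total
    prev: CutSite | None = None
    for i in range(n):
        c = candidates[i]
        if suffix[i] != remaining:
            continue
        if prev is None:
            if not _first_ok(c, params):
                continue
        elif not _internal_ok(prev, c, params):
            continue
        cuts.append(c)
        prev = c
        remaining -= 1
        if remaining == 0:
            break
    return cuts


def _solve_target_count(candidates, a_len, b_len, params, k: int) -> list[CutSite]:
    max_frags = _max_fragment_count(candidates, a_len, b_len, params)
    m = k - 1  # cuts needed
    if m == 0:
        if not _whole_protein_ok(a_len, b_len, params):
            raise FeasibilityError("single-fragment scheme violates min length", max_frags)
        return []
    INF = float("inf")
    n = len(candidates)
    # best[i][t]: (evenness cost, cut-column path) choosing cut i as the
    # leftmost of t cuts that validly finish the protein.
    best: list[list[tuple[float, tuple[int, ...]] | None]] = [[None] * (m + 1) for _ in range(n)]
    for i in range(n - 1, -1, -1):
        ci = candidates[i]
        if _last_ok(ci, a_len, b_len, params):
            best[i][1] = (0.0, (ci.column,))
        for t in range(2, m + 1):
            choice: tuple[float, tuple[int, ...]] | None = None
            for j in range(i + 1, n):
                nxt = best[j][t - 1]
                if nxt is None or not _internal_ok(ci, candidates[j], params):
                    continue
                la = candidates[j].a_pos - ci.a_pos
                lb = candidates[j].b_pos - ci.b_pos
                cand = (nxt[0] + la * la + lb * lb, (ci.column,) + nxt[1])
                if choice is None or cand < choice:
                    choice = cand
            best[i][t] = choice
    winner: tuple[float, tuple[int, ...]] | None = None
    for i in range(n):
        entry = best[i][m]
        if entry is not None and _first_ok(candidates[i], params):
            if winner is None or entry < winner:
                winner = entry
    if winner is None:
        raise FeasibilityError(
            f"target fragment count {k} infeasible; maximum achievable is {max_frags}",
            max_frags,
        )
    by_column = {c.column: c for c in candidates}
    return [by_column[col] for col in winner[1]]


def _max_fragment_count(candidates, a_len, b_len, params) -> int:
    try:
        cuts = _solve_max_count(candidates, a_len, b_len, params)
    except FeasibilityError:
        return 0
    return len(cuts) + 1


def _build_scheme(cuts: list[CutSite], a_len: int, b_len: int, params: DemarcationParams) -> FragmentScheme:
    a_bounds = [0] + [c.a_pos for c in cuts] + [a_len]
    b_bounds = [0] + [c.b_pos for c in cuts] + [b_len]
    fragments = []
    n_frag = len(cuts) + 1
    for i in range(n_frag):
        fragments.append(
            Fragment(
                name=f"M{i + 1}",
                a_interval=(a_bounds[i] + 1, a_bounds[i + 1]),
                b_interval=(b_bounds[i] + 1, b_bounds[i + 1]),
                terminal=(i == 0 or i == n_frag - 1),
            )
        )
    return FragmentScheme(fragments=fragments, params=params)


# ---------------------------------------------------------------------------
# validation and brute force


def validate_scheme(scheme: FragmentScheme, ap: AlignedParents) -> list[Violation]:
    """Empty list iff every scheme invariant holds; one violation per breach."""
    out: list[Violation] = []
    p = scheme.params
    frags = scheme.fragments
    # tiling on both parents
    for axis, total in (("a", len(ap.parent_a.seq)), ("b", len(ap.parent_b.seq))):
        cursor = 1
        for f in frags:
            start, end = getattr(f, f"{axis}_interval")
            if start != cursor:
                out.append(
                    Violation("tiling", f.name, f"parent {axis.upper()} interval starts at {start}, expected {cursor}")
                )
            if end < start:
                out.append(Violation("tiling", f.name, f"empty interval on parent {axis.upper()}"))
            cursor = end + 1
        if frags and cursor != total + 1:
            out.append(
                Violation("tiling", frags[-1].name, f"parent {axis.upper()} tiling ends at {cursor - 1}, expected {total}")
            )
    # terminal flags
    for i, f in enumerate(frags):
        expect = i == 0 or i == len(frags) - 1
        if f.terminal != expect:
            out.append(Violation("terminal", f.name, f"terminal flag should be {expect}"))
    # lengths
    for i, f in enumerate(frags):
        internal = 0 < i < len(frags) - 1
        for axis, length in (("A", f.length_a()), ("B", f.length_b())):
            if internal and length > p.max_internal_len:
                out.append(
                    Violation("length", f.name, f"internal fragment spans {length} residues on parent {axis} (> {p.max_internal_len})")
                )
            if length < p.min_fragment_len:
                out.append(
                    Violation("length", f.name, f"fragment spans {length} residues on parent {axis} (< {p.min_fragment_len})")
                )
    # boundaries must not interrupt H/E runs
    for f in frags[:-1]:
        if _splits_run(ap.ss_a.states, f.a_interval[1]):
            out.append(Violation("ss", f.name, "boundary splits a structure run on parent A"))
        if _splits_run(ap.ss_b.states, f.b_interval[1]):
            out.append(Violation("ss", f.name, "boundary splits a structure run on parent B"))
    return out


def write_scheme_tsv(scheme: FragmentScheme, path) -> None:
    """Write a scheme as TSV: name, a_start, a_end, b_start, b_end, terminal."""
    from pathlib import Path

    lines = ["name\ta_start\ta_end\tb_start\tb_end\tterminal"]
    for f in scheme.fragments:
        lines.append(
            f"{f.name}\t{f.a_interval[0]}\t{f.a_interval[1]}\t{f.b_interval[0]}\t{f.b_interval[1]}\t{int(f.terminal)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme_tsv(path, params: DemarcationParams | None = None) -> FragmentScheme:
    from pathlib import Path

    from .errors import FormatError

    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or lines[0].split("\t")[:6] != ["name", "a_start", "a_end", "b_start", "b_end", "terminal"]:
        raise FormatError(f"{path}: not a scheme TSV")
    fragments = []
    for line in lines[1:]:
        name, a0, a1, b0, b1, term = line.split("\t")[:6]
        fragments.append(
            Fragment(
                name=name,
                a_interval=(int(a0), int(a1)),
                b_interval=(int(b0), int(b1)),
                terminal=bool(int(term)),
            )
        )
    return FragmentScheme(fragments=fragments, params=params or DemarcationParams())


def enumerate_schemes(ap: AlignedParents, params: DemarcationParams | None = None) -> Iterator[list[CutSite]]:
    """Yield every valid cut subset by exhaustive enumeration.

    Exponential; intended as an independent oracle for small alignments
    (<= ~60 columns), not for production use.
    """
    params = params or DemarcationParams()
    candidates = find_cut_candidates(ap, params)
    a_len, b_len = len(ap.parent_a.seq), len(ap.parent_b.seq)
    if _whole_protein_ok(a_len, b_len, params):
        yield []
    for r in range(1, len(candidates) + 1):
        for subset in combinations(candidates, r):
            if not _first_ok(subset[0], params):
                continue
            if not _last_ok(subset[-1], a_len, b_len, params):
                continue
            if all(_internal_ok(subset[i], subset[i + 1], params) for i in range(r - 1)):
                yield list(subset)
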