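"""Geometric hydrogen-bond detection and frame-occupancy statistics.

Post-processing for multi-model coordinate files: a donor–acceptor pair is
hydrogen bonded in a frame when the heavy-atom distance is within a cutoff
and the donor–hydrogen–acceptor angle is wide enough; the occupancy rate
of a pair is the percentage of frames in an analysis window where the bond
is present.  This works on any frame source (MD snapshots exported as
multi-model PDB, NMR ensembles) and is decoupled from any simulation
engine.  Frames without hydrogens fall back to a distance-only criterion,
flagged in the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, InputError
from .formats_io import Atom, StructureModel

# donor heavy atoms (N/O/S with bonded hydrogens) per residue type; "*"
# applies to every residue (backbone amide)
DEFAULT_DONORS: dict[str, tuple[str, ...]] = {
    "*": ("N",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "HOH": ("O",),
}

DEFAULT_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "HOH": ("O",),
}

MAX_DH_BOND_DIST = 1.25  # Angstrom; hydrogen "belongs" to the nearest donor within this


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Defaults (3.5 A donor-acceptor, >= 120 deg D-H-A) are the common
    structural-biology convention; both are tunable because published
    analyses rarely state theirs.
    """

    max_da_dist: float = 3.5
    min_dha_angle: float = 120.0
    donors: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_DONORS))
    acceptors: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_ACCEPTORS))

    def __post_init__(self):
        if self.max_da_dist <= 0:
            raise InputError("max_da_dist must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise InputError("min_dha_angle must be in (0, 180]")

    def is_donor(self, atom: Atom) -> bool:
        res = atom.res_name.upper()
        return atom.atom_name in self.donors.get(res, ()) or atom.atom_name in self.donors.get("*", ())

    def is_acceptor(self, atom: Atom) -> bool:
        res = atom.res_name.upper()
        return atom.atom_name in self.acceptors.get(res, ()) or atom.atom_name in self.acceptors.get("*", ())


@dataclass(frozen=True)
class HBond:
    donor: str  # atom id, e.g. "S_115@OG"
    hydrogen: str | None  # None in distance-only mode
    acceptor: str


@dataclass(frozen=True)
class OccupancyRecord:
    acceptor: str
    donor: str
    occupancy_pct: float
    distance_only: bool = False

    def __post_init__(self):
        if not 0.0 <= self.occupancy_pct <= 100.0:
            raise InputError("occupancy_pct out of [0, 100]")


def _dist(a: Atom, b: Atom) -> float:
    return math.dist(a.coords, b.coords)


def _angle_deg(a, vertex, b) -> float:
    v1 = np.asarray(a.coords) - np.asarray(vertex.coords)
    v2 = np.asarray(b.coords) - np.asarray(vertex.coords)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, float(cosang)))))


def _attach_hydrogens(frame: StructureModel, donors: list[Atom]) -> dict[tuple, list[Atom]]:
    """Assign each hydrogen to the nearest donor heavy atom of the same
    residue within a covalent-bond distance."""
    attached: dict[tuple, list[Atom]] = {}
    hydrogens = [a for a in frame.atoms if a.atom_name.startswith("H")]
    for h in hydrogens:
        best = None
        best_d = MAX_DH_BOND_DIST
        for d in donors:
            if (d.chain, d.res_seq) != (h.chain, h.res_seq):
                continue
            dist = _dist(d, h)
            if dist <= best_d:
                best, best_d = d, dist
        if best is not None:
            attached.setdefault((best.chain, best.res_seq, best.atom_name), []).append(h)
    return attached


def detect_hbonds(frame: StructureModel, criteria: HBondCriteria | None = None) -> set[HBond]:
    """All donor/hydrogen/acceptor triples satisfying the criteria in one frame.

    Intra-residue pairs are excluded.  If the frame carries no hydrogens
    at all (e.g. a crystallographic model), detection degrades to the
    donor-acceptor distance criterion alone and the returned bonds have
    ``hydrogen=None``.
    """
    criteria = criteria or HBondCriteria()
    if not frame.atoms:
        raise InputError("empty frame")
    donors = [a for a in frame.atoms if criteria.is_donor(a)]
    acceptors = [a for a in frame.atoms if criteria.is_acceptor(a)]
    attached = _attach_hydrogens(frame, donors)
    has_hydrogens = bool(attached)
    bonds: set[HBond] = set()
    for d in donors:
        for acc in acceptors:
            if (d.chain, d.res_seq) == (acc.chain, acc.res_seq):
                continue
            if _dist(d, acc) > criteria.max_da_dist:
                continue
            if not has_hydrogens:
                bonds.add(HBond(donor=d.atom_id, hydrogen=None, acceptor=acc.atom_id))
                continue
            for h in attached.get((d.chain, d.res_seq, d.atom_name), ()):
                if _angle_deg(d, h, acc) >= criteria.min_dha_angle:
                    bonds.add(HBond(donor=d.atom_id, hydrogen=h.atom_id, acceptor=acc.atom_id))
    return bonds


def occupancy(
    frames: list[StructureModel],
    pairs: str | list[tuple[str, str]] = "all",
    criteria: HBondCriteria | None = None,
    window: tuple[int, int] | None = None,
) -> list[OccupancyRecord]:
    """Per-pair occupancy over a frame window, sorted descending.

    ``window`` is a half-open (start, stop) index range over ``frames``
    (None = all frames).  ``pairs="all"`` reports every (donor, acceptor)
    pair bonded in at least one window frame; an explicit pair list is
    reported even at 0%.
    """
    criteria = criteria or HBondCriteria()
    if not frames:
        raise InputError("no frames")
    roster = frames[0].roster()
    for f in frames[1:]:
        if f.roster() != roster:
            raise ConsistencyError(
                f"atom roster of model {f.model_index} differs from model {frames[0].model_index}"
            )
    selected = frames[window[0] : window[1]] if window is not None else frames
    if not selected:
        raise InputError("window selects no frames")
    distance_only = False
    counts: dict[tuple[str, str], int] = {}
    for frame in selected:
        bonds = detect_hbonds(frame, criteria)
        seen = set()
        for b in bonds:
            if b.hydrogen is None:
                distance_only = True
            seen.add((b.donor, b.acceptor))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    n = len(selected)
    if pairs == "all":
        wanted = list(counts)
    else:
        wanted = [(d, a) for d, a in pairs]
    if distance_only:
        warnings.warn("no hydrogens in frames: occupancies use distance-only criterion", stacklevel=2)
    records = [
        OccupancyRecord(
            acceptor=a,
            donor=d,
            occupancy_pct=100.0 * counts.get((d, a), 0) / n,
            distance_only=distance_only,
        )
        for d, a in wanted
    ]
    records.sort(key=lambda r: (-r.occupancy_pct, r.acceptor, r.donor))
    return records


def last_fraction_window(n_frames: int, fraction: float) -> tuple[int, int]:
    """Window covering the trailing ``fraction`` of frames (>= 1 frame),
    e.g. the last quarter of a trajectory after equilibration."""
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    start = n_frames - max(1, int(round(n_frames * fraction)))
    return (max(0, start), n_frames)
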