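"""Hybrid-enzyme construction and overlap-extension PCR primer design.

A chimera is a recipient parent with one or more fragments replaced by the
donor's alignment-mediated counterparts.  Constructs are named the way the
field labels them — recipient id, dash, slash-joined fragment labels in
ascending order (``XylE-M3/M6``) — and carry per-residue provenance so a
construct can be reverse-translated codon-faithfully from the parent CDSs
and equipped with junction-spanning primer pairs for two-step overlap PCR.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align_ss import AlignedParents
from .demarcation import FragmentScheme
from .errors import ConsistencyError, GeometryError, InputError, LookupFailure
from .formats_io import SeqRecord

# ---------------------------------------------------------------------------
# chimera assembly


@dataclass
class ChimeraConstruct:
    name: str
    sequence: str
    provenance: str  # per residue: 'A' or 'B'
    recipient: str  # parent record id
    donor: str
    swapped: frozenset[str]
    #: per-residue (parent label, 1-based parent position); used by
    #: reverse_translate to inherit codons
    residue_origin: list[tuple[str, int]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if len(self.provenance) != len(self.sequence):
            raise InputError("provenance must be per-residue")


def _fragment_index(name: str) -> int:
    match = re.fullmatch(r"M(\d+)", name)
    if not match:
        raise LookupFailure(f"bad fragment name {name!r}")
    return int(match.group(1))


def construct_name(recipient_id: str, fragments: Iterable[str]) -> str:
    labels = sorted(set(fragments), key=_fragment_index)
    return f"{recipient_id}-" + "/".join(labels)


def parse_construct_name(name: str) -> tuple[str, frozenset[str]]:
    """Inverse of :func:`construct_name`."""
    recipient, _, tail = name.rpartition("-")
    if not recipient or not tail:
        raise InputError(f"cannot parse construct name {name!r}")
    labels = tail.split("/")
    for lab in labels:
        _fragment_index(lab)
    return recipient, frozenset(labels)


def _assemble(
    scheme: FragmentScheme,
    ap: AlignedParents,
    recipient_is_a: bool,
    swapped: frozenset[str],
) -> ChimeraConstruct:
    seq_a, seq_b = ap.parent_a.seq, ap.parent_b.seq
    parts: list[str] = []
    provenance: list[str] = []
    origin: list[tuple[str, int]] = []
    recipient_label = "A" if recipient_is_a else "B"
    donor_label = "B" if recipient_is_a else "A"
    for frag in scheme.fragments:
        use_donor = frag.name in swapped
        label = donor_label if use_donor else recipient_label
        interval = frag.a_interval if label == "A" else frag.b_interval
        source = seq_a if label == "A" else seq_b
        start, end = interval
        parts.append(source[start - 1 : end])
        provenance.extend(label * (end - start + 1))
        origin.extend((label, pos) for pos in range(start, end + 1))
    recipient_id = ap.parent_a.id if recipient_is_a else ap.parent_b.id
    donor_id = ap.parent_b.id if recipient_is_a else ap.parent_a.id
    return ChimeraConstruct(
        name=construct_name(recipient_id, swapped) if swapped else recipient_id,
        sequence="".join(parts),
        provenance="".join(provenance),
        recipient=recipient_id,
        donor=donor_id,
        swapped=swapped,
        residue_origin=origin,
    )


def generate_chimeras(
    scheme: FragmentScheme,
    ap: AlignedParents,
    recipient: str,
    fragments: str | tuple[str, Iterable[str]] | Iterable[str] = "all-singles",
) -> list[ChimeraConstruct]:
    """Build hybrid constructs for a recipient parent.

    ``fragments`` is either an explicit set of fragment names (one
    construct with all of them swapped), the string ``"all-singles"``
    (one construct per fragment), or ``("combinations-of", names)`` for
    every non-empty subset of ``names``.  Output order is deterministic:
    subsets sorted by size, then by fragment indices.
    """
    if recipient == ap.parent_a.id or recipient == "A":
        recipient_is_a = True
    elif recipient == ap.parent_b.id or recipient == "B":
        recipient_is_a = False
    else:
        raise LookupFailure(f"recipient {recipient!r} is neither parent")

    known = set(scheme.names)

    def check(names: Iterable[str]) -> frozenset[str]:
        names = frozenset(names)
        unknown = names - known
        if unknown:
            raise LookupFailure(f"unknown fragment name(s) {sorted(unknown)}")
        return names

    if fragments == "all-singles":
        subsets = [frozenset({name}) for name in scheme.names]
    elif isinstance(fragments, tuple) and len(fragments) == 2 and fragments[0] == "combinations-of":
        pool = sorted(check(fragments[1]), key=_fragment_index)
        subsets = [
            frozenset(combo)
            for r in range(1, len(pool) + 1)
            for combo in itertools.combinations(pool, r)
        ]
    else:
        subsets = [check(fragments)]
    return [_assemble(scheme, ap, recipient_is_a, s) for s in subsets]


# ---------------------------------------------------------------------------
# reverse translation


def _preferred_codons(table_name: str) -> dict[str, str]:
    """Deterministic codon per amino acid: the alphabetically first
    synonymous codon of the named NCBI table."""
    table = CodonTable.unambiguous_dna_by_name[table_name]
    out: dict[str, str] = {}
    for codon in sorted(table.forward_table):
        aa = table.forward_table[codon]
        out.setdefault(aa, codon)
    return out


def _check_cds(cds: SeqRecord, protein: str, label: str) -> None:
    if len(cds.seq) % 3 != 0:
        raise ConsistencyError(f"CDS {cds.id!r} length is not a multiple of 3")
    translated = str(Seq(cds.seq).translate())
    translated = translated.removesuffix("*")
    if len(translated) != len(protein):
        raise ConsistencyError(
            f"CDS {cds.id!r} encodes {len(translated)} residues but parent {label} has {len(protein)}"
        )
    for i, (got, want) in enumerate(zip(translated, protein), start=1):
        if got != want:
            raise ConsistencyError(
                f"CDS {cds.id!r} codon {i} ({cds.seq[3*(i-1):3*i]}) encodes {got}, parent {label} has {want}"
            )


def reverse_translate(
    construct: ChimeraConstruct,
    ap: AlignedParents,
    cds_a: SeqRecord | None = None,
    cds_b: SeqRecord | None = None,
    codon_table: str = "Standard",
) -> SeqRecord:
    """DNA for a construct: codons inherited from the provenance parent's
    CDS where available, otherwise the table's canonical codon."""
    if cds_a is not None:
        _check_cds(cds_a, ap.parent_a.seq, "A")
    if cds_b is not None:
        _check_cds(cds_b, ap.parent_b.seq, "B")
    preferred = _preferred_codons(codon_table)
    codons: list[str] = []
    for aa, (label, pos) in zip(construct.sequence, construct.residue_origin):
        cds = cds_a if label == "A" else cds_b
        if cds is not None:
            codons.append(cds.seq[3 * (pos - 1) : 3 * pos])
        else:
            codons.append(preferred[aa])
    dna = "".join(codons)
    back = str(Seq(dna).translate())
    if back != construct.sequence:  # pragma: no cover - internal invariant
        raise ConsistencyError("reverse translation does not round-trip")
    return SeqRecord(id=construct.name, seq=dna, description="reverse-translated CDS", moltype="dna")


# ---------------------------------------------------------------------------
# primer design


@dataclass(frozen=True)
class PrimerPair:
    junction: int  # nt position after which the junction falls
    forward: str  # 5'->3' sense strand
    reverse: str  # 5'->3' antisense strand
    tm_forward: float
    tm_reverse: float
    overlap_len: int
    within_band: bool = True


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tm_wallace(seq: str) -> float:
    """Wallace 2+4 rule: 2 degC per A/T plus 4 degC per G/C."""
    seq = seq.upper()
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


# SantaLucia (1998) unified nearest-neighbor parameters at 1 M NaCl:
# dH in kcal/mol, dS in cal/(mol K) per 5'->3' dinucleotide step.
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_R_GAS = 1.987  # cal/(mol K)


def tm_nearest_neighbor(seq: str, dnac1_nM: float = 25.0, dnac2_nM: float = 25.0) -> float:
    """Duplex melting temperature (degC) from unified nearest-neighbor
    thermodynamics at the 1 M Na+ reference (no salt correction).

    Strand concentrations default to 25 nM each (non-self-complementary
    duplex, effective concentration dnac1 - dnac2/2).
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise InputError("nearest-neighbor Tm needs >= 2 nt")
    d_h, d_s = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        dh, ds = _NN_INIT[end]
        d_h += dh
        d_s += ds
    for i in range(len(seq) - 1):
        dh, ds = _NN_PARAMS[seq[i : i + 2]]
        d_h += dh
        d_s += ds
    conc = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    return 1000.0 * d_h / (d_s + _R_GAS * math.log(conc)) - 273.15


def _tm(seq: str, method: str) -> float:
    if method == "wallace":
        return tm_wallace(seq)
    if method == "nearest_neighbor":
        return tm_nearest_neighbor(seq)
    raise InputError(f"unknown tm_method {method!r}")


def design_overlap_primers(
    dna: SeqRecord,
    junctions: Sequence[int],
    min_flank: int = 15,
    tm_method: Literal["nearest_neighbor", "wallace"] = "nearest_neighbor",
    tm_band: tuple[float, float] = (55.0, 65.0),
    max_len: int = 40,
) -> list[PrimerPair]:
    """Junction-spanning primer pairs for two-step overlap-extension PCR.

    Each primer window starts ``min_flank`` nt on both sides of the
    junction and grows symmetrically one nt at a time until both Tms lie
    in ``tm_band`` or ``max_len`` is hit; unreachable bands yield
    best-effort primers flagged ``within_band=False`` with a warning.
    """
    if dna.moltype != "dna":
        raise InputError("primer design needs a DNA record")
    n = len(dna.seq)
    pairs: list[PrimerPair] = []
    for j in junctions:
        if j < min_flank or n - j < min_flank:
            raise GeometryError(
                f"junction {j} is closer than min_flank={min_flank} nt to a sequence end"
            )
        left = right = min_flank
        while True:
            window = dna.seq[j - left : j + right]
            fwd = window
            rev = reverse_complement(window)
            tm_f, tm_r = _tm(fwd, tm_method), _tm(rev, tm_method)
            in_band = tm_band[0] <= tm_f <= tm_band[1] and tm_band[0] <= tm_r <= tm_band[1]
            can_grow = len(window) < max_len and (j - left > 0 or j + right < n)
            if in_band or not can_grow:
                if not in_band:
                    warnings.warn(
                        f"junction {j}: Tm band {tm_band} unreachable within {max_len} nt; "
                        "emitting best-effort primers",
                        stacklevel=2,
                    )
                pairs.append(
                    PrimerPair(
                        junction=j,
                        forward=fwd,
                        reverse=rev,
                        tm_forward=tm_f,
                        tm_reverse=tm_r,
                        overlap_len=len(window),
                        within_band=in_band,
                    )
                )
                break
            if j - left > 0:
                left += 1
            if len(window) + 1 < max_len and j + right < n:
                right += 1
    return pairs


_CLONING_SITES = {"EcoRI": "GAATTC", "NotI": "GCGGCCGC"}


def check_cloning_sites(dna: SeqRecord) -> list[str]:
    """Warn about internal EcoRI/NotI sites that would interfere with
    cloning into the expression vector; returns the offending enzymes."""
    hits = [name for name, site in _CLONING_SITES.items() if site in dna.seq]
    for name in hits:
        warnings.warn(f"internal {name} site present in {dna.id}", stacklevel=2)
    return hits
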