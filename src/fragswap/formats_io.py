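"""Readers and writers for the external formats the toolkit touches.

No science lives here: FASTA records, fixed-column PDB coordinate files
(single- and multi-model) and delimited assay tables are parsed, validated
and written back faithfully.  All residue numbering downstream is 1-based
on the mature sequence; a configurable offset in the callers maps author
numbering onto it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlphabetError, FormatError, InputError, LookupFailure, SchemaError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

AssayKind = Literal["kinetics", "thermal_T50", "thermal_decay", "synergy"]

#: required column names per assay kind; the first entry is the independent
#: variable the table is sorted by.
ASSAY_SCHEMAS: dict[str, tuple[str, ...]] = {
    "kinetics": ("substrate_mg_per_mL", "rate"),
    "thermal_T50": ("temperature_C", "residual_pct"),
    "thermal_decay": ("time_h", "residual_pct"),
    "synergy": ("time_h", "cellulase_only", "xylanase_only", "both"),
}


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (amino acid by default, or a DNA CDS)."""

    id: str
    seq: str
    description: str = ""
    moltype: Literal["protein", "dna"] = "protein"

    def __post_init__(self):
        if not self.seq:
            raise InputError(f"sequence {self.id!r} is empty")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        for i, ch in enumerate(self.seq, start=1):
            if ch.isspace():
                raise AlphabetError(f"whitespace in sequence {self.id!r} at position {i}")
            if ch not in alphabet:
                raise AlphabetError(
                    f"illegal {self.moltype} residue {ch!r} at position {i} of {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, moltype: Literal["protein", "dna"] = "protein") -> list[SeqRecord]:
    """Read a multi-record FASTA file, uppercasing sequences, order preserved."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(id=rec.id, seq=str(rec.seq).upper(), description=rec.description, moltype=moltype)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def coords(self):
        return (self.x, self.y, self.z)

    @property
    def atom_id(self) -> str:
        """Label in ``<res1>_<seq>@<atom>`` style, e.g. ``E_153@OE2``."""
        return f"{_three_to_one(self.res_name)}_{self.res_seq}@{self.atom_name}"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _three_to_one(res_name: str) -> str:
    return _THREE_TO_ONE.get(res_name.upper(), "X")


@dataclass
class StructureModel:
    """One coordinate frame: a flat list of atoms in file order."""

    model_index: int
    atoms: list[Atom]
    source: str = ""

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.res_seq, a.atom_name)
            if key in seen:
                raise FormatError(
                    f"duplicate atom {a.atom_name} in residue {a.chain}:{a.res_seq} of model {self.model_index}"
                )
            seen.add(key)
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise FormatError(f"non-finite coordinate in atom {key}")

    def chain_residues(self, chain: str) -> dict[int, dict[str, Atom]]:
        """Atoms of one chain grouped by residue number (sorted)."""
        out: dict[int, dict[str, Atom]] = {}
        for a in self.atoms:
            if a.chain == chain:
                out.setdefault(a.res_seq, {})[a.atom_name] = a
        if not out:
            raise LookupFailure(f"chain {chain!r} not present")
        return dict(sorted(out.items()))

    def roster(self) -> tuple:
        return tuple((a.chain, a.res_seq, a.res_name, a.atom_name) for a in self.atoms)


def read_pdb(path: str | Path, model: int | str = "all") -> StructureModel | list[StructureModel]:
    """Parse ATOM/HETATM records from a PDB file, fixed-column dialect.

    ``model="all"`` returns a list with one :class:`StructureModel` per
    MODEL block (or a single-element list for an unblocked file); an
    integer returns that model index.  altLoc other than blank/'A' is
    skipped with a warning; insertion codes are rejected so that residue
    numbering stays unambiguous.
    """
    path = Path(path)
    models: list[StructureModel] = []
    atoms: list[Atom] = []
    current_index = 0
    saw_model_record = False

    def flush(idx):
        models.append(StructureModel(model_index=idx, atoms=list(atoms), source=str(path)))
        atoms.clear()

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "MODEL":
                if atoms:
                    flush(current_index)
                saw_model_record = True
                try:
                    current_index = int(raw[10:14])
                except ValueError:
                    current_index = len(models) + 1
            elif rec == "ENDMDL":
                flush(current_index)
            elif rec in ("ATOM", "HETATM"):
                line = raw.rstrip("\n")
                if len(line) < 54:
                    raise FormatError(f"{path}:{lineno}: ATOM record shorter than coordinate columns")
                alt_loc = line[16]
                if alt_loc not in (" ", "A"):
                    warnings.warn(
                        f"{path}:{lineno}: skipping altLoc {alt_loc!r}", stacklevel=2
                    )
                    continue
                if line[26] != " ":
                    raise FormatError(
                        f"{path}:{lineno}: insertion code {line[26]!r} unsupported"
                    )
                try:
                    atom = Atom(
                        chain=line[21].strip() or "A",
                        res_seq=int(line[22:26]),
                        res_name=line[17:20].strip(),
                        atom_name=line[12:16].strip(),
                        x=float(line[30:38]),
                        y=float(line[38:46]),
                        z=float(line[46:54]),
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed fixed-width field ({exc})") from exc
                atoms.append(atom)
    if atoms:
        # trailing atoms without ENDMDL
        flush(current_index if saw_model_record else 0)
    if not models:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    if model == "all":
        return models
    for m in models:
        if m.model_index == model:
            return m
    raise LookupFailure(f"model {model} not in {path} (have {[m.model_index for m in models]})")


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or more models; multiple models get MODEL/ENDMDL blocks."""
    if isinstance(models, StructureModel):
        models = [models]
    path = Path(path)
    multi = len(models) > 1
    with path.open("w") as fh:
        for m in models:
            if multi:
                fh.write(f"MODEL {m.model_index:>8d}\n")
            for serial, a in enumerate(m.atoms, start=1):
                name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
                element = a.atom_name[0] if a.atom_name else " "
                fh.write(
                    f"ATOM  {serial:>5d} {name:<4s} {a.res_name:<3s} {a.chain:1s}"
                    f"{a.res_seq:>4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# assay tables


@dataclass
class AssayTable:
    """A validated delimited assay dataset plus free-form metadata.

    ``data`` holds named numeric columns of equal length, sorted
    ascending by the independent variable of the declared ``kind``.
    Metadata (pH, temperature, enzyme name, ...) is recorded verbatim and
    never interpreted by any computation.
    """

    kind: AssayKind
    data: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        required = ASSAY_SCHEMAS[self.kind]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SchemaError(
                f"assay kind {self.kind!r} requires columns {list(required)}; missing {missing}"
            )
        for col in self.data.columns:
            values = pd.to_numeric(self.data[col], errors="coerce")
            bad = values.index[values.isna() | ~values.map(math.isfinite)]
            if len(bad):
                raise FormatError(
                    f"non-numeric or non-finite cell at row {int(bad[0])}, column {col!r}"
                )
            self.data[col] = values.astype(float)
        indep = required[0]
        self.data = self.data.sort_values(indep, kind="mergesort").reset_index(drop=True)

    @property
    def independent(self) -> str:
        return ASSAY_SCHEMAS[self.kind][0]

    def column(self, name: str):
        if name not in self.data.columns:
            raise LookupFailure(f"no column {name!r} in {self.kind} table")
        return self.data[name].to_numpy()


def _sniff_sep(path: Path) -> str:
    with path.open() as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty table")


def read_assay_table(path: str | Path, kind: AssayKind) -> AssayTable:
    """Read a CSV/TSV assay table; ``# key: value`` header lines become metadata."""
    path = Path(path)
    if kind not in ASSAY_SCHEMAS:
        raise InputError(f"unknown assay kind {kind!r}")
    metadata: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                metadata[key.strip()] = value.strip()
        else:
            body.append(line)
    if not any(l.strip() for l in body):
        raise FormatError(f"{path}: empty table")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep=_sniff_sep(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    return AssayTable(kind=kind, data=df, metadata=metadata)


def write_assay_table(table: AssayTable, path: str | Path, sep: str = ",") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in table.metadata.items():
            fh.write(f"# {key}: {value}\n")
        table.data.to_csv(fh, sep=sep, index=False)
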