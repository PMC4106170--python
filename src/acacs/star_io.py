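"""Reading and writing per-residue assigned chemical shifts.

The on-disk format is a minimal NMR-STAR-like dialect: one save frame per
protein, each containing a single ``loop_`` whose tagged columns give the
residue sequence number, residue name (three- or one-letter), atom label and
shift value in ppm.  Only this subset is supported; the full NMR-STAR
grammar is out of scope.

Atom labels found in real shift lists vary ("HA" vs "HA2"/"HA3" for glycine,
"H" vs "HN"), so parsing goes through a :class:`ShiftFileDialect` that maps
raw labels onto the four canonical backbone atom kinds.  Rows whose label
does not map are skipped and counted, never silently lost.

This module also parses the paired one-line sequence + secondary-structure
dialect: each record is an optional ``>`` header line, a single-line
sequence, and the aligned secondary-structure string on the next line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .alphabets import (
    AA3_TO_1,
    AA_SET,
    ATOMS,
    SS_SET,
    check_atom,
)

#: Default raw-label mapping.  Glycine's HA2/HA3 both count as alpha-proton
#: observations: both are alpha protons and dropping them would bias the
#: glycine cell.
DEFAULT_ATOM_MAP: dict[str, str] = {
    "N": "N15",
    "CA": "C13A",
    "HA": "H1A",
    "HA2": "H1A",
    "HA3": "H1A",
    "H": "H1N",
    "HN": "H1N",
}

#: Optional sanity ranges per atom kind, ppm (warn-only, never filtering).
SANITY_RANGES: dict[str, tuple[float, float]] = {
    "N15": (0.0, 250.0),
    "C13A": (0.0, 250.0),
    "H1A": (-2.0, 15.0),
    "H1N": (-2.0, 15.0),
}

_REQUIRED_TAGS = ("Seq_ID", "Comp_ID", "Atom_ID", "Val")


class StarParseError(ValueError):
    """A shift document is structurally malformed (e.g. a missing column)."""


@dataclass(frozen=True)
class ShiftObservation:
    """One assigned chemical shift: atom ``i`` of residue ``j`` at a position."""

    protein_id: str
    residue_index: int  # 1-based
    residue: str  # one-letter code
    atom: str  # one of N15, C13A, H1A, H1N
    shift_ppm: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(
                f"residue_index must be >= 1, got {self.residue_index}"
            )
        if self.residue not in AA_SET:
            raise ValueError(f"non-standard residue {self.residue!r}")
        check_atom(self.atom)


@dataclass(frozen=True)
class ShiftFileDialect:
    """How raw atom labels in a shift file map onto the four atom kinds."""

    atom_name_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ATOM_MAP))
    skip_unmapped: bool = True
    check_shift_ranges: bool = False

    def __post_init__(self) -> None:
        for raw, target in self.atom_name_map.items():
            if target not in ATOMS:
                raise ValueError(
                    f"dialect maps {raw!r} to unknown atom kind {target!r}"
                )


@dataclass
class ParseReport:
    """Per-row accounting: every raw loop row is accepted, skipped or errored."""

    accepted: int = 0
    skipped: int = 0
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def errored(self) -> int:
        return len(self.errors)

    @property
    def total_rows(self) -> int:
        return self.accepted + self.skipped + self.errored


@dataclass
class ParseResult:
    """Observations plus the row-level report; iterates as the observation list."""

    observations: list[ShiftObservation]
    report: ParseReport

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def __getitem__(self, item):
        return self.observations[item]


@dataclass(frozen=True)
class ProteinSample:
    """A protein with its residue string and aligned 3-state SS string."""

    protein_id: str
    sequence: str
    ss: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.ss):
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} != "
                f"secondary-structure length {len(self.ss)}"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")
        for pos, k in enumerate(self.ss, start=1):
            if k not in SS_SET:
                raise ValueError(
                    f"{self.protein_id}: secondary-structure symbol {k!r} at "
                    f"position {pos} is not one of H/E/C"
                )

    @property
    def L(self) -> int:
        return len(self.sequence)


def _normalise_residue(name: str) -> str:
    name = name.strip().upper()
    if len(name) == 3:
        try:
            return AA3_TO_1[name]
        except KeyError:
            raise ValueError(f"unknown residue name {name!r}") from None
    if len(name) == 1 and name in AA_SET:
        return name
    raise ValueError(f"unknown residue name {name!r}")


def parse_shift_file(path_or_text, dialect: ShiftFileDialect | None = None) -> ParseResult:
    """Parse a star-like shift document into :class:`ShiftObservation` rows.

    ``path_or_text`` may be a path, an open text handle, or the document
    itself (anything containing a newline is treated as text).  Rows with
    unmapped atom labels are skipped when ``dialect.skip_unmapped`` (counted
    in the report); malformed rows are recorded as row-level errors with
    their line number.  A loop missing a required column raises
    :class:`StarParseError`.
    """
    dialect = dialect or ShiftFileDialect()
    text = _read_text(path_or_text)
    result = ParseResult(observations=[], report=ParseReport())

    current_protein: str | None = None
    lines = text.splitlines()
    n = len(lines)
    idx = 0
    saw_loop = False
    while idx < n:
        line = lines[idx].strip()
        if line.startswith("save_") and len(line) > len("save_"):
            current_protein = line[len("save_"):]
            # allow a friendlier prefix in frame names
            if current_protein.startswith("shifts_"):
                current_protein = current_protein[len("shifts_"):]
            idx += 1
            continue
        if line.split()[:1] == ["_Entity.ID"]:
            current_protein = line.split(None, 1)[1].strip()
            idx += 1
            continue
        if line == "loop_":
            idx = _parse_loop(lines, idx + 1, current_protein, dialect, result)
            saw_loop = True
            continue
        idx += 1
    if not saw_loop:
        raise StarParseError("document contains no chemical-shift loop_")
    return result


def _parse_loop(
    lines: list[str],
    idx: int,
    protein_id: str | None,
    dialect: ShiftFileDialect,
    result: ParseResult,
) -> int:
    # collect column tags
    tags: list[str] = []
    n = len(lines)
    while idx < n:
        stripped = lines[idx].strip()
        if stripped.startswith("_"):
            tags.append(stripped.split()[0])
            idx += 1
        else:
            break
    columns = {tag.rsplit(".", 1)[-1]: pos for pos, tag in enumerate(tags)}
    for required in _REQUIRED_TAGS:
        if required not in columns:
            raise StarParseError(
                f"chemical-shift loop is missing required column {required!r}"
            )
    seq_c, comp_c, atom_c, val_c = (columns[t] for t in _REQUIRED_TAGS)
    entity_c = columns.get("Entity_ID")

    report = result.report
    while idx < n:
        raw = lines[idx].strip()
        lineno = idx + 1
        idx += 1
        if raw == "stop_":
            break
        if not raw or raw.startswith("#"):
            continue
        if raw.startswith(("save_", "loop_", "_")):
            idx -= 1
            break
        fields = raw.split()
        if len(fields) < len(tags):
            report.errors.append(f"line {lineno}: expected {len(tags)} fields, got {len(fields)}")
            continue
        raw_atom = fields[atom_c]
        mapped = dialect.atom_name_map.get(raw_atom.upper())
        if mapped is None:
            if dialect.skip_unmapped:
                report.skipped += 1
                continue
            report.errors.append(f"line {lineno}: unmapped atom label {raw_atom!r}")
            continue
        try:
            residue = _normalise_residue(fields[comp_c])
        except ValueError as exc:
            report.errors.append(f"line {lineno}: {exc}")
            continue
        try:
            seq_id = int(fields[seq_c])
            shift = float(fields[val_c])
        except ValueError:
            report.errors.append(
                f"line {lineno}: non-numeric residue index or shift value"
            )
            continue
        pid = fields[entity_c] if entity_c is not None else protein_id
        if pid is None:
            report.errors.append(f"line {lineno}: no protein id in scope")
            continue
        if dialect.check_shift_ranges:
            lo, hi = SANITY_RANGES[mapped]
            if not (lo <= shift <= hi):
                report.warnings.append(
                    f"line {lineno}: {mapped} shift {shift} ppm outside [{lo}, {hi}]"
                )
        try:
            obs = ShiftObservation(pid, seq_id, residue, mapped, shift)
        except ValueError as exc:
            report.errors.append(f"line {lineno}: {exc}")
            continue
        result.observations.append(obs)
        report.accepted += 1
    return idx


def write_shift_file(observations: list[ShiftObservation]) -> str:
    """Serialise observations to the star-like dialect, one frame per protein.

    Round-trips exactly through :func:`parse_shift_file`: shift values are
    written with full ``repr`` precision.
    """
    if not observations:
        raise ValueError("cannot write an empty observation list")
    _REVERSE_ATOM = {"N15": "N", "C13A": "CA", "H1A": "HA", "H1N": "H"}
    from .alphabets import AA1_TO_3

    by_protein: dict[str, list[ShiftObservation]] = {}
    for obs in observations:
        by_protein.setdefault(obs.protein_id, []).append(obs)

    out = io.StringIO()
    for pid, group in by_protein.items():
        out.write(f"save_shifts_{pid}\n")
        out.write("  loop_\n")
        for tag in _REQUIRED_TAGS:
            out.write(f"    _Atom_chem_shift.{tag}\n")
        for obs in group:
            out.write(
                f"    {obs.residue_index} {AA1_TO_3[obs.residue]} "
                f"{_REVERSE_ATOM[obs.atom]} {obs.shift_ppm!r}\n"
            )
        out.write("  stop_\n")
        out.write("save_\n\n")
    return out.getvalue()


def observations_to_tsv(observations: list[ShiftObservation]) -> str:
    """Tabular TSV export: protein_id, residue_index, residue, atom, shift_ppm."""
    rows = ["protein_id\tresidue_index\tresidue\tatom\tshift_ppm"]
    for obs in observations:
        rows.append(
            f"{obs.protein_id}\t{obs.residue_index}\t{obs.residue}\t"
            f"{obs.atom}\t{obs.shift_ppm!r}"
        )
    return "\n".join(rows) + "\n"


def parse_paired_sequence_ss(path_or_text) -> list[ProteinSample]:
    """Parse the paired one-line sequence + secondary-structure dialect.

    Each record is ``[>header]``, a single-line sequence, then its aligned
    H/E/C string on the next line.  Headerless records are numbered P1,
    P2, ...  A length mismatch or a bad SS symbol raises with the record
    name and position.
    """
    text = _read_text(path_or_text)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    samples: list[ProteinSample] = []
    idx = 0
    counter = 0
    while idx < len(lines):
        if lines[idx].startswith(">"):
            header = lines[idx][1:].strip()
            name = header.split()[0] if header else None
            idx += 1
        else:
            name = None
        if name is None:
            counter += 1
            name = f"P{counter}"
        if idx >= len(lines):
            raise ValueError(f"record {name}: missing sequence line")
        seq = lines[idx]
        if idx + 1 >= len(lines):
            raise ValueError(f"record {name}: missing secondary-structure line")
        ss = lines[idx + 1]
        idx += 2
        if len(seq) != len(ss):
            raise ValueError(
                f"record {name}: sequence length {len(seq)} does not match "
                f"secondary-structure length {len(ss)}"
            )
        samples.append(ProteinSample(name, seq.upper(), ss.upper()))
    return samples


def write_paired_sequence_ss(samples: list[ProteinSample]) -> str:
    """Inverse of :func:`parse_paired_sequence_ss` (always writes headers)."""
    chunks = []
    for s in samples:
        chunks.append(f">{s.protein_id}\n{s.sequence}\n{s.ss}\n")
    return "".join(chunks)


def _read_text(path_or_text) -> str:
    if hasattr(path_or_text, "read"):
        return path_or_text.read()
    text = str(path_or_text)
    if "\n" in text:
        return text
    with open(text, "r", encoding="utf-8") as handle:
        return handle.read()
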