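"""Readers for the three per-protein input formats.

A prediction run consumes, for every protein, a FASTA entry, a PSI-BLAST
ASCII PSSM (the ``-out_ascii_pssm`` dialect) and a PSIPRED ``.ss2``
(VFORMAT) secondary-structure probability file.  The parsers here load
those files into validated domain objects and enforce that the three
views describe the same sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: The 20 standard amino acids, in the fixed alphabetical one-letter order
#: used for all per-residue feature vectors in this package.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of a PSIPRED VFORMAT .ss2 file: coil, helix, strand.
SS2_FILE_COLUMNS = ("C", "H", "E")

#: Internal secondary-structure column convention: helix, strand, coil.
SS_ORDER = ("H", "E", "C")


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class ConsistencyError(ValueError):
    """Two files that must describe the same protein disagree."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus a validated amino-acid sequence.

    The sequence must consist solely of the 20 standard one-letter codes;
    entries with ambiguity codes (B, Z, X, U, ...) are rejected rather than
    imputed, mirroring the usual dataset pre-processing for this task.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in STANDARD_AA:
                raise ValidationError(
                    f"record {self.id!r}: non-standard residue {ch!r} at position {pos}"
                )

    @property
    def L(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMProfile:
    """An L x 20 integer log-odds matrix aligned to a sequence.

    ``columns`` records the amino-acid order of the score columns exactly as
    read from the file header; all lookups go through it rather than assuming
    an order.
    """

    record_id: str
    scores: np.ndarray  # (L, 20) int
    columns: str  # 20 amino-acid letters in file column order

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.record_id!r}: expected an L x 20 matrix, got {scores.shape}"
            )
        if sorted(self.columns) != sorted(STANDARD_AA):
            raise ValidationError(
                f"PSSM for {self.record_id!r}: column letters {self.columns!r} are not "
                "the 20 standard amino acids"
            )
        object.__setattr__(self, "scores", scores.astype(np.int64))

    def column_of(self, aa: str) -> int:
        """Index of amino acid ``aa`` in the score matrix."""
        return self.columns.index(aa)


@dataclass(frozen=True)
class SSProbMatrix:
    """Per-residue helix/strand/coil probabilities in (H, E, C) order."""

    record_id: str
    probs: np.ndarray  # (L, 3) float, columns (H, E, C)

    #: maximum deviation of a row sum from 1 tolerated for 3-decimal files
    ROW_SUM_TOL = 0.05

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValidationError(
                f"ss2 for {self.record_id!r}: expected an L x 3 matrix, got {probs.shape}"
            )
        if np.any(probs < 0.0) or np.any(probs > 1.0):
            raise ValidationError(
                f"ss2 for {self.record_id!r}: probability outside [0, 1]"
            )
        bad = np.abs(probs.sum(axis=1) - 1.0) > self.ROW_SUM_TOL
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"ss2 for {self.record_id!r}: row {row + 1} sums to "
                f"{probs[row].sum():.3f}, not 1"
            )
        object.__setattr__(self, "probs", probs)


def parse_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into validated records, order preserved.

    Sequences are upper-cased before validation.  An empty file raises
    :class:`FormatError`; a non-standard residue raises
    :class:`ValidationError` naming the record and position.
    """
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def parse_pssm(path: str | Path, record: ProteinRecord) -> PSSMProfile:
    """Read a PSI-BLAST ASCII PSSM and check it against ``record``.

    The standard ``-out_ascii_pssm`` layout has two header lines (the second
    naming 40 amino-acid columns), then one row per residue carrying the
    position index, the residue letter, 20 integer log-odds, 20 weighted
    percentages and two information-content columns.  Only the first 20
    (log-odds) columns are kept; the percentage block and trailing statistics
    are ignored.
    """
    lines = Path(path).read_text().splitlines()

    header_cols: str | None = None
    rows: list[list[int]] = []
    residues: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if header_cols is None:
            # header: 20 or 40 single-letter amino-acid column labels
            if len(tokens) in (20, 40) and all(
                t in STANDARD_AA and len(t) == 1 for t in tokens
            ):
                letters = tokens[:20]
                if sorted(letters) != sorted(STANDARD_AA):
                    raise FormatError(
                        f"{path}:{lineno}: header does not name the 20 standard "
                        "amino acids"
                    )
                header_cols = "".join(letters)
            continue
        if not tokens:
            break  # blank line after the matrix: trailing statistics follow
        if not tokens[0].isdigit():
            break
        if len(tokens) < 22:
            raise FormatError(
                f"{path}:{lineno}: expected at least 20 score columns, "
                f"found {len(tokens) - 2}"
            )
        residue = tokens[1]
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable score row") from exc
        residues.append(residue)
        rows.append(scores)

    if header_cols is None:
        raise FormatError(f"{path}: no PSSM column header found")
    if not rows:
        raise FormatError(f"{path}: no PSSM score rows found")
    if len(rows) != record.L:
        raise ConsistencyError(
            f"{path}: {len(rows)} PSSM rows but sequence {record.id!r} has "
            f"length {record.L}"
        )
    for m, (res, expected) in enumerate(zip(residues, record.sequence), start=1):
        if res != expected:
            raise ConsistencyError(
                f"{path}: residue column reads {res!r} at position {m} but "
                f"sequence {record.id!r} has {expected!r}"
            )
    return PSSMProfile(record_id=record.id, scores=np.array(rows), columns=header_cols)


def parse_ss2(path: str | Path, record: ProteinRecord) -> SSProbMatrix:
    """Read a PSIPRED VFORMAT ``.ss2`` file and check it against ``record``.

    File rows are ``index residue label pC pH pE`` (coil, helix, strand —
    see :data:`SS2_FILE_COLUMNS`); the returned matrix is re-ordered to the
    internal (H, E, C) convention of :data:`SS_ORDER`.
    """
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 6:
            raise FormatError(
                f"{path}:{lineno}: expected 6 columns "
                "(index residue label pC pH pE), found "
                f"{len(tokens)}"
            )
        try:
            p_c, p_h, p_e = (float(t) for t in tokens[3:6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable probability") from exc
        for p in (p_c, p_h, p_e):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: probability {p} outside [0, 1]"
                )
        residues.append(tokens[1])
        rows.append([p_h, p_e, p_c])  # file (C,H,E) -> internal (H,E,C)

    if not rows:
        raise FormatError(f"{path}: no ss2 rows found")
    if len(rows) != record.L:
        raise ConsistencyError(
            f"{path}: {len(rows)} ss2 rows but sequence {record.id!r} has "
            f"length {record.L}"
        )
    for m, (res, expected) in enumerate(zip(residues, record.sequence), start=1):
        if res != expected:
            raise ConsistencyError(
                f"{path}: residue column reads {res!r} at position {m} but "
                f"sequence {record.id!r} has {expected!r}"
            )
    return SSProbMatrix(record_id=record.id, probs=np.array(rows))


@dataclass
class TripleReport:
    """Per-record outcome of a FASTA / PSSM-dir / ss2-dir consistency check."""

    record_id: str
    ok: bool
    messages: list[str] = field(default_factory=list)


def validate_triples(
    fasta: str | Path, pssm_dir: str | Path, ss2_dir: str | Path
) -> list[TripleReport]:
    """Cross-check every FASTA record against ``<id>.pssm`` and ``<id>.ss2``.

    Short sequences (< 50 residues) produce a warning message only — the
    50-residue cut used when curating benchmark datasets is a dataset rule,
    not a parser rule.
    """
    reports: list[TripleReport] = []
    for record in parse_fasta(fasta):
        report = TripleReport(record_id=record.id, ok=True)
        if record.L < 50:
            report.messages.append(
                f"warning: sequence shorter than 50 residues (L={record.L})"
            )
        for suffix, parser, dirname in (
            (".pssm", parse_pssm, pssm_dir),
            (".ss2", parse_ss2, ss2_dir),
        ):
            candidate = Path(dirname) / f"{record.id}{suffix}"
            if not candidate.exists():
                report.ok = False
                report.messages.append(f"missing file: {candidate}")
                continue
            try:
                parser(candidate, record)
            except (FormatError, ConsistencyError, ValidationError) as exc:
                report.ok = False
                report.messages.append(str(exc))
        reports.append(report)
    return reports
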