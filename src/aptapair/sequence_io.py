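"""Readers and domain types for sequences, pair tables, PSSM profiles and disorder tracks.

File formats are 1-based where they carry coordinates (PSSM row indices,
disorder-track indices); everything is 0-based once in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
from Bio import SeqIO

from .errors import DimensionError, ParseError, ValidationError

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTU")
#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS)
#: Ambiguity / non-standard letters accepted only in permissive mode.
PROTEIN_EXTENDED = frozenset("BZXUO")
#: PSI-BLAST ASCII column order.
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA/RNA sequence. ``residues`` keeps the original letters (U allowed);
    :attr:`dna` maps U->T so DNA and RNA share one K-tuple property table."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise ValidationError(
                    f"invalid nucleotide {ch!r} in record {self.id!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def dna(self) -> str:
        return self.residues.replace("U", "T")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 standard amino acids.

    ``permissive`` additionally admits B/Z/X/U/O; encoders assign those letters a
    zero contribution.
    """

    id: str
    residues: str
    permissive: bool = False

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        allowed = PROTEIN_ALPHABET | PROTEIN_EXTENDED if self.permissive else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValidationError(
                    f"invalid amino acid {ch!r} in record {self.id!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionPair:
    aptamer_id: str
    protein_id: str
    label: int  # 1 = interacting, 0 = non-interacting


@dataclass
class PairDataset:
    """A labelled collection of aptamer-protein pairs with id-indexed sequence stores."""

    pairs: list[InteractionPair]
    aptamers: dict[str, NucleotideSequence]
    proteins: dict[str, ProteinSequence]

    def __post_init__(self):
        for p in self.pairs:
            if p.aptamer_id not in self.aptamers:
                raise ValidationError(f"pair references unknown aptamer {p.aptamer_id!r}")
            if p.protein_id not in self.proteins:
                raise ValidationError(f"pair references unknown protein {p.protein_id!r}")

    @property
    def n_pos(self) -> int:
        return sum(p.label == 1 for p in self.pairs)

    @property
    def n_neg(self) -> int:
        return sum(p.label == 0 for p in self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PSSMProfile:
    """L x 20 evolutionary score matrix in PSI-BLAST ASCII column order
    (A R N D C Q E G H I L K M F P S T W Y V)."""

    protein_id: str
    matrix: np.ndarray
    column_order: str = PSSM_COLUMN_ORDER

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 20:
            raise DimensionError(
                f"PSSM for {self.protein_id!r} must be L x 20, got {m.shape}"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def zero(cls, protein_id: str, length: int) -> "PSSMProfile":
        """Zero-matrix fallback used when a protein has no detectable homologs."""
        return cls(protein_id, np.zeros((length, 20)))

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue intrinsic-disorder scores in [0, 1]."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size < 1:
            raise DimensionError(f"disorder track for {self.protein_id!r} must be 1-D")
        if np.any((s < 0.0) | (s > 1.0)):
            bad = int(np.argmax((s < 0.0) | (s > 1.0)))
            raise ValidationError(
                f"disorder score {s[bad]} outside [0, 1] for {self.protein_id!r} "
                f"at residue {bad + 1}"
            )
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return self.scores.size


# ---------------------------------------------------------------------------
# readers


def read_fasta(
    path: str | Path,
    molecule: Literal["nucleotide", "protein"],
    permissive: bool = False,
) -> list[NucleotideSequence] | list[ProteinSequence]:
    """Read a FASTA file, uppercase and validate each record.

    Record order is preserved. Invalid residues raise :class:`ValidationError`
    naming the record and 1-based position.
    """
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}: expected FASTA header '>'", line=line_no)
                break
        else:
            raise ParseError(f"{path}: empty FASTA file", line=1)

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if molecule == "nucleotide":
            records.append(NucleotideSequence(rec.id, residues))
        elif molecule == "protein":
            records.append(ProteinSequence(rec.id, residues, permissive=permissive))
        else:
            raise ValueError(f"unknown molecule kind {molecule!r}")
    return records


def write_fasta(sequences: Iterable[NucleotideSequence | ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def _try_plain_pssm(lines: list[str]) -> np.ndarray | None:
    rows = []
    for ln in lines:
        parts = ln.split()
        if not parts:
            continue
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            return None
    if not rows:
        return None
    widths = {len(r) for r in rows}
    if widths != {20}:
        raise DimensionError(
            f"plain PSSM table must have 20 columns, found widths {sorted(widths)}"
        )
    return np.array(rows, dtype=float)


def read_pssm(path: str | Path, protein_id: str | None = None) -> PSSMProfile:
    """Read a PSSM from either the PSI-BLAST ``-out_ascii_pssm`` dialect or a
    plain whitespace L x 20 table; the dialect is auto-detected.

    Only the 20 log-odds columns are kept; PSI-BLAST's percentage columns and
    trailing statistics are ignored. Row indices in the file are 1-based.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()

    plain = _try_plain_pssm(lines)
    if plain is not None:
        return PSSMProfile(protein_id, plain)

    rows: list[list[float]] = []
    expected_index = 1
    for ln in lines:
        parts = ln.split()
        # data rows look like:  <idx> <residue> <20 log-odds> [<20 pct> <2 stats>]
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1 and parts[1].isalpha():
            if int(parts[0]) != expected_index:
                raise ParseError(f"{path}: non-consecutive PSSM row index {parts[0]}")
            try:
                scores = [float(x) for x in parts[2:22]]
            except ValueError as exc:
                raise ParseError(f"{path}: malformed PSSM row {parts[0]}") from exc
            rows.append(scores)
            expected_index += 1
    if not rows:
        raise ParseError(f"{path}: no PSSM data rows recognised in either dialect")
    return PSSMProfile(protein_id, np.array(rows, dtype=float))


def write_pssm_ascii(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ``-out_ascii_pssm`` dialect (log-odds half)."""
    cols = " ".join(f"{a:>3}" for a in profile.column_order)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(f"         {cols}\n")
        for i, row in enumerate(profile.matrix, start=1):
            vals = " ".join(f"{int(round(v)):>3d}" for v in row)
            pct = " ".join("  0" for _ in range(20))
            fh.write(f"{i:>5d} X  {vals} {pct}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3240\n")


def read_disorder_track(path: str | Path, protein_id: str | None = None) -> DisorderTrack:
    """Read per-residue disorder scores from one-score-per-line or
    ``<1-based index> <score>`` two-column text."""
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    scores = []
    for line_no, ln in enumerate(path.read_text().splitlines(), start=1):
        parts = ln.split()
        if not parts:
            continue
        try:
            value = float(parts[-1])
        except ValueError as exc:
            raise ParseError(f"{path}: malformed disorder line", line=line_no) from exc
        if not 0.0 <= value <= 1.0:
            raise ValidationError(
                f"{path}: disorder score {value} outside [0, 1] at line {line_no}"
            )
        scores.append(value)
    if not scores:
        raise ParseError(f"{path}: empty disorder track")
    return DisorderTrack(protein_id, np.array(scores))


def write_disorder_track(track: DisorderTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(track.scores, start=1):
            fh.write(f"{i}\t{s:.4f}\n")


_LABEL_MAP = {"1": 1, "0": 0, "positive": 1, "negative": 0}


def read_pair_table(
    path: str | Path,
    aptamers: Mapping[str, NucleotideSequence],
    proteins: Mapping[str, ProteinSequence],
) -> PairDataset:
    """Read a TSV with header ``aptamer_id  protein_id  label``
    (label 1/0 or positive/negative) and resolve ids against the stores."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty pair table")
    header = lines[0].split("\t")
    if header[:3] != ["aptamer_id", "protein_id", "label"]:
        raise ParseError(f"{path}: expected header 'aptamer_id\\tprotein_id\\tlabel'", line=1)
    pairs = []
    for line_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: expected 3 tab-separated fields", line=line_no)
        label = _LABEL_MAP.get(parts[2].strip().lower())
        if label is None:
            raise ValidationError(f"{path}: unknown label {parts[2]!r} at line {line_no}")
        pairs.append(InteractionPair(parts[0], parts[1], label))
    dataset = PairDataset(pairs, dict(aptamers), dict(proteins))
    assert dataset.n_pos + dataset.n_neg == len(dataset.pairs)
    return dataset


def write_pair_table(dataset: PairDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("aptamer_id\tprotein_id\tlabel\n")
        for p in dataset.pairs:
            fh.write(f"{p.aptamer_id}\t{p.protein_id}\t{p.label}\n")


def corpus_min_length(sequences: Iterable[NucleotideSequence | ProteinSequence]) -> int:
    """Minimum residue count over a non-empty sequence collection.

    This statistic parameterizes the encoders: the pseudo K-tuple lag default is
    ``L_min - K`` over the aptamer corpus, and the disorder autocovariance uses
    ``L_min - 1`` lags over the protein corpus.
    """
    lengths = [len(s) for s in sequences]
    if not lengths:
        raise ValidationError("cannot take the minimum length of an empty collection")
    return min(lengths)
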