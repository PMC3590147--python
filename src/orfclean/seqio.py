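"""Sequence input/output and run parameters.

Ortholog sets arrive as one FASTA file per set, holding either amino-acid
sequences or indel-free, in-frame nucleotide sequences.  Nucleotide input is
translated to protein for analysis and corrections are back-translated
afterwards, with inferred-missing residues ("X") rendered as "NNN" triplets.

All sequence coordinates in this package are 1-based inclusive (BLAST
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Valid residue alphabet: the 20 standard amino acids plus "X" (missing /
#: ambiguous data).
ALPHABET = frozenset(AMINO_ACIDS + "X")

FIVE_PRIME = "5prime"
THREE_PRIME = "3prime"
ENDS = (FIVE_PRIME, THREE_PRIME)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class CorrectionParams:
    """Tunable thresholds of the correction algorithm.

    Parameters
    ----------
    trim5_min, trim3_min:
        Minimum consensus overhang (in AA) at the 5'/3' end for a trim or
        pad correction to fire (CLI flags ``-a``/``-b``; defaults 5 and 20).
    min_identity:
        Minimum fraction of identical aligned columns for a reference to
        participate in correction (CLI flag ``-d``; default 0.9).
    evalue:
        Alignment expectation cutoff (CLI flag ``-e``; default 1e-5).
    chimera5_min, chimera3_min:
        Minimum consensus overhang, required of *both* query and reference,
        for an end to be called chimeric (CLI flags ``-f``/``-g``; defaults
        10 and 30).  Chimera thresholds dominate the trim/pad thresholds.
    max_targets:
        Report cap passed to the external aligner (CLI flag ``-j``).
    max_comparisons:
        Maximum query-reference comparisons used per query (CLI flag ``-k``).
    max_hits:
        Maximum stored hits per query (CLI flag ``-l``).  References 100%
        identical to the query are always retained preferentially within
        this cap.
    min_refs:
        Minimum number of qualifying references required to attempt
        correction of a query (default 5).
    consensus_frac:
        Minimum fraction of comparisons that must agree on an end-overhang
        pair for it to become a consensus candidate (default 0.33).
    bimodal_frac:
        Fraction of correctable queries proposing both trims and pads at one
        end that marks the set as bimodal there, suppressing trims in favor
        of the longer form (default 0.40).
    """

    trim5_min: int = 5
    trim3_min: int = 20
    min_identity: float = 0.9
    evalue: float = 1e-5
    chimera5_min: int = 10
    chimera3_min: int = 30
    max_targets: int = 5
    max_comparisons: int = 1000
    max_hits: int = 1000
    min_refs: int = 5
    consensus_frac: float = 0.33
    bimodal_frac: float = 0.40

    def __post_init__(self) -> None:
        for name in ("trim5_min", "trim3_min", "chimera5_min", "chimera3_min",
                     "max_targets", "max_comparisons", "max_hits", "min_refs"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if not 0 < self.consensus_frac <= 1:
            raise ValueError("consensus_frac must be in (0, 1]")
        if not 0 < self.bimodal_frac <= 0.5:
            raise ValueError("bimodal_frac must be in (0, 0.5]")
        if self.chimera5_min < self.trim5_min or self.chimera3_min < self.trim3_min:
            raise ValueError("chimera thresholds must dominate trim thresholds "
                             "(chimera5_min >= trim5_min, chimera3_min >= trim3_min)")

    def trim_threshold(self, end: str) -> int:
        return self.trim5_min if end == FIVE_PRIME else self.trim3_min

    def chimera_threshold(self, end: str) -> int:
        return self.chimera5_min if end == FIVE_PRIME else self.chimera3_min


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a unique identifier.

    ``residues`` may contain "X" denoting missing data; positions are
    1-based.  ``origin`` records whether the sequence was read as protein or
    translated from nucleotides.
    """

    id: str
    residues: str
    origin: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence id must be non-empty")
        if not self.residues:
            raise DataError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise DataError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrthologSet:
    """A named collection of sequences assumed orthologous, with conserved
    true start and stop positions."""

    name: str
    members: tuple[ProteinSequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        seen: set[str] = set()
        for m in self.members:
            if m.id in seen:
                raise DataError(f"duplicate sequence id {m.id!r} in set {self.name!r}")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.members)

    def get(self, seq_id: str) -> ProteinSequence:
        for m in self.members:
            if m.id == seq_id:
                return m
        raise KeyError(seq_id)

    def ids(self) -> list[str]:
        return [m.id for m in self.members]


def _normalize_residues(seq_id: str, raw: str) -> str:
    s = raw.upper()
    if s.endswith("*"):
        warnings.warn(f"stripping terminal stop symbol '*' from {seq_id!r}")
        s = s[:-1]
    if "*" in s:
        raise DataError(f"internal stop symbol '*' in sequence {seq_id!r}")
    return s


def read_ortholog_set(path: str | Path) -> OrthologSet:
    """Read one ortholog set from a protein FASTA file.

    Ids are the first whitespace token of each header; residues are
    uppercased; a single terminal "*" is stripped with a warning; record
    order is preserved.  Empty files and duplicate ids are errors.
    """
    path = Path(path)
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        members.append(ProteinSequence(rec.id, _normalize_residues(rec.id, str(rec.seq))))
    if not members:
        raise DataError(f"no FASTA records in {path}")
    return OrthologSet(path.stem, members)


def write_ortholog_set(oset: OrthologSet, path: str | Path, width: int = 60) -> None:
    """Write an ortholog set as wrapped FASTA, preserving member order."""
    with open(path, "w") as fh:
        for m in oset.members:
            fh.write(f">{m.id}\n")
            for i in range(0, len(m.residues), width):
                fh.write(m.residues[i:i + width] + "\n")


def translate_nt(nt_seq: str, seq_id: str = "seq") -> ProteinSequence:
    """Translate an indel-free, in-frame nucleotide ORF to protein.

    Frame 1, standard genetic code; a terminal stop codon is dropped;
    ambiguous codons (any N) translate to X.  Length not divisible by 3 or
    an internal stop codon is an error.
    """
    nt = nt_seq.upper().replace("U", "T")
    if len(nt) % 3 != 0:
        raise DataError(
            f"nucleotide sequence {seq_id!r} length {len(nt)} is not a multiple "
            "of 3; input must be in-frame and free of indels")
    if set(nt) - set("ACGTN"):
        raise DataError(f"invalid nucleotide characters in {seq_id!r}")
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise DataError(f"internal stop codon in {seq_id!r}")
    if not aa:
        raise DataError(f"nucleotide sequence {seq_id!r} encodes no residues")
    return ProteinSequence(seq_id, aa, origin="translated-nucleotide")


def backtranslate_correction(
    original_nt: str,
    corrected_aa: ProteinSequence,
    trim5: int = 0,
    trim3: int = 0,
    pad5: int = 0,
    pad3: int = 0,
    retain_stop: bool = False,
) -> str:
    """Project a protein-level correction back onto the original ORF.

    Removes 3 nt per trimmed residue from the corresponding end and renders
    each padded "X" as "NNN".  If the original ORF carried a terminal stop
    codon it is dropped by default (``retain_stop=False``); with
    ``retain_stop=True`` it is re-appended after any 3' padding.
    """
    nt = original_nt.upper().replace("U", "T")
    aa0 = translate_nt(nt, corrected_aa.id)
    has_stop = len(nt) == 3 * (len(aa0) + 1)
    body = nt[:len(nt) - 3] if has_stop else nt
    expected = len(aa0) - trim5 - trim3 + pad5 + pad3
    if expected != len(corrected_aa):
        raise DataError(
            f"inconsistent correction bookkeeping for {corrected_aa.id!r}: "
            f"{len(aa0)} AA - trims {trim5}+{trim3} + pads {pad5}+{pad3} "
            f"!= corrected length {len(corrected_aa)}")
    if trim5 + trim3 >= len(aa0):
        raise DataError(f"trims consume entire sequence {corrected_aa.id!r}")
    core = body[3 * trim5: len(body) - 3 * trim3]
    out = "N" * (3 * pad5) + core + "N" * (3 * pad3)
    if retain_stop and has_stop:
        out += nt[-3:]
    return out
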