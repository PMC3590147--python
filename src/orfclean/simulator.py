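"""Synthetic ortholog families and ground-truthed annotation errors.

The generator emulates the validation substrate the corrector is designed
for: families of closely related orthologs with exactly conserved start and
stop positions that diverge by substitutions only.  Into such families it
injects the three annotation-inconsistency classes at per-sequence-end
rates, logging every change so corrections can be scored against ground
truth:

* overextension — unrelated residues prepended/appended to an end,
* truncation    — genuine terminal residues deleted,
* chimera       — genuine terminal residues replaced by unrelated sequence.

Error lengths are a per-type minimum plus a Poisson-distributed excess.
Added residues come from a donor pool unrelated to the analyzed families
(segments are additionally reversed, destroying any residual homology).
Only sequences that retain at least ``min_refs`` unmodified orthologs in
their family are altered, and each sequence end receives at most one error
per replicate, drawn in the fixed order chimera, overextension, truncation.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    ENDS,
    FIVE_PRIME,
    THREE_PRIME,
    CorrectionParams,
    OrthologSet,
    ProteinSequence,
)

ERR_CHIMERA = "chimera"
ERR_OVEREXTENSION = "overextension"
ERR_TRUNCATION = "truncation"
#: Fixed draw order; at most one error per sequence end.
ERROR_TYPES = (ERR_CHIMERA, ERR_OVEREXTENSION, ERR_TRUNCATION)


def _default_min_len() -> dict[tuple[str, str], int]:
    # shortest errors detectable under the default thresholds
    return {
        (ERR_OVEREXTENSION, FIVE_PRIME): 5,
        (ERR_TRUNCATION, FIVE_PRIME): 5,
        (ERR_OVEREXTENSION, THREE_PRIME): 20,
        (ERR_TRUNCATION, THREE_PRIME): 20,
        (ERR_CHIMERA, FIVE_PRIME): 10,
        (ERR_CHIMERA, THREE_PRIME): 30,
    }


@dataclass(frozen=True)
class SimulationProfile:
    """Error-injection design for one experiment.

    Default rates are per sequence end: 5% for 5' overextensions and
    truncations, 1% for the 3' equivalents, and 0.1% for chimeras at either
    end — deliberately far above rates seen in real annotations, so that
    sensitivity can be estimated.  ``min_len`` gives the per-(type, end)
    minimum error length in AA; ``poisson_lambda`` the mean excess above it.
    """

    rate_over5: float = 0.05
    rate_trunc5: float = 0.05
    rate_over3: float = 0.01
    rate_trunc3: float = 0.01
    rate_chim5: float = 0.001
    rate_chim3: float = 0.001
    min_len: dict[tuple[str, str], int] = field(default_factory=_default_min_len)
    poisson_lambda: float = 5.0
    seed: int | None = None
    replicates: int = 50

    def __post_init__(self) -> None:
        for name in ("rate_over5", "rate_trunc5", "rate_over3", "rate_trunc3",
                     "rate_chim5", "rate_chim3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.poisson_lambda < 0:
            raise ValueError("poisson_lambda must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for key, v in self.min_len.items():
            if v < 1:
                raise ValueError(f"min_len[{key}] must be >= 1")

    def rate(self, error_type: str, end: str) -> float:
        table = {
            (ERR_OVEREXTENSION, FIVE_PRIME): self.rate_over5,
            (ERR_TRUNCATION, FIVE_PRIME): self.rate_trunc5,
            (ERR_OVEREXTENSION, THREE_PRIME): self.rate_over3,
            (ERR_TRUNCATION, THREE_PRIME): self.rate_trunc3,
            (ERR_CHIMERA, FIVE_PRIME): self.rate_chim5,
            (ERR_CHIMERA, THREE_PRIME): self.rate_chim3,
        }
        return table[(error_type, end)]


@dataclass(frozen=True)
class SimulationRecord:
    """Ground truth for one injected error.

    ``removed_seq`` stores the deleted residues themselves so the original
    dataset can be reconstructed exactly from the modified one.
    """

    family: str
    seq_id: str
    end: str
    error_type: str
    removed: int
    added: int
    donor_id: str | None = None
    removed_seq: str = ""

    def __post_init__(self) -> None:
        if self.error_type == ERR_OVEREXTENSION and not (
                self.removed == 0 and self.added >= 1):
            raise ValueError("overextension record requires removed=0, added>=1")
        if self.error_type == ERR_TRUNCATION and not (
                self.added == 0 and self.removed >= 1):
            raise ValueError("truncation record requires added=0, removed>=1")
        if self.error_type == ERR_CHIMERA and not (
                self.removed >= 1 and self.added >= 1):
            raise ValueError("chimera record requires removed>=1 and added>=1")
        if len(self.removed_seq) != self.removed:
            raise ValueError("removed_seq length must equal removed count")


def generate_family(
    name: str,
    n_seqs: int,
    length: int,
    identity_target: float,
    rng: np.random.Generator,
) -> OrthologSet:
    """Simulate one family of orthologs with exactly conserved termini.

    A random ancestor beginning with M is drawn uniformly over the 20
    amino acids; each descendant substitutes non-initial positions
    independently at rate 1 - sqrt(identity_target), so the expected
    pairwise identity between descendants is approximately
    ``identity_target``.  All members share length and true start/stop
    positions exactly.
    """
    if n_seqs < 2:
        raise ValueError("a family needs at least 2 sequences")
    if not 0.5 <= identity_target <= 1.0:
        raise ValueError("identity_target must be in [0.5, 1.0]")
    if length < 2:
        raise ValueError("length must be >= 2")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    anc = rng.integers(0, 20, size=length)
    anc[0] = AMINO_ACIDS.index("M")
    mu = 1.0 - math.sqrt(identity_target)
    members = []
    for i in range(n_seqs):
        seq = anc.copy()
        hit = np.flatnonzero(rng.random(length) < mu)
        hit = hit[hit > 0]  # conserved initiator M
        if hit.size:
            # substitute to a uniformly random *different* residue
            seq[hit] = (seq[hit] + rng.integers(1, 20, size=hit.size)) % 20
        residues = aa[seq].tobytes().decode()
        members.append(ProteinSequence(f"{name}_s{i:03d}", residues))
    return OrthologSet(name, members)


def generate_dataset(
    n_families: int,
    n_seqs: int,
    length: int,
    identity_target: float,
    rng: np.random.Generator,
    name_prefix: str = "fam",
) -> list[OrthologSet]:
    """Simulate a dataset of independent ortholog families."""
    return [
        generate_family(f"{name_prefix}{i:03d}", n_seqs, length,
                        identity_target, rng)
        for i in range(n_families)
    ]


def generate_donor_pool(
    n_seqs: int, length: int, rng: np.random.Generator,
    name_prefix: str = "donor",
) -> list[ProteinSequence]:
    """Unrelated random sequences serving as sources of inserted residues."""
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    return [
        ProteinSequence(f"{name_prefix}{i:03d}",
                        aa[rng.integers(0, 20, size=length)].tobytes().decode())
        for i in range(n_seqs)
    ]


def sample_error_length(min_len: int, lam: float, rng: np.random.Generator) -> int:
    """Error length: a hard minimum plus a Poisson-distributed excess."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return int(min_len + rng.poisson(lam))


def _donor_segment(
    donor_pool: list[ProteinSequence], length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """A random donor segment, reversed to destroy residual homology."""
    donor = donor_pool[int(rng.integers(0, len(donor_pool)))]
    if len(donor) <= length:
        seg = donor.residues
    else:
        start = int(rng.integers(0, len(donor) - length + 1))
        seg = donor.residues[start:start + length]
    return seg[::-1], donor.id


def _apply_end_error(
    residues: str,
    end: str,
    error_type: str,
    profile: SimulationProfile,
    donor_pool: list[ProteinSequence],
    rng: np.random.Generator,
) -> tuple[str, dict] | None:
    """Mutate one end; returns (new_residues, record fields) or None if the
    sequence is too short to sustain the error."""
    min_len = profile.min_len[(error_type, end)]
    removed = added = 0
    removed_seq = ""
    donor_id = None
    if error_type in (ERR_TRUNCATION, ERR_CHIMERA):
        removed = sample_error_length(min_len, profile.poisson_lambda, rng)
        if removed >= len(residues) - 10:
            return None
    if error_type in (ERR_OVEREXTENSION, ERR_CHIMERA):
        added = sample_error_length(min_len, profile.poisson_lambda, rng)
        seg, donor_id = _donor_segment(donor_pool, added, rng)
        added = len(seg)
    if end == FIVE_PRIME:
        if removed:
            removed_seq = residues[:removed]
            residues = residues[removed:]
        if added:
            residues = seg + residues
    else:
        if removed:
            removed_seq = residues[len(residues) - removed:]
            residues = residues[:len(residues) - removed]
        if added:
            residues = residues + seg
    return residues, dict(end=end, error_type=error_type, removed=removed,
                          added=added, donor_id=donor_id,
                          removed_seq=removed_seq)


def inject_errors(
    dataset: list[OrthologSet],
    profile: SimulationProfile,
    params: CorrectionParams,
    donor_pool: list[ProteinSequence],
    rng: np.random.Generator,
) -> tuple[list[OrthologSet], list[SimulationRecord]]:
    """Inject annotation errors into a dataset, respecting correctability.

    Per family at most ``len(family) - params.min_refs`` sequences are
    altered, so every altered sequence keeps at least ``min_refs``
    unmodified orthologs.  Families too small to satisfy the constraint are
    skipped with a warning.  Every change is logged as a SimulationRecord.
    """
    dataset_ids = {m.id for fam in dataset for m in fam}
    if dataset_ids & {d.id for d in donor_pool}:
        raise ValueError("donor pool must be disjoint from the dataset")
    if not donor_pool:
        raise ValueError("donor pool is empty")
    modified: list[OrthologSet] = []
    records: list[SimulationRecord] = []
    for fam in dataset:
        budget = len(fam) - params.min_refs
        if budget <= 0:
            warnings.warn(
                f"family {fam.name!r} has {len(fam)} members; cannot keep "
                f"{params.min_refs} unmodified orthologs — skipped")
            modified.append(fam)
            continue
        altered = 0
        new_members = []
        for m in fam.members:
            chosen: list[str | None] = []
            for end in ENDS:
                pick = None
                for etype in ERROR_TYPES:
                    if rng.random() < profile.rate(etype, end):
                        pick = etype
                        break
                chosen.append(pick)
            if all(p is None for p in chosen) or altered >= budget:
                new_members.append(m)
                continue
            residues = m.residues
            seq_records = []
            applied = False
            for end, etype in zip(ENDS, chosen):
                if etype is None:
                    continue
                out = _apply_end_error(residues, end, etype, profile,
                                       donor_pool, rng)
                if out is None:
                    continue
                residues, fields = out
                seq_records.append(SimulationRecord(
                    family=fam.name, seq_id=m.id, **fields))
                applied = True
            if applied:
                altered += 1
                new_members.append(replace(m, residues=residues))
                records.extend(seq_records)
            else:
                new_members.append(m)
        modified.append(OrthologSet(fam.name, new_members))
    return modified, records


def invert_errors(
    modified: list[OrthologSet], records: list[SimulationRecord]
) -> list[OrthologSet]:
    """Undo injected errors using their ground-truth records (applied in
    reverse order), reconstructing the original dataset exactly."""
    seqs = {fam.name: {m.id: m.residues for m in fam} for fam in modified}
    for rec in reversed(records):
        residues = seqs[rec.family][rec.seq_id]
        if rec.end == FIVE_PRIME:
            residues = rec.removed_seq + residues[rec.added:]
        else:
            residues = residues[:len(residues) - rec.added] + rec.removed_seq
        seqs[rec.family][rec.seq_id] = residues
    return [
        OrthologSet(fam.name, [replace(m, residues=seqs[fam.name][m.id])
                               for m in fam])
        for fam in modified
    ]


TRUTH_COLUMNS = ["family", "seq_id", "end", "error_type", "removed", "added",
                 "donor_id", "removed_seq"]


def write_truth(records: list[SimulationRecord], path: str | Path) -> None:
    """Write ground-truth records as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for r in records:
            w.writerow([r.family, r.seq_id, r.end, r.error_type, r.removed,
                        r.added, r.donor_id or "NA", r.removed_seq or "-"])


def read_truth(path: str | Path) -> list[SimulationRecord]:
    """Read ground-truth records written by ``write_truth``."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(SimulationRecord(
                family=row["family"], seq_id=row["seq_id"], end=row["end"],
                error_type=row["error_type"], removed=int(row["removed"]),
                added=int(row["added"]),
                donor_id=None if row["donor_id"] == "NA" else row["donor_id"],
                removed_seq="" if row["removed_seq"] == "-" else row["removed_seq"],
            ))
    return records
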