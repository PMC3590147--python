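"""Run orchestration over directories of ortholog sets, the end-to-end
simulation experiment, and supermatrix concatenation.

Ortholog sets are independent work units: correction runs are
embarrassingly parallel across sets and are merged in deterministic
(sorted file name) order, so results are identical for any thread count.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .align import BackendUnavailableError, require_backend
from .corrector import (
    KIND_OK,
    KIND_UNCORRECTABLE,
    CorrectionCall,
    correct_set,
    write_correction_report,
)
from .evaluator import Metrics, metrics_frame, score_corrections, write_metrics
from .seqio import (
    CorrectionParams,
    DataError,
    OrthologSet,
    ProteinSequence,
    backtranslate_correction,
    read_ortholog_set,
    translate_nt,
    write_ortholog_set,
)
from .simulator import (
    SimulationProfile,
    generate_dataset,
    generate_donor_pool,
    inject_errors,
    read_truth,
    write_truth,
)

logger = logging.getLogger("orfclean")

FASTA_SUFFIXES = {".fa", ".faa", ".fasta", ".fna"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one correction run."""

    input_dir: Path
    output_dir: Path
    params: CorrectionParams = field(default_factory=CorrectionParams)
    backend: str = "sw"
    threads: int = 1
    nucleotide: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


def _fasta_files(input_dir: Path) -> list[Path]:
    files = sorted(p for p in Path(input_dir).iterdir()
                   if p.suffix.lower() in FASTA_SUFFIXES)
    if not files:
        raise DataError(f"no FASTA files found in {input_dir}")
    return files


def _read_nt_set(path: Path) -> tuple[OrthologSet, dict[str, str]]:
    nt_by_id: dict[str, str] = {}
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in nt_by_id:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        nt = str(rec.seq).upper()
        nt_by_id[rec.id] = nt
        members.append(translate_nt(nt, rec.id))
    if not members:
        raise DataError(f"no FASTA records in {path}")
    return OrthologSet(path.stem, members), nt_by_id


def _write_nt_set(
    oset: OrthologSet,
    calls: list[CorrectionCall],
    nt_by_id: dict[str, str],
    path: Path,
) -> None:
    by_seq: dict[str, dict[str, CorrectionCall]] = {}
    for c in calls:
        by_seq.setdefault(c.seq_id, {})[c.end] = c
    with open(path, "w") as fh:
        for m in oset.members:
            c5 = by_seq[m.id]["5prime"]
            c3 = by_seq[m.id]["3prime"]
            nt = backtranslate_correction(
                nt_by_id[m.id], m, trim5=c5.trim, trim3=c3.trim,
                pad5=c5.pad, pad3=c3.pad)
            fh.write(f">{m.id}\n")
            for i in range(0, len(nt), 60):
                fh.write(nt[i:i + 60] + "\n")


def _correct_one_file(args: tuple) -> tuple[str, int, int]:
    """Worker: correct a single ortholog-set file and write its outputs."""
    path_str, out_dir_str, params, backend, nucleotide = args
    path = Path(path_str)
    out_dir = Path(out_dir_str)
    if nucleotide:
        oset, nt_by_id = _read_nt_set(path)
    else:
        oset = read_ortholog_set(path)
        nt_by_id = None
    corrected, calls = correct_set(oset, params, backend=backend)
    out_fasta = out_dir / path.name
    if nucleotide:
        _write_nt_set(corrected, calls, nt_by_id, out_fasta)
    else:
        write_ortholog_set(corrected, out_fasta)
    write_correction_report(calls, out_dir / f"{path.stem}.report.tsv")
    n_corrected = sum(1 for c in calls
                      if c.kind not in (KIND_OK, KIND_UNCORRECTABLE))
    n_uncorrectable = sum(1 for c in calls if c.kind == KIND_UNCORRECTABLE)
    return path.name, n_corrected, n_uncorrectable


def run_correct(config: RunConfig) -> list[tuple[str, int, int]]:
    """Correct every ortholog-set FASTA in ``input_dir``.

    Writes, per set, a corrected FASTA and a TSV correction report, plus a
    run-level log recording every parameter needed to reproduce the run.
    Returns (file name, corrected-end count, uncorrectable-end count)
    per set in name order.
    """
    require_backend(config.backend)
    files = _fasta_files(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    work = [(str(p), str(out_dir), config.params, config.backend,
             config.nucleotide) for p in files]
    if config.threads > 1:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(_correct_one_file, work))
    else:
        results = [_correct_one_file(w) for w in work]
    results.sort(key=lambda r: r[0])
    _write_run_log(out_dir / "run.log", config, results)
    return results


def _write_run_log(path: Path, config: RunConfig,
                   results: list[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        fh.write(f"orfclean version\t{__version__}\n")
        fh.write(f"input_dir\t{config.input_dir}\n")
        fh.write(f"output_dir\t{config.output_dir}\n")
        fh.write(f"backend\t{config.backend}\n")
        fh.write(f"threads\t{config.threads}\n")
        fh.write(f"nucleotide\t{config.nucleotide}\n")
        fh.write(f"seed\t{config.seed}\n")
        for f in dataclasses.fields(config.params):
            fh.write(f"param.{f.name}\t{getattr(config.params, f.name)}\n")
        fh.write("set\tcorrected_ends\tuncorrectable_ends\n")
        for name, n_corr, n_unc in results:
            fh.write(f"{name}\t{n_corr}\t{n_unc}\n")


# ---------------------------------------------------------------------------
# simulation experiment
# ---------------------------------------------------------------------------

def simulate_replicates(
    out_dir: Path,
    profile: SimulationProfile,
    params: CorrectionParams,
    n_families: int = 13,
    seqs_per_family: int = 16,
    length: int = 150,
    identity_target: float = 0.95,
    donor_pool_size: int = 20,
) -> None:
    """Write ``replicates`` simulated datasets under ``out_dir``.

    Layout: ``rep_000/<family>.faa`` plus ``rep_000/truth.tsv``.  The base
    (error-free) families are also written under ``base/``.
    """
    rng = np.random.default_rng(profile.seed)
    base = generate_dataset(n_families, seqs_per_family, length,
                            identity_target, rng)
    donors = generate_donor_pool(donor_pool_size, length, rng)
    out_dir = Path(out_dir)
    base_dir = out_dir / "base"
    base_dir.mkdir(parents=True, exist_ok=True)
    for fam in base:
        write_ortholog_set(fam, base_dir / f"{fam.name}.faa")
    for rep in range(profile.replicates):
        rep_dir = out_dir / f"rep_{rep:03d}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        modified, records = inject_errors(base, profile, params, donors, rng)
        for fam in modified:
            write_ortholog_set(fam, rep_dir / f"{fam.name}.faa")
        write_truth(records, rep_dir / "truth.tsv")


def evaluate_replicates(
    sim_dir: Path,
    out_path: Path,
    params: CorrectionParams,
    backend: str = "sw",
    threads: int = 1,
) -> pd.DataFrame:
    """Correct and score every ``rep_*`` directory under ``sim_dir``."""
    sim_dir = Path(sim_dir)
    rep_dirs = sorted(p for p in sim_dir.iterdir()
                      if p.is_dir() and p.name.startswith("rep_"))
    if not rep_dirs:
        raise DataError(f"no rep_* directories under {sim_dir}")
    require_backend(backend)
    per_rep = []
    for rep_dir in rep_dirs:
        truth = read_truth(rep_dir / "truth.tsv")
        calls: list[CorrectionCall] = []
        for fasta in _fasta_files(rep_dir):
            oset = read_ortholog_set(fasta)
            _corr, set_calls = correct_set(oset, params, backend=backend)
            calls.extend(set_calls)
        per_rep.append(score_corrections(calls, truth))
    frame = metrics_frame(per_rep)
    write_metrics(frame, out_path)
    return frame


def run_simulate_evaluate(
    profile: SimulationProfile,
    params: CorrectionParams,
    n_families: int = 13,
    seqs_per_family: int = 16,
    length: int = 150,
    identity_target: float = 0.95,
    donor_pool_size: int = 20,
    backend: str = "sw",
    mismatch_as_fp: bool = True,
) -> tuple[pd.DataFrame, list[dict[tuple[str, str], Metrics]]]:
    """The full in-memory experiment: generate families, inject errors at
    the profile rates, correct every replicate, score against ground truth
    and pool across replicates.

    Returns the pooled metrics table and the per-replicate metrics.
    """
    require_backend(backend)
    rng = np.random.default_rng(profile.seed)
    base = generate_dataset(n_families, seqs_per_family, length,
                            identity_target, rng)
    donors = generate_donor_pool(donor_pool_size, length, rng)
    per_rep = []
    for _rep in range(profile.replicates):
        modified, records = inject_errors(base, profile, params, donors, rng)
        calls: list[CorrectionCall] = []
        for fam in modified:
            _corr, set_calls = correct_set(fam, params, backend=backend)
            calls.extend(set_calls)
        per_rep.append(score_corrections(calls, records,
                                         mismatch_as_fp=mismatch_as_fp))
    return metrics_frame(per_rep), per_rep


# ---------------------------------------------------------------------------
# supermatrix concatenation
# ---------------------------------------------------------------------------

def concatenate_alignments(
    aligned_sets: list[OrthologSet],
    taxa: list[str] | None = None,
    min_col_occupancy: float = 0.0,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate pre-aligned ortholog sets into a per-taxon supermatrix.

    Within each set all sequences must share one alignment length and each
    sequence id names a taxon (a taxon may appear at most once per set).
    Taxa missing from a set receive an all-"X" block of that set's length.
    Columns whose fraction of non-X, non-gap characters falls below
    ``min_col_occupancy`` are removed; partition boundaries (1-based
    inclusive) are reported after column filtering.  Partitions whose
    columns are entirely filtered out are dropped from the table.
    """
    if not 0.0 <= min_col_occupancy <= 1.0:
        raise ValueError("min_col_occupancy must be in [0, 1]")
    if taxa is None:
        seen = []
        for s in aligned_sets:
            for m in s:
                if m.id not in seen:
                    seen.append(m.id)
        taxa = seen
    set_lengths = []
    for s in aligned_sets:
        lengths = {len(m) for m in s}
        if len(lengths) != 1:
            raise DataError(f"set {s.name!r} members differ in aligned length")
        ids = s.ids()
        if len(ids) != len(set(ids)):
            raise DataError(f"a taxon appears twice in set {s.name!r}")
        set_lengths.append(lengths.pop())

    rows = {t: [] for t in taxa}
    col_set_index: list[int] = []
    for idx, (s, L) in enumerate(zip(aligned_sets, set_lengths)):
        by_taxon = {m.id: m.residues for m in s}
        for t in taxa:
            rows[t].append(by_taxon.get(t, "X" * L))
        col_set_index.extend([idx] * L)
    matrix = {t: "".join(parts) for t, parts in rows.items()}

    n_taxa = len(taxa)
    keep: list[int] = []
    if n_taxa == 0:
        raise DataError("no taxa to concatenate")
    total_len = len(col_set_index)
    for col in range(total_len):
        occupied = sum(
            1 for t in taxa
            if matrix[t][col] not in ("X", "-"))
        if occupied / n_taxa >= min_col_occupancy:
            keep.append(col)
    filtered = {t: "".join(matrix[t][c] for c in keep) for t in taxa}

    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for idx, s in enumerate(aligned_sets):
        n_kept = sum(1 for c in keep if col_set_index[c] == idx)
        if n_kept:
            partitions.append((s.name, pos + 1, pos + n_kept))
            pos += n_kept
    return filtered, partitions


def write_supermatrix(
    matrix: dict[str, str],
    partitions: list[tuple[str, int, int]],
    fasta_path: Path,
    partitions_path: Path,
) -> None:
    """Write the supermatrix FASTA and its partition table (1-based
    inclusive coordinates)."""
    with open(fasta_path, "w") as fh:
        for taxon, seq in matrix.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    with open(partitions_path, "w") as fh:
        fh.write("set\tstart\tend\n")
        for name, start, end in partitions:
            fh.write(f"{name}\t{start}\t{end}\n")
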