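"""Local pairwise protein alignment behind a backend-agnostic contract.

Two interchangeable backends produce one best local alignment per
query-reference pair:

* ``"sw"`` — exact Smith-Waterman via Biopython's ``PairwiseAligner``
  (BLOSUM62, gap open 11 / extend 1, the BLASTp defaults), with approximate
  Karlin-Altschul e-values.  Dependency-free and fully deterministic.
* ``"blastp"`` — the external NCBI BLAST+ ``blastp`` binary with
  composition-based statistics disabled, matching the configuration the
  correction thresholds were tuned against.  Heuristic alignment extension
  means its coordinates can differ from the exact backend by a column or
  two.

Hit lists are capped at ``max_hits`` with references 100% identical to the
query retained preferentially, so that overextended references (which score
higher against the query than shorter but otherwise identical ones) cannot
crowd out the evidence for the true terminus.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import CorrectionParams, OrthologSet, ProteinSequence, write_ortholog_set

BACKENDS = ("sw", "blastp")

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
# (the values BLAST+ uses for these penalties); e-values from the internal
# backend are approximate and used only for the expectation cutoff.
_KA_LAMBDA = 0.267
_KA_K = 0.041


class BackendUnavailableError(RuntimeError):
    """The requested alignment backend cannot be used."""


@dataclass(frozen=True)
class PairwiseHit:
    """One local alignment of a query against a reference.

    Coordinates are 1-based inclusive; ``identity`` is identical columns
    divided by alignment length including gapped columns (BLAST "pident"
    convention).
    """

    query_id: str
    ref_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError(f"bad query coordinates in hit {self!r}")
        if not (1 <= self.s_start <= self.s_end):
            raise ValueError(f"bad reference coordinates in hit {self!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of range in hit {self!r}")


@dataclass(frozen=True)
class EndOverhangs:
    """Unaligned residue counts at the four sequence ends of one hit."""

    q5: int
    r5: int
    q3: int
    r3: int

    def end(self, which: str) -> tuple[int, int]:
        """(query, reference) overhang pair for one end."""
        from .seqio import FIVE_PRIME
        return (self.q5, self.r5) if which == FIVE_PRIME else (self.q3, self.r3)


def end_overhangs(hit: PairwiseHit, query_len: int, ref_len: int) -> EndOverhangs:
    """Count unaligned residues outside the local alignment at each end."""
    if hit.q_end > query_len or hit.s_end > ref_len:
        raise ValueError("hit coordinates exceed sequence lengths")
    ov = EndOverhangs(
        q5=hit.q_start - 1,
        r5=hit.s_start - 1,
        q3=query_len - hit.q_end,
        r3=ref_len - hit.s_end,
    )
    # span bookkeeping must close exactly
    assert ov.q5 + (hit.q_end - hit.q_start + 1) + ov.q3 == query_len
    assert ov.r5 + (hit.s_end - hit.s_start + 1) + ov.r3 == ref_len
    return ov


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def _bitscore(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2.0)


def _evalue(bits: float, query_len: int, db_len: int) -> float:
    return query_len * db_len * 2.0 ** (-bits)


def sw_align_pair(
    query: ProteinSequence, ref: ProteinSequence, db_len: int | None = None
) -> PairwiseHit | None:
    """Best Smith-Waterman local alignment of a single pair, or None if no
    positive-scoring alignment exists."""
    result = _aligner().align(query.residues, ref.residues)
    if len(result) == 0 or result[0].score <= 0:
        return None
    best = result[0]
    q_blocks, s_blocks = best.aligned
    q_start = int(q_blocks[0][0]) + 1
    q_end = int(q_blocks[-1][1])
    s_start = int(s_blocks[0][0]) + 1
    s_end = int(s_blocks[-1][1])
    n_aligned = 0
    n_ident = 0
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        n_aligned += qb - qa
        for k in range(qb - qa):
            if query.residues[qa + k] == ref.residues[sa + k]:
                n_ident += 1
    q_span = q_end - q_start + 1
    s_span = s_end - s_start + 1
    aln_len = q_span + s_span - n_aligned  # columns incl. gaps on either side
    bits = _bitscore(best.score)
    return PairwiseHit(
        query_id=query.id,
        ref_id=ref.id,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        identity=n_ident / aln_len,
        evalue=_evalue(bits, len(query), db_len if db_len is not None else len(ref)),
        bitscore=bits,
    )


def _order_and_cap(hits: list[PairwiseHit], max_hits: int) -> list[PairwiseHit]:
    """Deterministic hit ordering with 100%-identity references first, then
    by descending bitscore, ascending e-value, lexicographic reference id;
    truncated to ``max_hits``."""
    ordered = sorted(
        hits, key=lambda h: (h.identity < 1.0, -h.bitscore, h.evalue, h.ref_id))
    return ordered[:max_hits]


def align_query(
    query: ProteinSequence,
    refs: OrthologSet,
    params: CorrectionParams,
    backend: str = "sw",
) -> list[PairwiseHit]:
    """Align one query against its reference set.

    Returns at most one (best) hit per reference, excluding hits above the
    e-value cutoff, capped at ``params.max_hits`` with 100%-identity hits
    retained preferentially.
    """
    if any(r.id == query.id for r in refs):
        raise ValueError("reference set must exclude the query itself")
    if len(refs) == 0:
        raise ValueError("reference set is empty")
    if len(query) < 3:
        warnings.warn(f"query {query.id!r} shorter than 3 AA; skipping alignment")
        return []
    if backend == "sw":
        db_len = sum(len(r) for r in refs)
        hits = []
        for r in refs:
            h = sw_align_pair(query, r, db_len=db_len)
            if h is not None and h.evalue <= params.evalue:
                hits.append(h)
        return _order_and_cap(hits, params.max_hits)
    if backend == "blastp":
        oset = OrthologSet("q_and_refs", (query, *refs.members))
        by_query = _blastp_align_set(oset, params)
        return by_query.get(query.id, [])
    raise BackendUnavailableError(f"unknown alignment backend {backend!r}")


def align_set(
    oset: OrthologSet, params: CorrectionParams, backend: str = "sw"
) -> dict[str, list[PairwiseHit]]:
    """All-vs-all alignment within one ortholog set.

    Returns, for each member id, its capped hit list against all other
    members.  The SW backend computes each unordered pair once and mirrors
    the alignment; the blastp backend runs a single database search.
    """
    if backend == "sw":
        members = oset.members
        total_len = sum(len(m) for m in members)
        raw: dict[str, list[PairwiseHit]] = {m.id: [] for m in members}
        for i, q in enumerate(members):
            if len(q) < 3:
                warnings.warn(f"query {q.id!r} shorter than 3 AA; skipping alignment")
                continue
            db_q = total_len - len(q)
            for r in members[i + 1:]:
                if len(r) < 3:
                    continue
                h = sw_align_pair(q, r, db_len=db_q)
                if h is None:
                    continue
                if h.evalue <= params.evalue:
                    raw[q.id].append(h)
                mirrored = PairwiseHit(
                    query_id=r.id, ref_id=q.id,
                    q_start=h.s_start, q_end=h.s_end,
                    s_start=h.q_start, s_end=h.q_end,
                    identity=h.identity,
                    evalue=_evalue(h.bitscore, len(r), total_len - len(r)),
                    bitscore=h.bitscore,
                )
                if mirrored.evalue <= params.evalue:
                    raw[r.id].append(mirrored)
        return {qid: _order_and_cap(hits, params.max_hits)
                for qid, hits in raw.items()}
    if backend == "blastp":
        return _blastp_align_set(oset, params)
    raise BackendUnavailableError(f"unknown alignment backend {backend!r}")


def require_backend(backend: str) -> None:
    """Raise BackendUnavailableError early if the backend cannot run."""
    if backend == "sw":
        return
    if backend == "blastp":
        for tool in ("makeblastdb", "blastp"):
            if shutil.which(tool) is None:
                raise BackendUnavailableError(
                    f"backend 'blastp' requires the NCBI BLAST+ binary {tool!r} on PATH")
        return
    raise BackendUnavailableError(f"unknown alignment backend {backend!r}")


_BLAST_FIELDS = "qseqid sseqid qstart qend sstart send pident evalue bitscore"


def _blastp_align_set(
    oset: OrthologSet, params: CorrectionParams
) -> dict[str, list[PairwiseHit]]:
    require_backend("blastp")
    by_query: dict[str, list[PairwiseHit]] = {m.id: [] for m in oset.members}
    with tempfile.TemporaryDirectory(prefix="orfclean_blast_") as tmp:
        fasta = Path(tmp) / "set.faa"
        write_ortholog_set(oset, fasta)
        db = Path(tmp) / "setdb"
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot",
             "-out", str(db)],
            check=True, capture_output=True, text=True)
        proc = subprocess.run(
            ["blastp", "-query", str(fasta), "-db", str(db),
             "-evalue", str(params.evalue),
             # +1 so the guaranteed self-hit does not displace a reference
             "-max_target_seqs", str(params.max_hits + 1),
             "-comp_based_stats", "F",
             "-outfmt", f"6 {_BLAST_FIELDS}"],
            check=True, capture_output=True, text=True)
        best: dict[tuple[str, str], PairwiseHit] = {}
        for line in proc.stdout.splitlines():
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            if qid == sid:
                continue
            hit = PairwiseHit(
                query_id=qid, ref_id=sid,
                q_start=int(f[2]), q_end=int(f[3]),
                s_start=int(f[4]), s_end=int(f[5]),
                identity=float(f[6]) / 100.0,
                evalue=float(f[7]), bitscore=float(f[8]),
            )
            key = (qid, sid)
            prev = best.get(key)
            if prev is None or (hit.bitscore, -hit.evalue) > (prev.bitscore, -prev.evalue):
                best[key] = hit
        for (qid, _sid), hit in best.items():
            by_query[qid].append(hit)
    return {qid: _order_and_cap(hits, params.max_hits)
            for qid, hits in by_query.items()}
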