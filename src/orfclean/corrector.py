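"""Consensus end calling, per-end classification, and sequence correction.

Each sequence in an ortholog set is in turn treated as the query and locally
aligned against every other member (its references).  For every
query-reference comparison the counts of unaligned residues at the 5' and 3'
ends of both sequences (the "end overhangs") are recorded.  An end-overhang
pair that recurs in at least ``consensus_frac`` of the comparisons becomes
the consensus for that end; if several pairs qualify, the one implying the
longest corrected sequence wins.

Classification per end, writing (q, r) for the consensus query/reference
overhangs and using the chimera threshold t (``chimera5_min``/``chimera3_min``)
and the trim/pad threshold s (``trim5_min``/``trim3_min``):

* chimeric      — q >= t and r >= t: the query end is unrelated sequence;
                  trim the q spurious residues and pad r "X"s for the
                  residues the reference says are missing.
* overextended  — q >= s: the query carries q spurious terminal residues;
                  trim them.
* truncated     — r >= s: the query is missing r genuine residues; pad with
                  r "X"s to denote missing data.
* ok            — neither overhang reaches its threshold.

A set-level bimodality guard protects ortholog sets with two genuinely
common start (or stop) sites: when at least ``bimodal_frac`` of the
correctable queries at one end propose trims and another ``bimodal_frac``
propose pads, the trims are suppressed so the set converges on the longer
form rather than being split in both directions.

Terminal "X" runs from earlier corrections are treated as aligned
mismatches when counting overhangs, so running the corrector on its own
output proposes no further changes.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

from .align import EndOverhangs, PairwiseHit, align_set, end_overhangs
from .seqio import (
    ENDS,
    FIVE_PRIME,
    THREE_PRIME,
    CorrectionParams,
    OrthologSet,
    ProteinSequence,
)

KIND_OK = "ok"
KIND_OVEREXTENDED = "overextended"
KIND_TRUNCATED = "truncated"
KIND_CHIMERIC = "chimeric"
KIND_UNCORRECTABLE = "uncorrectable"


@dataclass(frozen=True)
class ConsensusCall:
    """The modal end-overhang pair for one end of one query."""

    end: str
    q_overhang: int
    r_overhang: int
    support: float
    n_comparisons: int


@dataclass(frozen=True)
class CorrectionCall:
    """Classification and correction amounts for one end of one sequence."""

    seq_id: str
    end: str
    kind: str
    trim: int = 0
    pad: int = 0
    consensus: ConsensusCall | None = None

    def __post_init__(self) -> None:
        if self.kind == KIND_OVEREXTENDED and not (self.trim > 0 and self.pad == 0):
            raise ValueError("overextended call requires trim>0, pad=0")
        if self.kind == KIND_TRUNCATED and not (self.pad > 0 and self.trim == 0):
            raise ValueError("truncated call requires pad>0, trim=0")
        if self.kind == KIND_CHIMERIC and not (self.trim > 0 and self.pad >= 0):
            raise ValueError("chimeric call requires trim>0, pad>=0")
        if self.kind in (KIND_OK, KIND_UNCORRECTABLE) and (self.trim or self.pad):
            raise ValueError(f"{self.kind} call must have trim=pad=0")


def qualifying_hits(
    hits: list[PairwiseHit], params: CorrectionParams
) -> list[PairwiseHit]:
    """Select the reference hits a query may be corrected against.

    Keeps hits at identity >= ``min_identity``, truncated to the first
    ``max_comparisons`` (hit lists arrive with 100%-identity references
    first).  Returns an empty list — signalling the query is uncorrectable —
    when fewer than ``min_refs`` qualify.
    """
    kept = [h for h in hits if h.identity >= params.min_identity]
    kept = kept[:params.max_comparisons]
    if len(kept) < params.min_refs:
        return []
    return kept


def absorb_terminal_x(
    ov: EndOverhangs, query: ProteinSequence, ref: ProteinSequence
) -> EndOverhangs:
    """Treat terminal "X" runs as aligned mismatches.

    A previously padded query (or reference) carries leading/trailing "X"s
    that a score-based local aligner leaves unaligned, producing equal
    query/reference overhangs that would spuriously re-trigger corrections.
    Pair off overhang residues at each end for as many columns as either
    side has "X"s there, and drop them from both counts.
    """
    q5_region = query.residues[:ov.q5]
    r5_region = ref.residues[:ov.r5]
    absorb5 = min(ov.q5, ov.r5, max(q5_region.count("X"), r5_region.count("X")))
    q3_region = query.residues[len(query) - ov.q3:]
    r3_region = ref.residues[len(ref) - ov.r3:]
    absorb3 = min(ov.q3, ov.r3, max(q3_region.count("X"), r3_region.count("X")))
    if absorb5 == 0 and absorb3 == 0:
        return ov
    return EndOverhangs(q5=ov.q5 - absorb5, r5=ov.r5 - absorb5,
                        q3=ov.q3 - absorb3, r3=ov.r3 - absorb3)


def _classify_pair(q: int, r: int, end: str, params: CorrectionParams
                   ) -> tuple[str, int, int]:
    """(kind, trim, pad) implied by a consensus overhang pair at one end."""
    t = params.chimera_threshold(end)
    s = params.trim_threshold(end)
    if q >= t and r >= t:
        return KIND_CHIMERIC, q, r
    if q >= s:
        return KIND_OVEREXTENDED, q, 0
    if r >= s:
        return KIND_TRUNCATED, 0, r
    return KIND_OK, 0, 0


def consensus_end(
    overhangs: list[EndOverhangs], end: str, params: CorrectionParams
) -> ConsensusCall | None:
    """Find the consensus (query, reference) overhang pair for one end.

    Pairs supported by >= ``consensus_frac`` of the comparisons are
    candidates; among several candidates the one whose implied corrected
    sequence is longest wins (ties: smaller query overhang, then smaller
    reference overhang).  Returns None when no pair reaches the threshold.
    """
    if not overhangs:
        raise ValueError("no overhangs to form a consensus from")
    n = len(overhangs)
    counts = Counter(ov.end(end) for ov in overhangs)
    candidates = [(pair, c) for pair, c in counts.items()
                  if c / n >= params.consensus_frac]
    if not candidates:
        return None

    def sort_key(item: tuple[tuple[int, int], int]):
        (q, r), _c = item
        _kind, trim, pad = _classify_pair(q, r, end, params)
        return (-(pad - trim), q, r)

    (q, r), c = min(candidates, key=sort_key)
    return ConsensusCall(end=end, q_overhang=q, r_overhang=r,
                         support=c / n, n_comparisons=n)


def classify_end(
    seq_id: str, call: ConsensusCall, params: CorrectionParams
) -> CorrectionCall:
    """Turn a consensus overhang pair into a per-end correction call."""
    kind, trim, pad = _classify_pair(
        call.q_overhang, call.r_overhang, call.end, params)
    return CorrectionCall(seq_id=seq_id, end=call.end, kind=kind,
                          trim=trim, pad=pad, consensus=call)


def bimodal_guard(
    calls: list[CorrectionCall], params: CorrectionParams
) -> list[CorrectionCall]:
    """Suppress trims at an end where the set proposes both trims and pads.

    ``calls`` must cover every correctable query of one ortholog set at one
    end.  If at least ``bimodal_frac`` of them propose a trim and another
    ``bimodal_frac`` propose a pad, the set has two common termini there;
    trim-only calls are converted to ``ok`` so the set converges on the
    longer form.
    """
    n = len(calls)
    if n == 0:
        return calls
    p_trim = sum(1 for c in calls if c.trim > 0) / n
    p_pad = sum(1 for c in calls if c.pad > 0) / n
    if p_trim >= params.bimodal_frac and p_pad >= params.bimodal_frac:
        return [
            replace(c, kind=KIND_OK, trim=0, pad=0)
            if c.kind == KIND_OVEREXTENDED else c
            for c in calls
        ]
    return calls


def apply_correction(
    seq: ProteinSequence, call5: CorrectionCall, call3: CorrectionCall
) -> ProteinSequence:
    """Apply per-end trims then pads; internal residues are never edited."""
    if call5.end != FIVE_PRIME or call3.end != THREE_PRIME:
        raise ValueError("apply_correction expects one 5' and one 3' call")
    trim5, pad5 = call5.trim, call5.pad
    trim3, pad3 = call3.trim, call3.pad
    if trim5 + trim3 >= len(seq):
        raise ValueError(
            f"trims ({trim5}+{trim3}) would consume sequence {seq.id!r} "
            f"of length {len(seq)}")
    core = seq.residues[trim5: len(seq.residues) - trim3]
    return replace(seq, residues="X" * pad5 + core + "X" * pad3)


def correct_set(
    oset: OrthologSet,
    params: CorrectionParams,
    backend: str = "sw",
) -> tuple[OrthologSet, list[CorrectionCall]]:
    """Run the full correction algorithm on one ortholog set.

    Returns the corrected set (member order preserved) and one
    CorrectionCall per member per end.  Queries lacking ``min_refs``
    qualifying references are emitted unchanged with kind
    ``uncorrectable``.  Deterministic for a fixed input order and backend.
    """
    members = oset.members
    by_id = {m.id: m for m in members}
    if len(members) < params.min_refs + 1:
        calls = [CorrectionCall(m.id, end, KIND_UNCORRECTABLE)
                 for m in members for end in ENDS]
        return oset, calls

    hits_by_query = align_set(oset, params, backend=backend)

    prelim: dict[str, dict[str, CorrectionCall]] = {}
    correctable: dict[str, bool] = {}
    for m in members:
        qh = qualifying_hits(hits_by_query.get(m.id, []), params)
        if not qh:
            prelim[m.id] = {end: CorrectionCall(m.id, end, KIND_UNCORRECTABLE)
                            for end in ENDS}
            correctable[m.id] = False
            continue
        correctable[m.id] = True
        overhangs = [
            absorb_terminal_x(
                end_overhangs(h, len(m), len(by_id[h.ref_id])),
                m, by_id[h.ref_id])
            for h in qh
        ]
        calls: dict[str, CorrectionCall] = {}
        for end in ENDS:
            cons = consensus_end(overhangs, end, params)
            if cons is None:
                calls[end] = CorrectionCall(m.id, end, KIND_OK)
            else:
                calls[end] = classify_end(m.id, cons, params)
        prelim[m.id] = calls

    # set-level bimodality guard, per end, over correctable queries only
    final: dict[str, dict[str, CorrectionCall]] = {
        mid: dict(cs) for mid, cs in prelim.items()}
    for end in ENDS:
        guarded = bimodal_guard(
            [prelim[m.id][end] for m in members if correctable[m.id]], params)
        it = iter(guarded)
        for m in members:
            if correctable[m.id]:
                final[m.id][end] = next(it)

    corrected = []
    all_calls: list[CorrectionCall] = []
    for m in members:
        c5 = final[m.id][FIVE_PRIME]
        c3 = final[m.id][THREE_PRIME]
        try:
            corrected.append(apply_correction(m, c5, c3))
        except ValueError:
            # degenerate: trims would consume the sequence — leave it
            # unmodified and flag both ends
            c5 = CorrectionCall(m.id, FIVE_PRIME, KIND_UNCORRECTABLE)
            c3 = CorrectionCall(m.id, THREE_PRIME, KIND_UNCORRECTABLE)
            corrected.append(m)
        all_calls.extend([c5, c3])
    return OrthologSet(oset.name, corrected), all_calls


REPORT_COLUMNS = [
    "seq_id", "end", "kind", "consensus_q_overhang", "consensus_r_overhang",
    "support", "n_comparisons", "trim", "pad",
]


def write_correction_report(calls: list[CorrectionCall], path: str | Path) -> None:
    """Write the per-set correction summary as TSV.

    Overhang, trim and pad columns are residue counts at 1-based inclusive
    sequence ends.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for c in calls:
            cons = c.consensus
            w.writerow([
                c.seq_id, c.end, c.kind,
                cons.q_overhang if cons else "NA",
                cons.r_overhang if cons else "NA",
                f"{cons.support:.4f}" if cons else "NA",
                cons.n_comparisons if cons else "NA",
                c.trim, c.pad,
            ])


def read_correction_report(path: str | Path) -> list[CorrectionCall]:
    """Read back a correction report written by ``write_correction_report``."""
    calls = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cons = None
            if row["consensus_q_overhang"] != "NA":
                cons = ConsensusCall(
                    end=row["end"],
                    q_overhang=int(row["consensus_q_overhang"]),
                    r_overhang=int(row["consensus_r_overhang"]),
                    support=float(row["support"]),
                    n_comparisons=int(row["n_comparisons"]),
                )
            calls.append(CorrectionCall(
                seq_id=row["seq_id"], end=row["end"], kind=row["kind"],
                trim=int(row["trim"]), pad=int(row["pad"]), consensus=cons))
    return calls
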