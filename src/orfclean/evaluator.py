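"""Confusion-matrix scoring of corrections against simulation ground truth.

Every evaluable sequence end (ends of sequences the corrector deemed
correctable) is classified per stratum — one stratum per (error type, end)
plus an overall pool:

* TP — an injected error of the stratum's type received a correction of the
  matching type (the corrected length need not be exact; accuracy is scored
  separately),
* FP — a correction of that type where no such error was injected; by
  default an injected error corrected with the *wrong* type also counts as
  FP in its own stratum (``mismatch_as_fp=False`` downgrades it to FN),
* TN — no error injected, no correction made,
* FN — an injected error left uncorrected.

Derived rates (percentages): sensitivity Sn = TP/(TP+FN)*100, specificity
Sp = TN/(FP+TN)*100, precision = TP/(TP+FP)*100 and
F = 2*precision*Sn/(precision+Sn).  Correction accuracy over TPs:
``pct_exact`` is the percentage restoring the exact original length and
``mean_dev`` the mean absolute AA deviation among inexact corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corrector import (
    KIND_CHIMERIC,
    KIND_OK,
    KIND_OVEREXTENDED,
    KIND_TRUNCATED,
    KIND_UNCORRECTABLE,
    CorrectionCall,
)
from .seqio import ENDS
from .simulator import ERROR_TYPES, SimulationRecord

#: (error type, end) strata plus the overall pool.
STRATA = [(etype, end) for etype in ERROR_TYPES for end in ENDS]
OVERALL = ("all", "both")

_KIND_TO_ERROR = {
    KIND_CHIMERIC: "chimera",
    KIND_OVEREXTENDED: "overextension",
    KIND_TRUNCATED: "truncation",
}


@dataclass
class Metrics:
    """Pooled confusion counts and correction-accuracy tallies."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    exact_tp: int = 0
    inexact_tp: int = 0
    dev_sum: float = 0.0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sn(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def sp(self) -> float:
        return 100.0 * self.tn / (self.fp + self.tn) if self.fp + self.tn else math.nan

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.sn
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2.0 * p * r / (p + r)

    @property
    def pct_exact(self) -> float:
        n = self.exact_tp + self.inexact_tp
        return 100.0 * self.exact_tp / n if n else math.nan

    @property
    def mean_dev(self) -> float:
        return self.dev_sum / self.inexact_tp if self.inexact_tp else math.nan

    def add(self, other: "Metrics") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.tn += other.tn
        self.fn += other.fn
        self.exact_tp += other.exact_tp
        self.inexact_tp += other.inexact_tp
        self.dev_sum += other.dev_sum


def _expected_correction(rec: SimulationRecord) -> tuple[int, int]:
    """(trim, pad) that would exactly undo an injected error."""
    return rec.added, rec.removed


def score_corrections(
    calls: list[CorrectionCall],
    truth: list[SimulationRecord],
    mismatch_as_fp: bool = True,
) -> dict[tuple[str, str], Metrics]:
    """Score one corrected replicate against its ground truth.

    ``calls`` must contain one call per sequence end of the dataset
    (uncorrectable ends are excluded from every denominator, matching the
    simulator's guarantee that altered sequences always retain enough
    unmodified references).  Returns Metrics per stratum plus the overall
    pool under key ``OVERALL``.
    """
    call_ids = {c.seq_id for c in calls}
    missing = {r.seq_id for r in truth} - call_ids
    if missing:
        raise ValueError(
            f"truth records refer to sequences absent from the calls: "
            f"{sorted(missing)[:5]}")
    truth_by_end: dict[tuple[str, str], SimulationRecord] = {}
    for r in truth:
        key = (r.seq_id, r.end)
        if key in truth_by_end:
            raise ValueError(f"multiple truth records for {key}")
        truth_by_end[key] = r

    out = {key: Metrics() for key in STRATA}
    out[OVERALL] = Metrics()
    for c in calls:
        if c.kind == KIND_UNCORRECTABLE:
            continue
        rec = truth_by_end.get((c.seq_id, c.end))
        called = _KIND_TO_ERROR.get(c.kind)  # None for "ok"
        injected = rec.error_type if rec else None
        for etype, end in STRATA:
            if end != c.end:
                continue
            m = out[(etype, end)]
            if injected == etype:
                if called == etype:
                    m.tp += 1
                    _tally_accuracy(m, c, rec)
                elif called is None:
                    m.fn += 1
                else:  # corrected with the wrong type
                    if mismatch_as_fp:
                        m.fp += 1
                    else:
                        m.fn += 1
            else:
                if called == etype:
                    m.fp += 1
                else:
                    m.tn += 1
        m = out[OVERALL]
        if injected is not None:
            if called == injected:
                m.tp += 1
                _tally_accuracy(m, c, rec)
            elif called is None:
                m.fn += 1
            else:
                m.fp += 1 if mismatch_as_fp else 0
                m.fn += 0 if mismatch_as_fp else 1
        else:
            if called is None:
                m.tn += 1
            else:
                m.fp += 1
    return out


def _tally_accuracy(m: Metrics, call: CorrectionCall, rec: SimulationRecord) -> None:
    exp_trim, exp_pad = _expected_correction(rec)
    dev = abs(call.trim - exp_trim) + abs(call.pad - exp_pad)
    if dev == 0:
        m.exact_tp += 1
    else:
        m.inexact_tp += 1
        m.dev_sum += dev


def pool_replicates(
    per_replicate: list[dict[tuple[str, str], Metrics]]
) -> dict[tuple[str, str], Metrics]:
    """Union of confusion counts across replicates; rates recomputed from
    the pooled counts."""
    if not per_replicate:
        raise ValueError("need at least one replicate")
    pooled = {key: Metrics() for key in per_replicate[0]}
    for rep in per_replicate:
        for key, m in rep.items():
            pooled[key].add(m)
    return pooled


def metrics_frame(
    per_replicate: list[dict[tuple[str, str], Metrics]]
) -> pd.DataFrame:
    """Tabulate pooled metrics per stratum with per-replicate mean +/- sd.

    One row per (error_type, end) stratum plus the overall pool; rate
    columns are percentages, NA where undefined.
    """
    pooled = pool_replicates(per_replicate)
    rows = []
    for key in list(STRATA) + [OVERALL]:
        m = pooled[key]
        rep_sn = [r[key].sn for r in per_replicate if not math.isnan(r[key].sn)]
        rep_sp = [r[key].sp for r in per_replicate if not math.isnan(r[key].sp)]
        rows.append({
            "error_type": key[0],
            "end": key[1],
            "TP": m.tp, "FP": m.fp, "TN": m.tn, "FN": m.fn,
            "Sn": m.sn, "Sp": m.sp,
            "precision": m.precision, "F": m.f_score,
            "pct_exact": m.pct_exact, "mean_dev": m.mean_dev,
            "Sn_rep_mean": float(pd.Series(rep_sn).mean()) if rep_sn else math.nan,
            "Sn_rep_sd": float(pd.Series(rep_sn).std(ddof=1)) if len(rep_sn) > 1 else math.nan,
            "Sp_rep_mean": float(pd.Series(rep_sp).mean()) if rep_sp else math.nan,
            "Sp_rep_sd": float(pd.Series(rep_sp).std(ddof=1)) if len(rep_sp) > 1 else math.nan,
            "n_replicates": len(per_replicate),
        })
    return pd.DataFrame(rows)


def write_metrics(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.4f")
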