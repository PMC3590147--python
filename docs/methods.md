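# Methods

## Model and assumptions

`orfclean` treats an ortholog set as a sample of sequences that share a
single true start and a single true stop position, diverge by
substitutions only, and are closely enough related that a local protein
alignment between any two members recovers their homologous core. Under
these assumptions an annotation inconsistency at a sequence end appears as
a reproducible *overhang pattern* across that sequence's comparisons:

* a spurious extension leaves the query's extra residues unaligned
  (query overhang q > 0, reference overhang r ≈ 0);
* a truncation leaves the references' genuine residues unaligned
  (q ≈ 0, r > 0);
* a chimeric end leaves both unaligned (q and r both large), because the
  replaced residues align to nothing and the genuine residues are gone.

The algorithm therefore never edits internal residues: corrections are
terminal trims and `X`-pads only, and undoing them reconstructs the input
exactly. Sequences violating the assumptions — paralogs, rate-accelerated
lineages, genuinely alternative termini — are the known failure modes; the
identity threshold *d* and the bimodality guard are the two defenses.

## Procedure

For each query in a set of n members:

1. Align against the other n−1 members (one best local alignment per
   pair). Hits above the e-value cutoff *e* are dropped; hit lists are
   capped at *l* with 100%-identity references kept preferentially, since
   overextended references outscore shorter identical ones and would
   otherwise bias the sample.
2. Keep hits with identity ≥ *d*; truncate to the first *k*. Fewer than
   `min_refs` qualifying hits ⇒ the query is *uncorrectable* and emitted
   unchanged.
3. Per end, count the exact (q, r) overhang pairs over the comparisons.
   Pairs supported by ≥ `consensus_frac` are candidates; the candidate
   implying the longest corrected sequence wins.
4. Classify: chimeric if both q and r reach the chimera threshold
   (*f* 5′ / *g* 3′), else overextended if q reaches the trim threshold
   (*a* 5′ / *b* 3′), else truncated if r does, else ok.
5. Across the set and per end, apply the bimodality guard: if ≥
   `bimodal_frac` of correctable queries propose trims and ≥
   `bimodal_frac` propose pads, the trims are suppressed.
6. Apply trims, then pads.

The consensus is computed over **joint** (q, r) pairs, not per-sequence
marginals: a chimera call requires the *same* comparisons to exhibit both
overhangs, and joint counting is the only reading that makes the chimera
trigger well defined.

## Parameters

| name              | flag | default | meaning                                        |
|-------------------|------|---------|------------------------------------------------|
| `trim5_min`       | -a   | 5 AA    | 5′ overhang needed to trim or pad              |
| `trim3_min`       | -b   | 20 AA   | 3′ overhang needed to trim or pad              |
| `min_identity`    | -d   | 0.9     | identity floor for a usable reference          |
| `evalue`          | -e   | 1e-5    | alignment expectation cutoff                   |
| `chimera5_min`    | -f   | 10 AA   | 5′ overhang (both seqs) for a chimera call     |
| `chimera3_min`    | -g   | 30 AA   | 3′ overhang (both seqs) for a chimera call     |
| `max_targets`     | -j   | 5       | report cap handed to the external aligner      |
| `max_comparisons` | -k   | 1000    | comparisons used per query                     |
| `max_hits`        | -l   | 1000    | stored hits per query                          |
| `min_refs`        |      | 5       | qualifying references required                 |
| `consensus_frac`  |      | 0.33    | agreement fraction for a consensus             |
| `bimodal_frac`    |      | 0.40    | per-direction fraction flagging bimodality     |

3′ thresholds are deliberately larger than 5′ ones: stop-codon detection
is more reliable than start-site choice, so 3′ heterogeneity is more often
genuine and demands stronger evidence. All threshold comparisons use ≥ —
an error exactly at a threshold is the shortest detectable one. The
benchmark configuration used by `scripts/acceptance.py` sets b = 10 so the
3′ trim/pad rules operate in the same regime as the 5′ ones.

The external-aligner report cap `-j` and the storage cap `-l` are in
tension if `-j` is handed to BLAST directly: a cap of 5 would make the
100%-identity retention guarantee impossible. The blastp backend therefore
submits `max_hits` (+1 for the self-hit) as `-max_target_seqs` and keeps
`-j` only as a user-visible knob for strict replication of external runs.

## Alignment backends and numerical choices

* Built-in backend: exact Smith–Waterman (Biopython `PairwiseAligner`,
  local mode, BLOSUM62, gap open 11 / extend 1 — the BLASTp defaults).
  Identity = identical columns / alignment length including gap columns
  (BLAST `pident` convention). E-values use Karlin–Altschul statistics
  with standard gapped BLOSUM62 constants (λ = 0.267, K = 0.041) and the
  summed reference length as database size; they are approximate and used
  only for the cutoff, never ranking.
* External backend: `makeblastdb` + `blastp -comp_based_stats F`, one
  database per set, best HSP per pair. Heuristic extension means its
  coordinates can differ from the exact backend by a column or two; the
  test suite bounds the disagreement (±2 columns, ±0.02 identity).
* One hit per reference (best bitscore, ties by e-value then reference
  id), avoiding double-counting of ends from multiple HSPs.
* Consensus ties: longest corrected sequence, then smaller query
  overhang, then smaller reference overhang — fully deterministic.
* Terminal `X` runs are treated as aligned mismatches when counting
  overhangs (`absorb_terminal_x`): without this, a previously padded end
  would re-present as an overhang and re-trigger corrections; with it,
  correction is idempotent (asserted on the synthetic suite).
* Degenerate inputs: queries shorter than 3 AA produce a warning and no
  hits; trims that would consume an entire sequence leave it unmodified
  and flagged uncorrectable; empty files and duplicate ids are hard
  errors.
* The bimodality guard resolves in favor of extension (trims suppressed,
  pads kept): converging on the longer form is the only resolution
  consistent with preferring the longest consensus, and losing residues
  is the costlier mistake.
* Classification direction: a large *query* overhang means the query
  carries extra residues (overextension ⇒ trim); a large *reference*
  overhang means the query is missing residues (truncation ⇒ pad). The
  correction amounts follow the coordinates: trim = consensus query
  overhang, pad = consensus reference overhang.

## What the simulator emulates — and what it does not

`generate_family` draws a random ancestor (initial M conserved) and
mutates each descendant position independently at rate 1 − √t, giving
expected pairwise identity ≈ t between descendants; all members share
length and termini exactly. Errors are injected per sequence end at the
design rates (5% 5′ over/trunc, 1% 3′ over/trunc, 0.1% chimeras), each
with length = per-type minimum + Poisson(λ = 5); added residues come from
an unrelated random donor pool, segment-reversed to destroy residual
homology; at most one error per end (drawn chimera → overextension →
truncation), and every family keeps ≥ `min_refs` unmodified members, so
injected errors are always evaluable. Ground-truth records store the
deleted residues, making injection exactly invertible — the round-trip is
a tested invariant.

Not emulated: indels, rate heterogeneity across sites and lineages,
paralogy, horizontal transfer, genuinely alternative start/stop sites,
biased amino-acid composition, and donor inserts with real homology to
anything. Passing the simulation benchmark therefore demonstrates the
algorithm's behavior under its own assumptions — near-perfect sensitivity
and specificity on clean substitution-only families — not its error rate
on real proteomes, where divergent lineages and genuine terminal variation
make both false corrections and misses more likely. In particular the
built-in exact aligner extends less eagerly into chimeric junk than
heuristic aligners do, so chimera sensitivity here is higher than a
BLAST-based run would show on the same data; chimera correction *accuracy*
(exactness of the restored length) remains the weakest number, as the
alignment boundary inside a chimeric end is intrinsically fuzzy.

## Problem sizes

The packaged benchmark (`scripts/acceptance.py`) uses 13 families × 24
sequences × 150 AA at target identity 0.95, 50 replicates; the acceptance
test suite uses 13 × 16 × 150 with 12 replicates. These sizes give
hundreds of injected 5′ events and O(100) 3′ events per run while keeping
a full run to minutes on a single CPU with the built-in aligner; chimera
strata at the 0.1% design rate collect only tens of events, so their
sensitivity estimates are coarse and are reported rather than bounded.

## Evaluation conventions

A corrected end is a TP for its stratum when an error of that type was
injected there and the correction has the matching type; exactness of the
restored length is scored separately (`pct_exact` over TPs, `mean_dev` in
AA over inexact TPs). An injected error corrected with the wrong type
counts as FP in its own stratum by default (`mismatch_as_fp=False`
downgrades it to FN). Uncorrectable ends are excluded from all
denominators. Replicates are pooled by summing confusion counts before
computing rates; per-replicate mean ± sd are reported alongside, and the
two disagree whenever replicate sizes differ — both are emitted.

## Known limitations

* Corrections are only as good as the ortholog sets: paralogs or
  rate-accelerated members can seed false consensus calls, the motivation
  for the conservative d = 0.9 default.
* Frameshifts are out of scope by design — the method works at the
  protein level and cannot distinguish programmed frameshifts from
  sequencing error.
* Nucleotide mode requires indel-free, in-frame ORFs and corrects only
  what the protein-level analysis sees.
* The internal e-value is approximate; runs needing exact BLAST
  statistics should use the blastp backend.
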