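# orfclean

Consensus-based detection and correction of inconsistent ORF start/stop
annotations in sets of closely related orthologs.

## The problem

Automated gene callers annotate orthologous open reading frames
inconsistently: the same protein may be reported with a spurious upstream
extension in one genome (often a missed GTG/TTG alternative start), missing
its genuine terminal residues in another (wrong internal start, premature
stop, or a contig edge), or carrying unrelated sequence fused onto one end
(mis-assembly or frame merging). These inconsistencies make truly identical
sequences appear to differ and bias downstream comparative and phylogenomic
analyses. `orfclean` corrects them **without genome reannotation**, using
only the structure of each ortholog set itself, and is aimed at anyone
assembling per-gene ortholog families for alignment, supermatrix
construction or comparative genomics.

## The method

Each sequence in an ortholog set (one FASTA file per set) is in turn the
*query*, locally aligned against every other member (its *references*).
For each query–reference comparison the numbers of unaligned residues at
the 5′ and 3′ ends of both sequences — the *end overhangs* (q, r) — are
recorded. A correction is attempted only when at least `min_refs` (default
5) references reach identity ≥ *d* (default 0.9) in the aligned region.
An overhang pair seen in ≥ 33% of the comparisons is the consensus for that
end (ties resolve to the longest implied sequence). Writing *t* for the
chimera threshold (*f* = 10 AA at 5′, *g* = 30 AA at 3′) and *s* for the
trim/pad threshold (*a* = 5 AA at 5′, *b* = 20 AA at 3′):

| consensus overhangs      | call          | action                       |
|--------------------------|---------------|------------------------------|
| q ≥ t **and** r ≥ t      | chimeric      | trim q residues, pad r × `X` |
| q ≥ s                    | overextended  | trim q residues              |
| r ≥ s                    | truncated     | pad r × `X`                  |
| otherwise                | ok            | none                         |

`X` marks inferred missing data (back-translated as `NNN` in nucleotide
mode). A set-level *bimodality guard* suppresses trims when ≥ 40% of the
correctable queries at one end propose trims and another ≥ 40% propose
pads — a signature of two genuinely common start/stop sites — so the set
converges on the longer form.

Alignment backends: a built-in exact Smith–Waterman (BLOSUM62, gap
open 11 / extend 1) and external NCBI BLASTp (composition-based statistics
disabled) behind the same contract.

The package also ships the validation harness: a simulator that builds
substitution-only ortholog families with conserved termini and injects
ground-truthed overextensions, truncations and chimeras (Poisson-distributed
lengths above per-type minimums), an evaluator computing sensitivity,
specificity, precision and F-score per error class from pooled confusion
counts, and a supermatrix concatenator with X-padding for missing taxa and
a column-occupancy filter.

## Worked example

Given `in/rpsD.faa` holding eight orthologs in which one sequence carries
eight spurious leading residues and another is missing its first six:

```sh
$ orfclean run -i in -o out -d 0.9
corrected 2 sequence ends across 1 sets -> out
$ head -5 out/rpsD.report.tsv
seq_id	end	kind	consensus_q_overhang	consensus_r_overhang	support	n_comparisons	trim	pad
rpsD_s000	5prime	overextended	8	0	0.8571	7	8	0
rpsD_s000	3prime	ok	0	0	1.0000	7	0	0
rpsD_s001	5prime	truncated	0	6	0.8571	7	0	6
rpsD_s001	3prime	ok	0	0	1.0000	7	0	0
```

`rpsD_s000` showed a consensus query overhang of 8 AA at the 5′ end in
86% of its 7 usable comparisons, so its 8 spurious residues are trimmed;
`rpsD_s001` showed a consensus *reference* overhang of 6 AA, so it is
padded with `XXXXXX` to mark the residues its annotation lost:

```
>rpsD_s001
XXXXXXCAETPWMPYRPMNWGTQAIVNASRTECVAMCGLKKAADAQMPGPSILYTYIQYQ
```

The same operations are available as library functions
(`orfclean.correct_set`, `orfclean.run_simulate_evaluate`, …), and
`orfclean simulate` / `orfclean evaluate` / `orfclean concat` drive the
benchmark harness and supermatrix step from the shell.

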