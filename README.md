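# spliceoscope

Transcriptome analysis of spliceosome-mutated myelodysplasia: splice-event
cataloging and PSI quantification from junction counts, differential
splicing between mutation-defined groups, transcript-consequence
classification, PSI-adjusted canonical-transcript expression testing,
CHX-based NMD-sensitivity assessment, positional splicing-enhancer motif
enrichment, and a functional-target filtering cascade — plus a seeded
synthetic-cohort generator with a complete ground-truth ledger for
validating every stage end to end.

## Who it is for

Hematology/genomics groups analysing RNA-seq of myeloid neoplasms with
mutations in splicing factors (SF3B1, SRSF2, U2AF1, ZRSR2). The package
takes what an aligner already produced — splice-junction count tables, a
GTF annotation, a genome FASTA and a sample sheet — and is equally usable
as a library or from the `spliceoscope` command line. Raw patient data
for such studies are typically controlled-access; the synthetic generator
lets you develop and validate against cohorts with known truth.

## The core quantities

For each alternative-splicing event (cassette exon, alt 5'/3' splice
site within 500 nt, intron retention, mutually exclusive and terminal
exons), the **percent spliced in** is

    PSI = 100 · inclusion / (inclusion + exclusion)

from summed junction reads (boundary-count means for intron retention),
undefined below 5 informative reads. Group differences use Welch's
two-sided t-test with Benjamini–Hochberg correction per (mutation × cell
fraction) family, significant at q < 0.01. Events are classified against
the longest-CDS transcript into truncating (frameshift or premature
termination codon), non-truncating, alternative first/last coding exon,
or non-coding. NMD sensitivity comes from paired cycloheximide (CHX)
experiments via the Cochran–Mantel–Haenszel test on pair-stratified
inclusion/exclusion counts; canonical-transcript expression is tested
with a TMM-normalized negative-binomial GLM likelihood-ratio test after
scaling gene counts by (100 − PSI)/100 for the strongest truncating
event. See `docs/methods.md` for the full model description.

## Worked example

Simulate the default study (one marrow fraction: 30 SF3B1-, 15 SRSF2-,
16 U2AF1-mutated, 40 control samples; planted alt-3'SS spikes, a mild
intron-retention decrease and cassette shifts), then catalogue events,
quantify PSI and test differential splicing:

```python
from spliceoscope.simulate import SimulationConfig, simulate_reference, simulate_cohort
from spliceoscope.events import enumerate_events, compute_psi
from spliceoscope.diffsplice import differential_splicing, tally_by_type

cfg = SimulationConfig(seed=1)
ref = simulate_reference(cfg)
table, counts, sheet, truth = simulate_cohort(ref)

events = enumerate_events(ref.models, table)
psi = compute_psi(events, table, min_reads=5)
res = differential_splicing(psi, sheet, ["SF3B1", "SRSF2"], q_cutoff=0.01)

print(f"{len(events)} events, PSI matrix {psi.psi.shape}")
print(tally_by_type(res).to_string(index=False))
top = res.sort_values("q").iloc[0]
print(f"{top.comparison}: mean PSI {top.mean_psi_mut:.1f}% vs "
      f"{top.mean_psi_ctrl:.1f}%, t={top.t:.1f}, q={top.q:.2e}, {top.direction}")
```

prints

```
146 events, PSI matrix (146, 101)
      event_type      direction  n
         alt_3ss   up_in_mutant 20
         alt_5ss   up_in_mutant  4
  alt_first_exon   up_in_mutant  2
   alt_last_exon   up_in_mutant  2
   cassette_exon down_in_mutant  8
   cassette_exon   up_in_mutant  7
intron_retention down_in_mutant  4
SF3B1: mean PSI 26.9% vs 0.8%, t=25.9, q=6.69e-21, up_in_mutant
```

The tally reads as in the study design: SF3B1 carriers gain cryptic 3'
splice sites (20 events up) and lose intron retention (4 down);
SRSF2 carriers shift cassette exons in both directions. The top event is
a planted SF3B1-specific cryptic acceptor — essentially absent in
controls (0.8%) and used at 27% of reads in carriers.

The same steps are available from the shell:

```bash
spliceoscope simulate --out study/ --seed 1
spliceoscope events --gtf study/annotation.gtf --junctions study/junctions.tsv \
    --boundaries study/boundaries.tsv --samples study/samples.tsv
spliceoscope diff-splice --psi psi.tsv --samples study/samples.tsv --compare SF3B1
spliceoscope mutex --table 13,53,0,32
```

The last command tests mutation mutual exclusivity on a 2×2 table and
prints `{"odds_ratio": 16.401869158878505, "p": 0.008170740190850574}` —
with A-at-−3 cryptic-exon usage shared by U2AF1 S34 and Q157 mutants,
EZH2 lesions concentrate in the Q157 group.

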