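"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal route available
(full translation, exhaustive enumeration) and stay independent of the
implementation paths they check.
"""

from __future__ import annotations

from math import comb

from spliceoscope.consequence import alternative_exons
from spliceoscope.core_io import Transcript

STOPS = ("TAA", "TAG", "TGA")
CODON_TABLE = None


def translate_to_stop(seq: str, start_1based: int) -> str:
    """Amino-acid string from a start position to the first stop codon,
    using codon identity only (X per sense codon is enough to compare
    products)."""
    out = []
    for i in range(start_1based - 1, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in STOPS:
            break
        out.append(codon)
    return "|".join(out)


def oracle_consequence(event, transcript: Transcript, genome: dict[str, str]) -> str:
    """Classify an event by fully translating canonical and alternative
    isoforms and comparing the products."""
    if not transcript.is_coding:
        return "non_coding"
    alt = Transcript(transcript.transcript_id + "|o", transcript.gene_id,
                     transcript.chrom, transcript.strand,
                     alternative_exons(event, transcript))
    can_seq = transcript.spliced_sequence(genome)
    alt_seq = alt.spliced_sequence(genome)
    cs, ce = transcript.cds_interval_in_transcript()
    start_g = transcript.cds_start if transcript.strand == "+" else transcript.cds_end
    stop_g = transcript.cds_end if transcript.strand == "+" else transcript.cds_start
    try:
        start_t = alt.genomic_to_transcript(start_g)
    except ValueError:
        return "alt_first_coding_exon"
    try:
        stop_t = alt.genomic_to_transcript(stop_g)
    except ValueError:
        return "alt_last_coding_exon"
    if alt_seq[start_t - 1:stop_t] == can_seq[cs - 1:ce]:
        return "non_coding"
    prot_can = translate_to_stop(can_seq, cs).split("|")
    prot_alt = translate_to_stop(alt_seq, start_t).split("|")
    tail = prot_can[-10:]
    if len(prot_alt) >= len(tail) and prot_alt[-len(tail):] == tail:
        return "non_truncating"
    return "truncating"


def fisher_two_sided_bruteforce(table) -> float:
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities
    of every margin-fixed table whose point probability is at most the
    observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def mann_whitney_exact_bruteforce(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by exhaustive enumeration of all
    label assignments (no ties expected)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    u_min_obs = min(u_obs, nx * len(y) - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(xs, ys)
        if min(u, nx * len(ys) - u) <= u_min_obs:
            count += 1
        total += 1
    return float(u_obs), count / total
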