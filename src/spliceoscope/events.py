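"""Alternative-splicing event enumeration and PSI quantification.

Events are typed by comparing observed splice junctions against annotated
introns. A novel junction is assigned to at most one event type using the
precedence rule alt 5'/3' splice site (shared anchor site) > cassette exon
(both flanks annotated) > mutually exclusive > alternative first/last exon,
so that one junction feeds one event. Intron-retention events are created
only for annotated introns, with exon–intron boundary counts as inclusion
evidence.

PSI (percent spliced in) is the fraction (x100) of reads supporting the
alternative isoform over total informative reads:
``PSI = 100 * inclusion / (inclusion + exclusion)``, with inclusion and
exclusion junction reads summed per set, undefined below a per-sample read
threshold (default 5). For intron retention the inclusion evidence is the
mean of the two boundary counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spliceoscope.core_io import (
    GeneModelSet,
    JunctionTable,
    boundary_key,
    junction_key,
)

logger = logging.getLogger(__name__)

EVENT_TYPES = (
    "cassette_exon",
    "alt_5ss",
    "alt_3ss",
    "intron_retention",
    "mutually_exclusive",
    "alt_first_exon",
    "alt_last_exon",
)

#: maximum distance of an alternative 5'/3' splice site from the annotated one
MAX_ALT_SS_OFFSET = 500


@dataclass(frozen=True)
class SpliceEvent:
    """A typed alternative-splicing event anchored to a transcript.

    ``inclusion`` holds evidence keys for the *alternative* isoform
    (junction keys, or the two boundary ids for intron retention);
    ``exclusion`` holds canonical-isoform junction keys. ``offset`` is the
    signed displacement (nt, transcript orientation; negative = upstream)
    of the alternative splice site for alt 5'/3'SS events. Geometry fields
    (``intron``, ``alt_intron``, ``exon``) carry what isoform
    reconstruction needs.
    """

    event_id: str
    etype: str
    chrom: str
    strand: str
    gene_id: str
    transcript_id: str
    inclusion: tuple[str, ...]
    exclusion: tuple[str, ...]
    offset: int | None = None
    intron: tuple[int, int] | None = None
    alt_intron: tuple[int, int] | None = None
    exon: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype}")
        if not self.inclusion or not self.exclusion:
            raise ValueError(f"{self.event_id}: inclusion and exclusion must be non-empty")
        if set(self.inclusion) & set(self.exclusion):
            raise ValueError(f"{self.event_id}: inclusion/exclusion sets overlap")
        if self.etype in ("alt_5ss", "alt_3ss"):
            if self.offset is None or abs(self.offset) > MAX_ALT_SS_OFFSET:
                raise ValueError(f"{self.event_id}: alt SS offset out of range")


def make_event_id(gene_id: str, etype: str, chrom: str, span: tuple[int, int],
                  strand: str) -> str:
    return f"{gene_id}|{etype}|{chrom}:{span[0]}-{span[1]}:{strand}"


def _donor_acceptor(start: int, end: int, strand: str) -> tuple[int, int]:
    """Genomic positions of the donor (5') and acceptor (3') intronic ends."""
    return (start, end) if strand == "+" else (end, start)


def make_alt_ss_event(models_or_tx, etype: str, canonical: tuple[int, int],
                      alt: tuple[int, int], transcript) -> SpliceEvent:
    """Construct an alt 5'/3' splice-site event from canonical/alternative
    intron extents (shared by enumeration and the simulator so ids agree)."""
    t = transcript
    strand = t.strand
    can_d, can_a = _donor_acceptor(*canonical, strand)
    alt_d, alt_a = _donor_acceptor(*alt, strand)
    sign = 1 if strand == "+" else -1
    if etype == "alt_3ss":
        offset = sign * (alt_a - can_a)
    else:
        offset = sign * (alt_d - can_d)
    return SpliceEvent(
        event_id=make_event_id(t.gene_id, etype, t.chrom, alt, strand),
        etype=etype,
        chrom=t.chrom,
        strand=strand,
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        inclusion=(junction_key(t.chrom, alt[0], alt[1], strand),),
        exclusion=(junction_key(t.chrom, canonical[0], canonical[1], strand),),
        offset=offset,
        intron=canonical,
        alt_intron=alt,
    )


def make_cassette_event(transcript, exon_index: int) -> SpliceEvent:
    """Cassette event for exon ``exon_index`` (0-based, genomic order) of a
    transcript; the alternative isoform is the *skipping* isoform."""
    t = transcript
    exon = t.exons[exon_index]
    up_intron = t.introns[exon_index - 1]
    down_intron = t.introns[exon_index]
    skip = (up_intron[0], down_intron[1])
    return SpliceEvent(
        event_id=make_event_id(t.gene_id, "cassette_exon", t.chrom, exon, t.strand),
        etype="cassette_exon",
        chrom=t.chrom,
        strand=t.strand,
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        inclusion=(junction_key(t.chrom, skip[0], skip[1], t.strand),),
        exclusion=(
            junction_key(t.chrom, up_intron[0], up_intron[1], t.strand),
            junction_key(t.chrom, down_intron[0], down_intron[1], t.strand),
        ),
        intron=None,
        exon=exon,
    )


def make_ir_event(transcript, intron_index: int) -> SpliceEvent:
    t = transcript
    intron = t.introns[intron_index]
    return SpliceEvent(
        event_id=make_event_id(t.gene_id, "intron_retention", t.chrom, intron, t.strand),
        etype="intron_retention",
        chrom=t.chrom,
        strand=t.strand,
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        inclusion=(
            boundary_key(t.chrom, intron[0], intron[1], t.strand, "L"),
            boundary_key(t.chrom, intron[0], intron[1], t.strand, "R"),
        ),
        exclusion=(junction_key(t.chrom, intron[0], intron[1], t.strand),),
        intron=intron,
    )


def make_terminal_exon_event(anchor, alt_transcript, which: str) -> SpliceEvent:
    """Alternative first/last exon event: the alternative transcript's
    terminal exon replaces the anchor's, evidenced by their distinct
    terminal junctions."""
    etype = "alt_first_exon" if which == "first" else "alt_last_exon"
    # terminal exon in transcript orientation
    first_genomic = (which == "first") == (anchor.strand == "+")
    idx = 0 if first_genomic else -1
    anchor_intron = anchor.introns[0] if first_genomic else anchor.introns[-1]
    alt_intron = alt_transcript.introns[0] if first_genomic else alt_transcript.introns[-1]
    alt_exon = alt_transcript.exons[idx]
    return SpliceEvent(
        event_id=make_event_id(anchor.gene_id, etype, anchor.chrom, alt_exon, anchor.strand),
        etype=etype,
        chrom=anchor.chrom,
        strand=anchor.strand,
        gene_id=anchor.gene_id,
        transcript_id=anchor.transcript_id,
        inclusion=(junction_key(anchor.chrom, alt_intron[0], alt_intron[1], anchor.strand),),
        exclusion=(junction_key(anchor.chrom, anchor_intron[0], anchor_intron[1],
                                anchor.strand),),
        exon=alt_exon,
    )


def anchor_transcript(models: GeneModelSet, gene_id: str):
    """Anchor = the longest-CDS transcript of the gene (ties: id order);
    falls back to the longest transcript for non-coding genes."""
    txs = sorted(models.transcripts_of_gene(gene_id), key=lambda t: t.transcript_id)
    coding = [t for t in txs if t.is_coding]
    if coding:
        return max(coding, key=lambda t: (t.cds_length, t.transcript_id))
    return max(txs, key=lambda t: (t.length, t.transcript_id))


def enumerate_events(models: GeneModelSet, junctions: JunctionTable) -> list[SpliceEvent]:
    """Enumerate typed splicing events from gene models plus observed
    junctions; deterministic and independent of sample order."""
    annotated = models.annotated_introns()
    chroms = models.chromosomes

    # index annotated introns by (chrom, strand, donor) and (chrom, strand, acceptor)
    by_donor: dict[tuple, list] = {}
    by_acceptor: dict[tuple, list] = {}
    for key, (tid, _) in annotated.items():
        chrom, span, strand = key.rsplit(":", 2)
        s, e = (int(x) for x in span.split("-"))
        d, a = _donor_acceptor(s, e, strand)
        by_donor.setdefault((chrom, strand, d), []).append((s, e, tid))
        by_acceptor.setdefault((chrom, strand, a), []).append((s, e, tid))

    # annotated splice-site pairs per transcript for cassette detection
    tx_sites = {}
    for tid, t in models.transcripts.items():
        tx_sites[tid] = {intr: i for i, intr in enumerate(t.introns)}

    obs = junctions.junctions[["chrom", "intron_start", "intron_end", "strand"]]
    obs = obs.drop_duplicates().sort_values(["chrom", "intron_start", "intron_end", "strand"])

    events: dict[str, SpliceEvent] = {}
    skipped_chroms = 0
    unclassified = 0
    cassette_meta: dict[str, tuple[str, int]] = {}  # event_id -> (tid, exon_index)

    for chrom, s, e, strand in obs.itertuples(index=False):
        if chrom not in chroms:
            skipped_chroms += 1
            continue
        key = junction_key(chrom, s, e, strand)
        if key in annotated:
            continue
        d, a = _donor_acceptor(s, e, strand)
        # alt 3'SS: shared annotated donor, *unannotated* acceptor within
        # 500 nt of the annotated acceptor (an annotated acceptor at the
        # other end means a skipping junction, handled below)
        ev = None
        acceptor_annotated = (chrom, strand, a) in by_acceptor
        donor_annotated = (chrom, strand, d) in by_donor
        if not acceptor_annotated:
            for cs, ce, tid in by_donor.get((chrom, strand, d), []):
                can_a = _donor_acceptor(cs, ce, strand)[1]
                if a != can_a and abs(a - can_a) <= MAX_ALT_SS_OFFSET:
                    ev = make_alt_ss_event(models, "alt_3ss", (cs, ce), (s, e),
                                           models.transcripts[tid])
                    break
        if ev is None and not donor_annotated:
            for cs, ce, tid in by_acceptor.get((chrom, strand, a), []):
                can_d = _donor_acceptor(cs, ce, strand)[0]
                if d != can_d and abs(d - can_d) <= MAX_ALT_SS_OFFSET:
                    ev = make_alt_ss_event(models, "alt_5ss", (cs, ce), (s, e),
                                           models.transcripts[tid])
                    break
        if ev is None:
            # cassette: donor of intron i joined to the acceptor of the next
            # intron in transcript direction, skipping the exon between them
            for cs, ce, tid in by_donor.get((chrom, strand, d), []):
                t = models.transcripts[tid]
                i = tx_sites[tid].get((cs, ce))
                if i is None:
                    continue
                j = i + 1 if strand == "+" else i - 1  # next intron, 5'→3'
                if not 0 <= j < len(t.introns):
                    continue
                nxt = t.introns[j]
                skip = (cs, nxt[1]) if strand == "+" else (nxt[0], ce)
                if _donor_acceptor(*nxt, strand)[1] == a and (s, e) == skip:
                    exon_idx = max(i, j)  # genomic index of the skipped exon
                    ev = make_cassette_event(t, exon_idx)
                    cassette_meta[ev.event_id] = (tid, exon_idx)
                    break
        if ev is None:
            unclassified += 1
            continue
        events.setdefault(ev.event_id, ev)

    observed_keys = {
        junction_key(c, s, e, st)
        for c, s, e, st in obs.itertuples(index=False)
    }
    _merge_mutually_exclusive(models, events, cassette_meta, observed_keys)

    # alternative terminal exons: annotation-declared (a second transcript
    # whose first/last exon differs from the anchor's) plus junction support
    for ev in _terminal_events(models, observed_keys):
        events.setdefault(ev.event_id, ev)

    # intron retention: only annotated introns, only where boundary data exist
    if junctions.boundaries is not None and not junctions.boundaries.empty:
        have = set(junctions.boundaries["boundary_id"])
        for key, (tid, _) in annotated.items():
            t = models.transcripts[tid]
            chrom, span, strand = key.rsplit(":", 2)
            s, e = (int(x) for x in span.split("-"))
            if boundary_key(chrom, s, e, strand, "L") in have:
                idx = tx_sites[tid][(s, e)]
                ev = make_ir_event(t, idx)
                events.setdefault(ev.event_id, ev)

    if skipped_chroms:
        logger.warning("skipped %d junctions on chromosomes absent from models",
                       skipped_chroms)
    if unclassified:
        logger.info("%d novel junctions did not match any event type", unclassified)
    return [events[k] for k in sorted(events)]


def _terminal_events(models: GeneModelSet, observed_keys: set[str]):
    """Alt first/last exon events declared by the annotation and supported
    by an observed junction from the alternative terminal exon."""
    out = []
    for gid in sorted(models.genes):
        txs = models.transcripts_of_gene(gid)
        if len(txs) < 2:
            continue
        anchor = anchor_transcript(models, gid)
        if not anchor.introns:
            continue
        for t in sorted(txs, key=lambda x: x.transcript_id):
            if t.transcript_id == anchor.transcript_id or not t.introns:
                continue
            for which in ("first", "last"):
                first_genomic = (which == "first") == (anchor.strand == "+")
                alt_intron = t.introns[0] if first_genomic else t.introns[-1]
                anchor_intron = (anchor.introns[0] if first_genomic
                                 else anchor.introns[-1])
                alt_exon = t.exons[0 if first_genomic else -1]
                anchor_exon = anchor.exons[0 if first_genomic else -1]
                if alt_intron == anchor_intron or alt_exon == anchor_exon:
                    continue
                key = junction_key(t.chrom, alt_intron[0], alt_intron[1], t.strand)
                if key in observed_keys:
                    out.append(make_terminal_exon_event(anchor, t, which))
    return out


def _merge_mutually_exclusive(models, events, cassette_meta, observed_keys) -> None:
    """Replace pairs of cassette events on adjacent exons with one
    mutually_exclusive event when no observed junction joins the two exons
    (so they are never co-included in the data)."""
    by_tx: dict[str, list[tuple[int, str]]] = {}
    for eid, (tid, idx) in cassette_meta.items():
        by_tx.setdefault(tid, []).append((idx, eid))
    for tid, items in by_tx.items():
        t = models.transcripts[tid]
        items.sort()
        for (i, eid_a), (j, eid_b) in zip(items, items[1:]):
            if j != i + 1 or eid_a not in events or eid_b not in events:
                continue
            middle = t.introns[i]  # intron between exon i and exon i+1 = j
            if junction_key(t.chrom, middle[0], middle[1], t.strand) in observed_keys:
                continue
            ev_a, ev_b = events.pop(eid_a), events.pop(eid_b)
            span = (t.exons[i][0], t.exons[j][1])
            mxe = SpliceEvent(
                event_id=make_event_id(t.gene_id, "mutually_exclusive", t.chrom, span,
                                       t.strand),
                etype="mutually_exclusive",
                chrom=t.chrom,
                strand=t.strand,
                gene_id=t.gene_id,
                transcript_id=tid,
                inclusion=ev_a.inclusion,   # exon-i-skipping isoform (uses exon j)
                exclusion=ev_b.inclusion,   # exon-j-skipping isoform (uses exon i)
                exon=span,
            )
            events[mxe.event_id] = mxe


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


@dataclass
class PsiMatrix:
    """Events × samples PSI values (percent, NaN where undefined) with the
    supporting inclusion/exclusion read totals."""

    psi: pd.DataFrame = field(repr=False)
    inclusion: pd.DataFrame = field(repr=False)
    exclusion: pd.DataFrame = field(repr=False)
    events: dict[str, SpliceEvent] = field(default_factory=dict, repr=False)
    min_reads: int = 5

    @property
    def event_ids(self) -> list[str]:
        return self.psi.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.psi.columns.tolist()

    def event_type(self, event_id: str) -> str:
        return self.events[event_id].etype


def compute_psi(events: list[SpliceEvent], junctions: JunctionTable,
                min_reads: int = 5) -> PsiMatrix:
    """Quantify PSI for every event and sample.

    The read threshold applies to the inclusion+exclusion total per sample;
    evidence keys absent from the table count as zero (logged).
    """
    counts = junctions.counts_by_key()
    bcounts = junctions.boundary_counts()
    samples = sorted(set(counts.columns) | set(bcounts.columns if not bcounts.empty else []))
    counts = counts.reindex(columns=samples, fill_value=0)
    if not bcounts.empty:
        bcounts = bcounts.reindex(columns=samples, fill_value=0)

    zero = np.zeros(len(samples))
    missing_keys = 0

    def lookup(key: str, is_boundary: bool) -> np.ndarray:
        nonlocal missing_keys
        src = bcounts if is_boundary else counts
        if src.empty or key not in src.index:
            missing_keys += 1
            return zero
        return src.loc[key].to_numpy(dtype=float)

    inc_rows, exc_rows, ids = [], [], []
    for ev in events:
        if ev.etype == "intron_retention":
            inc = np.mean([lookup(k, True) for k in ev.inclusion], axis=0)
        else:
            inc = np.sum([lookup(k, False) for k in ev.inclusion], axis=0)
        exc = np.sum([lookup(k, False) for k in ev.exclusion], axis=0)
        inc_rows.append(inc)
        exc_rows.append(exc)
        ids.append(ev.event_id)

    inc_df = pd.DataFrame(inc_rows, index=ids, columns=samples)
    exc_df = pd.DataFrame(exc_rows, index=ids, columns=samples)
    total = inc_df + exc_df
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = 100.0 * inc_df / total
    psi = psi.where(total >= min_reads)
    if missing_keys:
        logger.info("%d evidence keys absent from junction table (counted as 0)",
                    missing_keys)
    return PsiMatrix(psi=psi, inclusion=inc_df, exclusion=exc_df,
                     events={e.event_id: e for e in events}, min_reads=min_reads)


def intronic_read_fraction(coverage: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of reads mapped to intronic regions:
    intronic / (intronic + exonic); NaN (flagged) for zero-total samples."""
    piv = coverage.pivot_table(index="sample_id", columns="region_class",
                               values="count", aggfunc="sum", fill_value=0)
    for cls in ("exonic", "intronic"):
        if cls not in piv.columns:
            piv[cls] = 0
    total = piv["exonic"] + piv["intronic"]
    frac = piv["intronic"] / total.where(total > 0)
    if frac.isna().any():
        logger.warning("samples with zero coverage: %s",
                       frac.index[frac.isna()].tolist())
    return frac.rename("intronic_read_fraction")
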