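"""Transcript-level consequences of splicing events.

Each event is applied to its anchor transcript (longest CDS among the
gene's transcripts) to reconstruct the alternative mRNA, and the change is
classified into one of five classes: truncating (frameshift or in-frame
premature termination codon), non-truncating, alternative first coding
exon, alternative last coding exon, or a change confined to non-coding
regions.

A PTC is any in-frame stop strictly 5' of the annotated stop codon in the
reconstructed isoform. Frameshifts are labelled truncating regardless of
where (or whether) a new stop occurs. The 50-nt exon-junction rule for
predicted NMD is emitted as an auxiliary annotation only; NMD sensitivity
itself is determined empirically from CHX experiments elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from spliceoscope.core_io import GeneModelSet, Transcript
from spliceoscope.events import SpliceEvent, anchor_transcript

STOPS = ("TAA", "TAG", "TGA")


class ReconstructionError(ValueError):
    """Event cannot be applied to the given transcript."""


@dataclass(frozen=True)
class ConsequenceLabel:
    """Classified transcript-level consequence of one event."""

    event_id: str
    transcript_id: str
    consequence: str   # truncating | non_truncating | alt_first_coding_exon |
    #                    alt_last_coding_exon | non_coding
    mechanism: str     # frameshift | PTC_in_frame | none
    length_change: int
    ptc_position: int | None = None   # transcript coordinate in the alt isoform
    nmd_50nt_rule: bool | None = None  # auxiliary: PTC >50 nt upstream of the
    #                                    last exon–exon junction
    non_coding_transcript: bool = False


def _parse_junction(key: str) -> tuple[str, int, int, str]:
    chrom, span, strand = key.rsplit(":", 2)
    s, e = span.split("-")
    return chrom, int(s), int(e), strand


def alternative_exons(event: SpliceEvent, transcript: Transcript) -> list[tuple[int, int]]:
    """Exon intervals (genomic, sorted) of the isoform with the event applied."""
    exons = list(transcript.exons)
    et = event.etype
    if et in ("alt_3ss", "alt_5ss"):
        if event.intron is None or event.alt_intron is None:
            raise ReconstructionError(f"{event.event_id}: missing intron geometry")
        s, e = event.intron
        up = next((i for i, (_, ee) in enumerate(exons) if ee == s - 1), None)
        dn = next((i for i, (ss, _) in enumerate(exons) if ss == e + 1), None)
        if up is None or dn is None:
            raise ReconstructionError(
                f"{event.event_id}: intron not flanked by transcript exons")
        a_s, a_e = event.alt_intron
        exons[up] = (exons[up][0], a_s - 1)
        exons[dn] = (a_e + 1, exons[dn][1])
    elif et == "intron_retention":
        s, e = event.intron
        up = next((i for i, (_, ee) in enumerate(exons) if ee == s - 1), None)
        if up is None or up + 1 >= len(exons) or exons[up + 1][0] != e + 1:
            raise ReconstructionError(f"{event.event_id}: intron not in transcript")
        merged = (exons[up][0], exons[up + 1][1])
        exons = exons[:up] + [merged] + exons[up + 2:]
    elif et in ("cassette_exon", "mutually_exclusive"):
        _, js, je, _ = _parse_junction(event.inclusion[0])
        removed = [ex for ex in exons if ex[0] > js and ex[1] < je]
        if not removed:
            raise ReconstructionError(
                f"{event.event_id}: no transcript exon inside the skip junction")
        exons = [ex for ex in exons if ex not in removed]
    elif et in ("alt_first_exon", "alt_last_exon"):
        if event.exon is None:
            raise ReconstructionError(f"{event.event_id}: missing alt terminal exon")
        first_genomic = (et == "alt_first_exon") == (transcript.strand == "+")
        exons = ([event.exon] + exons[1:]) if first_genomic else (exons[:-1] + [event.exon])
        exons = sorted(exons)
    else:
        raise ReconstructionError(f"unsupported event type {et}")
    if len(exons) < 1 or any(s > e for s, e in exons):
        raise ReconstructionError(f"{event.event_id}: degenerate reconstruction")
    return exons


def reconstruct_isoform(event: SpliceEvent, transcript: Transcript,
                        genome: dict[str, str]) -> tuple[str, tuple[int, int] | None]:
    """mRNA sequence of the alternative isoform and its CDS interval
    (1-based transcript coordinates), keeping the annotated start codon.

    The CDS is None when the transcript is non-coding or the start codon
    is removed by the event (classified alt_first_coding_exon downstream).
    """
    if transcript.chrom not in genome:
        raise ReconstructionError(f"no sequence for {transcript.chrom}")
    alt = Transcript(transcript.transcript_id + "|alt", transcript.gene_id,
                     transcript.chrom, transcript.strand,
                     alternative_exons(event, transcript))
    seq = alt.spliced_sequence(genome)
    if not transcript.is_coding:
        return seq, None
    start_g = (transcript.cds_start if transcript.strand == "+"
               else transcript.cds_end)
    try:
        start_t = alt.genomic_to_transcript(start_g)
    except ValueError:
        return seq, None
    # translate from the annotated start to the first in-frame stop
    for i in range(start_t - 1, len(seq) - 2, 3):
        if seq[i:i + 3] in STOPS:
            return seq, (start_t, i + 3)
    return seq, (start_t, len(seq))


def classify_consequence(event: SpliceEvent, transcript: Transcript,
                         genome: dict[str, str]) -> ConsequenceLabel:
    """Classify an event's transcript-level consequence (see module doc)."""
    if not transcript.is_coding:
        return ConsequenceLabel(event.event_id, transcript.transcript_id,
                                "non_coding", "none", 0,
                                non_coding_transcript=True)
    alt_exons = alternative_exons(event, transcript)
    alt = Transcript(transcript.transcript_id + "|alt", transcript.gene_id,
                     transcript.chrom, transcript.strand, alt_exons)
    alt_seq = alt.spliced_sequence(genome)
    can_seq = transcript.spliced_sequence(genome)
    cs, ce = transcript.cds_interval_in_transcript()
    canonical_cds = can_seq[cs - 1:ce]

    start_g = transcript.cds_start if transcript.strand == "+" else transcript.cds_end
    stop_g = transcript.cds_end if transcript.strand == "+" else transcript.cds_start
    try:
        start_t = alt.genomic_to_transcript(start_g)
    except ValueError:
        return ConsequenceLabel(event.event_id, transcript.transcript_id,
                                "alt_first_coding_exon", "none",
                                _net_length_change(transcript, alt))
    try:
        stop_t = alt.genomic_to_transcript(stop_g)
    except ValueError:
        return ConsequenceLabel(event.event_id, transcript.transcript_id,
                                "alt_last_coding_exon", "none",
                                _net_length_change(transcript, alt))

    alt_cds_span = alt_seq[start_t - 1:stop_t]
    if alt_cds_span == canonical_cds:
        return ConsequenceLabel(event.event_id, transcript.transcript_id,
                                "non_coding", "none",
                                _net_length_change(transcript, alt))
    delta = len(alt_cds_span) - len(canonical_cds)
    ptc = _first_inframe_stop(alt_seq, start_t, stop_t)
    if delta % 3 != 0:
        return ConsequenceLabel(event.event_id, transcript.transcript_id,
                                "truncating", "frameshift", delta, ptc,
                                _nmd_rule(alt, ptc))
    if ptc is not None:
        return ConsequenceLabel(event.event_id, transcript.transcript_id,
                                "truncating", "PTC_in_frame", delta, ptc,
                                _nmd_rule(alt, ptc))
    return ConsequenceLabel(event.event_id, transcript.transcript_id,
                            "non_truncating", "none", delta)


def _net_length_change(canonical: Transcript, alt: Transcript) -> int:
    return alt.length - canonical.length


def _first_inframe_stop(alt_seq: str, start_t: int, stop_t: int) -> int | None:
    """First stop codon in the start-codon frame strictly 5' of the
    annotated stop codon (whose last base sits at stop_t)."""
    for i in range(start_t - 1, len(alt_seq) - 2, 3):
        if alt_seq[i:i + 3] in STOPS:
            if i + 3 < stop_t:
                return i + 1           # premature stop
            return None                # annotated stop (or downstream of it)
    return None


def _nmd_rule(alt: Transcript, ptc_position: int | None) -> bool | None:
    """Auxiliary 50-nt rule: PTC more than 50 nt upstream of the last
    exon–exon junction predicts NMD."""
    if ptc_position is None:
        return None
    lengths = alt.exon_lengths
    if alt.strand == "-":
        lengths = lengths[::-1]
    if len(lengths) < 2:
        return False
    last_junction = sum(lengths[:-1])
    return (last_junction - (ptc_position + 2)) > 50


def classify_all(events: list[SpliceEvent], models: GeneModelSet,
                 genome: dict[str, str]) -> list[ConsequenceLabel]:
    """Classify every event against its gene's anchor transcript."""
    out = []
    for ev in events:
        tx = models.transcripts.get(ev.transcript_id)
        if tx is None or not tx.is_coding:
            tx = anchor_transcript(models, ev.gene_id)
        out.append(classify_consequence(ev, tx, genome))
    return out
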