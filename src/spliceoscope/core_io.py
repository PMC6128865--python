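"""Shared data model and readers/writers for all pipeline stages.

Coordinate convention: all coordinates are 1-based inclusive (GTF dialect).
Junction coordinates denote the first and last **intronic** bases, and
junction keys are strand-qualified. Sequence-level operations always work on
the sense strand (minus-strand features are reverse-complemented on access).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: columns of the package's minimal junction TSV dialect
JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "sample_id", "count"]
BOUNDARY_COLUMNS = ["boundary_id", "sample_id", "count"]
COVERAGE_COLUMNS = ["region_id", "region_class", "sample_id", "count"]

SF_GENES = ("SF3B1", "SRSF2", "U2AF1", "ZRSR2")


class AnnotationError(ValueError):
    """Malformed or internally inconsistent gene annotation."""


class ValidationError(ValueError):
    """Input table violates a data-model invariant."""


def junction_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def boundary_key(chrom: str, start: int, end: int, strand: str, side: str) -> str:
    """Identifier of an exon–intron boundary of the intron (start, end).

    ``side`` is 'L' for the boundary at the lower-coordinate end of the
    intron and 'R' for the higher-coordinate end.
    """
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    return f"{chrom}:{start}-{end}:{strand}:{side}"


@dataclass
class Transcript:
    """A transcript model: ordered exons plus an optional CDS.

    Exons are stored sorted by ascending genomic coordinate regardless of
    strand; ``cds_start``/``cds_end`` are genomic (min/max of the CDS span).
    A transcript without a CDS is non-coding.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(f"{self.transcript_id}: exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping or unordered exons near {s}"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.transcript_id}: partial CDS specification")
        if self.cds_start is not None:
            if not any(s <= self.cds_start <= e for s, e in self.exons) or not any(
                s <= self.cds_end <= e for s, e in self.exons
            ):
                raise AnnotationError(f"{self.transcript_id}: CDS outside exon union")
            if self.cds_length < 3:
                raise AnnotationError(f"{self.transcript_id}: CDS shorter than one codon")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons (first/last intronic bases)."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        return sum(
            min(e, self.cds_end) - max(s, self.cds_start) + 1
            for s, e in self.exons
            if e >= self.cds_start and s <= self.cds_end
        )

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position (must be exonic) to a 1-based transcript
        coordinate measured 5'→3' along the sense strand."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                plus_coord = offset + (pos - s) + 1
                if self.strand == "+":
                    return plus_coord
                return self.length - plus_coord + 1
            offset += e - s + 1
        raise ValueError(f"position {pos} is not exonic in {self.transcript_id}")

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Sense-strand mRNA sequence (exons concatenated)."""
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s - 1 : e] for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_interval_in_transcript(self) -> tuple[int, int] | None:
        """CDS as 1-based inclusive transcript coordinates, or None."""
        if not self.is_coding:
            return None
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end)
        return (min(a, b), max(a, b))


@dataclass
class GeneModelSet:
    """Validated set of gene/transcript models (the reference annotation)."""

    genes: dict[str, tuple[str, str]]  # gene_id -> (chrom, strand)
    transcripts: dict[str, Transcript]

    def __post_init__(self) -> None:
        for t in self.transcripts.values():
            if t.gene_id not in self.genes:
                raise AnnotationError(f"{t.transcript_id}: unknown gene {t.gene_id}")
            chrom, strand = self.genes[t.gene_id]
            if (t.chrom, t.strand) != (chrom, strand):
                raise AnnotationError(f"{t.transcript_id}: chrom/strand disagree with gene")

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    @property
    def chromosomes(self) -> set[str]:
        return {chrom for chrom, _ in self.genes.values()}

    def annotated_introns(self) -> dict[str, tuple[str, str]]:
        """Map junction key -> (transcript_id, gene_id) of every annotated
        intron (first transcript wins for shared introns)."""
        out: dict[str, tuple[str, str]] = {}
        for tid in sorted(self.transcripts):
            t = self.transcripts[tid]
            for s, e in t.introns:
                out.setdefault(junction_key(t.chrom, s, e, t.strand), (tid, t.gene_id))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModelSet):
            return NotImplemented
        return self.genes == other.genes and self.transcripts == other.transcripts


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def load_annotation(path: str | os.PathLike) -> GeneModelSet:
    """Load a GTF file into a validated :class:`GeneModelSet`.

    Exon and (optionally) CDS features are used; transcripts lacking CDS
    features are retained as non-coding. Raises :class:`AnnotationError`
    on malformed coordinates or overlapping exons.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        if feat.start > feat.end:
            raise AnnotationError(
                f"{path}: {feat.featuretype} start {feat.start} > end {feat.end} ({tid})"
            )
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))

    genes: dict[str, tuple[str, str]] = {}
    transcripts: dict[str, Transcript] = {}
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in exons:
            raise AnnotationError(f"{tid}: transcript has CDS but no exon features")
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        genes.setdefault(gid, (chrom, strand))
        transcripts[tid] = Transcript(tid, gid, chrom, strand, exons[tid], cds_start, cds_end)
    return GeneModelSet(genes, transcripts)


def write_gtf(models: GeneModelSet, path: str | os.PathLike, source: str = "spliceoscope") -> None:
    """Write a GeneModelSet as GTF (gene/transcript/exon/CDS rows)."""
    lines = []
    for gid in sorted(models.genes):
        chrom, strand = models.genes[gid]
        tids = sorted(t.transcript_id for t in models.transcripts_of_gene(gid))
        gstart = min(models.transcripts[t].exons[0][0] for t in tids)
        gend = max(models.transcripts[t].exons[-1][1] for t in tids)
        attrs = f'gene_id "{gid}";'
        lines.append(f"{chrom}\t{source}\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t{attrs}")
        for tid in tids:
            t = models.transcripts[tid]
            tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            lines.append(
                f"{chrom}\t{source}\ttranscript\t{t.exons[0][0]}\t{t.exons[-1][1]}"
                f"\t.\t{strand}\t.\t{tattrs}"
            )
            for s, e in t.exons:
                lines.append(f"{chrom}\t{source}\texon\t{s}\t{e}\t.\t{strand}\t.\t{tattrs}")
            if t.is_coding:
                for s, e in t.exons:
                    cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                    if cs <= ce:
                        lines.append(
                            f"{chrom}\t{source}\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t{tattrs}"
                        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def load_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

CELL_FRACTIONS = ("BMMNC", "CD34", "cell_line", "erythroid_d7", "erythroid_d14")


@dataclass
class SampleSheet:
    """Cohort design: genotypes, cell fraction, CHX pairing, clone identity.

    ``genotype`` is a per-sample map gene -> variant label (e.g.
    ``{"SF3B1": "K700E"}``); samples without splicing-factor mutations have
    none of ``SF3B1/SRSF2/U2AF1/ZRSR2`` as keys.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ["sample_id", "cell_fraction", "genotype", "chx_status", "pair_id", "clone_id"]

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_ids: {dups}")
        bad = set(df["cell_fraction"]) - set(CELL_FRACTIONS)
        if bad:
            raise ValidationError(f"unknown cell fractions: {sorted(bad)}")
        treated = df[df["chx_status"] == "treated"]
        untreated = df[df["chx_status"] == "untreated"]
        for pid in treated["pair_id"].dropna():
            if pid == "":
                continue
            n = (untreated["pair_id"] == pid).sum()
            if n != 1:
                raise ValidationError(
                    f"treated pair_id {pid!r} matches {n} untreated samples (need exactly 1)"
                )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def genotype_of(self, sample_id: str) -> dict[str, str]:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return parse_genotype(row["genotype"].iloc[0])

    def samples_with_mutation(self, spec: str, fraction: str | None = None) -> list[str]:
        """Samples carrying a mutation matching ``spec``.

        ``spec`` is either a gene name ("SF3B1": any variant) or
        "GENE:PREFIX" ("U2AF1:S34" matches S34F and S34Y)."""
        gene, _, prefix = spec.partition(":")
        out = []
        for _, row in self.table.iterrows():
            if fraction is not None and row["cell_fraction"] != fraction:
                continue
            gt = parse_genotype(row["genotype"])
            if gene in gt and gt[gene].startswith(prefix):
                out.append(row["sample_id"])
        return out

    def control_samples(self, fraction: str | None = None) -> list[str]:
        """Samples with no splicing-factor mutation."""
        out = []
        for _, row in self.table.iterrows():
            if fraction is not None and row["cell_fraction"] != fraction:
                continue
            gt = parse_genotype(row["genotype"])
            if not any(g in gt for g in SF_GENES):
                out.append(row["sample_id"])
        return out

    def chx_pairs(self) -> list[tuple[str, str]]:
        """(untreated, treated) sample-id pairs, ordered by pair_id."""
        df = self.table
        pairs = []
        for pid in sorted(p for p in df.loc[df["chx_status"] == "treated", "pair_id"] if p):
            u = df.loc[(df["pair_id"] == pid) & (df["chx_status"] == "untreated"), "sample_id"]
            t = df.loc[(df["pair_id"] == pid) & (df["chx_status"] == "treated"), "sample_id"]
            pairs.append((u.iloc[0], t.iloc[0]))
        return pairs


def parse_genotype(label: str) -> dict[str, str]:
    """Parse 'SF3B1:K700E;TET2:Q1523*' into a gene->variant map ('none' -> {})."""
    if not label or pd.isna(label) or label == "none":
        return {}
    out = {}
    for part in str(label).split(";"):
        gene, _, var = part.partition(":")
        out[gene.strip()] = var.strip()
    return out


def format_genotype(gt: dict[str, str]) -> str:
    if not gt:
        return "none"
    return ";".join(f"{g}:{v}" for g, v in sorted(gt.items()))


def load_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Junction table
# ---------------------------------------------------------------------------


@dataclass
class JunctionTable:
    """Per-sample junction read counts plus optional boundary/region coverage.

    ``junctions``: chrom, intron_start, intron_end, strand, sample_id, count.
    ``boundaries``: boundary_id, sample_id, count (exon–intron boundaries,
    inclusion evidence for intron retention).
    ``coverage``: region_id, region_class in {exonic, intronic}, sample_id,
    count (for the intronic-read-fraction summary).
    """

    junctions: pd.DataFrame = field(repr=False)
    boundaries: pd.DataFrame | None = field(default=None, repr=False)
    coverage: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.junctions
        missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"junction table missing columns: {missing}")
        df = df.astype(
            {"chrom": str, "intron_start": int, "intron_end": int, "strand": str,
             "sample_id": str, "count": int}
        )
        if (df["count"] < 0).any():
            raise ValidationError("negative junction counts")
        if (df["intron_start"] > df["intron_end"]).any():
            raise ValidationError("junction with intron_start > intron_end")
        keys = df[["chrom", "intron_start", "intron_end", "strand", "sample_id"]]
        if keys.duplicated().any():
            raise ValidationError("duplicate (junction, sample) rows")
        self.junctions = df.reset_index(drop=True)
        if self.boundaries is not None:
            b = self.boundaries.astype({"boundary_id": str, "sample_id": str, "count": int})
            if (b["count"] < 0).any():
                raise ValidationError("negative boundary counts")
            self.boundaries = b.reset_index(drop=True)
        if self.coverage is not None:
            c = self.coverage.astype(
                {"region_id": str, "region_class": str, "sample_id": str, "count": int}
            )
            bad = set(c["region_class"]) - {"exonic", "intronic"}
            if bad:
                raise ValidationError(f"unknown region classes: {sorted(bad)}")
            self.coverage = c.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.junctions["sample_id"].unique())

    def counts_by_key(self) -> pd.DataFrame:
        """Wide matrix: junction key × sample_id -> count (absent = 0)."""
        df = self.junctions.copy()
        df["key"] = [
            junction_key(c, s, e, st)
            for c, s, e, st in zip(
                df["chrom"], df["intron_start"], df["intron_end"], df["strand"]
            )
        ]
        return df.pivot_table(index="key", columns="sample_id", values="count",
                              fill_value=0, aggfunc="sum")

    def boundary_counts(self) -> pd.DataFrame:
        if self.boundaries is None or self.boundaries.empty:
            return pd.DataFrame()
        return self.boundaries.pivot_table(index="boundary_id", columns="sample_id",
                                           values="count", fill_value=0, aggfunc="sum")


def load_junction_table(
    path: str | os.PathLike,
    sheet: SampleSheet | None = None,
    boundaries_path: str | os.PathLike | None = None,
    coverage_path: str | os.PathLike | None = None,
) -> JunctionTable:
    """Load the junction TSV dialect (and optional boundary/coverage TSVs).

    When a sample sheet is supplied, every sample_id in the tables must be
    declared in it."""
    df = pd.read_csv(path, sep="\t")
    bdf = pd.read_csv(boundaries_path, sep="\t") if boundaries_path else None
    cdf = pd.read_csv(coverage_path, sep="\t") if coverage_path else None
    table = JunctionTable(df, bdf, cdf)
    if sheet is not None:
        known = set(sheet.sample_ids)
        unknown = sorted(set(table.junctions["sample_id"]) - known)
        if unknown:
            raise ValidationError(f"junction table references unknown samples: {unknown}")
    return table


def write_junction_table(table: JunctionTable, path: str | os.PathLike,
                         boundaries_path: str | os.PathLike | None = None,
                         coverage_path: str | os.PathLike | None = None) -> None:
    cols = JUNCTION_COLUMNS
    table.junctions[cols].sort_values(cols[:5]).to_csv(path, sep="\t", index=False)
    if boundaries_path and table.boundaries is not None:
        table.boundaries[BOUNDARY_COLUMNS].sort_values(BOUNDARY_COLUMNS[:2]).to_csv(
            boundaries_path, sep="\t", index=False)
    if coverage_path and table.coverage is not None:
        table.coverage[COVERAGE_COLUMNS].sort_values(COVERAGE_COLUMNS[:3]).to_csv(
            coverage_path, sep="\t", index=False)


def convert_sj_table(path: str | os.PathLike, sample_id: str) -> pd.DataFrame:
    """Convert the common 9-column splice-junction dialect (chrom, start,
    end, strand code 0/1/2, motif, annotated, unique, multi, overhang) to
    the package dialect, keeping uniquely mapped counts."""
    sj = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "strand_code", "motif",
                            "annotated", "unique", "multi", "overhang"])
    strand = sj["strand_code"].map({0: ".", 1: "+", 2: "-"})
    return pd.DataFrame({
        "chrom": sj["chrom"].astype(str),
        "intron_start": sj["start"].astype(int),
        "intron_end": sj["end"].astype(int),
        "strand": strand,
        "sample_id": sample_id,
        "count": sj["unique"].astype(int),
    })


# ---------------------------------------------------------------------------
# Generic results writer
# ---------------------------------------------------------------------------


def write_results_table(records, path: str | os.PathLike, float_precision: int = 6) -> None:
    """Write a homogeneous list of records (dicts / dataclasses / DataFrame)
    as TSV with deterministic column order and fixed float precision.

    write→read→write is byte-identical."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                rows.append(dict(r))
        schemas = {tuple(r.keys()) for r in rows}
        if len(schemas) > 1:
            raise ValidationError("records do not share a schema")
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g")


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
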