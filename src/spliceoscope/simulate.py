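"""Seeded synthetic-study generator with a complete ground-truth ledger.

From one seed this module emits a full toy study with the statistical
structure the analysis assumes:

* a reference — multi-exon gene models with CDS, exon/intron sequences in
  two intron regimes (short/GC-rich vs long/GC-poor), planted alternative
  splice sites, controllable CCNG/GGNG exon composition and acceptor
  −3/+1 context;
* mutation-stratified cohorts of junction counts with beta-binomially
  overdispersed PSI and event-type-specific planted effects (alternative
  3' splice-site spikes in SF3B1 groups, small broad intron-retention
  decreases, cassette-exon shifts in SRSF2/U2AF1 groups);
* paired CHX/untreated samples in which reads of PTC-bearing isoforms are
  depleted by an NMD survival factor d in untreated samples and restored
  (d→1) under CHX;
* gene-level negative-binomial counts coupled to truncating-event PSI;
* isogenic mutant/wild-type clone panels for recapitulation testing.

Fixing the seed fixes every emitted byte. Every nonzero planted effect
appears exactly once in the truth ledger.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from spliceoscope.core_io import (
    GeneModelSet,
    JunctionTable,
    SampleSheet,
    Transcript,
    format_genotype,
)
from spliceoscope.events import (
    SpliceEvent,
    make_alt_ss_event,
    make_cassette_event,
    make_ir_event,
    make_terminal_exon_event,
)

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CONSEQUENCE_CLASSES = (
    "truncating", "non_truncating", "alt_first_coding_exon",
    "alt_last_coding_exon", "non_coding",
)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class IntronRegime:
    """Log-normal intron length regime with a target GC fraction.

    Defaults reproduce the two populations seen in spliceosome-mutated
    myelodysplasia: retention-prone introns are short and GC-rich
    (median ≈0.41 kb, GC ≈54%) while constitutive introns are long and
    GC-poor (median ≈1.8 kb, GC ≈43%); log-sigma values are chosen so the
    simulated IQRs match the observed 0.16–1.1 kb and 0.58–5.8 kb."""

    median_bp: float
    log_sigma: float
    gc: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        ln = rng.lognormal(np.log(self.median_bp), self.log_sigma, size=n)
        return np.maximum(ln.astype(int), 70)


SHORT_GC_RICH = IntronRegime(median_bp=410.0, log_sigma=1.43, gc=0.54)
LONG_GC_POOR = IntronRegime(median_bp=1800.0, log_sigma=1.71, gc=0.43)


@dataclass
class PlantedEffect:
    """One bucket of planted events sharing a type, target group and effect.

    ``group`` is a mutation spec ("SF3B1", "U2AF1:S34", ...); ``delta_psi``
    is the absolute PSI shift (percentage points) in carriers of that
    mutation; ``nmd_d`` is the survival fraction of PTC-isoform reads under
    physiological NMD (1 = insensitive, 0 = completely degraded);
    ``consequence`` requests the transcript-level consequence realised by
    the planted site (None = determined by geometry)."""

    etype: str
    group: str
    n_events: int
    baseline_psi: float
    delta_psi: float
    consequence: str | None = None
    nmd_d: float = 1.0
    offset: int = -21
    couple_expression: bool = False
    motif_class: str | None = None  # exon class for cassette sites


def default_effects() -> list[PlantedEffect]:
    """Study-condition effect table: SF3B1-specific alternative 3' splice
    sites (largely truncating, NMD-sensitive), a broad mild intron-retention
    decrease, and cassette-exon shifts in SRSF2/U2AF1 groups."""
    return [
        PlantedEffect("alt_3ss", "SF3B1", 8, 1.0, 25.0, "truncating_ptc",
                      nmd_d=0.25, offset=-21, couple_expression=True),
        PlantedEffect("alt_3ss", "SF3B1", 4, 1.0, 25.0, "truncating_frameshift",
                      nmd_d=0.25, offset=-20, couple_expression=True),
        PlantedEffect("alt_3ss", "SF3B1", 4, 1.0, 25.0, "non_truncating", offset=-21),
        PlantedEffect("alt_3ss", "SF3B1", 4, 1.0, 25.0, "non_coding_utr", offset=-21),
        PlantedEffect("alt_5ss", "SF3B1", 4, 2.0, 10.0, offset=18),
        PlantedEffect("intron_retention", "SF3B1", 30, 15.0, -3.0),
        PlantedEffect("cassette_exon", "SRSF2", 8, 40.0, -15.0,
                      motif_class="included"),
        PlantedEffect("cassette_exon", "SRSF2", 8, 40.0, 15.0,
                      motif_class="skipped"),
        PlantedEffect("cassette_exon", "U2AF1:S34", 6, 30.0, 12.0),
        PlantedEffect("cassette_exon", "U2AF1:Q157", 6, 30.0, 12.0),
        PlantedEffect("alt_first_exon", "SRSF2", 2, 5.0, 10.0),
        PlantedEffect("alt_last_exon", "SRSF2", 2, 5.0, 10.0),
    ]


def default_cohort() -> dict[str, dict[str, int]]:
    """Cohort design per cell fraction (mutation spec -> group size)."""
    return {
        "BMMNC": {"SF3B1:K700E": 30, "SRSF2:P95H": 15, "U2AF1:S34F": 8,
                  "U2AF1:Q157R": 8, "control": 40},
    }


@dataclass
class SimulationConfig:
    """All tunable knobs of the synthetic study (see module docstring)."""

    seed: int = 0
    n_genes: int = 40                      # minimum; grows to fit planted sites
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_length: tuple[int, int] = (90, 240)
    utr5_length: int = 60
    utr3_length: int = 60
    frac_minus_strand: float = 0.3
    short_regime: IntronRegime = field(default_factory=lambda: SHORT_GC_RICH)
    long_regime: IntronRegime = field(default_factory=lambda: LONG_GC_POOR)
    frac_short_introns: float = 0.3        # retention-prone introns
    exon_gc: float = 0.50
    # cohort
    cohort: dict[str, dict[str, int]] = field(default_factory=default_cohort)
    effects: list[PlantedEffect] = field(default_factory=default_effects)
    n_null_events: int = 60
    null_baseline_range: tuple[float, float] = (10.0, 90.0)
    rho: float = 0.02                      # beta-binomial intraclass correlation
    depth: float = 100.0                   # mean informative reads per event/sample
    purity: float = 0.95                   # fraction of cells expressing the variant
    # intronic coverage summary
    coverage_depth: float = 10000.0
    intronic_coverage_fraction: float = 0.12
    ir_coverage_factor: float = 0.8        # applied to SF3B1 carriers
    # CHX experiment
    chx_pairs: dict[str, int] = field(
        default_factory=lambda: {"SF3B1:K700E": 4, "SRSF2:P95H": 0})
    chx_depth: float = 500.0
    n_chx_specific: int = 0                # planted d=0 events (invisible untreated)
    # clones
    n_clones_per_genotype: int = 3
    clone_rho: float = 0.002
    clone_depth: float = 300.0
    # expression
    expr_log_mean: float = np.log(200.0)
    expr_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    # motif composition (per-nt planted rates per exon quarter, 5'→3')
    motif_rates: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=lambda: {
            "constitutive": {"CCNG": (0.008,) * 4, "GGNG": (0.008,) * 4},
            "included": {"CCNG": (0.008, 0.008, 0.008, 0.016),
                         "GGNG": (0.008,) * 4},
            "skipped": {"CCNG": (0.008,) * 4,
                        "GGNG": (0.008, 0.008, 0.008, 0.016)},
        })
    # acceptor −3 base frequencies (last intronic base before the AG)
    minus3_freq: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "default": {"T": 0.70, "C": 0.24, "A": 0.04, "G": 0.02},
            "cryptic": {"A": 0.45, "C": 0.40, "T": 0.10, "G": 0.05},
        })

    def validate(self) -> None:
        for name, v in [("frac_minus_strand", self.frac_minus_strand),
                        ("frac_short_introns", self.frac_short_introns),
                        ("rho", self.rho), ("purity", self.purity)]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        for eff in self.effects:
            lo, hi = sorted((eff.baseline_psi, eff.baseline_psi + eff.delta_psi))
            if lo < 0.0 or hi > 100.0:
                raise ConfigError(
                    f"effect on {eff.etype}/{eff.group}: PSI leaves [0,100]")
            if not 0.0 <= eff.nmd_d <= 1.0:
                raise ConfigError("nmd_d must lie in [0,1]")
        for fraction, groups in self.cohort.items():
            for g, n in groups.items():
                if n < 2:
                    raise ConfigError(f"group {g} in {fraction} has size {n} (<2)")
        if self.exon_length[0] < 30:
            raise ConfigError("exons must be at least 30 nt for motif/CDS placement")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class EventSite:
    """Geometry and truth of one planted (or null) event site."""

    event: SpliceEvent
    baseline_psi: float
    effect: PlantedEffect | None = None
    consequence: str | None = None      # one of CONSEQUENCE_CLASSES, or None
    mechanism: str = "none"             # frameshift | PTC_in_frame | none
    length_change: int = 0


@dataclass
class Reference:
    """Simulated reference: models, genome and the planted-site registry."""

    models: GeneModelSet
    genome: dict[str, str]
    sites: list[EventSite]
    exon_classes: pd.DataFrame          # gene_id, chrom, strand, start, end, class
    gene_base_mean: pd.Series           # expression base means per gene
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            eff = s.effect
            rows.append({
                "event_id": s.event.event_id,
                "etype": s.event.etype,
                "gene_id": s.event.gene_id,
                "group": eff.group if eff else "",
                "baseline_psi": s.baseline_psi,
                "delta_psi": eff.delta_psi if eff else 0.0,
                "nmd_d": eff.nmd_d if eff else 1.0,
                "consequence": s.consequence or "",
                "mechanism": s.mechanism,
                "length_change": s.length_change,
                "couple_expression": bool(eff.couple_expression) if eff else False,
            })
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Complete ledger of every planted quantity of a simulated dataset."""

    events: pd.DataFrame
    exons: pd.DataFrame
    genes: pd.DataFrame


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    if n <= 0:
        return ""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=n, p=p)
    return bytes(_BASES[idx]).decode()


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _sample_base(rng: np.random.Generator, freq: dict[str, float]) -> str:
    bases = sorted(freq)
    p = np.array([freq[b] for b in bases], dtype=float)
    return rng.choice(bases, p=p / p.sum())


_MOTIF_BG = re.compile(r"(?=([CG][CG].G))")


def _scrub_motifs(rng: np.random.Generator, seq: str) -> str:
    """Destroy background SSNG (CC.G / GG.G) matches by mutating the
    second base to A (cannot create a new S,S pair)."""
    s = list(seq)
    for _ in range(4):
        hits = [m.start() for m in _MOTIF_BG.finditer("".join(s))]
        if not hits:
            break
        for h in hits:
            s[h + 1] = "A"
    return "".join(s)


_MIN_PLANT_SPACING = 7


def _plant_motifs(rng: np.random.Generator, seq: str,
                  rates: dict[str, tuple[float, ...]]) -> str:
    """Plant motif instances at per-quarter Poisson rates (first base in
    the quarter).

    Instances are spaced so their ±3 nt neighbourhoods do not interact,
    and incidental matches created at an instance's flanks are destroyed
    (offending background base set to A, which cannot participate in an
    SSNG-family match). Each planted instance therefore contributes
    exactly one overlapping-countable match, keeping realized densities
    Poisson at the configured rates."""
    s = list(seq)
    L = len(s)
    if L < 8:
        return seq
    bounds = [round(q * L / 4) for q in range(5)]
    taken: set[int] = set()
    for motif in sorted(rates):
        for q in range(4):
            lo, hi = bounds[q], bounds[q + 1]
            n = rng.poisson(rates[motif][q] * (hi - lo))
            slots = [i for i in range(lo, min(hi, L - 3))
                     if all(abs(i - t) >= _MIN_PLANT_SPACING for t in taken)]
            if not slots or n == 0:
                continue
            chosen = rng.choice(slots, size=min(n, len(slots)), replace=False)
            for i in np.sort(chosen):
                if any(abs(i - t) < _MIN_PLANT_SPACING for t in taken):
                    continue
                i = int(i)
                inst = list(motif)
                for j, ch in enumerate(inst):
                    if ch == "N":
                        inst[j] = "ACGT"[rng.integers(4)]
                    elif ch == "S":
                        inst[j] = "CG"[rng.integers(2)]
                s[i:i + 4] = inst
                taken.add(i)
                # destroy incidental matches straddling the instance
                for j in range(max(0, i - 3), min(i + 4, L - 3)):
                    if j == i:
                        continue
                    window = "".join(s[j:j + 4])
                    if (window[0] in "CG" and window[1] in "CG"
                            and window[3] == "G"):
                        # background, non-wildcard position to overwrite
                        bg = [p for p in range(j, j + 4)
                              if (p < i or p > i + 3) and p != j + 2]
                        if bg:
                            s[bg[0]] = "A"
    return "".join(s)


def count_motif(seq: str, motif: str) -> int:
    """Overlapping IUPAC motif matches (S = C/G, N = any)."""
    trans = {"S": "[CG]", "N": "."}
    pat = "".join(trans.get(c, c) for c in motif.upper())
    return len(re.findall(f"(?=({pat}))", seq.upper()))


# ---------------------------------------------------------------------------
# Gene assembly
# ---------------------------------------------------------------------------


@dataclass
class _GeneDraft:
    """Sense-space scaffold of one gene before contig assembly."""

    gene_id: str
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    cds_lo: int          # transcript coordinates, 1-based inclusive
    cds_hi: int
    site_kind: str | None = None        # requested archetype
    site_payload: dict = field(default_factory=dict)
    exon_class: dict[int, str] = field(default_factory=dict)  # exon idx -> class


def _transcript_exon_bounds(exon_seqs: list[str]) -> list[tuple[int, int]]:
    out, pos = [], 0
    for s in exon_seqs:
        out.append((pos + 1, pos + len(s)))
        pos += len(s)
    return out


def _cds_of(draft: _GeneDraft) -> str:
    tx = "".join(draft.exon_seqs)
    return tx[draft.cds_lo - 1 : draft.cds_hi]


def _scan_consequence(canonical_cds: str, alt_cds_region: str,
                      length_change: int) -> tuple[str, str]:
    """(class, mechanism) of a CDS-internal change by reading-frame
    arithmetic: frameshift if the net length change is not a multiple of 3,
    else PTC_in_frame if a new in-frame stop appears upstream of the
    annotated stop, else non_truncating."""
    if length_change % 3 != 0:
        return "truncating", "frameshift"
    body = alt_cds_region[: len(canonical_cds) - 3 + length_change]
    for i in range(0, len(body) - 2, 3):
        if body[i:i + 3] in STOPS:
            return "truncating", "PTC_in_frame"
    return "non_truncating", "none"


def _build_gene(rng: np.random.Generator, cfg: SimulationConfig, gene_id: str,
                kind: str | None, payload: dict) -> _GeneDraft:
    """Draft one gene; ``kind`` requests a planted-site archetype."""
    lo, hi = cfg.exons_per_gene
    n_exons = int(rng.integers(max(lo, 3), hi + 1))
    elo, ehi = cfg.exon_length
    exon_lens = rng.integers(elo, ehi + 1, size=n_exons)
    strand = "-" if rng.random() < cfg.frac_minus_strand else "+"

    utr5 = cfg.utr5_length
    if kind == "alt_3ss" and payload.get("consequence") == "non_coding_utr":
        # first intron must lie inside the 5'UTR: start codon in exon 2
        utr5 = int(exon_lens[0]) + 30
    utr3 = cfg.utr3_length
    total = int(exon_lens.sum())
    cds_len = total - utr5 - utr3
    cds_len -= cds_len % 3
    if cds_len < 60:
        grow = 60 - cds_len + 3
        exon_lens[-1] += grow
        total = int(exon_lens.sum())
        cds_len = total - utr5 - utr3
        cds_len -= cds_len % 3
    # UTRs use the same stop-free codon pool as the CDS so exonic base
    # composition is homogeneous (fully coding vs UTR-containing exons
    # would otherwise differ slightly in C content, biasing motif ratios)
    utr3_len = total - utr5 - cds_len
    tx_seq = (_rand_cds(rng, utr5 // 3 + 1)[:utr5] + "ATG"
              + _rand_cds(rng, cds_len // 3 - 2) + "TAA"
              + _rand_cds(rng, utr3_len // 3 + 1)[:utr3_len])
    exon_seqs, pos = [], 0
    for L in exon_lens:
        exon_seqs.append(tx_seq[pos:pos + int(L)])
        pos += int(L)

    # introns
    n_short = int(rng.binomial(n_exons - 1, cfg.frac_short_introns))
    short_idx = set(rng.choice(n_exons - 1, size=n_short, replace=False).tolist())
    intron_seqs = []
    for i in range(n_exons - 1):
        regime = cfg.short_regime if i in short_idx else cfg.long_regime
        L = int(regime.sample(rng, 1)[0])
        body = _rand_seq(rng, L - 5, regime.gc)
        m3 = _sample_base(rng, cfg.minus3_freq["default"])
        intron_seqs.append("GT" + body + m3 + "AG")
    if kind == "intron_retention":
        # retention-prone introns come from the short/GC-rich regime
        i = payload.setdefault("intron_index", 1 if n_exons > 2 else 0)
        L = int(cfg.short_regime.sample(rng, 1)[0])
        body = _rand_seq(rng, L - 5, cfg.short_regime.gc)
        intron_seqs[i] = ("GT" + body
                          + _sample_base(rng, cfg.minus3_freq["default"]) + "AG")

    return _GeneDraft(gene_id, strand, exon_seqs, intron_seqs,
                      utr5 + 1, utr5 + cds_len, kind, dict(payload))


def _plant_alt_ss(rng: np.random.Generator, cfg: SimulationConfig,
                  draft: _GeneDraft) -> None:
    """Install a cryptic acceptor (alt_3ss) or donor (alt_5ss) and shape
    the inserted segment for the requested transcript consequence."""
    kind = draft.site_kind
    payload = draft.site_payload
    offset = payload.get("offset", -21)
    k = abs(offset)
    consequence = payload.get("consequence")
    intron_idx = payload.get("intron_index")
    if intron_idx is None:
        intron_idx = 0 if consequence == "non_coding_utr" else \
            min(1, len(draft.intron_seqs) - 1)
        payload["intron_index"] = intron_idx
    intron = list(draft.intron_seqs[intron_idx])
    if len(intron) < k + 10:
        raise ConfigError(f"{draft.gene_id}: intron too short for offset {offset}")

    exon_bounds = _transcript_exon_bounds(draft.exon_seqs)
    insert_point = exon_bounds[intron_idx][1]  # after this transcript position

    n = len(intron)
    if kind == "alt_3ss":
        # cryptic AG at k nt upstream of the canonical acceptor, with a
        # configurable −3 context; the last k intronic bases become exonic
        intron[n - k - 2 : n - k] = ["A", "G"]
        intron[n - k - 3] = _sample_base(rng, cfg.minus3_freq["cryptic"])
        free = slice(n - k, n - 2)          # insert minus its trailing AG
        insert_start = n - k                # intron index of insert offset 0
        free_offsets = range(0, k - 2)      # insert offsets open to edits
        insert_of = lambda s: "".join(s[n - k:])
    else:  # alt_5ss: cryptic GT k nt downstream of the canonical donor
        intron[k : k + 2] = ["G", "T"]
        free = slice(2, k)
        insert_start = 0                    # insert = first k intronic bases
        free_offsets = range(2, k)          # offsets 0,1 are the canonical GT
        insert_of = lambda s: "".join(s[:k])

    cds = _cds_of(draft)
    in_cds = draft.cds_lo <= insert_point < draft.cds_hi
    if consequence == "non_coding_utr":
        if in_cds:
            raise ConfigError(f"{draft.gene_id}: UTR archetype intron is inside CDS")
        draft.site_payload.update(consequence_truth="non_coding", mechanism="none",
                                  length_change=k)
    elif not in_cds:
        draft.site_payload.update(consequence_truth="non_coding", mechanism="none",
                                  length_change=k)
    else:
        cds_offset = insert_point - (draft.cds_lo - 1)  # CDS nt before insert
        if consequence == "truncating_ptc":
            if k % 3 != 0:
                raise ConfigError("truncating_ptc requires a 3n insert")
            start = (3 - cds_offset % 3) % 3
            slots = [j for j in range(start, k - 2, 3)
                     if j in free_offsets and (j + 2) in free_offsets]
            if not slots:
                raise ConfigError(f"{draft.gene_id}: no in-frame slot for PTC")
            j = int(rng.choice(slots))
            intron[insert_start + j : insert_start + j + 3] = list("TAA")
            draft.site_payload.update(consequence_truth="truncating",
                                      mechanism="PTC_in_frame", length_change=k)
        elif consequence == "non_truncating":
            if k % 3 != 0:
                raise ConfigError("non_truncating requires a 3n insert")
            ok = False
            for _ in range(200):
                ins = insert_of(intron)
                alt_cds = cds[:cds_offset] + ins + cds[cds_offset:]
                cls, _mech = _scan_consequence(cds, alt_cds, k)
                if cls == "non_truncating":
                    ok = True
                    break
                nfree = free.stop - free.start
                intron[free] = list(_rand_seq(rng, nfree, 0.6))
            if not ok:
                raise ConfigError(f"{draft.gene_id}: could not realise a stop-free insert")
            draft.site_payload.update(consequence_truth="non_truncating",
                                      mechanism="none", length_change=k)
        else:  # frameshift or unconstrained: classify whatever was generated
            ins = insert_of(intron)
            alt_cds = cds[:cds_offset] + ins + cds[cds_offset:]
            cls, mech = _scan_consequence(cds, alt_cds, k)
            draft.site_payload.update(consequence_truth=cls, mechanism=mech,
                                      length_change=k)
    draft.intron_seqs[intron_idx] = "".join(intron)


def _resolve_cassette(draft: _GeneDraft) -> None:
    """Truth label for skipping the chosen cassette exon."""
    idx = draft.site_payload.setdefault("exon_index", len(draft.exon_seqs) // 2)
    bounds = _transcript_exon_bounds(draft.exon_seqs)
    lo, hi = bounds[idx]
    L = hi - lo + 1
    cds = _cds_of(draft)
    if hi < draft.cds_lo or lo > draft.cds_hi:
        cls, mech = "non_coding", "none"
    elif not (hi < draft.cds_lo or lo > draft.cds_lo + 2):
        cls, mech = "alt_first_coding_exon", "none"   # start codon removed
    elif not (hi < draft.cds_hi - 2 or lo > draft.cds_hi):
        cls, mech = "alt_last_coding_exon", "none"    # stop codon removed
    else:
        a, b = lo - draft.cds_lo, hi - draft.cds_lo + 1  # 0-based CDS slice
        alt_cds = cds[:a] + cds[b:]
        cls, mech = _scan_consequence(cds, alt_cds, -L)
    draft.site_payload.update(consequence_truth=cls, mechanism=mech,
                              length_change=-L)


def _resolve_alt_ss(draft: _GeneDraft) -> None:
    """Re-derive the truth label of an uncontrolled alt 5'/3' SS site from
    the final sequences (codons spanning the insert boundary involve exon
    bases that later edits may have changed)."""
    payload = draft.site_payload
    k = abs(payload.get("offset", -21))
    idx = payload["intron_index"]
    intron = draft.intron_seqs[idx]
    ins = intron[-k:] if draft.site_kind == "alt_3ss" else intron[:k]
    bounds = _transcript_exon_bounds(draft.exon_seqs)
    insert_point = bounds[idx][1]
    cds = _cds_of(draft)
    if draft.cds_lo <= insert_point < draft.cds_hi:
        off = insert_point - (draft.cds_lo - 1)
        cls, mech = _scan_consequence(cds, cds[:off] + ins + cds[off:], k)
    else:
        cls, mech = "non_coding", "none"
    payload.update(consequence_truth=cls, mechanism=mech, length_change=k)


def _resolve_ir(draft: _GeneDraft) -> None:
    idx = draft.site_payload["intron_index"]
    bounds = _transcript_exon_bounds(draft.exon_seqs)
    insert_point = bounds[idx][1]
    ins = draft.intron_seqs[idx]
    cds = _cds_of(draft)
    if draft.cds_lo <= insert_point < draft.cds_hi:
        off = insert_point - (draft.cds_lo - 1)
        alt_cds = cds[:off] + ins + cds[off:]
        cls, mech = _scan_consequence(cds, alt_cds, len(ins))
    else:
        cls, mech = "non_coding", "none"
    draft.site_payload.update(consequence_truth=cls, mechanism=mech,
                              length_change=len(ins))


def _repair_cds_stops(draft: _GeneDraft) -> None:
    """Remove in-frame stops accidentally introduced into the canonical CDS
    (e.g. by motif planting), keeping the annotated stop codon last."""
    exon_bounds = _transcript_exon_bounds(draft.exon_seqs)
    tx = "".join(draft.exon_seqs)
    cds = list(tx[draft.cds_lo - 1 : draft.cds_hi])
    changed = []
    for i in range(0, len(cds) - 3, 3):
        if "".join(cds[i:i + 3]) in STOPS:
            # T->A breaks the stop and can neither create nor destroy an
            # SSNG-family motif match (A is not S and not the terminal G)
            cds[i] = "A"
            changed.append(draft.cds_lo - 1 + i)
    if not changed:
        return
    tx_list = list(tx)
    tx_list[draft.cds_lo - 1 : draft.cds_hi] = cds
    tx = "".join(tx_list)
    draft.exon_seqs = [tx[lo - 1:hi] for lo, hi in exon_bounds]


# ---------------------------------------------------------------------------
# simulate_reference
# ---------------------------------------------------------------------------

_PAD = 80  # random flanking sequence per contig


def simulate_reference(config: SimulationConfig) -> Reference:
    """Emit the synthetic reference (models + genome + site registry).

    Deterministic under a fixed config seed. One planted site per gene;
    gene count grows as needed to host every configured effect and null
    event."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    # site requests: effects first (in order), then cycling null sites
    requests: list[tuple[str | None, dict]] = []
    for eff in config.effects:
        for j in range(eff.n_events):
            requests.append((eff.etype, {
                "effect": eff,
                "consequence": eff.consequence,
                "offset": eff.offset,
                "motif_class": eff.motif_class,
            }))
    for eff_d in range(config.n_chx_specific):
        requests.append(("alt_3ss", {
            "effect": PlantedEffect("alt_3ss", "SF3B1", 1, 40.0, 0.0,
                                    "truncating_ptc", nmd_d=0.0, offset=-21),
            "consequence": "truncating_ptc", "offset": -21, "motif_class": None,
        }))
    null_kinds = ["alt_3ss", "cassette_exon", "intron_retention"]
    for j in range(config.n_null_events):
        requests.append((null_kinds[j % 3], {"effect": None, "offset": -21,
                                             "consequence": None,
                                             "motif_class": None}))
    n_genes = max(config.n_genes, len(requests))
    while len(requests) < n_genes:
        requests.append((None, {}))

    genome: dict[str, str] = {}
    genes: dict[str, tuple[str, str]] = {}
    transcripts: dict[str, Transcript] = {}
    sites: list[EventSite] = []
    exon_rows: list[dict] = []

    for g, (kind, payload) in enumerate(requests):
        gene_id = f"G{g:05d}"
        draft = _build_gene(rng, config, gene_id, kind, payload)
        if kind in ("alt_3ss", "alt_5ss"):
            _plant_alt_ss(rng, config, draft)
        elif kind == "cassette_exon":
            _resolve_cassette(draft)
        elif kind == "intron_retention":
            _resolve_ir(draft)

        # motif classes: the cassette exon gets the requested class, all
        # other exons are constitutive; planting precedes truth resolution
        # for sequence-scanned kinds, so scrub/plant first, then re-resolve
        cassette_idx = (draft.site_payload.get("exon_index")
                        if kind == "cassette_exon" else None)
        content_controlled = payload.get("consequence") in (
            "truncating_ptc", "non_truncating", "non_coding_utr")
        for i, seq in enumerate(draft.exon_seqs):
            cls = "constitutive"
            if i == cassette_idx and payload.get("motif_class"):
                cls = payload["motif_class"]
            draft.exon_class[i] = cls
            if not content_controlled:
                seq = _scrub_motifs(rng, seq)
                seq = _plant_motifs(rng, seq, config.motif_rates[cls])
                draft.exon_seqs[i] = seq
        if not content_controlled:
            _repair_cds_stops(draft)
            if kind == "cassette_exon":
                _resolve_cassette(draft)
            elif kind == "intron_retention":
                _resolve_ir(draft)
            elif kind in ("alt_3ss", "alt_5ss"):
                _resolve_alt_ss(draft)

        # assemble the sense-space locus, then place on the contig;
        # terminal-exon archetypes add an alternative terminal exon plus
        # its own intron outside the anchor transcript's span
        alt_exon_len, alt_intron_len = 120, 200
        prefix = suffix = ""
        if kind == "alt_first_exon":
            prefix = (_rand_seq(rng, alt_exon_len, config.exon_gc) + "GT"
                      + _rand_seq(rng, alt_intron_len - 5, 0.45)
                      + _sample_base(rng, config.minus3_freq["default"]) + "AG")
        elif kind == "alt_last_exon":
            suffix = ("GT" + _rand_seq(rng, alt_intron_len - 5, 0.45)
                      + _sample_base(rng, config.minus3_freq["default"]) + "AG"
                      + _rand_seq(rng, alt_exon_len, config.exon_gc))
        pieces = []
        for i, e in enumerate(draft.exon_seqs):
            pieces.append(e)
            if i < len(draft.intron_seqs):
                pieces.append(draft.intron_seqs[i])
        body = "".join(pieces)
        sense = (_rand_seq(rng, _PAD, 0.4) + prefix + body + suffix
                 + _rand_seq(rng, _PAD, 0.4))
        chrom = f"ctg{gene_id}"
        N = len(sense)
        if draft.strand == "+":
            genome[chrom] = sense
            def to_genomic(a, b):
                return (a, b)
        else:
            comp = sense.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            genome[chrom] = comp
            def to_genomic(a, b):
                return (N - b + 1, N - a + 1)

        # sense-locus coordinates of exons
        pos = _PAD + len(prefix)
        exon_sense, intron_sense = [], []
        for i, e in enumerate(draft.exon_seqs):
            exon_sense.append((pos + 1, pos + len(e)))
            pos += len(e)
            if i < len(draft.intron_seqs):
                intron_sense.append((pos + 1, pos + len(draft.intron_seqs[i])))
                pos += len(draft.intron_seqs[i])
        exons_genomic = sorted(to_genomic(a, b) for a, b in exon_sense)

        # genomic CDS bounds from transcript coordinates
        bounds = _transcript_exon_bounds(draft.exon_seqs)
        def tx_to_sense(p):
            for (lo, hi), (sa, sb) in zip(bounds, exon_sense):
                if lo <= p <= hi:
                    return sa + (p - lo)
            raise AssertionError(p)
        cds_g = to_genomic(*sorted((tx_to_sense(draft.cds_lo),
                                    tx_to_sense(draft.cds_hi))))
        tid = f"{gene_id}.t1"
        tx = Transcript(tid, gene_id, chrom, draft.strand, exons_genomic,
                        min(cds_g), max(cds_g))
        genes[gene_id] = (chrom, draft.strand)
        transcripts[tid] = tx

        if kind in ("alt_first_exon", "alt_last_exon"):
            if kind == "alt_first_exon":
                alt_sense = (_PAD + 1, _PAD + alt_exon_len)
                kept = [to_genomic(a, b) for a, b in exon_sense[1:]]
            else:
                end_pos = _PAD + len(prefix) + len(body)
                alt_sense = (end_pos + alt_intron_len + 1,
                             end_pos + alt_intron_len + alt_exon_len)
                kept = [to_genomic(a, b) for a, b in exon_sense[:-1]]
            alt_genomic = tuple(sorted(to_genomic(*alt_sense)))
            tid2 = f"{gene_id}.t2"
            tx2 = Transcript(tid2, gene_id, chrom, draft.strand,
                             sorted([alt_genomic] + [tuple(sorted(g)) for g in kept]))
            transcripts[tid2] = tx2
            draft.site_payload["alt_transcript"] = tx2

        for i, (sa, sb) in enumerate(exon_sense):
            ga, gb = sorted(to_genomic(sa, sb))
            exon_rows.append({"gene_id": gene_id, "chrom": chrom,
                              "strand": draft.strand, "start": ga, "end": gb,
                              "exon_class": draft.exon_class[i]})

        site = _make_site(rng, config, draft, tx, intron_sense, to_genomic,
                          transcripts, genes)
        if site is not None:
            sites.append(site)

    models = GeneModelSet(genes, transcripts)
    base = pd.Series(
        np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd,
                          size=len(genes))),
        index=sorted(genes), name="base_mean")
    return Reference(models, genome, sites,
                     pd.DataFrame(exon_rows), base, config)


def _make_site(rng, config, draft, tx, intron_sense, to_genomic,
               transcripts, genes) -> EventSite | None:
    """Instantiate the SpliceEvent for a drafted gene's planted site."""
    kind = draft.site_kind
    if kind is None:
        return None
    payload = draft.site_payload
    eff: PlantedEffect | None = payload.get("effect")
    baseline = (eff.baseline_psi if eff else
                float(rng.uniform(*config.null_baseline_range)))

    # exon/intron indices are in transcript (sense) order; genomic order on
    # the minus strand is reversed
    n_ex = len(draft.exon_seqs)

    def genomic_exon_index(tx_index):
        return tx_index if draft.strand == "+" else n_ex - 1 - tx_index

    def genomic_intron_index(tx_index):
        return tx_index if draft.strand == "+" else (n_ex - 2) - tx_index

    if kind in ("alt_3ss", "alt_5ss"):
        i = payload["intron_index"]
        sa, sb = intron_sense[i]
        k = abs(payload.get("offset", -21))
        if kind == "alt_3ss":
            alt_sense = (sa, sb - k)
        else:
            alt_sense = (sa + k, sb)
        canonical = tuple(sorted(to_genomic(sa, sb)))
        alt = tuple(sorted(to_genomic(*alt_sense)))
        ev = make_alt_ss_event(None, kind, canonical, alt, tx)
    elif kind == "cassette_exon":
        ev = make_cassette_event(tx, genomic_exon_index(payload["exon_index"]))
    elif kind == "intron_retention":
        ev = make_ir_event(tx, genomic_intron_index(payload["intron_index"]))
    elif kind in ("alt_first_exon", "alt_last_exon"):
        tx2 = payload["alt_transcript"]
        which = "first" if kind == "alt_first_exon" else "last"
        ev = make_terminal_exon_event(tx, tx2, which)
        payload.setdefault("consequence_truth",
                           "alt_first_coding_exon" if kind == "alt_first_exon"
                           else "alt_last_coding_exon")
        payload.setdefault("mechanism", "none")
        payload.setdefault("length_change", 0)
    else:
        raise ConfigError(f"unsupported planted site kind {kind}")
    return EventSite(ev, baseline, eff,
                     payload.get("consequence_truth"),
                     payload.get("mechanism", "none"),
                     payload.get("length_change", 0))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _build_sample_sheet(config: SimulationConfig) -> SampleSheet:
    rows = []
    for fraction in sorted(config.cohort):
        for group in sorted(config.cohort[fraction]):
            n = config.cohort[fraction][group]
            for j in range(n):
                if group == "control":
                    gt, purity = {}, ""
                else:
                    gene, _, var = group.partition(":")
                    gt = {gene: var or "mut"}
                    purity = f"{config.purity:.2f}"
                rows.append({
                    "sample_id": f"{fraction}_{group.replace(':', '_')}_{j:03d}",
                    "cell_fraction": fraction,
                    "genotype": format_genotype(gt),
                    "chx_status": "untreated",
                    "pair_id": "",
                    "clone_id": "",
                    "purity": purity,
                })
    return SampleSheet(pd.DataFrame(rows))


def _betabin_inclusion(rng, mu_pct: np.ndarray, totals: np.ndarray,
                       rho: float) -> np.ndarray:
    """Beta-binomial inclusion draws: inclusion ~ Bin(total, Beta(mu, rho))."""
    mu = np.clip(mu_pct / 100.0, 1e-6, 1.0 - 1e-6)
    conc = 1.0 / rho - 1.0
    p = rng.beta(mu * conc, (1.0 - mu) * conc)
    return rng.binomial(totals, p)


def _allocate_rows(site: EventSite, samples: list[str], inc: np.ndarray,
                   exc: np.ndarray, jrows: list, brows: list) -> None:
    """Distribute event-level inclusion/exclusion counts over the event's
    evidence keys so that compute_psi recovers the drawn PSI exactly."""
    ev = site.event

    def parse(key):
        chrom, span, strand = key.rsplit(":", 2)
        s, e = span.split("-")
        return chrom, int(s), int(e), strand

    if ev.etype == "intron_retention":
        for key in ev.inclusion:  # two boundary ids; both carry `inc`
            brows.append((key, samples, inc))
    else:
        chrom, s, e, strand = parse(ev.inclusion[0])
        jrows.append((chrom, s, e, strand, samples, inc))
    n_exc = len(ev.exclusion)
    base = exc // n_exc
    rem = exc - base * n_exc
    for j, key in enumerate(ev.exclusion):
        chrom, s, e, strand = parse(key)
        cnt = base + (rem if j == 0 else 0)
        jrows.append((chrom, s, e, strand, samples, cnt))


def _rows_to_frames(jrows, brows):
    if jrows:
        ns = [len(r[4]) for r in jrows]
        jdf = pd.DataFrame({
            "chrom": np.repeat([r[0] for r in jrows], ns),
            "intron_start": np.repeat([r[1] for r in jrows], ns),
            "intron_end": np.repeat([r[2] for r in jrows], ns),
            "strand": np.repeat([r[3] for r in jrows], ns),
            "sample_id": np.concatenate([np.asarray(r[4]) for r in jrows]),
            "count": np.concatenate(
                [np.asarray(r[5], dtype=int) for r in jrows]),
        })
    else:
        jdf = pd.DataFrame(columns=["chrom", "intron_start", "intron_end",
                                    "strand", "sample_id", "count"])
    bdf = None
    if brows:
        ns = [len(r[1]) for r in brows]
        bdf = pd.DataFrame({
            "boundary_id": np.repeat([r[0] for r in brows], ns),
            "sample_id": np.concatenate([np.asarray(r[1]) for r in brows]),
            "count": np.concatenate(
                [np.asarray(r[2], dtype=int) for r in brows]),
        })
    return jdf, bdf


def _site_mu(site: EventSite, sheet: SampleSheet, samples: list[str]) -> np.ndarray:
    mu = np.full(len(samples), site.baseline_psi)
    if site.effect is not None and site.effect.delta_psi != 0.0:
        carriers = set(sheet.samples_with_mutation(site.effect.group))
        mask = np.array([s in carriers for s in samples])
        mu[mask] += site.effect.delta_psi
    return mu


def simulate_cohort(reference: Reference, config: SimulationConfig | None = None,
                    ) -> tuple[JunctionTable, pd.DataFrame, SampleSheet, GroundTruth]:
    """Simulate the primary cohort: junction/boundary/coverage tables, a
    gene-count matrix, the sample sheet and the ground-truth ledger.

    PSI noise is beta-binomial (intraclass correlation ``rho``); reads of
    truncating isoforms survive physiological NMD with probability ``d``
    (inclusion reads thinned binomially), so observed aberrant-isoform
    fractions follow the closed-form mixture d·ψ/(d·ψ + 1 − ψ).
    """
    cfg = config or reference.config
    cfg.validate()
    for eff in cfg.effects:
        if eff.group != "control" and not any(
                _group_matches(eff.group, g)
                for groups in cfg.cohort.values() for g in groups):
            raise ConfigError(f"effect group {eff.group!r} absent from cohort design")
    rng = np.random.default_rng([cfg.seed, 202])
    sheet = _build_sample_sheet(cfg)
    samples = sheet.sample_ids
    n = len(samples)

    sites = reference.sites
    mu = np.vstack([_site_mu(s, sheet, samples) for s in sites]) if sites else \
        np.zeros((0, n))
    totals = rng.poisson(cfg.depth, size=mu.shape)
    m = np.clip(mu / 100.0, 1e-6, 1.0 - 1e-6)
    conc = 1.0 / cfg.rho - 1.0
    inc = rng.binomial(totals, rng.beta(m * conc, (1.0 - m) * conc))
    exc = totals - inc
    d_vec = np.array([s.effect.nmd_d if s.effect is not None else 1.0
                      for s in sites])
    thin = np.array([s.consequence == "truncating" for s in sites]) & (d_vec < 1.0)
    if thin.any():
        inc[thin] = rng.binomial(inc[thin], d_vec[thin, None])

    jrows, brows = [], []
    for i, site in enumerate(sites):
        _allocate_rows(site, samples, inc[i], exc[i], jrows, brows)
    jdf, bdf = _rows_to_frames(jrows, brows)

    # region coverage for the intronic-read-fraction summary
    sf_carriers = set(sheet.samples_with_mutation("SF3B1"))
    cov_rows = []
    for s in samples:
        exonic = rng.poisson(cfg.coverage_depth)
        lam = cfg.coverage_depth * cfg.intronic_coverage_fraction
        if s in sf_carriers:
            lam *= cfg.ir_coverage_factor
        cov_rows.append(("global", "exonic", s, exonic))
        cov_rows.append(("global", "intronic", s, rng.poisson(lam)))
    cdf = pd.DataFrame(cov_rows, columns=["region_id", "region_class",
                                          "sample_id", "count"])
    table = JunctionTable(jdf, bdf, cdf)

    counts = _simulate_gene_counts(rng, reference, cfg, sheet, samples)
    truth = GroundTruth(
        events=reference.truth_frame(),
        exons=reference.exon_classes.copy(),
        genes=reference.gene_base_mean.rename("base_mean").reset_index()
        .rename(columns={"index": "gene_id"}),
    )
    return table, counts, sheet, truth


def _group_matches(spec: str, group: str) -> bool:
    gene, _, prefix = spec.partition(":")
    ggene, _, gvar = group.partition(":")
    return gene == ggene and gvar.startswith(prefix)


def _simulate_gene_counts(rng, reference: Reference, cfg: SimulationConfig,
                          sheet: SampleSheet, samples: list[str]) -> pd.DataFrame:
    """NB gene counts; for genes whose planted truncating event couples to
    expression, the mean is scaled by (1−ψ) + ψ·d (splicing diverts a
    fraction ψ of transcripts into an isoform surviving NMD with rate d)."""
    gene_ids = reference.gene_base_mean.index.tolist()
    base = reference.gene_base_mean.to_numpy()
    scale = np.ones((len(gene_ids), len(samples)))
    gindex = {g: i for i, g in enumerate(gene_ids)}
    for site in reference.sites:
        eff = site.effect
        if eff is None or not eff.couple_expression or site.consequence != "truncating":
            continue
        mu = _site_mu(site, sheet, samples) / 100.0
        scale[gindex[site.event.gene_id]] = (1.0 - mu) + mu * eff.nmd_d
    mean = base[:, None] * scale
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=gene_ids, columns=samples)


# ---------------------------------------------------------------------------
# CHX experiment
# ---------------------------------------------------------------------------


def simulate_chx_experiment(reference: Reference,
                            config: SimulationConfig | None = None,
                            ) -> tuple[JunctionTable, SampleSheet, GroundTruth]:
    """Paired CHX-treated/untreated samples.

    For NMD-sensitive (truncating) events the treated sample is regenerated
    with d := 1 while the untreated sample keeps the configured d (d = 0 is
    allowed: the event is invisible untreated, i.e. CHX-specific). Each
    pair shares one underlying PSI draw, so non-sensitive events are
    identical in distribution between arms."""
    cfg = config or reference.config
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 303])

    rows = []
    pair_no = 0
    for group in sorted(cfg.chx_pairs):
        for j in range(cfg.chx_pairs[group]):
            pair_no += 1
            gene, _, var = group.partition(":")
            gt = format_genotype({gene: var or "mut"})
            for status in ("untreated", "treated"):
                rows.append({
                    "sample_id": f"chx{pair_no:02d}_{status}",
                    "cell_fraction": "BMMNC",
                    "genotype": gt,
                    "chx_status": status,
                    "pair_id": f"P{pair_no:02d}",
                    "clone_id": "",
                    "purity": f"{cfg.purity:.2f}",
                })
    if not rows:
        raise ConfigError("chx_pairs defines no pairs")
    sheet = SampleSheet(pd.DataFrame(rows))
    pairs = sheet.chx_pairs()

    jrows, brows = [], []
    samples = [s for pair in pairs for s in pair]
    for site in reference.sites:
        eff = site.effect
        d = eff.nmd_d if eff is not None else 1.0
        sensitive = site.consequence == "truncating" and d < 1.0
        # carriers among CHX samples
        mu_by_sample = _site_mu(site, sheet, samples)
        inc_all, exc_all = [], []
        for p, (u, t) in enumerate(pairs):
            mu = mu_by_sample[2 * p]  # same underlying biology in both arms
            total_u = rng.poisson(cfg.chx_depth)
            total_t = rng.poisson(cfg.chx_depth)
            conc = 1.0 / cfg.rho - 1.0
            m = np.clip(mu / 100.0, 1e-6, 1 - 1e-6)
            psi_pair = rng.beta(m * conc, (1 - m) * conc)
            inc_u = rng.binomial(total_u, psi_pair)
            inc_t = rng.binomial(total_t, psi_pair)
            exc_all += [total_u - inc_u, total_t - inc_t]
            if sensitive:  # degraded aberrant reads vanish; canonical unchanged
                inc_u = rng.binomial(inc_u, d)
            inc_all += [inc_u, inc_t]
        _allocate_rows(site, samples, np.array(inc_all), np.array(exc_all),
                       jrows, brows)
    jdf, bdf = _rows_to_frames(jrows, brows)
    table = JunctionTable(jdf, bdf)
    truth = GroundTruth(events=reference.truth_frame(),
                        exons=reference.exon_classes.copy(),
                        genes=pd.DataFrame())
    return table, sheet, truth


# ---------------------------------------------------------------------------
# Isogenic clones
# ---------------------------------------------------------------------------


def simulate_clones(reference: Reference, config: SimulationConfig | None = None,
                    genotype: str = "SF3B1:K700E",
                    ) -> tuple[JunctionTable, SampleSheet]:
    """Isogenic cell-line panel: n mutant vs n wild-type clones with low
    within-clone overdispersion, carrying the same planted effects."""
    cfg = config or reference.config
    rng = np.random.default_rng([cfg.seed, 404])
    rows = []
    for j in range(cfg.n_clones_per_genotype):
        rows.append({"sample_id": f"clone_mut_{j}", "cell_fraction": "cell_line",
                     "genotype": genotype.replace(":", ":", 1)
                     if ":" in genotype else genotype,
                     "chx_status": "untreated", "pair_id": "",
                     "clone_id": f"M{j}", "purity": "1.00"})
        rows.append({"sample_id": f"clone_wt_{j}", "cell_fraction": "cell_line",
                     "genotype": "none", "chx_status": "untreated",
                     "pair_id": "", "clone_id": f"W{j}", "purity": ""})
    sheet = SampleSheet(pd.DataFrame(rows))
    samples = sheet.sample_ids
    jrows, brows = [], []
    for site in reference.sites:
        mu = _site_mu(site, sheet, samples)
        totals = rng.poisson(cfg.clone_depth, size=len(samples))
        inc = _betabin_inclusion(rng, mu, totals, cfg.clone_rho)
        exc = totals - inc
        _allocate_rows(site, samples, inc, exc, jrows, brows)
    jdf, bdf = _rows_to_frames(jrows, brows)
    return JunctionTable(jdf, bdf), sheet
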