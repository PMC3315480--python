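"""Spliced-EST evidence over a gene locus: coverage, junctions, PTC isoforms.

Expressed sequence tags aligned to the genome with gaps reveal splicing:
an alignment gap flanked by GT..AG is an exon-exon junction, and rare
junctions or intronic coverage expose minor isoforms.  For RPS9-like genes
the minor isoforms of interest carry premature termination codons (PTCs)
and are predicted substrates of nonsense-mediated decay (NMD) — the
signature of autoregulation by regulated unproductive splicing.

Coordinates are 0-based half-open throughout; BED12 blocks follow the
standard (blockStarts relative to chromStart).  Dinucleotide checks are
strand-aware: on the minus strand GT/AG is read on the reverse complement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

STOP_CODONS = ("taa", "tag", "tga")

CANONICAL = "CANONICAL"
CASSETTE_EXON = "CASSETTE_EXON"
ALT_5SS = "ALT_5SS"
ALT_3SS = "ALT_3SS"
RETAINED_INTRON = "RETAINED_INTRON"

#: minimum gap length for the spliced-EST track qualification
MIN_TRACK_INTRON = 32

#: PTCs more than this many nt upstream of the last exon-exon junction are
#: predicted NMD substrates (multi-intron gene models).
NMD_JUNCTION_RULE_NT = 50


class UnclassifiableIsoformError(ValueError):
    """The isoform's junction pattern fits none of the event categories."""


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        ex = self.exons
        if any(s >= e for s, e in ex):
            raise ValueError("empty exon")
        if any(ex[i][1] > ex[i + 1][0] for i in range(len(ex) - 1)):
            raise ValueError("exons must be sorted and non-overlapping")

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Canonical junctions as (gap_start, gap_end) genomic intervals."""
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return self.junctions

    @property
    def canonical_stop(self) -> int:
        """Genomic coordinate of the stop codon's transcript-first base."""
        return self.cds_end - 3 if self.strand == "+" else self.cds_start + 2


@dataclass(frozen=True)
class SplicedAlignment:
    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        b = self.blocks
        if any(s >= e for s, e in b):
            raise ValueError("empty block")
        if any(b[i][1] > b[i + 1][0] for i in range(len(b) - 1)):
            raise ValueError("blocks must be sorted and non-overlapping")

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.blocks[i][1], self.blocks[i + 1][0])
                     for i in range(len(self.blocks) - 1))

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass(frozen=True)
class JunctionCall:
    """One distinct junction; ends are the genomic gap bounds (left, right)."""
    donor_end: int
    acceptor_start: int
    count: int
    donor_dinuc: str
    acceptor_dinuc: str


@dataclass(frozen=True)
class CoverageTrack:
    region: tuple[int, int]
    counts: np.ndarray

    @property
    def max_cov(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0


@dataclass(frozen=True)
class IsoformAnnotation:
    isoform_id: str
    event: str
    ptc_position: int | None
    nmd_predicted: bool


def splice_dinucs(chrom_seq: str, gap: tuple[int, int],
                  strand: str) -> tuple[str, str]:
    """(donor, acceptor) dinucleotides of a gap, read in transcript sense."""
    gs, ge = gap
    left = chrom_seq[gs:gs + 2].upper()
    right = chrom_seq[ge - 2:ge].upper()
    if strand == "+":
        return left, right
    return reverse_complement(right), reverse_complement(left)


def filter_spliced_track(alignments: Sequence[SplicedAlignment],
                         genome: Mapping[str, str],
                         min_intron: int = MIN_TRACK_INTRON,
                         ) -> list[SplicedAlignment]:
    """Keep alignments spanning >=1 canonical GT..AG gap of >= min_intron nt.

    This reproduces the qualification rule of a "spliced EST" track: an
    alignment with only short or non-GT/AG gaps is not splicing evidence.
    """
    kept = []
    for aln in alignments:
        if aln.chrom not in genome:
            raise KeyError(f"chromosome {aln.chrom!r} not in genome")
        chrom_seq = str(genome[aln.chrom])
        for gap in aln.gaps:
            if gap[1] - gap[0] < min_intron:
                continue
            if splice_dinucs(chrom_seq, gap, aln.strand) == ("GT", "AG"):
                kept.append(aln)
                break
    return kept


def coverage_per_base(alignments: Sequence[SplicedAlignment],
                      region: tuple[int, int]) -> CoverageTrack:
    """Per-base count of alignments whose blocks cover each position."""
    start, end = region
    counts = np.zeros(end - start, dtype=int)
    for aln in alignments:
        for bs, be in aln.blocks:
            lo, hi = max(bs, start), min(be, end)
            if lo < hi:
                counts[lo - start:hi - start] += 1
    return CoverageTrack(region, counts)


def percentile_lines(track: CoverageTrack) -> tuple[float, float]:
    """The 5%/95%-of-maximum coverage thresholds for a gene's track.

    Features below the low line are "rare" (minor isoforms, unspliced
    leakage); these are fractions of the per-gene maximum, not quantiles.
    """
    if track.max_cov == 0:
        raise ValueError("percentile lines undefined on an all-zero track")
    return 0.05 * track.max_cov, 0.95 * track.max_cov


def infer_junctions(alignments: Sequence[SplicedAlignment],
                    genome: Mapping[str, str]) -> list[JunctionCall]:
    """Distinct GT/AG junctions with supporting-alignment counts.

    Gaps without GT/AG flanks are excluded from junction output (the
    alignments still contribute coverage elsewhere).  Sorted genomically.
    """
    tallies: Counter = Counter()
    dinucs: dict[tuple[int, int], tuple[str, str]] = {}
    for aln in alignments:
        chrom_seq = str(genome[aln.chrom])
        for gap in aln.gaps:
            dn, ac = splice_dinucs(chrom_seq, gap, aln.strand)
            if (dn, ac) == ("GT", "AG"):
                tallies[gap] += 1
                dinucs[gap] = (dn, ac)
    return [JunctionCall(g[0], g[1], n, *dinucs[g])
            for g, n in sorted(tallies.items())]


# ---------------------------------------------------------------------------
# Isoform annotation

def _spliced_seq(chrom_seq: str, exons: Sequence[tuple[int, int]],
                 strand: str) -> tuple[str, list[int]]:
    """Transcript sequence plus per-base genomic coordinates."""
    seq = "".join(chrom_seq[s:e] for s, e in exons)
    coords = [p for s, e in exons for p in range(s, e)]
    if strand == "-":
        seq = reverse_complement(seq)
        coords = coords[::-1]
    return seq.lower(), coords


def classify_event(model: GeneModel,
                   isoform_exons: Sequence[tuple[int, int]]) -> str:
    """Label the splicing event an isoform's exon chain implies.

    CASSETTE_EXON: an added exon internal to a canonical intron, both of
    its junctions novel.  ALT_5SS / ALT_3SS: a single novel junction
    sharing its acceptor / donor (strand-aware) with a canonical one.
    RETAINED_INTRON: a canonical junction absent while its intron is fully
    covered by one isoform exon.  CANONICAL otherwise.
    """
    iso = tuple(tuple(e) for e in isoform_exons)
    ij = tuple((iso[i][1], iso[i + 1][0]) for i in range(len(iso) - 1))
    cj = set(model.junctions)
    novel = [j for j in ij if j not in cj]

    if not novel:
        for d, a in model.junctions:
            if (d, a) in ij:
                continue
            if any(s <= d and a <= e for s, e in iso):
                return RETAINED_INTRON
        return CANONICAL

    # cassette: an isoform exon inside a canonical intron flanked by two
    # novel junctions
    for i in range(1, len(iso) - 1):
        s, e = iso[i]
        left, right = ij[i - 1], ij[i]
        if left in novel and right in novel:
            if any(d <= s and e <= a for d, a in model.junctions):
                return CASSETTE_EXON

    if len(novel) == 1:
        l, r = novel[0]
        shares_left = any(cl == l for cl, cr in cj)
        shares_right = any(cr == r for cl, cr in cj)
        if shares_right and not shares_left:
            # left (genomic) end moved: donor on +, acceptor on -
            return ALT_5SS if model.strand == "+" else ALT_3SS
        if shares_left and not shares_right:
            return ALT_3SS if model.strand == "+" else ALT_5SS

    raise UnclassifiableIsoformError(
        f"{model.gene_id}: junction pattern {novel} fits no event category")


def annotate_ptc(model: GeneModel,
                 isoform_exons: Sequence[tuple[int, int]],
                 genome: Mapping[str, str],
                 isoform_id: str = "isoform") -> IsoformAnnotation:
    """Translate an isoform from the annotated start and flag the first PTC.

    The isoform must contain the annotated start codon.  ``ptc_position``
    is the genomic coordinate of the transcript-first base of the first
    stop codon lying 5' (in transcript sense) of the canonical stop; None
    when translation runs to the canonical stop (or off the end).

    NMD prediction: for multi-intron models a PTC more than 50 nt upstream
    of the isoform's last exon-exon junction; for single-intron models, a
    retained intron contributing an in-frame stop.
    """
    chrom_seq = str(genome[model.chrom])
    event = classify_event(model, isoform_exons)
    seq, coords = _spliced_seq(chrom_seq, isoform_exons, model.strand)

    start_g = model.cds_start if model.strand == "+" else model.cds_end - 1
    try:
        t0 = coords.index(start_g)
    except ValueError:
        raise ValueError(
            f"{isoform_id}: isoform lacks the annotated start codon")

    stop_t = None
    for t in range(t0, len(seq) - 2, 3):
        if seq[t:t + 3] in STOP_CODONS:
            stop_t = t
            break

    ptc_position = None
    if stop_t is not None:
        g = coords[stop_t]
        canon = model.canonical_stop
        upstream = g < canon if model.strand == "+" else g > canon
        if g != canon and upstream:
            ptc_position = g

    nmd = False
    if ptc_position is not None:
        n_introns = len(model.exons) - 1
        if n_introns >= 2:
            iso = tuple(tuple(e) for e in isoform_exons)
            junc_left = [iso[i][1] for i in range(len(iso) - 1)]
            if junc_left:
                # transcript offset of the last junction (donor-side edge)
                if model.strand == "+":
                    last_j = coords.index(junc_left[-1] - 1) + 1
                else:
                    last_j = coords.index(iso[0][1] - 1)
                nmd = (last_j - stop_t) > NMD_JUNCTION_RULE_NT
        else:
            nmd = event == RETAINED_INTRON

    return IsoformAnnotation(isoform_id, event, ptc_position, nmd)


# ---------------------------------------------------------------------------
# BED12 interchange

BED12_COLUMNS = ["chrom", "chromStart", "chromEnd", "name", "score",
                 "strand", "thickStart", "thickEnd", "itemRgb",
                 "blockCount", "blockSizes", "blockStarts"]


def read_bed12(path) -> list[SplicedAlignment]:
    df = pd.read_csv(path, sep="\t", names=BED12_COLUMNS, comment="#")
    out = []
    for _, r in df.iterrows():
        start = int(r.chromStart)
        sizes = [int(x) for x in str(r.blockSizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(r.blockStarts).rstrip(",").split(",")]
        blocks = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
        out.append(SplicedAlignment(str(r["name"]), str(r.chrom),
                                    str(r.strand), blocks))
    return out


def write_bed12(alignments: Iterable[SplicedAlignment], path) -> None:
    rows = []
    for aln in alignments:
        start, end = aln.span
        sizes = ",".join(str(e - s) for s, e in aln.blocks)
        offs = ",".join(str(s - start) for s, _ in aln.blocks)
        rows.append([aln.chrom, start, end, aln.read_id, 0, aln.strand,
                     start, end, "0", len(aln.blocks), sizes, offs])
    pd.DataFrame(rows, columns=BED12_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False)
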