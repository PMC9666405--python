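"""Full-length transcript classification of long direct-RNA reads.

Nanopore direct RNA sequencing starts from the transcript 3' end, so a large
fraction of reads terminate before reaching the alternative 5' exons that
distinguish the isoforms of a multi-promoter gene.  This module implements
the long-read stage of the analysis:

1. keep reads overlapping the gene locus (:func:`filter_locus`);
2. call each read full-length, truncated or aberrant
   (:func:`call_full_length`, :func:`classify_read`) — full-length means the
   read runs from the 3' terminal exon all the way into an annotated 5' exon
   (or an extended-exon transcription start), aberrant means the read's
   junction chain is inconsistent with the gene model;
3. assign each full-length read an isoform from its first exon
   (:func:`assign_isoform`), resolving internal-exon-initiated isoforms via
   their extended-exon start and diagnostic junction;
4. extract the alternative-splicing features (:func:`splice_features`):
   Δ (skipping of the two cassette exons) and the +/- acceptor choice;
5. tabulate the isoform distribution over full-length reads
   (:func:`tabulate`).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .gene_model import GeneModel

__all__ = [
    "ReadStatus",
    "PlusMinus",
    "ClassifyConfig",
    "LongReadAlignment",
    "TranscriptCall",
    "IsoformDistribution",
    "ContigMismatchError",
    "filter_locus",
    "call_full_length",
    "assign_isoform",
    "splice_features",
    "classify_read",
    "classify_reads",
    "tabulate",
    "calls_to_frame",
]

UNASSIGNED = "unassigned"


class ReadStatus(str, enum.Enum):
    FULL_LENGTH = "full_length"
    TRUNCATED = "truncated"
    ABERRANT = "aberrant"


class PlusMinus(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"
    INDETERMINATE = "indeterminate"


class ContigMismatchError(ValueError):
    """No input read shares the model's contig; suggests a rename map."""


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for full-length calling and junction extraction.

    upstream_slack
        bp a read's 5' end may start upstream of an annotated 5' exon (or
        extended-exon start) and still be called full-length.
    min_overlap
        minimum bp the 5' end must reach into the 5' exon when it starts
        inside it.
    gap_merge
        adjacent blocks separated by fewer than this many bp are merged
        before junction extraction, absorbing small unaligned gaps typical
        of nanopore alignments.
    junction_tolerance
        maximum bp by which an observed intron boundary may deviate from an
        annotated junction and still match it.
    """

    upstream_slack: int = 50
    min_overlap: int = 1
    gap_merge: int = 10
    junction_tolerance: int = 0


@dataclass(frozen=True)
class LongReadAlignment:
    """One BED12 record: a blocked (spliced) read alignment.

    ``blocks`` are ``(genomic_start, length)`` pairs sorted by coordinate,
    contained in ``[start, end)``; the first block starts at ``start`` and
    the last ends at ``end``.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id}: no blocks")
        prev_end = None
        for s, size in self.blocks:
            if size <= 0:
                raise ValueError(f"read {self.read_id}: non-positive block size")
            if s < self.start or s + size > self.end:
                raise ValueError(f"read {self.read_id}: block outside [start, end)")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"read {self.read_id}: blocks overlap or are unsorted")
            prev_end = s + size
        if self.blocks[0][0] != self.start:
            raise ValueError(f"read {self.read_id}: first block does not start at start")
        if self.blocks[-1][0] + self.blocks[-1][1] != self.end:
            raise ValueError(f"read {self.read_id}: last block does not end at end")

    @property
    def aligned_bp(self) -> int:
        return sum(size for _, size in self.blocks)

    def merged_blocks(self, gap_merge: int) -> list[tuple[int, int]]:
        """Blocks as (start, end) intervals with gaps < gap_merge closed."""
        merged: list[list[int]] = []
        for s, size in self.blocks:
            e = s + size
            if merged and s - merged[-1][1] < gap_merge:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def introns(self, gap_merge: int = 10) -> list[tuple[int, int]]:
        """Genomic intron intervals implied by the (merged) block structure."""
        blocks = self.merged_blocks(gap_merge)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(blocks[:-1], blocks[1:])]

    def five_prime_pos(self, gene_strand: str) -> int:
        """Genomic coordinate of the read's transcript-5'-most aligned base."""
        return self.start if gene_strand == "+" else self.end - 1

    def three_prime_pos(self, gene_strand: str) -> int:
        return self.end - 1 if gene_strand == "+" else self.start

    def overlaps(self, start: int, end: int) -> bool:
        """True if any aligned block overlaps [start, end)."""
        return any(s < end and s + size > start for s, size in self.blocks)


@dataclass(frozen=True)
class TranscriptCall:
    """Classification of one read against the gene model."""

    read_id: str
    status: ReadStatus
    isoform: Optional[str] = None
    five_prime_exon: Optional[str] = None
    delta: Optional[bool] = None
    plus_minus: Optional[PlusMinus] = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class IsoformDistribution:
    """Isoform counts and percentage fractions over full-length reads.

    Fractions are computed over full-length, non-aberrant, isoform-assigned
    calls only and sum to 100 when any such call exists; ``fractions`` is
    empty (and ``undefined`` True) otherwise rather than NaN-propagating.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    n_total: int
    n_full_length: int
    n_truncated: int
    n_aberrant: int
    n_unassigned: int = 0
    n_strand_discordant: int = 0

    @property
    def undefined(self) -> bool:
        return not self.fractions

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "isoform": name,
                "count": self.counts.get(name, 0),
                "percent": self.fractions.get(name, float("nan")),
            }
            for name in sorted(self.counts)
        ]
        return pd.DataFrame(rows, columns=["isoform", "count", "percent"])


# ------------------------------------------------------------------ pipeline


def filter_locus(
    reads: Sequence[LongReadAlignment], model: GeneModel
) -> list[LongReadAlignment]:
    """Keep reads whose span overlaps the model locus by >= 1 bp, in order.

    If the input is non-empty but no read matches the model contig at all,
    raise :class:`ContigMismatchError` (likely a chr-name convention clash).
    """
    if reads and not any(r.contig == model.contig for r in reads):
        seen = sorted({r.contig for r in reads})[:5]
        raise ContigMismatchError(
            f"no read maps to contig {model.contig!r}; input contigs include "
            f"{seen} — provide a contig rename map"
        )
    return [
        r
        for r in reads
        if r.contig == model.contig
        and r.start < model.locus_end
        and r.end > model.locus_start
    ]


def _match_junctions(
    read: LongReadAlignment, model: GeneModel, cfg: ClassifyConfig
) -> tuple[list, bool]:
    """Match the read's introns to model junctions.

    Returns (matched junction list in transcript order, all_matched flag).
    """
    introns = read.introns(cfg.gap_merge)
    tol = cfg.junction_tolerance
    matched = []
    ok = True
    for a, b in introns:
        hit = None
        if tol == 0:
            hit = model.junction_by_key((read.contig, a, b, model.strand))
        else:
            for j in model.junctions:
                if abs(j.intron_start - a) <= tol and abs(j.intron_end - b) <= tol:
                    hit = j
                    break
        if hit is None:
            ok = False
        matched.append(hit)
    if model.strand == "-":
        matched = matched[::-1]
    return matched, ok


def _chain_consistent(matched: list) -> bool:
    """Each junction's downstream exon must start the next junction."""
    for a, b in zip(matched[:-1], matched[1:]):
        if a is None or b is None:
            continue
        if a.down_exon != b.up_exon:
            return False
    return True


def _five_prime_entry(
    read: LongReadAlignment, model: GeneModel, cfg: ClassifyConfig
) -> Optional[tuple[str, str]]:
    """Locate the transcript start implied by the read's 5' end.

    Returns ``(kind, exon_name)`` where kind is "five_prime" or "extended",
    or None when the 5' end lies in no valid start window.  A 5' end inside
    an extended exon's *extension* region (strictly upstream of the exon
    proper, up to ``upstream_slack`` further upstream) is an extended-exon
    start; a 5' end at or past the exon boundary is not, so truncated reads
    are never promoted to extended-exon transcripts.
    """
    pos = read.five_prime_pos(model.strand)
    for exon in model.five_prime_exons:
        if model.strand == "+":
            lo, hi = exon.start - cfg.upstream_slack, exon.end - cfg.min_overlap
        else:
            lo, hi = exon.start + cfg.min_overlap - 1, exon.end - 1 + cfg.upstream_slack
        if lo <= pos <= hi:
            return "five_prime", exon.name
    for exon in model.exons:
        for label in exon.start_extensions:
            ext_lo, ext_hi = exon.extension_interval(label, model.strand)
            if model.strand == "+":
                lo, hi = ext_lo - cfg.upstream_slack, ext_hi - 1
            else:
                lo, hi = ext_lo, ext_hi - 1 + cfg.upstream_slack
            if lo <= pos <= hi:
                return "extended", exon.name
    return None


def call_full_length(
    read: LongReadAlignment, model: GeneModel, cfg: ClassifyConfig = ClassifyConfig()
) -> ReadStatus:
    """Full-length vs truncated call for a locus read.

    A read is full-length when (a) its 3' end lies inside the 3' terminal
    exon and (b) its 5' end lies inside (>= ``min_overlap`` bp) or at most
    ``upstream_slack`` bp upstream of an annotated 5' exon or extended-exon
    start region.  Aberrance is not judged here (see :func:`classify_read`).
    """
    tp = model.three_prime_exon
    p3 = read.three_prime_pos(model.strand)
    if not (tp.start <= p3 < tp.end):
        return ReadStatus.TRUNCATED
    if _five_prime_entry(read, model, cfg) is None:
        return ReadStatus.TRUNCATED
    return ReadStatus.FULL_LENGTH


def splice_features(
    read: LongReadAlignment, model: GeneModel, cfg: ClassifyConfig = ClassifyConfig()
) -> tuple[Optional[bool], PlusMinus]:
    """(delta, plus_minus) for a read; None / indeterminate when not covered.

    delta is True when the junction chain uses a declared skip of the
    cassette exons, False when the read instead covers them, None when the
    read does not reach the region.  plus_minus reports which acceptor
    variant is used at the +/- alternative splice region.
    """
    matched, _ = _match_junctions(read, model, cfg)
    feats = model.splice_features
    delta: Optional[bool] = None
    d = feats.get("delta")
    if d:
        if any(j is not None and j.feature == "delta" for j in matched):
            delta = True
        else:
            skipped = [model.exon(e) for e in d.get("skipped_exons", ())]
            if any(read.overlaps(e.start, e.end) for e in skipped):
                delta = False
    pm = feats.get("plus_minus")
    plus_minus = PlusMinus.INDETERMINATE
    if pm:
        for j in matched:
            if j is not None and j.down_exon == pm["exon"]:
                plus_minus = (
                    PlusMinus.PLUS if j.variant == pm["plus_variant"] else PlusMinus.MINUS
                )
                break
    return delta, plus_minus


def assign_isoform(
    read: LongReadAlignment, model: GeneModel, cfg: ClassifyConfig = ClassifyConfig()
) -> TranscriptCall:
    """Full classification of one full-length candidate read.

    The 5' exon containing the read's 5' end selects the isoform;
    internal-exon-initiated isoforms are resolved through their extended-exon
    start region and confirmed by the diagnostic junction when the read shows
    any junctions.  Reads whose junction chain contains a junction absent
    from the model, or that is internally inconsistent (skipping exons other
    than via a declared feature), are aberrant.
    """
    return classify_read(read, model, cfg)


def classify_read(
    read: LongReadAlignment, model: GeneModel, cfg: ClassifyConfig = ClassifyConfig()
) -> TranscriptCall:
    matched, all_matched = _match_junctions(read, model, cfg)
    if not all_matched or not _chain_consistent(matched):
        return TranscriptCall(read_id=read.read_id, status=ReadStatus.ABERRANT)
    status = call_full_length(read, model, cfg)
    if status is not ReadStatus.FULL_LENGTH:
        return TranscriptCall(read_id=read.read_id, status=status)
    delta, pm = splice_features(read, model, cfg)
    entry = _five_prime_entry(read, model, cfg)
    assert entry is not None  # guaranteed by the full-length call
    kind, exon_name = entry
    flags: tuple[str, ...] = ()
    if kind == "extended":
        iso = model.extended_exon_isoform(exon_name)
    else:
        iso_def = model.isoform_for_first_exon(exon_name)
        iso = iso_def
    if iso is None:
        isoform = UNASSIGNED
        flags = ("no_isoform_for_first_exon",)
    else:
        isoform = iso.name
    return TranscriptCall(
        read_id=read.read_id,
        status=ReadStatus.FULL_LENGTH,
        isoform=isoform,
        five_prime_exon=exon_name,
        delta=delta,
        plus_minus=pm,
        flags=flags,
    )


def classify_reads(
    reads: Sequence[LongReadAlignment],
    model: GeneModel,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> tuple[list[TranscriptCall], int]:
    """Classify strand-concordant locus reads.

    Direct RNA sequencing is stranded, so reads aligned opposite the model
    strand are excluded up front; their count is returned alongside the
    calls so totals remain auditable.
    """
    calls: list[TranscriptCall] = []
    discordant = 0
    for read in reads:
        if read.strand in ("+", "-") and read.strand != model.strand:
            discordant += 1
            continue
        calls.append(classify_read(read, model, cfg))
    return calls, discordant


def tabulate(
    calls: Iterable[TranscriptCall], n_strand_discordant: int = 0
) -> IsoformDistribution:
    """Isoform distribution over full-length calls.

    Percentages are taken over full-length, isoform-assigned reads;
    truncated, aberrant and unassigned-5'-exon reads are counted separately.
    With zero assignable full-length calls the fractions are flagged
    undefined instead of NaN.
    """
    calls = list(calls)
    status_counts = Counter(c.status for c in calls)
    assigned = [
        c
        for c in calls
        if c.status is ReadStatus.FULL_LENGTH and c.isoform not in (None, UNASSIGNED)
    ]
    n_unassigned = sum(
        1 for c in calls if c.status is ReadStatus.FULL_LENGTH and c.isoform == UNASSIGNED
    )
    counts = Counter(c.isoform for c in assigned)
    n_assigned = sum(counts.values())
    fractions = (
        {k: 100.0 * v / n_assigned for k, v in counts.items()} if n_assigned else {}
    )
    return IsoformDistribution(
        counts=dict(counts),
        fractions=fractions,
        n_total=len(calls),
        n_full_length=status_counts.get(ReadStatus.FULL_LENGTH, 0),
        n_truncated=status_counts.get(ReadStatus.TRUNCATED, 0),
        n_aberrant=status_counts.get(ReadStatus.ABERRANT, 0),
        n_unassigned=n_unassigned,
        n_strand_discordant=n_strand_discordant,
    )


def calls_to_frame(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    """Per-read call table (read_id, status, isoform, delta, plus_minus)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "read_id": c.read_id,
                "status": c.status.value,
                "isoform": c.isoform if c.isoform else "",
                "five_prime_exon": c.five_prime_exon if c.five_prime_exon else "",
                "delta": "" if c.delta is None else str(c.delta),
                "plus_minus": c.plus_minus.value if c.plus_minus else "",
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "status", "isoform", "five_prime_exon", "delta", "plus_minus", "flags"],
    )
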