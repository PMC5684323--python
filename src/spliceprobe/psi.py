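"""Read assignment and percent-spliced-in (PSI) quantification.

Spliced reads are assigned to the alternative of a local splicing event
whose unique evidence they carry: either they span an alternative-specific
splice junction with a minimum overhang on both sides, or they map fully
inside an alternative-exclusive exonic segment.  Raw counts n1/n2 are
normalized by the unique-region lengths to densities c1/c2 and

    PSI = c1 / (c1 + c2)

ranging from 0 to 1.  Condition-level change is the difference of mean PSI
between treatment and matched control (dPSI); events pass the read-support
filter when at least one alternative reaches a normalized density of 0.003
reads per nucleotide in at least one sample.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .events import AltEvent, Interval, UniqueRegions

logger = logging.getLogger(__name__)

DENSITY_MIN_DEFAULT = 0.003
DELTA_PSI_THRESHOLD = 0.4

# CIGAR op codes (pysam numeric encoding)
_CONSUME_BLOCK = {0, 7, 8, 2}  # M, =, X extend the block; D bridged within it
_GAP = 3  # N: splice junction
_NO_REF = {1, 4, 5, 6}  # I, S, H, P: no reference advance


class Assignment(enum.Enum):
    ALT1 = 1
    ALT2 = 2
    NEITHER = 0
    AMBIGUOUS = -1


@dataclass(frozen=True)
class SplicedAlignment:
    """One aligned read: ordered genomic blocks, gaps are splice junctions."""

    read_id: str
    sample_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    fragment_id: str | None = None
    is_read1: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment needs at least one block")
        for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:]):
            if e0 >= s1:
                raise ValueError("blocks must be sorted and separated by gaps")

    @property
    def junctions(self) -> tuple[Interval, ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:])
        )

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass(frozen=True)
class EventCounts:
    """Per-event, per-sample raw and length-normalized evidence counts."""

    event_id: str
    sample_id: str
    n1: int
    n2: int
    c1: float
    c2: float

    @property
    def density(self) -> float:
        return max(self.c1, self.c2)


@dataclass(frozen=True)
class PsiRecord:
    """Replicate-level PSI values of one event under one condition."""

    event_id: str
    condition: str
    psi_per_sample: tuple[float, ...]

    @property
    def psi_mean(self) -> float:
        vals = [p for p in self.psi_per_sample if not math.isnan(p)]
        return sum(vals) / len(vals) if vals else math.nan


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def blocks_from_cigar(pos: int, cigartuples: Sequence[tuple[int, int]]) -> tuple[Interval, ...]:
    """Reconstruct aligned genomic blocks; N gaps split blocks, D does not."""
    blocks: list[Interval] = []
    start = cur = pos
    for op, length in cigartuples:
        if op in _CONSUME_BLOCK:
            cur += length
        elif op == _GAP:
            if cur > start:
                blocks.append((start, cur))
            start = cur = cur + length
        elif op in _NO_REF:
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


def read_sam(path: str, sample_id: str = "") -> list[SplicedAlignment]:
    """Read spliced alignments from a SAM file.

    Unmapped, secondary and supplementary records are dropped; records with
    unsupported CIGAR operations are skipped (the count is logged).
    """
    out: list[SplicedAlignment] = []
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                blocks = blocks_from_cigar(rec.reference_start, rec.cigartuples or ())
            except ValueError:
                skipped += 1
                continue
            if not blocks:
                skipped += 1
                continue
            out.append(
                SplicedAlignment(
                    read_id=f"{rec.query_name}/{2 if rec.is_read2 else 1}",
                    sample_id=sample_id,
                    chrom=rec.reference_name or "",
                    strand="-" if rec.is_reverse else "+",
                    blocks=blocks,
                    fragment_id=rec.query_name,
                    is_read1=not rec.is_read2,
                )
            )
    if skipped:
        logger.warning("read_sam(%s): skipped %d records with unusable CIGAR", path, skipped)
    return out


# ---------------------------------------------------------------------------
# Assignment and quantification
# ---------------------------------------------------------------------------

def assign_read(
    event: AltEvent,
    regions: UniqueRegions,
    aln: SplicedAlignment,
    min_overhang: int = 1,
) -> Assignment:
    """Assign one read to an event alternative.

    ``ALT1``/``ALT2`` when the read spans an alternative-specific junction
    with >= ``min_overhang`` aligned nt on both sides, or lies fully within
    an alternative-exclusive exonic segment.  Evidence for both alternatives
    yields ``AMBIGUOUS``.  Reads whose start or end falls exactly on a
    splice-site boundary carry no junction overhang and therefore never
    count as junction-spanning evidence.
    """
    if aln.chrom != event.chrom:
        return Assignment.NEITHER
    votes: set[int] = set()
    j1 = set(regions.junctions1)
    j2 = set(regions.junctions2)
    if len(aln.blocks) > 1 and (j1 or j2):
        lens = [e - s for s, e in aln.blocks]
        total = sum(lens)
        left = 0
        for i, junction in enumerate(aln.junctions):
            left += lens[i]
            right = total - left
            if left >= min_overhang and right >= min_overhang:
                if junction in j1:
                    votes.add(1)
                if junction in j2:
                    votes.add(2)
    if len(aln.blocks) == 1:
        s, e = aln.blocks[0]
        if any(ss <= s and e <= se for ss, se in regions.segments1):
            votes.add(1)
        if any(ss <= s and e <= se for ss, se in regions.segments2):
            votes.add(2)
    if votes == {1}:
        return Assignment.ALT1
    if votes == {2}:
        return Assignment.ALT2
    if votes:
        return Assignment.AMBIGUOUS
    return Assignment.NEITHER


def quantify_event(
    event: AltEvent,
    regions: UniqueRegions,
    alignments: Iterable[SplicedAlignment],
    sample_id: str,
    min_overhang: int = 1,
) -> EventCounts:
    """Tally alternative-specific reads and normalize by unique lengths.

    Mates are assigned independently; a fragment whose two mates support
    conflicting alternatives contributes nothing.
    """
    if regions.unique_length1 == 0 or regions.unique_length2 == 0:
        raise ValueError(
            f"event {event.event_id}: zero unique length; filter upstream"
        )
    by_fragment: dict[str, list[Assignment]] = {}
    singletons: list[Assignment] = []
    for aln in alignments:
        a = assign_read(event, regions, aln, min_overhang)
        if a in (Assignment.ALT1, Assignment.ALT2):
            if aln.fragment_id is None:
                singletons.append(a)
            else:
                by_fragment.setdefault(aln.fragment_id, []).append(a)
    n1 = n2 = 0
    for assignments in by_fragment.values():
        kinds = set(assignments)
        if Assignment.ALT1 in kinds and Assignment.ALT2 in kinds:
            continue  # conflicting mates: the fragment contributes 0
        n1 += sum(a is Assignment.ALT1 for a in assignments)
        n2 += sum(a is Assignment.ALT2 for a in assignments)
    n1 += sum(a is Assignment.ALT1 for a in singletons)
    n2 += sum(a is Assignment.ALT2 for a in singletons)
    return EventCounts(
        event_id=event.event_id,
        sample_id=sample_id,
        n1=n1,
        n2=n2,
        c1=n1 / regions.unique_length1,
        c2=n2 / regions.unique_length2,
    )


def compute_psi(counts: EventCounts) -> float:
    """PSI = c1/(c1+c2); NaN (never 0) when both densities are zero."""
    total = counts.c1 + counts.c2
    if total == 0:
        return math.nan
    return counts.c1 / total


def counts_table(counts: Iterable[EventCounts]) -> pd.DataFrame:
    rows = [
        {
            "event_id": c.event_id,
            "sample_id": c.sample_id,
            "n1": c.n1,
            "n2": c.n2,
            "c1": c.c1,
            "c2": c.c2,
            "psi": compute_psi(c),
        }
        for c in counts
    ]
    return pd.DataFrame(
        rows, columns=["event_id", "sample_id", "n1", "n2", "c1", "c2", "psi"]
    )


def filter_events(
    counts: pd.DataFrame, density_min: float = DENSITY_MIN_DEFAULT
) -> list[str]:
    """Event ids whose normalized density reaches ``density_min`` for at
    least one alternative in at least one sample."""
    keep = counts.loc[
        (counts["c1"] >= density_min) | (counts["c2"] >= density_min), "event_id"
    ]
    return sorted(keep.unique())


def delta_psi(
    treated: PsiRecord,
    control: PsiRecord,
    threshold: float = DELTA_PSI_THRESHOLD,
) -> tuple[float, bool]:
    """Signed dPSI = mean(treated) - mean(control) and its change flag.

    The flag is ``|dPSI| > threshold``; an undefined side propagates NaN and
    an unflagged event.
    """
    if treated.event_id != control.event_id:
        raise ValueError("dPSI requires matching events")
    delta = treated.psi_mean - control.psi_mean
    flagged = (not math.isnan(delta)) and abs(delta) > threshold
    return delta, flagged


def compute_rpkm(gene_count: float, transcript_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length <= 0 or total_mapped <= 0:
        raise ValueError("transcript_length and total_mapped must be positive")
    return gene_count / (transcript_length / 1_000) / (total_mapped / 1_000_000)


def count_splice_site_spanning(
    alignments: Iterable[SplicedAlignment], splice_site: int
) -> int:
    """Reads whose aligned blocks cover ``splice_site`` on both sides.

    A read whose start or end coordinate maps exactly onto the splice site
    does not cover it and is excluded.
    """
    n = 0
    for aln in alignments:
        if any(s < splice_site < e for s, e in aln.blocks):
            n += 1
    return n
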