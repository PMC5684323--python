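"""Local alternative-splicing event catalogs from transcript annotations.

A *local* alternative-splicing event is a bounded structural difference
between two transcript isoforms of the same gene, flanked on both sides by
splice-site coordinates the two isoforms share.  Comparing every isoform
pair and deduplicating yields a catalog of events, each with two
alternatives (e.g. inclusion vs. skipping of a cassette exon).  Events are
classified into six templates:

``CASSETTE``
    inclusion or skipping of a single internal exon
``INTERNAL3``
    alternative 3' acceptor splice site (length polymorphism)
``INTERNAL5``
    alternative 5' donor splice site (length polymorphism)
``LCASSETTE``
    joint inclusion or skipping of two consecutive exons
``MUT_EXCLU``
    mutually exclusive usage of one out of two exons
``XCASSETTE``
    joint inclusion or skipping of three or more exons

Pairwise differences that match none of the templates are kept with
category ``OTHER`` and excluded from downstream PSI analysis.

All coordinates are 0-based half-open on the genome axis; GTF input
(1-based closed) is converted at the parsing boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

from gffutils.feature import feature_from_line

Interval = tuple[int, int]

CATEGORIES = (
    "CASSETTE",
    "INTERNAL3",
    "INTERNAL5",
    "LCASSETTE",
    "MUT_EXCLU",
    "XCASSETTE",
    "OTHER",
)

#: categories eligible for PSI quantification
PSI_CATEGORIES = tuple(c for c in CATEGORIES if c != "OTHER")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed or lacks required attributes."""


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon chain of one transcript on the genome axis.

    Exons are 0-based half-open intervals, strictly sorted and
    non-overlapping, all on ``chrom``/``strand``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"empty/inverted exon ({s}, {e}) in {self.transcript_id}")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Donor-acceptor coordinate pairs between consecutive exons."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class AltEvent:
    """A classified local splicing event with two alternatives.

    ``flank5``/``flank3`` are the anchor splice-site coordinates shared by
    both alternatives, named in transcription order (on '-' strand flank5 is
    the genomically larger coordinate).  ``alt1``/``alt2`` are the exonic
    fragments of the variable region for each alternative; ``alt1`` is the
    alternative with the larger exonic content (the inclusion form for
    cassette-type events).  ``junctions1``/``junctions2`` are the
    donor-acceptor pairs unique to each alternative.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    category: str
    flank5: int
    flank3: int
    alt1: tuple[Interval, ...]
    alt2: tuple[Interval, ...]
    junctions1: tuple[Interval, ...]
    junctions2: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.alt1 == self.alt2:
            raise ValueError("alternatives must differ")

    @property
    def region(self) -> Interval:
        """Genomic (left, right) anchors of the variable region."""
        return (min(self.flank5, self.flank3), max(self.flank5, self.flank3))


@dataclass(frozen=True)
class UniqueRegions:
    """Per-alternative unique evidence of an event given read geometry.

    ``segments*`` are exonic stretches fully specific to one alternative;
    ``junctions*`` the alternative-specific splice junctions.
    ``unique_length*`` counts the distinct read-start positions that yield
    alternative-specific evidence for a read of length ``read_len`` with at
    least ``min_overhang`` nt on both sides of a junction: each junction
    contributes ``read_len - 2*min_overhang + 1`` positions, each exclusive
    segment of length ``l`` contributes ``max(0, l - read_len + 1)``
    fully-contained positions.
    """

    event_id: str
    read_len: int
    min_overhang: int
    segments1: tuple[Interval, ...]
    segments2: tuple[Interval, ...]
    junctions1: tuple[Interval, ...]
    junctions2: tuple[Interval, ...]
    unique_length1: int
    unique_length2: int


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into :class:`TranscriptModel` s.

    Exon lines are grouped by ``transcript_id``; exons are sorted by genomic
    coordinate regardless of file order.  Transcript features without exon
    lines are skipped with a warning.  Malformed lines raise
    :class:`GtfParseError` naming the offending line number.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    declared: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}: cannot parse line {lineno}: {exc}") from exc
            if feat.featuretype == "transcript":
                try:
                    declared.add(feat.attributes["transcript_id"][0])
                except (KeyError, IndexError):
                    pass
                continue
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError) as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon lacks gene_id/transcript_id"
                ) from exc
            # GTF is 1-based closed; convert to 0-based half-open.
            exons.setdefault(tx_id, []).append((feat.start - 1, feat.end))
            meta.setdefault(tx_id, (gene_id, feat.seqid, feat.strand))
    for tx_id in sorted(declared - exons.keys()):
        warnings.warn(f"transcript {tx_id} has no exon features; skipped")
    models = []
    for tx_id, ivs in exons.items():
        gene_id, chrom, strand = meta[tx_id]
        models.append(
            TranscriptModel(tx_id, gene_id, chrom, strand, tuple(sorted(ivs)))
        )
    models.sort(key=lambda m: (m.chrom, m.span, m.gene_id, m.transcript_id))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str, source: str = "spliceprobe") -> None:
    """Write transcript models as GTF exon (and transcript) features."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            s, e = m.span
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for xs, xe in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Event enumeration
# ---------------------------------------------------------------------------

def _pieces(exons: Sequence[Interval], left: int, right: int) -> tuple[Interval, ...]:
    """Exonic coverage of a chain strictly between two anchor coordinates."""
    return tuple(
        (max(s, left), min(e, right)) for s, e in exons if e > left and s < right
    )


def _is_internal_exon(piece: Interval, left: int, right: int) -> bool:
    return left < piece[0] and piece[1] < right


def _classify(
    p1: tuple[Interval, ...],
    p2: tuple[Interval, ...],
    left: int,
    right: int,
    strand: str,
) -> str:
    if not p1 or not p2:
        full = p1 or p2
        if all(_is_internal_exon(p, left, right) for p in full):
            return {1: "CASSETTE", 2: "LCASSETTE"}.get(len(full), "XCASSETTE")
        return "OTHER"
    if len(p1) == 1 and len(p2) == 1:
        (s1, e1), (s2, e2) = p1[0], p2[0]
        if s1 == s2 and e1 != e2:
            # donor-side length polymorphism
            return "INTERNAL5" if strand == "+" else "INTERNAL3"
        if e1 == e2 and s1 != s2:
            # acceptor-side length polymorphism
            return "INTERNAL3" if strand == "+" else "INTERNAL5"
        if (e1 <= s2 or e2 <= s1) and all(
            _is_internal_exon(p, left, right) for p in (p1[0], p2[0])
        ):
            return "MUT_EXCLU"
    return "OTHER"


def _pair_events(t1: TranscriptModel, t2: TranscriptModel) -> Iterator[AltEvent]:
    ends1 = {e for _, e in t1.exons[:-1]}
    ends2 = {e for _, e in t2.exons[:-1]}
    starts1 = {s for s, _ in t1.exons[1:]}
    starts2 = {s for s, _ in t2.exons[1:]}
    sync = sorted((ends1 & ends2) | (starts1 & starts2))
    for left, right in zip(sync, sync[1:]):
        p1 = _pieces(t1.exons, left, right)
        p2 = _pieces(t2.exons, left, right)
        if p1 == p2:
            continue
        category = _classify(p1, p2, left, right, t1.strand)
        in1 = tuple(i for i in t1.introns if left <= i[0] and i[1] <= right)
        in2 = tuple(i for i in t2.introns if left <= i[0] and i[1] <= right)
        j1 = tuple(sorted(set(in1) - set(in2)))
        j2 = tuple(sorted(set(in2) - set(in1)))
        # alternative 1 = larger exonic content (inclusion form); ties by coords
        key1 = (-sum(e - s for s, e in p1), p1)
        key2 = (-sum(e - s for s, e in p2), p2)
        if key2 < key1:
            p1, p2, j1, j2 = p2, p1, j2, j1
        if t1.strand == "+":
            flank5, flank3 = left, right
        else:
            flank5, flank3 = right, left
        alt_repr = ";".join(
            ",".join(f"{s}-{e}" for s, e in alt) or "." for alt in (p1, p2)
        )
        event_id = (
            f"{t1.gene_id}|{t1.chrom}:{left}-{right}|{t1.strand}|{category}|{alt_repr}"
        )
        yield AltEvent(
            event_id=event_id,
            gene_id=t1.gene_id,
            chrom=t1.chrom,
            strand=t1.strand,
            category=category,
            flank5=flank5,
            flank3=flank3,
            alt1=p1,
            alt2=p2,
            junctions1=j1,
            junctions2=j2,
        )


def enumerate_events(transcripts: Sequence[TranscriptModel]) -> list[AltEvent]:
    """Enumerate deduplicated local splicing events for one gene.

    Every transcript pair is compared; maximal local differences flanked by
    shared splice sites are extracted, classified and deduplicated by their
    canonical key.  The result is invariant to transcript input order and to
    duplication of transcripts.
    """
    if len(transcripts) < 2:
        return []
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(gene_ids)}")
    if len({(t.chrom, t.strand) for t in transcripts}) != 1:
        raise ValueError("transcripts of one gene must share chrom and strand")
    events: dict[str, AltEvent] = {}
    for t1, t2 in combinations(
        sorted(transcripts, key=lambda t: (t.exons, t.transcript_id)), 2
    ):
        for ev in _pair_events(t1, t2):
            events.setdefault(ev.event_id, ev)
    return sorted(
        events.values(), key=lambda e: (e.chrom, e.region, e.category, e.event_id)
    )


def build_catalog(
    transcripts: Sequence[TranscriptModel],
) -> list[AltEvent]:
    """Enumerate events across all genes of a transcript set."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    catalog: list[AltEvent] = []
    for gene in sorted(by_gene):
        catalog.extend(enumerate_events(by_gene[gene]))
    return catalog


# ---------------------------------------------------------------------------
# Unique regions
# ---------------------------------------------------------------------------

def _subtract(intervals: Sequence[Interval], others: Sequence[Interval]) -> tuple[Interval, ...]:
    """Interval-set subtraction on sorted, non-overlapping half-open intervals."""
    out: list[Interval] = []
    for s, e in intervals:
        pieces = [(s, e)]
        for os, oe in others:
            nxt: list[Interval] = []
            for ps, pe in pieces:
                if oe <= ps or os >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < os:
                    nxt.append((ps, os))
                if oe < pe:
                    nxt.append((oe, pe))
            pieces = nxt
        out.extend(pieces)
    return tuple(out)


def compute_unique_regions(
    event: AltEvent, read_len: int = 50, min_overhang: int = 1
) -> UniqueRegions:
    """Unique evidence regions and read-start position counts per alternative.

    Requires ``read_len >= 2 * min_overhang`` so a junction-spanning read
    can satisfy the overhang on both sides (at equality each junction
    retains exactly one valid start position).
    """
    if read_len < 2 * min_overhang:
        raise ValueError(
            f"read_len ({read_len}) must exceed 2*min_overhang ({2 * min_overhang})"
        )
    seg1 = _subtract(event.alt1, event.alt2)
    seg2 = _subtract(event.alt2, event.alt1)
    per_junction = read_len - 2 * min_overhang + 1

    def _length(segments: Sequence[Interval], junctions: Sequence[Interval]) -> int:
        body = sum(max(0, (e - s) - read_len + 1) for s, e in segments)
        return body + per_junction * len(junctions)

    u1 = _length(seg1, event.junctions1)
    u2 = _length(seg2, event.junctions2)
    if u1 == 0 or u2 == 0:
        warnings.warn(
            f"event {event.event_id}: an alternative has no unique read-start "
            "positions at this read geometry"
        )
    return UniqueRegions(
        event_id=event.event_id,
        read_len=read_len,
        min_overhang=min_overhang,
        segments1=seg1,
        segments2=seg2,
        junctions1=event.junctions1,
        junctions2=event.junctions2,
        unique_length1=u1,
        unique_length2=u2,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def event_to_dict(event: AltEvent, regions: UniqueRegions | None = None) -> dict:
    d = {
        "event_id": event.event_id,
        "gene_id": event.gene_id,
        "chrom": event.chrom,
        "strand": event.strand,
        "category": event.category,
        "flank5": event.flank5,
        "flank3": event.flank3,
        "alt1": [list(iv) for iv in event.alt1],
        "alt2": [list(iv) for iv in event.alt2],
        "junctions1": [list(iv) for iv in event.junctions1],
        "junctions2": [list(iv) for iv in event.junctions2],
    }
    if regions is not None:
        d.update(
            {
                "read_len": regions.read_len,
                "min_overhang": regions.min_overhang,
                "segments1": [list(iv) for iv in regions.segments1],
                "segments2": [list(iv) for iv in regions.segments2],
                "unique_length1": regions.unique_length1,
                "unique_length2": regions.unique_length2,
            }
        )
    return d


def event_from_dict(d: dict) -> tuple[AltEvent, UniqueRegions | None]:
    ev = AltEvent(
        event_id=d["event_id"],
        gene_id=d["gene_id"],
        chrom=d["chrom"],
        strand=d["strand"],
        category=d["category"],
        flank5=d["flank5"],
        flank3=d["flank3"],
        alt1=tuple(tuple(iv) for iv in d["alt1"]),
        alt2=tuple(tuple(iv) for iv in d["alt2"]),
        junctions1=tuple(tuple(iv) for iv in d["junctions1"]),
        junctions2=tuple(tuple(iv) for iv in d["junctions2"]),
    )
    ur = None
    if "unique_length1" in d:
        ur = UniqueRegions(
            event_id=d["event_id"],
            read_len=d["read_len"],
            min_overhang=d["min_overhang"],
            segments1=tuple(tuple(iv) for iv in d["segments1"]),
            segments2=tuple(tuple(iv) for iv in d["segments2"]),
            junctions1=ev.junctions1,
            junctions2=ev.junctions2,
            unique_length1=d["unique_length1"],
            unique_length2=d["unique_length2"],
        )
    return ev, ur


def write_events_json(
    events: Sequence[AltEvent],
    path: str,
    regions: Sequence[UniqueRegions] | None = None,
) -> None:
    """Write events (optionally with unique regions) as JSON lines."""
    regs = regions if regions is not None else [None] * len(events)
    with open(path, "w") as fh:
        for ev, ur in zip(events, regs):
            fh.write(json.dumps(event_to_dict(ev, ur), sort_keys=True) + "\n")


def read_events_json(path: str) -> list[tuple[AltEvent, UniqueRegions | None]]:
    with open(path) as fh:
        return [event_from_dict(json.loads(line)) for line in fh if line.strip()]
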