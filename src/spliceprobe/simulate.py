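"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators are pure functions of (seed, parameters): identical inputs give
byte-identical outputs, and each returns a truth record sufficient to score
every downstream call.

* :func:`gen_transcriptome` — two-isoform gene models realizing each of the
  six local splicing-event classes (exon lengths 80-300 nt, introns
  100-2000 nt), including one cassette gene whose variable exon carries the
  purine-rich ESE2 element ``AAAAAGAAGGAAGG``.
* :func:`gen_reads` — paired-end spliced reads (default 2 x 50 bp): each
  fragment is drawn from the inclusion or skipping isoform (by default
  emulating length-proportional library sampling at molar PSI), placed
  uniformly on the chosen isoform (insert length normal(250, 30) truncated
  to the read span) and emitted as pre-aligned records with M/N CIGAR
  blocks.
* :func:`gen_silac` — 10-sample heavy/light ratio tables with a spiked
  enriched subset, label-swapped samples, and decoy rows exercising every
  branch of the protein filter chain.
* :func:`gen_dose_response` — 5-concentration x 3-replicate abundance
  matrices with a spiked monotonically displaced subset (linear decrease,
  total drop ``n_levels * drop_per_level``).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .displacement import DEFAULT_LEVELS
from .events import Interval, TranscriptModel
from .psi import SplicedAlignment

ESE2_SEQUENCE = "AAAAAGAAGGAAGG"

_EVENT_CATEGORIES = (
    "CASSETTE",
    "INTERNAL3",
    "INTERNAL5",
    "LCASSETTE",
    "MUT_EXCLU",
    "XCASSETTE",
)


# ---------------------------------------------------------------------------
# Transcriptome generator
# ---------------------------------------------------------------------------

def _exon_len(rng: np.random.Generator) -> int:
    return int(rng.integers(80, 301))


def _intron_len(rng: np.random.Generator) -> int:
    return int(rng.integers(100, 2001))


def _chain(rng: np.random.Generator, start: int, n: int) -> list[Interval]:
    """n exons separated by random introns, starting at ``start``."""
    exons = []
    cursor = start
    for i in range(n):
        if i:
            cursor += _intron_len(rng)
        length = _exon_len(rng)
        exons.append((cursor, cursor + length))
        cursor += length
    return exons


def _alt_sort(
    p1: tuple[Interval, ...], p2: tuple[Interval, ...]
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    key1 = (-sum(e - s for s, e in p1), p1)
    key2 = (-sum(e - s for s, e in p2), p2)
    return (p1, p2) if key1 <= key2 else (p2, p1)


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    category: str,
    flank_exons: int = 3,
) -> tuple[TranscriptModel, TranscriptModel, dict]:
    chrom = f"chr_{gene_id}"
    strand = "+" if rng.random() < 0.5 else "-"
    start = int(rng.integers(1_000, 5_001))
    up = _chain(rng, start, flank_exons)

    def _after(prev_end: int, n: int) -> list[Interval]:
        return _chain(rng, prev_end + _intron_len(rng), n)

    if category in ("CASSETTE", "LCASSETTE", "XCASSETTE"):
        n_inner = {"CASSETTE": 1, "LCASSETTE": 2, "XCASSETTE": 3}[category]
        inner = _after(up[-1][1], n_inner)
        dn = _after(inner[-1][1], flank_exons)
        exons_a = up + inner + dn
        exons_b = up + dn
        alt1, alt2 = tuple(inner), ()
        flank_left, flank_right = up[-1][1], dn[0][0]
    elif category == "MUT_EXCLU":
        x1 = _after(up[-1][1], 1)[0]
        x2 = _after(x1[1], 1)[0]
        dn = _after(x2[1], flank_exons)
        exons_a = up + [x1] + dn
        exons_b = up + [x2] + dn
        alt1, alt2 = _alt_sort((x1,), (x2,))
        flank_left, flank_right = up[-1][1], dn[0][0]
    elif category in ("INTERNAL3", "INTERNAL5"):
        inner = _after(up[-1][1], 1)[0]
        dn = _after(inner[1], flank_exons)
        s, e = inner
        delta = int(rng.integers(30, min(121, (e - s) - 40)))
        # acceptor-side polymorphism sits at the genomic start on '+',
        # at the genomic end on '-'
        shift_start = (category == "INTERNAL3") == (strand == "+")
        if shift_start:
            short = (s + delta, e)
            flank_left, flank_right = up[-1][1], e
        else:
            short = (s, e - delta)
            flank_left, flank_right = s, dn[0][0]
        exons_a = up + [inner] + dn
        exons_b = up + [short] + dn
        alt1, alt2 = (inner,), (short,)
    else:
        raise ValueError(f"cannot generate category {category!r}")

    t_a = TranscriptModel(f"{gene_id}.A", gene_id, chrom, strand, tuple(exons_a))
    t_b = TranscriptModel(f"{gene_id}.B", gene_id, chrom, strand, tuple(exons_b))
    truth = {
        "gene_id": gene_id,
        "chrom": chrom,
        "strand": strand,
        "category": category,
        "flank_left": flank_left,
        "flank_right": flank_right,
        "alt1": tuple(alt1),
        "alt2": tuple(alt2),
    }
    return t_a, t_b, truth


def gen_transcriptome(
    seed: int = 0,
    events_per_category: int | Mapping[str, int] = 2,
    include_ese2_gene: bool = True,
    flank_exons: int = 3,
) -> tuple[list[TranscriptModel], dict]:
    """Two-isoform gene models seeding one event per requested category.

    Returns (models, truth); ``truth['genes']`` lists per-gene expected
    event records (category, flanks, alternatives), ``truth['ese2']``
    describes the cassette fixture gene whose variable exon carries the
    ESE2 element (exonic sequence included).
    """
    if isinstance(events_per_category, int):
        requested = {c: events_per_category for c in _EVENT_CATEGORIES}
    else:
        requested = dict(events_per_category)
    unknown = set(requested) - set(_EVENT_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if any(v < 0 for v in requested.values()):
        raise ValueError("event counts must be >= 0")
    rng = np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    genes: list[dict] = []
    counter = 0
    for category in _EVENT_CATEGORIES:
        for _ in range(requested.get(category, 0)):
            counter += 1
            t_a, t_b, truth = _build_gene(rng, f"g{counter:03d}", category, flank_exons)
            models.extend([t_a, t_b])
            genes.append(truth)
    ese2 = None
    if include_ese2_gene:
        carrier = next((g for g in genes if g["category"] == "CASSETTE"), None)
        if carrier is None:
            counter += 1
            t_a, t_b, carrier = _build_gene(rng, f"g{counter:03d}", "CASSETTE", flank_exons)
            models.extend([t_a, t_b])
            genes.append(carrier)
        exon = carrier["alt1"][0]
        exon_len = exon[1] - exon[0]
        offset = int(rng.integers(0, exon_len - len(ESE2_SEQUENCE) + 1))
        bases = rng.choice(list("ACGT"), size=exon_len)
        seq = "".join(bases)
        seq = seq[:offset] + ESE2_SEQUENCE + seq[offset + len(ESE2_SEQUENCE):]
        ese2 = {
            "gene_id": carrier["gene_id"],
            "exon": exon,
            "offset": offset,
            "sequence": seq,
        }
    return models, {"genes": genes, "ese2": ese2}


# ---------------------------------------------------------------------------
# Read generator
# ---------------------------------------------------------------------------

def _cumulative(exons: Sequence[Interval]) -> list[int]:
    cum = [0]
    for s, e in exons:
        cum.append(cum[-1] + (e - s))
    return cum


def _project(exons: Sequence[Interval], cum: Sequence[int], ts: int, te: int) -> tuple[Interval, ...]:
    """Map a transcript-coordinate interval [ts, te) to genomic blocks."""
    blocks: list[Interval] = []
    for (gs, ge), cs, ce in zip(exons, cum, cum[1:]):
        lo = max(ts, cs)
        hi = min(te, ce)
        if lo < hi:
            blocks.append((gs + (lo - cs), gs + (hi - cs)))
    return tuple(blocks)


def gen_reads(
    models: Sequence[TranscriptModel],
    psi_map: Mapping[str, float],
    depth: int,
    read_len: int = 50,
    paired: bool = True,
    frag_mean: float = 250.0,
    frag_sd: float = 30.0,
    seed: int = 0,
    sample_id: str = "S1",
    isoform_sampling: str = "molar",
) -> tuple[list[SplicedAlignment], dict]:
    """Simulate pre-aligned spliced fragments for the genes in ``psi_map``.

    ``psi_map`` maps gene_id -> PSI of the inclusion isoform (the isoform
    with the larger exonic length; ties by transcript id).  ``depth``
    fragments are drawn per gene; each fragment's insert length is drawn
    first and the fragment is placed uniformly over the valid start
    positions of the chosen isoform.

    With ``isoform_sampling='molar'`` (default) the per-fragment inclusion
    probability is ``psi*W1 / (psi*W1 + (1-psi)*W2)`` where ``W_i`` is the
    number of valid placements on isoform i — the sampling of a sequencing
    library fragmented from a transcript pool whose *molar* inclusion
    fraction is psi, which is the quantity the length-normalized PSI
    estimator measures.  ``'bernoulli'`` draws the inclusion isoform with
    probability psi per fragment regardless of isoform length, so psi is
    the inclusion fraction of fragments instead.

    Transcript coordinates run in genomic order.  Truth records each
    fragment's source isoform.
    """
    if isoform_sampling not in ("molar", "bernoulli"):
        raise ValueError("isoform_sampling must be 'molar' or 'bernoulli'")
    for gene, psi in psi_map.items():
        if not 0.0 <= psi <= 1.0:
            raise ValueError(f"psi for {gene} outside [0, 1]")
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    alignments: list[SplicedAlignment] = []
    truth_rows: list[tuple[str, str, bool]] = []
    for gene in sorted(psi_map):
        if gene not in by_gene:
            raise ValueError(f"no transcripts for gene {gene}")
        isoforms = sorted(by_gene[gene], key=lambda t: (-t.length, t.transcript_id))
        if len(isoforms) != 2:
            raise ValueError(f"gene {gene} must have exactly two isoforms")
        inclusion, skipping = isoforms
        psi_val = psi_map[gene]
        flens = np.rint(rng.normal(frag_mean, frag_sd, depth)).astype(int)
        flens = np.clip(flens, read_len, min(inclusion.length, skipping.length))
        if isoform_sampling == "molar":
            w1 = inclusion.length - flens + 1
            w2 = skipping.length - flens + 1
            p_inc = psi_val * w1 / (psi_val * w1 + (1.0 - psi_val) * w2)
        else:
            p_inc = np.full(depth, psi_val)
        pick = rng.random(depth) < p_inc
        cums = {
            t.transcript_id: _cumulative(t.exons) for t in (inclusion, skipping)
        }
        for i in range(depth):
            iso = inclusion if pick[i] else skipping
            iso_len = iso.length
            flen = int(flens[i])
            start = int(rng.integers(0, iso_len - flen + 1))
            cum = cums[iso.transcript_id]
            frag_id = f"{gene}:{sample_id}:f{i:06d}"
            mate_spans = [(start, start + read_len)]
            if paired:
                mate_spans.append((start + flen - read_len, start + flen))
            for mate_idx, (ts, te) in enumerate(mate_spans):
                blocks = _project(iso.exons, cum, ts, te)
                alignments.append(
                    SplicedAlignment(
                        read_id=f"{frag_id}/{mate_idx + 1}",
                        sample_id=sample_id,
                        chrom=iso.chrom,
                        strand="+" if mate_idx == 0 else "-",
                        blocks=blocks,
                        fragment_id=frag_id,
                        is_read1=mate_idx == 0,
                    )
                )
            truth_rows.append((frag_id, gene, bool(pick[i])))
    truth = {
        "fragments": truth_rows,
        "inclusion_isoform": {
            gene: sorted(by_gene[gene], key=lambda t: (-t.length, t.transcript_id))[0].transcript_id
            for gene in sorted(psi_map)
        },
    }
    return alignments, truth


def write_sam(
    alignments: Sequence[SplicedAlignment],
    models: Sequence[TranscriptModel],
    path: str,
) -> None:
    """Write simulated alignments as a valid SAM file (M/N CIGAR, '*' SEQ)."""
    chrom_len: dict[str, int] = {}
    for m in models:
        chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), m.span[1] + 1_000)
    chroms = sorted(chrom_len)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    mates: dict[tuple[str, bool], SplicedAlignment] = {
        (a.fragment_id, a.is_read1): a for a in alignments if a.fragment_id
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.fragment_id or aln.read_id
            rec.reference_id = tid[aln.chrom]
            rec.reference_start = aln.blocks[0][0]
            rec.mapping_quality = 60
            cigar = []
            prev_end = None
            for s, e in aln.blocks:
                if prev_end is not None:
                    cigar.append(f"{s - prev_end}N")
                cigar.append(f"{e - s}M")
                prev_end = e
            rec.cigarstring = "".join(cigar)
            mate = mates.get((aln.fragment_id, not aln.is_read1)) if aln.fragment_id else None
            if mate is not None:
                flag = 0x1 | 0x2 | (0x40 if aln.is_read1 else 0x80)
                flag |= 0x20 if aln.is_read1 else 0x10
                rec.flag = flag
                rec.next_reference_id = tid[mate.chrom]
                rec.next_reference_start = mate.blocks[0][0]
                span_left = min(aln.blocks[0][0], mate.blocks[0][0])
                span_right = max(aln.blocks[-1][1], mate.blocks[-1][1])
                rec.template_length = (
                    span_right - span_left if aln.is_read1 else span_left - span_right
                )
            else:
                rec.flag = 0
                rec.next_reference_id = -1
                rec.next_reference_start = -1
            out.write(rec)


# ---------------------------------------------------------------------------
# SILAC table generator
# ---------------------------------------------------------------------------

def gen_silac(
    seed: int = 0,
    n_proteins: int = 500,
    n_enriched: int = 25,
    effect_log2: float = 2.0,
    sd: float = 0.3,
    n_samples: int = 10,
    n_swapped: int = 5,
    missing_rate: float = 0.05,
    n_low_evidence: int = 40,
    n_extra_bands: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Heavy/light ratio table with a spiked enriched subset.

    Core proteins carry mean log2 ratio 0 (null) or ``effect_log2``
    (enriched) with per-sample noise N(0, sd^2); the last ``n_swapped``
    samples are emitted label-swapped (ratios inverted).  Decoy rows
    violate one filter each (single peptide, score <= 31, sparse
    detection); ``n_extra_bands`` core proteins get a lower-abundance
    duplicate gel-band row.  Missingness is MCAR at ``missing_rate``.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    swapped = samples[n_samples - n_swapped:] if n_swapped else []
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    enriched = sorted(rng.choice(ids, size=n_enriched, replace=False).tolist())
    enriched_set = set(enriched)

    def _ratio_row(mu: float) -> dict[str, float]:
        vals = mu + rng.normal(0.0, sd, n_samples)
        miss = rng.random(n_samples) < missing_rate
        row = {}
        for j, name in enumerate(samples):
            if miss[j]:
                row[f"ratio_{name}"] = np.nan
            else:
                v = vals[j]
                row[f"ratio_{name}"] = float(2.0 ** (-v if name in swapped else v))
        return row

    rows = []
    for pid in ids:
        mu = effect_log2 if pid in enriched_set else 0.0
        row = {
            "protein_id": pid,
            "band_id": int(rng.integers(1, 8)),
            "n_quant_peptides": int(rng.integers(2, 16)),
            "score": float(rng.uniform(35.0, 300.0)),
            "intensity": float(rng.lognormal(15.0, 1.0)),
        }
        row.update(_ratio_row(mu))
        rows.append(row)

    # duplicate gel-band rows that must lose the best-band selection
    dup_ids = sorted(rng.choice(ids, size=min(n_extra_bands, n_proteins), replace=False).tolist())
    base = {r["protein_id"]: r for r in rows}
    for pid in dup_ids:
        mu = effect_log2 if pid in enriched_set else 0.0
        primary = base[pid]
        row = {
            "protein_id": pid,
            "band_id": primary["band_id"] + 1,
            "n_quant_peptides": max(2, primary["n_quant_peptides"] - 1),
            "score": float(rng.uniform(35.0, 300.0)),
            "intensity": primary["intensity"] * 0.1,
        }
        row.update(_ratio_row(mu))
        rows.append(row)

    # decoys, each violating exactly one filter branch
    for i in range(n_low_evidence):
        pid = f"D{i + 1:04d}"
        kind = i % 3
        row = {
            "protein_id": pid,
            "band_id": int(rng.integers(1, 8)),
            "n_quant_peptides": 1 if kind == 0 else int(rng.integers(2, 16)),
            "score": float(rng.uniform(5.0, 31.0)) if kind == 1 else float(rng.uniform(35.0, 300.0)),
            "intensity": float(rng.lognormal(15.0, 1.0)),
        }
        ratios = _ratio_row(0.0)
        if kind == 2:
            present = rng.choice(n_samples, size=int(rng.integers(0, 7)), replace=False)
            keep = {samples[j] for j in present}
            ratios = {
                k: (v if k[len("ratio_"):] in keep else np.nan)
                for k, v in ratios.items()
            }
        row.update(ratios)
        rows.append(row)

    table = pd.DataFrame(rows)
    table = table.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )
    truth = {"enriched": enriched, "swapped_samples": swapped, "core_ids": ids}
    return table, truth


# ---------------------------------------------------------------------------
# Dose-response generator
# ---------------------------------------------------------------------------

def gen_dose_response(
    seed: int = 0,
    n_proteins: int = 200,
    n_displaced: int = 10,
    drop_per_level: float = 0.5,
    sd: float = 0.25,
    levels: Sequence[float] = DEFAULT_LEVELS,
    replicates: int = 3,
    missing_rate: float = 0.05,
    baseline_mean: float = 20.0,
    baseline_sd: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Protein x sample log-abundance matrix with displaced spike-ins.

    Null proteins are flat; displaced proteins decrease linearly across the
    ordered concentration levels with a total drop of
    ``len(levels) * drop_per_level``.  Gaussian noise N(0, sd^2),
    missingness MCAR at ``missing_rate``.  Returns (matrix, design, truth).
    """
    if n_displaced > n_proteins:
        raise ValueError("n_displaced cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    levels = tuple(sorted(levels))
    n_levels = len(levels)
    samples = [f"c{lvl:g}_r{r + 1}" for lvl in levels for r in range(replicates)]
    level_of = np.repeat(np.arange(n_levels), replicates)
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    displaced = sorted(rng.choice(ids, size=n_displaced, replace=False).tolist())
    displaced_mask = np.isin(ids, displaced)
    base = rng.normal(baseline_mean, baseline_sd, n_proteins)
    total_drop = n_levels * drop_per_level
    profile = np.outer(
        displaced_mask.astype(float), total_drop * level_of / (n_levels - 1)
    )
    values = base[:, None] - profile + rng.normal(0.0, sd, (n_proteins, len(samples)))
    if missing_rate > 0:
        values = np.where(
            rng.random(values.shape) < missing_rate, np.nan, values
        )
    matrix = pd.DataFrame(values, index=ids, columns=samples)
    matrix.index.name = "protein_id"
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "concentration_uM": [levels[i] for i in level_of],
            "replicate": [r + 1 for _ in levels for r in range(replicates)],
        }
    )
    truth = {"displaced": displaced, "levels": levels, "total_drop": total_drop}
    return matrix, design, truth
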