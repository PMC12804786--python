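"""Homozygosity-bin detection from per-sample genotype calls.

A *homozygosity bin* is a maximal run of SNP records over which at least
``min_per_class`` samples are consistently homozygous-alternate (1/1) and
at least ``min_per_class`` other samples are consistently
homozygous-reference (0/0), tolerating up to ``max_mismatch`` discordant
records inside the run.  Bins with enough genes supply the contrasting
sample trios for downstream expression analysis.

Consistency is tracked as running intersections of the hom-alt and
hom-ref sample sets: a record extends the run only if both intersections
stay at or above ``min_per_class``; any other record (non-qualifying or
set-breaking) consumes one mismatch credit.  Bin boundaries are the
positions of the first and last *consistent qualifying* record; trailing
skipped records are never included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

HOM_REF = "0/0"
HET = "0/1"
HOM_ALT = "1/1"
MISSING = "./."


class SortOrderError(ValueError):
    """Input records are not sorted by (chrom, pos)."""


@dataclass(frozen=True)
class GenotypeRecord:
    """One biallelic site with per-sample diploid calls."""

    chrom: str
    pos: int
    calls: dict[str, str] = field(hash=False)

    def hom_sets(self) -> tuple[frozenset, frozenset]:
        """(hom-alt samples, hom-ref samples); het/missing join neither."""
        alt = frozenset(s for s, c in self.calls.items() if c in ("1/1", "1|1"))
        ref = frozenset(s for s, c in self.calls.items() if c in ("0/0", "0|0"))
        return alt, ref


@dataclass
class HomozygosityBin:
    chrom: str
    start: int  # 1-based position of the first supporting record
    end: int    # 1-based position of the last supporting record
    alt_trio: tuple[str, ...]
    ref_trio: tuple[str, ...]
    n_records: int
    n_mismatches: int
    genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ContrastSet:
    """The 3+3 contrasting samples selected from one gene-rich bin."""

    bin: HomozygosityBin
    alt_trio: tuple[str, ...]
    ref_trio: tuple[str, ...]


def read_vcf(path: str | Path, min_gq: None = None) -> list[GenotypeRecord]:
    """Read biallelic SNP records from a VCF (GT field only).

    Multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records = []
    n_skipped = 0
    code = {0: HOM_REF, 1: HET, 2: HOM_ALT, 3: MISSING}
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        calls = {s: code[int(g)] for s, g in zip(samples, v.gt_types)}
        records.append(GenotypeRecord(v.CHROM, v.POS, calls))
    if n_skipped:
        logger.info("skipped %d non-biallelic records", n_skipped)
    return records


def records_from_frame(df: pd.DataFrame, samples: list[str]) -> list[GenotypeRecord]:
    """Build records from the simulator's genotype DataFrame."""
    return [
        GenotypeRecord(row.chrom, int(row.pos),
                       {s: getattr(row, s) for s in samples})
        for row in df.itertuples(index=False)
    ]


def qualify_record(
    record: GenotypeRecord, min_per_class: int = 3
) -> tuple[bool, frozenset, frozenset]:
    """A record qualifies when >= ``min_per_class`` samples are 1/1 AND
    >= ``min_per_class`` samples are 0/0.  Returns the full sets."""
    alt, ref = record.hom_sets()
    return (len(alt) >= min_per_class and len(ref) >= min_per_class, alt, ref)


def _check_sorted(records: list[GenotypeRecord]) -> None:
    seen_chroms: dict[str, int] = {}
    prev_chrom, prev_pos = None, None
    for r in records:
        if r.chrom != prev_chrom:
            if r.chrom in seen_chroms:
                raise SortOrderError(
                    f"chromosome {r.chrom} appears in two blocks (at pos {r.pos})"
                )
            seen_chroms[r.chrom] = 1
            prev_chrom, prev_pos = r.chrom, r.pos
            continue
        if r.pos <= prev_pos:
            raise SortOrderError(
                f"records not sorted at {r.chrom}:{r.pos} (previous {prev_pos})"
            )
        prev_pos = r.pos


def _smallest_trio(samples: frozenset, k: int = 3) -> tuple[str, ...]:
    return tuple(sorted(samples)[:k])


def build_bins(
    records: list[GenotypeRecord],
    min_per_class: int = 3,
    max_mismatch: int = 2,
) -> list[HomozygosityBin]:
    """Single-pass detection of maximal homozygosity bins.

    Records must be sorted by (chrom, pos) with no duplicate positions.
    After a bin closes, the skipped records that followed its last
    consistent record are replayed so a new bin can start among them.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    _check_sorted(records)
    bins: list[HomozygosityBin] = []
    by_chrom: dict[str, list[GenotypeRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, recs in by_chrom.items():
        bins.extend(_bins_one_chrom(recs, min_per_class, max_mismatch))
    return bins


def _bins_one_chrom(
    recs: list[GenotypeRecord], min_per_class: int, max_mismatch: int
) -> list[HomozygosityBin]:
    bins: list[HomozygosityBin] = []
    i = 0
    n = len(recs)
    while i < n:
        ok, alt, ref = qualify_record(recs[i], min_per_class)
        if not ok:
            i += 1
            continue
        # open a bin at record i and extend greedily
        A, R = alt, ref
        start_pos = recs[i].pos
        last_pos = recs[i].pos
        last_idx = i
        n_records = 1
        n_mismatch = 0
        pending = 0
        j = i + 1
        while j < n:
            ok_j, alt_j, ref_j = qualify_record(recs[j], min_per_class)
            consistent = False
            if ok_j:
                A2, R2 = A & alt_j, R & ref_j
                if len(A2) >= min_per_class and len(R2) >= min_per_class:
                    consistent = True
            if consistent:
                A, R = A2, R2
                n_mismatch += pending
                n_records += pending + 1
                pending = 0
                last_pos = recs[j].pos
                last_idx = j
            else:
                pending += 1
                if n_mismatch + pending > max_mismatch:
                    break
            j += 1
        bins.append(
            HomozygosityBin(
                chrom=recs[i].chrom, start=start_pos, end=last_pos,
                alt_trio=_smallest_trio(A), ref_trio=_smallest_trio(R),
                n_records=n_records, n_mismatches=n_mismatch,
            )
        )
        i = last_idx + 1  # replay trailing skipped records
    return bins


def annotate_bins(
    bins: list[HomozygosityBin],
    gene_spans: pd.DataFrame,
) -> list[HomozygosityBin]:
    """Fill ``genes``/``n_genes`` by gene-body interval intersection.

    ``gene_spans`` needs columns gene_id, chrom, start, end (1-based
    inclusive, the GFF gene feature span).  A bin whose chromosome is
    absent from the annotation gets n_genes = 0 with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for row in gene_spans.itertuples(index=False):
        # half-open tree coordinates
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start - 1, row.end, row.gene_id
        )
    known = set(trees)
    for b in bins:
        if b.chrom not in known:
            logger.warning("bin chromosome %s absent from annotation", b.chrom)
            b.genes = []
            continue
        hits = trees[b.chrom].overlap(b.start - 1, b.end)
        b.genes = sorted(h.data for h in hits)
    return bins


def select_sample_sets(
    bins: list[HomozygosityBin], min_genes: int = 20
) -> list[ContrastSet]:
    """One 3+3 contrast per bin spanning at least ``min_genes`` genes."""
    return [
        ContrastSet(bin=b, alt_trio=b.alt_trio, ref_trio=b.ref_trio)
        for b in bins
        if b.n_genes >= min_genes
    ]


def polymorphism_density(
    records: list[GenotypeRecord], chromosome_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome polymorphism counts and sites/kb, plus a genome row."""
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
    counts = {c: 0 for c in chromosome_lengths}
    for r in records:
        if r.chrom not in counts:
            raise ValueError(f"record on unknown chromosome {r.chrom!r}")
        counts[r.chrom] += 1
    rows = [
        {"chrom": c, "n_sites": counts[c],
         "density_per_kb": counts[c] / (chromosome_lengths[c] / 1000)}
        for c in chromosome_lengths
    ]
    total_len = sum(chromosome_lengths.values())
    rows.append({
        "chrom": "genome", "n_sites": sum(counts.values()),
        "density_per_kb": sum(counts.values()) / (total_len / 1000),
    })
    return pd.DataFrame(rows)


def bins_to_frame(bins: list[HomozygosityBin]) -> pd.DataFrame:
    """BED-compatible table (0-based half-open start/end)."""
    rows = []
    for i, b in enumerate(bins, 1):
        rows.append({
            "chrom": b.chrom, "start": b.start - 1, "end": b.end,
            "bin_id": f"bin{i:04d}",
            "alt_trio": ",".join(b.alt_trio), "ref_trio": ",".join(b.ref_trio),
            "n_records": b.n_records, "n_mismatches": b.n_mismatches,
            "n_genes": b.n_genes, "genes": ",".join(b.genes),
        })
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "bin_id", "alt_trio",
                       "ref_trio", "n_records", "n_mismatches",
                       "n_genes", "genes"],
    )


def bins_from_frame(df: pd.DataFrame) -> list[HomozygosityBin]:
    out = []
    for row in df.itertuples(index=False):
        genes = [] if (not isinstance(row.genes, str) or row.genes == "") \
            else row.genes.split(",")
        out.append(HomozygosityBin(
            chrom=row.chrom, start=int(row.start) + 1, end=int(row.end),
            alt_trio=tuple(row.alt_trio.split(",")),
            ref_trio=tuple(row.ref_trio.split(",")),
            n_records=int(row.n_records), n_mismatches=int(row.n_mismatches),
            genes=genes,
        ))
    return out
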