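"""Genic-context annotation of insertion points and enrichment statistics.

Each insertion point is assigned one of six genic categories — 2 kb
upstream, 5'UTR, CDS, intron, 3'UTR, 2 kb downstream — or intergenic.
When a point matches several categories (overlapping genes, flank over
another gene's body) the highest-priority category wins under the
precedence cds > utr5 > utr3 > intron > upstream2kb > downstream2kb.
Superfamily x context counts feed a Pearson chi-squared independence
test whose per-cell contributions mirror bubble-plot enrichment figures,
and length-standardised densities (insertions per unit of cumulative
category length) make categories of different total size comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .insertions import InsertionSite

logger = logging.getLogger(__name__)

GENIC_CONTEXTS = ("upstream2kb", "utr5", "cds", "intron", "utr3",
                  "downstream2kb")
ALL_CONTEXTS = GENIC_CONTEXTS + ("intergenic",)
#: smaller rank wins when one point matches several categories
PRECEDENCE = {"cds": 0, "utr5": 1, "utr3": 2, "intron": 3,
              "upstream2kb": 4, "downstream2kb": 5}
FLANK_BP = 2000


class AnnotationError(ValueError):
    pass


@dataclass
class GeneModel:
    """Strand-aware gene with sub-feature intervals (1-based inclusive).

    For multi-transcript genes the sub-features are unions over
    transcripts; introns are the mRNA span minus the exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)
    upstream2kb: tuple[int, int] | None = None
    downstream2kb: tuple[int, int] | None = None

    def intervals(self, category: str) -> list[tuple[int, int]]:
        if category == "upstream2kb":
            return [self.upstream2kb] if self.upstream2kb else []
        if category == "downstream2kb":
            return [self.downstream2kb] if self.downstream2kb else []
        if category == "intron":
            return self.introns
        return getattr(self, category)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(span: tuple[int, int], holes: list[tuple[int, int]]) -> list:
    """Span minus a merged interval list."""
    s0, e0 = span
    out = []
    cursor = s0
    for s, e in holes:
        if e < s0 or s > e0:
            continue
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= e0:
        out.append((cursor, e0))
    return out


def _flank(start, end, strand, length, chrom_len) -> tuple:
    """Strand-aware (upstream, downstream) flanks clipped to [1, chrom_len]."""
    left = (max(1, start - length), start - 1) if start > 1 else None
    right = (end + 1, min(chrom_len, end + length)) if end < chrom_len else None
    if strand == "+":
        return left, right
    return right, left


def build_gene_models(
    gff_path: str | Path,
    chromosome_lengths: dict[str, int] | None = None,
    flank_bp: int = FLANK_BP,
) -> list[GeneModel]:
    """Parse a GFF3 into gene models with derived introns and flanks.

    UTRs are taken from explicit five_prime_UTR/three_prime_UTR features
    when present, otherwise derived as exon-minus-CDS split at the CDS
    (5' side vs 3' side in transcription order).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    lengths = dict(chromosome_lengths or {})
    if not lengths:
        for d in db.directives:
            if d.startswith("sequence-region"):
                parts = d.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons, cds, utr5, utr3 = [], [], [], []
        mrna_spans = []
        for mrna in db.children(gene, featuretype="mRNA"):
            mrna_spans.append((mrna.start, mrna.end))
            for f in db.children(mrna):
                iv = (f.start, f.end)
                if f.featuretype == "exon":
                    exons.append(iv)
                elif f.featuretype == "CDS":
                    if not (mrna.start <= f.start and f.end <= mrna.end):
                        raise AnnotationError(
                            f"CDS {iv} outside mRNA span for {gene.id}"
                        )
                    cds.append(iv)
                elif f.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif f.featuretype == "three_prime_UTR":
                    utr3.append(iv)
        exons = _merge(exons)
        cds = _merge(cds)
        utr5, utr3 = _merge(utr5), _merge(utr3)
        span = (gene.start, gene.end)
        mrna_union = _merge(mrna_spans) or [span]
        introns = []
        for ms, me in mrna_union:
            introns.extend(_subtract((ms, me), exons))
        introns = _merge(introns)
        if not (utr5 or utr3) and cds and exons:
            utr5, utr3 = _derive_utrs(exons, cds, gene.strand)
        chrom_len = lengths.get(gene.seqid, 2**62)
        up, down = _flank(gene.start, gene.end, gene.strand, flank_bp, chrom_len)
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, cds=cds, utr5=utr5, utr3=utr3,
            introns=introns, upstream2kb=up, downstream2kb=down,
        ))
    return models


def _derive_utrs(exons, cds, strand):
    """Exonic sequence outside the CDS, split into 5' and 3' sides."""
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    non_cds = []
    for ex in exons:
        non_cds.extend(_subtract(ex, cds))
    low = [iv for iv in non_cds if iv[1] < cds_lo]
    high = [iv for iv in non_cds if iv[0] > cds_hi]
    if strand == "+":
        return _merge(low), _merge(high)
    return _merge(high), _merge(low)


@dataclass(frozen=True)
class ContextAssignment:
    site_key: str
    context: str
    associated_genes: tuple[str, ...]


class ContextIndex:
    """Per-chromosome interval index over gene-model categories."""

    def __init__(self, models: list[GeneModel]):
        self.models = models
        self._cat_trees: dict[str, IntervalTree] = {}
        self._assoc_trees: dict[str, IntervalTree] = {}
        for m in models:
            cat_tree = self._cat_trees.setdefault(m.chrom, IntervalTree())
            assoc_tree = self._assoc_trees.setdefault(m.chrom, IntervalTree())
            for cat in GENIC_CONTEXTS:
                for s, e in m.intervals(cat):
                    if e >= s:
                        cat_tree.addi(s - 1, e, (cat, m.gene_id))
            assoc_lo = min(x[0] for x in
                           filter(None, [m.upstream2kb, m.downstream2kb,
                                         (m.start, m.end)]))
            assoc_hi = max(x[1] for x in
                           filter(None, [m.upstream2kb, m.downstream2kb,
                                         (m.start, m.end)]))
            assoc_tree.addi(assoc_lo - 1, assoc_hi, m.gene_id)

    def assign(self, chrom: str, pos: int, site_key: str) -> ContextAssignment:
        if chrom not in self._cat_trees:
            logger.warning("site chromosome %s absent from annotation", chrom)
            return ContextAssignment(site_key, "intergenic", ())
        hits = self._cat_trees[chrom][pos - 1]
        if not hits:
            return ContextAssignment(site_key, "intergenic", ())
        best = min(hits, key=lambda h: PRECEDENCE[h.data[0]])
        genes = sorted(h.data for h in self._assoc_trees[chrom][pos - 1])
        return ContextAssignment(site_key, best.data[0], tuple(genes))


def assign_context(
    site: InsertionSite, index: ContextIndex
) -> ContextAssignment:
    """Genic context of one insertion point (single-base semantics)."""
    return index.assign(site.chrom, site.pos, site.key)


def assign_contexts(
    sites: list[InsertionSite], models: list[GeneModel]
) -> list[ContextAssignment]:
    index = ContextIndex(models)
    return [assign_context(s, index) for s in sites]


def context_counts(
    assignments: list[ContextAssignment],
    sites: list[InsertionSite],
) -> pd.DataFrame:
    """Superfamily x context count matrix (with the intergenic column)."""
    sup_by_key = {s.key: s.superfamily for s in sites}
    unknown = [a.site_key for a in assignments if a.site_key not in sup_by_key]
    if unknown:
        raise ValueError(f"assignments for unknown sites: {unknown}")
    sups = sorted({s.superfamily for s in sites})
    mat = pd.DataFrame(0, index=sups, columns=list(ALL_CONTEXTS))
    for a in assignments:
        mat.loc[sup_by_key[a.site_key], a.context] += 1
    mat.index.name = "superfamily"
    return mat


def cumulative_category_lengths(
    models: list[GeneModel], chromosome_lengths: dict[str, int] | None = None
) -> dict[str, int]:
    """Genome-wide cumulative bp per category (overlaps merged within a
    category, never across categories)."""
    out = {}
    for cat in GENIC_CONTEXTS:
        by_chrom: dict[str, list] = {}
        for m in models:
            for iv in m.intervals(cat):
                by_chrom.setdefault(m.chrom, []).append(iv)
        total = 0
        for ivs in by_chrom.values():
            total += sum(e - s + 1 for s, e in _merge(ivs))
        out[cat] = total
    return out


def standardized_density(
    counts: pd.DataFrame,
    cumulative_lengths: dict[str, int],
    per: int = 100_000,
) -> pd.DataFrame:
    """Insertions per ``per`` bp of cumulative category length."""
    cols = [c for c in counts.columns if c in cumulative_lengths]
    rates = {}
    for c in cols:
        length = cumulative_lengths[c]
        if length <= 0:
            if counts[c].sum() > 0:
                raise ValueError(f"zero cumulative length for {c} with counts")
            rates[c] = counts[c] * 0.0
        else:
            rates[c] = counts[c] / (length / per)
    out = pd.DataFrame(rates, index=counts.index)
    out.index.name = counts.index.name
    return out


@dataclass
class EnrichmentTable:
    counts: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    residuals: pd.DataFrame       # (obs - exp) / sqrt(exp)
    contributions: pd.DataFrame   # residual**2, sums to chi2


def chi_squared_enrichment(counts: pd.DataFrame) -> EnrichmentTable:
    """Pearson chi-squared independence test with per-cell contributions."""
    obs = counts.to_numpy(dtype=float)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: zero row or column sum")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    resid = (obs - expected) / np.sqrt(expected)
    return EnrichmentTable(
        counts=counts,
        expected=pd.DataFrame(expected, index=counts.index,
                              columns=counts.columns),
        chi2=float(chi2), dof=int(dof), p_value=float(p),
        residuals=pd.DataFrame(resid, index=counts.index,
                               columns=counts.columns),
        contributions=pd.DataFrame(resid**2, index=counts.index,
                                   columns=counts.columns),
    )


def chromosome_density(
    sites: list[InsertionSite],
    chromosome_lengths: dict[str, int],
    per: int = 100_000,
) -> pd.DataFrame:
    """Per-chromosome insertion counts and rates plus the genome average."""
    for c, ln in chromosome_lengths.items():
        if ln <= 0:
            raise ValueError(f"chromosome {c} has non-positive length")
    counts = {c: 0 for c in chromosome_lengths}
    for s in sites:
        if s.chrom not in counts:
            raise ValueError(f"site on unknown chromosome {s.chrom!r}")
        counts[s.chrom] += 1
    rows = [
        {"chrom": c, "n_sites": counts[c],
         "rate": counts[c] / (chromosome_lengths[c] / per)}
        for c in chromosome_lengths
    ]
    total_len = sum(chromosome_lengths.values())
    rows.append({"chrom": "genome", "n_sites": sum(counts.values()),
                 "rate": sum(counts.values()) / (total_len / per)})
    return pd.DataFrame(rows)
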