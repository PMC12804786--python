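"""Synthetic miniature study generator.

Emulates the data layout of a MITE-insertion / expression study in two
segregating F2 families of 12 plants each: a GFF3 gene annotation, a
biallelic-SNP VCF with planted homozygosity tracts, a PopoolationTE2-style
insertion-signature table with planted per-sample zygosities, per-algorithm
differential-expression tables with planted effects, a MITE family
catalogue, and a TPM-like expression matrix.  Every generator is a pure
function of its :class:`SimulationConfig`; ground truth (planted tracts,
zygosities, genic contexts, DEG labels) is recorded alongside the files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SUPERFAMILIES = ("hAT", "Mutator", "Stowaway", "Tourist", "uc")
ZYGOSITY_LABELS = ("hom_occupied", "het", "hom_empty")
#: target signature frequency for each true zygosity
ZYGOSITY_FREQ = {"hom_occupied": 1.0, "het": 0.5, "hom_empty": 0.0}
GENOTYPE_CODES = ("0/0", "0/1", "1/1", "./.")

# per-stage stream tags so each generator is independently deterministic
_TAG_ANNOTATION = 101
_TAG_GENOTYPES = 202
_TAG_SIGNATURES = 303
_TAG_DE = 404
_TAG_EXPRESSION = 505
_TAG_STUDY = 606


class SimulationError(ValueError):
    """Raised for configurations that cannot be realised."""


@dataclass(frozen=True)
class PlantedTract:
    """A planted homozygosity tract: ``alt_trio`` samples are 1/1 and
    ``ref_trio`` samples are 0/0 at every emitted site inside
    [start, end] (1-based inclusive), except for optionally injected
    discordant 'mismatch' sites."""

    chrom: str
    start: int
    end: int
    alt_trio: tuple[str, ...]
    ref_trio: tuple[str, ...]
    n_mismatch_sites: int = 0
    consecutive_mismatches: bool = False


@dataclass(frozen=True)
class PlantedInsertion:
    """A planted MITE insertion with true per-sample zygosity."""

    chrom: str
    pos: int
    family: str
    mode: str  # "reference" | "nonreference"
    zygosity: dict[str, str] = field(hash=False)


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    chromosome_length_bp: int = 1_000_000
    n_genes: int = 60
    n_samples: int = 12
    n_families: int = 20
    snp_density: float = 1.0  # SNP sites per kb
    tract_spec: list[PlantedTract] = field(default_factory=list)
    insertion_spec: list[PlantedInsertion] = field(default_factory=list)
    effect_spec: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    population: str = "P1"

    @property
    def samples(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_samples + 1)]

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosomes}

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise SimulationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_samples < 1 or self.n_chromosomes < 1:
            raise SimulationError("need at least one sample and one chromosome")
        lengths = self.chromosome_lengths
        samples = set(self.samples)
        for t in self.tract_spec:
            if t.chrom not in lengths:
                raise SimulationError(f"tract on unknown chromosome {t.chrom!r}")
            if not (1 <= t.start <= t.end <= lengths[t.chrom]):
                raise SimulationError(
                    f"tract {t.chrom}:{t.start}-{t.end} outside chromosome bounds"
                )
            alt, ref = set(t.alt_trio), set(t.ref_trio)
            if len(alt) < 3 or len(ref) < 3:
                raise SimulationError("tract trios need >= 3 samples each")
            if alt & ref:
                raise SimulationError("tract trios must be disjoint")
            if not (alt | ref) <= samples:
                raise SimulationError("tract trio samples not in configured samples")
        by_chrom: dict[str, list[PlantedTract]] = {}
        for t in self.tract_spec:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, tracts in by_chrom.items():
            tracts = sorted(tracts, key=lambda t: t.start)
            for a, b in zip(tracts, tracts[1:]):
                if b.start <= a.end:
                    raise SimulationError(
                        f"planted tracts overlap on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )
        for ins in self.insertion_spec:
            if ins.chrom not in lengths:
                raise SimulationError(f"insertion on unknown chromosome {ins.chrom!r}")
            if not (1 <= ins.pos <= lengths[ins.chrom]):
                raise SimulationError(f"insertion {ins.chrom}:{ins.pos} out of bounds")
            if ins.mode not in ("reference", "nonreference"):
                raise SimulationError(f"unknown insertion mode {ins.mode!r}")
            for s, z in ins.zygosity.items():
                if z not in ZYGOSITY_LABELS:
                    raise SimulationError(f"unknown zygosity {z!r} for sample {s}")


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class SimGene:
    """In-memory gene model used for ground truth and GFF3 emission.

    All intervals are 1-based inclusive (GFF3 convention).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


def generate_annotation(config: SimulationConfig) -> list[SimGene]:
    """Place non-overlapping genes (with 2 kb clearance on both sides) on
    the configured chromosomes and build their exon/CDS/UTR structure."""
    config.validate()
    rng = _rng(config, _TAG_ANNOTATION)
    genes: list[SimGene] = []
    if config.n_genes == 0:
        return genes
    # distribute genes across chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gi = 0
    for chrom, n_here in zip(config.chromosomes, per_chrom):
        if n_here == 0:
            continue
        lengths = rng.integers(2000, 6001, size=n_here)
        footprint = int(lengths.sum()) + 4000 * n_here
        slack = config.chromosome_length_bp - footprint
        if slack < 0:
            raise SimulationError(
                f"cannot place {n_here} genes with 2 kb flanks on {chrom} "
                f"({config.chromosome_length_bp} bp)"
            )
        # random gaps between/around genes that sum to the slack
        gaps = rng.multinomial(slack, np.full(n_here + 1, 1.0 / (n_here + 1)))
        cursor = 1 + 2000  # leave room for the first upstream flank
        for k in range(n_here):
            cursor += int(gaps[k])
            start = cursor
            end = start + int(lengths[k]) - 1
            gi += 1
            genes.append(
                _build_gene_structure(
                    f"gene{gi:04d}", chrom, start, end, rng
                )
            )
            cursor = end + 1 + 4000  # 2 kb downstream + 2 kb next upstream
    return genes


def _build_gene_structure(
    gene_id: str, chrom: str, start: int, end: int, rng: np.random.Generator
) -> SimGene:
    strand = "+" if rng.random() < 0.5 else "-"
    length = end - start + 1
    n_exons = int(rng.integers(1, 4))
    # carve introns (>= 100 bp each) out of the span, keeping exons >= 300 bp
    while n_exons > 1 and length < 300 * n_exons + 500 * (n_exons - 1):
        n_exons -= 1
    if n_exons == 1:
        exons = [(start, end)]
    else:
        intron_sizes = rng.integers(100, 501, size=n_exons - 1)
        exonic_total = length - int(intron_sizes.sum())
        cuts = rng.multinomial(
            exonic_total - 300 * n_exons, np.full(n_exons, 1.0 / n_exons)
        )
        exon_sizes = cuts + 300
        exons = []
        cursor = start
        for i in range(n_exons):
            exons.append((cursor, cursor + int(exon_sizes[i]) - 1))
            cursor = exons[-1][1] + 1
            if i < n_exons - 1:
                cursor += int(intron_sizes[i])
        # absorb rounding into the last exon
        exons[-1] = (exons[-1][0], end)
    exonic_len = sum(e - s + 1 for s, e in exons)
    utr5_len = int(rng.integers(100, min(301, exonic_len // 4)))
    utr3_len = int(rng.integers(100, min(301, exonic_len // 4)))
    cds, utr5, utr3 = _split_exons(exons, strand, utr5_len, utr3_len)
    return SimGene(gene_id, chrom, strand, start, end, exons, cds, utr5, utr3)


def _split_exons(
    exons: list[tuple[int, int]], strand: str, utr5_len: int, utr3_len: int
) -> tuple[list, list, list]:
    """Split the exon union into 5'UTR / CDS / 3'UTR in transcription order."""
    low_len = utr5_len if strand == "+" else utr3_len
    high_len = utr3_len if strand == "+" else utr5_len
    low_parts, rest = _take_prefix(exons, low_len)
    rest_rev = [(-e, -s) for s, e in reversed(rest)]
    high_rev, cds_rev = _take_prefix(rest_rev, high_len)
    high_parts = [(-e, -s) for s, e in reversed(high_rev)]
    cds = [(-e, -s) for s, e in reversed(cds_rev)]
    if strand == "+":
        return cds, low_parts, high_parts
    return cds, high_parts, low_parts


def _take_prefix(
    intervals: list[tuple[int, int]], n: int
) -> tuple[list, list]:
    """Split a sorted interval list after its first ``n`` covered bases."""
    taken, rest = [], []
    remaining = n
    for s, e in intervals:
        size = e - s + 1
        if remaining <= 0:
            rest.append((s, e))
        elif size <= remaining:
            taken.append((s, e))
            remaining -= size
        else:
            taken.append((s, s + remaining - 1))
            rest.append((s + remaining, e))
            remaining = 0
    return taken, rest


def annotation_to_gff3(genes: list[SimGene], config: SimulationConfig) -> str:
    lines = ["##gff-version 3"]
    for chrom in config.chromosomes:
        lines.append(f"##sequence-region {chrom} 1 {config.chromosome_length_bp}")
    def row(chrom, ftype, s, e, strand, attrs):
        return f"{chrom}\tmitelink_sim\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        mrna = f"{g.gene_id}.t1"
        lines.append(row(g.chrom, "gene", g.start, g.end, g.strand,
                         f"ID={g.gene_id};Name={g.gene_id}"))
        lines.append(row(g.chrom, "mRNA", g.start, g.end, g.strand,
                         f"ID={mrna};Parent={g.gene_id}"))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(row(g.chrom, "exon", s, e, g.strand,
                             f"ID={mrna}.exon{i};Parent={mrna}"))
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(row(g.chrom, "CDS", s, e, g.strand,
                             f"ID={mrna}.cds{i};Parent={mrna}"))
        for i, (s, e) in enumerate(g.utr5, 1):
            lines.append(row(g.chrom, "five_prime_UTR", s, e, g.strand,
                             f"ID={mrna}.utr5p{i};Parent={mrna}"))
        for i, (s, e) in enumerate(g.utr3, 1):
            lines.append(row(g.chrom, "three_prime_UTR", s, e, g.strand,
                             f"ID={mrna}.utr3p{i};Parent={mrna}"))
    return "\n".join(lines) + "\n"


def chromosome_table(config: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": config.chromosomes,
         "length": [config.chromosome_length_bp] * config.n_chromosomes}
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class TractTruth:
    tract: PlantedTract
    site_positions: list[int]          # emitted SNP positions inside the tract
    mismatch_positions: list[int]      # subset made discordant on purpose


def generate_genotypes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[TractTruth]]:
    """Emit biallelic SNP genotypes with planted homozygosity tracts.

    Returns a DataFrame with columns chrom, pos, ref, alt and one column
    per sample holding diploid GT strings, plus per-tract ground truth.
    Inside a planted tract every site carries the tract's trio pattern
    (alt trio 1/1, ref trio 0/0); outside, sites are forced to violate the
    >=3/>=3 two-homozygote-classes rule with probability 0.95.
    """
    config.validate()
    if config.snp_density <= 0:
        raise SimulationError("snp_density must be > 0")
    rng = _rng(config, _TAG_GENOTYPES)
    samples = config.samples
    bases = np.array(list("ACGT"))
    rows: list[list] = []
    tract_truth = [TractTruth(t, [], []) for t in config.tract_spec]
    for chrom in config.chromosomes:
        n_sites = int(round(config.chromosome_length_bp / 1000 * config.snp_density))
        n_sites = min(n_sites, config.chromosome_length_bp)
        pos = np.sort(
            rng.choice(config.chromosome_length_bp, size=n_sites, replace=False)
        ) + 1
        tracts_here = [tt for tt in tract_truth if tt.tract.chrom == chrom]
        for p in pos:
            p = int(p)
            ref, alt = rng.choice(4, size=2, replace=False)
            tract = next(
                (tt for tt in tracts_here if tt.tract.start <= p <= tt.tract.end),
                None,
            )
            if tract is not None:
                calls = _tract_calls(tract.tract, samples, rng)
                tract.site_positions.append(p)
            else:
                calls = _background_calls(samples, rng)
            rows.append([chrom, p, bases[ref], bases[alt], *calls])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *samples])
    # inject requested discordant sites per tract
    for tt in tract_truth:
        k = tt.tract.n_mismatch_sites
        if k == 0:
            continue
        if k > len(tt.site_positions):
            raise SimulationError(
                f"tract {tt.tract.chrom}:{tt.tract.start}-{tt.tract.end} has "
                f"{len(tt.site_positions)} sites, cannot inject {k} mismatches"
            )
        n = len(tt.site_positions)
        if tt.tract.consecutive_mismatches:
            first = (n - k) // 2
            idx = list(range(first, first + k))
        else:
            idx = sorted(rng.choice(n, size=k, replace=False).tolist())
        victim = sorted(tt.tract.alt_trio)[0]
        for i in idx:
            p = tt.site_positions[i]
            df.loc[(df["chrom"] == tt.tract.chrom) & (df["pos"] == p), victim] = "0/1"
            tt.mismatch_positions.append(p)
    return df, tract_truth


def _tract_calls(
    tract: PlantedTract, samples: list[str], rng: np.random.Generator
) -> list[str]:
    calls = []
    alt, ref = set(tract.alt_trio), set(tract.ref_trio)
    codes = np.array(GENOTYPE_CODES)
    others = rng.choice(4, size=len(samples), p=[0.3, 0.4, 0.25, 0.05])
    for s, o in zip(samples, others):
        if s in alt:
            calls.append("1/1")
        elif s in ref:
            calls.append("0/0")
        else:
            calls.append(codes[o])
    return calls


def _background_calls(samples: list[str], rng: np.random.Generator) -> list[str]:
    codes = np.array(GENOTYPE_CODES)
    draw = codes[rng.choice(4, size=len(samples), p=[0.3, 0.4, 0.25, 0.05])]
    if rng.random() < 0.05:
        return draw.tolist()  # fully random; may occasionally qualify
    # force a violation of the >=3 hom-alt AND >=3 hom-ref rule
    deficient = "1/1" if rng.random() < 0.5 else "0/0"
    where = np.flatnonzero(draw == deficient)
    keep = int(rng.integers(0, 3))
    for i in where[keep:]:
        draw[i] = "0/1"
    return draw.tolist()


def genotypes_to_vcf(df: pd.DataFrame, config: SimulationConfig) -> str:
    samples = config.samples
    lines = ["##fileformat=VCFv4.2", "##source=mitelink_sim"]
    for chrom in config.chromosomes:
        lines.append(f"##contig=<ID={chrom},length={config.chromosome_length_bp}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for row in df.itertuples(index=False):
        gt = "\t".join(getattr(row, s) for s in samples)
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gt}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# insertion signatures
# ---------------------------------------------------------------------------


def generate_signatures(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the per-sample signature table and the true zygosity matrix.

    Reference-mode insertions produce paired F and R rows (independent
    noise per row); non-reference insertions produce a single FR row.
    Frequencies are the zygosity target (1.0 / 0.5 / 0.0) plus truncated
    Gaussian noise of sd ``noise_sd``; rows whose frequency comes out
    exactly 0 are omitted (absence is encoded as frequency 0 downstream).
    """
    config.validate()
    rng = _rng(config, _TAG_SIGNATURES)
    samples = config.samples
    rows = []
    truth_rows = {}
    for ins in config.insertion_spec:
        key = f"{ins.chrom}:{ins.pos}:{ins.family}:{ins.mode}"
        truth_rows[key] = {
            s: ins.zygosity.get(s, "hom_empty") for s in samples
        }
        for s in samples:
            target = ZYGOSITY_FREQ[truth_rows[key][s]]
            sigs = ("F", "R") if ins.mode == "reference" else ("FR",)
            for sig in sigs:
                freq = target + rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else target
                freq = float(min(1.0, max(0.0, freq)))
                if freq == 0.0:
                    continue
                rows.append(
                    [s, ins.chrom, ins.pos, ins.family, sig, freq, ins.mode]
                )
    table = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "family", "signature",
                 "frequency", "mode"],
    )
    truth = pd.DataFrame.from_dict(truth_rows, orient="index", columns=samples)
    truth.index.name = "site"
    return table, truth


def family_catalogue(config: SimulationConfig) -> pd.DataFrame:
    """MITE family ids cycled over the five superfamilies."""
    fams = [f"fam{i:02d}" for i in range(1, config.n_families + 1)]
    sups = [SUPERFAMILIES[i % len(SUPERFAMILIES)] for i in range(config.n_families)]
    return pd.DataFrame({"family": fams, "superfamily": sups})


# ---------------------------------------------------------------------------
# differential-expression tables and expression matrix
# ---------------------------------------------------------------------------

DEFAULT_ALGORITHMS = ("alg1", "alg2", "alg3")


def generate_de_tables(
    config: SimulationConfig,
    genes: list[SimGene],
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """One DE result table per pseudo-algorithm plus the true DEG labels.

    Planted effects get adjusted p < 0.05 with the planted sign in every
    table; null genes draw padj uniformly from (0.05, 1].
    """
    config.validate()
    rng = _rng(config, _TAG_DE)
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)
    effects = dict(config.effect_spec)
    for gid in effects:
        if gid not in known:
            raise SimulationError(f"effect_spec references unknown gene {gid!r}")
    tables = {}
    for alg in algorithms:
        lfc, padj = [], []
        for gid in gene_ids:
            if gid in effects:
                base = effects[gid]
                jitter = 1.0 + rng.normal(0.0, 0.1)
                lfc.append(base * max(jitter, 0.2))  # keep the planted sign
                padj.append(10.0 ** rng.uniform(-8, math.log10(0.049)))
            else:
                lfc.append(rng.normal(0.0, 0.3))
                padj.append(0.05 + rng.uniform(0.0, 0.95))
        tables[alg] = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": lfc, "padj": padj, "algorithm": alg}
        )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": [
                ("up" if effects[g] > 0 else "down") if g in effects else "null"
                for g in gene_ids
            ],
            "log2fc": [effects.get(g, 0.0) for g in gene_ids],
        }
    )
    return tables, truth


def generate_expression(
    config: SimulationConfig,
    genes: list[SimGene],
    zygosity_truth: pd.DataFrame,
    site_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """TPM-like genes x samples matrix realising the planted effects.

    Genes with a planted effect linked to an insertion (``site_gene`` maps
    site key -> gene id) scale each sample's expression by
    2**(log2fc * dosage) where dosage is 1 / 0.5 / 0 for occupied / het /
    empty at the linked site.  Unlinked planted effects fall back to a
    half/half split so the DE contrast remains realisable.
    """
    config.validate()
    rng = _rng(config, _TAG_EXPRESSION)
    samples = config.samples
    effects = dict(config.effect_spec)
    gene_site = {}
    if site_gene:
        for site, gid in site_gene.items():
            gene_site[gid] = site
    dosage = {"hom_occupied": 1.0, "het": 0.5, "hom_empty": 0.0}
    data = {}
    for g in genes:
        base = float(rng.lognormal(mean=3.0, sigma=1.0))
        lfc = effects.get(g.gene_id, 0.0)
        row = []
        for i, s in enumerate(samples):
            d = 0.0
            if lfc != 0.0:
                site = gene_site.get(g.gene_id)
                if site is not None and site in zygosity_truth.index:
                    d = dosage[zygosity_truth.loc[site, s]]
                else:
                    d = 1.0 if i < len(samples) // 2 else 0.0
            val = base * (2.0 ** (lfc * d)) * float(rng.lognormal(0.0, 0.1))
            row.append(val)
        data[g.gene_id] = row
    mat = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    mat.index.name = "gene_id"
    return mat


# ---------------------------------------------------------------------------
# default miniature study and bundle writer
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    true_tracts: list[TractTruth]
    true_zygosity: pd.DataFrame              # site key x sample labels
    true_context: dict[str, str]             # site key -> context label
    true_deg: pd.DataFrame                   # gene_id, label, log2fc
    site_gene: dict[str, str]                # planted site key -> linked gene


@dataclass
class StudyBundle:
    config: SimulationConfig
    genes: list[SimGene]
    genotypes: pd.DataFrame
    signatures: pd.DataFrame
    families: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    truth: GroundTruth


def default_config(seed: int = 0, population: str = "P1") -> SimulationConfig:
    """The default miniature study: 2 chromosomes x 1 Mb, 60 genes,
    12 samples, 5 planted tracts (two of them spanning >= 20 genes),
    40 insertions of which 9 drive planted expression effects."""
    cfg = SimulationConfig(seed=seed, population=population)
    genes = generate_annotation(cfg)
    rng = np.random.default_rng([seed, _TAG_STUDY])
    samples = cfg.samples
    trio_a = (("S01", "S02", "S03"), ("S04", "S05", "S06"))
    trio_b = (("S07", "S08", "S09"), ("S10", "S11", "S12"))
    by_chrom: dict[str, list[SimGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.start)
    chr1, chr2 = cfg.chromosomes[0], cfg.chromosomes[1]
    # large tracts spanning 22 consecutive genes each; boundaries padded
    tracts = []
    large_genes: list[list[SimGene]] = []
    for chrom, (alt, ref) in ((chr1, trio_a), (chr2, trio_b)):
        gs = by_chrom[chrom][1:23]
        large_genes.append(gs)
        tracts.append(
            PlantedTract(chrom, max(1, gs[0].start - 500), gs[-1].end + 500,
                         alt, ref)
        )
    # three small tracts (3 genes each) below the 20-gene threshold
    for chrom, lo, (alt, ref) in (
        (chr1, 24, trio_b), (chr2, 24, trio_a), (chr2, 27, trio_b)
    ):
        gs = by_chrom[chrom][lo:lo + 3]
        start = max(1, gs[0].start - 200)
        end = min(cfg.chromosome_length_bp, gs[-1].end + 200)
        tracts.append(PlantedTract(chrom, start, end, alt, ref))
    fams = family_catalogue(cfg)["family"].tolist()
    insertions: list[PlantedInsertion] = []
    effect_spec: list[tuple[str, float]] = []
    site_gene: dict[str, str] = {}
    # 9 effect insertions segregating with the host tract's trios
    targets = large_genes[0][2:7] + large_genes[1][2:6]
    trios = [trio_a] * 5 + [trio_b] * 4
    for i, (g, (alt, ref)) in enumerate(zip(targets, trios)):
        pos = _insertion_position(g, rng)
        fam = fams[i % len(fams)]
        mode = "reference" if i % 2 == 0 else "nonreference"
        zyg = {s: "het" for s in samples}
        for s in alt:
            zyg[s] = "hom_occupied"
        for s in ref:
            zyg[s] = "hom_empty"
        insertions.append(PlantedInsertion(g.chrom, pos, fam, mode, zyg))
        site_gene[f"{g.chrom}:{pos}:{fam}:{mode}"] = g.gene_id
        effect_spec.append((g.gene_id, 2.0 if i % 2 == 0 else -2.0))
    # one planted DEG with no MITE nearby (inside the first large tract)
    lone = large_genes[0][10]
    effect_spec.append((lone.gene_id, 1.5))
    # background insertions at random loci with random zygosities
    occupied = set()
    for ins in insertions:
        occupied.add((ins.chrom, ins.pos))
    n_background = 40 - len(insertions)
    while n_background > 0:
        chrom = cfg.chromosomes[int(rng.integers(cfg.n_chromosomes))]
        pos = int(rng.integers(1, cfg.chromosome_length_bp + 1))
        if (chrom, pos) in occupied:
            continue
        occupied.add((chrom, pos))
        fam = fams[int(rng.integers(len(fams)))]
        mode = "reference" if rng.random() < 0.5 else "nonreference"
        zyg = {
            s: ZYGOSITY_LABELS[int(rng.choice(3, p=[0.4, 0.2, 0.4]))]
            for s in samples
        }
        insertions.append(PlantedInsertion(chrom, pos, fam, mode, zyg))
        n_background -= 1
    return dataclasses.replace(
        cfg, tract_spec=tracts, insertion_spec=insertions,
        effect_spec=effect_spec,
    )


def _insertion_position(g: SimGene, rng: np.random.Generator) -> int:
    """Pick an insertion point upstream, in an intron, or in the CDS."""
    choices = []
    up = (g.start - 1500, g.start - 100) if g.strand == "+" else (g.end + 100, g.end + 1500)
    choices.append(up)
    if g.introns:
        s, e = g.introns[0]
        if e > s:
            choices.append((s, e))
    s, e = g.cds[0]
    choices.append((s, e))
    lo, hi = choices[int(rng.integers(len(choices)))]
    return int(rng.integers(lo, hi + 1))


def _true_context(ins: PlantedInsertion, genes: list[SimGene]) -> str:
    """Direct membership check with the cds > utr5 > utr3 > intron >
    upstream > downstream precedence; independent of the annotation module."""
    order = ["cds", "utr5", "utr3", "intron", "upstream2kb", "downstream2kb"]
    hits = set()
    for g in genes:
        if g.chrom != ins.chrom:
            continue
        p = ins.pos
        def _in(iv):
            return any(s <= p <= e for s, e in iv)
        if _in(g.cds):
            hits.add("cds")
        if _in(g.utr5):
            hits.add("utr5")
        if _in(g.utr3):
            hits.add("utr3")
        if _in(g.introns):
            hits.add("intron")
        if g.strand == "+":
            up = (g.start - 2000, g.start - 1)
            down = (g.end + 1, g.end + 2000)
        else:
            up = (g.end + 1, g.end + 2000)
            down = (g.start - 2000, g.start - 1)
        if up[0] <= p <= up[1]:
            hits.add("upstream2kb")
        if down[0] <= p <= down[1]:
            hits.add("downstream2kb")
    for cat in order:
        if cat in hits:
            return cat
    return "intergenic"


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Run every generator for one configuration and collect ground truth."""
    genes = generate_annotation(config)
    genotypes, tract_truth = generate_genotypes(config)
    signatures, zyg_truth = generate_signatures(config)
    de_tables, deg_truth = generate_de_tables(config, genes)
    site_gene = {}
    for ins in config.insertion_spec:
        key = f"{ins.chrom}:{ins.pos}:{ins.family}:{ins.mode}"
        host = next(
            (g for g in genes
             if g.chrom == ins.chrom and g.start - 2000 <= ins.pos <= g.end + 2000),
            None,
        )
        if host is not None:
            site_gene.setdefault(key, host.gene_id)
    expression = generate_expression(config, genes, zyg_truth, site_gene)
    truth = GroundTruth(
        true_tracts=tract_truth,
        true_zygosity=zyg_truth,
        true_context={
            f"{i.chrom}:{i.pos}:{i.family}:{i.mode}": _true_context(i, genes)
            for i in config.insertion_spec
        },
        true_deg=deg_truth,
        site_gene=site_gene,
    )
    return StudyBundle(
        config=config, genes=genes, genotypes=genotypes,
        signatures=signatures, families=family_catalogue(config),
        de_tables=de_tables, expression=expression, truth=truth,
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialise a study bundle to plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    paths = {
        "gff": outdir / "annotation.gff3",
        "chrom_lengths": outdir / "chromosomes.tsv",
        "vcf": outdir / "genotypes.vcf",
        "signatures": outdir / "signatures.tsv",
        "families": outdir / "families.tsv",
        "expression": outdir / "expression.tsv",
    }
    paths["gff"].write_text(annotation_to_gff3(bundle.genes, cfg))
    chromosome_table(cfg).to_csv(paths["chrom_lengths"], sep="\t", index=False)
    paths["vcf"].write_text(genotypes_to_vcf(bundle.genotypes, cfg))
    sig = bundle.signatures.copy()
    sig["frequency"] = sig["frequency"].map(lambda v: f"{v:.6f}")
    sig.to_csv(paths["signatures"], sep="\t", index=False)
    bundle.families.to_csv(paths["families"], sep="\t", index=False)
    bundle.expression.to_csv(paths["expression"], sep="\t",
                             float_format="%.6f")
    for alg, table in bundle.de_tables.items():
        p = outdir / f"de_{alg}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.8g")
        paths[f"de_{alg}"] = p
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    bundle.truth.true_zygosity.to_csv(tdir / "zygosity.tsv", sep="\t")
    bundle.truth.true_deg.to_csv(tdir / "deg.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(bundle.truth.true_context.items()), columns=["site", "context"]
    ).to_csv(tdir / "context.tsv", sep="\t", index=False)
    rows = []
    for tt in bundle.truth.true_tracts:
        rows.append([
            tt.tract.chrom, tt.tract.start, tt.tract.end,
            ",".join(tt.tract.alt_trio), ",".join(tt.tract.ref_trio),
            len(tt.site_positions), len(tt.mismatch_positions),
        ])
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "alt_trio", "ref_trio",
                       "n_sites", "n_mismatch_sites"]
    ).to_csv(tdir / "tracts.tsv", sep="\t", index=False)
    paths["truth_dir"] = tdir
    return paths
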