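"""DEG calling from per-algorithm tables and MITE-DEG association.

Differential-expression result tables (one per algorithm) are combined
into consensus DEG calls; DEGs are located in homozygosity bins; insertion
sites whose associated genes are DEGs become association records carrying
a 3+3 occupied/empty sample contrast; and per-gene expression contrasts
are exported as the row-z-scored table underlying presence/absence
heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genic_context import ContextAssignment, GeneModel
from .homozygosity import HomozygosityBin
from .insertions import InsertionSite

logger = logging.getLogger(__name__)

COMBINATION_RULES = ("intersection", "union", "single")


@dataclass
class DEGCall:
    gene_id: str
    log2fc: dict[str, float]
    padj: dict[str, float]
    is_deg: bool
    direction: str | None = None  # "up" | "down" when is_deg


def call_degs(
    de_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    rule: str = "intersection",
) -> list[DEGCall]:
    """Combine per-algorithm DE tables into consensus DEG calls.

    ``intersection`` requires padj < alpha in every table, ``union`` in at
    least one, ``single`` uses the first table only.  Direction is the sign
    of the mean log2fc among the algorithms calling the gene; genes whose
    calling algorithms disagree in sign are excluded and logged.
    """
    if rule not in COMBINATION_RULES:
        raise ValueError(f"unknown combination rule {rule!r}")
    algs = list(de_tables)
    if rule == "single":
        algs = algs[:1]
    universe: list[str] = []
    seen = set()
    for alg in algs:
        for g in de_tables[alg]["gene_id"]:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    lfc = {alg: dict(zip(de_tables[alg]["gene_id"], de_tables[alg]["log2fc"]))
           for alg in algs}
    padj = {alg: dict(zip(de_tables[alg]["gene_id"], de_tables[alg]["padj"]))
            for alg in algs}
    calls = []
    n_ambiguous = 0
    for g in universe:
        g_lfc = {a: lfc[a][g] for a in algs if g in lfc[a]}
        g_p = {a: padj[a][g] for a in algs if g in padj[a]}
        hits = [a for a in algs if g_p.get(a, 1.0) < alpha]
        if rule == "intersection":
            is_deg = len(hits) == len(algs) and all(g in padj[a] for a in algs)
        else:
            is_deg = len(hits) >= 1
        direction = None
        if is_deg:
            signs = {np.sign(g_lfc[a]) for a in hits}
            if len(signs) > 1:
                n_ambiguous += 1
                logger.warning("gene %s: conflicting log2fc signs, excluded", g)
                is_deg = False
            else:
                mean_lfc = float(np.mean([g_lfc[a] for a in hits]))
                direction = "up" if mean_lfc > 0 else "down"
        calls.append(DEGCall(gene_id=g, log2fc=g_lfc, padj=g_p,
                             is_deg=is_deg, direction=direction))
    if n_ambiguous:
        logger.info("%d ambiguous-direction genes excluded", n_ambiguous)
    return calls


def degs_in_bins(
    degs: list[DEGCall], bins: list[HomozygosityBin]
) -> tuple[pd.DataFrame, dict]:
    """Per-bin and global DEG fractions among bin genes (set semantics:
    a gene in several bins counts once globally)."""
    deg_ids = {d.gene_id for d in degs if d.is_deg}
    rows = []
    all_genes: set[str] = set()
    for i, b in enumerate(bins, 1):
        genes = set(b.genes)
        all_genes |= genes
        n_deg = len(genes & deg_ids)
        rows.append({
            "bin_id": f"bin{i:04d}", "chrom": b.chrom, "start": b.start,
            "end": b.end, "n_genes": len(genes), "n_degs": n_deg,
            "fraction": (n_deg / len(genes)) if genes else 0.0,
        })
    n_global_deg = len(all_genes & deg_ids)
    summary = {
        "n_genes": len(all_genes),
        "n_degs": n_global_deg,
        "fraction": (n_global_deg / len(all_genes)) if all_genes else 0.0,
    }
    return pd.DataFrame(rows), summary


@dataclass
class AssociationRecord:
    gene_id: str
    site_key: str
    family: str
    superfamily: str
    context: str
    distance: int  # bp from insertion point to nearest gene-body edge
    deg_direction: str
    insertion_trio: tuple[str, ...]  # hom_occupied at the site
    empty_trio: tuple[str, ...]      # hom_empty at the site
    bin_id: str | None = None
    complete: bool = True


def _distance_to_body(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def _pick_trio(candidates: list[str], preferred: tuple[str, ...]) -> tuple:
    pref = [s for s in sorted(preferred) if s in candidates]
    rest = [s for s in sorted(candidates) if s not in pref]
    chosen = (pref + rest)[:3]
    return tuple(chosen) if len(chosen) == 3 else ()


def associate(
    degs: list[DEGCall],
    assignments: list[ContextAssignment],
    zygosity: pd.DataFrame,
    bins: list[HomozygosityBin],
    sites: list[InsertionSite],
    models: list[GeneModel],
) -> list[AssociationRecord]:
    """One record per (DEG, insertion) pair where the gene is among the
    site's associated genes.

    The occupied/empty contrast reuses the host bin's alt/ref trio samples
    when their zygosity at the site matches; otherwise any 3+3 split of
    matching homozygous samples is taken (bin-trio members preferred,
    lexicographic).  Pairs lacking a valid 3+3 contrast are emitted with
    empty trios and flagged incomplete.
    """
    deg_by_gene = {d.gene_id: d for d in degs if d.is_deg}
    model_by_gene = {m.gene_id: m for m in models}
    site_by_key = {s.key: s for s in sites}
    bin_of_gene: dict[str, tuple[str, HomozygosityBin]] = {}
    for i, b in enumerate(bins, 1):
        for g in b.genes:
            bin_of_gene.setdefault(g, (f"bin{i:04d}", b))
    records = []
    for a in assignments:
        site = site_by_key.get(a.site_key)
        if site is None:
            raise KeyError(f"assignment for unknown site {a.site_key}")
        for gene_id in a.associated_genes:
            deg = deg_by_gene.get(gene_id)
            if deg is None:
                continue
            model = model_by_gene.get(gene_id)
            if model is None:
                raise KeyError(f"gene {gene_id} absent from annotation")
            calls = zygosity.loc[a.site_key]
            occupied = [s for s in calls.index if calls[s] == "hom_occupied"]
            empty = [s for s in calls.index if calls[s] == "hom_empty"]
            bin_id, host_bin = bin_of_gene.get(gene_id, (None, None))
            preferred_occ: tuple[str, ...] = ()
            preferred_emp: tuple[str, ...] = ()
            if host_bin is not None:
                for trio in (host_bin.alt_trio, host_bin.ref_trio):
                    if all(s in occupied for s in trio):
                        preferred_occ = trio
                    elif all(s in empty for s in trio):
                        preferred_emp = trio
            ins_trio = _pick_trio(occupied, preferred_occ)
            emp_trio = _pick_trio(empty, preferred_emp)
            complete = bool(ins_trio and emp_trio)
            records.append(AssociationRecord(
                gene_id=gene_id, site_key=a.site_key, family=site.family,
                superfamily=site.superfamily, context=a.context,
                distance=_distance_to_body(site.pos, model.start, model.end),
                deg_direction=deg.direction or "",
                insertion_trio=ins_trio if complete else (),
                empty_trio=emp_trio if complete else (),
                bin_id=bin_id, complete=complete,
            ))
    return records


def direction_summary(records: list[AssociationRecord]) -> pd.DataFrame:
    """Up/down DEG counts per superfamily and per context; a gene
    associated with several sites of one superfamily counts once."""
    seen = set()
    rows = []
    for r in records:
        key = (r.superfamily, r.gene_id)
        if key in seen:
            continue
        seen.add(key)
        rows.append({"superfamily": r.superfamily, "context": r.context,
                     "direction": r.deg_direction})
    if not rows:
        return pd.DataFrame(columns=["superfamily", "up", "down"])
    df = pd.DataFrame(rows)
    out = (
        df.pivot_table(index="superfamily", columns="direction",
                       aggfunc="size", fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    out.columns.name = None
    return out


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "gene_id": r.gene_id, "site": r.site_key, "family": r.family,
            "superfamily": r.superfamily, "context": r.context,
            "distance": r.distance, "direction": r.deg_direction,
            "insertion_trio": ",".join(r.insertion_trio),
            "empty_trio": ",".join(r.empty_trio),
            "bin_id": r.bin_id or "", "complete": int(r.complete),
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "site", "family", "superfamily", "context", "distance",
        "direction", "insertion_trio", "empty_trio", "bin_id", "complete"])


def expression_report(
    records: list[AssociationRecord],
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format contrast table underlying the presence/absence heatmap.

    One row per (record, sample): expression value and the row z-score
    over the six contrast samples ((x - mean) / population sd).  Rows with
    zero spread get z-scores of 0 and a flag.
    """
    rows = []
    for r in records:
        if not r.complete:
            continue
        samples = list(r.insertion_trio) + list(r.empty_trio)
        values = expression.loc[r.gene_id, samples].to_numpy(dtype=float)
        mean = values.mean()
        sd = values.std()  # population sd over the 6 contrast samples
        zero_sd = sd == 0.0
        if zero_sd:
            logger.warning("gene %s: zero expression spread in contrast",
                           r.gene_id)
        z = np.zeros_like(values) if zero_sd else (values - mean) / sd
        for s, v, zz in zip(samples, values, z):
            rows.append({
                "gene_id": r.gene_id, "site": r.site_key,
                "context": r.context, "direction": r.deg_direction,
                "sample": s,
                "group": "occupied" if s in r.insertion_trio else "empty",
                "expression": float(v), "zscore": float(zz),
                "zero_sd": int(zero_sd),
            })
    return pd.DataFrame(rows, columns=[
        "gene_id", "site", "context", "direction", "sample", "group",
        "expression", "zscore", "zero_sd"])
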