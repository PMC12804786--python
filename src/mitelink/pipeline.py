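"""End-to-end orchestration: files in, stage outputs + run manifest out.

The pipeline is a pure function of its inputs and parameters: identical
input digests and parameters produce byte-identical stage outputs.  Every
stage can also be run standalone through the library API; this module
only chains them and records provenance.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, association, genic_context, homozygosity
from . import insertions as ins_mod
from . import permutation as perm_mod
from .insertions import ZYGOSITY_CODE

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_per_class": 3,
    "max_mismatch": 2,
    "min_genes": 20,
    "het_low": 0.3,
    "het_high": 0.7,
    "alpha": 0.05,
    "deg_rule": "intersection",
    "flank_bp": 2000,
    "n_permutations": 1000,
    "perm_alpha": 0.01,
    "seed": 17,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    vcf: Path
    gff: Path
    chrom_lengths: Path
    signatures: Path
    families: Path
    de_tables: list[Path]
    outdir: Path
    expression: Path | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    def validate(self) -> None:
        p = self.params
        if p["max_mismatch"] < 0:
            raise ConfigError("max_mismatch must be >= 0")
        if p["min_per_class"] < 1:
            raise ConfigError("min_per_class must be >= 1")
        if p["min_genes"] < 0:
            raise ConfigError("min_genes must be >= 0")
        if not (0 < p["alpha"] < 1) or not (0 < p["perm_alpha"] < 1):
            raise ConfigError("alpha values must lie in (0, 1)")
        if p["n_permutations"] < 1:
            raise ConfigError("n_permutations must be >= 1")
        required = [self.vcf, self.gff, self.chrom_lengths, self.signatures,
                    self.families, *self.de_tables]
        if self.expression is not None:
            required.append(self.expression)
        missing = [str(f) for f in required if not Path(f).is_file()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat TOML config with [inputs], [params], [output] tables."""
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    inputs = raw.get("inputs", {})
    base = Path(path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        cfg = PipelineConfig(
            vcf=resolve(inputs["vcf"]),
            gff=resolve(inputs["gff"]),
            chrom_lengths=resolve(inputs["chrom_lengths"]),
            signatures=resolve(inputs["signatures"]),
            families=resolve(inputs["families"]),
            de_tables=[resolve(p) for p in inputs["de_tables"]],
            expression=(resolve(inputs["expression"])
                        if "expression" in inputs else None),
            outdir=resolve(raw.get("output", {}).get("dir", "mitelink_out")),
            params=raw.get("params", {}),
        )
    except KeyError as e:
        raise ConfigError(f"config missing required input {e}") from None
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the map of written output files."""
    config.validate()
    p = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    chrom_df = pd.read_csv(config.chrom_lengths, sep="\t")
    chrom_lengths = dict(zip(chrom_df["chrom"], chrom_df["length"]))

    # --- stage 1: homozygosity bins ------------------------------------
    records = homozygosity.read_vcf(config.vcf)
    logger.info("stage bins: %d genotype records", len(records))
    density = homozygosity.polymorphism_density(records, chrom_lengths)
    models = genic_context.build_gene_models(
        config.gff, chrom_lengths, flank_bp=p["flank_bp"])
    gene_spans = pd.DataFrame(
        [{"gene_id": m.gene_id, "chrom": m.chrom, "start": m.start,
          "end": m.end} for m in models]
    )
    bins = homozygosity.build_bins(
        records, min_per_class=p["min_per_class"],
        max_mismatch=p["max_mismatch"])
    homozygosity.annotate_bins(bins, gene_spans)
    contrasts = homozygosity.select_sample_sets(bins, min_genes=p["min_genes"])
    logger.info("stage bins: %d bins, %d contrast sets", len(bins),
                len(contrasts))
    out["polymorphism_density"] = outdir / "polymorphism_density.tsv"
    _write(density, out["polymorphism_density"])
    out["bins"] = outdir / "bins.tsv"
    _write(homozygosity.bins_to_frame(bins), out["bins"])

    # --- stage 2: insertion matrix --------------------------------------
    catalogue = pd.read_csv(config.families, sep="\t")
    sig_table = ins_mod.read_signatures(config.signatures)
    sites = ins_mod.parse_signatures(sig_table, catalogue)
    samples = sorted(sig_table["sample"].unique())
    logger.info("stage matrix: %d sites, %d samples", len(sites), len(samples))
    freq = ins_mod.frequency_matrix(sites, samples)
    zyg = ins_mod.zygosity_matrix(sites, samples, low=p["het_low"],
                                  high=p["het_high"])
    fam_counts, sup_counts, copies = ins_mod.zygosity_counts(sites, samples)
    out["frequency_matrix"] = outdir / "frequency_matrix.tsv"
    _write(freq, out["frequency_matrix"], index=True)
    out["zygosity_matrix"] = outdir / "zygosity_matrix.tsv"
    _write(zyg.apply(lambda col: col.map(ZYGOSITY_CODE)),
           out["zygosity_matrix"], index=True)
    out["family_counts"] = outdir / "family_counts.tsv"
    _write(fam_counts, out["family_counts"], index=True)
    out["superfamily_counts"] = outdir / "superfamily_counts.tsv"
    _write(sup_counts, out["superfamily_counts"], index=True)
    out["sample_copies"] = outdir / "sample_copies.tsv"
    _write(copies.to_frame(), out["sample_copies"], index=True)

    # --- stage 3: genic context ------------------------------------------
    assignments = genic_context.assign_contexts(sites, models)
    counts = genic_context.context_counts(assignments, sites)
    cum_len = genic_context.cumulative_category_lengths(models, chrom_lengths)
    dens = genic_context.standardized_density(counts, cum_len)
    chrom_dens = genic_context.chromosome_density(sites, chrom_lengths)
    out["context_assignments"] = outdir / "context_assignments.tsv"
    _write(pd.DataFrame(
        [{"site": a.site_key, "context": a.context,
          "genes": ",".join(a.associated_genes)} for a in assignments]
    ), out["context_assignments"])
    out["context_counts"] = outdir / "context_counts.tsv"
    _write(counts, out["context_counts"], index=True)
    out["context_density"] = outdir / "context_density.tsv"
    _write(dens, out["context_density"], index=True)
    out["chromosome_density"] = outdir / "chromosome_density.tsv"
    _write(chrom_dens, out["chromosome_density"])
    genic = counts[list(genic_context.GENIC_CONTEXTS)]
    # drop empty rows/columns so sparse tables stay testable
    genic = genic.loc[genic.sum(axis=1) > 0, genic.sum(axis=0) > 0]
    enrich_json: dict = {"skipped": True}
    if genic.shape[0] >= 2 and genic.shape[1] >= 2:
        enrich = genic_context.chi_squared_enrichment(genic)
        out["enrichment_residuals"] = outdir / "enrichment_residuals.tsv"
        _write(enrich.residuals, out["enrichment_residuals"], index=True)
        out["enrichment_contributions"] = outdir / "enrichment_contributions.tsv"
        _write(enrich.contributions, out["enrichment_contributions"],
               index=True)
        enrich_json = {"chi2": enrich.chi2, "dof": enrich.dof,
                       "p_value": enrich.p_value}
    else:
        logger.warning("enrichment skipped: zero row/column in genic counts")
    out["enrichment_summary"] = outdir / "enrichment_summary.json"
    out["enrichment_summary"].write_text(
        json.dumps(enrich_json, indent=2, sort_keys=True) + "\n")

    # --- stage 4: DEG / MITE association ---------------------------------
    de_tables = {}
    for path in config.de_tables:
        df = pd.read_csv(path, sep="\t")
        alg = str(df["algorithm"].iloc[0]) if "algorithm" in df and len(df) \
            else Path(path).stem
        de_tables[alg] = df
    degs = association.call_degs(de_tables, alpha=p["alpha"],
                                 rule=p["deg_rule"])
    n_deg = sum(d.is_deg for d in degs)
    logger.info("stage assoc: %d DEGs under rule %s", n_deg, p["deg_rule"])
    per_bin, global_summary = association.degs_in_bins(degs, bins)
    out["deg_calls"] = outdir / "deg_calls.tsv"
    _write(pd.DataFrame(
        [{"gene_id": d.gene_id, "is_deg": int(d.is_deg),
          "direction": d.direction or ""} for d in degs]
    ), out["deg_calls"])
    out["degs_in_bins"] = outdir / "degs_in_bins.tsv"
    _write(per_bin, out["degs_in_bins"])
    records_assoc = association.associate(degs, assignments, zyg, bins,
                                          sites, models)
    out["associations"] = outdir / "associations.tsv"
    _write(association.records_to_frame(records_assoc), out["associations"])
    out["direction_summary"] = outdir / "direction_summary.tsv"
    _write(association.direction_summary(records_assoc),
           out["direction_summary"])
    if config.expression is not None:
        expr = pd.read_csv(config.expression, sep="\t", index_col="gene_id")
        report = association.expression_report(records_assoc, expr)
        out["expression_report"] = outdir / "expression_report.tsv"
        _write(report, out["expression_report"])

    # --- stage 5: permutation test ---------------------------------------
    bin_genes: list[str] = []
    seen: set[str] = set()
    for c in contrasts:
        for g in c.bin.genes:
            if g not in seen:
                seen.add(g)
                bin_genes.append(g)
    bin_genes.sort()
    deg_ids = {d.gene_id for d in degs if d.is_deg}
    mite_genes: set[str] = set()
    for a in assignments:
        mite_genes.update(a.associated_genes)
    flags = perm_mod.gene_mite_flags(bin_genes, deg_ids, mite_genes)
    out["gene_flags"] = outdir / "gene_flags.tsv"
    _write(flags, out["gene_flags"])
    perm_json: dict = {"skipped": True}
    if len(bin_genes) > 0 and flags["is_deg"].sum() > 0:
        result = perm_mod.permutation_test(
            flags["is_deg"].to_numpy(), flags["has_mite"].to_numpy(),
            n_permutations=p["n_permutations"], seed=p["seed"],
            alpha=p["perm_alpha"])
        logger.info("stage permtest: P_obs=%d p=%.4g", result.p_obs,
                    result.p_value)
        perm_json = result.to_dict()
        out["permutation_pi"] = outdir / "permutation_pi.tsv"
        _write(pd.DataFrame({"P_i": result.p_i}), out["permutation_pi"])
    else:
        logger.warning("permutation skipped: no DEGs in the bin-gene universe")
    out["permutation"] = outdir / "permutation.json"
    out["permutation"].write_text(
        json.dumps(perm_json, indent=2, sort_keys=True) + "\n")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "tool": "mitelink",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {
            "vcf": {"path": str(config.vcf), "sha256": _sha256(config.vcf)},
            "gff": {"path": str(config.gff), "sha256": _sha256(config.gff)},
            "chrom_lengths": {"path": str(config.chrom_lengths),
                              "sha256": _sha256(config.chrom_lengths)},
            "signatures": {"path": str(config.signatures),
                           "sha256": _sha256(config.signatures)},
            "families": {"path": str(config.families),
                         "sha256": _sha256(config.families)},
            "de_tables": [{"path": str(t), "sha256": _sha256(t)}
                          for t in config.de_tables],
            "expression": ({"path": str(config.expression),
                            "sha256": _sha256(config.expression)}
                           if config.expression else None),
        },
        "params": config.params,
    }
    out["manifest"] = outdir / "manifest.json"
    out["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def make_report(outdir: str | Path, report_dir: str | Path | None = None) -> dict:
    """Figure-style views over the pipeline TSVs (plots are views only;
    every plotted number already exists in a TSV).  Missing stage outputs
    skip their section with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    report_dir = Path(report_dir) if report_dir else outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    sections: dict[str, str] = {}

    contrib = outdir / "enrichment_contributions.tsv"
    resid = outdir / "enrichment_residuals.tsv"
    if contrib.is_file() and resid.is_file():
        c = pd.read_csv(contrib, sep="\t", index_col=0)
        r = pd.read_csv(resid, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(7, 4))
        for i, sup in enumerate(c.index):
            for j, ctx in enumerate(c.columns):
                ax.scatter(j, i, s=40 * c.loc[sup, ctx] + 5,
                           c="tab:red" if r.loc[sup, ctx] > 0 else "tab:blue")
        ax.set_xticks(range(len(c.columns)), c.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(c.index)), c.index)
        ax.set_title("chi-squared contributions (size) and residual sign")
        fig.tight_layout()
        fig.savefig(report_dir / "context_bubble.png", dpi=100)
        plt.close(fig)
        sections["context_bubble"] = "ok"
    else:
        logger.warning("report: enrichment tables missing, bubble skipped")
        sections["context_bubble"] = "skipped"

    dens = outdir / "context_density.tsv"
    if dens.is_file():
        d = pd.read_csv(dens, sep="\t", index_col=0)
        ax = d.T.plot.bar(figsize=(7, 4))
        ax.set_ylabel("insertions per 100 kb of category")
        ax.figure.tight_layout()
        ax.figure.savefig(report_dir / "context_density.png", dpi=100)
        plt.close(ax.figure)
        sections["context_density"] = "ok"
    else:
        logger.warning("report: density table missing, bars skipped")
        sections["context_density"] = "skipped"

    perm_pi = outdir / "permutation_pi.tsv"
    perm_json = outdir / "permutation.json"
    if perm_pi.is_file() and perm_json.is_file():
        pi = pd.read_csv(perm_pi, sep="\t")["P_i"]
        meta = json.loads(perm_json.read_text())
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(pi, bins=range(int(pi.max()) + 3), color="grey")
        if "P_obs" in meta:
            ax.axvline(meta["P_obs"], color="red", label="observed")
            ax.legend()
        ax.set_xlabel("permuted MITE/DEG association count")
        fig.tight_layout()
        fig.savefig(report_dir / "permutation_hist.png", dpi=100)
        plt.close(fig)
        sections["permutation_hist"] = "ok"
    else:
        logger.warning("report: permutation outputs missing, histogram skipped")
        sections["permutation_hist"] = "skipped"

    expr = outdir / "expression_report.tsv"
    if expr.is_file():
        e = pd.read_csv(expr, sep="\t")
        if len(e):
            wide = e.pivot_table(index=["gene_id", "site"], columns="sample",
                                 values="zscore")
            fig, ax = plt.subplots(
                figsize=(6, max(2, 0.3 * len(wide))))
            im = ax.imshow(wide.to_numpy(), aspect="auto", cmap="RdBu_r")
            ax.set_yticks(range(len(wide)),
                          [f"{g} ({s})" for g, s in wide.index], fontsize=6)
            ax.set_xticks(range(len(wide.columns)), wide.columns, rotation=90)
            fig.colorbar(im, label="row z-score")
            fig.tight_layout()
            fig.savefig(report_dir / "expression_heatmap.png", dpi=100)
            plt.close(fig)
        sections["expression_heatmap"] = "ok"
    else:
        logger.warning("report: expression report missing, heatmap skipped")
        sections["expression_heatmap"] = "skipped"

    (report_dir / "sections.json").write_text(
        json.dumps(sections, indent=2, sort_keys=True) + "\n")
    return sections
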