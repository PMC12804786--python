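"""Gene-model building, point-context assignment, enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from oracles import oracle_context, textbook_chi2

from mitelink import genic_context as gc
from mitelink.insertions import InsertionSite


def write_gff(tmp_path, body, lengths={"chr1": 100_000}):
    lines = ["##gff-version 3"]
    for c, ln in lengths.items():
        lines.append(f"##sequence-region {c} 1 {ln}")
    path = tmp_path / "g.gff3"
    path.write_text("\n".join(lines + body) + "\n")
    return path


def feature(chrom, ftype, s, e, strand, attrs):
    return f"{chrom}\tt\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"


class TestGeneModels:
    def test_single_exon_full_cds_has_no_introns_or_utrs(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 5000, 6000, "+", "ID=g1"),
            feature("chr1", "mRNA", 5000, 6000, "+", "ID=t1;Parent=g1"),
            feature("chr1", "exon", 5000, 6000, "+", "ID=e1;Parent=t1"),
            feature("chr1", "CDS", 5000, 6000, "+", "ID=c1;Parent=t1"),
        ])
        (m,) = gc.build_gene_models(gff)
        assert m.introns == [] and m.utr5 == [] and m.utr3 == []
        assert m.cds == [(5000, 6000)]

    def test_two_exon_gene_has_gap_intron(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 5000, 8000, "+", "ID=g1"),
            feature("chr1", "mRNA", 5000, 8000, "+", "ID=t1;Parent=g1"),
            feature("chr1", "exon", 5000, 6000, "+", "ID=e1;Parent=t1"),
            feature("chr1", "exon", 7000, 8000, "+", "ID=e2;Parent=t1"),
            feature("chr1", "CDS", 5000, 6000, "+", "ID=c1;Parent=t1"),
            feature("chr1", "CDS", 7000, 8000, "+", "ID=c2;Parent=t1"),
        ])
        (m,) = gc.build_gene_models(gff)
        assert m.introns == [(6001, 6999)]

    def test_minus_strand_upstream_lies_past_span_end(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 5000, 6000, "-", "ID=g1"),
            feature("chr1", "mRNA", 5000, 6000, "-", "ID=t1;Parent=g1"),
            feature("chr1", "exon", 5000, 6000, "-", "ID=e1;Parent=t1"),
            feature("chr1", "CDS", 5000, 6000, "-", "ID=c1;Parent=t1"),
        ])
        (m,) = gc.build_gene_models(gff)
        assert m.upstream2kb == (6001, 8000)
        assert m.downstream2kb == (3000, 4999)

    def test_flanks_clipped_at_chromosome_ends(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 500, 99_800, "+", "ID=g1"),
            feature("chr1", "mRNA", 500, 99_800, "+", "ID=t1;Parent=g1"),
            feature("chr1", "exon", 500, 99_800, "+", "ID=e1;Parent=t1"),
            feature("chr1", "CDS", 500, 99_800, "+", "ID=c1;Parent=t1"),
        ])
        (m,) = gc.build_gene_models(gff)
        assert m.upstream2kb == (1, 499)
        assert m.downstream2kb == (99_801, 100_000)

    def test_utrs_derived_from_exon_minus_cds_when_absent(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 5000, 6000, "+", "ID=g1"),
            feature("chr1", "mRNA", 5000, 6000, "+", "ID=t1;Parent=g1"),
            feature("chr1", "exon", 5000, 6000, "+", "ID=e1;Parent=t1"),
            feature("chr1", "CDS", 5200, 5800, "+", "ID=c1;Parent=t1"),
        ])
        (m,) = gc.build_gene_models(gff)
        assert m.utr5 == [(5000, 5199)]
        assert m.utr3 == [(5801, 6000)]

    def test_cds_outside_mrna_span_rejected(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 5000, 6000, "+", "ID=g1"),
            feature("chr1", "mRNA", 5000, 6000, "+", "ID=t1;Parent=g1"),
            feature("chr1", "exon", 5000, 6000, "+", "ID=e1;Parent=t1"),
            feature("chr1", "CDS", 4000, 6000, "+", "ID=c1;Parent=t1"),
        ])
        with pytest.raises(gc.AnnotationError):
            gc.build_gene_models(gff)


def site(chrom, pos, family="fam01", mode="reference", sup="hAT"):
    return InsertionSite(chrom=chrom, pos=pos, family=family, mode=mode,
                         superfamily=sup)


class TestAssignContext:
    def test_point_in_cds(self, gene_models, bundle):
        m = gene_models[0]
        idx = gc.ContextIndex(gene_models)
        a = idx.assign(m.chrom, m.cds[0][0], "k")
        assert a.context == "cds"
        assert m.gene_id in a.associated_genes

    def test_strand_aware_flanks(self, tmp_path):
        gff = write_gff(tmp_path, [
            feature("chr1", "gene", 50_000, 52_000, "+", "ID=plus"),
            feature("chr1", "mRNA", 50_000, 52_000, "+", "ID=tp;Parent=plus"),
            feature("chr1", "exon", 50_000, 52_000, "+", "ID=ep;Parent=tp"),
            feature("chr1", "CDS", 50_000, 52_000, "+", "ID=cp;Parent=tp"),
            feature("chr2", "gene", 50_000, 52_000, "-", "ID=minus"),
            feature("chr2", "mRNA", 50_000, 52_000, "-", "ID=tm;Parent=minus"),
            feature("chr2", "exon", 50_000, 52_000, "-", "ID=em;Parent=tm"),
            feature("chr2", "CDS", 50_000, 52_000, "-", "ID=cm;Parent=tm"),
        ], lengths={"chr1": 100_000, "chr2": 100_000})
        models = gc.build_gene_models(gff)
        idx = gc.ContextIndex(models)
        assert idx.assign("chr1", 49_500, "a").context == "upstream2kb"
        assert idx.assign("chr2", 49_500, "b").context == "downstream2kb"

    def test_flank_boundary_at_exactly_2kb(self, gene_models):
        plus = next(m for m in gene_models if m.strand == "+"
                    and m.start > 3000)
        idx = gc.ContextIndex(gene_models)
        at = idx.assign(plus.chrom, plus.start - 2000, "a")
        assert at.context != "intergenic"
        assert plus.gene_id in at.associated_genes

    def test_unknown_chromosome_is_intergenic_with_warning(self, gene_models,
                                                           caplog):
        idx = gc.ContextIndex(gene_models)
        with caplog.at_level("WARNING"):
            a = idx.assign("chrZ", 5, "x")
        assert a.context == "intergenic" and a.associated_genes == ()

    def test_agreement_with_bruteforce_membership_oracle(self, gene_models,
                                                         bundle):
        rng = np.random.default_rng(123)
        idx = gc.ContextIndex(gene_models)
        lengths = bundle.config.chromosome_lengths
        for _ in range(2000):
            chrom = bundle.config.chromosomes[int(rng.integers(2))]
            pos = int(rng.integers(1, lengths[chrom] + 1))
            got = idx.assign(chrom, pos, "k")
            exp_ctx, exp_genes = oracle_context(gene_models, chrom, pos)
            assert got.context == exp_ctx, (chrom, pos)
            if got.context != "intergenic":
                assert got.associated_genes == exp_genes

    def test_simulator_ground_truth_recovered(self, gene_models, bundle):
        from mitelink.insertions import parse_signatures

        sites = parse_signatures(bundle.signatures, bundle.families)
        assignments = gc.assign_contexts(sites, gene_models)
        for a in assignments:
            assert a.context == bundle.truth.true_context[a.site_key], a.site_key


class TestCountsAndDensity:
    def make_counts(self, gene_models, bundle):
        from mitelink.insertions import parse_signatures

        sites = parse_signatures(bundle.signatures, bundle.families)
        assignments = gc.assign_contexts(sites, gene_models)
        return gc.context_counts(assignments, sites), sites

    def test_counts_conserved(self, gene_models, bundle):
        counts, sites = self.make_counts(gene_models, bundle)
        assert counts.to_numpy().sum() == len(sites)

    def test_unknown_family_listed_in_error(self, gene_models, bundle):
        from mitelink.insertions import parse_signatures

        sites = parse_signatures(bundle.signatures, bundle.families)
        assignments = gc.assign_contexts(sites, gene_models)
        ghost = gc.ContextAssignment("chr9:1:famXX:reference", "cds", ("g",))
        with pytest.raises(ValueError, match="famXX"):
            gc.context_counts(assignments + [ghost], sites)

    def test_density_arithmetic_and_scaling(self):
        counts = pd.DataFrame({"cds": [50], "intron": [0]}, index=["hAT"])
        lengths = {"cds": 5_000_000, "intron": 1_000_000}
        d = gc.standardized_density(counts, lengths, per=100_000)
        assert d.loc["hAT", "cds"] == 1.0
        assert d.loc["hAT", "intron"] == 0.0
        halved = gc.standardized_density(
            counts, {k: 2 * v for k, v in lengths.items()}, per=100_000)
        assert halved.loc["hAT", "cds"] == 0.5

    def test_zero_length_with_counts_is_an_error(self):
        counts = pd.DataFrame({"cds": [5]}, index=["hAT"])
        with pytest.raises(ValueError):
            gc.standardized_density(counts, {"cds": 0})

    def test_density_invariant_to_interval_splitting(self, gene_models):
        whole = gc.cumulative_category_lengths(gene_models)
        # split every CDS interval in two via artificial models
        import copy

        split = copy.deepcopy(gene_models)
        for m in split:
            new = []
            for s, e in m.cds:
                if e > s:
                    mid = (s + e) // 2
                    new += [(s, mid), (mid + 1, e)]
                else:
                    new.append((s, e))
            m.cds = new
        assert gc.cumulative_category_lengths(split)["cds"] == whole["cds"]

    def test_chromosome_density(self, bundle):
        sites = [site("chr1", 10)] * 9
        d = gc.chromosome_density(sites, {"chr1": 100_000}, per=100_000)
        assert d.set_index("chrom").loc["chr1", "rate"] == 9.0
        empty = gc.chromosome_density([], {"chr1": 100_000})
        assert (empty["n_sites"] == 0).all()
        with pytest.raises(ValueError, match="chrX"):
            gc.chromosome_density([site("chrX", 1)], {"chr1": 100})


class TestChiSquared:
    def test_uniform_table_has_zero_statistic(self):
        t = pd.DataFrame([[10, 10], [10, 10]])
        e = gc.chi_squared_enrichment(t)
        assert e.chi2 == 0.0
        assert (e.residuals.to_numpy() == 0).all()

    def test_hand_computed_2x2(self):
        e = gc.chi_squared_enrichment(pd.DataFrame([[20, 10], [10, 20]]))
        assert e.chi2 == pytest.approx(6.6667, abs=5e-5)
        assert e.dof == 1
        assert (e.expected.to_numpy() == 15).all()

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            obs = rng.integers(1, 60, size=(rng.integers(2, 6),
                                            rng.integers(2, 7)))
            e = gc.chi_squared_enrichment(pd.DataFrame(obs))
            chi2, dof = textbook_chi2(obs)
            assert e.chi2 == pytest.approx(chi2, rel=1e-9)
            assert e.dof == dof
            assert e.contributions.to_numpy().sum() == \
                pytest.approx(e.chi2, rel=1e-9, abs=1e-12)

    def test_row_permutation_permutes_residuals(self):
        obs = pd.DataFrame([[20, 10], [10, 20], [5, 30]],
                           index=["a", "b", "c"])
        e1 = gc.chi_squared_enrichment(obs)
        e2 = gc.chi_squared_enrichment(obs.loc[["c", "a", "b"]])
        assert np.allclose(e1.residuals.loc[["c", "a", "b"]].to_numpy(),
                           e2.residuals.to_numpy())

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gc.chi_squared_enrichment(pd.DataFrame([[0, 0], [5, 5]]))
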