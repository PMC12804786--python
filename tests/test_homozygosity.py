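"""Bin detection against construction examples and an exhaustive oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from oracles import bins_as_tuples, oracle_bins

from conftest import random_records
from mitelink import simulate
from mitelink.homozygosity import (
    GenotypeRecord,
    SortOrderError,
    annotate_bins,
    bins_from_frame,
    bins_to_frame,
    build_bins,
    polymorphism_density,
    qualify_record,
    read_vcf,
    records_from_frame,
    select_sample_sets,
)

S = [f"S{i:02d}" for i in range(1, 13)]


def rec(pos, alt=(), ref=(), het=(), missing=(), chrom="chr1"):
    calls = {}
    for group, code in ((alt, "1/1"), (ref, "0/0"), (het, "0/1"),
                        (missing, "./.")):
        for s in group:
            calls[s] = code
    return GenotypeRecord(chrom, pos, calls)


class TestQualify:
    def test_four_alt_three_ref_qualifies_with_full_sets(self):
        r = rec(1, alt=S[:4], ref=S[4:7], het=S[7:12])
        ok, alt, ref = qualify_record(r)
        assert ok and len(alt) == 4 and len(ref) == 3

    def test_two_alt_homozygotes_do_not_qualify(self):
        r = rec(1, alt=S[:2], ref=S[2:12])
        assert not qualify_record(r)[0]

    def test_missing_calls_join_neither_class(self):
        r = rec(1, alt=S[:3], missing=S[3:6], ref=S[6:12])
        ok, alt, ref = qualify_record(r)
        assert ok
        assert alt == frozenset(S[:3])
        assert not (alt | ref) & set(S[3:6])


def run_records(n, start=100, step=100, alt=None, ref=None):
    alt = alt or S[:3]
    ref = ref or S[3:6]
    return [rec(start + i * step, alt=alt, ref=ref, het=S[6:12])
            for i in range(n)]


class TestBuildBins:
    def test_clean_run_is_one_bin(self):
        bins = build_bins(run_records(10))
        assert len(bins) == 1
        b = bins[0]
        assert (b.start, b.end) == (100, 1000)
        assert b.n_records == 10 and b.n_mismatches == 0
        assert b.alt_trio == tuple(S[:3]) and b.ref_trio == tuple(S[3:6])

    @pytest.mark.parametrize("n_bad,n_bins", [(1, 1), (2, 1), (3, 2)])
    def test_mismatch_budget_merges_up_to_two(self, n_bad, n_bins):
        recs = run_records(5)
        bad = [rec(600 + i * 10, het=S) for i in range(n_bad)]
        tail = [rec(700 + i * 100, alt=S[:3], ref=S[3:6], het=S[6:12])
                for i in range(5)]
        bins = build_bins(recs + bad + tail)
        assert len(bins) == n_bins
        if n_bins == 1:
            assert bins[0].n_mismatches == n_bad
            assert bins[0].end == tail[-1].pos
        else:
            assert bins[0].n_mismatches == 0
            assert bins[0].end == recs[-1].pos  # trailing skips excluded

    def test_trio_breaking_record_counts_as_mismatch(self):
        # middle record qualifies but with disjoint sample sets
        recs = run_records(3) + [rec(350, alt=S[6:9], ref=S[9:12])] \
            + run_records(3, start=400)
        bins = build_bins(recs)
        assert len(bins) == 1
        assert bins[0].n_mismatches == 1

    def test_unsorted_input_names_position(self):
        recs = [rec(100), rec(50)]
        with pytest.raises(SortOrderError, match="50"):
            build_bins(recs)

    def test_oracle_equivalence_on_random_streams(self):
        rng = np.random.default_rng(2024)
        for trial in range(60):
            recs = random_records(rng, n_records=int(rng.integers(5, 31)))
            got = bins_as_tuples(build_bins(recs))
            expected = oracle_bins(recs)
            assert got == expected, f"trial {trial}"

    @pytest.mark.parametrize("mm", [0, 1, 2, 3])
    def test_monotonicity_in_mismatch_budget(self, mm):
        # raising the budget never increases bin count nor shortens bins
        rng = np.random.default_rng(77)
        for _ in range(20):
            recs = random_records(rng, n_records=25)
            lo = build_bins(recs, max_mismatch=mm)
            hi = build_bins(recs, max_mismatch=mm + 1)
            assert len(hi) <= len(lo)
            for b in lo:
                cover = [h for h in hi
                         if h.start <= b.start and h.end >= b.end]
                assert cover, "bin lost when budget raised"

    def test_roundtrip_through_frame_is_lossless(self):
        bins = build_bins(run_records(10))
        again = bins_from_frame(bins_to_frame(bins))
        assert bins_as_tuples(bins) == bins_as_tuples(again)


class TestPlantedTractRecovery:
    def make_bundle_records(self, n_mismatch=0, consecutive=False, seed=5):
        tract = simulate.PlantedTract(
            "chr1", 300_000, 700_000, ("S01", "S02", "S03"),
            ("S04", "S05", "S06"), n_mismatch_sites=n_mismatch,
            consecutive_mismatches=consecutive)
        cfg = simulate.SimulationConfig(
            n_chromosomes=1, n_genes=0, seed=seed, tract_spec=[tract])
        df, truth = simulate.generate_genotypes(cfg)
        return records_from_frame(df, cfg.samples), truth[0]

    def find_covering(self, bins, truth):
        return [b for b in bins
                if b.chrom == truth.tract.chrom
                and b.start <= truth.site_positions[0]
                and b.end >= truth.site_positions[-1]]

    def test_noise_free_tract_detected_exactly(self):
        recs, truth = self.make_bundle_records()
        bins = build_bins(recs)
        cover = self.find_covering(bins, truth)
        assert len(cover) == 1
        b = cover[0]
        assert b.alt_trio == truth.tract.alt_trio
        assert b.ref_trio == truth.tract.ref_trio
        # every inside-tract record supports the bin
        assert b.start == truth.site_positions[0]
        assert b.end == truth.site_positions[-1]

    def test_two_injected_mismatches_keep_single_bin(self):
        recs, truth = self.make_bundle_records(n_mismatch=2, consecutive=True)
        bins = build_bins(recs, max_mismatch=2)
        cover = self.find_covering(bins, truth)
        assert len(cover) == 1
        assert cover[0].n_mismatches == 2

    def test_three_consecutive_mismatches_split_the_tract(self):
        recs, truth = self.make_bundle_records(n_mismatch=3, consecutive=True)
        bins = build_bins(recs, max_mismatch=2)
        assert not self.find_covering(bins, truth)
        halves = [b for b in bins
                  if truth.tract.start <= b.start <= truth.tract.end
                  and b.n_records > 10]
        assert len(halves) == 2


class TestAnnotateAndSelect:
    def test_gene_intersection_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "chrom": "chr1",
            "start": (starts := np.sort(rng.integers(1, 90_000, size=200))),
            "end": starts + rng.integers(10, 3000, size=200),
        })
        bins = build_bins(run_records(50, start=10_000, step=1000))
        annotate_bins(bins, genes)
        b = bins[0]
        expected = sorted(
            row.gene_id for row in genes.itertuples()
            if row.start <= b.end and row.end >= b.start)
        assert b.genes == expected

    def test_boundary_overlap_counts(self):
        bins = build_bins(run_records(10))  # span 100..1000
        genes = pd.DataFrame({
            "gene_id": ["touch", "miss"], "chrom": ["chr1", "chr1"],
            "start": [1000, 1001], "end": [1500, 1500]})
        annotate_bins(bins, genes)
        assert bins[0].genes == ["touch"]

    def test_unknown_chromosome_yields_zero_genes(self):
        bins = build_bins(run_records(5))
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chrX"],
                              "start": [1], "end": [10]})
        annotate_bins(bins, genes)
        assert bins[0].n_genes == 0

    @pytest.mark.parametrize("n_genes,selected", [(19, 0), (20, 1), (25, 1)])
    def test_min_genes_threshold_is_inclusive(self, n_genes, selected):
        bins = build_bins(run_records(5))
        bins[0].genes = [f"g{i}" for i in range(n_genes)]
        sets = select_sample_sets(bins, min_genes=20)
        assert len(sets) == selected
        if sets:
            assert sets[0].alt_trio == tuple(S[:3])

    def test_empty_bins_give_empty_selection(self):
        assert select_sample_sets([], min_genes=20) == []


class TestDensityAndIO:
    def test_density_arithmetic(self):
        recs = [rec(i + 1) for i in range(1000)]
        df = polymorphism_density(recs, {"chr1": 100_000})
        assert df.set_index("chrom").loc["chr1", "density_per_kb"] == 10.0

    def test_no_records_zero_density(self):
        df = polymorphism_density([], {"chr1": 100_000, "chr2": 50_000})
        assert (df["density_per_kb"] == 0).all()

    def test_counts_conserved_across_chromosomes(self):
        recs = [rec(i + 1) for i in range(10)] + \
            [rec(i + 1, chrom="chr2") for i in range(5)]
        df = polymorphism_density(recs, {"chr1": 1000, "chr2": 1000})
        per = df[df.chrom != "genome"]["n_sites"].sum()
        assert per == df[df.chrom == "genome"]["n_sites"].iloc[0] == 15

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrX"):
            polymorphism_density([rec(1, chrom="chrX")], {"chr1": 1000})

    def test_vcf_reader_matches_simulated_frame(self, bundle, bundle_dir):
        records = read_vcf(bundle_dir["vcf"])
        assert len(records) == len(bundle.genotypes)
        direct = records_from_frame(bundle.genotypes, bundle.config.samples)
        assert records[0].calls == direct[0].calls
        assert records[-1].calls == direct[-1].calls
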