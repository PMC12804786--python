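import numpy as np
import pytest

from mitelink import homozygosity, simulate


@pytest.fixture(scope="session")
def bundle():
    """Noise-free default miniature study (fixed seed)."""
    cfg = simulate.default_config(seed=11)
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths = simulate.write_bundle(bundle, out)
    return paths


@pytest.fixture(scope="session")
def gene_models(bundle_dir, bundle):
    from mitelink import genic_context

    return genic_context.build_gene_models(
        bundle_dir["gff"], bundle.config.chromosome_lengths)


def random_records(rng: np.random.Generator, n_records: int = 30,
                   n_samples: int = 8, chrom: str = "chrT"):
    """Random genotype streams tilted toward homozygous calls so that
    qualifying runs and partial trio consistency actually occur."""
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    codes = np.array(["0/0", "0/1", "1/1", "./."])
    pos = np.sort(rng.choice(100_000, size=n_records, replace=False)) + 1
    records = []
    for p in pos:
        draw = codes[rng.choice(4, size=n_samples, p=[0.35, 0.2, 0.35, 0.1])]
        records.append(homozygosity.GenotypeRecord(
            chrom, int(p), dict(zip(samples, draw))))
    return records
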