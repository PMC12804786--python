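"""Run the whole pipeline on a synthetic bundle and render the report.

Equivalent to the CLI:  mitelink simulate --seed 1 --out bundle/
followed by  mitelink run run.toml  and  mitelink report out/.
"""

import json
import tempfile
from pathlib import Path

from mitelink import pipeline as pipe
from mitelink import simulate

with tempfile.TemporaryDirectory() as tmp:
    cfg = simulate.default_config(seed=1)
    bundle = simulate.simulate_study(cfg)
    paths = simulate.write_bundle(bundle, Path(tmp) / "bundle")

    pcfg = pipe.PipelineConfig(
        vcf=paths["vcf"], gff=paths["gff"],
        chrom_lengths=paths["chrom_lengths"],
        signatures=paths["signatures"], families=paths["families"],
        de_tables=[paths["de_alg1"], paths["de_alg2"], paths["de_alg3"]],
        expression=paths["expression"],
        outdir=Path(tmp) / "out", params={"seed": 17})
    outputs = pipe.run_pipeline(pcfg)

    print("stage outputs:")
    for name, path in sorted(outputs.items()):
        print(f"  {name}: {path.name}")
    perm = json.loads(outputs["permutation"].read_text())
    print(f"\nP_obs = {perm['P_obs']}, p = {perm['p']:.4g} over "
          f"N = {perm['N']} permutations")

    sections = pipe.make_report(pcfg.outdir)
    print(f"report sections: {sections}")
# Every plotted number is first written as a TSV; the PNGs under
# out/report are views over those tables.
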