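#!/usr/bin/env python
"""Generate the synthetic study dataset.

Builds the 200-gene toy genome (20 divergent promoter pairs, ~15% of genes
induced >= 5x under treatment), simulates the full sample grid — input,
mock ChIP, factor ChIP and RNAPII Ser5P-style ChIP under control and
treatment conditions at 2e5 fragments each — and writes the annotation,
transcription-rate table and fragment BEDs under results/dataset/.

Run:  python analysis/01_simulate_dataset.py [seed]
"""

import sys
import time

import chipbias as cb
from chipbias import io
from chipbias.pipeline import simulate_samples

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    t0 = time.time()
    out = io.ensure_dir("results/dataset")
    genome = cb.build_toy_genome(n_genes=200, n_divergent_pairs=20, seed=SEED)
    cfg = cb.SimConfig(seed=SEED, n_fragments=200_000)
    cfg.to_yaml(out / "sim_config.yaml")
    io.write_gff3(genome, out / "annotation.gff3")
    io.write_bed12(genome, out / "annotation.bed12")
    io.write_tr_table(genome, out / "tr_table.tsv")
    samples = simulate_samples(genome, cfg)
    for (kind, cond), fs in samples.items():
        io.write_bed(fs, out / f"{kind}_{cond}.bed")
    print(
        f"wrote {len(samples)} samples x {cfg.n_fragments} fragments, "
        f"{len(genome.genes)} genes on {len(genome.chromosomes)} chromosomes "
        f"({sum(l for _, l in genome.chromosomes)/1e3:.0f} kb) "
        f"to {out} in {time.time()-t0:.1f}s"
    )
    print(f"induced (Up) genes: {len(genome.up_genes())}")


if __name__ == "__main__":
    main()
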