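#!/usr/bin/env python
"""Input- vs mock-corrected differential binding and the quadrant overlay.

Runs the four-pair design — factor ChIP under control and treatment, each
peak-called against the matching input and mock controls at low (q=2) and
high (q=20) stringency, followed by MA normalization between conditions
and DBT calling at q=5 — and then overlays the gene-body DBTs on the
(delta RNAPII occupancy, delta expression) plane.

Expected outcome: the mock branch yields fewer DBTs and a lower gene-body
percentage at both stringencies, and the gene-body DBTs sit almost
entirely in the upper-right quadrant — apparent 'binding' that simply
tracks transcriptional induction.

Run:  python analysis/06_differential_binding.py [seed]
"""

import sys

import numpy as np
import pandas as pd

import chipbias as cb
from chipbias import io
from chipbias.genome import CONTROL, TREATMENT
from chipbias.pipeline import simulate_samples

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    out = io.ensure_dir("results/differential_binding")
    genome = cb.build_toy_genome(200, 20, seed=SEED)
    sizes, genes = genome.chrom_sizes, genome.genes_frame()
    cfg = cb.SimConfig(seed=SEED, n_fragments=100_000)
    samples = simulate_samples(genome, cfg)
    summary, details = cb.four_pair_comparison(
        {c: samples[("tf_chip", c)] for c in (CONTROL, TREATMENT)},
        {c: samples[("input", c)] for c in (CONTROL, TREATMENT)},
        {c: samples[("mock", c)] for c in (CONTROL, TREATMENT)},
        genes,
        sizes,
    )
    io.write_table(summary.round(2), out / "four_pair_summary.tsv")
    for (kind, label), table in details.items():
        io.write_table(table.round(4), out / f"dbts_{kind}_{label}.tsv")
    print(summary.round(1).to_string(index=False))

    body_genes = (
        details[("input", "low")]
        .query("orf_overlap == 'gene_body'")["gene_id"]
        .unique()
        .tolist()
    )
    occ = {
        cond: cb.gene_body_occupancy(
            cb.count_midpoints(samples[("rnapii_chip", cond)], sizes), genes
        ).set_index("gene_id")["occupancy"]
        for cond in (CONTROL, TREATMENT)
    }
    trf = genome.tr_frame().pivot(index="gene_id", columns="condition", values="tr")
    rng = np.random.default_rng(SEED)
    delta_expr = pd.Series(
        np.log2(trf[TREATMENT] / trf[CONTROL]) + rng.normal(0, 0.1, len(trf)),
        index=trf.index,
    )
    table, frac, dropped = cb.quadrant_overlay(
        body_genes, occ[TREATMENT] - occ[CONTROL], delta_expr
    )
    io.write_table(table.round(4), out / "quadrant_overlay.tsv")
    print(f"\n{len(table)} gene-body DBT genes (input branch, low stringency): "
          f"{100*frac:.0f}% in the upper-right quadrant ({dropped} dropped)")
    print(f"-> uncorrected DBTs misleadingly suggest the factor activates "
          f"induced genes; tables in {out}")


if __name__ == "__main__":
    main()
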