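#!/usr/bin/env python
"""Directional signal at divergent promoters.

When an activator is recruited to a shared bidirectional promoter upon
induction, the simulated binding signal develops an exponential tail into
the induced partner's gene body. The asymmetry score per pair — (AUC over
the first kb of the Up gene − AUC toward the partner) / sum — is strongly
positive under treatment and indistinguishable from zero under control,
so the skew identifies which of the two divergent genes is the real
target.

Run:  python analysis/04_divergent_asymmetry.py [seed]
"""

import sys

import pandas as pd

import chipbias as cb
from chipbias import io
from chipbias.genome import CONTROL, TREATMENT

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    out = io.ensure_dir("results/asymmetry")
    genome = cb.build_toy_genome(200, 20, seed=SEED)
    sizes = genome.chrom_sizes
    cfg = cb.SimConfig(seed=SEED, n_fragments=200_000, tail_decay=500.0)
    rows = []
    for cond in (CONTROL, TREATMENT):
        fs = cb.simulate_fragments(genome, "tf_chip", cond, cfg)
        track = cb.normalize_rpm(cb.extend_and_count(fs.as_reads(), sizes))
        res = cb.divergent_asymmetry(track, genome)
        io.write_table(res.per_pair.round(4), out / f"per_pair_{cond}.tsv")
        rows.append(
            {"condition": cond, "mean_score": res.mean, "se": res.se,
             "z": res.mean / res.se, "n_pairs": res.n_pairs,
             "n_excluded": res.n_excluded}
        )
        print(f"{cond}: mean asymmetry {res.mean:+.3f} +- {res.se:.3f} "
              f"(z = {res.mean/res.se:+.1f}, {res.n_pairs} pairs)")
    io.write_table(pd.DataFrame(rows).round(4), out / "summary.tsv")
    print(f"-> the tail reveals the induced partner only after treatment; "
          f"tables in {out}")


if __name__ == "__main__":
    main()
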