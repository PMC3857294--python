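"""Toy yeast-like genome layouts for ChIP-seq background simulations.

The genome is a set of short chromosomes tiled with non-overlapping genes,
each carrying a per-condition transcription-rate proxy (TR, the quantity a
RNAPII Ser5P ChIP would report). A subset of genes are *divergent pairs*:
two genes on opposite strands transcribed away from a shared intergenic
promoter, the configuration in which a factor bound at the promoter can show
an asymmetric downstream signal tail. A designated "Up" subset is
transcriptionally induced (>= 5x TR) in the treatment condition, standing in
for stress-responsive genes.

Coordinates are 0-based half-open throughout; for minus-strand genes the TSS
is the exclusive end of the interval (first transcribed base is ``tss - 1``).
All coordinates are multiples of 10 so gene boundaries align with the default
coverage binning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"
CONDITIONS = (CONTROL, TREATMENT)

#: TR ratio (treatment/control) at or above which a gene counts as "Up".
UP_RATIO = 5.0


@dataclass
class SimGene:
    """A gene with strand-aware TSS/TES and per-condition transcription rate.

    ``binding_sites`` holds (offset upstream of the TSS in bp, affinity >= 0)
    pairs describing true factor binding sites in the gene's promoter.
    """

    id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    tes: int
    tr: dict[str, float] = field(default_factory=dict)
    binding_sites: list[tuple[int, float]] = field(default_factory=list)

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.body_end - self.body_start

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.length < 300:
            raise ValueError(f"gene {self.id}: body shorter than 300 bp")
        for cond, rate in self.tr.items():
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"gene {self.id}: bad TR for {cond}: {rate}")


@dataclass
class SimGenome:
    """Chromosome layout + genes + nucleosome phasing parameters."""

    chromosomes: list[tuple[str, int]]
    genes: list[SimGene]
    nucleosome_repeat: int = 165
    linker_len: int = 20
    divergent_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {g.id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")

    # -- basic accessors -------------------------------------------------

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def gene(self, gene_id: str) -> SimGene:
        return self._by_id[gene_id]

    def genes_frame(self) -> pd.DataFrame:
        """Gene table with body interval and transcription-coordinate TSS/TES."""
        rows = [
            {
                "gene_id": g.id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.body_start,
                "end": g.body_end,
                "tss": g.tss,
                "tes": g.tes,
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows)

    def tr_frame(self) -> pd.DataFrame:
        """Long-format per-gene, per-condition transcription-rate table."""
        rows = [
            {"gene_id": g.id, "condition": cond, "tr": rate}
            for g in self.genes
            for cond, rate in sorted(g.tr.items())
        ]
        return pd.DataFrame(rows)

    def tr_series(self, condition: str) -> pd.Series:
        return pd.Series(
            {g.id: g.tr[condition] for g in self.genes}, name="tr"
        ).rename_axis("gene_id")

    def up_genes(self, ratio: float = UP_RATIO) -> list[str]:
        """Genes induced >= ``ratio``-fold in treatment relative to control."""
        out = []
        for g in self.genes:
            ctl = g.tr.get(CONTROL, 0.0)
            trt = g.tr.get(TREATMENT, 0.0)
            if ctl > 0 and trt / ctl >= ratio:
                out.append(g.id)
        return out

    # -- nucleosome phasing ---------------------------------------------

    def linker_intervals(self) -> dict[str, np.ndarray]:
        """Per-chromosome sorted (start, end) linker intervals.

        Nucleosomes are tiled in phase from each TSS: the +1 dyad sits 60 bp
        downstream of the TSS and successive dyads follow at the nucleosome
        repeat. Each nucleosome protects ``repeat - linker_len`` bp centred
        on its dyad; the gaps between consecutive protected stretches within
        a gene body are the linkers. Intergenic DNA is left unphased.
        """
        repeat = self.nucleosome_repeat
        half = (repeat - self.linker_len) // 2  # protected half-width
        per_chrom: dict[str, list[tuple[int, int]]] = {
            name: [] for name, _ in self.chromosomes
        }
        for g in self.genes:
            dyads = []
            k = 0
            while True:
                dyad = g.tss + g.direction * (60 + k * repeat)
                if g.strand == "-":
                    dyad -= 1  # first transcribed base is tss-1
                # tile while the dyad is inside the body; the +1 particle may
                # protrude slightly past the TSS
                if not g.body_start <= dyad < g.body_end:
                    break
                dyads.append(dyad)
                k += 1
            dyads.sort()
            for d0, d1 in zip(dyads, dyads[1:]):
                per_chrom[g.chrom].append((d0 + half + 1, d1 - half))
        out = {}
        for name, ivals in per_chrom.items():
            arr = np.array(sorted(ivals), dtype=np.int64).reshape(-1, 2)
            out[name] = arr
        return out

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        sizes = self.chrom_sizes
        for g in self.genes:
            g.validate()
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chrom}")
            if g.body_start < 0 or g.body_end > sizes[g.chrom]:
                raise ValueError(f"gene {g.id}: outside chromosome bounds")
        # same-strand genes must not overlap
        frame = self.genes_frame()
        for (_, _), grp in frame.groupby(["chrom", "strand"]):
            grp = grp.sort_values("start")
            bad = grp["start"].values[1:] < grp["end"].values[:-1]
            if bad.any():
                raise ValueError("overlapping same-strand genes")
        for a_id, b_id in self.divergent_pairs:
            a, b = self.gene(a_id), self.gene(b_id)
            if a.strand == b.strand:
                raise ValueError(f"divergent pair ({a_id},{b_id}) on same strand")
            minus, plus = (a, b) if a.strand == "-" else (b, a)
            gap = plus.tss - minus.tss
            if gap < 200:
                raise ValueError(
                    f"divergent pair ({a_id},{b_id}): shared promoter < 200 bp"
                )


def _draw_tr(rng: np.random.Generator, n: int) -> np.ndarray:
    """Basal TR, log-uniform over three orders of magnitude."""
    return 10.0 ** rng.uniform(0.0, 3.0, size=n)


def build_toy_genome(
    n_genes: int = 200,
    n_divergent_pairs: int = 20,
    seed: int = 0,
    n_chromosomes: int = 2,
    up_fraction: float = 0.15,
    max_chrom_length: int | None = None,
) -> SimGenome:
    """Deterministically lay out a toy genome.

    Genes (400-2000 bp) are placed left to right with >= 500 bp intergenic
    spacers. Divergent pairs share a 200-390 bp promoter between their
    facing TSSs. One member of every divergent pair, plus enough additional
    single genes to reach ``round(up_fraction * n_genes)``, is designated
    "Up": its basal TR is drawn from the middle of the range and multiplied
    by 5-20x in the treatment condition, so induced genes reach the top of
    the treatment TR distribution. All other genes keep identical TR in both
    conditions. Promoter binding sites (for a simulated factor ChIP) are
    placed at every shared divergent promoter and at every fifth single
    gene's promoter.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if n_genes < 2 * n_divergent_pairs:
        raise ValueError("n_genes must be >= 2 * n_divergent_pairs")
    rng = np.random.default_rng(seed)

    n_singles = n_genes - 2 * n_divergent_pairs
    units = ["pair"] * n_divergent_pairs + ["single"] * n_singles
    rng.shuffle(units)

    # choose Up slots before layout so TR draws stay tied to gene identity
    n_up = max(n_divergent_pairs, int(round(up_fraction * n_genes)))
    n_up = min(n_up, n_genes)

    genes: list[SimGene] = []
    pairs: list[tuple[str, str]] = []
    chrom_names = [f"chrS{i + 1}" for i in range(n_chromosomes)]
    cursors = {name: 500 for name in chrom_names}
    gene_idx = 0
    single_idx = 0
    n_up_singles = min(max(n_up - n_divergent_pairs, 0), n_singles)
    if n_up_singles:
        up_single_idx = set(
            np.linspace(0, n_singles - 1, n_up_singles).round().astype(int).tolist()
        )
    else:
        up_single_idx = set()

    def new_gene(chrom: str, strand: str, start: int, length: int, up: bool) -> SimGene:
        nonlocal gene_idx
        gid = f"g{gene_idx:04d}"
        gene_idx += 1
        end = start + length
        tss, tes = (start, end) if strand == "+" else (end, start)
        if up:
            base = 10.0 ** rng.uniform(1.3, 2.3)
            tr = {CONTROL: base, TREATMENT: base * rng.uniform(5.0, 20.0)}
        else:
            base = float(_draw_tr(rng, 1)[0])
            tr = {CONTROL: base, TREATMENT: base}
        return SimGene(id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes, tr=tr)

    def glen() -> int:
        return int(rng.integers(40, 201)) * 10  # 400..2000

    def spacer() -> int:
        return int(rng.integers(50, 121)) * 10  # 500..1200

    for ui, unit in enumerate(units):
        chrom = chrom_names[ui % n_chromosomes]
        pos = cursors[chrom]
        if unit == "pair":
            # minus-strand gene, shared promoter, plus-strand gene
            l1, l2 = glen(), glen()
            promoter = int(rng.integers(20, 40)) * 10  # 200..390
            up_first = bool(rng.integers(0, 2))
            g_minus = new_gene(chrom, "-", pos, l1, up=up_first)
            g_plus = new_gene(chrom, "+", pos + l1 + promoter, l2, up=not up_first)
            mid = pos + l1 + promoter // 2
            affinity = float(10.0 ** rng.normal(0.0, 0.15))
            g_minus.binding_sites.append((g_minus.tss - mid, affinity))
            g_plus.binding_sites.append((g_plus.tss - mid, affinity))
            genes.extend([g_minus, g_plus])
            pairs.append((g_minus.id, g_plus.id))
            cursors[chrom] = g_plus.body_end + spacer()
        else:
            strand = "+" if rng.integers(0, 2) else "-"
            g = new_gene(chrom, strand, pos, glen(), up=single_idx in up_single_idx)
            if single_idx % 5 == 0:
                g.binding_sites.append((100, float(10.0 ** rng.normal(0.0, 0.15))))
            single_idx += 1
            genes.append(g)
            cursors[chrom] = g.body_end + spacer()

    chromosomes = [(name, cursors[name] + 500) for name in chrom_names]
    if max_chrom_length is not None:
        for name, length in chromosomes:
            if length > max_chrom_length:
                raise ValueError(
                    f"chromosome {name} needs {length} bp > limit {max_chrom_length}"
                )
    genome = SimGenome(
        chromosomes=chromosomes, genes=genes, divergent_pairs=pairs
    )
    genome.validate()
    return genome


def genome_to_dict(genome: SimGenome) -> dict:
    """JSON/YAML-serializable representation (round-trips via dict_to_genome)."""
    return {
        "chromosomes": [[n, int(l)] for n, l in genome.chromosomes],
        "nucleosome_repeat": genome.nucleosome_repeat,
        "linker_len": genome.linker_len,
        "divergent_pairs": [list(p) for p in genome.divergent_pairs],
        "genes": [
            {
                **{
                    k: v
                    for k, v in dataclasses.asdict(g).items()
                    if k not in ("binding_sites",)
                },
                "binding_sites": [list(bs) for bs in g.binding_sites],
            }
            for g in genome.genes
        ],
    }


def dict_to_genome(d: dict) -> SimGenome:
    genes = [
        SimGene(
            id=g["id"],
            chrom=g["chrom"],
            strand=g["strand"],
            tss=int(g["tss"]),
            tes=int(g["tes"]),
            tr={k: float(v) for k, v in g["tr"].items()},
            binding_sites=[(int(o), float(a)) for o, a in g["binding_sites"]],
        )
        for g in d["genes"]
    ]
    return SimGenome(
        chromosomes=[(n, int(l)) for n, l in d["chromosomes"]],
        genes=genes,
        nucleosome_repeat=int(d.get("nucleosome_repeat", 165)),
        linker_len=int(d.get("linker_len", 20)),
        divergent_pairs=[tuple(p) for p in d.get("divergent_pairs", [])],
    )
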