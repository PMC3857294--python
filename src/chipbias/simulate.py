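"""Mechanistic fragment simulator for ChIP-seq background artifacts.

Each sample is a mixture over three fragment sources:

* **uniform background** — sonicated chromatin with no preference;
* **expression-bias component** — a gene is chosen with probability
  proportional to ``TR**gamma`` for the simulated condition and the fragment
  midpoint is uniform within its body. This models non-specific recovery of
  open, highly transcribed chromatin and is *stronger in mock ChIP than in
  input* by default;
* **true-binding component** (factor ChIP only) — midpoints Gaussian around
  promoter binding sites, with an optional exponentially decaying tail
  extending into the gene body of a condition-induced ("Up") divergent
  partner.

Independently of the source, both fragment ends are relocated into the
nearest nucleosome linker with configurable odds, modelling the greater
shearing susceptibility of linker DNA; this is what imprints nucleosomal
periodicity on the coverage of every sample, controls included.

Library amplification is modelled as repeated coverage-weighted resampling:
fragments from already well-represented loci are preferentially duplicated,
magnifying whatever representation bias the library started with.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genome import CONTROL, TREATMENT, SimGenome

SAMPLE_KINDS = ("input", "mock", "tf_chip", "rnapii_chip")


def _default_w_expr() -> dict[str, float]:
    return {"input": 0.15, "mock": 0.5, "tf_chip": 0.3, "rnapii_chip": 0.9}


@dataclass
class SimConfig:
    """Knobs of the fragment mixture model.

    Per-sample mixture weights must sum to <= 1; the remainder is uniform
    background. ``linker_pref`` is the odds multiplier favouring fragment
    ends in linkers (1 = no preference). ``amp_alpha`` > 1 makes library
    amplification super-linear in local coverage.
    """

    seed: int = 0
    n_fragments: int = 200_000
    frag_len_mean: float = 200.0
    frag_len_sd: float = 40.0
    w_expr: dict[str, float] = field(default_factory=_default_w_expr)
    gamma: float = 1.0
    linker_pref: float = 5.0
    peak_weight: float = 0.4
    tail_decay: float = 500.0
    tail_weight: float = 0.3
    site_sd: float = 50.0
    induced_site_boost: float = 4.0
    amp_alpha: float = 1.3
    amp_rounds: int = 0

    def validate(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be positive")
        if self.frag_len_mean <= 0 or self.frag_len_sd < 0:
            raise ValueError("bad fragment length parameters")
        for kind, w in self.w_expr.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"w_expr[{kind}] outside [0,1]")
        if not 0.0 <= self.peak_weight <= 1.0:
            raise ValueError("peak_weight outside [0,1]")
        if self.w_expr.get("tf_chip", 0.0) + self.peak_weight > 1.0 + 1e-9:
            raise ValueError("tf_chip mixture weights exceed 1")
        if not 0.0 <= self.tail_weight <= 1.0:
            raise ValueError("tail_weight outside [0,1]")
        if self.linker_pref < 1.0:
            raise ValueError("linker_pref must be >= 1")
        if self.amp_alpha < 1.0:
            raise ValueError("amp_alpha must be >= 1")
        if self.amp_rounds < 0:
            raise ValueError("amp_rounds must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class FragmentSet:
    """Aligned fragment intervals for one sample.

    ``records`` is a DataFrame with columns chrom, start, end, strand,
    sorted by (chrom, start). ``single_end=True`` marks reads that only
    define a 5' position and need extension before counting.
    """

    sample_id: str
    sample_kind: str
    condition: str
    records: pd.DataFrame
    single_end: bool = False

    def __post_init__(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS + ("unknown",):
            raise ValueError(f"unknown sample kind {self.sample_kind!r}")
        req = ["chrom", "start", "end", "strand"]
        if list(self.records.columns[:4]) != req:
            self.records = self.records[req]

    @property
    def n(self) -> int:
        return len(self.records)

    def as_reads(self) -> "FragmentSet":
        """Single-end sequencing view: each fragment is read from one end
        (the strand column picks which), to be 3'-extended when counted.
        Coverage built this way preserves fragment-end periodicity that
        whole-fragment coverage would low-pass away."""
        return replace(self, single_end=True)

    def sorted(self) -> "FragmentSet":
        rec = (
            self.records.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )
        return replace(self, records=rec)


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """One RNG stream per (config seed, sample id); no global state."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def _genome_arrays(genome: SimGenome):
    """Global-coordinate helpers: chrom offsets and gene/site tables."""
    names = [n for n, _ in genome.chromosomes]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    off_by_name = {n: int(offsets[i]) for i, n in enumerate(names)}
    return names, lengths, offsets, off_by_name


def _collect_sites(genome: SimGenome, condition: str, induced_boost: float = 1.0):
    """Unique absolute binding sites with tail metadata.

    Sites shared by both members of a divergent pair are deduplicated by
    absolute position. Sites at genes (or divergent partners of genes) that
    are induced in the simulated condition have their affinity multiplied by
    ``induced_boost`` — condition-responsive recruitment of the factor to
    activated promoters — and, when the induced gene sits in a divergent
    pair, the site gains a downstream tail into that gene's body.
    """
    _, _, _, off = _genome_arrays(genome)
    up = set(genome.up_genes())
    pair_of = {}
    for a, b in genome.divergent_pairs:
        pair_of[a] = b
        pair_of[b] = a
    seen: dict[tuple[str, int], int] = {}
    pos, aff = [], []
    tail_tss, tail_dir, tail_len = [], [], []
    for g in genome.genes:
        for offset, affinity in g.binding_sites:
            abs_pos = g.tss - g.direction * offset + off[g.chrom]
            key = (g.chrom, abs_pos)
            if key in seen:
                continue
            seen[key] = len(pos)
            pos.append(abs_pos)
            # condition-responsive recruitment + tail toward the induced
            # divergent partner's gene body
            target = None
            induced = False
            if condition == TREATMENT:
                for cand in (g.id, pair_of.get(g.id)):
                    if cand in up:
                        induced = True
                        if pair_of.get(cand) is not None:
                            target = genome.gene(cand)
                        break
            aff.append(affinity * (induced_boost if induced else 1.0))
            if target is None:
                tail_tss.append(-1)
                tail_dir.append(0)
                tail_len.append(0)
            else:
                tail_tss.append(target.tss + off[target.chrom])
                tail_dir.append(target.direction)
                tail_len.append(target.length)
    return (
        np.array(pos, dtype=np.int64),
        np.array(aff, dtype=float),
        np.array(tail_tss, dtype=np.int64),
        np.array(tail_dir, dtype=np.int64),
        np.array(tail_len, dtype=np.int64),
    )


def _truncated_exponential(
    rng: np.random.Generator, scale: float, upper: np.ndarray
) -> np.ndarray:
    """Exact inverse-CDF draw from Exp(scale) truncated to [0, upper)."""
    u = rng.random(len(upper))
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def _relocate_to_linkers(
    rng: np.random.Generator,
    positions: np.ndarray,
    linker_start: np.ndarray,
    linker_end: np.ndarray,
    linker_pref: float,
    max_dist: int,
) -> np.ndarray:
    """Move each position into its nearest linker with odds (pref-1):1."""
    if linker_pref <= 1.0 or len(linker_start) == 0:
        return positions
    mids = (linker_start + linker_end) // 2
    j = np.searchsorted(mids, positions)
    j_lo = np.clip(j - 1, 0, len(mids) - 1)
    j_hi = np.clip(j, 0, len(mids) - 1)
    pick_hi = np.abs(mids[j_hi] - positions) < np.abs(mids[j_lo] - positions)
    nearest = np.where(pick_hi, j_hi, j_lo)
    dist = np.abs(mids[nearest] - positions)
    p_move = (linker_pref - 1.0) / linker_pref
    move = (dist <= max_dist) & (rng.random(len(positions)) < p_move)
    width = linker_end[nearest] - linker_start[nearest]
    new_pos = linker_start[nearest] + np.floor(
        rng.random(len(positions)) * width
    ).astype(np.int64)
    return np.where(move, new_pos, positions)


def simulate_fragments(
    genome: SimGenome,
    kind: str,
    condition: str,
    config: SimConfig,
    sample_id: str | None = None,
) -> FragmentSet:
    """Draw a FragmentSet from the mixture model. Deterministic given
    (genome, kind, condition, config, sample_id)."""
    if kind not in SAMPLE_KINDS:
        raise ValueError(f"unknown sample kind {kind!r}")
    if genome.total_length <= 0:
        raise ValueError("zero-length genome")
    config.validate()
    if sample_id is None:
        sample_id = f"{kind}_{condition}"
    rng = sample_rng(config.seed, sample_id)
    n = config.n_fragments

    w_expr = float(config.w_expr.get(kind, 0.0))
    w_peak = float(config.peak_weight) if kind == "tf_chip" else 0.0
    w_bg = 1.0 - w_expr - w_peak
    if w_bg < -1e-9:
        raise ValueError("mixture weights exceed 1")
    w_bg = max(w_bg, 0.0)

    names, lengths, offsets, off = _genome_arrays(genome)
    total = int(offsets[-1])

    comp = rng.choice(3, size=n, p=[w_bg, w_expr, w_peak])
    mid = np.empty(n, dtype=np.int64)

    # uniform background
    bg = comp == 0
    mid[bg] = rng.integers(0, total, size=int(bg.sum()))

    # expression-bias component: gene ~ TR**gamma, midpoint uniform in body
    ex = comp == 1
    n_ex = int(ex.sum())
    if n_ex:
        body_start = np.array(
            [g.body_start + off[g.chrom] for g in genome.genes], dtype=np.int64
        )
        body_len = np.array([g.length for g in genome.genes], dtype=np.int64)
        tr = np.array(
            [g.tr.get(condition, 0.0) for g in genome.genes], dtype=float
        )
        weights = tr**config.gamma
        if weights.sum() <= 0:
            raise ValueError(f"no positive TR for condition {condition!r}")
        gi = rng.choice(len(weights), size=n_ex, p=weights / weights.sum())
        mid[ex] = body_start[gi] + np.floor(
            rng.random(n_ex) * body_len[gi]
        ).astype(np.int64)

    # true-binding component: Gaussian at sites + exponential tail
    pk = comp == 2
    n_pk = int(pk.sum())
    if n_pk:
        pos, aff, t_tss, t_dir, t_len = _collect_sites(
            genome, condition, config.induced_site_boost
        )
        if len(pos) == 0:
            raise ValueError("peak component requested but genome has no sites")
        si = rng.choice(len(pos), size=n_pk, p=aff / aff.sum())
        m = pos[si] + np.round(rng.normal(0.0, config.site_sd, n_pk)).astype(
            np.int64
        )
        if config.tail_decay > 0:
            in_tail = (t_dir[si] != 0) & (rng.random(n_pk) < config.tail_weight)
            if in_tail.any():
                upper = t_len[si][in_tail].astype(float)
                d = _truncated_exponential(rng, config.tail_decay, upper)
                d = np.floor(d).astype(np.int64)
                tss = t_tss[si][in_tail]
                direction = t_dir[si][in_tail]
                m[in_tail] = np.where(
                    direction > 0, tss + d, tss - 1 - d
                )
        mid[pk] = m

    # fragment extent
    flen = np.clip(
        np.round(rng.normal(config.frag_len_mean, config.frag_len_sd, n)),
        50,
        None,
    ).astype(np.int64)
    starts = mid - flen // 2
    ends = starts + flen

    # linker-preferential shearing, applied to every component
    if config.linker_pref > 1.0:
        link = genome.linker_intervals()
        ls = np.concatenate(
            [link[name][:, 0] + off[name] for name in names]
            + [np.array([], dtype=np.int64)]
        )
        le = np.concatenate(
            [link[name][:, 1] + off[name] for name in names]
            + [np.array([], dtype=np.int64)]
        )
        order = np.argsort(ls)
        ls, le = ls[order], le[order]
        starts = _relocate_to_linkers(
            rng, starts, ls, le, config.linker_pref, genome.nucleosome_repeat
        )
        ends = _relocate_to_linkers(
            rng, ends, ls, le, config.linker_pref, genome.nucleosome_repeat
        )
        starts, ends = np.minimum(starts, ends), np.maximum(starts, ends)
        ends = np.where(ends > starts, ends, starts + 1)

    # map global -> per-chromosome coordinates, clip at chromosome ends
    mid_clip = np.clip((starts + ends) // 2, 0, total - 1)
    ci = np.searchsorted(offsets, mid_clip, side="right") - 1
    local_start = starts - offsets[ci]
    local_end = ends - offsets[ci]
    clen = lengths[ci]
    local_start = np.clip(local_start, 0, clen - 1)
    local_end = np.clip(local_end, local_start + 1, clen)

    records = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(ci, categories=names).astype(str),
            "start": local_start,
            "end": local_end,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )
    return FragmentSet(
        sample_id=sample_id,
        sample_kind=kind,
        condition=condition,
        records=records,
    ).sorted()


def amplify_library(
    frags: FragmentSet, config: SimConfig, cov_bin: int = 100
) -> FragmentSet:
    """PCR-style magnification: coverage-weighted resampling with replacement.

    Each round resamples the library back to its original size with
    per-fragment weight proportional to (local midpoint coverage, in
    ``cov_bin``-bp bins) ** (amp_alpha - 1). ``amp_alpha=1`` or
    ``amp_rounds=0`` is the identity in distribution; the output always has
    exactly as many fragments as the input.
    """
    if config.amp_alpha < 1.0:
        raise ValueError("amp_alpha must be >= 1")
    if config.amp_rounds == 0 or frags.n == 0:
        return replace(frags, records=frags.records.copy())
    rng = sample_rng(config.seed, frags.sample_id + "/amplify")
    rec = frags.records
    chroms = sorted(rec["chrom"].unique())
    chrom_code = rec["chrom"].map({c: i for i, c in enumerate(chroms)}).to_numpy()
    for _ in range(config.amp_rounds):
        midpoint = (rec["start"].to_numpy() + rec["end"].to_numpy()) // 2
        key = chrom_code * (midpoint.max() // cov_bin + 2) + midpoint // cov_bin
        _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
        cov = counts[inverse].astype(float)
        w = cov ** (config.amp_alpha - 1.0)
        idx = rng.choice(len(rec), size=len(rec), p=w / w.sum())
        rec = rec.iloc[idx].reset_index(drop=True)
        chrom_code = chrom_code[idx]
    out = replace(frags, sample_id=frags.sample_id, records=rec)
    return out.sorted()


def simulate_qpcr(
    frags: FragmentSet,
    amplicons: list[tuple],
    curve: tuple[float, float] = (-3.32, 38.0),
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
    noise_sd: float = 0.15,
    max_cycle: float = 40.0,
    n_tech_reps: int = 3,
) -> pd.DataFrame:
    """Standard-curve qPCR readout of a fragment library.

    The template quantity for an amplicon is the number of fragments fully
    containing it; Ct = intercept + slope * log10(quantity) + N(0, noise_sd),
    with ``n_tech_reps`` technical replicates per amplicon. Zero template is
    censored at ``max_cycle``. Amplicons are (id, chrom, start, end) or
    (chrom, start, end) with 80-100 bp extent.
    """
    slope, intercept = curve
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    rng = np.random.default_rng([seed, zlib.crc32(frags.sample_id.encode())])
    rec = frags.records
    rows = []
    for i, amp in enumerate(amplicons):
        if len(amp) == 4:
            amp_id, chrom, a_start, a_end = amp
        else:
            chrom, a_start, a_end = amp
            amp_id = f"amp{i:02d}"
        alen = a_end - a_start
        if not 80 <= alen <= 100:
            raise ValueError(f"amplicon {amp_id}: length {alen} outside 80-100 bp")
        if chrom_sizes is not None:
            if chrom not in chrom_sizes or a_start < 0 or a_end > chrom_sizes[chrom]:
                raise ValueError(f"amplicon {amp_id} outside genome")
        sel = rec["chrom"] == chrom
        template = int(
            (
                (rec.loc[sel, "start"] <= a_start) & (rec.loc[sel, "end"] >= a_end)
            ).sum()
        )
        for rep in range(1, n_tech_reps + 1):
            if template == 0:
                ct, censored = max_cycle, True
            else:
                ct = intercept + slope * np.log10(template) + rng.normal(
                    0.0, noise_sd
                )
                censored = False
            rows.append(
                {
                    "amplicon_id": amp_id,
                    "chrom": chrom,
                    "start": a_start,
                    "end": a_end,
                    "template": template,
                    "tech_rep": rep,
                    "ct": float(ct),
                    "censored": censored,
                }
            )
    return pd.DataFrame(rows)
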