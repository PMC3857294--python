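"""Binned coverage tracks, metagene profiles and per-gene occupancy.

Two counting modes are used deliberately:

* ``extend_and_count`` — every (extended) fragment adds 1 to every bin it
  overlaps. This is browser-style coverage and is what profiles, peak
  calling and subtraction operate on.
* ``count_midpoints`` — every fragment adds 1 to the single bin holding its
  midpoint, so bin sums are fragment counts. Per-gene occupancy
  (reads per kb per million mapped) is computed from this mode so that its
  units match read counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import FragmentSet

log = logging.getLogger(__name__)

RAW, RPM, SUBTRACTED = "raw", "rpm", "subtracted"


@dataclass
class CoverageTrack:
    """Fixed-bin per-chromosome coverage vectors with normalization state."""

    data: dict[str, np.ndarray]
    bin_size: int = 10
    norm_state: str = RAW
    total_fragments: int = 0
    mode: str = "extended"  # or "midpoint"

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) * self.bin_size for c, v in self.data.items()}

    def copy(self) -> "CoverageTrack":
        return replace(self, data={c: v.copy() for c, v in self.data.items()})

    def genome_sum(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Track value of the bin containing each base position."""
        v = self.data[chrom]
        idx = np.clip(positions // self.bin_size, 0, len(v) - 1)
        return v[idx]


def _effective_intervals(frags: FragmentSet, extension: int):
    """Fragment intervals to count; single-end reads get 3'-extended."""
    rec = frags.records
    start = rec["start"].to_numpy()
    end = rec["end"].to_numpy()
    if frags.single_end and extension > 0:
        plus = rec["strand"].to_numpy() == "+"
        end = np.where(plus, start + extension, end)
        start = np.where(plus, start, np.maximum(end - extension, 0))
    return rec["chrom"].to_numpy(), start, end


def extend_and_count(
    frags: FragmentSet,
    chrom_sizes: dict[str, int],
    extension: int = 75,
    bin_size: int = 10,
) -> CoverageTrack:
    """Overlap-count fragments into fixed bins (raw coverage).

    Each fragment increments every bin it overlaps, clipped at chromosome
    ends. Records on unknown chromosomes or fully outside the genome are
    dropped with a logged warning.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    data = {
        c: np.zeros(int(np.ceil(l / bin_size)), dtype=float)
        for c, l in chrom_sizes.items()
    }
    chrom, start, end = _effective_intervals(frags, extension)
    n_bad = 0
    for c in np.unique(chrom):
        if c not in data:
            n_bad += int((chrom == c).sum())
            continue
        sel = chrom == c
        clen = chrom_sizes[c]
        s = start[sel]
        e = end[sel]
        outside = (e <= 0) | (s >= clen) | (s >= e)
        n_bad += int(outside.sum())
        s = np.clip(s[~outside], 0, clen)
        e = np.clip(e[~outside], 0, clen)
        b0 = s // bin_size
        b1 = (e - 1) // bin_size
        diff = np.zeros(len(data[c]) + 1, dtype=float)
        np.add.at(diff, b0, 1.0)
        np.add.at(diff, b1 + 1, -1.0)
        data[c] += np.cumsum(diff[:-1])
    if n_bad:
        log.warning("extend_and_count: dropped %d out-of-genome records", n_bad)
    return CoverageTrack(
        data=data,
        bin_size=bin_size,
        norm_state=RAW,
        total_fragments=frags.n - n_bad,
        mode="extended",
    )


def count_midpoints(
    frags: FragmentSet, chrom_sizes: dict[str, int], bin_size: int = 10
) -> CoverageTrack:
    """Fragment-midpoint counts per bin (bin sums are fragment counts)."""
    data = {
        c: np.zeros(int(np.ceil(l / bin_size)), dtype=float)
        for c, l in chrom_sizes.items()
    }
    chrom, start, end = _effective_intervals(frags, 0)
    mid = (start + end) // 2
    n_bad = 0
    for c in np.unique(chrom):
        if c not in data:
            n_bad += int((chrom == c).sum())
            continue
        sel = chrom == c
        m = mid[sel]
        ok = (m >= 0) & (m < chrom_sizes[c])
        n_bad += int((~ok).sum())
        np.add.at(data[c], m[ok] // bin_size, 1.0)
    if n_bad:
        log.warning("count_midpoints: dropped %d out-of-genome records", n_bad)
    return CoverageTrack(
        data=data,
        bin_size=bin_size,
        norm_state=RAW,
        total_fragments=frags.n - n_bad,
        mode="midpoint",
    )


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Divide every bin by the mapped-fragment total and scale by 1e6."""
    if track.norm_state != RAW:
        raise ValueError(f"normalize_rpm requires a raw track, got {track.norm_state}")
    if track.total_fragments <= 0:
        raise ValueError("normalize_rpm: total_fragments is zero")
    factor = 1e6 / track.total_fragments
    out = track.copy()
    for c in out.data:
        out.data[c] *= factor
    out.norm_state = RPM
    return out


def subtract_control(chip: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Binwise chip - control, floored at zero. Both tracks must be RPM."""
    if chip.norm_state != RPM or control.norm_state != RPM:
        raise ValueError("subtract_control requires two rpm-normalized tracks")
    if chip.bin_size != control.bin_size:
        raise ValueError("bin size mismatch")
    if set(chip.data) != set(control.data) or any(
        len(chip.data[c]) != len(control.data[c]) for c in chip.data
    ):
        raise ValueError("genome mismatch")
    out = chip.copy()
    for c in out.data:
        out.data[c] = np.maximum(out.data[c] - control.data[c], 0.0)
    out.norm_state = SUBTRACTED
    return out


@dataclass
class MetageneProfile:
    """Per-offset mean coverage across a gene group, anchored at the TSS."""

    offsets: np.ndarray  # bp downstream of the TSS, transcription direction
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_genes: int
    anchor: str = "TSS"
    degenerate: bool = False  # single gene: CI not estimable
    matrix: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean": self.mean,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n": self.n_genes,
            }
        )


def _as_genes_frame(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    # accept SimGenome for convenience
    return genes.genes_frame()


def metagene_profile(
    track: CoverageTrack,
    genes,
    window: int = 1500,
    keep_matrix: bool = False,
) -> MetageneProfile:
    """TSS-anchored average profile over [0, window) in transcription
    direction; minus-strand genes are reversed. 95% CI across genes
    (normal approximation). Genes whose window leaves the chromosome are
    skipped with a warning.
    """
    frame = _as_genes_frame(genes)
    if len(frame) == 0:
        raise ValueError("metagene_profile: empty gene set")
    bs = track.bin_size
    nb = window // bs
    offsets = np.arange(nb) * bs
    rows = []
    skipped = 0
    for g in frame.itertuples(index=False):
        if g.chrom not in track.data:
            skipped += 1
            continue
        if g.strand == "+":
            pos = g.tss + offsets
        else:
            pos = g.tss - 1 - offsets
        clen = len(track.data[g.chrom]) * bs
        if pos.min() < 0 or pos.max() >= clen:
            skipped += 1
            continue
        rows.append(track.values_at(g.chrom, pos))
    if skipped:
        log.warning("metagene_profile: skipped %d genes at chromosome edges", skipped)
    if not rows:
        raise ValueError("metagene_profile: no usable genes")
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    n = len(rows)
    degenerate = n < 2
    if degenerate:
        ci_lo = mean.copy()
        ci_hi = mean.copy()
        warnings.warn("metagene_profile: single gene, CI degenerate")
    else:
        se = mat.std(axis=0, ddof=1) / np.sqrt(n)
        ci_lo = mean - 1.96 * se
        ci_hi = mean + 1.96 * se
    return MetageneProfile(
        offsets=offsets,
        mean=mean,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        n_genes=n,
        degenerate=degenerate,
        matrix=mat if keep_matrix else None,
    )


def gene_sums(track: CoverageTrack, genes) -> pd.Series:
    """Sum of track bins whose span lies within each gene body."""
    frame = _as_genes_frame(genes)
    bs = track.bin_size
    out = {}
    for g in frame.itertuples(index=False):
        v = track.data[g.chrom]
        b0 = int(np.ceil(g.start / bs))
        b1 = int(g.end // bs)
        out[g.gene_id] = float(v[b0:b1].sum())
    return pd.Series(out, name="sum").rename_axis("gene_id")


def gene_body_occupancy(
    track: CoverageTrack,
    genes,
    sample_id: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """Reads per kb per million mapped over each gene body [TSS, TES).

    Requires a raw midpoint-count track so the numerator is a fragment
    count, matching read-counting semantics.
    """
    if track.mode != "midpoint" or track.norm_state != RAW:
        raise ValueError("gene_body_occupancy requires a raw midpoint-count track")
    if track.total_fragments <= 0:
        raise ValueError("gene_body_occupancy: empty track")
    frame = _as_genes_frame(genes)
    if (frame["end"] - frame["start"] <= 0).any():
        raise ValueError("zero-length gene in annotation")
    counts = gene_sums(track, frame)
    kb = (frame.set_index("gene_id")["end"] - frame.set_index("gene_id")["start"]) / 1e3
    occ = counts / kb / (track.total_fragments / 1e6)
    out = pd.DataFrame(
        {
            "gene_id": occ.index,
            "sample_id": sample_id,
            "condition": condition,
            "occupancy": occ.values,
        }
    )
    return out.reset_index(drop=True)


def _top_k(scores: pd.Series, k: int) -> list[str]:
    """Deterministic top-k: score descending, gene_id ascending on ties."""
    frame = scores.rename("score").reset_index()
    frame = frame.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return frame["gene_id"].head(k).tolist()


def rank_top(occ: pd.DataFrame, k: int = 100) -> list[str]:
    """Top-k genes by occupancy (the paper-style 'high TR' definition)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = occ.set_index("gene_id")["occupancy"]
    if k > len(scores):
        log.warning("rank_top: k=%d exceeds %d genes, returning all", k, len(scores))
    return _top_k(scores, k)


def rank_condition_up(
    occ_treat: pd.DataFrame, occ_control: pd.DataFrame, k: int = 100
) -> list[str]:
    """Top-k genes by occupancy(treatment) - occupancy(control)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    t = occ_treat.set_index("gene_id")["occupancy"]
    c = occ_control.set_index("gene_id")["occupancy"]
    if set(t.index) != set(c.index):
        raise ValueError("rank_condition_up: mismatched gene universes")
    diff = t - c.reindex(t.index)
    if (diff == 0).all():
        log.warning("rank_condition_up: all differences zero; lexical top-k")
    return _top_k(diff, k)
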