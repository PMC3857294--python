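"""Simplified Poisson local-lambda peak calling and MA-based differential
binding.

``call_peaks`` slides a fixed window along each chromosome, counts ChIP
fragment midpoints per window and tests them against a Poisson expectation
lambda = max(genome-wide rate, control-local rate in 1-kb and 10-kb windows
scaled to ChIP depth), with Benjamini-Hochberg correction over all tested
windows. ``ma_normalize``/``identify_dbts`` fit a linear M-A relation on
peaks shared between two samples, recentre all candidate regions, and call
treatment-specific differential binding targets (DBTs) with a Poisson test
against the rescaled control — regions where the control exceeds the
treatment are ignored. These are deliberately simplified, fully specified
surrogates for the MACS2 + MAnorm combination; no model building, broad
peaks or Bayesian read allocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import FragmentSet

log = logging.getLogger(__name__)

PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "summit",
    "fold_enrichment",
    "neglog10_q",
    "n_windows",
]


def poisson_sf(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper-tail P(X >= k) for X ~ Poisson(lam)."""
    return stats.poisson.sf(np.asarray(k) - 1, np.asarray(lam))


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def _midpoint_bins(
    frags: FragmentSet, chrom_sizes: dict[str, int], step: int
) -> dict[str, np.ndarray]:
    rec = frags.records
    mid = ((rec["start"].to_numpy() + rec["end"].to_numpy()) // 2).astype(np.int64)
    chrom = rec["chrom"].to_numpy()
    out = {}
    for c, clen in chrom_sizes.items():
        nb = int(np.ceil(clen / step))
        v = np.zeros(nb, dtype=np.int64)
        sel = chrom == c
        if sel.any():
            m = np.clip(mid[sel], 0, clen - 1)
            np.add.at(v, m // step, 1)
        out[c] = v
    return out


def _centered_rolling_rate(
    counts: np.ndarray, span_bins: int, w_bins: int
) -> np.ndarray:
    """Per-window expected count from a centred local span, edge-corrected."""
    nb = len(counts)
    cum = np.concatenate([[0], np.cumsum(counts)])
    n_windows = nb - w_bins + 1
    centers = np.arange(n_windows) + w_bins // 2
    lo = np.clip(centers - span_bins // 2, 0, nb)
    hi = np.clip(centers + span_bins // 2, 0, nb)
    local = cum[hi] - cum[lo]
    width = np.maximum(hi - lo, 1)
    return local * (w_bins / width)


@dataclass
class WindowScan:
    """Per-window Poisson statistics for one chip/control pair."""

    chrom: np.ndarray
    start: np.ndarray  # window start, bp
    k: np.ndarray  # chip fragment count in window
    lam: np.ndarray
    neglog10_q: np.ndarray
    window: int
    step: int
    chip_bins: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)


def scan_windows(
    chip: FragmentSet,
    control: FragmentSet,
    chrom_sizes: dict[str, int],
    window: int = 300,
    step: int = 10,
    local_spans: tuple[int, int] = (1_000, 10_000),
) -> WindowScan:
    """Sliding-window Poisson scan; q-values BH-corrected genome-wide."""
    if chip.n == 0:
        raise ValueError("empty chip fragment set")
    genome_len = sum(chrom_sizes.values())
    chip_bins = _midpoint_bins(chip, chrom_sizes, step)
    ctl_bins = _midpoint_bins(control, chrom_sizes, step)
    n_ctl = control.n
    if n_ctl == 0:
        log.warning("scan_windows: zero-depth control; genome-wide lambda only")
    ratio = chip.n / n_ctl if n_ctl else 0.0
    lam_bg = chip.n * window / genome_len
    w_bins = max(1, window // step)

    chroms, starts, ks, lams = [], [], [], []
    for c in sorted(chrom_sizes):
        cb = chip_bins[c]
        if len(cb) < w_bins:
            continue
        cum = np.concatenate([[0], np.cumsum(cb)])
        k = cum[w_bins:] - cum[:-w_bins]
        lam = np.full(len(k), lam_bg, dtype=float)
        if n_ctl:
            tb = ctl_bins[c]
            # window-sized control rate guards against sub-kilobase hotspots
            # that the broader local spans would average away
            ccum = np.concatenate([[0], np.cumsum(tb)])
            lam = np.maximum(lam, (ccum[w_bins:] - ccum[:-w_bins]) * ratio)
            for span in local_spans:
                local = _centered_rolling_rate(tb, span // step, w_bins)
                lam = np.maximum(lam, local * ratio)
        chroms.append(np.full(len(k), c, dtype=object))
        starts.append(np.arange(len(k), dtype=np.int64) * step)
        ks.append(k)
        lams.append(lam)
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts)
    k = np.concatenate(ks)
    lam = np.concatenate(lams)
    p = poisson_sf(k, lam)
    q = np.clip(bh_qvalues(p), 1e-300, None)
    return WindowScan(
        chrom=chrom,
        start=start,
        k=k,
        lam=lam,
        neglog10_q=-np.log10(q),
        window=window,
        step=step,
        chip_bins=chip_bins,
        chrom_sizes=dict(chrom_sizes),
    )


def peaks_from_scan(scan: WindowScan, qmin: float) -> pd.DataFrame:
    """Merge overlapping significant windows into peaks.

    Peak lists are nested across thresholds: every window significant at a
    higher qmin is significant at a lower one, so high-stringency peaks lie
    within low-stringency peaks.
    """
    if qmin <= 0:
        raise ValueError("qmin must be > 0")
    sig = (scan.neglog10_q >= qmin) & (scan.k > 0)
    rows = []
    for c in np.unique(scan.chrom[sig]):
        sel = sig & (scan.chrom == c)
        s = scan.start[sel]
        k = scan.k[sel]
        lam = scan.lam[sel]
        nlq = scan.neglog10_q[sel]
        order = np.argsort(s)
        s, k, lam, nlq = s[order], k[order], lam[order], nlq[order]
        e = s + scan.window
        # split where consecutive significant windows stop overlapping
        breaks = np.nonzero(s[1:] > e[:-1] + 0)[0] + 1
        for seg in np.split(np.arange(len(s)), breaks):
            start = int(s[seg[0]])
            end = int(e[seg[-1]])
            clen = scan.chrom_sizes[c]
            end = min(end, clen)
            bins = scan.chip_bins[c]
            b0, b1 = start // scan.step, int(np.ceil(end / scan.step))
            summit_bin = b0 + int(np.argmax(bins[b0:b1]))
            summit = min(summit_bin * scan.step + scan.step // 2, clen - 1)
            best = int(np.argmax(k[seg] / lam[seg]))
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "summit": summit,
                    "fold_enrichment": float(k[seg][best] / lam[seg][best]),
                    "neglog10_q": float(nlq[seg].max()),
                    "n_windows": int(len(seg)),
                }
            )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def call_peaks(
    chip: FragmentSet,
    control: FragmentSet,
    chrom_sizes: dict[str, int],
    qmin: float = 2.0,
    window: int = 300,
    step: int = 10,
) -> pd.DataFrame:
    """Poisson local-lambda peak calling (see module docstring)."""
    scan = scan_windows(chip, control, chrom_sizes, window=window, step=step)
    return peaks_from_scan(scan, qmin)


def _merge_intervals(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of peak intervals across lists, merged where overlapping."""
    allp = pd.concat(frames, ignore_index=True)
    rows = []
    for c, grp in allp.groupby("chrom"):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append({"chrom": c, "start": int(cur_s), "end": int(cur_e)})
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append({"chrom": c, "start": int(cur_s), "end": int(cur_e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _region_counts(
    frags: FragmentSet, regions: pd.DataFrame, chrom_sizes: dict[str, int]
) -> np.ndarray:
    rec = frags.records
    mid = ((rec["start"].to_numpy() + rec["end"].to_numpy()) // 2).astype(np.int64)
    chrom = rec["chrom"].to_numpy()
    out = np.zeros(len(regions), dtype=np.int64)
    for c, grp in regions.groupby("chrom"):
        m = np.sort(mid[chrom == c])
        lo = np.searchsorted(m, grp["start"].to_numpy())
        hi = np.searchsorted(m, grp["end"].to_numpy())
        out[grp.index.to_numpy()] = hi - lo
    return out


def _overlaps_any(regions: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(regions), dtype=bool)
    for c, grp in regions.groupby("chrom"):
        pk = peaks[peaks["chrom"] == c]
        if pk.empty:
            continue
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        for i, (s, e) in zip(grp.index, zip(grp["start"], grp["end"])):
            flags[i] = bool(((ps < e) & (pe > s)).any())
    return flags


@dataclass
class MaNormalization:
    """Candidate regions with raw and recentred M values plus the fitted line."""

    regions: pd.DataFrame  # chrom,start,end,summit,count_treat,count_ctrl,A,M,M_norm,common
    slope: float
    intercept: float


def _tile_regions(regions: pd.DataFrame, max_width: int) -> pd.DataFrame:
    """Chop merged regions longer than ``max_width`` into equal tiles.

    Keeps candidate regions at peak-like width so that a promoter summit
    and the adjacent gene-body signal are scored separately instead of
    blurring into one multi-kb candidate.
    """
    rows = []
    for r in regions.itertuples(index=False):
        width = r.end - r.start
        n = max(1, int(np.ceil(width / max_width)))
        edges = np.linspace(r.start, r.end, n + 1).round().astype(int)
        for s, e in zip(edges[:-1], edges[1:]):
            if e > s:
                rows.append({"chrom": r.chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def ma_normalize(
    peaks_treat: pd.DataFrame,
    peaks_ctrl: pd.DataFrame,
    frags_treat: FragmentSet,
    frags_ctrl: FragmentSet,
    chrom_sizes: dict[str, int],
    min_common: int = 10,
    step: int = 10,
    max_region: int = 500,
) -> MaNormalization:
    """Fit M = a + b*A on common peaks and recentre all candidate regions.

    Candidate regions are the merged union of both peak lists, tiled to at
    most ``max_region`` bp; a region is a *common peak* when it overlaps
    (>= 1 bp) a peak from each list. The least-squares fit makes the
    common-peak mean of the recentred M exactly zero, removing global
    efficiency/depth differences between samples.
    """
    if peaks_treat.empty or peaks_ctrl.empty:
        raise ValueError("ma_normalize: a peak list is empty")
    regions = _merge_intervals([peaks_treat, peaks_ctrl])
    regions = _tile_regions(regions, max_region).reset_index(drop=True)
    t = _region_counts(frags_treat, regions, chrom_sizes)
    c = _region_counts(frags_ctrl, regions, chrom_sizes)
    M = np.log2((t + 0.5) / (c + 0.5))
    A = 0.5 * np.log2((t + 0.5) * (c + 0.5))
    common = _overlaps_any(regions, peaks_treat) & _overlaps_any(regions, peaks_ctrl)
    if common.sum() < min_common:
        raise ValueError(
            f"ma_normalize: only {int(common.sum())} common peaks (< {min_common});"
            " cannot fit the M-A relation"
        )
    b, a = np.polyfit(A[common], M[common], 1)
    M_norm = M - (a + b * A)
    # summit = densest treatment bin within each region
    tb = _midpoint_bins(frags_treat, chrom_sizes, step)
    summits = np.empty(len(regions), dtype=np.int64)
    for i, r in regions.iterrows():
        bins = tb[r["chrom"]]
        b0 = min(r["start"] // step, len(bins) - 1)
        b1 = int(np.clip(np.ceil(r["end"] / step), b0 + 1, len(bins)))
        summits[i] = (b0 + int(np.argmax(bins[b0:b1]))) * step + step // 2
    out = regions.assign(
        summit=summits,
        count_treat=t,
        count_ctrl=c,
        A=A,
        M=M,
        M_norm=M_norm,
        common=common,
    )
    return MaNormalization(regions=out, slope=float(b), intercept=float(a))


def identify_dbts(ma: MaNormalization, qmin: float = 5.0) -> pd.DataFrame:
    """Treatment-specific DBTs from recentred candidate regions.

    Regions where the rescaled control meets or exceeds the treatment
    (M_norm <= 0) are not tested. For the rest, the treatment count is
    tested against Poisson(lambda = rescaled control count), BH-corrected
    over the tested regions; DBTs are sorted by normalized fold change.
    """
    reg = ma.regions
    tested = reg["M_norm"].to_numpy() > 0
    out = reg.loc[tested].copy()
    if out.empty:
        out["neglog10_q"] = pd.Series(dtype=float)
        return out
    lam = np.maximum(
        (out["count_ctrl"].to_numpy() + 0.5)
        * 2.0 ** (ma.intercept + ma.slope * out["A"].to_numpy())
        - 0.5,
        1e-9,
    )
    p = poisson_sf(out["count_treat"].to_numpy(), lam)
    q = np.clip(bh_qvalues(p), 1e-300, None)
    out["neglog10_q"] = -np.log10(q)
    out = out[out["neglog10_q"] >= qmin]
    return out.sort_values("M_norm", ascending=False).reset_index(drop=True)


@dataclass
class DBTSummary:
    control_kind: str
    stringency: str
    n_peaks_per_condition: dict[str, int]
    n_dbts: int
    n_dbts_in_gene_bodies: int
    pct_in_gene_bodies: float

    def to_row(self) -> dict:
        row = {
            "control_kind": self.control_kind,
            "stringency": self.stringency,
            "n_dbts": self.n_dbts,
            "n_dbts_in_gene_bodies": self.n_dbts_in_gene_bodies,
            "pct_in_gene_bodies": self.pct_in_gene_bodies,
        }
        for cond, n in self.n_peaks_per_condition.items():
            row[f"n_peaks_{cond}"] = n
        return row


def assign_to_orfs(
    dbts: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_bp: int = 500,
    control_kind: str = "",
    stringency: str = "",
    n_peaks_per_condition: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, DBTSummary]:
    """Classify each DBT summit as gene_body / promoter / intergenic.

    A summit inside [gene start, gene end) is gene_body; within
    ``promoter_bp`` upstream of a TSS (strand-aware) it is promoter;
    otherwise intergenic. The mapped gene id is recorded for downstream
    expression overlays.
    """
    classes = []
    gene_ids = []
    for r in dbts.itertuples(index=False):
        cls, gid = "intergenic", ""
        sub = genes[genes["chrom"] == r.chrom]
        inside = sub[(sub["start"] <= r.summit) & (r.summit < sub["end"])]
        if not inside.empty:
            cls, gid = "gene_body", inside.iloc[0]["gene_id"]
        else:
            for g in sub.itertuples(index=False):
                if g.strand == "+":
                    lo, hi = g.tss - promoter_bp, g.tss
                else:
                    lo, hi = g.tss, g.tss + promoter_bp
                if lo <= r.summit < hi:
                    cls, gid = "promoter", g.gene_id
                    break
        classes.append(cls)
        gene_ids.append(gid)
    out = dbts.copy()
    out["orf_overlap"] = classes
    out["gene_id"] = gene_ids
    n = len(out)
    n_body = int((out["orf_overlap"] == "gene_body").sum()) if n else 0
    summary = DBTSummary(
        control_kind=control_kind,
        stringency=stringency,
        n_peaks_per_condition=n_peaks_per_condition or {},
        n_dbts=n,
        n_dbts_in_gene_bodies=n_body,
        pct_in_gene_bodies=100.0 * n_body / n if n else 0.0,
    )
    return out, summary


def quadrant_overlay(
    dbt_genes: list[str],
    delta_rnapii: pd.Series,
    delta_expression: pd.Series,
) -> tuple[pd.DataFrame, float, int]:
    """Place DBT genes on the (dRNAPII occupancy, dExpression) plane.

    Returns the classification table, the fraction of DBT genes in the
    upper-right quadrant (both deltas positive — the signature of
    apparent binding that simply tracks condition-specific activation),
    and the number of genes dropped for missing deltas. The fraction is
    NaN for an empty gene list.
    """
    rows = []
    dropped = 0
    for gid in dbt_genes:
        if gid not in delta_rnapii.index or gid not in delta_expression.index:
            dropped += 1
            continue
        dr = float(delta_rnapii[gid])
        de = float(delta_expression[gid])
        quadrant = ("upper" if de > 0 else "lower") + "_" + (
            "right" if dr > 0 else "left"
        )
        rows.append(
            {"gene_id": gid, "delta_rnapii": dr, "delta_expression": de,
             "quadrant": quadrant}
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "delta_rnapii", "delta_expression", "quadrant"]
    )
    frac = (
        float((table["quadrant"] == "upper_right").mean())
        if len(table)
        else float("nan")
    )
    return table, frac, dropped


def four_pair_comparison(
    chip: dict[str, FragmentSet],
    input_ctrl: dict[str, FragmentSet],
    mock_ctrl: dict[str, FragmentSet],
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    stringencies: tuple[float, float] = (2.0, 20.0),
    dbt_qmin: float = 5.0,
    conditions: tuple[str, str] = ("control", "treatment"),
) -> tuple[pd.DataFrame, dict]:
    """The four-pair input-vs-mock design.

    ChIP samples from two conditions are each peak-called against the
    matching input and mock controls (four chip/control pairs), at a low
    and a high stringency; within each control branch the two conditions
    are then MA-normalized against each other and treatment-specific DBTs
    are identified and assigned to ORFs. Returns a summary table (one row
    per control kind x stringency) and the per-branch DBT tables.
    """
    ctl_cond, trt_cond = conditions
    summaries = []
    details: dict = {}
    for kind, controls in (("input", input_ctrl), ("mock", mock_ctrl)):
        scan_ctl = scan_windows(chip[ctl_cond], controls[ctl_cond], chrom_sizes)
        scan_trt = scan_windows(chip[trt_cond], controls[trt_cond], chrom_sizes)
        for qmin in stringencies:
            label = "low" if qmin == min(stringencies) else "high"
            pk_ctl = peaks_from_scan(scan_ctl, qmin)
            pk_trt = peaks_from_scan(scan_trt, qmin)
            n_peaks = {ctl_cond: len(pk_ctl), trt_cond: len(pk_trt)}
            try:
                ma = ma_normalize(
                    pk_trt, pk_ctl, chip[trt_cond], chip[ctl_cond], chrom_sizes
                )
                dbts = identify_dbts(ma, dbt_qmin)
            except ValueError as err:
                log.warning("four_pair %s/%s: %s", kind, label, err)
                dbts = pd.DataFrame(
                    columns=["chrom", "start", "end", "summit", "M_norm"]
                )
            assigned, summary = assign_to_orfs(
                dbts,
                genes,
                control_kind=kind,
                stringency=label,
                n_peaks_per_condition=n_peaks,
            )
            summaries.append(summary.to_row())
            details[(kind, label)] = assigned
    return pd.DataFrame(summaries), details
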