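"""Scalar diagnostics for ChIP-seq background artifacts.

The expression-bias statistic pair (high-TR/complement occupancy ratio and
genome-wide Spearman rho of occupancy vs TR) is this package's
operationalization of the qualitative "expression bias" — reports label it
as such. Periodicity is estimated in the lag domain (autocorrelation of the
detrended metagene profile) because the 1.5-kb window holds only ~9
nucleosome repeats, too few for a useful spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import (
    RPM,
    CoverageTrack,
    _as_genes_frame,
    gene_sums,
    metagene_profile,
    subtract_control,
)
from .genome import SimGenome

log = logging.getLogger(__name__)


@dataclass
class ExpressionBias:
    ratio: float  # mean occupancy(high-TR set) / mean occupancy(complement)
    rho: float  # Spearman of occupancy vs TR over all genes
    rho_defined: bool = True


@dataclass
class BiasReport:
    sample_id: str
    expr_bias_ratio: float
    expr_bias_rho: float
    period_bp: float
    period_amplitude: float
    asymmetry: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def expression_bias(
    occ: pd.DataFrame, tr: pd.Series, high_set: list[str] | set[str]
) -> ExpressionBias:
    """Occupancy enrichment of a high-TR gene set plus rank coupling to TR."""
    scores = occ.set_index("gene_id")["occupancy"]
    high = [g for g in high_set if g in scores.index]
    if not high:
        raise ValueError("high_set is empty or disjoint from the occupancy table")
    comp = scores.index.difference(high)
    if len(comp) == 0:
        raise ValueError("complement of high_set is empty")
    denom = scores.loc[comp].mean()
    ratio = float(scores.loc[high].mean() / denom) if denom > 0 else np.inf
    aligned = tr.reindex(scores.index)
    if scores.nunique() < 2 or aligned.nunique() < 2:
        log.warning("expression_bias: constant input, rho undefined -> 0")
        return ExpressionBias(ratio=ratio, rho=0.0, rho_defined=False)
    rho = float(stats.spearmanr(scores.values, aligned.values).statistic)
    return ExpressionBias(ratio=ratio, rho=rho)


def _detrend(x: np.ndarray, width: int) -> np.ndarray:
    """Subtract a centred moving average (width forced odd); trims edges."""
    width = max(3, width | 1)
    kernel = np.ones(width) / width
    trend = np.convolve(x, kernel, mode="valid")
    half = width // 2
    return x[half : len(x) - half] - trend


def profile_periodicity(
    values: np.ndarray,
    bin_size: int,
    lag_range: tuple[int, int] = (100, 260),
) -> tuple[float, float]:
    """(period_bp, amplitude) from one profile via normalized autocorrelation.

    The profile is detrended with a moving average spanning the middle of
    the lag range; the normalized autocorrelation r(lag) = sum(x_t x_{t+l})
    / sum(x_t^2) is maximized over the lag range. A white-noise profile has
    amplitude near zero; a pure cosine of in-range period has amplitude
    near one at its period.
    """
    lo, hi = lag_range
    width = int(round(((lo + hi) / 2) / bin_size))
    x = _detrend(np.asarray(values, dtype=float), width)
    lag_lo = max(1, int(np.ceil(lo / bin_size)))
    lag_hi = int(hi // bin_size)
    if len(x) < 2 * lag_hi:
        raise ValueError("profile window shorter than twice the maximum lag")
    denom = float(np.dot(x, x))
    if denom <= 0:
        return 0.0, 0.0
    best_lag, best_r = lag_lo, -np.inf
    for lag in range(lag_lo, lag_hi + 1):
        r = float(np.dot(x[:-lag], x[lag:])) / denom
        if r > best_r:
            best_lag, best_r = lag, r
    return float(best_lag * bin_size), float(best_r)


def periodicity(
    track: CoverageTrack,
    genes,
    lag_range: tuple[int, int] = (100, 260),
    window: int = 1500,
) -> tuple[float, float]:
    """Nucleosome-repeat estimate over a gene set's mean TSS profile."""
    frame = _as_genes_frame(genes)
    if len(frame) == 0:
        raise ValueError("periodicity: empty gene set")
    if window < 2 * lag_range[1]:
        raise ValueError("window shorter than twice the maximum lag")
    prof = metagene_profile(track, frame, window=window)
    return profile_periodicity(prof.mean, track.bin_size, lag_range)


def periodicity_null_bound(
    values: np.ndarray,
    bin_size: int,
    lag_range: tuple[int, int] = (100, 260),
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """95th percentile of the amplitude under bin-shuffled profiles."""
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    amps = np.empty(n_perm)
    for i in range(n_perm):
        _, amps[i] = profile_periodicity(rng.permutation(x), bin_size, lag_range)
    return float(np.quantile(amps, 0.95))


@dataclass
class CorrectionComparison:
    table: pd.DataFrame  # rows: correction in {none, input, mock}; column rho
    best_control: str  # which control shrinks |rho| more

    def rho(self, correction: str) -> float:
        return float(self.table.set_index("correction").loc[correction, "rho"])


def _occupancy_rho(track: CoverageTrack, genes: pd.DataFrame, tr: pd.Series) -> float:
    per_kb = gene_sums(track, genes) / (
        (genes.set_index("gene_id")["end"] - genes.set_index("gene_id")["start"]) / 1e3
    )
    if per_kb.nunique() < 2:
        return 0.0
    rho = stats.spearmanr(per_kb.values, tr.reindex(per_kb.index).values).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def correction_comparison(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    mock_track: CoverageTrack,
    tr: pd.Series,
    genes,
) -> CorrectionComparison:
    """Spearman rho(gene-body signal, TR) for chip uncorrected and after
    input/mock subtraction; reports which control removes more of the
    transcription-rate coupling."""
    for t in (chip, input_track, mock_track):
        if t.norm_state != RPM:
            raise ValueError("correction_comparison requires rpm tracks")
    frame = _as_genes_frame(genes)
    rows = [
        {"correction": "none", "rho": _occupancy_rho(chip, frame, tr)},
        {
            "correction": "input",
            "rho": _occupancy_rho(subtract_control(chip, input_track), frame, tr),
        },
        {
            "correction": "mock",
            "rho": _occupancy_rho(subtract_control(chip, mock_track), frame, tr),
        },
    ]
    table = pd.DataFrame(rows)
    corrected = table[table["correction"] != "none"]
    best = corrected.loc[corrected["rho"].abs().idxmin(), "correction"]
    return CorrectionComparison(table=table, best_control=str(best))


@dataclass
class AsymmetryResult:
    per_pair: pd.DataFrame  # pair_id, up_gene, score
    mean: float
    se: float
    n_pairs: int
    n_excluded: int


def divergent_asymmetry(
    track: CoverageTrack,
    genome: SimGenome,
    up_labels: set[str] | None = None,
    window: int = 1000,
) -> AsymmetryResult:
    """Signed signal asymmetry at divergent promoters.

    For each divergent pair with exactly one Up member, integrate the track
    over the first ``window`` bp of each partner's gene body downstream of
    the shared promoter; score = (AUC toward Up - AUC toward partner) /
    (sum), so +1 means all signal over the Up gene. Pairs without exactly
    one Up label are excluded and counted.
    """
    if up_labels is None:
        up_labels = set(genome.up_genes())
    rows = []
    excluded = 0
    for pair_idx, (a_id, b_id) in enumerate(genome.divergent_pairs):
        a, b = genome.gene(a_id), genome.gene(b_id)
        if min(a.body_end, b.body_end) > max(a.body_start, b.body_start):
            raise ValueError(f"pair ({a_id},{b_id}): overlapping gene bodies")
        ups = [g for g in (a, b) if g.id in up_labels]
        if len(ups) != 1:
            excluded += 1
            continue
        up = ups[0]
        other = b if up is a else a
        aucs = {}
        for g in (up, other):
            span = min(window, g.length)
            body = pd.DataFrame(
                [
                    {
                        "gene_id": g.id,
                        "chrom": g.chrom,
                        "start": g.tss if g.strand == "+" else g.tss - span,
                        "end": g.tss + span if g.strand == "+" else g.tss,
                    }
                ]
            )
            aucs[g.id] = float(gene_sums(track, body).iloc[0])
        total = aucs[up.id] + aucs[other.id]
        score = 0.0 if total == 0 else (aucs[up.id] - aucs[other.id]) / total
        rows.append({"pair_id": pair_idx, "up_gene": up.id, "score": score})
    per_pair = pd.DataFrame(rows, columns=["pair_id", "up_gene", "score"])
    n = len(per_pair)
    mean = float(per_pair["score"].mean()) if n else float("nan")
    se = float(per_pair["score"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return AsymmetryResult(
        per_pair=per_pair, mean=mean, se=se, n_pairs=n, n_excluded=excluded
    )


def qpcr_relative_quantify(
    ct_table: pd.DataFrame,
    curve: tuple[float, float],
    targets: list[str],
    controls: list[str],
) -> pd.DataFrame:
    """Standard-curve relative quantification.

    Each Ct maps back to a template quantity via 10**((Ct - intercept) /
    slope); censored wells count as zero template. The log2 fold change of
    a target is log2(mean target quantity / mean control quantity), one
    value per (target, control, biological replicate); the reported sd is
    over biological replicates (an optional ``replicate`` column; absent
    means a single replicate, sd 0). Targets with zero quantity are
    reported as lower bounds at the single-molecule detection limit.
    """
    slope, intercept = curve
    if slope >= 0:
        raise ValueError("slope must be negative")
    if not controls:
        raise ValueError("at least one control amplicon is required")
    ct = ct_table.copy()
    if "replicate" not in ct.columns:
        ct["replicate"] = 1
    q = 10.0 ** ((ct["ct"] - intercept) / slope)
    if "censored" in ct.columns:
        q = q.where(~ct["censored"].astype(bool), 0.0)
    ct["quantity"] = q
    mean_q = (
        ct.groupby(["replicate", "amplicon_id"], sort=True)["quantity"]
        .mean()
        .unstack("amplicon_id")
    )
    rows = []
    for target in targets:
        for control in controls:
            lfcs, lower = [], False
            for _, rep in mean_q.iterrows():
                tq, cq = rep.get(target, np.nan), rep.get(control, np.nan)
                if not np.isfinite(tq) or not np.isfinite(cq) or cq <= 0:
                    continue
                if tq <= 0:
                    tq, lower = 1.0, True  # detection limit; FC is a lower bound
                lfcs.append(np.log2(tq / cq))
            if not lfcs:
                continue
            rows.append(
                {
                    "amplicon_id": target,
                    "control_id": control,
                    "log2_fold_change": float(np.mean(lfcs)),
                    "sd": float(np.std(lfcs, ddof=1)) if len(lfcs) > 1 else 0.0,
                    "n_replicates": len(lfcs),
                    "lower_bound": lower,
                }
            )
    return pd.DataFrame(rows)
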