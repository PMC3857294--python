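"""End-to-end workflow: simulate -> coverage -> diagnostics -> differential
binding, with deterministic on-disk outputs and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, coverage, diagnostics, io, peaks
from .genome import CONTROL, TREATMENT, build_toy_genome
from .simulate import SimConfig, simulate_fragments

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults mirror the analysis presets
    (10-bp bins, 1.5-kb TSS window, 75-bp extension, top-100 gene sets,
    peak stringencies 2/20, DBT q threshold 5)."""

    out_dir: str = "results/run"
    seed: int = 0
    # synthetic genome
    n_genes: int = 200
    n_divergent_pairs: int = 20
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)
    # analysis parameters
    bin_size: int = 10
    extension: int = 75
    window: int = 1500
    top_k: int = 100
    stringencies: tuple[float, float] = (2.0, 20.0)
    dbt_qmin: float = 5.0
    promoter_bp: int = 500
    # optional external inputs (simulation is used when absent)
    annotation_path: str | None = None
    tr_table_path: str | None = None
    fragment_beds: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed
        self.stringencies = tuple(self.stringencies)

    def validate(self) -> None:
        self.sim.validate()
        for name in ("annotation_path", "tr_table_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for sid, p in self.fragment_beds.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"fragment bed {sid}: {p} does not exist")

    def params_hash(self) -> str:
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "log_level"):  # not analysis parameters
            payload.pop(key, None)
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def simulate_samples(genome, config: SimConfig, conditions=(CONTROL, TREATMENT)):
    """The study's sample grid: input/mock/factor/RNAPII x two conditions."""
    samples = {}
    for kind in ("input", "mock", "tf_chip", "rnapii_chip"):
        for cond in conditions:
            samples[(kind, cond)] = simulate_fragments(genome, kind, cond, config)
    return samples


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns a dict of result paths + key numbers.

    Deterministic for a fixed config: the same config yields byte-identical
    tables. Any stage failure aborts with the stage name in the message.
    """
    config.validate()
    phash = config.params_hash()
    out = io.ensure_dir(config.out_dir)
    stage = "setup"
    try:
        stage = "simulate"
        genome = build_toy_genome(
            n_genes=config.n_genes,
            n_divergent_pairs=config.n_divergent_pairs,
            seed=config.seed,
        )
        samples = simulate_samples(genome, config.sim)
        genes = genome.genes_frame()
        sizes = genome.chrom_sizes
        io.write_gff3(genome, out / "annotation.gff3")
        io.write_tr_table(genome, out / "tr_table.tsv")
        for (kind, cond), fs in samples.items():
            io.write_bed(fs, out / f"{kind}_{cond}.bed")

        stage = "coverage"
        rpm = {
            key: coverage.normalize_rpm(
                coverage.extend_and_count(fs, sizes, config.extension, config.bin_size)
            )
            for key, fs in samples.items()
        }
        mid = {
            key: coverage.count_midpoints(fs, sizes, config.bin_size)
            for key, fs in samples.items()
        }
        io.write_wiggle(rpm[("tf_chip", TREATMENT)], out / "tf_chip_treatment.wig")
        occ = {
            key: coverage.gene_body_occupancy(
                track, genes, sample_id=f"{key[0]}_{key[1]}", condition=key[1]
            )
            for key, track in mid.items()
        }
        occ_table = pd.concat(occ.values(), ignore_index=True)
        io.write_table(occ_table, out / "gene_occupancy.tsv", phash)
        top_k = min(config.top_k, max(1, len(genes) // 2))
        high_tr = coverage.rank_top(occ[("rnapii_chip", CONTROL)], top_k)
        up_genes = coverage.rank_condition_up(
            occ[("rnapii_chip", TREATMENT)],
            occ[("rnapii_chip", CONTROL)],
            top_k,
        )
        profile = coverage.metagene_profile(
            rpm[("mock", CONTROL)], genes[genes["gene_id"].isin(high_tr)],
            window=config.window,
        )
        io.write_table(profile.to_frame(), out / "metagene_mock_highTR.tsv", phash)

        stage = "diagnostics"
        tr_ctl = genome.tr_series(CONTROL)
        reports = []
        for kind in ("input", "mock", "tf_chip", "rnapii_chip"):
            eb = diagnostics.expression_bias(
                occ[(kind, CONTROL)], tr_ctl, high_tr
            )
            period, amp = diagnostics.periodicity(
                rpm[(kind, CONTROL)], genes, window=config.window
            )
            reports.append(
                {
                    "sample_id": f"{kind}_{CONTROL}",
                    "expr_bias_ratio": eb.ratio,
                    "expr_bias_rho": eb.rho,
                    "period_bp": period,
                    "period_amplitude": amp,
                }
            )
        bias_table = pd.DataFrame(reports)
        comparison = diagnostics.correction_comparison(
            rpm[("tf_chip", CONTROL)],
            rpm[("input", CONTROL)],
            rpm[("mock", CONTROL)],
            tr_ctl,
            genes,
        )
        asym = diagnostics.divergent_asymmetry(
            rpm[("tf_chip", TREATMENT)], genome, up_labels=set(up_genes)
        )
        io.write_table(bias_table, out / "bias_report.tsv", phash)
        io.write_table(comparison.table, out / "correction_comparison.tsv", phash)
        io.write_table(asym.per_pair, out / "divergent_asymmetry.tsv", phash)

        stage = "differential_binding"
        summary, details = peaks.four_pair_comparison(
            {c: samples[("tf_chip", c)] for c in (CONTROL, TREATMENT)},
            {c: samples[("input", c)] for c in (CONTROL, TREATMENT)},
            {c: samples[("mock", c)] for c in (CONTROL, TREATMENT)},
            genes,
            sizes,
            stringencies=config.stringencies,
            dbt_qmin=config.dbt_qmin,
        )
        io.write_table(summary, out / "dbt_summary.tsv", phash)
        for (kind, label), table in details.items():
            io.write_table(table, out / f"dbts_{kind}_{label}.tsv", phash)

        stage = "manifest"
        manifest = {
            "package": "chipbias",
            "version": __version__,
            "seed": config.seed,
            "params_hash": phash,
            "n_genes": config.n_genes,
            "n_fragments": config.sim.n_fragments,
            "best_control": comparison.best_control,
            "asymmetry_mean": asym.mean,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:  # annotate which stage died
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    return {
        "out_dir": str(out),
        "params_hash": phash,
        "high_tr": high_tr,
        "up_genes": up_genes,
        "bias_report": bias_table,
        "correction": comparison,
        "asymmetry": asym,
        "dbt_summary": summary,
    }
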