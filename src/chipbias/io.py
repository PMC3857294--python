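"""Readers and writers for the interchange formats.

BED (0-based half-open) is the fragment interchange; annotation comes in as
GFF3 gene features (parsed with gffutils) or BED12, and goes out the same
way; coverage tracks export as fixedStep wiggle and TSV. All writers are
deterministic so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import SimGenome
from .simulate import FragmentSet


class BedFormatError(ValueError):
    """Malformed BED content; the message names offending line numbers."""


def read_bed(
    path,
    sample_id: str | None = None,
    sample_kind: str = "unknown",
    condition: str = "",
    chrom_sizes: dict[str, int] | None = None,
) -> FragmentSet:
    """Read a 3-6 column BED file into a FragmentSet (sorted records)."""
    path = Path(path)
    rows = []
    bad: list[tuple[int, str]] = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if not 3 <= len(parts) <= 6:
                bad.append((lineno, "expected 3-6 tab-separated columns"))
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                bad.append((lineno, "non-integer coordinates"))
                continue
            if start < 0 or start >= end:
                bad.append((lineno, f"invalid interval [{start},{end})"))
                continue
            chrom = parts[0]
            if chrom_sizes is not None:
                if chrom not in chrom_sizes or end > chrom_sizes[chrom]:
                    bad.append((lineno, "coordinates exceed declared genome"))
                    continue
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            if len(parts) >= 4:
                names.add(parts[3])
            rows.append((chrom, start, end, strand))
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:10])
        raise BedFormatError(f"{path.name}: {len(bad)} malformed line(s): {detail}")
    if not rows:
        raise BedFormatError(f"{path.name}: empty BED file")
    if sample_id is None:
        sample_id = names.pop() if len(names) == 1 else path.stem
    records = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentSet(
        sample_id=sample_id,
        sample_kind=sample_kind,
        condition=condition,
        records=records,
    ).sorted()


def write_bed(frags: FragmentSet, path) -> None:
    """Write fragments as 6-column BED (name = sample_id, score = 0)."""
    rec = frags.sorted().records
    out = pd.DataFrame(
        {
            "chrom": rec["chrom"],
            "start": rec["start"],
            "end": rec["end"],
            "name": frags.sample_id,
            "score": 0,
            "strand": rec["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _check_duplicates(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id(s) in {what}: {sorted(set(dup))[:5]}")


def read_annotation(path) -> pd.DataFrame:
    """Read GFF3 gene features or BED12 into the canonical gene table.

    Columns: gene_id, chrom, strand, start, end, tss, tes; for
    minus-strand genes TSS = interval end (transcription coordinates).
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
        rows = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            if feat.strand not in "+-":
                raise ValueError(f"gene {feat.id}: missing strand")
            start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
            rows.append(
                {
                    "gene_id": feat.attributes["ID"][0],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "start": start,
                    "end": end,
                }
            )
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
        )
        if (~frame["strand"].isin(["+", "-"])).any():
            raise ValueError("BED12 record with missing strand")
        frame = frame[["gene_id", "chrom", "strand", "start", "end"]]
    if frame.empty:
        raise ValueError(f"{path.name}: no gene records")
    _check_duplicates(frame["gene_id"], path.name)
    frame["tss"] = np.where(frame["strand"] == "+", frame["start"], frame["end"])
    frame["tes"] = np.where(frame["strand"] == "+", frame["end"], frame["start"])
    return frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )


def write_gff3(genome: SimGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in sorted(genome.genes, key=lambda g: (g.chrom, g.body_start)):
            fh.write(
                f"{g.chrom}\tchipbias\tgene\t{g.body_start + 1}\t{g.body_end}\t."
                f"\t{g.strand}\t.\tID={g.id}\n"
            )


def write_bed12(genome: SimGenome, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genome.genes, key=lambda g: (g.chrom, g.body_start)):
            fields = [
                g.chrom,
                g.body_start,
                g.body_end,
                g.id,
                0,
                g.strand,
                g.body_start,
                g.body_end,
                "0,0,0",
                1,
                g.length,
                0,
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def write_wiggle(track: CoverageTrack, path, name: str = "chipbias") -> None:
    """Export a track as fixedStep wiggle (1-based starts)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(track.data):
            fh.write(
                f"fixedStep chrom={chrom} start=1 step={track.bin_size}"
                f" span={track.bin_size}\n"
            )
            np.savetxt(fh, track.data[chrom], fmt="%.6g")


def write_track_tsv(track: CoverageTrack, path, params_hash: str = "") -> None:
    rows = []
    for chrom in sorted(track.data):
        v = track.data[chrom]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": np.arange(len(v)) * track.bin_size,
                    "value": v,
                }
            )
        )
    write_table(pd.concat(rows, ignore_index=True), path, params_hash)


def write_tr_table(genome: SimGenome, path) -> None:
    genome.tr_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tr_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "condition", "tr"}
    if not need.issubset(frame.columns):
        raise ValueError(f"TR table must have columns {sorted(need)}")
    return frame


def write_table(frame: pd.DataFrame, path, params_hash: str = "") -> None:
    """TSV writer; tables carry the parameter hash of the producing run."""
    with open(path, "w") as fh:
        if params_hash:
            fh.write(f"# params_hash={params_hash}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ensure_dir(path) -> Path:
    path = Path(path)
    os.makedirs(path, exist_ok=True)
    return path
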