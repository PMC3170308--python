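"""Readers and writers for the plain-text formats the pipeline touches.

BED is 0-based half-open; GFF is 1-based inclusive and converted on read.
Interval records are reduced to their floor midpoint. All writers emit UTF-8
tab-separated text with '.' for a missing strand.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, GenomicPoint, PositionSet, Promoter
from .profiles import ProfileTrack

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_int(text: str, what: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"{path}: line {lineno}: malformed {what} {text!r}") from None


def read_points(
    path,
    fmt: str = "bed",
    label: str = "",
    condition: str = "n/a",
    gff_coord: str = "midpoint",
) -> PositionSet:
    """Read point positions from BED, GFF, or a two-column TSV.

    Interval records (BED/GFF) are reduced to their floor midpoint. Because
    the coordinate a GFF TFBS dump reports can be either a site span or a
    site start, ``gff_coord`` selects "midpoint" (default) or "start".
    Chromosome names are passed through verbatim.
    """
    fmt = fmt.lower()
    if fmt not in ("bed", "gff", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    if gff_coord not in ("midpoint", "start"):
        raise ValueError(f"gff_coord must be 'midpoint' or 'start', got {gff_coord!r}")
    by_chrom: dict[str, list[int]] = {}
    with open(path, encoding="utf-8") as fh:
        header_skipped = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if fmt in ("bed", "gff") and line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if fmt == "tsv":
                if not header_skipped:
                    header_skipped = True
                    if fields[0].lower() in ("chrom", "chr", "chromosome"):
                        continue
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
                chrom = fields[0]
                pos = _parse_int(fields[1], "position", path, lineno)
            elif fmt == "bed":
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
                chrom = fields[0]
                start = _parse_int(fields[1], "start", path, lineno)
                end = _parse_int(fields[2], "end", path, lineno)
                if not start < end:
                    raise ValueError(f"{path}: line {lineno}: require start < end")
                pos = (start + end - 1) // 2
            else:  # gff: 1-based inclusive
                if len(fields) < 5:
                    raise ValueError(f"{path}: line {lineno}: expected >= 5 GFF columns")
                chrom = fields[0]
                start1 = _parse_int(fields[3], "start", path, lineno)
                end1 = _parse_int(fields[4], "end", path, lineno)
                if not start1 <= end1:
                    raise ValueError(f"{path}: line {lineno}: require start <= end")
                start0, end0 = start1 - 1, end1  # 0-based half-open
                pos = start0 if gff_coord == "start" else (start0 + end0 - 1) // 2
            if pos < 0:
                raise ValueError(f"{path}: line {lineno}: negative position")
            by_chrom.setdefault(chrom, []).append(pos)
    return PositionSet(by_chrom, label=label, condition=condition)


def write_points(points: PositionSet, path) -> None:
    """Write a PositionSet as single-base BED records (name = label)."""
    name = points.label or "."
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in points.chroms():
            for pos in points.positions(chrom):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\n")


def read_intervals(path) -> list[GenomicInterval]:
    """Read BED intervals (e.g. CpG islands), 0-based half-open."""
    out: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


_PROMOTER_COLUMNS = [
    "id",
    "chrom",
    "strand",
    "tss",
    "tag_positions",
    "width",
    "arch_class",
    "has_tata",
    "has_cpg",
    "gene_id",
]


def _opt_bool(val) -> bool | None:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return None
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    return str(val).strip().lower() in ("1", "true", "t", "yes")


def read_promoters(path) -> list[Promoter]:
    """Read a promoter table: TSV with header; required columns id, chrom,
    strand, tss plus tag_positions (comma-separated) and/or width."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "chrom", "strand", "tss"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "tag_positions" not in df.columns and "width" not in df.columns:
        raise ValueError(f"{path}: need a tag_positions or width column")
    promoters: list[Promoter] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        if rec["strand"] not in ("+", "-"):
            raise ValueError(f"{path}: line {lineno}: strand must be '+' or '-'")
        if rec["tss"] == "":
            raise ValueError(f"{path}: line {lineno}: tss is required")
        tags_text = rec.get("tag_positions", "") or ""
        tags = tuple(int(t) for t in tags_text.split(",") if t != "")
        width_text = rec.get("width", "") or ""
        width = int(width_text) if width_text != "" else None
        if not tags and width is None:
            raise ValueError(f"{path}: line {lineno}: neither tag_positions nor width given")
        promoters.append(
            Promoter(
                id=rec["id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss=_parse_int(rec["tss"], "tss", path, lineno),
                tag_positions=tags,
                width=width,
                arch_class=rec.get("arch_class", "") or "unclassified",
                has_tata=_opt_bool(rec.get("has_tata")),
                has_cpg=_opt_bool(rec.get("has_cpg")),
                gene_id=rec.get("gene_id") or None,
            )
        )
    return promoters


def write_promoters(promoters: Sequence[Promoter], path) -> None:
    rows = []
    for p in promoters:
        rows.append(
            {
                "id": p.id,
                "chrom": p.chrom,
                "strand": p.strand,
                "tss": p.tss,
                "tag_positions": ",".join(str(t) for t in p.tag_positions),
                "width": "" if p.width is None else p.width,
                "arch_class": p.arch_class,
                "has_tata": "" if p.has_tata is None else str(bool(p.has_tata)).lower(),
                "has_cpg": "" if p.has_cpg is None else str(bool(p.has_cpg)).lower(),
                "gene_id": p.gene_id or "",
            }
        )
    pd.DataFrame(rows, columns=_PROMOTER_COLUMNS).to_csv(path, sep="\t", index=False)


def write_profile(track: ProfileTrack, path) -> None:
    """Write a profile as a two-column TSV (offset, proportion)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("offset\tproportion\n")
        for off, val in zip(track.offsets, track.values):
            fh.write(f"{off}\t{float(val)!r}\n")


def read_profile(path, n_tss: int = 0, feature_label: str = "", class_label: str = "") -> ProfileTrack:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ProfileTrack(
        offsets=df["offset"].to_numpy(dtype=np.int64) if len(df) else np.empty(0, np.int64),
        values=df["proportion"].to_numpy(dtype=float) if len(df) else np.empty(0),
        n_tss=n_tss,
        feature_label=feature_label,
        class_label=class_label,
    )


def read_expression(path) -> pd.DataFrame:
    """Read a gene expression table: TSV with gene_id, intensity and an
    optional present column (Present/Absent call; defaults to present)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "present" not in df.columns:
        df["present"] = True
    else:
        df["present"] = df["present"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "t", "yes", "p", "present")
        )
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id entries")
    if (df["intensity"] < 0).any():
        raise ValueError(f"{path}: negative intensities")
    return df[["gene_id", "intensity", "present"]]


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
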