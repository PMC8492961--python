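"""Plain-text readers/writers: bedGraph tracks, BED annotation/dyads,
TSV tables, and key=value parameter configs."""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .fitting import SAMPLED_FIELDS, ParameterRanges
from .seqproc import SignalTrack
from .simulator import ModelParameters

__all__ = [
    "write_bedgraph", "read_bedgraph", "write_track", "read_track",
    "write_annotation_bed", "read_annotation_bed",
    "write_dyads_bed", "read_dyads_bed",
    "read_model_parameters", "read_parameter_ranges",
]


def write_bedgraph(path, chrom: str, values: np.ndarray) -> None:
    """Write one per-nt array as a run-length-merged bedGraph (0-based)."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        start = 0
        cur = values[0]
        for i in range(1, values.size + 1):
            v = values[i] if i < values.size else None
            if v != cur:
                if cur != 0:
                    fh.write(f"{chrom}\t{start}\t{i}\t{cur:g}\n")
                start = i
                cur = v


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome dense arrays."""
    out = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    for row in df.itertuples():
        if row.chrom not in out:
            raise DataError(f"unknown chromosome {row.chrom!r} in {path}")
        out[row.chrom][row.start:row.end] = row.value
    return out


def write_track(track: SignalTrack, outdir, prefix: str | None = None) -> list[Path]:
    """Write a SignalTrack as one bedGraph per chromosome strand, plus a
    chrom-sizes TSV. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or track.sample
    paths = []
    sizes = {}
    for chrom, strands in track.data.items():
        sizes[chrom] = track.chrom_length(chrom)
        for strand, arr in strands.items():
            tag = "plus" if strand == "+" else "minus"
            p = outdir / f"{prefix}.{chrom}.{tag}.bedgraph"
            write_bedgraph(p, chrom, arr)
            paths.append(p)
    sp = outdir / f"{prefix}.chrom.sizes"
    pd.Series(sizes).to_csv(sp, sep="\t", header=False)
    paths.append(sp)
    return paths


def read_track(outdir, prefix: str) -> SignalTrack:
    """Read a track written by :func:`write_track`."""
    outdir = Path(outdir)
    sizes = pd.read_csv(outdir / f"{prefix}.chrom.sizes", sep="\t",
                        header=None, index_col=0)[1].to_dict()
    data: dict[str, dict[str, np.ndarray]] = {}
    for chrom, n in sizes.items():
        data[chrom] = {}
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / f"{prefix}.{chrom}.{tag}.bedgraph"
            data[chrom][strand] = read_bedgraph(p, {chrom: int(n)})[chrom]
    return SignalTrack(prefix, data)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """BED6 + biotype column."""
    df = annotation[["chrom", "start", "end", "gene_id"]].copy()
    df["score"] = 0
    df["strand"] = annotation["strand"]
    df["biotype"] = annotation.get("biotype", "protein_coding")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "gene_id", "score", "strand", "biotype"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["length"] = df["end"] - df["start"]
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["pas"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    return df.drop(columns=["score"])


def write_dyads_bed(dyads: pd.DataFrame, path, chrom: str = "synI") -> None:
    """One record per dyad: name = gene:label, score = replicate."""
    with open(path, "w") as fh:
        for row in dyads.itertuples():
            c = getattr(row, "chrom", chrom)
            fh.write(f"{c}\t{row.pos}\t{row.pos + 1}\t"
                     f"{row.gene_id}:{row.label}\t{row.replicate}\t.\n")


def read_dyads_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    gene, label = zip(*(n.rsplit(":", 1) for n in df["name"]))
    return pd.DataFrame({"gene_id": gene, "label": label,
                         "pos": df["start"], "replicate": df["score"]})


def _parse_cfg(path) -> configparser.ConfigParser:
    cfg = configparser.ConfigParser()
    read = cfg.read(path)
    if not read:
        raise ConfigError(f"cannot read config {path}")
    return cfg


def read_model_parameters(path, section: str = "parameters") -> ModelParameters:
    """Read a ``key = value`` parameter config into ModelParameters."""
    cfg = _parse_cfg(path)
    sec = cfg[section] if cfg.has_section(section) else cfg[cfg.sections()[0]]
    kwargs = {}
    for key, value in sec.items():
        if key in ("window1_end", "gene_length", "footprint"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return ModelParameters(**kwargs)


def read_parameter_ranges(path, section: str = "ranges") -> ParameterRanges:
    """Read a ``key = min,max`` ranges config; unlisted keys keep defaults."""
    from .fitting import DEFAULT_RANGES
    cfg = _parse_cfg(path)
    sec = cfg[section] if cfg.has_section(section) else cfg[cfg.sections()[0]]
    bounds = dict(DEFAULT_RANGES)
    for key, value in sec.items():
        if key not in SAMPLED_FIELDS:
            raise ConfigError(f"unknown sweep dimension {key!r}")
        parts = [float(x) for x in value.split(",")]
        if len(parts) != 2:
            raise ConfigError(f"range for {key!r} must be 'min,max'")
        bounds[key] = (parts[0], parts[1])
    return ParameterRanges(bounds)
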