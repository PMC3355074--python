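"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are BED-style 0-based half-open everywhere.  FASTA goes through
pyfaidx on the read side; tables are tab-separated with headers except BED,
which is headerless by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import WindowGrid
from .methylome import WindowMethylome


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict, path) -> None:
    pd.DataFrame(chrom_sizes.items()).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + (names or [])
    df.columns = cols[: df.shape[1]] + [
        f"col{i}" for i in range(len(cols), df.shape[1])
    ]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = ["chrom", "start", "end"] + (columns or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    """SNP table as TSV (chrom, pos, ref, alt, ancestral)."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_snps_vcf(path) -> pd.DataFrame:
    """SNP table from a VCF; the ancestral allele comes from the AA info
    field (unknown when absent).  Only biallelic SNVs are kept; positions
    are converted to 0-based."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue
        aa = v.INFO.get("AA")
        aa = aa.upper() if isinstance(aa, str) and aa.upper() in "ACGT" else "N"
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0], aa))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ancestral"])


def read_fasta(path) -> dict:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_grid(grid: WindowGrid, path) -> None:
    df = grid.to_frame()
    df["name"] = [f"w{i}" for i in range(len(df))]
    df["score"] = (~df["excluded"]).astype(int)
    write_bed(df, path, columns=["name", "score"])


def read_grid(path, chrom_sizes: dict, window_size: int) -> WindowGrid:
    df = read_bed(path, names=["name", "score"])
    return WindowGrid(
        window_size=window_size,
        chrom_sizes=chrom_sizes,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        excluded=df["score"].to_numpy() == 0,
    )


def write_methylome(m: WindowMethylome, path) -> None:
    df = m.grid.to_frame()[["chrom", "start", "end"]]
    df["level"] = np.round(m.level, 6)
    df["events"] = m.events
    df["valid"] = m.valid.astype(int)
    write_bed(df, path, columns=["level", "events", "valid"])


def read_methylome(path, grid: WindowGrid) -> WindowMethylome:
    df = read_bed(path, names=["level", "events", "valid"])
    if len(df) != grid.n_windows:
        raise ValueError("methylome row count does not match grid")
    valid = df["valid"].to_numpy() == 1
    level = df["level"].to_numpy(dtype=float)
    level[~valid] = np.nan
    return WindowMethylome(
        grid,
        events=df["events"].to_numpy(dtype=np.int64),
        meth_events=np.zeros(grid.n_windows, dtype=np.int64),
        valid=valid,
        fixed_level=level,
    )


def write_dp_regions(df: pd.DataFrame, path) -> None:
    write_bed(df, path)


def write_pairs(pairs, path) -> None:
    rows = [
        (
            p.a.chrom, p.a.start, p.a.end,
            p.b.chrom, p.b.start, p.b.end,
            p.orientation, round(p.score, 3), round(p.density, 5),
            round(p.identity, 5) if p.identity == p.identity else "NA",
        )
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
            "orientation", "score", "density", "identity",
        ],
    ).to_csv(path, sep="\t", index=False)
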