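"""Plain-text interchange: TSV matrices, sample sheets, pair lists, BED."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .tmt import IntensityTable


def write_intensity_table(table: IntensityTable, outdir: str | Path, prefix: str = "ipms") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.values.rename_axis("protein").to_csv(outdir / f"{prefix}_intensities.tsv", sep="\t")
    table.samples.rename_axis("sample").to_csv(outdir / f"{prefix}_samples.tsv", sep="\t")
    if table.top3 is not None:
        table.top3.rename_axis("protein").to_csv(outdir / f"{prefix}_top3.tsv", sep="\t")


def read_intensity_table(outdir: str | Path, prefix: str = "ipms") -> IntensityTable:
    outdir = Path(outdir)
    values = pd.read_csv(outdir / f"{prefix}_intensities.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(outdir / f"{prefix}_samples.tsv", sep="\t", index_col=0)
    top3_path = outdir / f"{prefix}_top3.tsv"
    top3 = pd.read_csv(top3_path, sep="\t", index_col=0) if top3_path.exists() else None
    return IntensityTable(values=values, samples=samples, top3=top3)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "protein") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pairs(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_bed(frames: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    """One 6-column BED per RBP (0-based half-open windows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rbp, df in frames.items():
        df.to_csv(outdir / f"{rbp}.bed", sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def read_step_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_step_table(steps: Mapping[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("protein\tstep\n")
        for protein, step in sorted(steps.items()):
            fh.write(f"{protein}\t{step}\n")
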