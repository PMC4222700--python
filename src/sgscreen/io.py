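"""File-format glue: 16-bit TIFFs, layout/segment TSVs and FASTA.

Image files are single-channel 16-bit grayscale TIFFs named
``<strain>_<condition>_<rep>_<channel>.tif``; tables are tab-separated;
sequences go through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "field_filename",
    "save_field",
    "load_image",
    "write_tsv",
    "read_tsv",
    "write_fasta",
    "read_fasta",
]


def field_filename(strain: str, condition: str, replicate: int, channel: str) -> str:
    safe = lambda s: str(s).replace(" ", "-").replace("/", "-")
    return f"{safe(strain)}_{safe(condition)}_{replicate}_{safe(channel)}.tif"


def save_field(
    out_dir: Path | str,
    strain: str,
    condition: str,
    replicate: int,
    images: Mapping[str, np.ndarray],
) -> list[Path]:
    """Write one TIFF per channel; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, img in images.items():
        p = out_dir / field_filename(strain, condition, replicate, channel)
        tifffile.imwrite(p, np.asarray(img, dtype=np.uint16))
        paths.append(p)
    return paths


def load_image(path: Path | str) -> np.ndarray:
    return tifffile.imread(path)


def write_tsv(df: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(seqs: Mapping[str, str], path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(s), id=pid, description="") for pid, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
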