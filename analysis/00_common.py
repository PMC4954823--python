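"""Shared paths and loaders for the numbered analysis scripts.

Every script reads only files produced by earlier scripts (or generates
them, for 01), so the sequence is re-runnable from any intermediate.
"""

import os

import pandas as pd

from ploidymeth.genome import SAMPLES, GenomeAnnotation, ReadSet

HERE = os.path.dirname(os.path.abspath(__file__))
DATA = os.path.join(HERE, "..", "results", "analysis", "data")
OUT = os.path.join(HERE, "..", "results", "analysis")
SEED = 1


def ensure_dirs() -> None:
    os.makedirs(DATA, exist_ok=True)
    os.makedirs(OUT, exist_ok=True)


def load_annotation() -> GenomeAnnotation:
    return GenomeAnnotation.from_gff3(os.path.join(DATA, "genome.gff3"))


def load_reads() -> dict[str, ReadSet]:
    return {
        s: ReadSet.from_bed(os.path.join(DATA, f"reads_{s}.bed"), s)
        for s in SAMPLES
    }


def load_tsv(name: str, **kw) -> pd.DataFrame:
    return pd.read_csv(os.path.join(DATA, name), sep="\t", **kw)


def write_out(df: pd.DataFrame, name: str, index: bool = False) -> None:
    df.to_csv(os.path.join(OUT, name), sep="\t", index=index,
              float_format="%.6g")
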