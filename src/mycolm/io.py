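"""Readers and writers for the plain-text genomics formats used here.

All internal coordinates are 0-based half-open; GTF is converted to/from its
native 1-based inclusive convention at the boundary.  The files handled are
small, package-generated fixtures, so parsing is pandas-based.
"""

from __future__ import annotations

import io as _io
import re

import numpy as np
import pandas as pd

GTF_COLUMNS = ["seqname", "source", "feature", "start", "end",
               "score", "strand", "frame", "attributes"]

PAF_COLUMNS = ["qname", "qlen", "qstart", "qend", "strand",
               "tname", "tlen", "tstart", "tend", "matches", "block_len", "mapq"]


def write_fasta(records: dict[str, str], path=None, width: int = 60) -> str:
    """Write a FASTA string from ``{name: sequence}``; optionally to ``path``."""
    buf = _io.StringIO()
    for name, seq in records.items():
        buf.write(f">{name}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i:i + width] + "\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_fasta(source) -> dict[str, str]:
    """Read FASTA from a path or raw text into ``{name: sequence}``.

    Soft-masking (lowercase) is preserved.
    """
    from Bio import SeqIO

    if "\n" in str(source) or str(source).startswith(">"):
        handle = _io.StringIO(str(source))
    else:
        handle = source
    records = {r.id: str(r.seq) for r in SeqIO.parse(handle, "fasta")}
    if not records:
        raise ValueError("no FASTA records parsed")
    return records


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(source) -> pd.DataFrame:
    """Parse GTF into a DataFrame with 0-based half-open start/end columns."""
    if hasattr(source, "read") or "\n" in str(source):
        handle = _io.StringIO(str(source))
    else:
        handle = source
    df = pd.read_csv(handle, sep="\t", comment="#", header=None,
                     names=GTF_COLUMNS, dtype={"seqname": str})
    df["start"] = df["start"].astype(int) - 1      # to 0-based half-open
    df["end"] = df["end"].astype(int)
    for key in ("gene_id", "transcript_id"):
        df[key] = df["attributes"].map(
            lambda s, k=key: dict(_ATTR_RE.findall(s)).get(k))
    return df


def format_gtf(rows) -> str:
    """Format rows of (seqname, source, feature, start0, end0, strand, attrs)."""
    lines = []
    for seqname, source, feature, start, end, strand, attrs in rows:
        lines.append("\t".join([
            seqname, source, feature, str(start + 1), str(end),
            ".", strand, ".", attrs]))
    return "\n".join(lines) + "\n"


def read_bed(source) -> pd.DataFrame:
    if hasattr(source, "read") or "\n" in str(source):
        source = _io.StringIO(str(source))
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][:df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_bed(df: pd.DataFrame, path=None) -> str:
    text = df.to_csv(sep="\t", header=False, index=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_paf(source) -> pd.DataFrame:
    """Parse PAF; requires at least the 12 mandatory fields per line."""
    if hasattr(source, "read") or "\n" in str(source) or str(source) == "":
        lines = str(source).splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    rows = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"PAF line {ln} has {len(fields)} fields; "
                             "12 are required")
        rows.append(fields[:12])
    df = pd.DataFrame(rows, columns=PAF_COLUMNS)
    for col in ("qlen", "qstart", "qend", "tlen", "tstart", "tend",
                "matches", "block_len", "mapq"):
        df[col] = df[col].astype(int)
    return df


def write_bedgraph(chrom_values: dict[str, np.ndarray], path=None) -> str:
    """Write per-base values as run-length-collapsed bedGraph."""
    buf = _io.StringIO()
    for chrom, values in chrom_values.items():
        values = np.asarray(values)
        if values.size == 0:
            continue
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [values.size]])
        for s, e in zip(starts, ends):
            buf.write(f"{chrom}\t{s}\t{e}\t{values[s]:g}\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_bedgraph(source, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand bedGraph back to per-base arrays (missing intervals -> NaN)."""
    if hasattr(source, "read") or "\n" in str(source):
        source = _io.StringIO(str(source))
    df = pd.read_csv(source, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    out = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for row in df.itertuples(index=False):
        out[row.chrom][row.start:row.end] = row.value
    return out


# ---------------------------------------------------------------------------
# sequence helpers

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_onehot(seq: str) -> np.ndarray:
    """(L, 4) one-hot; soft-masking is ignored, N rows are all-zero."""
    arr = np.zeros((len(seq), 4))
    idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for base, col in BASE_INDEX.items():
        arr[idx == ord(base), col] = 1.0
    return arr


def onehot_to_seq(arr: np.ndarray) -> str:
    out = []
    for row in arr:
        out.append(BASES[int(np.argmax(row))] if row.sum() > 0 else "N")
    return "".join(out)
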