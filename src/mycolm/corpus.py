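"""Training-corpus construction: contigs -> filtered, masked, fold-assigned windows.

Reproduces the preprocessing rules of the modelling pipeline: minimum contig
length for the language-model corpus, end-trimming and mask-splitting for the
supervised corpus, fixed-stride windowing, the strict >7% repeat-content
filter, PAF-based homology removal (coverage = matches / query length,
identity = matches / block length), exon/repeat loss-weight masks with a 2-bp
exon "chew", unmappability clipping, and nucleotide-balanced fold assignment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio

LM_MIN_CONTIG = 32_768
SUPERVISED_TRIM = 1_024
SUPERVISED_MIN_PIECE = 16_384
SUPERVISED_MAX_PIECE = 786_432
DEFAULT_WINDOW = 16_384
LM_STRIDE = 4_096
SUPERVISED_STRIDE = 6_165
REGION_WEIGHT = 0.1


@dataclass
class Contig:
    """A (piece of a) contig with its offset in genome coordinates."""

    species: int
    chrom: str
    offset: int
    seq: str

    def __len__(self):
        return len(self.seq)


@dataclass
class GenomeWindow:
    """A fixed-length window with per-position masks and loss weights."""

    species: int
    chrom: str
    start: int
    end: int
    seq: str
    exon_mask: np.ndarray = None
    repeat_mask: np.ndarray = None
    unmap_mask: np.ndarray = None
    loss_weights: np.ndarray = None

    def __post_init__(self):
        L = self.end - self.start
        if len(self.seq) != L:
            raise ValueError("sequence length does not match coordinates")
        if self.repeat_mask is None:
            self.repeat_mask = np.frombuffer(
                self.seq.encode(), dtype=np.uint8) >= ord("a")
        for name in ("exon_mask", "unmap_mask"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(L, dtype=bool))
        if self.loss_weights is None:
            self.loss_weights = np.ones(L)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def window_id(self) -> str:
        return f"s{self.species}:{self.chrom}:{self.start}-{self.end}"

    def onehot(self) -> np.ndarray:
        return mio.seq_to_onehot(self.seq)

    @property
    def repeat_fraction(self) -> float:
        return float(self.repeat_mask.mean())

    @property
    def unmap_fraction(self) -> float:
        return float(self.unmap_mask.mean())


# ---------------------------------------------------------------------------
# contig preparation

def prepare_contigs(fasta, mode: str, mask_bed: pd.DataFrame | None = None,
                    species: int = 0, lm_min_contig: int = LM_MIN_CONTIG,
                    trim: int = SUPERVISED_TRIM,
                    min_piece: int = SUPERVISED_MIN_PIECE,
                    max_piece: int = SUPERVISED_MAX_PIECE) -> list[Contig]:
    """Prepare contigs for windowing.

    ``lm`` mode drops contigs shorter than ``lm_min_contig``.  ``supervised``
    mode splits contigs at mask intervals (assembly gaps / hypervariable
    regions), trims ``trim`` bp from each piece end, drops pieces shorter
    than ``min_piece`` and recursively halves pieces longer than ``max_piece``.
    """
    if mode not in ("lm", "supervised"):
        raise ValueError(f"unknown mode {mode!r}")
    records = fasta if isinstance(fasta, dict) else mio.read_fasta(fasta)
    out: list[Contig] = []
    for chrom, seq in records.items():
        if mode == "lm":
            if len(seq) >= lm_min_contig:
                out.append(Contig(species, chrom, 0, seq))
            continue
        pieces = _split_at_masks(chrom, seq, mask_bed)
        for off, piece in pieces:
            trimmed = piece[trim:len(piece) - trim]
            if len(trimmed) < min_piece:
                continue
            out.extend(_halve(species, chrom, off + trim, trimmed, max_piece))
    return out


def _split_at_masks(chrom, seq, mask_bed):
    if mask_bed is None or len(mask_bed) == 0:
        return [(0, seq)]
    ivals = mask_bed[mask_bed["chrom"] == chrom][["start", "end"]] \
        .sort_values("start").to_numpy()
    pieces, cursor = [], 0
    for s, e in ivals:
        if s > cursor:
            pieces.append((cursor, seq[cursor:s]))
        cursor = max(cursor, e)
    if cursor < len(seq):
        pieces.append((cursor, seq[cursor:]))
    return pieces


def _halve(species, chrom, offset, seq, max_piece):
    if len(seq) <= max_piece:
        return [Contig(species, chrom, offset, seq)]
    mid = len(seq) // 2
    return (_halve(species, chrom, offset, seq[:mid], max_piece)
            + _halve(species, chrom, offset + mid, seq[mid:], max_piece))


def segment_windows(contigs: list[Contig], window: int = DEFAULT_WINDOW,
                    stride: int = LM_STRIDE) -> list[GenomeWindow]:
    """Emit fully contained windows at starts 0, stride, 2*stride, ..."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = []
    for contig in contigs:
        for rel in range(0, len(contig) - window + 1, stride):
            start = contig.offset + rel
            out.append(GenomeWindow(contig.species, contig.chrom,
                                    start, start + window,
                                    contig.seq[rel:rel + window]))
    return out


# ---------------------------------------------------------------------------
# filters

def repeat_fraction_filter(windows, max_frac: float = 0.07):
    """Remove windows whose soft-masked fraction strictly exceeds ``max_frac``."""
    return [w for w in windows if w.repeat_fraction <= max_frac]


def build_position_masks(window: GenomeWindow, gtf: pd.DataFrame,
                         region_weight: float = REGION_WEIGHT,
                         chew: int = 2) -> GenomeWindow:
    """Fill exon mask (chewed by ``chew`` bp per side) and loss weights.

    Weights are assignments, not products: a position that is both exonic
    and repetitive gets ``region_weight`` once.  N bases get weight 0.
    """
    L = window.length
    exon_mask = np.zeros(L, dtype=bool)
    exons = gtf[(gtf["feature"] == "exon") & (gtf["seqname"] == window.chrom)]
    for _, row in exons.iterrows():
        s = max(int(row["start"]) + chew, window.start)
        e = min(int(row["end"]) - chew, window.end)
        if e > s:
            exon_mask[s - window.start:e - window.start] = True
    window.exon_mask = exon_mask
    weights = np.ones(L)
    weights[exon_mask | window.repeat_mask] = region_weight
    n_mask = ~np.isin(np.frombuffer(window.seq.upper().encode(), dtype=np.uint8),
                      np.frombuffer(b"ACGT", dtype=np.uint8))
    weights[n_mask] = 0.0
    window.loss_weights = weights
    return window


def filter_homologous_windows(windows, paf: pd.DataFrame,
                              cov_thr: float = 0.05, id_thr: float = 0.30):
    """Split windows into (kept, removed) by PAF homology evidence.

    A window is removed iff ANY of its alignments has
    coverage = matches/query_length >= ``cov_thr`` AND
    identity = matches/block_length >= ``id_thr``.
    """
    flagged = set()
    if len(paf):
        cov = paf["matches"] / paf["qlen"]
        ident = paf["matches"] / paf["block_len"]
        hit = paf.loc[(cov >= cov_thr) & (ident >= id_thr), "qname"]
        flagged = set(hit)
    kept = [w for w in windows if w.window_id not in flagged]
    removed = [w for w in windows if w.window_id in flagged]
    return kept, removed


@dataclass
class SplitAssignment:
    """window id -> fold index, plus the retained windows themselves."""

    folds: dict[str, int]
    windows: list[GenomeWindow] = field(default_factory=list)

    def fold_of(self, window) -> int:
        return self.folds[window.window_id]


def assign_folds(windows, n_folds: int = 8, umap_clip: float = 0.5,
                 seed: int = 0) -> SplitAssignment:
    """Greedy nucleotide-balanced fold assignment after unmappability clipping.

    Windows with unmappable fraction > ``umap_clip`` are removed; the rest
    are shuffled (seeded) and each is assigned to the fold with the smallest
    running nucleotide total.
    """
    retained = [w for w in windows if w.unmap_fraction <= umap_clip]
    if n_folds > len(retained):
        raise ValueError(f"{n_folds} folds requested for "
                         f"{len(retained)} retained windows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(retained))
    totals = np.zeros(n_folds, dtype=np.int64)
    folds: dict[str, int] = {}
    for i in order:
        w = retained[i]
        fold = int(np.argmin(totals))
        folds[w.window_id] = fold
        totals[fold] += w.length
    return SplitAssignment(folds=folds, windows=retained)


# ---------------------------------------------------------------------------
# shard serialization (HDF5 with zlib-compressed payloads)

def write_shards(windows, directory, shard_size: int = 32) -> list[str]:
    """Write windows to HDF5 shards of ``shard_size`` examples each.

    Stores sequence (bytes), masks, weights, coordinates and species, plus a
    per-shard adler32 checksum of the concatenated sequences.
    """
    import h5py
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for si in range(0, len(windows), shard_size):
        chunk = windows[si:si + shard_size]
        path = directory / f"shard_{si // shard_size:04d}.h5"
        with h5py.File(path, "w") as fh:
            seqs = [w.seq.encode() for w in chunk]
            fh.create_dataset("seq", data=seqs, compression="gzip")
            fh.create_dataset("species", data=[w.species for w in chunk])
            fh.create_dataset("chrom", data=[w.chrom.encode() for w in chunk])
            fh.create_dataset("start", data=[w.start for w in chunk])
            fh.create_dataset("end", data=[w.end for w in chunk])
            for name in ("exon_mask", "repeat_mask", "unmap_mask"):
                fh.create_dataset(
                    name, data=np.stack([getattr(w, name) for w in chunk]),
                    compression="gzip")
            fh.create_dataset(
                "loss_weights", data=np.stack([w.loss_weights for w in chunk]),
                compression="gzip")
            fh.attrs["checksum"] = zlib.adler32(b"".join(seqs))
        paths.append(str(path))
    return paths


def read_shards(paths) -> list[GenomeWindow]:
    """Read windows back from shards, verifying checksums."""
    import h5py

    out = []
    for path in paths:
        with h5py.File(path, "r") as fh:
            seqs = [s.tobytes() if isinstance(s, np.void) else bytes(s)
                    for s in fh["seq"][:]]
            if zlib.adler32(b"".join(seqs)) != fh.attrs["checksum"]:
                raise IOError(f"checksum failure in shard {path}")
            for i, raw in enumerate(seqs):
                out.append(GenomeWindow(
                    species=int(fh["species"][i]),
                    chrom=fh["chrom"][i].decode(),
                    start=int(fh["start"][i]), end=int(fh["end"][i]),
                    seq=raw.decode(),
                    exon_mask=fh["exon_mask"][i].astype(bool),
                    repeat_mask=fh["repeat_mask"][i].astype(bool),
                    unmap_mask=fh["unmap_mask"][i].astype(bool),
                    loss_weights=fh["loss_weights"][i]))
    return out


def split_train_eval(windows, eval_species: int = 0, val_chroms=(), test_chroms=()):
    """Chromosome-based train/valid/test split.

    Validation and test pools contain only windows of ``eval_species`` on the
    designated chromosomes; the training pool spans all species minus those
    chromosomes of the evaluation species.
    """
    val = [w for w in windows if w.species == eval_species
           and w.chrom in val_chroms]
    test = [w for w in windows if w.species == eval_species
            and w.chrom in test_chroms]
    train = [w for w in windows
             if not (w.species == eval_species
                     and w.chrom in set(val_chroms) | set(test_chroms))]
    return train, val, test
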