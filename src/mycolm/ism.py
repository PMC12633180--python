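"""In-silico saturation mutagenesis: maps, logos, time courses, distances.

Every single-base substitution within a promoter region (default -450..+50
around the TSS, on the gene's strand) is scored by the log2 fold-change it
induces in predicted exonic coverage.  Scores averaged over a track set
give a position x nucleotide map; zero-mean normalization per position and
projection onto the reference base gives the logo (a loss-of-function site
reads positive).  Time-course maps subtract the pre-induction (T0) map, and
flattened maps yield pairwise Euclidean distance matrices over timepoints.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as mio

ISM_REGION = (-450, 50)
BASES = "ACGT"


@dataclass
class SaturationVariant:
    offset: int          # position within the region, 0-based, 5'->3' on gene strand
    genome_pos: int      # 0-based genome coordinate
    ref: str
    alt: str


def enumerate_saturation_variants(seq_by_pos, tss: int, strand: str,
                                  region: tuple[int, int] = ISM_REGION
                                  ) -> list[SaturationVariant]:
    """All 3 x |region| single-base substitutions of a promoter region.

    ``seq_by_pos`` maps genome coordinates to reference bases (any indexable
    sequence).  The region is defined on the gene's strand: offsets run
    5'->3', so for a minus-strand gene the genomic coordinates mirror around
    the TSS.  Positions with N reference bases are skipped.
    """
    lo, hi = region
    variants = []
    for offset in range(hi - lo):
        rel = lo + offset
        pos = tss + rel if strand == "+" else tss - 1 - rel
        if pos < 0 or pos >= len(seq_by_pos):
            continue
        ref = seq_by_pos[pos].upper()
        if ref not in BASES:
            continue
        for alt in BASES:
            if alt != ref:
                variants.append(SaturationVariant(offset, pos, ref, alt))
    return variants


def variant_log2fc(pred_ref_bins, pred_alt_bins, bin_idx) -> float:
    """log2(sum_alt + 1) - log2(sum_ref + 1) over the gene's bin set."""
    bin_idx = np.asarray(bin_idx)
    if bin_idx.size == 0:
        raise ValueError("empty bin set")
    ref = np.asarray(pred_ref_bins, float)[bin_idx].sum()
    alt = np.asarray(pred_alt_bins, float)[bin_idx].sum()
    return float(np.log2(alt + 1.0) - np.log2(ref + 1.0))


def ism_scores(model, seq: str, window_start: int, tss: int, strand: str,
               bin_idx, region=ISM_REGION, species: int = 0,
               batch_size: int = 24, positions=None) -> np.ndarray:
    """(M, 4, n_tracks) pooled log2FC scores for a promoter region.

    The reference-base entry is 0 by construction (no mutation).  Scoring
    uses a single forward pass per mutant (shift {0}, forward strand) for
    speed; strand/shift ensembling is available upstream via
    ``coverage.ensemble_predict``.  With ``positions`` (genome
    coordinates) only those columns of the region are mutated — rows sum
    and normalize per position, so restricting columns leaves the scored
    columns' values unchanged.
    """
    from .lm_core import encode_input

    L = model.config.L
    variants = enumerate_saturation_variants(
        _GenomeView(seq, window_start), tss, strand, region)
    if positions is not None:
        wanted = set(int(p) for p in positions)
        variants = [v for v in variants if v.genome_pos in wanted]
    base_onehot = mio.seq_to_onehot(seq[:L])
    n_sp = model.config.n_species
    ref_pred = model.predict(
        encode_input(base_onehot, species, n_sp)[None])[0]
    n_tracks = ref_pred.shape[1]
    bin_idx = np.asarray(bin_idx)
    ref_sum = ref_pred[bin_idx].sum(axis=0)

    M = region[1] - region[0]
    scores = np.zeros((M, 4, n_tracks))
    inputs, meta = [], []
    for v in variants:
        local = v.genome_pos - window_start
        if not 0 <= local < L:
            continue
        mut = base_onehot.copy()
        mut[local] = 0.0
        mut[local, BASES.index(v.alt)] = 1.0
        inputs.append(encode_input(mut, species, n_sp))
        meta.append(v)
    for i in range(0, len(inputs), batch_size):
        preds = model.predict(np.stack(inputs[i:i + batch_size]))
        for v, pred in zip(meta[i:i + batch_size], preds):
            alt_sum = pred[bin_idx].sum(axis=0)
            scores[v.offset, BASES.index(v.alt)] = (
                np.log2(alt_sum + 1.0) - np.log2(ref_sum + 1.0))
    return scores


class _GenomeView:
    """Expose a window sequence as genome-coordinate indexable."""

    def __init__(self, seq, start):
        self.seq, self.start = seq, start

    def __len__(self):
        return self.start + len(self.seq)

    def __getitem__(self, pos):
        rel = pos - self.start
        if rel < 0 or rel >= len(self.seq):
            return "N"
        return self.seq[rel]


# ---------------------------------------------------------------------------
# maps and logos

@dataclass
class IsmMap:
    mean_map: np.ndarray     # M_{i,n}, track-set average
    zeroed: np.ndarray       # M-tilde, zero mean per position
    logo: np.ndarray         # per-position reference-base projection


def build_ism_map(scores: np.ndarray, track_idx, ref_onehot: np.ndarray
                  ) -> IsmMap:
    """Average over the track set, zero-mean per position, project on ref.

    ``scores`` is (M, 4, n_tracks); ``ref_onehot`` is (M, 4).  With the
    reference entry pinned at 0, a position where every mutation hurts gets
    a positive logo value (loss-of-function reads positive).
    """
    track_idx = np.asarray(track_idx)
    if track_idx.size == 0:
        raise ValueError("empty track set")
    mean_map = scores[:, :, track_idx].mean(axis=2)
    zeroed = mean_map - mean_map.mean(axis=1, keepdims=True)
    logo = (zeroed * ref_onehot).sum(axis=1)
    return IsmMap(mean_map=mean_map, zeroed=zeroed, logo=logo)


_TIME_RE = re.compile(r"T_?(\d+)")


def parse_timepoint(track_name: str) -> int:
    m = _TIME_RE.search(track_name)
    if m is None:
        raise ValueError(f"no timepoint label in track name {track_name!r}; "
                         "expected e.g. T0_rep1 or T_15_rep2")
    return int(m.group(1))


def timepoint_groups(track_names) -> dict[int, np.ndarray]:
    """Group track indices by the timepoint parsed from their names."""
    groups: dict[int, list[int]] = {}
    for j, name in enumerate(track_names):
        groups.setdefault(parse_timepoint(name), []).append(j)
    return {t: np.asarray(idx) for t, idx in sorted(groups.items())}


def delta_ism_timecourse(scores: np.ndarray, track_names,
                         ref_onehot: np.ndarray) -> dict[int, np.ndarray]:
    """Baseline-corrected, zero-mean-normalized per-timepoint maps.

    Returns {timepoint: delta map (M, 4)} where delta = M(T_t) - M(T0),
    zero-mean normalized per position.  T0 must be present.
    """
    groups = timepoint_groups(track_names)
    if 0 not in groups:
        raise ValueError(f"missing T0 tracks; found timepoints {list(groups)}")
    maps = {t: build_ism_map(scores, idx, ref_onehot).mean_map
            for t, idx in groups.items()}
    out = {}
    for t, m in maps.items():
        delta = m - maps[0]
        out[t] = delta - delta.mean(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# distances and trajectories

def ism_distance_matrix(maps_per_window: list[dict[int, np.ndarray]]):
    """Per-window and window-averaged Euclidean distances between timepoints.

    Each element of ``maps_per_window`` maps timepoint -> (M, 4) normalized
    map; all windows must share the same timepoint set.  Returns
    (list of per-window T x T matrices, mean matrix, sorted timepoints).
    """
    times = sorted(maps_per_window[0])
    for maps in maps_per_window:
        if sorted(maps) != times:
            raise ValueError("windows disagree on the timepoint set")
    mats = []
    for maps in maps_per_window:
        vecs = np.stack([maps[t].ravel() for t in times])
        diff = vecs[:, None, :] - vecs[None, :, :]
        mats.append(np.sqrt((diff ** 2).sum(axis=2)))
    return mats, np.mean(mats, axis=0), times


@dataclass
class GeneCoverageTrajectory:
    gene_id: str
    rpm_obs: dict[int, float]      # timepoint -> replicate-mean RPM
    rpm_pred: dict[int, float]


def rpm(cov: float, libsize: float) -> float:
    if libsize <= 0:
        raise ValueError("library size must be positive")
    return cov / libsize * 1e6


def rpm_trajectories(obs_bins, pred_bins, gene_map, libsizes,
                     track_names) -> list[GeneCoverageTrajectory]:
    """Replicate-averaged RPM trajectories per gene, observed and predicted.

    ``obs_bins``/``pred_bins`` are (n_bins, n_tracks); ``libsizes`` aligns
    with ``track_names``, whose labels carry the timepoints.
    """
    obs = np.asarray(obs_bins, float)
    pred = np.asarray(pred_bins, float)
    libsizes = np.asarray(libsizes, float)
    groups = timepoint_groups(track_names)
    out = []
    for g, idx in gene_map.items():
        cov_o = obs[idx].sum(axis=0)
        cov_p = pred[idx].sum(axis=0)
        rpm_o = cov_o / libsizes * 1e6
        rpm_p = cov_p / libsizes * 1e6
        out.append(GeneCoverageTrajectory(
            gene_id=g,
            rpm_obs={t: float(rpm_o[j].mean()) for t, j in groups.items()},
            rpm_pred={t: float(rpm_p[j].mean()) for t, j in groups.items()}))
    return out
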