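"""From PPMs to information-content logos, motif-discovery inputs, and TSS maps.

The information-content transform pseudocounts and renormalizes each PPM
row, measures per-position Shannon entropy in bits, and scales base
probabilities by the information content 2 - H so that letter heights sum
to the column information.  The log-odds transform prepares attributions
for seqlet-clustering tools (TF-MoDISco-style): each probability is
compared against the per-position mean background.  Seqlet hits coming
back from such a tool are mapped to genome coordinates and to their
nearest transcription start site.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IcmMatrix:
    """Information-content decomposition of a PPM."""

    p_tilde: np.ndarray      # pseudocounted probabilities
    p_bar: np.ndarray        # renormalized, rows sum to 1
    entropy: np.ndarray      # H_j, bits
    info: np.ndarray         # C_j = 2 - H_j, bits
    heights: np.ndarray      # h_{j,n} = p_bar * C_j
    eps: float


def ppm_to_icm(ppm: np.ndarray, eps: float = 1e-4) -> IcmMatrix:
    """Pseudocount, renormalize, and convert to information content (base 2)."""
    ppm = np.asarray(ppm, dtype=float)
    if np.any(ppm < 0):
        raise ValueError("PPM rows must be nonnegative")
    p_tilde = ppm + eps
    p_bar = p_tilde / p_tilde.sum(axis=-1, keepdims=True)
    entropy = -(p_bar * np.log2(p_bar)).sum(axis=-1)
    info = 2.0 - entropy
    heights = p_bar * info[..., None]
    return IcmMatrix(p_tilde=p_tilde, p_bar=p_bar, entropy=entropy,
                     info=info, heights=heights, eps=eps)


def modisco_logodds(ppm: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Log-odds attribution vs the per-position mean background (natural log).

    background p_bar_j = mean_n (p_{n,j} + eps);
    Delta_{n,j} = (p_{n,j} + eps) * ln((p_{n,j} + eps) / p_bar_j).
    """
    ppm = np.asarray(ppm, dtype=float)
    adjusted = ppm + eps
    background = adjusted.mean(axis=-1, keepdims=True)
    return adjusted * np.log(adjusted / background)


def modisco_bundle(ppms, onehots) -> dict[str, np.ndarray]:
    """Package truth/attribution arrays in the (samples, positions, 4) layout
    a seqlet-clustering tool expects."""
    x_true = np.stack([np.asarray(o, dtype=float) for o in onehots])
    x_pred = np.stack([modisco_logodds(p) for p in ppms])
    return {"x_true": x_true, "x_pred": x_pred}


# ---------------------------------------------------------------------------
# seqlet mapping and TSS context

@dataclass
class SeqletHit:
    pattern: str
    window_id: str
    offset_start: int
    offset_end: int
    strand: str
    chrom: str
    start: int
    end: int
    tss_distance: int | None = None


class TssIndex:
    """Sorted per-chromosome TSS positions with strand, for nearest lookup.

    The TSS is the 5' end of each transcript: the start coordinate on '+',
    the end coordinate on '-'.  Nearest is by absolute distance with ties
    broken toward the upstream side; signed distances are negative upstream
    of the TSS with respect to the TSS strand.
    """

    def __init__(self, gtf: pd.DataFrame):
        tx = gtf[gtf["feature"] == "transcript"]
        if tx.empty:
            tx = gtf[gtf["feature"] == "gene"]
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in tx.groupby("seqname"):
            tss = np.where(grp["strand"] == "+", grp["start"], grp["end"])
            strands = grp["strand"].to_numpy()
            order = np.argsort(tss, kind="stable")
            self._by_chrom[chrom] = (tss.astype(int)[order], strands[order])

    def chroms(self):
        return list(self._by_chrom)

    def nearest(self, chrom: str, pos: int):
        """Return (tss, strand, signed distance) of the nearest TSS."""
        if chrom not in self._by_chrom:
            return None
        tss, strands = self._by_chrom[chrom]
        i = bisect_left(tss.tolist(), pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d_signed = pos - int(tss[j]) if strands[j] == "+" \
                    else int(tss[j]) - pos
                cand = (abs(int(pos - tss[j])), d_signed >= 0, j, d_signed)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            return None
        j, d_signed = best[2], best[3]
        return int(tss[j]), strands[j], int(d_signed)


def map_seqlets(seqlets: pd.DataFrame, window_coords: pd.DataFrame,
                gtf: pd.DataFrame) -> list[SeqletHit]:
    """Lift seqlet offsets to genome coordinates and annotate TSS distance.

    ``seqlets`` needs columns pattern, window_id, start, end, strand;
    ``window_coords`` needs window_id, chrom, start.
    """
    coords = window_coords.set_index("window_id")
    index = TssIndex(gtf)
    hits = []
    for row in seqlets.itertuples(index=False):
        if row.window_id not in coords.index:
            raise KeyError(f"unknown window id {row.window_id!r}")
        w = coords.loc[row.window_id]
        gstart = int(w["start"]) + int(row.start)
        gend = int(w["start"]) + int(row.end)
        hit = SeqletHit(pattern=row.pattern, window_id=row.window_id,
                        offset_start=int(row.start), offset_end=int(row.end),
                        strand=row.strand, chrom=w["chrom"],
                        start=gstart, end=gend)
        near = index.nearest(w["chrom"], (gstart + gend) // 2)
        if near is not None:
            hit.tss_distance = near[2]
        hits.append(hit)
    return hits


def tss_enrichment(hits, gtf: pd.DataFrame, chrom_lengths: dict[str, int],
                   window: int = 2_500, bin_width: int = 50, seed: int = 0):
    """Observed vs background histograms of TSS distances within +/- window.

    The background draws one uniformly placed same-chromosome position per
    seqlet and computes its nearest-TSS distance identically.  Histograms
    are raw counts over fixed-width bins.
    """
    if not hits:
        raise ValueError("need at least one seqlet hit")
    index = TssIndex(gtf)
    rng = np.random.default_rng(seed)
    edges = np.arange(-window, window + bin_width, bin_width)

    obs_d, bg_d = [], []
    for h in hits:
        d = h.tss_distance
        if d is None:
            near = index.nearest(h.chrom, (h.start + h.end) // 2)
            d = near[2] if near else None
        if d is not None:
            obs_d.append(d)
        pos = int(rng.integers(0, chrom_lengths[h.chrom]))
        near = index.nearest(h.chrom, pos)
        if near is not None:
            bg_d.append(near[2])
    obs_hist, _ = np.histogram(obs_d, bins=edges)
    bg_hist, _ = np.histogram(bg_d, bins=edges)
    return obs_hist, bg_hist, edges
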