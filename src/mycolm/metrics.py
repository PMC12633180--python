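"""Evaluation statistics: bin-, gene- and track-level agreement measures.

Gene-level coverage is the log2(sum + 1) of a gene's exon-overlapping bins;
tracks within an assay group can be quantile-normalized to a shared
distribution and mean-centered per gene to isolate track specificity from
absolute scale.  R^2 is reported against the identity line
(1 - SSE/SST of prediction vs truth), measuring calibrated agreement rather
than refit correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def assign_bins_to_genes(bin_starts: np.ndarray, bin_width: int,
                         exons: pd.DataFrame, chrom: str,
                         min_overlap: float = 0.5) -> dict[str, np.ndarray]:
    """Map bins to genes by exon overlap of at least ``min_overlap`` x width.

    ``bin_starts`` are genome coordinates of bin left edges (window offset
    and crop already applied); ``exons`` needs gene_id/chrom/start/end.
    """
    need = min_overlap * bin_width
    out: dict[str, list[int]] = {}
    sub = exons[exons["chrom"] == chrom]
    starts = np.asarray(bin_starts)
    ends = starts + bin_width
    for gene_id, grp in sub.groupby("gene_id"):
        overlap = np.zeros(len(starts))
        for _, e in grp.iterrows():
            overlap += np.clip(np.minimum(ends, e["end"])
                               - np.maximum(starts, e["start"]), 0, None)
        idx = np.flatnonzero(overlap >= need)
        if idx.size:
            out[gene_id] = idx
    return out


def gene_log_totals(bins: np.ndarray, gene_map: dict[str, np.ndarray]
                    ) -> pd.DataFrame:
    """log2(sum of a gene's bins + 1), genes x tracks."""
    bins = np.asarray(bins, dtype=float)
    if bins.ndim == 1:
        bins = bins[:, None]
    rows = {g: np.log2(bins[idx].sum(axis=0) + 1.0)
            for g, idx in gene_map.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def _pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _identity_r2(pred, obs):
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    sst = ((obs - obs.mean()) ** 2).sum()
    if sst == 0:
        return np.nan
    return float(1.0 - ((obs - pred) ** 2).sum() / sst)


def gene_level_scores(pred_bins, obs_bins, gene_map) -> pd.DataFrame:
    """Per-track Pearson r and identity-line R^2 over gene log totals."""
    Y = gene_log_totals(obs_bins, gene_map)
    Yhat = gene_log_totals(pred_bins, gene_map)
    if len(Y) < 2:
        raise ValueError("need at least two genes per track")
    rows = []
    for j in range(Y.shape[1]):
        rows.append({"track": j,
                     "pearson_r": _pearson(Yhat.iloc[:, j], Y.iloc[:, j]),
                     "r2": _identity_r2(Yhat.iloc[:, j], Y.iloc[:, j])})
    return pd.DataFrame(rows)


def bin_level_scores(pred_bins, obs_bins) -> pd.DataFrame:
    """Per-track Pearson r and identity-line R^2 over all evaluated bins."""
    pred = np.asarray(pred_bins, float)
    obs = np.asarray(obs_bins, float)
    if pred.ndim == 2:
        pred, obs = pred[:, :, None], obs[:, :, None]
    rows = []
    for j in range(pred.shape[2]):
        p, o = pred[:, :, j].ravel(), obs[:, :, j].ravel()
        rows.append({"track": j, "pearson_r": _pearson(p, o),
                     "r2": _identity_r2(p, o)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quantile normalization + centering

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map each column onto the across-column mean quantile profile.

    Ranks are averaged at ties; fractional ranks interpolate linearly on
    the sorted mean profile.
    """
    values = matrix.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, len(target) + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_group(values: pd.DataFrame, groups: dict[str, list],
                    warn=None) -> pd.DataFrame:
    """Quantile-normalize within each assay group, then mean-center per gene.

    ``groups`` maps group name -> column labels.  A single-track group
    centers to all zeros (a warning callback may be supplied).
    """
    out = values.copy().astype(float)
    for name, cols in groups.items():
        if len(cols) < 2 and warn is not None:
            warn(f"assay group {name!r} has a single track; "
                 "centered values are all zero")
        block = quantile_normalize(values[cols]) if len(cols) > 1 \
            else values[cols].astype(float)
        out[cols] = block.sub(block.mean(axis=1), axis=0)
    return out


# ---------------------------------------------------------------------------
# within-gene consistency and track-level scores

def within_gene_consistency(pred_bins, obs_bins, gene_map,
                            var_floor: float = 1e-6,
                            var_percentile: float = 80.0) -> pd.Series:
    """Per-gene mean Pearson r over tracks with non-trivial variation.

    A gene-track pair is scored iff both log2 vectors have variance above
    ``var_floor`` AND the predicted variance exceeds the per-track
    ``var_percentile`` percentile across genes (linear-interpolation
    convention).  Genes with no retained track get NaN.
    """
    pred = np.asarray(pred_bins, float)
    obs = np.asarray(obs_bins, float)
    if pred.ndim == 1:
        pred, obs = pred[:, None], obs[:, None]
    genes = list(gene_map)
    n_tracks = pred.shape[1]
    pv = np.full((len(genes), n_tracks), np.nan)
    vectors_p, vectors_o = {}, {}
    for gi, g in enumerate(genes):
        idx = gene_map[g]
        vp = np.log2(_gene_bins(pred, idx) + 1.0)
        vo = np.log2(_gene_bins(obs, idx) + 1.0)
        vectors_p[g], vectors_o[g] = vp, vo
        pv[gi] = vp.var(axis=0)
    tau = np.nanpercentile(pv, var_percentile, axis=0)   # per-track cutoff
    scores = {}
    for gi, g in enumerate(genes):
        vp, vo = vectors_p[g], vectors_o[g]
        rs = []
        for j in range(n_tracks):
            if vp[:, j].var() <= var_floor or vo[:, j].var() <= var_floor:
                continue
            if vp[:, j].var() <= tau[j]:
                continue
            r = _pearson(vp[:, j], vo[:, j])
            if not np.isnan(r):
                rs.append(r)
        scores[g] = float(np.mean(rs)) if rs else np.nan
    return pd.Series(scores)


def _gene_bins(arr, idx):
    """(len(idx), n_tracks) slice of a (bins, tracks) array."""
    return arr[idx]


def track_level_scores(pred_table: pd.DataFrame, obs_table: pd.DataFrame
                       ) -> pd.DataFrame:
    """Per-gene correlation across the track axis (RNA-seq style tables)."""
    if pred_table.shape[1] < 2:
        raise ValueError("need at least two tracks")
    rows = []
    for g in obs_table.index:
        p, o = pred_table.loc[g].to_numpy(), obs_table.loc[g].to_numpy()
        rows.append({"gene_id": g, "pearson_r": _pearson(p, o),
                     "r2": _identity_r2(p, o)})
    return pd.DataFrame(rows).set_index("gene_id")
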