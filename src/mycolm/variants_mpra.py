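"""eQTL variant-effect scoring with matched negatives, and the MPRA harness.

A variant is scored by predicting coverage for the reference and alternate
alleles in a window centered on the SNP, summing bins overlapping the
target gene's exons, and taking log2(Cov_alt + 1) - log2(Cov_ref + 1).
Classification of positives vs matched negatives ranks variants by the
magnitude of the predicted effect.  The MPRA harness replaces a 110-bp
native window near a background gene's TSS with a reporter construct
(an 80-bp core wrapped in fixed assay flanks) and quantifies the predicted
expression change of the downstream gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, precision_recall_curve, auc

from . import io as mio
from .metrics import assign_bins_to_genes

CIS_THRESHOLD = 8_000
AF_MIN = 0.05
DIST_TOL = 100
FALLBACK_TOL = 200
DREAM_UPSTREAM = "TGCATTTTTTTCACATC"
DREAM_DOWNSTREAM = "GGTTACGGCTGTT"
DEFAULT_OFFSETS = tuple(range(100, 201, 10))
TSS_DISTANCE_BINS = (0, 1_000, 2_000, 4_000, 8_000)


def classify_cis_trans(variant_chrom: str, variant_pos: int,
                       gene_chrom: str, gene_pos: int,
                       threshold: int = CIS_THRESHOLD) -> str:
    """cis iff same chromosome and |distance| <= threshold (inclusive)."""
    if variant_chrom != gene_chrom:
        return "trans"
    return "cis" if abs(variant_pos - gene_pos) <= threshold else "trans"


@dataclass
class VariantScore:
    cov_ref: float
    cov_alt: float
    log2fc: float


def score_variant(model, contig_seq: str, chrom: str, pos1: int, ref: str,
                  alt: str, exons: pd.DataFrame, species: int = 0,
                  rc_average: bool = True) -> VariantScore:
    """Predict ref/alt coverage around a SNP and log2-fold-change it.

    ``pos1`` is 1-based.  The scoring window is centered on the SNP
    (clamped to the contig); the reference allele is verified against the
    sequence and a mismatch is a hard error.  Predictions average the
    forward and reverse-complement strands.
    """
    L = model.config.L
    pos0 = pos1 - 1
    found = contig_seq[pos0].upper()
    if found != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos1}: "
                         f"expected {ref}, genome has {found}")
    start = min(max(pos0 - L // 2, 0), max(len(contig_seq) - L, 0))
    window = contig_seq[start:start + L]
    if len(window) < L:
        raise ValueError(f"contig {chrom} shorter than the scoring window")
    alt_window = (window[:pos0 - start] + alt.upper()
                  + window[pos0 - start + 1:])

    bin_starts = start + model.crop_bp + np.arange(model.n_bins) * model.bin_width
    gene_map = assign_bins_to_genes(bin_starts, model.bin_width, exons, chrom)
    bin_idx = np.concatenate([idx for idx in gene_map.values()]) \
        if gene_map else np.array([], dtype=int)
    bin_idx = np.unique(bin_idx)
    if bin_idx.size == 0:
        raise ValueError("no bins overlap the target gene's exons")

    cov_ref, cov_alt = _strand_avg_sums(model, [window, alt_window],
                                        bin_idx, species, rc_average)
    return VariantScore(cov_ref=cov_ref, cov_alt=cov_alt,
                        log2fc=float(np.log2(cov_alt + 1.0)
                                     - np.log2(cov_ref + 1.0)))


def _strand_avg_sums(model, seqs, bin_idx, species, rc_average):
    """Batched forward over sequences (and their reverse complements)."""
    from .lm_core import encode_input

    batch = [encode_input(mio.seq_to_onehot(s), species, model.config.n_species)
             for s in seqs]
    if rc_average:
        batch += [encode_input(mio.seq_to_onehot(mio.revcomp(s)), species,
                               model.config.n_species) for s in seqs]
    preds = model.predict(np.stack(batch))
    out = []
    for i in range(len(seqs)):
        p = preds[i]
        if rc_average:
            p = 0.5 * (p + preds[len(seqs) + i][::-1])
        out.append(float(p[bin_idx].sum()))
    return out


# ---------------------------------------------------------------------------
# matched negative sampling

def sample_matched_negatives(positives: pd.DataFrame, candidates: pd.DataFrame,
                             n_sets: int = 4, af_min: float = AF_MIN,
                             dist_tol: int = DIST_TOL,
                             fallback_tol: int = FALLBACK_TOL,
                             seed: int = 0) -> list[pd.DataFrame]:
    """Draw ``n_sets`` independent TSS-distance-matched negative sets.

    Candidates are restricted to non-coding variants with AF >= ``af_min``
    that are not themselves positives.  Per positive, a same-chromosome
    candidate whose |TSS distance| matches within +/- ``dist_tol`` is drawn
    (fallback +/- ``fallback_tol``); each negative is used at most once per
    set.  Unmatched positives are recorded with a null row, not dropped.
    """
    pos_keys = set(zip(positives["chrom"], positives["pos"]))
    pool = candidates[
        (~candidates.get("coding", pd.Series(False, index=candidates.index)))
        & (candidates["af"] >= af_min)].copy()
    pool = pool[np.fromiter((k not in pos_keys
                             for k in zip(pool["chrom"], pool["pos"])),
                            dtype=bool, count=len(pool))]
    sets = []
    for it in range(n_sets):
        rng = np.random.default_rng(seed + it)
        used: set[int] = set()
        rows = []
        for p in positives.itertuples(index=False):
            match_idx = None
            for tol in (dist_tol, fallback_tol):
                elig = pool[(pool["chrom"] == p.chrom)
                            & (~pool.index.isin(used))
                            & ((pool["tss_dist"].abs()
                                - abs(p.tss_dist)).abs() <= tol)]
                if len(elig):
                    match_idx = elig.index[int(rng.integers(len(elig)))]
                    break
            if match_idx is None:
                rows.append({"chrom": p.chrom, "pos": None, "matched": False,
                             "positive_pos": p.pos})
            else:
                used.add(match_idx)
                row = pool.loc[match_idx].to_dict()
                row.update({"matched": True, "positive_pos": p.pos})
                rows.append(row)
        sets.append(pd.DataFrame(rows))
    return sets


# ---------------------------------------------------------------------------
# classification metrics

def auroc(pos_scores, neg_scores) -> float:
    """Rank-based AUROC with tie averaging (Mann-Whitney normalization)."""
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([pos_scores, neg_scores])
    return float(roc_auc_score(y, s))


def auprc(pos_scores, neg_scores) -> float:
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([pos_scores, neg_scores])
    precision, recall, _ = precision_recall_curve(y, s)
    return float(auc(recall, precision))


def eqtl_classification_eval(pos: pd.DataFrame, neg: pd.DataFrame,
                             score_col: str = "log2fc",
                             dist_col: str = "tss_dist",
                             bins=TSS_DISTANCE_BINS) -> dict:
    """AUROC/AUPRC overall and per TSS-distance bin, ranking by |score|."""
    ps = pos[score_col].abs().to_numpy()
    ns = neg[score_col].abs().to_numpy()
    out = {"auroc": auroc(ps, ns), "auprc": auprc(ps, ns), "bins": {}}
    edges = list(bins)
    for lo, hi in zip(edges[:-1], edges[1:]):
        pm = pos[dist_col].abs().between(lo, hi, inclusive="left")
        nm = neg[dist_col].abs().between(lo, hi, inclusive="left")
        label = f"{lo}-{hi}"
        if pm.any() and nm.any():
            out["bins"][label] = {
                "auroc": auroc(ps[pm.to_numpy()], ns[nm.to_numpy()]),
                "auprc": auprc(ps[pm.to_numpy()], ns[nm.to_numpy()]),
            }
        else:
            out["bins"][label] = None
    return out


# ---------------------------------------------------------------------------
# MPRA insertion harness

@dataclass
class MpraConstruct:
    gene_id: str
    strand: str
    offset: int
    midpoint: int
    window_start: int      # replacement window [start, start + 110)
    window_end: int
    sequence: str          # the 110-bp construct inserted


def dream_format(core: str) -> str:
    """Wrap an 80-bp core in the fixed reporter flanks (110 bp total)."""
    if any(b not in "ACGT" for b in core.upper()):
        raise ValueError("construct core contains non-ACGT characters")
    return DREAM_UPSTREAM + core.upper() + DREAM_DOWNSTREAM


def mpra_insertion_design(tss: int, strand: str, construct: str,
                          gene_id: str = "", offsets=DEFAULT_OFFSETS,
                          min_offset: int = 100,
                          contig_length: int | None = None
                          ) -> list[MpraConstruct]:
    """Replacement windows at each insertion offset upstream of the TSS.

    Forward strand: midpoint = TSS - offset; reverse: midpoint = TSS +
    offset.  The half-open window [midpoint - 55, midpoint + 55) is
    replaced by the 110-bp construct (an 80-bp core is wrapped in assay
    flanks first).
    """
    if len(construct) == 80:
        construct = dream_format(construct)
    if len(construct) != 110:
        raise ValueError("construct must be 80 bp (core) or 110 bp (formatted)")
    out = []
    for off in offsets:
        if off < min_offset:
            raise ValueError(f"offset {off} below minimum {min_offset}")
        midpoint = tss - off if strand == "+" else tss + off
        ws, we = midpoint - 55, midpoint + 55
        if ws < 0 or (contig_length is not None and we > contig_length):
            raise ValueError(f"insertion window [{ws},{we}) off contig")
        out.append(MpraConstruct(gene_id=gene_id, strand=strand, offset=off,
                                 midpoint=midpoint, window_start=ws,
                                 window_end=we, sequence=construct))
    return out


@dataclass
class MpraScore:
    log2fc_single: float
    per_background: dict = field(default_factory=dict)
    delta_log2fc_dual: float | None = None


def mpra_score(model, contig_seq: str, constructs: list[MpraConstruct],
               exons: pd.DataFrame, chrom: str, species: int = 0,
               alt_constructs: list[MpraConstruct] | None = None) -> MpraScore:
    """Predicted expression effect of inserting constructs near genes.

    Single mode: log2FC of the background gene's exonic coverage with the
    construct inserted vs the native sequence, averaged over backgrounds.
    Dual mode (``alt_constructs`` given, pairing by list order): scores ref
    and alt separately and reports their difference.
    """
    singles, per_bg = [], {}
    for c in constructs:
        fc = _insertion_log2fc(model, contig_seq, c, exons, chrom, species)
        per_bg[(c.gene_id, c.offset)] = fc
        singles.append(fc)
    score = MpraScore(log2fc_single=float(np.mean(singles)),
                      per_background=per_bg)
    if alt_constructs is not None:
        alts = [_insertion_log2fc(model, contig_seq, c, exons, chrom, species)
                for c in alt_constructs]
        score.delta_log2fc_dual = float(np.mean(alts) - np.mean(singles))
    return score


def _insertion_log2fc(model, contig_seq, c: MpraConstruct, exons, chrom,
                      species):
    L = model.config.L
    gexons = exons[exons["gene_id"] == c.gene_id] if c.gene_id else exons
    if len(gexons) and not (
            (gexons["end"] <= c.window_start) | (gexons["start"] >= c.window_end)
    ).all():
        raise ValueError("insertion window overlaps the scored gene's exons")
    center = (c.window_start + c.window_end) // 2
    start = min(max(center - L // 2, 0), max(len(contig_seq) - L, 0))
    native = contig_seq[start:start + L]
    rel = c.window_start - start
    inserted = native[:rel] + c.sequence + native[rel + 110:]

    bin_starts = start + model.crop_bp + np.arange(model.n_bins) * model.bin_width
    gene_map = assign_bins_to_genes(bin_starts, model.bin_width, gexons, chrom)
    if c.gene_id not in gene_map:
        raise ValueError(f"no bins overlap exons of {c.gene_id}")
    idx = gene_map[c.gene_id]
    cov_native = float(model.predict_window(native, species)[idx].sum())
    cov_mpra = float(model.predict_window(inserted, species)[idx].sum())
    return float(np.log2(cov_mpra + 1.0) - np.log2(cov_native + 1.0))
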