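"""Desk-scale reference protocol: the full pipeline on a laptop-sized problem.

This module fixes one set of study conditions - a synthetic genome with a
256-kb training contig and a held-out 16-kb contig, planted E-box-like
(constitutive, activating) and STRE-like (induction-ramped) promoter motifs
plus neutral genome-wide copies of the same consensus sequences, a
~80k-parameter language model over 4,096-bp windows, and an eight-track
induction time course - and exposes each pipeline stage as a function.
The same protocol backs the test suite and the reproduction script, so
every end-to-end claim (masked-LM motif recovery, transfer-learning
benefit, ISM logo enrichment at planted motifs, eQTL classification, and
the induction-ramped ΔISM response) is recomputed from scratch at this
scale.

Background copies of the promoter consensus sequences are planted outside
promoters with zero activity: the language model sees many instances of
each k-mer, while only promoter instances carry an expression effect, so
the supervised model must learn the promoter context rather than the bare
k-mer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import corpus as corpus_mod
from . import coverage as cov_mod
from . import io as mio
from . import ism as ism_mod
from . import lm_core
from . import metrics as metrics_mod
from .fixtures import (GroundTruth, MotifSpec, SyntheticGenomeSpec,
                       generate_genome, simulate_coverage, simulate_eqtls)

EBOX = MotifSpec("ebox", "CACGTG", rate_per_kb=6.0, promoter_only=True,
                 activity=1.2)
STRE = MotifSpec("stre", "AGGGGC", rate_per_kb=4.0, promoter_only=True,
                 activity=1.0)
TATA = MotifSpec("tata", "TATATAAA", rate_per_kb=0.4, promoter_only=False,
                 activity=0.0)
EBOX_BG = MotifSpec("ebox_bg", "CACGTG", rate_per_kb=5.0, promoter_only=False,
                    activity=0.0)
STRE_BG = MotifSpec("stre_bg", "AGGGGC", rate_per_kb=5.0, promoter_only=False,
                    activity=0.0)

TIMEPOINTS = (0, 15, 30, 60)
STRE_RAMP = {0: 0.0, 15: 0.5, 30: 1.0, 60: 1.5}


@dataclass
class DeskScale:
    """Problem sizes and training budgets for the desk-scale protocol."""

    seed: int = 0
    L: int = 4_096
    tower_widths: tuple = (16, 24, 32, 40, 48)
    n_transformer_blocks: int = 1
    n_heads: int = 2
    key_dim: int = 16
    contigs: tuple = (262_144, 16_384)      # chr1 train, chr2 held out
    gene_density: float = 3.0
    lm_stride: int = 1_024
    lm_batch: int = 6
    lm_epochs: int = 14
    lm_steps_per_epoch: int = 40
    lm_lr: float = 5e-3
    lm_clipnorm: float = 5.0
    lm_warmup: int = 30
    sup_stride: int = 512
    sup_batch: int = 4
    sup_steps_per_epoch: int = 60
    sup_epochs_main: int = 12
    transfer_lr: float = 6e-4
    random_lr: float = 1e-3
    libsize: float = 1e6
    noise: float = 0.05
    n_eqtl_pos: int = 24
    ism_region: tuple = (-250, 10)
    decoder_stages: int = 1
    crop_bins: int = 16

    def genome_spec(self) -> SyntheticGenomeSpec:
        return SyntheticGenomeSpec(
            contig_lengths=[list(self.contigs)],
            motif_catalog=[EBOX, STRE, TATA, EBOX_BG, STRE_BG],
            gene_density=self.gene_density,
            intron_rate=0.3,
            repeat_runs=(150, 0.5),
            seed=self.seed + 11)

    def lm_config(self) -> lm_core.LmConfig:
        return lm_core.LmConfig(
            L=self.L, tower_widths=self.tower_widths,
            n_transformer_blocks=self.n_transformer_blocks,
            n_heads=self.n_heads, key_dim=self.key_dim,
            seed=self.seed)

    def track_names(self) -> list[str]:
        return [f"T{t}_rep{r}" for t in TIMEPOINTS for r in (1, 2)]

    def track_modulation(self) -> pd.DataFrame:
        rows = {}
        for name in self.track_names():
            t = ism_mod.parse_timepoint(name)
            rows[name] = {"ebox": 1.0, "stre": STRE_RAMP[t], "tata": 1.0,
                          "ebox_bg": 1.0, "stre_bg": 1.0}
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DeskScaleData:
    fasta: str
    gtf: str
    gtf_df: pd.DataFrame
    truth: GroundTruth
    lm_train: list
    lm_val: list
    sup_train: list
    sup_val: list
    coverage: object
    sup_train_targets: np.ndarray
    sup_val_targets: np.ndarray


def build_data(ds: DeskScale) -> DeskScaleData:
    """Genome, LM corpus, coverage tracks and supervised targets."""
    fasta, gtf, truth = generate_genome(ds.genome_spec())
    gtf_df = mio.read_gtf(gtf)

    contigs = corpus_mod.prepare_contigs(fasta, "lm", lm_min_contig=ds.L)
    windows = corpus_mod.segment_windows(contigs, window=ds.L,
                                         stride=ds.lm_stride)
    windows = corpus_mod.repeat_fraction_filter(windows)
    windows = [corpus_mod.build_position_masks(w, gtf_df) for w in windows]
    lm_train = [w for w in windows if w.chrom == "chr1"]
    lm_val = [w for w in windows if w.chrom == "chr2"]

    coverage = simulate_coverage(
        truth, n_tracks=len(ds.track_names()), libsize=ds.libsize,
        noise=ds.noise, seed=ds.seed + 23,
        track_modulation=ds.track_modulation(),
        track_names=ds.track_names())

    bin_width = 2 ** (len(ds.tower_widths) - ds.decoder_stages)
    crop_bp = ds.crop_bins * bin_width
    sup_windows = corpus_mod.segment_windows(contigs, window=ds.L,
                                             stride=ds.sup_stride)
    sup_windows = [corpus_mod.build_position_masks(w, gtf_df)
                   for w in sup_windows]
    sup_train = [w for w in sup_windows if w.chrom == "chr1"]
    sup_val = [w for w in sup_windows if w.chrom == "chr2"][::2]
    tr_targets = cov_mod.window_targets(sup_train, coverage, crop=crop_bp,
                                        bin_width=bin_width)
    va_targets = cov_mod.window_targets(sup_val, coverage, crop=crop_bp,
                                        bin_width=bin_width)
    return DeskScaleData(fasta=fasta, gtf=gtf, gtf_df=gtf_df, truth=truth,
                         lm_train=lm_train, lm_val=lm_val,
                         sup_train=sup_train, sup_val=sup_val,
                         coverage=coverage,
                         sup_train_targets=tr_targets,
                         sup_val_targets=va_targets)


def pretrain_lm(ds: DeskScale, data: DeskScaleData) -> lm_core.LanguageModel:
    model = lm_core.build_lm(ds.lm_config())
    cfg = lm_core.TrainConfig(
        batch_size=ds.lm_batch, steps_per_epoch=ds.lm_steps_per_epoch,
        max_epochs=ds.lm_epochs, patience=ds.lm_epochs, lr=ds.lm_lr,
        clipnorm=ds.lm_clipnorm, warmup_steps=ds.lm_warmup,
        repeat_eval=1, seed=ds.seed)
    lm_core.train_lm(model, data.lm_train, data.lm_val, cfg)
    return model


def finetune(ds: DeskScale, data: DeskScaleData,
             lm: lm_core.LanguageModel | None, seed: int,
             epochs: int | None = None):
    """Fine-tune the coverage model; transfer init when ``lm`` is given.

    The transfer and from-scratch arms keep the full-scale optimizer split
    (transfer runs at a lower learning rate and the heavier momentum decay
    of the pretraining recipe), rescaled to desk-scale budgets.
    """
    epochs = epochs if epochs is not None else ds.sup_epochs_main
    model = cov_mod.CoverageModel(
        dataclasses.replace(ds.lm_config(), seed=seed + 100),
        n_tracks=len(ds.track_names()),
        decoder_stages=ds.decoder_stages, crop_bins=ds.crop_bins)
    if lm is not None:
        model.init_from_lm(lm)
    ft = cov_mod.FineTuneConfig(
        batch_size=ds.sup_batch, steps_per_epoch=ds.sup_steps_per_epoch,
        max_epochs=epochs, patience=epochs,
        lr=ds.transfer_lr if lm is not None else ds.random_lr,
        beta1=0.7 if lm is not None else 0.9,
        beta2=0.9 if lm is not None else 0.999,
        clipnorm=ds.lm_clipnorm, warmup_steps=10, seed=seed)
    model, history = cov_mod.train_supervised(
        model, data.sup_train, data.sup_train_targets,
        data.sup_val, data.sup_val_targets, ft)
    return model, history


def transfer_comparison(ds: DeskScale, data: DeskScaleData, lm,
                        seeds=(0, 1, 2), epochs: int | None = None):
    """Best validation loss of transfer vs from-scratch arms per seed.

    Both arms get the same step budget.  Returns (table, transfer models):
    the per-seed transfer-initialized models double as the cross-
    validation-style fold ensemble for downstream variant scoring and ISM.
    """
    rows, fold_models = [], []
    for seed in seeds:
        model_t, h_t = finetune(ds, data, lm, seed, epochs=epochs)
        _, h_r = finetune(ds, data, None, seed, epochs=epochs)
        fold_models.append(model_t)
        rows.append({"seed": seed,
                     "transfer_val": min(h_t["val_loss"]),
                     "random_val": min(h_r["val_loss"])})
    return pd.DataFrame(rows), fold_models


# ---------------------------------------------------------------------------
# end-to-end measurements

def motif_information_content(ds: DeskScale, data: DeskScaleData, lm,
                              max_windows: int = 6, seed: int = 0):
    """Per-position information content at planted motifs vs background.

    Returns (motif IC values, background IC values) pooled over windows
    containing planted instances (held-out windows first).
    """
    from .interpret import ppm_to_icm

    rng = np.random.default_rng(seed)
    placements = data.truth.motif_placements
    motif_ic, background_ic = [], []
    used = 0
    for w in data.lm_val + data.lm_train:
        if used >= max_windows:
            break
        inside = placements[(placements["chrom"] == w.chrom)
                            & (placements["start"] >= w.start)
                            & (placements["end"] <= w.end)
                            & (placements["name"] != "tata")]
        if inside.empty:
            continue
        used += 1
        res = lm_core.mask_predict_tile(lm, w, seed=seed + used)
        icm = ppm_to_icm(res.ppm)
        motif_pos = np.zeros(w.length, dtype=bool)
        for _, m in inside.iterrows():
            motif_pos[m["start"] - w.start:m["end"] - w.start] = True
        exclude = motif_pos | w.exon_mask | w.repeat_mask
        motif_ic.extend(icm.info[motif_pos])
        bg_pool = np.flatnonzero(~exclude)
        take = rng.choice(bg_pool, size=min(motif_pos.sum() * 4, bg_pool.size),
                          replace=False)
        background_ic.extend(icm.info[take])
    return np.asarray(motif_ic), np.asarray(background_ic)


def promoter_windows(ds: DeskScale, data: DeskScaleData, motif: str = "ebox",
                     max_genes: int = 6):
    """Genes whose promoter carries a planted instance of ``motif``, with a
    scoring window centred on the gene and inside the contig."""
    placements = data.truth.motif_placements
    has = placements[(placements["name"] == motif)
                     & placements["gene_id"].notna()]
    out = []
    for gene_id in pd.unique(has["gene_id"]):
        g = data.truth.genes.set_index("gene_id").loc[gene_id]
        contig = data.truth.contigs[(0, g["chrom"])]
        start = min(max(int(g["tss"]) - ds.L // 2, 0),
                    max(len(contig) - ds.L, 0))
        out.append((gene_id, g, contig, start))
        if len(out) >= max_genes:
            break
    return out


def _gene_ism(ds, data, models, gene_id, g, contig, start, positions=None):
    """Fold-averaged ISM scores for one gene's promoter region.

    ``models`` is one model or a list (fold ensemble; scores averaged).
    Returns (scores, region genome positions, reference one-hot), or
    None-tuple if no prediction bins overlap the gene.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    model = models[0]
    seq = contig[start:start + ds.L]
    bin_starts = (start + model.crop_bp
                  + np.arange(model.n_bins) * model.bin_width)
    exons = data.truth.exons
    gmap = metrics_mod.assign_bins_to_genes(
        bin_starts, model.bin_width,
        exons[exons["gene_id"] == gene_id], g["chrom"])
    if gene_id not in gmap:
        return None, None, None
    scores = np.mean([
        ism_mod.ism_scores(m, seq, start, int(g["tss"]), g["strand"],
                           gmap[gene_id], region=ds.ism_region,
                           positions=positions)
        for m in models], axis=0)
    lo, hi = ds.ism_region
    if g["strand"] == "+":
        region_pos = [int(g["tss"]) + r for r in range(lo, hi)]
    else:
        region_pos = [int(g["tss"]) - 1 - r for r in range(lo, hi)]
    ref_onehot = mio.seq_to_onehot(
        "".join(contig[p].upper() if 0 <= p < len(contig) else "N"
                for p in region_pos))
    return scores, region_pos, ref_onehot


def ism_motif_enrichment(ds: DeskScale, data: DeskScaleData, models,
                         max_genes: int = 5):
    """Mean |logo| at planted promoter-motif positions vs promoter background."""
    t0_idx = ism_mod.timepoint_groups(ds.track_names())[0]
    inside_vals, outside_vals = [], []
    for gene_id, g, contig, start in promoter_windows(ds, data,
                                                      max_genes=max_genes):
        scores, region_pos, ref_onehot = _gene_ism(ds, data, models,
                                                   gene_id, g, contig, start)
        if scores is None:
            continue
        m = ism_mod.build_ism_map(scores, t0_idx, ref_onehot)
        placements = data.truth.motif_placements
        planted = placements[(placements["gene_id"] == gene_id)
                             & (placements["name"].isin(["ebox", "stre"]))]
        mask = np.zeros(len(region_pos), dtype=bool)
        pos_to_offset = {p: i for i, p in enumerate(region_pos)}
        for _, mm in planted.iterrows():
            for p in range(mm["start"], mm["end"]):
                if p in pos_to_offset:
                    mask[pos_to_offset[p]] = True
        if mask.any() and (~mask).any():
            inside_vals.extend(np.abs(m.logo[mask]))
            outside_vals.extend(np.abs(m.logo[~mask]))
    return np.asarray(inside_vals), np.asarray(outside_vals)


def delta_ism_ramp(ds: DeskScale, data: DeskScaleData, models,
                   max_genes: int = 20):
    """Mean |ΔISM| over planted STRE columns per timepoint (pooled genes).

    Only the planted STRE columns are mutated (per-position normalization
    makes the restriction exact for those columns); pooling many promoters
    keeps the Monte-Carlo error of the mean below the ramp increments.
    """
    placements_all = data.truth.motif_placements
    per_window = []
    for gene_id, g, contig, start in promoter_windows(ds, data, motif="stre",
                                                      max_genes=max_genes):
        stre = placements_all[(placements_all["gene_id"] == gene_id)
                              & (placements_all["name"] == "stre")]
        positions = [p for _, mm in stre.iterrows()
                     for p in range(mm["start"], mm["end"])]
        scores, region_pos, ref_onehot = _gene_ism(ds, data, models,
                                                   gene_id, g, contig, start,
                                                   positions=positions)
        if scores is None:
            continue
        deltas = ism_mod.delta_ism_timecourse(scores, ds.track_names(),
                                              ref_onehot)
        placements = data.truth.motif_placements
        planted = placements[(placements["gene_id"] == gene_id)
                             & (placements["name"] == "stre")]
        pos_to_offset = {p: i for i, p in enumerate(region_pos)}
        cols = sorted({pos_to_offset[p] for _, mm in planted.iterrows()
                       for p in range(mm["start"], mm["end"])
                       if p in pos_to_offset})
        if not cols:
            continue
        per_window.append({t: float(np.abs(d[cols]).mean())
                           for t, d in deltas.items()})
    if not per_window:
        raise ValueError("no STRE-bearing promoters inside scoring windows")
    times = sorted(per_window[0])
    return {t: float(np.mean([pw[t] for pw in per_window])) for t in times}


def eqtl_benchmark(ds: DeskScale, data: DeskScaleData, models, seed: int = 0):
    """Score fixture positives vs matched negatives; returns (eval, pos, neg).

    ``models`` is one model or a fold ensemble; fold scores are averaged
    (signed) before ranking by magnitude.
    """
    from . import variants_mpra as vm

    if not isinstance(models, (list, tuple)):
        models = [models]
    positives, candidates = simulate_eqtls(data.truth, ds.n_eqtl_pos,
                                           seed=seed + 31)
    negatives = vm.sample_matched_negatives(positives, candidates, n_sets=1,
                                            seed=seed + 37)[0]
    negatives = negatives[negatives["matched"]]

    def score_table(table):
        scores = []
        for r in table.itertuples(index=False):
            contig = data.truth.contigs[(0, r.chrom)]
            exons = data.truth.exons[data.truth.exons["gene_id"] == r.gene_id]
            fold = [vm.score_variant(m, contig, r.chrom, int(r.pos), r.ref,
                                     r.alt, exons).log2fc for m in models]
            scores.append(float(np.mean(fold)))
        return np.asarray(scores)

    pos_scored = positives.assign(log2fc=score_table(positives))
    neg_scored = negatives.assign(log2fc=score_table(negatives))
    result = vm.eqtl_classification_eval(pos_scored, neg_scored)
    result["n_pos"] = len(pos_scored)
    result["n_neg"] = len(neg_scored)
    return result, pos_scored, neg_scored
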