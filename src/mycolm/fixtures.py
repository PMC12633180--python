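"""Synthetic multi-species genomes with planted regulatory ground truth.

The generator emulates the inputs the modelling stack consumes: soft-masked
FASTA contigs, GTF gene models with intron donor/branch signals, planted
transcription-factor motifs with known activities, Poisson-sampled coverage
tracks driven by a log-linear motif -> expression model, and matched
positive/negative variant tables.  Because the expression model is
log-linear in planted motif counts, every downstream analysis (masked-LM
motif recovery, ISM logos, eQTL classification) has a known answer.

Coordinates are 0-based half-open internally; emitted GTF is 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio

PROMOTER_LEN = 250          # bp upstream of the TSS scanned for motif effects
_GENE_LEN_RANGE = (600, 1200)
_INTRON_LEN_RANGE = (80, 150)
_DONOR = "GTATGT"
_BRANCH = "CTAACA"


@dataclass(frozen=True)
class MotifSpec:
    """A motif to plant: consensus, placement rate, and expression effect."""

    name: str
    consensus: str
    rate_per_kb: float
    promoter_only: bool = False
    activity: float = 0.0


@dataclass
class SyntheticGenomeSpec:
    """Study conditions for one synthetic genome draw.

    ``contig_lengths[s]`` lists contig lengths (bp) for species ``s``;
    ``gene_density`` is genes per 10 kb; ``repeat_runs`` is
    (run length bp, runs per 10 kb).
    """

    contig_lengths: list[list[int]]
    motif_catalog: list[MotifSpec] = field(default_factory=list)
    gc_content: float = 0.40
    gene_density: float = 3.0
    intron_rate: float = 0.2
    repeat_runs: tuple[int, float] = (100, 1.0)
    mutation_rate: float = 0.0
    seed: int = 0

    @property
    def n_species(self) -> int:
        return len(self.contig_lengths)

    def __post_init__(self):
        if not self.contig_lengths or any(
                length <= 0 for lens in self.contig_lengths for length in lens):
            raise ValueError("all contig lengths must be > 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if any(m.rate_per_kb < 0 for m in self.motif_catalog):
            raise ValueError("motif placement rates must be >= 0")
        if self.repeat_runs[0] <= 0 or self.repeat_runs[1] < 0:
            raise ValueError("repeat run length must be > 0, rate >= 0")


@dataclass
class GroundTruth:
    """Everything planted into a synthetic genome, retrievable for oracles."""

    contigs: dict[tuple[int, str], str]
    motif_placements: pd.DataFrame   # species, chrom, start, end, name, strand, gene_id
    genes: pd.DataFrame              # species, chrom, gene_id, strand, tss, start, end
    exons: pd.DataFrame              # gene_id, species, chrom, start, end
    activities: dict[str, float]
    per_track_modulation: pd.DataFrame | None = None

    def contig_length(self, species: int, chrom: str) -> int:
        return len(self.contigs[(species, chrom)])

    def promoter_motif_counts(self, modulated: dict[str, float] | None = None
                              ) -> pd.Series:
        """Per-gene summed motif activity over promoter placements."""
        acts = dict(self.activities)
        if modulated:
            acts = {k: v * modulated.get(k, 1.0) for k, v in acts.items()}
        placed = self.motif_placements
        placed = placed[placed["gene_id"].notna()]
        effect = placed["name"].map(acts).fillna(0.0)
        per_gene = effect.groupby(placed["gene_id"]).sum()
        return per_gene.reindex(self.genes["gene_id"], fill_value=0.0)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _plant(seq: np.ndarray, start: int, motif: str):
    seq[start:start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def generate_genome(spec: SyntheticGenomeSpec):
    """Generate (fasta_text, gtf_text, GroundTruth) deterministically.

    Genes are laid out on an even grid of slots per contig; each slot must
    fit the gene body plus a promoter margin, otherwise the requested gene
    density is infeasible and a ``ValueError`` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    contigs: dict[tuple[int, str], str] = {}
    gene_rows, exon_rows, motif_rows, gtf_rows = [], [], [], []
    activities = {m.name: m.activity for m in spec.motif_catalog}
    gene_counter = 0

    single = spec.n_species == 1
    for sp, lengths in enumerate(spec.contig_lengths):
        for ci, length in enumerate(lengths):
            chrom = f"chr{ci + 1}" if single else f"sp{sp}.chr{ci + 1}"
            seq = _random_sequence(rng, length, spec.gc_content)
            occupied = np.zeros(length, dtype=bool)   # exons + planted motifs

            # --- gene layout on an even grid -------------------------------
            n_genes = int(np.floor(length / 10_000 * spec.gene_density))
            promoters = []   # (gene_id, strand, prom_start, prom_end, tss)
            if n_genes > 0:
                slot = length // n_genes
                need = _GENE_LEN_RANGE[1] + PROMOTER_LEN + 100
                if slot < need:
                    raise ValueError(
                        f"contig {chrom} ({length} bp) too short for "
                        f"{n_genes} genes: slot {slot} < {need} bp required")
                for gi in range(n_genes):
                    gene_id = f"g{sp}_{gene_counter:04d}"
                    gene_counter += 1
                    glen = int(rng.integers(*_GENE_LEN_RANGE))
                    strand = "+" if rng.random() < 0.5 else "-"
                    lo = gi * slot + PROMOTER_LEN + 20
                    hi = min((gi + 1) * slot, length) - glen - PROMOTER_LEN - 20
                    gstart = int(rng.integers(lo, max(lo + 1, hi)))
                    gend = gstart + glen
                    tss = gstart if strand == "+" else gend
                    if strand == "+":
                        prom = (gene_id, strand, gstart - PROMOTER_LEN, gstart, tss)
                    else:
                        prom = (gene_id, strand, gend, gend + PROMOTER_LEN, tss)
                    promoters.append(prom)

                    # exon structure (possibly one intron)
                    if spec.intron_rate > 0 and rng.random() < spec.intron_rate \
                            and glen > 2 * sum(_INTRON_LEN_RANGE) // 2 + 200:
                        ilen = int(rng.integers(*_INTRON_LEN_RANGE))
                        e1 = int(rng.integers(80, glen - ilen - 80))
                        istart, iend = gstart + e1, gstart + e1 + ilen
                        _plant(seq, istart, _DONOR)
                        _plant(seq, iend - 6 - len(_BRANCH), _BRANCH)
                        exons = [(gstart, istart), (iend, gend)]
                    else:
                        exons = [(gstart, gend)]
                    for es, ee in exons:
                        occupied[es:ee] = True
                        exon_rows.append((gene_id, sp, chrom, es, ee))
                    gene_rows.append((sp, chrom, gene_id, strand, tss,
                                      gstart, gend))
                    attrs = (f'gene_id "{gene_id}"; '
                             f'transcript_id "{gene_id}.t1";')
                    gtf_rows.append((chrom, "mycolm", "gene",
                                     gstart, gend, strand, attrs))
                    gtf_rows.append((chrom, "mycolm", "transcript",
                                     gstart, gend, strand, attrs))
                    for es, ee in exons:
                        gtf_rows.append((chrom, "mycolm", "exon",
                                         es, ee, strand, attrs))

            # --- motif placement ------------------------------------------
            # promoter-only motifs first; promoters are then blocked so that
            # genome-wide (background) instances of the same consensus never
            # land in a promoter and muddy the motif -> expression map
            for motif in spec.motif_catalog:
                if not motif.promoter_only:
                    continue
                width = len(motif.consensus)
                for gene_id, strand, ps, pe, _tss in promoters:
                    lam = motif.rate_per_kb * (pe - ps) / 1000.0
                    count = int(rng.poisson(lam))
                    for _ in range(count):
                        pos = _place(rng, occupied, ps, pe - width, width)
                        if pos is None:
                            continue
                        _emit_motif(rng, seq, occupied, pos, motif,
                                    spec.mutation_rate, sp, chrom,
                                    gene_id, motif_rows)
            for _gene_id, _strand, ps, pe, _tss in promoters:
                occupied[ps:pe] = True
            for motif in spec.motif_catalog:
                if motif.promoter_only:
                    continue
                width = len(motif.consensus)
                count = int(rng.poisson(motif.rate_per_kb * length / 1000.0))
                for _ in range(count):
                    pos = _place(rng, occupied, 0, length - width, width)
                    if pos is None:
                        continue
                    _emit_motif(rng, seq, occupied, pos, motif,
                                spec.mutation_rate, sp, chrom,
                                None, motif_rows)

            # --- lowercase repeat runs -------------------------------------
            run_len, per_10kb = spec.repeat_runs
            n_runs = int(round(length / 10_000 * per_10kb))
            text = seq.tobytes().decode()
            lowered = list(text)
            for _ in range(n_runs):
                pos = _place(rng, occupied, 0, length - run_len, run_len)
                if pos is None:
                    continue
                occupied[pos:pos + run_len] = True
                for j in range(pos, pos + run_len):
                    lowered[j] = lowered[j].lower()
            contigs[(sp, chrom)] = "".join(lowered)

    fasta_text = mio.write_fasta({chrom: s for (_sp, chrom), s in contigs.items()})
    gtf_text = mio.format_gtf(gtf_rows)

    truth = GroundTruth(
        contigs=contigs,
        motif_placements=pd.DataFrame(
            motif_rows, columns=["species", "chrom", "start", "end",
                                 "name", "strand", "gene_id"]),
        genes=pd.DataFrame(
            gene_rows, columns=["species", "chrom", "gene_id", "strand",
                                "tss", "start", "end"]),
        exons=pd.DataFrame(
            exon_rows, columns=["gene_id", "species", "chrom", "start", "end"]),
        activities=activities,
    )
    return fasta_text, gtf_text, truth


def _place(rng, occupied, lo, hi, width, tries: int = 30):
    """Uniformly pick an unoccupied [pos, pos+width) in [lo, hi]."""
    if hi < lo:
        return None
    for _ in range(tries):
        pos = int(rng.integers(lo, hi + 1))
        if not occupied[pos:pos + width].any():
            return pos
    return None


def _emit_motif(rng, seq, occupied, pos, motif, mutation_rate,
                sp, chrom, gene_id, motif_rows):
    instance = motif.consensus
    if mutation_rate > 0:
        chars = list(instance)
        for j in range(len(chars)):
            if rng.random() < mutation_rate:
                chars[j] = "ACGT"[int(rng.integers(4))]
        instance = "".join(chars)
    strand = "+" if rng.random() < 0.5 else "-"
    _plant(seq, pos, instance if strand == "+" else mio.revcomp(instance))
    occupied[pos:pos + len(instance)] = True
    motif_rows.append((sp, chrom, pos, pos + len(instance),
                       motif.name, strand, gene_id))


# ---------------------------------------------------------------------------
# coverage simulation

@dataclass
class CoverageSet:
    """Per-track per-base coverage for one species, with expectations."""

    track_names: list[str]
    tracks: dict[str, dict[str, np.ndarray]]      # track -> chrom -> per-base
    expected: dict[str, dict[str, np.ndarray]]    # pre-Poisson means
    libsizes: dict[str, float]
    gene_expression: pd.DataFrame                 # gene x track expected expr

    def bedgraph(self, track: str) -> str:
        return mio.write_bedgraph(self.tracks[track])


def simulate_coverage(truth: GroundTruth, n_tracks: int, libsize: float = 1e5,
                      noise: float = 0.0, seed: int = 0, species: int = 0,
                      track_modulation: pd.DataFrame | None = None,
                      track_names: list[str] | None = None) -> CoverageSet:
    """Simulate exon-uniform Poisson coverage from the planted motif model.

    Gene expression is ``exp(sum_m activity_m * modulation_{track,m} + eps)``
    with ``eps ~ N(0, noise)``; reads are shared across genes proportionally
    to expression so each track totals ``libsize`` reads in expectation,
    spread uniformly over exonic bases (introns get zero) and then
    Poisson-sampled per base.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    if track_names is None:
        track_names = [f"T0_rep{i}" for i in range(n_tracks)]
    if track_modulation is None:
        track_modulation = pd.DataFrame(
            1.0, index=track_names, columns=list(truth.activities) or ["_none"])
    truth.per_track_modulation = track_modulation

    genes = truth.genes[truth.genes["species"] == species]
    chrom_lens = {c: truth.contig_length(species, c)
                  for (sp, c) in truth.contigs if sp == species}
    tracks, expected, libsizes = {}, {}, {}
    expr_table = pd.DataFrame(index=genes["gene_id"], columns=track_names,
                              dtype=float)
    for tname in track_names:
        mod = track_modulation.loc[tname].to_dict() \
            if tname in track_modulation.index else {}
        signal = truth.promoter_motif_counts(modulated=mod)
        signal = signal.loc[genes["gene_id"]]
        eps = rng.normal(0.0, noise, size=len(signal)) if noise > 0 else 0.0
        expr = np.exp(signal.to_numpy(dtype=float) + eps)
        total = expr.sum()
        reads = libsize * expr / total if total > 0 else np.zeros_like(expr)
        expr_table[tname] = expr

        lam = {c: np.zeros(n) for c, n in chrom_lens.items()}
        for gene_reads, (_, g) in zip(reads, genes.iterrows()):
            gexons = truth.exons[truth.exons["gene_id"] == g["gene_id"]]
            exon_len = int((gexons["end"] - gexons["start"]).sum())
            if exon_len == 0:
                continue
            per_base = gene_reads / exon_len
            for _, e in gexons.iterrows():
                lam[g["chrom"]][e["start"]:e["end"]] += per_base
        sampled = {c: rng.poisson(v).astype(float) for c, v in lam.items()}
        tracks[tname] = sampled
        expected[tname] = lam
        libsizes[tname] = float(sum(v.sum() for v in sampled.values()))
    return CoverageSet(track_names=track_names, tracks=tracks,
                       expected=expected, libsizes=libsizes,
                       gene_expression=expr_table)


# ---------------------------------------------------------------------------
# eQTL simulation

def simulate_eqtls(truth: GroundTruth, n_pos: int, seed: int = 0,
                   species: int = 0, n_candidates: int = 400):
    """Plant positive eQTLs (motif-destroying SNVs) and candidate negatives.

    Positives substitute the central base of a promoter motif instance with
    the transversion partner, destroying the consensus; the recorded effect
    sign is ``-sign(activity)``.  Candidates are non-exonic, non-motif
    positions with allele frequencies drawn Uniform(0.01, 0.5).
    """
    rng = np.random.default_rng(seed)
    placed = truth.motif_placements
    placed = placed[(placed["species"] == species) & placed["gene_id"].notna()]
    if len(placed) < n_pos:
        raise ValueError(
            f"only {len(placed)} promoter motif placements available, "
            f"{n_pos} positives requested")
    genes = truth.genes.set_index("gene_id")

    pick = placed.iloc[rng.permutation(len(placed))[:n_pos]] if n_pos else \
        placed.iloc[:0]
    pos_rows = []
    transversion = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for _, m in pick.iterrows():
        mid = (int(m["start"]) + int(m["end"])) // 2
        seq = truth.contigs[(species, m["chrom"])]
        ref = seq[mid].upper()
        alt = transversion[ref]
        g = genes.loc[m["gene_id"]]
        pos_rows.append((m["chrom"], mid + 1, ref, alt,
                         float(rng.uniform(0.01, 0.5)), m["gene_id"],
                         _signed_tss_distance(mid, g),
                         -np.sign(truth.activities.get(m["name"], 0.0)),
                         m["name"]))
    positives = pd.DataFrame(pos_rows, columns=[
        "chrom", "pos", "ref", "alt", "af", "gene_id", "tss_dist",
        "effect_sign", "motif"])

    # candidate negatives: non-coding positions clear of planted motifs
    exonic = {c: np.zeros(truth.contig_length(species, c), dtype=bool)
              for (sp, c) in truth.contigs if sp == species}
    sp_exons = truth.exons[truth.exons["species"] == species]
    for _, e in sp_exons.iterrows():
        exonic[e["chrom"]][e["start"]:e["end"]] = True
    blocked = {c: a.copy() for c, a in exonic.items()}
    for _, m in truth.motif_placements[
            truth.motif_placements["species"] == species].iterrows():
        blocked[m["chrom"]][m["start"]:m["end"]] = True

    sp_genes = truth.genes[truth.genes["species"] == species]
    cand_rows = []
    chroms = list(exonic)
    pos_set = {(r.chrom, r.pos) for r in positives.itertuples(index=False)}
    while len(cand_rows) < n_candidates:
        chrom = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(truth.contig_length(species, chrom)))
        if blocked[chrom][p] or (chrom, p + 1) in pos_set:
            continue
        seq = truth.contigs[(species, chrom)]
        ref = seq[p].upper()
        if ref == "N":
            continue
        alt = "ACGT"[int(rng.integers(4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(4))]
        near = sp_genes[sp_genes["chrom"] == chrom]
        if near.empty:
            continue
        d = (near["tss"] - p).abs()
        g = near.loc[d.idxmin()]
        cand_rows.append((chrom, p + 1, ref, alt,
                          float(rng.uniform(0.01, 0.5)), g["gene_id"],
                          _signed_tss_distance(p, g), False))
    candidates = pd.DataFrame(cand_rows, columns=[
        "chrom", "pos", "ref", "alt", "af", "gene_id", "tss_dist", "coding"])
    return positives, candidates


def _signed_tss_distance(pos0: int, gene) -> int:
    """Signed distance to the TSS (negative upstream on the gene's strand)."""
    if gene["strand"] == "+":
        return int(pos0 - gene["tss"])
    return int(gene["tss"] - pos0)
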