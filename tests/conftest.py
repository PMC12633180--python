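"""Shared fixtures: small synthetic genomes and the desk-scale protocol.

The session-scoped ``desk_*`` fixtures train the desk-scale models once and
are shared by the end-to-end tests; everything else is cheap and local.
"""

from __future__ import annotations

import numpy as np
import pytest

from mycolm import corpus as corpus_mod
from mycolm import deskscale as dk
from mycolm import io as mio
from mycolm.fixtures import MotifSpec, SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 36-kb single-species genome with planted motifs and repeats."""
    spec = SyntheticGenomeSpec(
        contig_lengths=[[24_000, 12_000]],
        motif_catalog=[
            MotifSpec("ebox", "CACGTG", 4.0, promoter_only=True, activity=1.0),
            MotifSpec("tata", "TATATAAA", 0.8, promoter_only=False),
        ],
        gene_density=3.0, intron_rate=0.5, repeat_runs=(120, 0.8), seed=7)
    fasta, gtf, truth = generate_genome(spec)
    return spec, fasta, gtf, truth


@pytest.fixture(scope="session")
def small_windows(small_genome):
    """1,024-bp masked windows over the small genome."""
    _, fasta, gtf, _ = small_genome
    gtf_df = mio.read_gtf(gtf)
    contigs = corpus_mod.prepare_contigs(fasta, "lm", lm_min_contig=1_024)
    windows = corpus_mod.segment_windows(contigs, window=1_024, stride=512)
    return [corpus_mod.build_position_masks(w, gtf_df) for w in windows]


# ---------------------------------------------------------------------------
# desk-scale protocol (heavy, session-scoped, trained once)

@pytest.fixture(scope="session")
def desk():
    ds = dk.DeskScale(seed=0)
    return ds, dk.build_data(ds)


@pytest.fixture(scope="session")
def desk_lm(desk):
    ds, data = desk
    return dk.pretrain_lm(ds, data)


@pytest.fixture(scope="session")
def desk_comparison(desk, desk_lm):
    """Transfer-vs-random table plus the transfer fold ensemble."""
    ds, data = desk
    return dk.transfer_comparison(ds, data, desk_lm, seeds=(0, 1, 2))


@pytest.fixture(scope="session")
def desk_models(desk_comparison):
    return desk_comparison[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
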