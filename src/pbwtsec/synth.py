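"""Synthetic haplotype panels with linkage structure, and planted queries.

Real population panels (the intended input is a phased SNP panel such as a
1000 Genomes chromosome) contain long shared haplotype blocks, so
set-longest matches of widely varying length exist.  The generator emulates
this with a founder-recombination model: each haplotype is a mosaic of a
small number of founder sequences with geometrically distributed block
lengths, plus point mutations.  It makes no attempt at demographic realism
(no coalescent genealogy, no allele-frequency spectrum) - it exists to give
the search and protocol tests panels whose match-length distribution is
panel-like rather than i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel

__all__ = ["SynthConfig", "generate_panel", "sample_query"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the founder-recombination generator.

    Defaults give a panel whose typical set-longest matches span roughly
    5-30 positions, the regime of an SNP query of a few dozen sites.
    """

    M: int = 100
    N: int = 200
    alphabet_size: int = 2
    n_founders: int = 4
    block_length_mean: float = 20.0
    mutation_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError("panel dimensions must be positive")
        if self.alphabet_size < 2:
            raise ValueError("alphabet size must be at least 2")
        if self.n_founders < 1:
            raise ValueError("need at least one founder haplotype")
        if self.block_length_mean < 1.0:
            raise ValueError("mean block length must be at least 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")


def generate_panel(cfg: SynthConfig) -> HaplotypePanel:
    """Generate a deterministic panel from a config (same seed, same panel)."""
    rng = np.random.default_rng(cfg.seed)
    founders = rng.integers(0, cfg.alphabet_size, size=(cfg.n_founders, cfg.N))
    seqs = np.empty((cfg.M, cfg.N), dtype=np.int64)
    p_switch = 1.0 / cfg.block_length_mean
    for i in range(cfg.M):
        pos = 0
        while pos < cfg.N:
            length = int(rng.geometric(p_switch))
            src = int(rng.integers(cfg.n_founders))
            end = min(pos + length, cfg.N)
            seqs[i, pos:end] = founders[src, pos:end]
            pos = end
    if cfg.mutation_rate > 0.0:
        hits = rng.random(seqs.shape) < cfg.mutation_rate
        shift = rng.integers(1, cfg.alphabet_size, size=seqs.shape)
        seqs[hits] = (seqs[hits] + shift[hits]) % cfg.alphabet_size
    return HaplotypePanel(seqs, alphabet_size=cfg.alphabet_size)


def sample_query(
    panel: HaplotypePanel,
    t: int,
    ell: int,
    divergence_point: int,
    seed: int | None = None,
) -> np.ndarray:
    """Plant a query of length ell at position t with a controllable match.

    The query copies a random panel row for ``divergence_point`` symbols and
    then flips every remaining symbol away from that row, so the donor row
    matches exactly ``divergence_point`` symbols.  The panel-wide
    set-longest match is therefore at least ``divergence_point`` (another
    row may match longer).
    """
    if not 1 <= t <= panel.N or t + ell - 1 > panel.N:
        raise ValueError("query window out of panel range")
    if not 0 <= divergence_point <= ell:
        raise ValueError("divergence point must lie in 0..ell")
    rng = np.random.default_rng(seed)
    donor = panel.sequences[int(rng.integers(panel.M)), t - 1 : t - 1 + ell]
    query = donor.copy()
    tail = ell - divergence_point
    if tail:
        shift = rng.integers(1, panel.alphabet_size, size=tail)
        query[divergence_point:] = (query[divergence_point:] + shift) % panel.alphabet_size
    return query
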