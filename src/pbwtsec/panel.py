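"""Haplotype panels: the server-side database of aligned allele sequences.

A panel is an M x N integer matrix over the alphabet {0, ..., |sigma|-1}:
M haplotypes observed at N aligned genomic positions (1-based positions
1..N in all search APIs).  For biallelic SNP panels the alphabet is binary
with REF -> 0 and ALT -> 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["HaplotypePanel", "read_panel", "write_panel", "read_vcf"]


@dataclass(frozen=True)
class HaplotypePanel:
    """An M x N matrix of allele symbols plus its alphabet size."""

    sequences: np.ndarray
    alphabet_size: int = 2

    def __post_init__(self) -> None:
        seqs = np.asarray(self.sequences)
        if seqs.ndim != 2 or seqs.size == 0:
            raise ValueError("panel must be a non-empty M x N matrix")
        if not np.issubdtype(seqs.dtype, np.integer):
            seqs = seqs.astype(np.int64)
        if self.alphabet_size < 2:
            raise ValueError("alphabet size must be at least 2")
        if seqs.min() < 0 or seqs.max() >= self.alphabet_size:
            raise ValueError(
                f"allele symbols must lie in 0..{self.alphabet_size - 1}"
            )
        object.__setattr__(self, "sequences", seqs)

    @property
    def M(self) -> int:
        return int(self.sequences.shape[0])

    @property
    def N(self) -> int:
        return int(self.sequences.shape[1])

    def row(self, i: int) -> np.ndarray:
        """Return haplotype i (0-based row index)."""
        return self.sequences[i]


def write_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel in the plain-text format: header ``M N |sigma|`` then
    one digit-string row per haplotype."""
    if panel.alphabet_size > 10:
        raise ValueError("plain panel format supports alphabets up to 10 symbols")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{panel.M} {panel.N} {panel.alphabet_size}\n")
        for i in range(panel.M):
            fh.write("".join(str(int(s)) for s in panel.sequences[i]) + "\n")


def read_panel(path: str | Path, format: str = "plain") -> HaplotypePanel:
    """Load a panel from ``plain`` text or ``vcf`` format."""
    if format == "plain":
        return _read_plain(Path(path))
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown panel format: {format!r}")


def _read_plain(path: Path) -> HaplotypePanel:
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError(f"{path}:1: header must be 'M N |sigma|'")
        try:
            m, n, a = (int(x) for x in header)
        except ValueError as exc:
            raise ValueError(f"{path}:1: non-integer header field") from exc
        rows = np.empty((m, n), dtype=np.int64)
        for i in range(m):
            line = fh.readline().strip()
            if len(line) != n:
                raise ValueError(
                    f"{path}:{i + 2}: expected {n} symbols, got {len(line)}"
                )
            try:
                rows[i] = [int(ch) for ch in line]
            except ValueError as exc:
                raise ValueError(f"{path}:{i + 2}: non-digit symbol") from exc
    return HaplotypePanel(rows, alphabet_size=a)


def read_vcf(path: str | Path) -> HaplotypePanel:
    """Build a binary panel from phased biallelic SNP records of a VCF.

    Each sample contributes two rows (one per haplotype); REF maps to 0 and
    ALT to 1.  Indel and multi-allelic records are skipped (with a log
    message); an unphased genotype is an error, never silently phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise ValueError(f"{path}: VCF has no samples")
    columns: list[np.ndarray] = []
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            logger.info("skipping non-biallelic-SNP record at %s:%s", rec.CHROM, rec.POS)
            continue
        col = np.empty(2 * n_samples, dtype=np.int64)
        for s, gt in enumerate(rec.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise ValueError(
                    f"{path}: unphased genotype for sample {vcf.samples[s]} "
                    f"at {rec.CHROM}:{rec.POS}"
                )
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"{path}: missing genotype at {rec.CHROM}:{rec.POS}"
                )
            col[2 * s] = a0
            col[2 * s + 1] = a1
        columns.append(col)
    if not columns:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    return HaplotypePanel(np.column_stack(columns), alphabet_size=2)
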