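"""Shared data model: genotype matrices, sample metadata, windows and allele frequencies.

Conventions used throughout the package:

* VCF positions are 1-based; windows are 0-based half-open (BED convention).
  A site at position ``P`` belongs to the window with ``start <= P - 1 < end``.
* Diploid genotypes are coded 0/1/2 = number of alternate alleles; ``-1``
  marks a missing genotype.
* Taxon labels are the five analysis groups: ``s`` (C. seguinii),
  ``m`` (C. mollissima), ``h`` (C. henryi var. henryi), ``o`` (the putative
  hybrid lineage, C. henryi var. omeiensis) and ``outgroup``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("hhscan")

MISSING = -1
TAXA = ("s", "m", "h", "o", "outgroup")


class VCFOrderError(ValueError):
    """Raised when a VCF is not coordinate-sorted within contigs."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for all samples on one or more contigs.

    Attributes
    ----------
    contig : array of str, one entry per site.
    pos : int64 array, 1-based positions, strictly increasing per contig.
    ref, alt : arrays of single-base alleles per site.
    geno : int8 array of shape (n_sites, n_samples); 0/1/2 alternate-allele
        dosage, -1 missing.
    samples : list of sample ids (column order of ``geno``).
    contig_lengths : mapping contig id -> length in bp.
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    samples: list[str]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.pos), len(self.samples)):
            raise ValueError("geno shape does not match site/sample counts")
        if self.geno.size and not (
            int(self.geno.min()) >= MISSING and int(self.geno.max()) <= 2
        ):
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        for ctg in dict.fromkeys(self.contig.tolist()):
            p = self.pos[self.contig == ctg]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                i = int(np.argmin(np.diff(p) > 0))
                raise VCFOrderError(
                    f"positions not strictly increasing on {ctg} near {p[i + 1]}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)


@dataclass
class SampleMetadata:
    """Maps every sample id to exactly one taxon label."""

    taxon_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {t for t in self.taxon_of.values() if t not in TAXA}
        if bad:
            raise ValueError(f"unknown taxon labels {sorted(bad)}; expected {TAXA}")

    def samples_of(self, taxon: str) -> list[str]:
        return [s for s, t in self.taxon_of.items() if t == taxon]

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        vcf = set(matrix.samples)
        meta = set(self.taxon_of)
        unknown = meta - vcf
        if unknown:
            raise ValueError(f"metadata samples absent from VCF: {sorted(unknown)}")
        unmapped = vcf - meta
        if unmapped:
            raise ValueError(f"VCF samples missing from metadata: {sorted(unmapped)}")


@dataclass(frozen=True)
class WindowSpec:
    """One genomic window, 0-based half-open."""

    contig: str
    start: int
    end: int
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TaxonFreqs:
    """Per-site alternate-allele frequency and usable allele count for one taxon."""

    p: np.ndarray  # alternate-allele frequency, NaN where n == 0
    n: np.ndarray  # non-missing allele copies
    usable: np.ndarray  # n >= min_alleles

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


@dataclass
class FreqTable:
    """Per-taxon allele frequencies at every retained site.

    Arrays are aligned with the site axis of the originating
    :class:`GenotypeMatrix` (``contig``/``pos`` are carried along so windowed
    statistics can slice sites without going back to genotypes).
    """

    contig: np.ndarray
    pos: np.ndarray
    taxa: dict[str, TaxonFreqs]
    min_alleles: int
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def usable_mask(self, taxa) -> np.ndarray:
        """Sites usable in every named taxon."""
        mask = np.ones(self.n_sites, dtype=bool)
        for t in taxa:
            mask &= self.taxa[t].usable
        return mask

    def site_indices(self, window: WindowSpec) -> np.ndarray:
        """Indices of sites falling in ``window`` (1-based pos vs half-open window)."""
        on_contig = np.flatnonzero(self.contig == window.contig)
        p0 = self.pos[on_contig] - 1  # to 0-based
        lo = np.searchsorted(p0, window.start, side="left")
        hi = np.searchsorted(p0, window.end, side="left")
        return on_contig[lo:hi]


def read_sample_metadata(path) -> SampleMetadata:
    """Read a two-column TSV ``sample_id<TAB>taxon``."""
    taxon_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"bad metadata line: {line!r}")
            sample, taxon = fields
            if sample in taxon_of:
                raise ValueError(f"duplicate sample {sample!r} in metadata")
            taxon_of[sample] = taxon
    return SampleMetadata(taxon_of)


def read_contig_lengths(path) -> dict[str, int]:
    """Read a two-column TSV ``contig<TAB>length``."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ctg, ln = line.split("\t")
            lengths[ctg] = int(ln)
    return lengths


def read_variants(vcf_path, metadata_path, contig_lengths=None):
    """Load biallelic SNPs from a VCF plus the sample->taxon map.

    Multiallelic and non-SNP records are dropped (counts logged). Missing
    genotypes are preserved as ``-1``. Contig lengths come from the VCF
    header when present, else from ``contig_lengths`` (a dict or a TSV path).

    Returns
    -------
    (GenotypeMatrix, SampleMetadata)
    """
    from cyvcf2 import VCF

    meta = read_sample_metadata(metadata_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)

    lengths: dict[str, int] = {}
    if vcf.seqnames and vcf.seqlens:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    if contig_lengths is not None:
        if not isinstance(contig_lengths, dict):
            contig_lengths = read_contig_lengths(contig_lengths)
        lengths.update(contig_lengths)

    contigs, pos, ref, alt, rows = [], [], [], [], []
    n_dropped = 0
    last: dict[str, int] = {}
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_dropped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise VCFOrderError(
                f"VCF not coordinate-sorted: {v.CHROM}:{v.POS} after {last[v.CHROM]}"
            )
        last[v.CHROM] = v.POS
        contigs.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = v.gt_types.astype(np.int8)  # gts012: 0,1,2; 3 = unknown
        g[g == 3] = MISSING
        rows.append(g)
    logger.info("read %d biallelic SNPs, dropped %d records", len(pos), n_dropped)

    matrix = GenotypeMatrix(
        contig=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        geno=(
            np.vstack(rows)
            if rows
            else np.empty((0, len(samples)), dtype=np.int8)
        ),
        samples=samples,
        contig_lengths=lengths,
    )
    meta.validate_against(matrix)
    return matrix, meta


def allele_frequencies(
    matrix: GenotypeMatrix, meta: SampleMetadata, min_alleles: int = 40
) -> FreqTable:
    """Per-taxon alternate-allele frequencies from non-missing genotypes.

    ``min_alleles`` is the usability floor in allele copies: with the default
    of 40 a taxon needs >= 20 fully called diploids at a site (the stricter
    reading of a "sample size >= 20" screen); pass 20 for the allele-copy
    reading. The floor is capped at a taxon's own capacity (2 x its sample
    count), so a small group — e.g. a handful of outgroup trees — is usable
    wherever it is fully called. Sites below the floor are flagged unusable
    for that taxon, never fabricated.
    """
    if min_alleles < 1:
        raise ValueError("min_alleles must be >= 1")
    taxa: dict[str, TaxonFreqs] = {}
    for taxon in TAXA:
        ids = meta.samples_of(taxon)
        present = [s for s in ids if s in matrix.samples]
        if not present:
            continue
        sub = matrix.geno[:, matrix.sample_index(present)]
        called = sub != MISSING
        n = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        floor = min(min_alleles, 2 * len(present))
        taxa[taxon] = TaxonFreqs(
            p=p.astype(float), n=n.astype(np.int64), usable=n >= floor
        )
    return FreqTable(
        contig=matrix.contig,
        pos=matrix.pos,
        taxa=taxa,
        min_alleles=min_alleles,
        contig_lengths=dict(matrix.contig_lengths),
    )


def iter_windows(contig_lengths: dict[str, int], size: int) -> list[WindowSpec]:
    """Tile each contig with nonoverlapping windows of ``size`` bp.

    The terminal window of a contig may be shorter; windows cover every bp
    exactly once.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows = []
    idx = 0
    for ctg, length in contig_lengths.items():
        for start in range(0, length, size):
            windows.append(WindowSpec(ctg, start, min(start + size, length), idx))
            idx += 1
    return windows
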