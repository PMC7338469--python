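"""Synthetic-data generator: coalescent datasets with known admixture truth.

Simulates the four-taxon-plus-outgroup hybrid-speciation demography
(:class:`hhscan.sfs.DemographicModel`) window by window: each nonoverlapping
window gets its own recombination rate and migration regime, drawn from a
:class:`GenomeLayout`, and windows are independent genealogies. "Barrier"
windows reduce h<->m migration by a configurable factor while h<->s
migration persists; optionally they also force the hybrid o's ancestry to a
single parental donor, emulating post-hybridization fixation of barrier
alleles. A :class:`TruthTable` records the per-window regime, recombination
rate and donor plus the global parameters, so genome-scan recovery can be
scored against ground truth.

Default desk scale: 2 contigs x 10 Mb, 100 kb windows, 10 diploids per
ingroup taxon and 4 outgroup diploids. All randomness flows from one seed
through ``numpy`` SeedSequence spawning; the same seed reproduces the same
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .core import (
    FreqTable,
    GenotypeMatrix,
    SampleMetadata,
    TaxonFreqs,
    WindowSpec,
    iter_windows,
)
from .sfs import DemographicModel

NORMAL = "normal"
BARRIER_HM = "barrier_hm"
BARRIER_HS = "barrier_hs"


@dataclass
class GenomeLayout:
    """Window tiling plus per-window recombination rate and migration regime."""

    contig_lengths: dict[str, int]
    window_size: int = 100_000
    recomb_rate: np.ndarray | float = 4.4e-8  # per bp per generation, per window
    regimes: np.ndarray | None = None  # regime tag per window
    donors: np.ndarray | None = None  # forced o donor per window: '', 'h' or 'm'
    migration_factor: float = 0.0  # multiplier on the reduced rate in barrier windows

    def __post_init__(self) -> None:
        self.windows = iter_windows(self.contig_lengths, self.window_size)
        n = len(self.windows)
        if np.isscalar(self.recomb_rate):
            self.recomb_rate = np.full(n, float(self.recomb_rate))
        self.recomb_rate = np.asarray(self.recomb_rate, dtype=float)
        if self.regimes is None:
            self.regimes = np.array([NORMAL] * n, dtype=object)
        if self.donors is None:
            self.donors = np.array([""] * n, dtype=object)
        if not (len(self.recomb_rate) == len(self.regimes) == len(self.donors) == n):
            raise ValueError("per-window arrays must match the window count")
        if (self.recomb_rate < 0).any():
            raise ValueError("recombination rates must be >= 0")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class TruthTable:
    """Per-window simulated ground truth plus the global parameter draw."""

    table: pd.DataFrame
    globals: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.globals.items():
                fh.write(f"#{k}={v}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        import io

        g = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, v = line[1:].rstrip("\n").split("=", 1)
                    try:
                        g[k] = float(v) if ("." in v or "e" in v) else int(v)
                    except ValueError:
                        g[k] = v
                else:
                    body.append(line)
        t = pd.read_csv(io.StringIO("".join(body)), sep="\t")
        return cls(table=t, globals=g)


def default_model(**kwargs) -> DemographicModel:
    """Desk-scale defaults for the hybrid-speciation demography (docs/methods.md)."""
    return DemographicModel(**kwargs)


def default_layout(
    n_contigs: int = 2,
    contig_length: int = 10_000_000,
    window_size: int = 100_000,
    recomb_rate=4.4e-8,
    **kwargs,
) -> GenomeLayout:
    lengths = {f"ctg{i + 1}": contig_length for i in range(n_contigs)}
    return GenomeLayout(lengths, window_size, recomb_rate, **kwargs)


def lognormal_rho(layout: GenomeLayout, sigma: float = 0.7, seed: int = 0) -> GenomeLayout:
    """Replace the layout's recombination rates with lognormal draws whose
    median is the current mean rate (window-heterogeneous map)."""
    rng = np.random.default_rng(seed)
    med = float(np.mean(layout.recomb_rate))
    layout.recomb_rate = med * rng.lognormal(0.0, sigma, layout.n_windows)
    return layout


def plant_barriers(
    layout: GenomeLayout,
    fraction: float,
    rho_bias: float = 0.0,
    migration_factor: float = 0.0,
    forced_donor: str | None = None,
    seed: int = 0,
) -> GenomeLayout:
    """Mark ceil(fraction * n_windows) windows as barrier_hm.

    Sampling weights decrease with the window recombination rate when
    ``rho_bias > 0`` (weights ``rho^-rho_bias``), placing barriers
    preferentially in low-recombination windows. ``forced_donor`` fixes the
    o ancestry of barrier windows to 'h', 'm', or an independent coin flip
    per window ('random'); None leaves the pulse mixture untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_plant = int(np.ceil(fraction * layout.n_windows))
    if n_plant == 0:
        return layout
    rng = np.random.default_rng(seed)
    rho = np.asarray(layout.recomb_rate, dtype=float)
    if rho_bias > 0:
        w = np.power(np.clip(rho, rho[rho > 0].min() * 1e-3, None), -rho_bias)
    else:
        w = np.ones_like(rho)
    idx = rng.choice(layout.n_windows, size=n_plant, replace=False, p=w / w.sum())
    layout.regimes[idx] = BARRIER_HM
    layout.migration_factor = migration_factor
    if forced_donor is not None:
        if forced_donor == "random":
            layout.donors[idx] = rng.choice(["h", "m"], size=n_plant)
        elif forced_donor in ("h", "m"):
            layout.donors[idx] = forced_donor
        else:
            raise ValueError("forced_donor must be 'h', 'm', 'random' or None")
    return layout


def _window_model(model: DemographicModel, regime: str, donor: str,
                  factor: float) -> DemographicModel:
    from dataclasses import replace

    kw = {}
    if regime == BARRIER_HM:
        kw["m_hm"] = model.m_hm * factor
    elif regime == BARRIER_HS:
        kw["m_hs"] = model.m_hs * factor
    if donor == "h":
        kw["H"] = 0.0
    elif donor == "m":
        kw["H"] = 1.0
    return replace(model, **kw) if kw else model


def simulate_dataset(
    model: DemographicModel,
    layout: GenomeLayout,
    n_per_taxon: int = 10,
    n_outgroup: int = 4,
    seed: int = 1,
) -> tuple[GenotypeMatrix, SampleMetadata, TruthTable]:
    """Window-by-window coalescent simulation of the full dataset.

    Returns the concatenated biallelic genotype matrix (binary mutation
    model, so every site is a 0/1 SNP), the sample->taxon map, and the truth
    table. Sample ids are ``<taxon><i>``.
    """
    taxa_n = {"s": n_per_taxon, "m": n_per_taxon, "h": n_per_taxon,
              "o": n_per_taxon, "outgroup": n_outgroup}
    for t, n in taxa_n.items():
        if n < 1:
            raise ValueError(f"need >= 1 diploid in taxon {t}")
    samples = [f"{t}{i + 1}" for t in taxa_n for i in range(taxa_n[t])]
    meta = SampleMetadata({f"{t}{i + 1}": t for t in taxa_n for i in range(taxa_n[t])})

    ss = np.random.SeedSequence(seed)
    child_seeds = [
        int(s.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1) + 1)
        for s in ss.spawn(2 * layout.n_windows)
    ]

    contigs, pos, rows = [], [], []
    truth_rows = []
    for wi, w in enumerate(layout.windows):
        regime = layout.regimes[wi]
        donor = layout.donors[wi]
        wmodel = _window_model(model, regime, donor, layout.migration_factor)
        demog = wmodel.to_demography()
        anc = msprime.sim_ancestry(
            samples=taxa_n,
            demography=demog,
            sequence_length=w.length,
            recombination_rate=float(layout.recomb_rate[wi]),
            random_seed=child_seeds[2 * wi],
        )
        ts = msprime.sim_mutations(
            anc, rate=model.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=child_seeds[2 * wi + 1],
        )
        if ts.num_sites:
            g = ts.genotype_matrix()  # (sites, haplotypes) in sample order
            geno = (g[:, ::2] + g[:, 1::2]).astype(np.int8)
            site_pos = (
                w.start + np.floor(ts.tables.sites.position).astype(np.int64) + 1
            )
            # discrete-genome collisions cannot occur (finite sites), but a
            # site may be non-variant after back mutation; keep segregating only
            seg = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < 2 * geno.shape[1])
            rows.append(geno[seg])
            pos.append(site_pos[seg])
            contigs.append(np.full(int(seg.sum()), w.contig, dtype=object))
        truth_rows.append(
            {
                "contig": w.contig, "start": w.start, "end": w.end,
                "regime": regime, "rho": float(layout.recomb_rate[wi]),
                "donor": donor if donor else ("mixed" if model.H not in (0, 1) else
                                              ("m" if model.H == 1 else "h")),
                "m_hm": wmodel.m_hm, "m_hs": wmodel.m_hs,
                "barrier": regime == BARRIER_HM,
            }
        )

    if rows:
        geno_all = np.vstack(rows)
        pos_all = np.concatenate(pos)
        ctg_all = np.concatenate(contigs)
    else:
        geno_all = np.empty((0, len(samples)), dtype=np.int8)
        pos_all = np.empty(0, dtype=np.int64)
        ctg_all = np.empty(0, dtype=object)
    n_sites = len(pos_all)
    matrix = GenotypeMatrix(
        contig=ctg_all,
        pos=pos_all,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        geno=geno_all,
        samples=samples,
        contig_lengths=dict(layout.contig_lengths),
    )
    truth = TruthTable(
        table=pd.DataFrame(truth_rows),
        globals={
            "H": model.H, "t1": model.t1, "t2": model.t2, "t3": model.t3,
            "t_out": model.t_out, "m_hm": model.m_hm, "m_hs": model.m_hs,
            "m_anc": model.m_anc, "mutation_rate": model.mutation_rate,
            "default_size": model.default_size, "seed": seed,
        },
    )
    return matrix, meta, truth


def freq_fixture(
    spec_table: dict[str, "np.ndarray | list"],
    n_alleles: int = 20,
    contig: str = "fix1",
    spacing: int = 100,
    min_alleles: int | None = None,
    contig_length: int | None = None,
) -> FreqTable:
    """Exact allele-frequency tables from literal per-taxon frequency lists.

    Builds a FreqTable directly (bypassing genotypes) for arithmetic unit
    tests; all taxa share the site count and every site is usable.
    """
    if not spec_table:
        return FreqTable(
            contig=np.empty(0, dtype=object), pos=np.empty(0, dtype=np.int64),
            taxa={}, min_alleles=min_alleles or n_alleles, contig_lengths={},
        )
    lengths = {len(np.atleast_1d(v)) for v in spec_table.values()}
    if len(lengths) != 1:
        raise ValueError("all taxa must list the same number of sites")
    k = lengths.pop()
    taxa = {}
    for t, p in spec_table.items():
        p = np.asarray(p, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"frequencies for {t!r} outside [0, 1]")
        taxa[t] = TaxonFreqs(
            p=p, n=np.full(k, n_alleles, dtype=np.int64),
            usable=np.ones(k, dtype=bool),
        )
    pos = np.arange(1, k + 1, dtype=np.int64) * spacing
    return FreqTable(
        contig=np.full(k, contig, dtype=object),
        pos=pos,
        taxa=taxa,
        min_alleles=min_alleles if min_alleles is not None else n_alleles,
        contig_lengths={contig: contig_length or int(pos[-1] + spacing)},
    )


# ---------------------------------------------------------------------------
# Output writing (all plain text, reloadable by hhscan.core)
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal sorted VCF v4.2 with contig headers and GT fields."""
    GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hhscan-simulate\n")
        for ctg, ln in matrix.contig_lengths.items():
            fh.write(f"##contig=<ID={ctg},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples) + "\n"
        )
        for i in range(matrix.n_sites):
            gts = "\t".join(GT[int(g)] for g in matrix.geno[i])
            fh.write(
                f"{matrix.contig[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_outputs(
    matrix: GenotypeMatrix,
    meta: SampleMetadata,
    truth: TruthTable,
    outdir,
) -> dict[str, Path]:
    """Write VCF, metadata TSV, truth TSV, rho BED and contig lengths TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "sim.vcf",
        "meta": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "rho": outdir / "rho.bed",
        "contigs": outdir / "contigs.tsv",
    }
    write_vcf(matrix, paths["vcf"])
    with open(paths["meta"], "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s}\t{meta.taxon_of[s]}\n")
    truth.to_tsv(paths["truth"])
    truth.table[["contig", "start", "end", "rho"]].to_csv(
        paths["rho"], sep="\t", index=False, header=False
    )
    with open(paths["contigs"], "w") as fh:
        for ctg, ln in matrix.contig_lengths.items():
            fh.write(f"{ctg}\t{ln}\n")
    return paths
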