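"""Unfolded joint 2D-SFS and coalescent composite-likelihood model selection.

The observed spectrum is counted directly from called genotypes: sites are
polarized by outgroup consensus, derived-allele counts are projected down to
fixed sample sizes with hypergeometric weights, and the resulting matrix is
compared to Monte-Carlo expected spectra under explicit demographic models
via a multinomial composite log-likelihood (monomorphic corner cells always
excluded; rare observed cells pooled, mirroring the minimum-entry masking
convention of SFS-based demographic fitting).

Expected spectra come from msprime: the mean branch-mode joint allele
frequency spectrum over ``n_sims`` independent non-recombining genealogies,
which is the infinite-sites expectation without mutation-sampling noise.

Model fitting uses a common-random-number grid over the single free
parameter (every likelihood evaluation reuses the same simulation seed, so
the profile is smooth in the parameter), a parabolic refinement, and a final
full-budget evaluation at the optimum. Passing the same seed to the fits of
competing models makes their final log-likelihoods directly comparable and
keeps AIC from rewarding Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix


@dataclass
class SFS2D:
    """Joint unfolded SFS: ``matrix[i, j]`` = (possibly fractional) count of
    sites with i derived copies in population A and j in B."""

    matrix: np.ndarray
    n_A: int
    n_B: int
    n_sites: float

    def proportions(self, mask_corners: bool = True) -> np.ndarray:
        m = self.matrix.astype(float).copy()
        if mask_corners:
            m[0, 0] = 0.0
            m[self.n_A, self.n_B] = 0.0
        tot = m.sum()
        return m / tot if tot > 0 else m


@dataclass
class DemographicModel:
    """The four-taxon hybrid-speciation demography plus its outgroup.

    Backwards in time: the hybrid o merges into its parents m and h at
    ``t3`` (fraction ``H`` into m), s and m merge into A_sm at ``t2``,
    A_sm and h merge at ``t1``, and the outgroup joins at ``t_out``.
    Optional continuous migration: h<->m between the present and ``t2``
    (rate ``m_hm`` per generation: the parents remain in sympatric contact —
    the hybrid lineage itself attests to recent m-h hybridization), h<->s
    between ``t3`` and ``t2`` (``m_hs``: s-h exchange is historical, ending
    by the time o formed, since s is allopatric today), and h<->A_sm between
    ``t2`` and ``t1`` (``m_anc``). Times are generations; ``from_years``
    converts, using the configured generation time.
    """

    tag: str = "model3"
    t1: float = 30_000.0
    t2: float = 15_000.0
    t3: float = 1_000.0
    t_out: float = 90_000.0
    H: float = 0.25
    sizes: dict = field(default_factory=dict)  # overrides per population
    default_size: float = 5_000.0
    m_hm: float = 0.0
    m_hs: float = 0.0
    m_anc: float = 0.0
    mutation_rate: float = 7.5e-8  # per site per generation (5e-9/yr x 15 yr/gen)
    generation_time: float = 15.0

    POPS = ("s", "m", "h", "o", "outgroup", "A_sm", "A_shm", "root")

    def __post_init__(self) -> None:
        if not (self.t_out > self.t1 > self.t2 > self.t3 > 0):
            raise ValueError("need t_out > t1 > t2 > t3 > 0")
        if not 0.0 <= self.H <= 1.0:
            raise ValueError("H must be in [0, 1]")
        if self.tag == "model1" and self.H != 0.0:
            raise ValueError("model1 forces H = 0")
        if self.tag == "model2" and self.H != 1.0:
            raise ValueError("model2 forces H = 1")
        if self.tag == "barrierA" and not self.m_hm < self.m_anc:
            raise ValueError("barrierA forces m_hm < m_anc")
        if self.tag == "barrierB" and not self.m_hm >= self.m_anc:
            raise ValueError("barrierB forces m_hm >= m_anc")
        for v in (self.default_size, *self.sizes.values()):
            if v <= 0:
                raise ValueError("population sizes must be positive")

    def size(self, pop: str) -> float:
        return float(self.sizes.get(pop, self.default_size))

    @classmethod
    def from_years(cls, t1_years, t2_years, t3_years, t_out_years,
                   generation_time: float = 15.0, **kwargs) -> "DemographicModel":
        g = generation_time
        return cls(
            t1=t1_years / g, t2=t2_years / g, t3=t3_years / g,
            t_out=t_out_years / g, generation_time=g, **kwargs,
        )

    def to_demography(self) -> msprime.Demography:
        d = msprime.Demography()
        for pop in self.POPS:
            d.add_population(name=pop, initial_size=self.size(pop))
        if self.m_hm > 0:
            d.set_symmetric_migration_rate(["h", "m"], self.m_hm)
        d.add_admixture(
            time=self.t3, derived="o", ancestral=["m", "h"],
            proportions=[self.H, 1.0 - self.H],
        )
        if self.m_hs > 0:
            d.add_symmetric_migration_rate_change(
                time=self.t3, populations=["h", "s"], rate=self.m_hs
            )
        d.add_population_split(time=self.t2, derived=["s", "m"], ancestral="A_sm")
        if self.m_anc > 0:
            d.add_symmetric_migration_rate_change(
                time=self.t2, populations=["h", "A_sm"], rate=self.m_anc
            )
        d.add_population_split(time=self.t1, derived=["A_sm", "h"], ancestral="A_shm")
        d.add_population_split(
            time=self.t_out, derived=["A_shm", "outgroup"], ancestral="root"
        )
        d.sort_events()
        return d


# ---------------------------------------------------------------------------
# Observed SFS from genotypes
# ---------------------------------------------------------------------------

def polarize_sites(matrix: GenotypeMatrix, outgroup_samples) -> np.ndarray:
    """Ancestral-state per site: 0 = REF ancestral, 1 = ALT ancestral,
    -1 = unpolarized (outgroup missing, polymorphic or heterozygous)."""
    if not list(outgroup_samples):
        raise ValueError("no outgroup samples given")
    sub = matrix.geno[:, matrix.sample_index(outgroup_samples)]
    called = sub >= 0
    any_called = called.any(axis=1)
    all_ref = np.where(called, sub == 0, True).all(axis=1)
    all_alt = np.where(called, sub == 2, True).all(axis=1)
    anc = np.full(matrix.n_sites, -1, dtype=np.int8)
    anc[any_called & all_ref] = 0
    anc[any_called & all_alt] = 1
    return anc


def derived_counts(matrix: GenotypeMatrix, samples, anc: np.ndarray):
    """Per-site derived-allele count and called allele copies for one group."""
    sub = matrix.geno[:, matrix.sample_index(samples)]
    called = sub >= 0
    n = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    d = np.where(anc == 0, alt, n - alt)
    d[anc < 0] = -1
    return d.astype(np.int64), n.astype(np.int64)


def _projection_weights(d, n, m) -> np.ndarray:
    """Hypergeometric projection: row s holds P(j derived in a draw of m | d of n)."""
    j = np.arange(m + 1)
    return stats.hypergeom.pmf(j[None, :], n[:, None], d[:, None], m)


def joint_sfs(
    matrix: GenotypeMatrix,
    samples_A,
    samples_B,
    anc: np.ndarray,
    projection: tuple[int, int],
) -> SFS2D:
    """Unfolded joint SFS of two groups, projected to fixed sample sizes.

    Sites are kept only if polarized and with at least ``projection`` called
    allele copies in each group; each retained site adds one unit of mass
    spread over cells by the product of per-group hypergeometric weights.
    """
    mA, mB = projection
    dA, nA = derived_counts(matrix, samples_A, anc)
    dB, nB = derived_counts(matrix, samples_B, anc)
    keep = (anc >= 0) & (nA >= mA) & (nB >= mB)
    from .core import logger

    logger.info("joint_sfs: %d of %d sites retained", int(keep.sum()), matrix.n_sites)
    WA = _projection_weights(dA[keep], nA[keep], mA)
    WB = _projection_weights(dB[keep], nB[keep], mB)
    return SFS2D(matrix=WA.T @ WB, n_A=mA, n_B=mB, n_sites=float(keep.sum()))


# ---------------------------------------------------------------------------
# Expected SFS and composite likelihood
# ---------------------------------------------------------------------------

def expected_sfs(
    model: DemographicModel,
    pops: tuple[str, str],
    n_A: int,
    n_B: int,
    n_sims: int = 20_000,
    seed: int = 1,
) -> np.ndarray:
    """Monte-Carlo expected joint-SFS proportions (corners excluded).

    ``n_A``/``n_B`` are haploid sample sizes. Averages the branch-mode joint
    allele-frequency spectrum over ``n_sims`` independent single-locus
    genealogies — the infinite-sites expectation given the genealogy, so no
    mutation noise enters.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_A % 2 or n_B % 2:
        raise ValueError("haploid sample sizes must be even (diploid samples)")
    demog = model.to_demography()
    samples = {pops[0]: n_A // 2, pops[1]: n_B // 2}
    total = np.zeros((n_A + 1, n_B + 1))
    reps = msprime.sim_ancestry(
        samples=samples, demography=demog, ploidy=2,
        num_replicates=n_sims, random_seed=seed,
    )
    sets = None
    for ts in reps:
        if sets is None:  # sample layout is identical across replicates
            sets = [ts.samples(population=demog[pops[0]].id),
                    ts.samples(population=demog[pops[1]].id)]
        total += ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=True
        )
    total[0, 0] = 0.0
    total[n_A, n_B] = 0.0
    s = total.sum()
    if s <= 0:
        raise RuntimeError("expected SFS degenerate (no segregating branch mass)")
    return total / s


def composite_loglik(
    observed: SFS2D, expected_proportions: np.ndarray, min_entry: int = 5
) -> float:
    """Multinomial composite log-likelihood with minimum-entry pooling.

    Corner cells are excluded. Observed cells with count < ``min_entry`` are
    pooled into a single residual cell on both the observed and expected
    side; ``min_entry=0`` disables pooling. Expected proportions are floored
    at 1e-12 to keep observed mass in empty expected cells finite.
    """
    obs = observed.matrix.astype(float).copy()
    exp = np.asarray(expected_proportions, dtype=float).copy()
    if obs.shape != exp.shape:
        raise ValueError("observed and expected SFS shapes differ")
    corner = np.zeros(obs.shape, dtype=bool)
    corner[0, 0] = corner[observed.n_A, observed.n_B] = True
    o = obs[~corner]
    e = exp[~corner]
    e = e / e.sum()
    if min_entry > 0:
        small = o < min_entry
        o_kept, e_kept = o[~small], e[~small]
        o = np.append(o_kept, o[small].sum())
        e = np.append(e_kept, e[small].sum())
    e = np.clip(e, 1e-12, None)
    return float((o * np.log(e)).sum())


# ---------------------------------------------------------------------------
# Model templates, fitting and AIC comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelTemplate:
    """A demographic model with one (or zero) free parameter.

    ``base`` supplies every fixed quantity; ``free_param`` names the
    DemographicModel field to optimize within ``bounds``. The model tag's
    constraints (e.g. model1 forcing H = 0) live in the base model.
    """

    name: str
    base: DemographicModel
    free_param: str | None = None
    bounds: tuple[float, float] | None = None

    @property
    def k(self) -> int:
        return 0 if self.free_param is None else 1

    def instantiate(self, value=None) -> DemographicModel:
        if self.free_param is None:
            return self.base
        return replace(self.base, **{self.free_param: float(value)})


@dataclass
class ModelFit:
    name: str
    params: dict
    free_param: str | None
    free_value: float | None
    loglik: float
    k: int
    aic: float
    n_sims: int
    seed: int
    trace: list


def fit_model(
    template: ModelTemplate,
    observed: SFS2D,
    pops: tuple[str, str],
    n_sims: int = 20_000,
    seed: int = 1,
    grid_points: int = 11,
    min_entry: int = 5,
) -> ModelFit:
    """Maximize the composite log-likelihood over the template's free parameter.

    ``n_sims`` is the total simulation budget for the fit: it is spread over
    a common-random-number grid of ``grid_points`` values of the free
    parameter, the best grid point is refined by a parabola through its
    neighbours, and the optimum is re-evaluated with the full budget (seeded
    by ``seed``; use the same seed for competing models so their final
    likelihoods share simulation randomness).
    """
    nA, nB = observed.n_A, observed.n_B

    def _eval(model, sims, s):
        e = expected_sfs(model, pops, nA, nB, n_sims=sims, seed=s)
        return composite_loglik(observed, e, min_entry=min_entry)

    trace: list = []
    if template.free_param is None:
        lnl = _eval(template.base, n_sims, seed)
        trace.append((None, lnl))
        best_val = None
    else:
        lo, hi = template.bounds
        grid = np.linspace(lo, hi, grid_points)
        per = max(200, n_sims // grid_points)
        lnls = []
        for v in grid:
            lnl_v = _eval(template.instantiate(v), per, seed + 1)  # CRN: shared seed
            lnls.append(lnl_v)
            trace.append((float(v), lnl_v))
        i = int(np.argmax(lnls))
        best_val = float(grid[i])
        if 0 < i < len(grid) - 1:
            y0, y1, y2 = lnls[i - 1], lnls[i], lnls[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # concave: parabola vertex
                step = 0.5 * (y0 - y2) / denom
                cand = float(grid[i] + step * (grid[1] - grid[0]))
                cand = min(max(cand, lo), hi)
                lnl_c = _eval(template.instantiate(cand), per, seed + 1)
                trace.append((cand, lnl_c))
                if lnl_c >= lnls[i]:
                    best_val = cand
        lnl = _eval(template.instantiate(best_val), n_sims, seed)
        trace.append((best_val, lnl))

    model = template.instantiate(best_val) if template.free_param else template.base
    params = {
        "tag": model.tag, "t1": model.t1, "t2": model.t2, "t3": model.t3,
        "t_out": model.t_out, "H": model.H, "m_hm": model.m_hm,
        "m_hs": model.m_hs, "m_anc": model.m_anc,
        "default_size": model.default_size,
    }
    return ModelFit(
        name=template.name, params=params, free_param=template.free_param,
        free_value=best_val, loglik=lnl, k=template.k,
        aic=2 * template.k - 2 * lnl, n_sims=n_sims, seed=seed, trace=trace,
    )


def fit_model_replicates(template, observed, pops, n_reps=20, n_sims=20_000, seed=1,
                         **kwargs):
    """Duplicate fits with different seeds; returns fits plus the SD of the
    free-parameter estimates across replicates."""
    fits = [
        fit_model(template, observed, pops, n_sims=n_sims, seed=seed + 1000 * r,
                  **kwargs)
        for r in range(n_reps)
    ]
    vals = [f.free_value for f in fits if f.free_value is not None]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return fits, sd


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted models by AIC; the winner carries delta_aic = 0."""
    t = pd.DataFrame(
        [
            {"model": f.name, "k": f.k, "loglik": f.loglik, "aic": f.aic,
             "free_param": f.free_param, "free_value": f.free_value}
            for f in fits
        ]
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    t["delta_aic"] = t["aic"] - t["aic"].iloc[0]
    t["winner"] = t["delta_aic"] == 0.0
    return t


def hybrid_origin_templates(base: DemographicModel) -> list[ModelTemplate]:
    """The three competing origins for o: sister to h (H=0), sister to m
    (H=1), or hybrid with free H."""
    return [
        ModelTemplate("model1", replace(base, tag="model1", H=0.0)),
        ModelTemplate("model2", replace(base, tag="model2", H=1.0)),
        ModelTemplate("model3", replace(base, tag="model3"),
                      free_param="H", bounds=(0.0, 1.0)),
    ]


def barrier_templates(base: DemographicModel, m_anc: float) -> list[ModelTemplate]:
    """Reduced vs non-reduced recent h<->m migration in a candidate window.

    barrierA lets m_hm float below the ancestral rate; barrierB pins
    m_hm = m_anc (migration unchanged since before the s/m split).
    """
    eps = 1e-9
    return [
        ModelTemplate(
            "barrierA", replace(base, tag="barrierA", m_anc=m_anc, m_hm=0.0),
            free_param="m_hm", bounds=(0.0, max(m_anc - eps, eps)),
        ),
        ModelTemplate(
            "barrierB", replace(base, tag="barrierB", m_anc=m_anc, m_hm=m_anc),
        ),
    ]
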