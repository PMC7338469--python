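"""Site-pattern (ABBA/BABA) introgression tests and f4-ratio admixture estimation.

For an ordered quartet (outgroup, T1, T2, T3) the frequency-weighted pattern
sums accumulate, per site,

    ABBA += q_out * q_1 * p_2 * p_3  +  p_out * p_1 * q_2 * q_3
    BABA += q_out * p_1 * q_2 * p_3  +  p_out * q_1 * p_2 * q_3
    BBAA += q_out * p_1 * p_2 * q_3  +  p_out * q_1 * q_2 * p_3

so ABBA measures derived-allele sharing between T2 and T3 and BABA between
T1 and T3. D = (ABBA - BABA)/(ABBA + BABA) is zero in expectation under the
species tree ((T1,T2),T3) with incomplete lineage sorting only.

The admixture proportion of the hybrid lineage o (fraction gamma derived from
the minor parent m, the rest from h) is estimated by the f4 ratio

    gamma = f4(out, s; o, h) / f4(out, s; m, h)

which is unbiased under the hybrid-speciation topology: after a pulse, o's
frequencies are a gamma-mixture of the parents', so the o-h contrast is
gamma times the m-h contrast, and projecting both onto the (out - s) axis
cancels the shared drift. Standard errors and z-scores come from a weighted
delete-one block jackknife over contiguous genomic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FreqTable


@dataclass
class PatternCounts:
    abba: float
    baba: float
    bbaa: float
    n_sites: int


@dataclass
class AdmixtureEstimate:
    gamma: float
    f4_num: float
    f4_den: float
    z: float
    p_value: float
    se_gamma: float
    n_blocks: int
    n_sites: int
    scope: str
    den_z: float = float("nan")  # jackknife z of the denominator f4 vs 0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def site_patterns(freqs: FreqTable, quartet) -> tuple[np.ndarray, ...]:
    """Per-site (abba, baba, bbaa) arrays for quartet = (out, T1, T2, T3) taxon names."""
    o, t1, t2, t3 = (freqs.taxa[t] for t in quartet)
    abba = o.q * t1.q * t2.p * t3.p + o.p * t1.p * t2.q * t3.q
    baba = o.q * t1.p * t2.q * t3.p + o.p * t1.q * t2.p * t3.q
    bbaa = o.q * t1.p * t2.p * t3.q + o.p * t1.q * t2.q * t3.p
    return abba, baba, bbaa


def site_pattern_counts(freqs: FreqTable, quartet, mask=None) -> PatternCounts:
    """Accumulated pattern sums over the usable sites selected by ``mask``."""
    for t in quartet:
        if t not in freqs.taxa:
            raise ValueError(f"quartet member {t!r} has no samples")
    abba, baba, bbaa = site_patterns(freqs, quartet)
    ok = freqs.usable_mask(quartet)
    if mask is not None:
        ok = ok & mask
    return PatternCounts(
        abba=float(abba[ok].sum()),
        baba=float(baba[ok].sum()),
        bbaa=float(bbaa[ok].sum()),
        n_sites=int(ok.sum()),
    )


def d_statistic(counts: PatternCounts) -> float:
    """D = (ABBA - BABA)/(ABBA + BABA); NaN when the denominator is zero."""
    tot = counts.abba + counts.baba
    return (counts.abba - counts.baba) / tot if tot > 0 else float("nan")


def site_f4(freqs: FreqTable, A, B, C, D) -> np.ndarray:
    """Per-site (p_A - p_B)(p_C - p_D)."""
    a, b, c, d = (freqs.taxa[t].p for t in (A, B, C, D))
    return (a - b) * (c - d)


def f4(freqs: FreqTable, A, B, C, D, mask=None) -> float:
    """Mean of (p_A - p_B)(p_C - p_D) over usable sites."""
    ok = freqs.usable_mask((A, B, C, D))
    if mask is not None:
        ok = ok & mask
    vals = site_f4(freqs, A, B, C, D)[ok]
    return float(vals.mean()) if len(vals) else float("nan")


# ---------------------------------------------------------------------------
# Weighted delete-one block jackknife (Busing-style, block sizes as weights)
# ---------------------------------------------------------------------------

def jackknife_ratio(num_b: np.ndarray, den_b: np.ndarray, weights=None):
    """SE of a ratio-of-sums statistic by weighted delete-one-block jackknife.

    ``num_b``/``den_b`` are per-block sums; the statistic is
    ``sum(num)/sum(den)``. Blocks are weighted by ``weights`` (default:
    ``den_b`` magnitudes, i.e. informative mass per block).

    Returns (theta_hat, se, n_blocks_used).
    """
    num_b = np.asarray(num_b, dtype=float)
    den_b = np.asarray(den_b, dtype=float)
    keep = den_b != 0
    N, Dn = num_b.sum(), den_b.sum()
    theta = N / Dn
    if weights is None:
        weights = np.abs(den_b)
    w = np.asarray(weights, dtype=float)[keep]
    num_b, den_b = num_b[keep], den_b[keep]
    B = len(num_b)
    if B < 2 or w.sum() <= 0:
        return theta, float("nan"), B
    n_tot = w.sum()
    loo = (N - num_b) / (Dn - den_b)  # delete-one estimates
    h = n_tot / w
    theta_J = B * theta - ((1 - w / n_tot) * loo).sum()
    tau = h * theta - (h - 1.0) * loo
    var = float(((tau - theta_J) ** 2 / (h - 1.0)).sum() / B)
    return float(theta), float(np.sqrt(max(var, 0.0))), B


def _block_ids_genomic(freqs: FreqTable, block_size: int) -> np.ndarray:
    """Assign every site to a contiguous genomic block of ``block_size`` bp."""
    ids = np.zeros(freqs.n_sites, dtype=np.int64)
    offset = 0
    for ctg in dict.fromkeys(freqs.contig.tolist()):
        sel = freqs.contig == ctg
        b = (freqs.pos[sel] - 1) // block_size
        ids[sel] = b + offset
        offset += b.max() + 1 if sel.any() else 0
    return ids


def _block_ids_equal_count(n_sites: int, n_blocks: int) -> np.ndarray:
    """Split ``n_sites`` ordered sites into ``n_blocks`` contiguous groups."""
    n_blocks = max(1, min(n_blocks, n_sites))
    return np.minimum((np.arange(n_sites) * n_blocks) // n_sites, n_blocks - 1)


def _block_sums(values: np.ndarray, ids: np.ndarray, n_blocks: int) -> np.ndarray:
    return np.bincount(ids, weights=values, minlength=n_blocks)


def d_test(
    freqs: FreqTable,
    quartet,
    mask=None,
    n_blocks: int = 10,
    block_ids=None,
):
    """D statistic with a block-jackknife test over contiguous site blocks.

    D is reported as the effect size, but the z-score tests the per-site
    mean of ABBA - BABA (the f4-type numerator) against zero: D = 0 iff
    E[ABBA - BABA] = 0, and the unnormalized mean is far better behaved
    under intra-window linkage than the ratio (the ABBA + BABA denominator
    concentrates jackknife weight on the few deepest genealogies, which
    underestimates the variance).

    Returns a dict with d, z, se (of the mean numerator), n_blocks, n_sites
    and the one/two-sided p-values from a t reference with n_blocks - 1 df.
    Degenerate windows (zero jackknife SE) get p = 0 if the numerator is
    nonzero, else p = 1.
    """
    abba, baba, _ = site_patterns(freqs, quartet)
    ok = freqs.usable_mask(quartet)
    if mask is not None:
        ok = ok & mask
    num = (abba - baba)[ok]
    den = (abba + baba)[ok]
    n_sites = len(num)
    if n_sites == 0 or den.sum() <= 0:
        return {
            "d": float("nan"), "z": float("nan"), "se": float("nan"),
            "p_two": float("nan"), "p_pos": float("nan"), "p_neg": float("nan"),
            "n_blocks": 0, "n_sites": n_sites, "testable": False,
        }
    if block_ids is None:
        ids = _block_ids_equal_count(n_sites, n_blocks)
    else:
        ids = block_ids[ok]
        _, ids = np.unique(ids, return_inverse=True)
    B = ids.max() + 1
    counts = np.bincount(ids, minlength=B).astype(float)
    d = float(num.sum() / den.sum())
    mean_num, se, B_used = jackknife_ratio(
        _block_sums(num, ids, B), counts, weights=counts
    )
    if not np.isfinite(se) or se == 0:
        z = np.inf * np.sign(mean_num) if mean_num != 0 else 0.0
        p_two = 0.0 if mean_num != 0 else 1.0
        p_pos = 0.0 if mean_num > 0 else 1.0
        p_neg = 0.0 if mean_num < 0 else 1.0
    else:
        z = mean_num / se
        df = max(B_used - 1, 1)
        p_two = 2 * stats.t.sf(abs(z), df)
        p_pos = stats.t.sf(z, df)   # H1: excess T2-T3 sharing (D > 0)
        p_neg = stats.t.cdf(z, df)  # H1: excess T1-T3 sharing (D < 0)
    return {
        "d": d, "z": float(z), "se": float(se),
        "p_two": float(p_two), "p_pos": float(p_pos), "p_neg": float(p_neg),
        "n_blocks": int(B_used), "n_sites": n_sites, "testable": True,
    }


# ---------------------------------------------------------------------------
# f4-ratio admixture-proportion estimation
# ---------------------------------------------------------------------------

GAMMA_NUM = ("outgroup", "s", "o", "h")
GAMMA_DEN = ("outgroup", "s", "m", "h")


def estimate_H(
    freqs: FreqTable,
    mask=None,
    block_size: int = 1_000_000,
    block_ids=None,
    n_blocks=None,
    scope: str = "genome",
    min_blocks: int = 5,
) -> AdmixtureEstimate:
    """f4-ratio estimate of the m-derived fraction of o, with jackknife z.

    The z-score (and p, two-sided) tests the numerator f4(out, s; o, h)
    against zero — the no-admixture null under which o is h-derived. With
    fewer than ``min_blocks`` informative blocks the estimate is returned
    with undefined significance.

    Blocks are contiguous ``block_size``-bp genomic blocks by default; pass
    ``n_blocks`` to use equal-site-count blocks instead (e.g. inside one
    window), or explicit ``block_ids``.
    """
    taxa = ("outgroup", "s", "o", "m", "h")
    ok = freqs.usable_mask(taxa)
    if mask is not None:
        ok = ok & mask
    num_site = site_f4(freqs, *GAMMA_NUM)[ok]
    den_site = site_f4(freqs, *GAMMA_DEN)[ok]
    n_sites = len(num_site)
    den_sum = den_site.sum()
    if n_sites == 0 or den_sum == 0:
        return AdmixtureEstimate(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), 0, n_sites, scope,
        )
    gamma = float(num_site.sum() / den_sum)
    if block_ids is not None:
        ids = block_ids[ok]
        _, ids = np.unique(ids, return_inverse=True)
    elif n_blocks is not None:
        ids = _block_ids_equal_count(n_sites, n_blocks)
    else:
        ids = _block_ids_genomic(freqs, block_size)[ok]
        _, ids = np.unique(ids, return_inverse=True)
    B = ids.max() + 1
    counts = np.bincount(ids, minlength=B).astype(float)
    num_b = _block_sums(num_site, ids, B)
    den_b = _block_sums(den_site, ids, B)
    # gamma SE: jackknife of the ratio
    _, se_gamma, _ = jackknife_ratio(num_b, den_b, weights=counts)
    # the ratio is meaningless when the denominator f4 (m-h contrast on the
    # out-s axis) is itself indistinguishable from zero; record its z
    fden, se_den, _ = jackknife_ratio(den_b, counts, weights=counts)
    den_z = fden / se_den if (np.isfinite(se_den) and se_den > 0) else np.inf
    # significance: jackknife of the numerator mean (no-admixture null)
    fnum, se_num, B_used = jackknife_ratio(num_b, counts, weights=counts)
    if B_used < min_blocks:
        z, p = float("nan"), float("nan")
    elif not np.isfinite(se_num) or se_num == 0:
        z = np.inf * np.sign(fnum) if fnum != 0 else 0.0
        p = 0.0 if fnum != 0 else 1.0
    else:
        # normal reference: blocks are few but each holds hundreds of sites,
        # so the jackknife SE is stable (t over-corrects on null simulations)
        z = fnum / se_num
        p = 2 * stats.norm.sf(abs(z))
    return AdmixtureEstimate(
        gamma=gamma, f4_num=float(fnum), f4_den=float(den_sum / n_sites),
        z=float(z), p_value=float(p), se_gamma=float(se_gamma),
        n_blocks=int(B_used), n_sites=n_sites, scope=scope, den_z=float(den_z),
    )


def estimate_H_individual(
    freqs: FreqTable, matrix, meta, individual: str, **kwargs
) -> AdmixtureEstimate:
    """Per-individual gamma: one o individual stands in for the o population.

    The individual contributes a 2-allele-copy frequency (0, 1/2, 1); its
    missing sites are excluded.
    """
    from .core import TaxonFreqs

    g = matrix.geno[:, matrix.sample_index([individual])[0]].astype(float)
    called = g >= 0
    p = np.where(called, g / 2.0, np.nan)
    n = np.where(called, 2, 0).astype(np.int64)
    taxa = dict(freqs.taxa)
    taxa["o"] = TaxonFreqs(p=p, n=n, usable=called)
    f_ind = FreqTable(
        contig=freqs.contig, pos=freqs.pos, taxa=taxa,
        min_alleles=freqs.min_alleles, contig_lengths=freqs.contig_lengths,
    )
    return estimate_H(f_ind, scope=f"individual:{individual}", **kwargs)


def window_H_scan(
    freqs: FreqTable,
    windows,
    n_blocks: int = 10,
    low_confidence_sites: int = 25,
) -> pd.DataFrame:
    """Per-window gamma with a within-window jackknife hybridization test.

    Each window's sites are split into ``n_blocks`` contiguous blocks for the
    jackknife. Windows whose denominator f4 is zero or statistically
    indistinguishable from zero (|den_z| < 2) are flagged undefined — the
    ratio is unbounded there; windows with fewer informative sites than
    ``low_confidence_sites`` are marked low-confidence.
    """
    rows = []
    taxa = ("outgroup", "s", "o", "m", "h")
    ok_all = freqs.usable_mask(taxa)
    for w in windows:
        idx = freqs.site_indices(w)
        mask = np.zeros(freqs.n_sites, dtype=bool)
        mask[idx] = True
        est = estimate_H(freqs, mask=mask & ok_all, n_blocks=n_blocks, scope="window")
        rows.append(
            {
                "contig": w.contig, "start": w.start, "end": w.end,
                "gamma": est.gamma, "z": est.z, "p": est.p_value,
                "n_sites": est.n_sites, "den_z": est.den_z,
                "defined": bool(np.isfinite(est.gamma) and abs(est.den_z) >= 2),
                "low_confidence": est.n_sites < low_confidence_sites,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regressions against the recombination map
# ---------------------------------------------------------------------------

def _align_rho(table: pd.DataFrame, rho: pd.DataFrame) -> pd.DataFrame:
    """Join a per-window table with a rho map on exact window coordinates,
    falling back to overlap-weighted mean rho when tilings differ."""
    merged = table.drop(columns=["rho"], errors="ignore").merge(
        rho[["contig", "start", "end", "rho"]], on=["contig", "start", "end"],
        how="inner",
    )
    if len(merged):
        return merged
    out = []
    for _, row in table.iterrows():
        r = rho[rho["contig"] == row["contig"]]
        ov = np.minimum(r["end"], row["end"]) - np.maximum(r["start"], row["start"])
        w = np.clip(ov, 0, None).to_numpy(dtype=float)
        if w.sum() == 0:
            continue
        d = dict(row)
        d["rho"] = float((r["rho"].to_numpy() * w).sum() / w.sum())
        out.append(d)
    return pd.DataFrame(out)


def _ols(y: np.ndarray, x: np.ndarray) -> RegressionResult:
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        n=int(fit.nobs),
    )


def correlate_H_rho(H_table: pd.DataFrame, rho: pd.DataFrame) -> RegressionResult:
    """OLS of per-window gamma on the window recombination rate."""
    col = "gamma" if "gamma" in H_table.columns else "H"
    t = _align_rho(H_table, rho)
    if "defined" in t.columns:
        t = t[t["defined"]]
    t = t[np.isfinite(t[col]) & np.isfinite(t["rho"])]
    if len(t) < 3:
        raise ValueError("need >= 3 windows defined in both tables")
    return _ols(t[col].to_numpy(), t["rho"].to_numpy())


def barrier_density_regression(
    barrier_table: pd.DataFrame, rho: pd.DataFrame
) -> RegressionResult:
    """OLS of the 0/1 barrier indicator on the window recombination rate."""
    col = "barrier" if "barrier" in barrier_table.columns else "indicator"
    t = _align_rho(barrier_table, rho)
    return _ols(t[col].to_numpy(dtype=float), t["rho"].to_numpy())
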