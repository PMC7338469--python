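"""Windowed nucleotide diversity, absolute divergence and Hudson's Fst.

Per-site building blocks work on allele frequencies/counts; window functions
aggregate over the usable sites of each nonoverlapping window (default
100 kbp tiling, built by :func:`hhscan.core.iter_windows`).

Estimators
----------
* ``Dxy`` per site: ``pA*qB + qA*pB`` — the probability that one allele drawn
  from each taxon differs; per-bp values divide the site sum by window length.
* ``pi`` per site: the unbiased ``n/(n-1) * 2 p q``.
* Hudson Fst per site: ``1 - Hw/Hb`` with ``Hw`` the mean of the two
  within-taxon heterozygosities and ``Hb = pA*qB + qA*pB``; window Fst is the
  ratio of averages ``1 - sum(Hw)/sum(Hb)``; ``maxFst`` is the maximum raw
  per-site value in the window and equals 1 exactly when the window holds a
  fully-usable fixed difference.

Negative site/window Fst values are retained in computation (`fst` column);
a clamped-to-zero companion column is provided for display parity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FreqTable, WindowSpec


def site_dxy(pA, qA, pB, qB):
    """Expected pairwise difference between one allele from each taxon."""
    return np.asarray(pA) * np.asarray(qB) + np.asarray(qA) * np.asarray(pB)


def site_pi(p, n):
    """Unbiased per-site heterozygosity ``n/(n-1) * 2pq``; NaN when n < 2."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, n / (n - 1.0) * 2.0 * p * (1.0 - p), np.nan)


def site_fst_hudson(kA, nA, kB, nB):
    """Per-site Hudson/Slatkin/Maddison Fst from allele counts.

    Returns NaN (undefined) where the between-taxon heterozygosity is zero,
    i.e. both taxa are fixed for the same allele.
    """
    kA, nA, kB, nB = (np.asarray(x, dtype=float) for x in (kA, nA, kB, nB))
    pA, pB = kA / nA, kB / nB
    hw = 0.5 * (site_pi(pA, nA) + site_pi(pB, nB))
    hb = site_dxy(pA, 1 - pA, pB, 1 - pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hb > 0, 1.0 - hw / hb, np.nan)


def _site_components(freqs: FreqTable, taxonA: str, taxonB: str):
    """Per-site (Hw, Hb) arrays over all sites; NaN where either taxon unusable."""
    A, B = freqs.taxa[taxonA], freqs.taxa[taxonB]
    ok = A.usable & B.usable
    hw = 0.5 * (site_pi(A.p, A.n) + site_pi(B.p, B.n))
    hb = site_dxy(A.p, A.q, B.p, B.q)
    hw = np.where(ok, hw, np.nan)
    hb = np.where(ok, hb, np.nan)
    return hw, hb, ok


def window_dxy(
    freqs: FreqTable, taxonA: str, taxonB: str, window: WindowSpec,
    normalize: str = "window",
) -> dict:
    """Per-bp absolute divergence in one window.

    Non-SNP positions contribute zero difference, so the default denominator
    is the full window length (``normalize='window'``); pass
    ``normalize='accessible'`` to divide by the usable-site count instead.
    Zero usable sites yields NaN, never 0.
    """
    idx = freqs.site_indices(window)
    A, B = freqs.taxa[taxonA], freqs.taxa[taxonB]
    ok = (A.usable & B.usable)[idx]
    vals = site_dxy(A.p[idx][ok], A.q[idx][ok], B.p[idx][ok], B.q[idx][ok])
    n_use = int(ok.sum())
    denom = window.length if normalize == "window" else max(n_use, 1)
    return {
        "dxy": float(vals.sum() / denom) if n_use else float("nan"),
        "n_sites": n_use,
    }


def window_pi(
    freqs: FreqTable, taxon: str, window: WindowSpec, normalize: str = "window"
) -> dict:
    """Per-bp nucleotide diversity of one taxon in one window."""
    idx = freqs.site_indices(window)
    T = freqs.taxa[taxon]
    ok = T.usable[idx]
    vals = site_pi(T.p[idx][ok], T.n[idx][ok])
    n_use = int(ok.sum())
    denom = window.length if normalize == "window" else max(n_use, 1)
    return {
        "pi": float(np.nansum(vals) / denom) if n_use else float("nan"),
        "n_sites": n_use,
    }


def window_fst(freqs: FreqTable, taxonA: str, taxonB: str, window: WindowSpec) -> dict:
    """Window Fst (ratio of averages) and maxFst (max raw per-site value).

    Sites monomorphic in both taxa (Hb = 0) are excluded; windows with no
    defined site return NaN for both statistics.
    """
    idx = freqs.site_indices(window)
    hw, hb, _ = _site_components(freqs, taxonA, taxonB)
    hw, hb = hw[idx], hb[idx]
    keep = np.isfinite(hb) & (hb > 0)
    n_def = int(keep.sum())
    if n_def == 0:
        return {"fst": float("nan"), "max_fst": float("nan"), "n_sites": 0}
    site_f = 1.0 - hw[keep] / hb[keep]
    return {
        "fst": float(1.0 - hw[keep].sum() / hb[keep].sum()),
        "max_fst": float(site_f.max()),
        "n_sites": n_def,
    }


def pair_window_stats(
    freqs: FreqTable,
    taxonA: str,
    taxonB: str,
    windows,
    normalize: str = "window",
) -> pd.DataFrame:
    """Per-window pi (both taxa), Dxy, Fst and maxFst for one taxon pair.

    Returns a BED-compatible frame: contig, start, end, n_sites, pi_A, pi_B,
    dxy, fst, fst_clamped, max_fst.
    """
    rows = []
    for w in windows:
        d = window_dxy(freqs, taxonA, taxonB, w, normalize)
        f = window_fst(freqs, taxonA, taxonB, w)
        piA = window_pi(freqs, taxonA, w, normalize)["pi"]
        piB = window_pi(freqs, taxonB, w, normalize)["pi"]
        rows.append(
            {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "n_sites": d["n_sites"],
                f"pi_{taxonA}": piA,
                f"pi_{taxonB}": piB,
                "dxy": d["dxy"],
                "fst": f["fst"],
                "fst_clamped": max(f["fst"], 0.0) if np.isfinite(f["fst"]) else f["fst"],
                "max_fst": f["max_fst"],
            }
        )
    return pd.DataFrame(rows)
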