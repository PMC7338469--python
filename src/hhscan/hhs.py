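"""The hhs statistic and its genome-wide bootstrap test.

hhs compares the mean nucleotide difference between the putative hybrid (o)
and its minor parent (m) against the difference between the major parent (h)
and m, summed over the sites of a genomic window:

    hhs = sum_k (p_ok * q_mk + p_mk * q_ok) / sum_k (p_hk * q_mk + p_mk * q_hk)

If o's genome is entirely h-derived, hhs = 1; any contribution from m pulls
hhs below 1 wherever the parents are diverged. The genome-wide test of
H0: hhs = 1 resamples whole windows with replacement (block bootstrap over
windows, robust to intra-window linkage) and asks how often a replicate's
summary reaches 1.0 — a one-sided test against H1: hhs < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FreqTable


@dataclass
class HhsBootstrap:
    estimate: float
    estimate_ratio_of_sums: float
    n_windows: int
    n_boot: int
    p_value: float
    seed: int
    replicates: np.ndarray

    def summary(self) -> dict:
        return {
            "estimate": self.estimate,
            "estimate_ratio_of_sums": self.estimate_ratio_of_sums,
            "n_windows": self.n_windows,
            "n_boot": self.n_boot,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def window_hhs(freqs: FreqTable, windows, taxa=("o", "m", "h")) -> pd.DataFrame:
    """Per-window hhs with its numerator/denominator sums.

    Sites unusable in any of o, m, h are excluded from both sums; a window
    whose denominator is zero (h indistinguishable from m) is returned with
    ``hhs`` NaN and is excluded from the bootstrap downstream.
    """
    o, m, h = (freqs.taxa[t] for t in taxa)
    ok_all = freqs.usable_mask(taxa)
    num_site = o.p * m.q + m.p * o.q
    den_site = h.p * m.q + m.p * h.q
    rows = []
    for w in windows:
        idx = freqs.site_indices(w)
        ok = ok_all[idx]
        num = float(num_site[idx][ok].sum())
        den = float(den_site[idx][ok].sum())
        rows.append(
            {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "n_sites": int(ok.sum()),
                "d_om": num,
                "d_hm": den,
                "hhs": num / den if den > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_hhs(
    window_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    summary: str = "mean",
) -> HhsBootstrap:
    """Bootstrap test of H0: hhs = 1 over windows.

    ``summary='mean'`` averages the per-window hhs values inside each
    replicate (the default replicate summary); ``summary='ratio'`` uses the
    genome-wide ratio of resampled numerator and denominator sums instead.
    The p-value is the fraction of replicates >= 1.0 with the (r+1)/(B+1)
    continuity correction.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ok = window_table["hhs"].notna() & (window_table["d_hm"] > 0)
    t = window_table[ok]
    if len(t) < 2:
        raise ValueError("need >= 2 defined windows to bootstrap")
    vals = t["hhs"].to_numpy()
    num = t["d_om"].to_numpy()
    den = t["d_hm"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(vals)
    draws = rng.integers(0, n, size=(n_boot, n))
    if summary == "mean":
        reps = vals[draws].mean(axis=1)
    elif summary == "ratio":
        reps = num[draws].sum(axis=1) / den[draws].sum(axis=1)
    else:
        raise ValueError("summary must be 'mean' or 'ratio'")
    p = (1 + int((reps >= 1.0).sum())) / (n_boot + 1)
    return HhsBootstrap(
        estimate=float(vals.mean()),
        estimate_ratio_of_sums=float(num.sum() / den.sum()),
        n_windows=n,
        n_boot=n_boot,
        p_value=float(p),
        seed=seed,
        replicates=reps,
    )
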