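"""Phylogenetically controlled discovery of barrier windows.

With the species tree ((s, m), h, out),
windows with a significant excess of derived-allele sharing between h and m
form the set M_hm, and windows with significant h-s sharing form M_hs.
Barrier loci — regions whose alleles block h<->m gene flow while h<->s
exchange persisted — are expected to land in M_hs but not in M_hm, so the
candidate set is the difference M_hs \\ M_hm.

Each candidate then receives a local-ancestry call for the hybrid lineage o:
if the nesting ((h, (o, m)), out) shows no residual admixture signal the
window's o material derives from m (MOLLISSIMA); if ((m, (o, h)), out) is
clean it derives from h (HENRYI); windows clean or dirty under both
topologies are AMBIGUOUS. Finally, each call is annotated with the h-vs-m
maxFst of the window; maxFst = 1.0 marks a fixed difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .admixture import d_test
from .core import FreqTable
from .divergence import window_fst

HENRYI = "HENRYI"
MOLLISSIMA = "MOLLISSIMA"
AMBIGUOUS = "AMBIGUOUS"

# quartet ordered (out, T1, T2, T3): ABBA = T2-T3 sharing, BABA = T1-T3 sharing
QUARTET_SMH = ("outgroup", "s", "m", "h")


def introgression_tests(
    freqs: FreqTable, windows, alpha: float = 0.05, n_blocks: int = 10,
    correction: str = "none",
) -> pd.DataFrame:
    """Per-window introgression tests in both orientations.

    One D statistic on the quartet (out, s, m, h) serves both orientations:
    D > 0 is excess m-h sharing (orientation h-m, s as the reference third
    taxon) and D < 0 excess s-h sharing (orientation h-s). One-sided
    p-values ``p_hm``/``p_hs`` define membership in M_hm/M_hs at ``alpha``,
    uncorrected by default; ``correction='bh'`` applies Benjamini-Hochberg
    across windows within each orientation. Untestable windows (no
    informative sites) are excluded from both sets.
    """
    if correction not in ("none", "bh"):
        raise ValueError("correction must be 'none' or 'bh'")
    rows = []
    for w in windows:
        idx = freqs.site_indices(w)
        mask = np.zeros(freqs.n_sites, dtype=bool)
        mask[idx] = True
        r = d_test(freqs, QUARTET_SMH, mask=mask, n_blocks=n_blocks)
        rows.append(
            {
                "contig": w.contig, "start": w.start, "end": w.end,
                "d": r["d"], "z": r["z"],
                "p_hm": r["p_pos"], "p_hs": r["p_neg"],
                "n_sites": r["n_sites"], "testable": r["testable"],
            }
        )
    table = pd.DataFrame(rows)
    for col, flag in (("p_hm", "in_M_hm"), ("p_hs", "in_M_hs")):
        p = table[col].to_numpy()
        ok = table["testable"].to_numpy()
        if correction == "bh":
            from statsmodels.stats.multitest import multipletests

            sig = np.zeros(len(table), dtype=bool)
            if ok.any():
                sig[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
        else:
            sig = ok & (p < alpha)
        table[flag] = sig
    return table


def candidate_barriers(table: pd.DataFrame) -> pd.DataFrame:
    """Set difference M_hs \\ M_hm over windows testable in both orientations."""
    out = table.copy()
    out["candidate"] = out["testable"] & out["in_M_hs"] & ~out["in_M_hm"]
    return out


def local_ancestry(
    freqs: FreqTable, window_mask, alpha: float = 0.05, n_blocks: int = 10
) -> dict:
    """Local-ancestry call for o in one window (boolean site mask).

    Tests the two nesting topologies with D statistics:

    * quartet (out, o, m, h): D != 0 is residual signal under the
      o-nested-with-m topology;
    * quartet (out, o, h, m): signal under o-nested-with-h.

    Exactly one clean topology gives a call; otherwise AMBIGUOUS.
    """
    r_m = d_test(freqs, ("outgroup", "o", "m", "h"), mask=window_mask, n_blocks=n_blocks)
    r_h = d_test(freqs, ("outgroup", "o", "h", "m"), mask=window_mask, n_blocks=n_blocks)
    if not (r_m["testable"] and r_h["testable"]):
        return {"ancestry": AMBIGUOUS, "reason": "untestable",
                "p_topo_m": r_m["p_two"], "p_topo_h": r_h["p_two"]}
    clean_m = r_m["p_two"] >= alpha  # no signal: o truly nested with m
    clean_h = r_h["p_two"] >= alpha
    if clean_m and not clean_h:
        call, reason = MOLLISSIMA, "clean_m_topology"
    elif clean_h and not clean_m:
        call, reason = HENRYI, "clean_h_topology"
    elif clean_m and clean_h:
        call, reason = AMBIGUOUS, "both_clean"
    else:
        call, reason = AMBIGUOUS, "both_signal"
    return {"ancestry": call, "reason": reason,
            "p_topo_m": r_m["p_two"], "p_topo_h": r_h["p_two"]}


def annotate_fixed_differences(
    calls: pd.DataFrame, fst_table: pd.DataFrame, tol: float = 1e-12
) -> pd.DataFrame:
    """Join h-vs-m maxFst per window; flag fixed differences (maxFst == 1)."""
    out = calls.merge(
        fst_table[["contig", "start", "end", "max_fst"]],
        on=["contig", "start", "end"], how="left",
    )
    out["fixed_diff"] = np.isfinite(out["max_fst"]) & (out["max_fst"] >= 1.0 - tol)
    return out


def barrier_scan(
    freqs: FreqTable,
    windows,
    alpha: float = 0.05,
    n_blocks: int = 10,
    call_ancestry: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full scan: tests, set difference, ancestry calls and maxFst annotation.

    Returns the per-window call table and a summary dict with candidate and
    per-ancestry counts.
    """
    table = candidate_barriers(introgression_tests(freqs, windows, alpha, n_blocks))
    anc = []
    for w, cand in zip(windows, table["candidate"]):
        if call_ancestry and cand:
            idx = freqs.site_indices(w)
            mask = np.zeros(freqs.n_sites, dtype=bool)
            mask[idx] = True
            anc.append(local_ancestry(freqs, mask, alpha, n_blocks))
        else:
            anc.append({"ancestry": "", "reason": "", "p_topo_m": np.nan,
                        "p_topo_h": np.nan})
    table = pd.concat([table.reset_index(drop=True), pd.DataFrame(anc)], axis=1)
    fst = pd.DataFrame(
        [
            {"contig": w.contig, "start": w.start, "end": w.end,
             **window_fst(freqs, "h", "m", w)}
            for w in windows
        ]
    )
    table = annotate_fixed_differences(table, fst)
    cands = table[table["candidate"]]
    summary = {
        "n_windows": int(len(table)),
        "n_testable": int(table["testable"].sum()),
        "n_candidates": int(len(cands)),
        "n_henryi": int((cands["ancestry"] == HENRYI).sum()),
        "n_mollissima": int((cands["ancestry"] == MOLLISSIMA).sum()),
        "n_ambiguous": int((cands["ancestry"] == AMBIGUOUS).sum()),
        "n_fixed_diff": int(cands["fixed_diff"].sum()),
    }
    return table, summary
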