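"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own formulas: Fst by enumerating all
allele pairs, SFS projection by enumerating all subsamples.
"""

import itertools

import numpy as np


def fst_enumeration_oracle(allelesA, allelesB):
    """Hudson Fst by direct pair counting: 1 - mean(within)/mean(between)."""
    within = []
    for alleles in (allelesA, allelesB):
        pairs = list(itertools.combinations(alleles, 2))
        within.append(np.mean([a != b for a, b in pairs]))
    between = np.mean([a != b for a in allelesA for b in allelesB])
    if between == 0:
        return np.nan
    return 1.0 - np.mean(within) / between


def projection_enumeration_oracle(derived_A, n_A, derived_B, n_B, proj):
    """Projected joint-SFS mass of one site by enumerating all subsamples."""
    mA, mB = proj
    hapA = [1] * derived_A + [0] * (n_A - derived_A)
    hapB = [1] * derived_B + [0] * (n_B - derived_B)
    out = np.zeros((mA + 1, mB + 1))
    combosA = list(itertools.combinations(hapA, mA))
    combosB = list(itertools.combinations(hapB, mB))
    for ca in combosA:
        for cb in combosB:
            out[sum(ca), sum(cb)] += 1.0
    return out / (len(combosA) * len(combosB))
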