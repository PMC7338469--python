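"""Pattern counts, D, f4-ratio gamma and the recombination regressions."""

import numpy as np
import pandas as pd
import pytest

from hhscan.admixture import (
    AdmixtureEstimate,
    PatternCounts,
    barrier_density_regression,
    correlate_H_rho,
    d_statistic,
    estimate_H,
    estimate_H_individual,
    f4,
    jackknife_ratio,
    site_pattern_counts,
)
from hhscan.simulate import freq_fixture

QUARTET = ("outgroup", "s", "m", "h")


def test_site_pattern_single_site_products():
    ft = freq_fixture({"outgroup": [0.0], "s": [0.0], "m": [1.0], "h": [1.0]})
    c = site_pattern_counts(ft, QUARTET)
    assert (c.abba, c.baba) == (1.0, 0.0)
    mono = freq_fixture({t: [0.0] for t in QUARTET})
    c0 = site_pattern_counts(mono, QUARTET)
    assert c0.abba == c0.baba == c0.bbaa == 0.0


def test_allele_flip_doubles_every_pattern_count(rng):
    p = {t: rng.uniform(size=10) for t in QUARTET}
    base = site_pattern_counts(freq_fixture(p), QUARTET)
    doubled = site_pattern_counts(
        freq_fixture({t: np.concatenate([v, 1 - v]) for t, v in p.items()}), QUARTET
    )
    assert doubled.abba == pytest.approx(2 * base.abba)
    assert doubled.baba == pytest.approx(2 * base.baba)
    assert doubled.bbaa == pytest.approx(2 * base.bbaa)


def test_empty_quartet_member_errors():
    ft = freq_fixture({"outgroup": [0.0], "s": [0.0], "m": [1.0]})
    with pytest.raises(ValueError, match="no samples"):
        site_pattern_counts(ft, QUARTET)


@pytest.mark.parametrize(
    "abba,baba,expected",
    [(30, 10, 0.5), (5, 5, 0.0), (7, 0, 1.0)],
)
def test_d_statistic_examples(abba, baba, expected):
    assert d_statistic(PatternCounts(abba, baba, 0, 1)) == pytest.approx(expected)


def test_d_statistic_undefined_on_zero_denominator():
    assert np.isnan(d_statistic(PatternCounts(0, 0, 5, 1)))


def test_f4_arithmetic_and_antisymmetry(rng):
    ft = freq_fixture({"a": rng.uniform(size=15), "b": rng.uniform(size=15),
                       "c": rng.uniform(size=15), "d": rng.uniform(size=15)})
    assert f4(ft, "a", "a", "c", "d") == pytest.approx(0.0)
    assert f4(ft, "a", "b", "c", "d") == pytest.approx(-f4(ft, "b", "a", "c", "d"))
    one = freq_fixture({"a": [0.0], "b": [1.0], "c": [0.25], "d": [0.0]})
    assert f4(one, "a", "b", "c", "d") == pytest.approx(-0.25)


def test_gamma_on_fixed_site_mixture_construction():
    k = 40
    ft = freq_fixture(
        {"outgroup": [0.0] * k, "s": [1.0] * k, "m": [1.0] * k,
         "h": [0.0] * k, "o": [0.25] * k},
        contig_length=4100,
    )
    est = estimate_H(ft, n_blocks=8)
    assert est.gamma == pytest.approx(0.25)
    assert est.f4_den == pytest.approx(-1.0)
    identical = freq_fixture(
        {"outgroup": [0.0] * k, "s": [1.0] * k, "m": [1.0] * k,
         "h": [0.3] * k, "o": [0.3] * k},
    )
    assert estimate_H(identical, n_blocks=8).gamma == pytest.approx(0.0)


def test_too_few_blocks_leaves_estimate_but_no_significance():
    k = 30
    ft = freq_fixture(
        {"outgroup": [0.0] * k, "s": [1.0] * k, "m": [1.0] * k,
         "h": [0.0] * k, "o": [0.25] * k},
    )
    est = estimate_H(ft, n_blocks=3, min_blocks=5)
    assert est.gamma == pytest.approx(0.25)
    assert np.isnan(est.z) and np.isnan(est.p_value)


def test_gamma_invariant_to_allele_relabeling(rng):
    p = {t: rng.uniform(size=60) for t in ("outgroup", "s", "m", "h", "o")}
    base = estimate_H(freq_fixture(p), n_blocks=6).gamma
    flip = rng.uniform(size=60) < 0.5
    flipped = estimate_H(
        freq_fixture({t: np.where(flip, 1 - v, v) for t, v in p.items()}),
        n_blocks=6,
    ).gamma
    assert base == pytest.approx(flipped)


def test_jackknife_matches_unweighted_form_on_equal_blocks(rng):
    vals = rng.normal(size=200)
    ids = np.repeat(np.arange(10), 20)
    num_b = np.bincount(ids, weights=vals)
    counts = np.bincount(ids).astype(float)
    theta, se, B = jackknife_ratio(num_b, counts, weights=counts)
    assert theta == pytest.approx(vals.mean())
    loo = np.array([vals[ids != b].mean() for b in range(10)])
    se_plain = np.sqrt((10 - 1) / 10 * ((loo - loo.mean()) ** 2).sum())
    assert se == pytest.approx(se_plain, rel=1e-6)
    assert B == 10


def test_genome_gamma_recovers_pulse_fraction(admixed_dataset):
    """Coalescent truth H = 0.25 on a 10-Mb genome: gamma within 0.05."""
    _, _, freqs, _, truth = admixed_dataset
    est = estimate_H(freqs)
    assert truth.globals["H"] == 0.25
    assert est.gamma == pytest.approx(0.25, abs=0.05)
    assert est.p_value < 0.001  # admixture detected
    assert est.n_blocks >= 5


def test_per_individual_gamma_agrees_with_population(admixed_dataset):
    matrix, meta, freqs, _, _ = admixed_dataset
    pop = estimate_H(freqs)
    per_ind = [
        estimate_H_individual(freqs, matrix, meta, ind).gamma
        for ind in meta.samples_of("o")[:5]
    ]
    assert np.mean(per_ind) == pytest.approx(pop.gamma, abs=3 * pop.se_gamma + 0.02)


def test_window_scan_flags_undefined_and_planted_windows(admixed_dataset):
    from hhscan.admixture import window_H_scan
    from hhscan.core import WindowSpec

    _, _, freqs, windows, _ = admixed_dataset
    scan = window_H_scan(freqs, windows[:30])
    assert scan["defined"].all()
    assert scan["gamma"].mean() == pytest.approx(0.25, abs=0.12)
    empty = window_H_scan(freqs, [WindowSpec("ctg1", 10_000_000, 10_100_000, 999)])
    assert not empty["defined"].iloc[0]


def _rho_frame(rho):
    n = len(rho)
    return pd.DataFrame(
        {"contig": "c", "start": np.arange(n) * 100_000,
         "end": (np.arange(n) + 1) * 100_000, "rho": rho}
    )


def test_regression_on_noiseless_line_and_permutation_control(rng):
    rho = rng.uniform(0.001, 0.01, size=80)
    t = _rho_frame(rho)
    H = pd.DataFrame({"contig": "c", "start": t["start"], "end": t["end"],
                      "gamma": 0.1 + 0.5 * rho})
    r = correlate_H_rho(H, t)
    assert r.slope == pytest.approx(0.5)
    assert r.intercept == pytest.approx(0.1)
    assert r.r_squared == pytest.approx(1.0)
    perm = H.copy()
    perm["gamma"] = rng.permutation(H["gamma"].to_numpy())
    r2 = correlate_H_rho(perm, t)
    assert r2.p_value > 0.05
    assert abs(r2.slope) < abs(r.slope)


def test_barrier_density_regression_examples(rng):
    rho = np.sort(rng.uniform(0.001, 0.01, size=100))
    t = _rho_frame(rho)
    zero = t.assign(barrier=0)
    r0 = barrier_density_regression(zero, t)
    assert r0.slope == pytest.approx(0.0)
    decile = t.assign(barrier=(np.arange(100) < 10).astype(int))
    r1 = barrier_density_regression(decile, t)
    assert r1.slope < 0
    assert r1.f_statistic > 10
    assert r1.p_value < 0.01


def test_random_indicator_p_values_roughly_uniform(rng):
    from scipy import stats

    rho = rng.uniform(0.001, 0.01, size=100)
    t = _rho_frame(rho)
    ps = []
    for _ in range(200):
        ind = t.assign(barrier=rng.binomial(1, 0.2, size=100))
        ps.append(barrier_density_regression(ind, t).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_gamma_scale_invariance():
    est = AdmixtureEstimate(0.25, -0.25, -1.0, 3.0, 0.01, 0.02, 10, 100, "genome")
    # scaling both f4 values leaves gamma unchanged by construction
    assert (est.f4_num * 7) / (est.f4_den * 7) == pytest.approx(est.gamma)
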