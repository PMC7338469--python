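"""Polarization, SFS projection, composite likelihood and model machinery."""

import itertools

import numpy as np
import pytest

from hhscan.core import GenotypeMatrix, SampleMetadata
from hhscan.sfs import (
    SFS2D,
    DemographicModel,
    ModelFit,
    ModelTemplate,
    barrier_templates,
    compare_models,
    composite_loglik,
    expected_sfs,
    fit_model,
    hybrid_origin_templates,
    joint_sfs,
    polarize_sites,
)
from hhscan.simulate import default_model


def _matrix(geno, samples):
    geno = np.asarray(geno, dtype=np.int8)
    n = geno.shape[0]
    return GenotypeMatrix(
        contig=np.array(["c"] * n, dtype=object),
        pos=np.arange(1, n + 1) * 10,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        geno=geno,
        samples=samples,
        contig_lengths={"c": 10 * n + 10},
    )


def test_polarize_by_outgroup_consensus():
    samples = ["o1", "o2", "x1"]
    m = _matrix(
        [[0, 0, 1],      # outgroup all ref -> ancestral REF
         [2, 2, 1],      # outgroup all alt -> ancestral ALT
         [0, 2, 1],      # outgroup polymorphic -> unpolarized
         [1, 1, 1],      # heterozygous outgroup -> unpolarized
         [-1, 0, 1],     # partial missing, consensus ref
         [-1, -1, 1]],   # no outgroup call -> unpolarized
        samples,
    )
    anc = polarize_sites(m, ["o1", "o2"])
    assert anc.tolist() == [0, 1, -1, -1, 0, -1]
    with pytest.raises(ValueError, match="no outgroup"):
        polarize_sites(m, [])
    # count agrees with a per-site brute-force scan
    brute = 0
    for i in range(m.n_sites):
        og = [g for g in m.geno[i, :2] if g >= 0]
        brute += bool(og) and (all(g == 0 for g in og) or all(g == 2 for g in og))
    assert (anc >= 0).sum() == brute


def test_joint_sfs_full_projection_single_cells():
    samples = ["o1", "a1", "a2", "b1", "b2"]
    m = _matrix([[0, 1, 1, 0, 0],   # A: 2 of 4 derived, B: 0 of 4
                 [0, 0, 0, 0, 0],   # monomorphic ancestral
                 [2, 0, 0, 1, 1]],  # anc=ALT: A derived 4 of 4, B 2 of 4
                samples)
    anc = polarize_sites(m, ["o1"])
    s = joint_sfs(m, ["a1", "a2"], ["b1", "b2"], anc, (4, 4))
    assert s.matrix[2, 0] == pytest.approx(1.0)
    assert s.matrix[0, 0] == pytest.approx(1.0)
    assert s.matrix[4, 2] == pytest.approx(1.0)
    assert s.matrix.sum() == pytest.approx(s.n_sites) == pytest.approx(3.0)


def test_projection_matches_subsample_enumeration():
    """Hypergeometric down-projection equals averaging over all subsamples."""
    samples = ["o1"] + [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    geno = [[0, 1, 1, 0, 1, 0, 0],
            [0, 2, 1, 2, 0, 0, 1],
            [0, 0, 1, 0, 2, 2, 2]]
    m = _matrix(geno, samples)
    anc = polarize_sites(m, ["o1"])
    A, B = [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)]
    proj = (2, 2)
    s = joint_sfs(m, A, B, anc, proj)
    expected = np.zeros((3, 3))
    for row in geno:
        hapA = [x for g in row[1:4] for x in ([1] * g + [0] * (2 - g))]
        hapB = [x for g in row[4:7] for x in ([1] * g + [0] * (2 - g))]
        combosA = list(itertools.combinations(hapA, 2))
        combosB = list(itertools.combinations(hapB, 2))
        for ca in combosA:
            for cb in combosB:
                expected[sum(ca), sum(cb)] += 1.0 / (len(combosA) * len(combosB))
    np.testing.assert_allclose(s.matrix, expected, atol=1e-12)
    assert s.matrix.sum() == pytest.approx(len(geno))


def test_composite_loglik_pooling_arithmetic():
    obs = SFS2D(np.array([[0.0, 10.0, 3.0], [7.0, 2.0, 20.0]]), 1, 2, 42.0)
    e = np.array([[0.0, 0.3, 0.1], [0.2, 0.1, 0.3]])
    # corners (0,0) and (1,2) excluded; min_entry=5 pools obs {3,2}
    e_in = np.array([0.3, 0.1, 0.2, 0.1]) / 0.7
    kept = 10 * np.log(e_in[0]) + 7 * np.log(e_in[2])
    pooled = (3 + 2) * np.log(e_in[1] + e_in[3])
    assert composite_loglik(obs, e, min_entry=5) == pytest.approx(kept + pooled)
    # min_entry=0: plain sum o_ij log e_ij
    plain = (10 * np.log(e_in[0]) + 3 * np.log(e_in[1]) + 7 * np.log(e_in[2])
             + 2 * np.log(e_in[3]))
    assert composite_loglik(obs, e, min_entry=0) == pytest.approx(plain)


def test_matching_proportions_maximize_loglik():
    rng = np.random.default_rng(3)
    true = rng.dirichlet(np.ones(8)).reshape(2, 4)
    obs = SFS2D(1000 * true, 1, 3, 1000.0)
    ln_true = composite_loglik(obs, true, min_entry=0)
    for _ in range(20):
        other = rng.dirichlet(np.ones(8)).reshape(2, 4)
        assert composite_loglik(obs, other, min_entry=0) <= ln_true + 1e-9


def test_expected_sfs_limit_behaviours():
    # ancient isolation: virtually no shared polymorphism off the margins
    iso = default_model(H=0.0, t3=100.0, t2=25_000.0, t1=29_000.0)
    e = expected_sfs(iso, ("m", "h"), 6, 6, n_sims=3000, seed=4)
    shared_iso = e[1:, 1:].sum()  # derived allele seen in both pops
    assert shared_iso < 0.12
    # near-panmixia: recent split, shared mass large and spectrum symmetric
    pan = default_model(H=0.0, t3=5.0, t2=10.0, t1=20.0)
    ep = expected_sfs(pan, ("m", "h"), 6, 6, n_sims=3000, seed=4)
    assert ep[1:, 1:].sum() > 3 * shared_iso
    np.testing.assert_allclose(ep, ep.T, atol=0.02)


def test_expected_sfs_two_seed_agreement():
    model = default_model(H=0.25)
    a = expected_sfs(model, ("o", "m"), 8, 8, n_sims=8000, seed=11)
    b = expected_sfs(model, ("o", "m"), 8, 8, n_sims=8000, seed=12)
    assert np.abs(a - b).max() < 0.01
    assert a.sum() == pytest.approx(1.0) and b.sum() == pytest.approx(1.0)


def test_model_constraints_enforced():
    with pytest.raises(ValueError, match="model1"):
        DemographicModel(tag="model1", H=0.3)
    with pytest.raises(ValueError, match="model2"):
        DemographicModel(tag="model2", H=0.3)
    with pytest.raises(ValueError, match="barrierA"):
        DemographicModel(tag="barrierA", m_hm=2e-4, m_anc=1e-4)
    templates = hybrid_origin_templates(default_model())
    assert [t.k for t in templates] == [0, 0, 1]
    bt = barrier_templates(default_model(), m_anc=1e-4)
    assert bt[0].free_param == "m_hm" and bt[1].free_param is None


def test_fixed_parameter_fit_returns_direct_loglik():
    model = default_model(H=0.25)
    e = expected_sfs(model, ("o", "m"), 8, 8, n_sims=4000, seed=2)
    obs = SFS2D(5000 * e, 8, 8, 5000.0)
    t = ModelTemplate("fixed", model)
    fit = fit_model(t, obs, ("o", "m"), n_sims=4000, seed=2)
    assert fit.loglik == pytest.approx(composite_loglik(obs, e))
    assert fit.k == 0 and fit.aic == pytest.approx(-2 * fit.loglik)


def test_aic_ranking_and_tie_breaking():
    fits = [
        ModelFit("a", {}, None, None, -100.0, 3, 2 * 3 + 200.0, 0, 0, []),
        ModelFit("b", {}, None, None, -100.0, 4, 2 * 4 + 200.0, 0, 0, []),
    ]
    t = compare_models(fits)
    assert t.iloc[0]["model"] == "a"  # same lnL: smaller k wins
    assert t.iloc[0]["winner"] and not t.iloc[1]["winner"]
    shifted = [
        ModelFit("a", {}, None, None, -100.0 + 55, 3, 2 * 3 + 200.0 - 110, 0, 0, []),
        ModelFit("b", {}, None, None, -100.0 + 55, 4, 2 * 4 + 200.0 - 110, 0, 0, []),
    ]
    t2 = compare_models(shifted)
    assert list(t2["model"]) == list(t["model"])  # invariant to lnL shift


def test_h_recovery_from_simulated_spectrum():
    """model3 fit to data generated under H = 0.25 recovers H within 0.08."""
    truth = default_model(H=0.25)
    e = expected_sfs(truth, ("o", "m"), 16, 16, n_sims=30_000, seed=31)
    obs = SFS2D(60_000 * e, 16, 16, 60_000.0)
    t3 = hybrid_origin_templates(default_model())[2]
    fit = fit_model(t3, obs, ("o", "m"), n_sims=10_000, seed=5)
    assert fit.free_value == pytest.approx(0.25, abs=0.08)
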