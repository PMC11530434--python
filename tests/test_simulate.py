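import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sigfitkit as sk
from sigfitkit.simulate import _filter_and_renormalize

from conftest import exposures_from


def make_table(rows: dict, sigs: list[str]) -> sk.EmpiricalWeightTable:
    df = pd.DataFrame(rows, index=sigs).T.fillna(0.0)
    return sk.EmpiricalWeightTable(cancer_type="toy", weights=df)


# -------------------------------------------------------- ground-truth weights

def test_sample_weights_single_donor_table():
    table = make_table({"d0": {"SBS1": 1.0}}, ["SBS1"])
    truth, prov = sk.sample_weights(table, n=5, m=100, seed=3)
    assert truth.weights.shape == (1, 5)
    assert (truth.weights.loc["SBS1"] == 1.0).all()
    assert set(prov["donor"]) == {"d0"}


@pytest.mark.parametrize(
    "m,expected_b", [(50, 0.0), (2000, 0.1)],
    ids=["cutoff-removes", "cutoff-keeps"],
)
def test_expected_contribution_cutoff(m, expected_b):
    # weight 0.1 contributes m*0.1 mutations; dropped iff below 10
    row = pd.Series({"A": 0.9, "B": 0.1})
    out = _filter_and_renormalize(row, m=m, min_contribution=10, sample_id="s0")
    if expected_b == 0.0:
        assert out["A"] == pytest.approx(1.0)
        assert out["B"] == 0.0
    else:
        assert out["A"] == pytest.approx(0.9)
        assert out["B"] == pytest.approx(0.1)
    assert out.sum() == pytest.approx(1.0)


def test_degenerate_sample_keeps_dominant_signature(caplog):
    row = pd.Series({"A": 0.06, "B": 0.04} | {f"X{i}": 0.09 for i in range(10)})
    with caplog.at_level("WARNING"):
        out = _filter_and_renormalize(row, m=50, min_contribution=10, sample_id="s9")
    assert out.sum() == pytest.approx(1.0)
    assert (out > 0).sum() == 1
    assert out.idxmax() == "X0"  # one of the tied-largest weights
    assert "s9" in caplog.text


def test_filtering_is_a_fixed_point():
    row = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
    once = _filter_and_renormalize(row, 40, 10, "s")
    twice = _filter_and_renormalize(once, 40, 10, "s")
    pd.testing.assert_series_equal(once, twice)


# ----------------------------------------------------------- mixture spectrum

def test_mixture_spectrum_identity_and_linearity(peaked_ref, onehot_ref):
    truth = exposures_from({"s0": {"SYN1": 1.0}})
    W = sk.mixture_spectrum(truth, peaked_ref)
    np.testing.assert_allclose(W["s0"], peaked_ref.profile["SYN1"])

    mix = exposures_from({"s0": {"H1": 0.5, "H2": 0.5}})
    W2 = sk.mixture_spectrum(mix, onehot_ref)
    assert W2["s0"].iloc[0] == pytest.approx(0.5)
    assert W2["s0"].iloc[1] == pytest.approx(0.5)
    assert W2["s0"].sum() == pytest.approx(1.0)


def test_mixture_spectrum_matches_hand_computation(peaked_ref):
    truth = exposures_from({"s0": {"SYN1": 0.2, "SYN2": 0.3, "SYN3": 0.5}})
    W = sk.mixture_spectrum(truth, peaked_ref)
    P = peaked_ref.profile
    expected = 0.2 * P["SYN1"] + 0.3 * P["SYN2"] + 0.5 * P["SYN3"]
    np.testing.assert_allclose(W["s0"], expected)
    with pytest.raises(KeyError):
        sk.mixture_spectrum(exposures_from({"s0": {"NOPE": 1.0}}), peaked_ref)


# --------------------------------------------------------------- count draws

def test_draw_counts_sums_and_degenerate_column(labels):
    W = pd.DataFrame({"s0": [1.0] + [0.0] * 95}, index=labels)
    cat = sk.draw_counts(W, m=77, seed=0)
    assert cat.counts["s0"].iloc[0] == 77
    assert cat.totals()["s0"] == 77


def test_draw_counts_mean_recovery(peaked_ref, labels):
    """Monte-Carlo oracle: empirical context means approach m*W within 4 SE."""
    p = peaked_ref.profile["SYN1"].to_numpy()
    m, reps = 200, 10_000
    W = pd.DataFrame({f"s{i}": p for i in range(reps)}, index=labels)
    counts = sk.draw_counts(W, m=m, seed=42).counts.to_numpy()
    mean = counts.mean(axis=1)
    se = np.sqrt(m * p * (1 - p) / reps)
    ok = np.abs(mean - m * p) <= 4 * se + 1e-12
    assert ok.all()


def test_draw_counts_chi_square_goodness_of_fit(labels):
    """1000 draws of one fixed column pass a chi-square test at alpha=0.001."""
    rng = np.random.default_rng(5)
    p = rng.dirichlet([1.0] * 8)
    full = np.zeros(96)
    full[:8] = p
    m, reps = 500, 1000
    W = pd.DataFrame({f"s{i}": full for i in range(reps)}, index=labels)
    counts = sk.draw_counts(W, m=m, seed=9).counts.to_numpy()
    observed = counts.sum(axis=1)[:8]
    expected = m * reps * p
    stat, pval = stats.chisquare(observed, expected)
    assert pval > 0.001


def test_draw_counts_rejects_non_stochastic(labels):
    W = pd.DataFrame({"s0": [0.5] + [0.0] * 95}, index=labels)
    with pytest.raises(ValueError, match="s0"):
        sk.draw_counts(W, m=10)


# ------------------------------------------------------------------- cohorts

def test_single_signature_cohort_truth_and_determinism(peaked_ref):
    c1 = sk.single_signature_cohort("SYN2", n=20, m=300, reference=peaked_ref, seed=8)
    assert (c1.truth.weights.loc["SYN2"] == 1.0).all()
    assert (c1.catalog.totals() == 300).all()
    c2 = sk.single_signature_cohort("SYN2", n=20, m=300, reference=peaked_ref, seed=8)
    pd.testing.assert_frame_equal(c1.catalog.counts, c2.catalog.counts)
    with pytest.raises(KeyError):
        sk.single_signature_cohort("NOPE", 5, 10, peaked_ref)


def test_heterogeneous_cohort_invariants_and_determinism(peaked_ref, weight_table):
    c = sk.heterogeneous_cohort(weight_table, n=30, m=500, reference=peaked_ref, seed=4)
    assert (c.catalog.totals() == 500).all()
    np.testing.assert_allclose(c.truth.weights.sum(axis=0), 1.0)
    pos = c.truth.weights.to_numpy()
    assert pos[pos > 0].min() >= 10 / 500 - 1e-12
    c2 = sk.heterogeneous_cohort(weight_table, n=30, m=500, reference=peaked_ref, seed=4)
    pd.testing.assert_frame_equal(c.catalog.counts, c2.catalog.counts)
    pd.testing.assert_frame_equal(c.truth.weights, c2.truth.weights)


def test_heterogeneous_cohort_large_m_approaches_spectrum(peaked_ref, weight_table):
    c = sk.heterogeneous_cohort(
        weight_table, n=3, m=1_000_000, reference=peaked_ref, seed=1
    )
    W = sk.mixture_spectrum(c.truth.drop_zero_rows(), peaked_ref)
    tv = 0.5 * (c.catalog.normalized() - W).abs().sum(axis=0)
    assert (tv < 0.01).all()


# -------------------------------------------------------------- perturbations

def test_group_difference_factor_one_is_identity():
    truth = exposures_from({"s0": {"A": 0.5, "B": 0.5}, "s1": {"A": 0.2, "B": 0.8}})
    out = sk.inject_group_difference(truth, "A", 1.0)
    pd.testing.assert_frame_equal(out.weights, truth.weights)


def test_group_difference_even_odd_arithmetic():
    truth = exposures_from(
        {"s0": {"SBS40": 0.5, "O": 0.5}, "s1": {"SBS40": 0.5, "O": 0.5}}
    )
    out = sk.inject_group_difference(truth, "SBS40", 1.3)
    assert out.weights.loc["SBS40", "s0"] == pytest.approx(0.65 / 1.15)
    assert out.weights.loc["SBS40", "s1"] == pytest.approx(
        (0.5 / 1.3) / (0.5 / 1.3 + 0.5)
    )
    np.testing.assert_allclose(out.weights.sum(axis=0), 1.0)


def test_group_difference_absent_signature_passthrough():
    truth = exposures_from({"s0": {"A": 1.0}, "s1": {"A": 1.0}})
    out = sk.inject_group_difference(truth, "SBS40", 1.3)
    pd.testing.assert_frame_equal(out.weights, truth.weights)


def test_out_of_reference_injection_arithmetic():
    truth = exposures_from({f"s{i}": {"A": 0.6, "B": 0.4} for i in range(6)})
    out = sk.inject_out_of_reference(
        truth, pool=["N1", "N2", "N3"], x=0.2, split=(0.5, 0.5), seed=0
    )
    w = out.weights
    np.testing.assert_allclose(w.sum(axis=0), 1.0)
    for sid in w.columns:
        assert w.loc["A", sid] == pytest.approx(0.6 * 0.8)
        assert w.loc["B", sid] == pytest.approx(0.4 * 0.8)
        injected = sorted(w.loc[["N1", "N2", "N3"], sid][lambda s: s > 0])
        assert injected == pytest.approx([0.1, 0.1])

    out73 = sk.inject_out_of_reference(
        truth, pool=["N1", "N2"], x=0.2, split=(0.7, 0.3), seed=0
    )
    vals = sorted(v for v in out73.weights.loc[["N1", "N2"], "s0"] if v > 0)
    assert vals == pytest.approx([0.06, 0.14])


def test_out_of_reference_x_zero_identity_and_errors():
    truth = exposures_from({"s0": {"A": 1.0}})
    out = sk.inject_out_of_reference(truth, ["N1", "N2"], x=0.0, seed=0)
    pd.testing.assert_frame_equal(out.weights, truth.weights)
    with pytest.raises(ValueError):
        sk.inject_out_of_reference(truth, ["N1"], x=0.2)


# ----------------------------------------------------------------- subsampling

def test_subsample_full_depth_returns_original(peaked_ref):
    c = sk.single_signature_cohort("SYN1", 4, 200, peaked_ref, seed=0)
    [sub] = sk.subsample_catalog(c.catalog, m=200, n_replicates=1, seed=1)
    pd.testing.assert_frame_equal(sub.counts, c.catalog.counts)


def test_subsample_single_mutation_and_error(peaked_ref):
    c = sk.single_signature_cohort("SYN1", 2, 50, peaked_ref, seed=0)
    [sub] = sk.subsample_catalog(c.catalog, m=1, seed=2)
    assert (sub.totals() == 1).all()
    drawn = sub.counts.to_numpy().nonzero()[0]
    orig = c.catalog.counts.to_numpy()
    for j, ctx in enumerate(drawn):
        assert orig[ctx, j] > 0
    with pytest.raises(ValueError):
        sk.subsample_catalog(c.catalog, m=51)


def test_subsample_mean_matches_hypergeometric(peaked_ref):
    """Mean subsampled fraction equals the original fraction (within 4 SE)."""
    c = sk.single_signature_cohort("SYN1", 1, 400, peaked_ref, seed=3)
    m, reps = 100, 2000
    subs = sk.subsample_catalog(c.catalog, m=m, n_replicates=reps, seed=4)
    stacked = np.stack([s.counts.to_numpy()[:, 0] for s in subs])
    mean = stacked.mean(axis=0)
    K = c.catalog.counts.to_numpy()[:, 0].astype(float)
    N = K.sum()
    expected = m * K / N
    var = m * (K / N) * (1 - K / N) * (N - m) / (N - 1)
    se = np.sqrt(var / reps)
    assert (np.abs(mean - expected) <= 4 * se + 1e-9).all()


# -------------------------------------------------------- synthetic fixtures

def test_synth_catalog_concentration_controls_flatness():
    peaked = sk.synth_signature_catalog(5, concentration=1e-3, seed=0)
    flat = sk.synth_signature_catalog(5, concentration=1e3, seed=0)
    peaked_div = [sk.exp_shannon(peaked.profile[n]) for n in peaked.names]
    flat_div = [sk.exp_shannon(flat.profile[n]) for n in flat.names]
    assert max(peaked_div) < 4.0
    assert min(flat_div) > 90.0
    with pytest.raises(ValueError):
        sk.synth_signature_catalog(5, concentration=0.0)


def test_synth_catalog_deterministic():
    a = sk.synth_signature_catalog(5, seed=12)
    b = sk.synth_signature_catalog(5, seed=12)
    pd.testing.assert_frame_equal(a.profile, b.profile)


def test_synth_weight_table_active_range(peaked_ref):
    table = sk.synth_weight_table(
        n_donors=60, signature_names=peaked_ref.names, active_range=(1, 5), seed=2
    )
    active = (table.weights > 0).sum(axis=1)
    assert active.min() >= 1 and active.max() <= 5
    np.testing.assert_allclose(table.weights.sum(axis=1), 1.0)


def test_glioblastoma_like_table_summary_statistics():
    table = sk.glioblastoma_like_weight_table(seed=0)
    w40 = table.weights["SBS40"]
    assert (w40 > 0).all()  # active in every donor
    assert np.median(w40) == pytest.approx(0.485, abs=0.01)
    np.testing.assert_allclose(table.weights.sum(axis=1), 1.0)
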