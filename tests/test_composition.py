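import numpy as np
import pandas as pd
import pytest
from scipy import special

from ribopause.composition import (CompositionError, codon_window_profile,
                                   encode_codons, feature_frequencies,
                                   gravy_index, peak_randomization_test,
                                   peak_to_codon_range, relative_frequency,
                                   zib_set_comparison)


def codons_of(seq):
    return encode_codons([seq[i:i + 3] for i in range(0, len(seq), 3)])


# --- frequencies -------------------------------------------------------------

def test_peak_codon_frequencies():
    units = {"pk": encode_codons(["GAA", "GAA", "GAT"])}
    t = feature_frequencies(units, family="codon").set_index("feature")
    assert t.loc["GAA", "freq"] == pytest.approx(2 / 3)
    assert t.loc["GAT", "freq"] == pytest.approx(1 / 3)
    assert t.loc["AAA", "freq"] == 0.0
    assert t["freq"].sum() == pytest.approx(1.0)


def test_peak_amino_acid_frequencies():
    units = {"pk": encode_codons(["GAA", "GAA", "GAT"])}
    t = feature_frequencies(units, family="amino_acid").set_index("feature")
    assert t.loc["E", "freq"] == pytest.approx(2 / 3)
    assert t.loc["D", "freq"] == pytest.approx(1 / 3)


def test_one_nt_peak_single_codon():
    assert peak_to_codon_range(4, 5) == (1, 2)
    units = {"pk": encode_codons(["GAA"])}
    t = feature_frequencies(units).set_index("feature")
    assert t.loc["GAA", "freq"] == 1.0


def test_frequencies_sum_to_one_per_unit():
    rng = np.random.default_rng(0)
    from ribopause.composition import CODONS
    units = {f"u{i}": encode_codons(list(rng.choice(CODONS, size=30)))
             for i in range(10)}
    for fam in ("codon", "amino_acid"):
        t = feature_frequencies(units, family=fam)
        sums = t.groupby("unit_id")["freq"].sum()
        assert np.allclose(sums, 1.0)


# --- randomization test ------------------------------------------------------

def test_randomization_p_floor_when_observed_above_all():
    # observed peak is pure GAA; the control pool contains no GAA at all,
    # so the observed mean is strictly above every control mean
    gene_codons = {
        "bg1": encode_codons(["ATG"] + ["CCC"] * 60 + ["TAA"]),
        "bg2": encode_codons(["ATG"] + ["GGG"] * 60 + ["TAA"]),
        "hot": encode_codons(["ATG"] + ["GAA"] * 5 + ["CCC"] * 56 + ["TAA"]),
    }
    pool = {g: v for g, v in gene_codons.items() if g != "hot"}
    peaks = [("hot", 3, 18)]  # the 5 GAA codons
    res = peak_randomization_test(peaks, gene_codons, n_controls=10_000, seed=1,
                                  control_pool=pool)
    row = res.table.set_index("feature").loc["GAA"]
    assert row["k"] == 0
    assert row["p_emp"] == pytest.approx(1.0 / 10_000)
    assert res.n_control_sets_drawn == 10_000


def test_randomization_exhaustive_enumeration_oracle():
    # two tiny genes, one 2-codon peak: control distribution enumerable
    gene_codons = {
        "gA": encode_codons(["GAA", "GAA", "CCC", "GGG", "CCC"]),
        "gB": encode_codons(["CCC", "GAA", "CCC", "TTT"]),
    }
    m = 2
    placements = []
    for gid, ids in gene_codons.items():
        arr = np.asarray(ids)
        for s in range(len(arr) - m + 1):
            window = arr[s:s + m]
            placements.append((window == encode_codons(["GAA"])[0]).mean())
    placements = np.array(placements)  # uniform over placements by design
    obs_freq = 0.5  # peak covering codons [1, 3) of gA: GAA, CCC
    q_ge = (placements >= obs_freq).mean()
    q_le = (placements <= obs_freq).mean()
    expected_p = min(q_ge, q_le)

    res = peak_randomization_test([("gA", 3, 9)], gene_codons,
                                  n_controls=10_000, seed=7)
    row = res.table.set_index("feature").loc["GAA"]
    assert row["mean_obs"] == pytest.approx(obs_freq)
    # binomial tolerance at 4 sigma
    tol = 4 * np.sqrt(expected_p * (1 - expected_p) / 10_000)
    assert row["p_emp"] == pytest.approx(expected_p, abs=tol)
    assert row["k"] + row["l"] >= 10_000  # ties counted in both


def test_randomization_reproducible_and_seed_sensitive():
    gene_codons = {"g": encode_codons(["ATG"] + ["GAA", "CCC"] * 30 + ["TAA"])}
    peaks = [("g", 3, 12)]
    a = peak_randomization_test(peaks, gene_codons, n_controls=500, seed=3)
    b = peak_randomization_test(peaks, gene_codons, n_controls=500, seed=3)
    c = peak_randomization_test(peaks, gene_codons, n_controls=500, seed=4)
    pd.testing.assert_frame_equal(a.table, b.table)
    assert not a.table.equals(c.table)


def test_randomization_control_peak_too_long_errors():
    gene_codons = {"g": encode_codons(["ATG", "GAA", "GAA", "TAA"])}
    short_pool = {"s": encode_codons(["ATG", "TAA"])}
    with pytest.raises(CompositionError, match="control peak"):
        peak_randomization_test([("g", 0, 12)], gene_codons, n_controls=10,
                                control_pool=short_pool)


def test_randomization_unknown_gene_errors():
    gene_codons = {"g": encode_codons(["ATG", "GAA", "TAA"])}
    with pytest.raises(CompositionError):
        peak_randomization_test([("nope", 0, 3)], gene_codons, n_controls=10)


# --- relative frequency ------------------------------------------------------

def test_relative_frequency_identity():
    assert relative_frequency(0.1, 0.1) == 0.0


def test_relative_frequency_substitution():
    assert relative_frequency(0.12, 0.10) == pytest.approx(0.2)


def test_relative_frequency_zero_control_nan():
    assert np.isnan(relative_frequency(0.1, 0.0))


# --- zero-inflated beta contrasts -------------------------------------------

def _zib_rows(rng, label, shift, n, zero_p=0.2, base_mu=0.10, phi=30.0):
    mu = special.expit(special.logit(base_mu) + shift)
    y = np.where(rng.random(n) < zero_p, 0.0, rng.beta(mu * phi, (1 - mu) * phi, n))
    return [{"set": label, "freq": v, "size": int(rng.integers(100, 300))}
            for v in y]


def test_zib_null_calibration():
    rng = np.random.default_rng(0)
    rows = []
    for f in range(150):
        for r in _zib_rows(rng, "A", 0.0, 60) + _zib_rows(rng, "B", 0.0, 60):
            rows.append({**r, "feature": f"f{f}"})
    res = zib_set_comparison(pd.DataFrame(rows))
    assert res["converged"].mean() > 0.9
    type1 = (res["p_positive"] <= 0.05).mean()
    assert 0.005 <= type1 <= 0.11


def test_zib_power_at_planted_shift():
    rng = np.random.default_rng(1)
    rows = []
    for f in range(40):
        for r in _zib_rows(rng, "A", 0.0, 200) + _zib_rows(rng, "B", 0.5, 200):
            rows.append({**r, "feature": f"p{f}"})
    res = zib_set_comparison(pd.DataFrame(rows))
    assert (res["p_positive"] <= 0.05).mean() >= 0.9


def test_zib_all_zero_set_degenerate():
    rng = np.random.default_rng(2)
    rows = [{**r, "feature": "x"} for r in _zib_rows(rng, "A", 0.0, 40, zero_p=0.1)]
    rows += [{"set": "B", "freq": 0.0, "size": 150, "feature": "x"}
             for _ in range(40)]
    res = zib_set_comparison(pd.DataFrame(rows))
    row = res.iloc[0]
    assert np.isnan(row["p_positive"])
    assert row["p_zero"] < 0.001  # zero proportions 10% vs 100%


def test_zib_requires_two_sets():
    df = pd.DataFrame([{"feature": "x", "set": "A", "freq": 0.1, "size": 10}])
    with pytest.raises(CompositionError):
        zib_set_comparison(df)


def test_zib_shrinks_exact_ones():
    rng = np.random.default_rng(3)
    rows = [{**r, "feature": "x"} for r in _zib_rows(rng, "A", 0.0, 40)]
    rows += [{"set": "B", "freq": 1.0, "size": 100, "feature": "x"}]
    rows += [{**r, "feature": "x"} for r in _zib_rows(rng, "B", 0.0, 39)]
    res = zib_set_comparison(pd.DataFrame(rows))  # must not blow up on y == 1
    assert len(res) == 1


# --- window profile ----------------------------------------------------------

def test_window_profile_flat_on_uniform():
    rng = np.random.default_rng(4)
    from ribopause.composition import CODONS
    sense = [c for c in CODONS if c not in ("TAA", "TAG", "TGA")]
    gene_codons = {f"g{i}": encode_codons(list(rng.choice(sense, size=200)))
                   for i in range(30)}
    peaks = [(f"g{i}", 300, 309) for i in range(30)]
    prof, n = codon_window_profile(peaks, gene_codons, window=10, n_windows=20)
    gaa = prof["GAA"]
    assert abs(gaa.loc[0] - 1 / 61) < 0.03
    assert gaa.dropna().std() < 0.02


def test_window_profile_planted_core():
    base = ["CCC"] * 100
    gene_codons = {}
    peaks = []
    for i in range(20):
        codons = list(base)
        codons[50:53] = ["GAA", "GAA", "GAA"]
        gene_codons[f"g{i}"] = encode_codons(codons)
        peaks.append((f"g{i}", 150, 159))
    prof, _ = codon_window_profile(peaks, gene_codons, window=10, n_windows=10)
    assert prof.loc[0, "GAA"] == pytest.approx(1.0)
    assert prof.loc[10, "GAA"] < 0.5
    assert prof.loc[-10, "GAA"] < 0.5


def test_window_profile_peak_at_start_no_error():
    gene_codons = {"g": encode_codons(["GAA"] * 3 + ["CCC"] * 50)}
    prof, n = codon_window_profile([("g", 0, 9)], gene_codons,
                                   window=10, n_windows=5)
    assert prof.loc[0, "GAA"] == pytest.approx(1.0)
    # upstream windows have no codons -> no contribution
    assert n.set_index("offset").loc[-5, "n_peaks"] == 0


def test_window_profile_boundary_codons_excluded():
    gene_codons = {"g": encode_codons(["GAA"] * 20)}
    boundary = {"g": np.array([i == 5 for i in range(20)])}
    prof_all, _ = codon_window_profile([("g", 30, 36)], gene_codons,
                                       window=3, n_windows=2)
    prof_excl, _ = codon_window_profile([("g", 30, 36)], gene_codons,
                                        boundary=boundary, window=3, n_windows=2)
    assert prof_all.loc[0, "GAA"] == prof_excl.loc[0, "GAA"] == 1.0


# --- hydropathy --------------------------------------------------------------

def test_gravy_constant_sequence():
    assert gravy_index("III") == pytest.approx(4.5)


def test_gravy_ordering():
    assert gravy_index("I") > gravy_index("R")


def test_gravy_hand_sum():
    # M 1.9, W -0.9, K -3.9
    assert gravy_index("MWK") == pytest.approx((1.9 - 0.9 - 3.9) / 3)


def test_gravy_skips_stop_and_unknown():
    assert gravy_index("I*X") == pytest.approx(4.5)
    assert np.isnan(gravy_index("**"))
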