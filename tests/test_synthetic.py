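import numpy as np
import pandas as pd
import pytest

from ribopause.synthetic import (STOPS, SimConfig, SimConfigError,
                                 expected_tdd_index, make_design,
                                 simulate_pileup, simulate_ribo_rna_coverage,
                                 simulate_tdd_counts, simulate_transcriptome)


# --- config validation -------------------------------------------------------

@pytest.mark.parametrize("kw", [
    {"n_genes": -1},
    {"biased_gene_fraction": 1.5},
    {"bias_multiplier": 0.5},
    {"k_base": -0.1},
    {"depth": 0},
    {"bias_codons": ("TAA",)},
    {"error_model": "bogus"},
])
def test_invalid_config_raises(kw):
    with pytest.raises(SimConfigError):
        SimConfig(**kw)


def test_infeasible_bias_raises():
    # 16 codons x multiplier 4 would exceed total frequency 1
    codons = tuple(c for c in
                   ("GAA GAT AAT AAA GAG GAC AAC AAG CAA CAT CAC CAG TCA TCT TCC TCG".split()))
    with pytest.raises(SimConfigError, match="infeasible"):
        SimConfig(bias_codons=codons, bias_multiplier=4.0)


# --- transcriptome -----------------------------------------------------------

def test_transcriptome_structure():
    tx = simulate_transcriptome(SimConfig(n_genes=30, seed=2))
    assert len(tx.genes) == 30
    for g in tx.genes:
        assert g.seq.startswith("ATG")
        assert g.seq[-3:] in STOPS
        assert len(g.seq) % 3 == 0
        assert not any(c in STOPS for c in g.codons[:-1])


def test_transcriptome_empty():
    tx = simulate_transcriptome(SimConfig(n_genes=0))
    assert tx.genes == [] and tx.genome == {} and len(tx.truth) == 0


def test_bias_multiplier_recovered():
    cfg = SimConfig(n_genes=80, gene_length_codons=(300, 300),
                    bias_codons=("GAA",), bias_multiplier=3.0,
                    biased_gene_fraction=0.5, seed=4)
    tx = simulate_transcriptome(cfg)
    flags = tx.truth.set_index("gene_id")["biased"]

    def gaa_freq(g):
        return g.codons.count("GAA") / len(g.codons)

    biased = np.mean([gaa_freq(g) for g in tx.genes if flags[g.gene_id]])
    background = np.mean([gaa_freq(g) for g in tx.genes if not flags[g.gene_id]])
    assert biased / background == pytest.approx(3.0, rel=0.15)


def test_bias_null_indistinguishable():
    cfg = SimConfig(n_genes=80, gene_length_codons=(300, 300),
                    bias_codons=("GAA",), bias_multiplier=1.0,
                    biased_gene_fraction=0.5, seed=4)
    tx = simulate_transcriptome(cfg)
    flags = tx.truth.set_index("gene_id")["biased"]
    freqs = {True: [], False: []}
    for g in tx.genes:
        freqs[bool(flags[g.gene_id])].append(g.codons.count("GAA") / len(g.codons))
    from scipy import stats
    _, p = stats.ttest_ind(freqs[True], freqs[False])
    assert p > 0.01


def test_transcriptome_deterministic(tmp_path):
    cfg = SimConfig(n_genes=10, seed=9)
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        simulate_transcriptome(cfg).write(d / "g.fa", d / "a.gtf", d / "t.tsv")
    for name in ("g.fa", "a.gtf", "t.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


# --- TDD counts --------------------------------------------------------------

def test_tdd_counts_noiseless_closed_form():
    cfg = SimConfig(n_genes=40, dispersion=0.0, k_base=0.1, k_tdd=0.2, seed=6)
    sim = simulate_tdd_counts(cfg, [f"g{i}" for i in range(40)])
    from ribopause import tdd
    res = tdd.run_tdd(sim.counts, sim.samples)
    truth = sim.truth.set_index("gene_id")
    idx = res.indices
    for gid, row in truth.iterrows():
        for t in (3.0, 5.0):
            for cond in ("CTRL", "TRT"):
                k_tdd = row["k_tdd_trt"] if cond == "TRT" else row["k_tdd_ctrl"]
                want = expected_tdd_index(row["k_base"], k_tdd, t)
                got = idx[(idx.gene_id == gid) & (idx.condition == cond)
                          & (idx.time_h == t)]["tdd_index"]
                assert np.allclose(got, want, atol=1e-9)


def test_tdd_counts_all_zero_ktdd_gives_zero_index():
    cfg = SimConfig(n_genes=20, dispersion=0.0, tdd_gene_fraction=0.0, seed=6)
    sim = simulate_tdd_counts(cfg, [f"g{i}" for i in range(20)])
    from ribopause import tdd
    res = tdd.run_tdd(sim.counts, sim.samples)
    assert np.allclose(res.indices["tdd_index"], 0.0, atol=1e-9)
    assert (res.results["tdd_class"] == "unchanged").all()


def test_design_without_t0_raises():
    cfg = SimConfig(n_genes=5)
    design = make_design(cfg)
    design = design[design["time_h"] > 0]
    with pytest.raises(SimConfigError, match="t=0"):
        simulate_tdd_counts(cfg, [f"g{i}" for i in range(5)], design=design)


def test_tdd_counts_deterministic():
    cfg = SimConfig(n_genes=10, seed=13)
    a = simulate_tdd_counts(cfg, [f"g{i}" for i in range(10)])
    b = simulate_tdd_counts(cfg, [f"g{i}" for i in range(10)])
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def true_size_factors(sim):
    """Oracle normalization from the generator's truth table: the expected
    count of gene g in sample j is lib * A_g(j) / sum_g A_g(j), so dividing by
    lib / sum_g A_g(j) recovers the absolute abundance scale."""
    truth = sim.truth.set_index("gene_id")
    factors = {}
    for row in sim.samples.itertuples(index=False):
        translating = row.regime in ("none", "Tci")
        k_tdd = truth["k_tdd_trt"] if row.condition == "TRT" else truth["k_tdd_ctrl"]
        k_eff = truth["k_base"] + (k_tdd if translating else 0.0)
        total = (truth["a0"] * np.exp(-k_eff * row.time_h)).sum()
        factors[row.sample] = 1.0 / total
    return pd.Series(factors)


def test_nb_noise_converges_to_closed_form():
    # dispersion -> 0 limit: Monte-Carlo mean approaches the closed form when
    # normalized with the generator's own (oracle) size factors
    cfg = SimConfig(n_genes=200, dispersion=0.002, k_base=0.1, k_tdd=0.2,
                    tdd_gene_fraction=1.0, stable_gene_fraction=0.0, seed=8,
                    lib_size=2e6)
    gene_ids = [f"g{i}" for i in range(200)]
    sim = simulate_tdd_counts(cfg, gene_ids)
    from ribopause import tdd
    norm = tdd.normalize_counts(sim.counts, true_size_factors(sim))
    indices = tdd.tdd_index_table(norm, sim.samples)
    trt3 = indices[(indices.condition == "TRT") & (indices.time_h == 3.0)]
    assert trt3["tdd_index"].mean() == pytest.approx(
        expected_tdd_index(0.1, 0.2, 3.0), abs=0.01)


# --- coverage ----------------------------------------------------------------

def test_coverage_truth_and_shapes():
    cfg = SimConfig(n_genes=15, seed=3)
    tx = simulate_transcriptome(cfg)
    cov = simulate_ribo_rna_coverage(cfg, tx.genes)
    for gid, bundle in cov.test.items():
        g = next(x for x in tx.genes if x.gene_id == gid)
        assert bundle.ribo.shape == (cfg.n_replicates, len(g.seq))
    seqs = {g.gene_id: g for g in tx.genes}
    for r in cov.truth.itertuples():
        assert seqs[r.gene_id].codons[r.codon_ordinal] == cfg.pause_codon
        assert r.end_nt - r.start_nt == 3


def test_coverage_pause_gene_without_codon_warns():
    cfg = SimConfig(n_genes=4, seed=5, pause_codon="TGG",
                    gene_length_codons=(10, 12))
    tx = simulate_transcriptome(cfg)
    # at this length some gene almost surely lacks TGG; force it
    has = [g for g in tx.genes if "TGG" in g.codons[1:-1]]
    if len(has) == len(tx.genes):
        pytest.skip("all genes contain the pause codon for this seed")
    with pytest.warns(UserWarning, match="absent"):
        cov = simulate_ribo_rna_coverage(cfg, tx.genes)
    assert set(cov.truth.gene_id) == {g.gene_id for g in has}


def test_coverage_null_intensity_symmetric_directions():
    # with no planted pause the caller output is pure false positives:
    # TC and CC kept-peak counts should be statistically indistinguishable
    cfg = SimConfig(n_genes=25, seed=3, pause_intensity=1.0)
    tx = simulate_transcriptome(cfg)
    cov = simulate_ribo_rna_coverage(cfg, tx.genes)
    from ribopause.peaks import bidirectional_call
    tc = cc = 0
    for gid in cov.test:
        res = bidirectional_call(cov.test[gid], cov.ctrl[gid])
        tc += sum(p.kept for p in res["TC"])
        cc += sum(p.kept for p in res["CC"])
    assert abs(tc - cc) <= 3 * np.sqrt(tc + cc) + 3


# --- pileups -----------------------------------------------------------------

def test_pileup_counts_sum_to_depth():
    cfg = SimConfig(n_sites=300, seed=7)
    sim = simulate_pileup(cfg)
    for t in sim.tables.values():
        assert (t[["A", "C", "G", "T"]].sum(axis=1) == t["depth"]).all()


def test_pileup_variant_sites_excluded_by_filter():
    cfg = SimConfig(n_sites=2000, seed=7, variant_fraction=0.05)
    sim = simulate_pileup(cfg)
    from ribopause.mutations import filter_sites
    filt = filter_sites(sim.tables["CTRL"], min_depth=1)
    variants = set(sim.truth.loc[sim.truth.is_variant, "site_id"])
    assert variants.isdisjoint(set(filt["site_id"]))


def test_pileup_null_refreq_small():
    cfg = SimConfig(n_sites=5000, seed=17, depth=2000,
                    error_rate_control=0.3, error_rate_treated=0.3)
    sim = simulate_pileup(cfg)
    from ribopause.mutations import compare_conditions, filter_sites
    filt = {c: filter_sites(t) for c, t in sim.tables.items()}
    comp = compare_conditions(filt["TRT"], filt["CTRL"])
    overall = comp[(comp.ref == "*") & (comp.alt == "*")].iloc[0]
    assert abs(overall["refreq_pct"]) < 5.0


def test_pileup_deterministic():
    cfg = SimConfig(n_sites=200, seed=23)
    a = simulate_pileup(cfg)
    b = simulate_pileup(cfg)
    for c in ("CTRL", "TRT"):
        pd.testing.assert_frame_equal(a.tables[c], b.tables[c])
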