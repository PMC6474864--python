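"""Differential-expression tests with independent literal oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenosplit.paired_de import (
    benjamini_hochberg,
    call_degs,
    estimate_dispersions,
    filter_low_expression,
    paired_nb_test,
    tmm_factors,
    _design_matrices,
)
from xenosplit.quantify import CountMatrix, make_meta
from xenosplit.synthetic_data import CohortDesign, simulate_counts, simulate_gene_pairs


def _paired_meta(n_pairs):
    records = {}
    for i in range(n_pairs):
        records[f"d{i}"] = {"patient_id": f"p{i}", "tissue": "donor",
                            "pipeline": "patient", "passage": None}
        records[f"x{i}"] = {"patient_id": f"p{i}", "tissue": "pdx",
                            "pipeline": "pdx", "passage": 1}
    return records


def _matrix(counts, genes=None):
    counts = np.asarray(counts)
    n_pairs = counts.shape[1] // 2
    samples = []
    for i in range(n_pairs):
        samples += [f"d{i}", f"x{i}"]
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(counts, genes, samples, make_meta(_paired_meta(n_pairs)))


# --------------------------------------------------------------------------
# CPM filter
# --------------------------------------------------------------------------


class TestFilter:
    def test_cpm5_gene_retained(self):
        counts = np.full((1, 18), 5)
        cm = _matrix(counts)
        # library sizes are tiny here, so scale: emulate lib 1e6 by padding gene
        big = np.vstack([counts, np.full((1, 18), 1_000_000 - 5)])
        cm = _matrix(big)
        kept = filter_low_expression(cm, 2.0)
        assert "g0" in kept.genes

    def test_rare_singleton_removed(self):
        top = np.zeros((1, 18), int)
        top[0, 0] = 1
        big = np.vstack([top, np.full((1, 18), 1_000_000)])
        kept = filter_low_expression(_matrix(big), 2.0)
        assert kept.genes == ["g1"]

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(500, 18))
        cm = _matrix(counts)
        kept = filter_low_expression(cm, 2.0)
        lib = counts.sum(axis=0)
        expect = [
            f"g{i}"
            for i in range(500)
            if np.mean(counts[i] / lib * 1e6) >= 2.0
        ]
        assert kept.genes == expect

    def test_all_removed_is_error(self):
        cm = _matrix(np.zeros((3, 4), int))
        with pytest.raises(ValueError):
            cm.cpm()  # zero library size already invalid
        cm2 = _matrix(np.vstack([np.ones((1, 4), int) * 0, np.full((1, 4), 10**7)]))
        with pytest.raises(ValueError):
            filter_low_expression(cm2, min_avg_cpm=1e9)

    def test_exact_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 80, size=(200, 6))
        doubled = counts.copy()
        doubled[:, 2] *= 2
        a = filter_low_expression(_matrix(counts), 2.0).genes
        b = filter_low_expression(_matrix(doubled), 2.0).genes
        assert a == b


# --------------------------------------------------------------------------
# TMM
# --------------------------------------------------------------------------


def tmm_oracle(counts):
    """Independent literal reimplementation of the documented TMM recipe."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        y, yr = counts[:, j], counts[:, ref]
        ok = (y > 0) & (yr > 0)
        p, pr = y[ok] / lib[j], yr[ok] / lib[ref]
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        w = (lib[j] - y[ok]) / (lib[j] * y[ok]) + (lib[ref] - yr[ok]) / (lib[ref] * yr[ok])
        n = m.size
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        factors.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        cm = _matrix(counts)
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        cm = _matrix(rng.integers(1, 500, size=(300, 6)))
        nf = tmm_factors(cm)
        assert abs(np.mean(np.log(nf.factors))) < 1e-12

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 400, size=(200, 4))
        cm = _matrix(counts)
        assert np.allclose(tmm_factors(cm).factors, tmm_oracle(counts), rtol=1e-10)

    def test_library_size_scaling_leaves_factor_almost_unchanged(self):
        """M-values are scale invariant; only the inverse-variance weights
        shift slightly when one sample's depth doubles."""
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 400, size=(300, 4))
        doubled = counts.copy()
        doubled[:, 1] *= 2
        f0 = tmm_factors(_matrix(counts)).factors
        f1 = tmm_factors(_matrix(doubled)).factors
        assert np.allclose(f0, f1, atol=0.02)

    def test_zero_library_is_error(self):
        counts = np.zeros((3, 4), int)
        counts[:, 0] = 5
        with pytest.raises(ValueError):
            tmm_factors(_matrix(counts))


# --------------------------------------------------------------------------
# BH
# --------------------------------------------------------------------------


def bh_oracle(p):
    """q_i = min over j with p_j >= p_i of p_j * m / rank_j (step-up)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i] - 1e-15]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert benjamini_hochberg([0.33])[0] == pytest.approx(0.33)

    def test_matches_min_over_tails_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_nan_propagates_and_is_excluded(self):
        q = benjamini_hochberg([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_oracle([0.01, 0.5]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([1.5])


# --------------------------------------------------------------------------
# Dispersion and the paired test
# --------------------------------------------------------------------------


def _null_cohort(n_genes, seed, phi=0.1, n_pairs=9):
    genes = simulate_gene_pairs(n_genes, stroma_proportion=0.0, seed=seed,
                                dispersion=phi)
    design = CohortDesign(n_pairs=n_pairs, seed=seed)
    return filter_low_expression(simulate_counts(genes, design))


class TestDispersions:
    def test_poisson_data_low_dispersion(self):
        genes = simulate_gene_pairs(600, stroma_proportion=0.0, seed=6,
                                    dispersion=1e-6)
        cm = filter_low_expression(simulate_counts(genes, CohortDesign(seed=6)))
        full, _ = _design_matrices(cm.meta, "tissue", ("pdx", "donor"), "patient_id")
        phi = estimate_dispersions(cm, full)
        assert np.median(phi) <= 0.05

    def test_nb_dispersion_recovered(self):
        cm = _null_cohort(600, seed=7)
        full, _ = _design_matrices(cm.meta, "tissue", ("pdx", "donor"), "patient_id")
        phi = estimate_dispersions(cm, full)
        assert 0.05 <= np.median(phi) <= 0.2

    def test_single_gene_common_is_itself(self):
        counts = np.array([[10, 30, 22, 5, 40, 18]])
        meta = make_meta({
            s: {"patient_id": f"p{i % 3}", "tissue": "donor" if i < 3 else "pdx",
                "pipeline": "x", "passage": None}
            for i, s in enumerate(["a", "b", "c", "d", "e", "f"])
        })
        cm = CountMatrix(counts, ["g0"], ["a", "b", "c", "d", "e", "f"], meta)
        full, _ = _design_matrices(cm.meta, "tissue", ("pdx", "donor"), None)
        phi_half = estimate_dispersions(cm, full, shrink_weight=0.5)
        phi_raw = estimate_dispersions(cm, full, shrink_weight=0.0)
        assert phi_half == pytest.approx(phi_raw)  # common equals the gene's own


class TestPairedTest:
    def test_identical_conditions_give_null_result(self):
        counts = np.tile([[40], [100], [7]], (1, 8))
        cm = _matrix(counts)
        res = paired_nb_test(cm, dispersions=np.full(3, 0.1))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert np.allclose(res["pvalue"], 1.0, atol=1e-6)

    def test_unpaired_patients_rejected(self):
        cm = _matrix(np.ones((2, 6), int) * 5)
        meta = cm.meta.copy()
        meta.loc["x2", "patient_id"] = "p0"  # p2 loses its pdx, p0 gains two
        cm2 = CountMatrix(cm.counts, cm.genes, cm.samples, meta)
        with pytest.raises(ValueError, match="unpaired"):
            paired_nb_test(cm2)

    def test_known_fold_change_recovered(self):
        rng = np.random.default_rng(8)
        n_pairs, n_genes = 9, 300
        base = rng.lognormal(np.log(200), 0.4, n_genes)
        donor = rng.poisson(base[:, None] * np.ones((1, n_pairs)))
        pdx = rng.poisson(base[:, None] / 4 * np.ones((1, n_pairs)))  # log2fc -2
        cols, samples = [], []
        for i in range(n_pairs):
            cols += [donor[:, i], pdx[:, i]]
            samples += [f"d{i}", f"x{i}"]
        cm = CountMatrix(np.stack(cols, 1), [f"g{i}" for i in range(n_genes)],
                         samples, make_meta(_paired_meta(n_pairs)))
        res = paired_nb_test(cm)
        med = np.median(res["log2fc"])
        # composition: every gene drops 4x, so TMM centres fold changes at 0;
        # recover the raw effect from the library-size ratio
        lib_ratio = np.log2(cm.counts[:, 1::2].sum() / cm.counts[:, 0::2].sum())
        assert med + lib_ratio == pytest.approx(-2.0, abs=0.15)

    def test_null_calibration_single_seed(self):
        cm = _null_cohort(800, seed=9)
        res = paired_nb_test(cm)
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08
        assert (res["fdr"] < 0.05).mean() <= 0.01

    def test_pairing_absorbs_patient_effects(self):
        """Shuffling patient labels within condition destroys power when the
        condition effect rides on strong patient-correlated expression."""
        rng = np.random.default_rng(10)
        n_pairs, n_genes = 9, 400
        base = rng.lognormal(np.log(150), 0.3, n_genes)
        patient = rng.lognormal(0, 0.8, size=(n_genes, n_pairs))
        effect = np.where(rng.random(n_genes) < 0.3, 2 ** -1.5, 1.0)
        cols, samples = [], []
        for i in range(n_pairs):
            mu = base * patient[:, i]
            cols += [rng.poisson(mu), rng.poisson(mu * effect)]
            samples += [f"d{i}", f"x{i}"]
        cm = CountMatrix(np.stack(cols, 1), [f"g{i}" for i in range(n_genes)],
                         samples, make_meta(_paired_meta(n_pairs)))
        paired = call_degs(paired_nb_test(cm), lfc=1.0)["n_total"]
        meta_shuffled = cm.meta.copy()
        donors = [f"d{i}" for i in range(n_pairs)]
        perm = np.roll(np.arange(n_pairs), 1)
        meta_shuffled.loc[donors, "patient_id"] = [f"p{j}" for j in perm]
        cm_shuf = CountMatrix(cm.counts, cm.genes, cm.samples, meta_shuffled)
        shuffled = call_degs(paired_nb_test(cm_shuf), lfc=1.0)["n_total"]
        assert shuffled <= 0.5 * paired

    def test_approximate_depth_invariance(self):
        """Doubling one sample's counts (and hence its library size) leaves
        fold changes essentially unchanged; exact invariance cannot hold for
        a count model since depth carries information."""
        cm = _null_cohort(300, seed=11)
        doubled = cm.counts.copy()
        doubled[:, 3] *= 2
        cm2 = CountMatrix(doubled, cm.genes, cm.samples, cm.meta)
        phi = np.full(len(cm.genes), 0.1)
        a = paired_nb_test(cm, dispersions=phi)
        b = paired_nb_test(cm2, dispersions=phi)
        diff = np.abs(a["log2fc"].to_numpy() - b["log2fc"].to_numpy())
        assert np.median(diff) < 0.01
        assert diff.max() < 0.1
        assert np.corrcoef(a["pvalue"], b["pvalue"])[0, 1] > 0.99


class TestCallDegs:
    def test_empty_when_nothing_passes(self):
        res = pd.DataFrame({"gene_id": ["a"], "log2fc": [0.2],
                            "pvalue": [0.5], "fdr": [0.9]})
        out = call_degs(res)
        assert out["up"] == set() and out["down"] == set()

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(12)
        n = 200
        res = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "log2fc": rng.normal(0, 2, n),
            "pvalue": rng.random(n),
            "fdr": rng.random(n),
        })
        out = call_degs(res, alpha=0.1, lfc=0.5)
        expect_up = {r.gene_id for r in res.itertuples()
                     if r.fdr < 0.1 and abs(r.log2fc) > 0.5 and r.log2fc > 0}
        expect_down = {r.gene_id for r in res.itertuples()
                       if r.fdr < 0.1 and abs(r.log2fc) > 0.5 and r.log2fc < 0}
        assert out["up"] == expect_up and out["down"] == expect_down

    def test_stroma_loss_dominated_by_downregulation(self, small_cohort):
        truth = small_cohort["truth"]
        filt = filter_low_expression(truth)
        res = paired_nb_test(filt)
        out = call_degs(res)
        assert out["n_total"] > 0
        assert out["down_fraction"] > 0.5
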