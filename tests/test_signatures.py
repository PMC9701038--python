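"""Catalog construction, NMF recovery and cosine matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from pgkit.io import CHANNELS_96, MutationTable
from pgkit.signatures import (
    MutationCatalog,
    build_catalog,
    cosine_similarity,
    factorize,
    match_to_reference,
    select_k,
)


def catalog_from(counts: np.ndarray, n_samples: int) -> MutationCatalog:
    return MutationCatalog(pd.DataFrame(
        counts, index=list(CHANNELS_96),
        columns=[f"S{j}" for j in range(n_samples)]))


def mutation_record(sample, ctx, ref, alt, vclass="missense"):
    return {"sample_id": sample, "gene": "G1", "variant_class": vclass,
            "ref_allele": ref, "alt_allele": alt,
            "trinucleotide_context": ctx, "protein_change": None}


class TestBuildCatalog:
    def test_single_snv_increments_one_channel(self):
        table = MutationTable(pd.DataFrame(
            [mutation_record("T1", "ACA", "C", "T")]))
        catalog = build_catalog(table, ["T1", "T2"])
        assert catalog.counts.to_numpy().sum() == 1
        assert catalog.counts.loc["A[C>T]A", "T1"] == 1

    def test_only_frameshifts_gives_zero_catalog(self):
        table = MutationTable(pd.DataFrame(
            [mutation_record("T1", None, "A", "-", "frameshift")]))
        catalog = build_catalog(table, ["T1"])
        assert catalog.counts.to_numpy().sum() == 0

    def test_unknown_sample_rejected(self):
        table = MutationTable(pd.DataFrame(
            [mutation_record("TX", "ACA", "C", "T")]))
        with pytest.raises(ValueError, match="TX"):
            build_catalog(table, ["T1"])

    def test_multinomial_sampling_distribution(self, rng):
        """1000 variants from a known channel law land chi-square-consistent."""
        p = rng.dirichlet(np.ones(96) * 5)
        idx = rng.choice(96, size=1000, p=p)
        rows = []
        for i in idx:
            ch = CHANNELS_96[i]
            rows.append(mutation_record("T1", ch[0] + ch[2] + ch[6],
                                        ch[2], ch[4]))
        catalog = build_catalog(MutationTable(pd.DataFrame(rows)), ["T1"])
        obs = catalog.counts["T1"].to_numpy()
        gof = stats.chisquare(obs, f_exp=1000 * p)
        assert gof.pvalue > 0.01


class TestFactorize:
    def test_exact_low_rank_recovered(self, rng):
        # identifiable planted pair: disjoint signature supports and
        # exposures that include near-pure samples
        W0 = np.zeros((96, 2))
        W0[:48, 0] = rng.dirichlet(np.ones(48) * 0.3)
        W0[48:, 1] = rng.dirichlet(np.ones(48) * 0.3)
        H0 = (rng.dirichlet(np.ones(2) * 0.3, size=20).T
              * rng.uniform(200, 1000, size=20))
        catalog = catalog_from(W0 @ H0, 20)
        dec = factorize(catalog, 2, n_restarts=4, rng_seed=0)
        C = np.array([[cosine_similarity(W0[:, i], dec.W.iloc[:, j])
                       for j in range(2)] for i in range(2)])
        ri, ci = linear_sum_assignment(-C)
        assert np.all(C[ri, ci] >= 0.99)

    def test_rank_one_is_exact(self, rng):
        w = rng.dirichlet(np.ones(96))
        catalog = catalog_from(np.outer(w, rng.uniform(100, 1000, 15)), 15)
        dec = factorize(catalog, 1, n_restarts=2, rng_seed=0)
        V = catalog.counts.to_numpy()
        assert dec.reconstruction_error / np.linalg.norm(V) < 1e-6

    def test_normalizations_hold(self, rng):
        catalog = catalog_from(rng.poisson(20, size=(96, 12)), 12)
        dec = factorize(catalog, 3, n_restarts=2, rng_seed=1)
        np.testing.assert_allclose(dec.W.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(dec.H.sum(axis=0), 1.0, atol=1e-9)
        assert (dec.W.to_numpy() >= 0).all() and (dec.H.to_numpy() >= 0).all()

    def test_error_non_increasing_in_k(self, rng):
        catalog = catalog_from(rng.poisson(30, size=(96, 15)), 15)
        errs = [factorize(catalog, k, n_restarts=3,
                          rng_seed=0).reconstruction_error
                for k in (1, 2, 3, 4)]
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_sample_permutation_equivariance(self, rng):
        counts = rng.poisson(30, size=(96, 10))
        perm = rng.permutation(10)
        d1 = factorize(catalog_from(counts, 10), 2, n_restarts=2, rng_seed=5)
        d2 = factorize(catalog_from(counts[:, perm], 10), 2, n_restarts=2,
                       rng_seed=5)
        # W identical up to component order; exposures follow the permutation
        C = d1.W.T.to_numpy() @ d2.W.to_numpy()
        ri, ci = linear_sum_assignment(-C)
        norm = (np.linalg.norm(d1.W.to_numpy(), axis=0)[ri]
                * np.linalg.norm(d2.W.to_numpy(), axis=0)[ci])
        assert np.all(C[ri, ci] / norm > 0.999)

    def test_all_zero_catalog_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            factorize(catalog_from(np.zeros((96, 5)), 5), 1)

    def test_k_out_of_range_rejected(self, rng):
        catalog = catalog_from(rng.poisson(5, size=(96, 4)), 4)
        with pytest.raises(ValueError):
            factorize(catalog, 5)


class TestSelectK:
    def test_rank_one_forced_minimum(self, rng):
        w = rng.dirichlet(np.ones(96) * 0.5)
        catalog = catalog_from(
            np.outer(w, rng.uniform(500, 1500, 30)).round(), 30)
        assert select_k(catalog, range(1, 5), rng_seed=0) == 1

    def test_iid_noise_gives_one(self, rng):
        catalog = catalog_from(rng.poisson(20, size=(96, 30)).astype(float), 30)
        assert select_k(catalog, range(1, 5), rng_seed=0) == 1

    def test_empty_range_rejected(self, rng):
        catalog = catalog_from(rng.poisson(5, size=(96, 5)), 5)
        with pytest.raises(ValueError, match="empty"):
            select_k(catalog, [], rng_seed=0)


class TestMatchToReference:
    def reference(self, rng, r=4):
        ref = rng.dirichlet(np.ones(96) * 0.1, size=r).T
        return pd.DataFrame(ref, index=list(CHANNELS_96),
                            columns=[f"R{i}" for i in range(r)])

    def test_identity_match(self, rng):
        ref = self.reference(rng)
        W = ref[["R2"]].rename(columns={"R2": "S1"})
        m = match_to_reference(W, ref)
        assert m.loc[0, "reference"] == "R2"
        assert m.loc[0, "cosine"] == pytest.approx(1.0)

    def test_mixture_matches_dominant_with_exact_cosine(self, rng):
        ref = self.reference(rng)
        w = 0.9 * ref["R0"] + 0.1 * ref["R1"]
        m = match_to_reference(w.to_frame("S1"), ref)
        assert m.loc[0, "reference"] == "R0"
        brute = float(w @ ref["R0"]) / (np.linalg.norm(w)
                                        * np.linalg.norm(ref["R0"]))
        assert m.loc[0, "cosine"] == pytest.approx(brute, abs=1e-12)

    def test_scale_invariance(self, rng):
        ref = self.reference(rng)
        w = rng.dirichlet(np.ones(96))
        m1 = match_to_reference(pd.DataFrame({"S1": w}, index=list(CHANNELS_96)),
                                ref)
        m2 = match_to_reference(pd.DataFrame({"S1": 7.3 * w},
                                             index=list(CHANNELS_96)), ref)
        assert m1.loc[0, "reference"] == m2.loc[0, "reference"]
        assert m1.loc[0, "cosine"] == pytest.approx(m2.loc[0, "cosine"])

    def test_orthogonal_one_hot_cosine_zero(self):
        a = np.zeros(96); a[0] = 1.0
        b = np.zeros(96); b[1] = 1.0
        assert cosine_similarity(a, b) == 0.0

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity(np.zeros(96), np.ones(96))
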