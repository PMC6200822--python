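import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npclkit.popgen import (
    HaplotypeAlignment,
    HKALocus,
    TajimaComponents,
    harmonic_a1,
    hka_test,
    per_population_report,
    summarize,
    tajimas_D,
)

from _oracles import hka_grid_minimum, hka_x2_reference, tajima_d_reference


def _haps(seqs, locus="loc1", pop="pop1"):
    return HaplotypeAlignment(
        locus_id=locus, population_id=pop,
        sequences=[(f"h{i}", s) for i, s in enumerate(seqs)],
    )


class TestSummarize:
    def test_monomorphic_alignment(self):
        s = summarize(_haps(["ACGTACGTAC"] * 4))
        assert (s.S, s.H, s.Hd, s.pi) == (0, 1, 0.0, 0.0)
        assert s.tajima_D is None

    def test_haplotype_diversity_nei_formula(self):
        # counts (2,1,1) in n=4: Hd = (4/3)(1 - (0.25 + 0.0625 + 0.0625))
        s = summarize(_haps(["AAAA", "AAAA", "AAAT", "AATT"]))
        assert s.H == 3
        assert s.Hd == pytest.approx((4 / 3) * (1 - 0.375))

    def test_mean_pairwise_differences(self):
        # pairwise diffs {1, 2, 3} over L=10: k_hat = 2, pi = 0.2
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAATTT"]
        # diffs: (0,1)=1, (0,2)=3, (1,2)=2
        s = summarize(_haps(seqs))
        assert s.k_hat == pytest.approx(2.0)
        assert s.pi == pytest.approx(0.2)

    def test_segregating_sites_ignore_missing_only_columns(self):
        s = summarize(_haps(["ACGT-N", "ACGAAN", "ACGAAN"]))
        assert s.S == 1  # column 3 varies; gap/N columns don't segregate alone

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            _haps(["ACGT"])

    def test_invariant_under_relabeling_and_reordering(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
        a = summarize(_haps(seqs))
        b = summarize(_haps(seqs[::-1]))
        assert (a.S, a.H, a.Hd, a.k_hat, a.pi) == (b.S, b.H, b.Hd, b.k_hat, b.pi)


class TestTajimasD:
    def test_zero_when_khat_equals_watterson(self):
        n, S = 10, 5
        k_hat = S / harmonic_a1(n)
        assert tajimas_D((S, k_hat), n) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value_n4(self):
        # a1 = 11/6, a2 = 49/36 for n = 4
        t = TajimaComponents(4)
        assert t.a1 == pytest.approx(11 / 6)
        assert t.a2 == pytest.approx(49 / 36)
        assert tajimas_D((3, 2.0), 4) == pytest.approx(2.01, abs=0.01)

    def test_undefined_for_no_segregating_sites(self):
        with pytest.raises(ValueError):
            tajimas_D((0, 0.0), 10)

    @given(
        st.integers(4, 60),
        st.integers(1, 80),
        st.floats(0.01, 40.0),
    )
    def test_matches_independent_formula_evaluation(self, n, S, k_hat):
        assert tajimas_D((S, k_hat), n) == pytest.approx(
            tajima_d_reference(S, k_hat, n), abs=1e-9
        )

    def test_constants_positive_for_n_at_least_4(self):
        for n in range(4, 40):
            t = TajimaComponents(n)
            assert min(t.a1, t.a2, t.b1, t.b2, t.c1, t.c2, t.e1, t.e2) > 0


class TestHKA:
    TOY = [
        HKALocus("l1", S=10, n=10, D=20.0, L_poly=500, L_div=500),
        HKALocus("l2", S=2, n=10, D=22.0, L_poly=500, L_div=500),
    ]

    def test_exact_expectations_give_x2_zero(self):
        theta, T = 0.004, 8.0
        loci = []
        for i, n in enumerate((10, 12)):
            a1 = harmonic_a1(n)
            L = 500
            loci.append(
                HKALocus(
                    f"l{i}",
                    S=theta * L * a1,
                    n=n,
                    D=theta * L * (T + (n + 1) / (2 * n)),
                    L_poly=L,
                    L_div=L,
                )
            )
        res = hka_test(loci)
        assert res.X2 == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle_on_toy_table(self):
        res = hka_test(self.TOY)
        grid_x2, _ = hka_grid_minimum(
            [(l.S, l.n, l.D, l.L_poly, l.L_div) for l in self.TOY]
        )
        assert res.X2 == pytest.approx(grid_x2, abs=1e-3)

    def test_fitted_x2_not_above_any_grid_point(self, rng):
        res = hka_test(self.TOY)
        loci = [(l.S, l.n, l.D, l.L_poly, l.L_div) for l in self.TOY]
        for _ in range(200):
            thetas = rng.uniform(1e-4, 0.05, size=2)
            T = rng.uniform(0.1, 30.0)
            assert res.X2 <= hka_x2_reference(thetas, T, loci) + 1e-9

    def test_joint_doubling_scales_theta_not_T(self):
        # exact scale-equivariance holds on a self-consistent table (the
        # quadratic variance terms break it on arbitrary data): doubling S,
        # D and lengths doubles per-locus theta, leaves per-site theta and T
        theta, T = 0.006, 5.0
        loci = []
        for i, n in enumerate((10, 10)):
            a1 = harmonic_a1(n)
            L = 400
            loci.append(
                HKALocus(f"l{i}", S=theta * L * a1, n=n,
                         D=theta * L * (T + (n + 1) / (2 * n)), L_poly=L, L_div=L)
            )
        doubled = [
            HKALocus(l.locus_id, S=2 * l.S, n=l.n, D=2 * l.D,
                     L_poly=2 * l.L_poly, L_div=2 * l.L_div)
            for l in loci
        ]
        res1, res2 = hka_test(loci), hka_test(doubled)
        assert res2.T == pytest.approx(res1.T, abs=1e-3)
        for t1, t2 in zip(res1.thetas, res2.thetas):
            assert t2 == pytest.approx(t1, rel=1e-3)  # per-site theta unchanged
        assert res2.X2 == pytest.approx(res1.X2, abs=1e-3)

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError):
            hka_test(self.TOY[:1])

    def test_degrees_of_freedom(self):
        assert hka_test(self.TOY).df == 1


class TestIupacExpansion:
    def test_het_sites_become_segregating_and_seed_is_deterministic(self):
        from npclkit.popgen import expand_iupac_haplotypes

        records = [("ind1", "ACRTA"), ("ind2", "ACGTA")]
        haps = expand_iupac_haplotypes(records, seed=4)
        assert len(haps) == 4
        alleles = {haps[0][1][2], haps[1][1][2]}
        assert alleles == {"A", "G"}  # R expands to both alleles
        assert haps == expand_iupac_haplotypes(records, seed=4)
        s = summarize(_haps([seq for _, seq in haps]))
        assert s.S == 1  # only the heterozygous column segregates

    def test_unknown_codes_become_n(self):
        from npclkit.popgen import expand_iupac_haplotypes

        haps = expand_iupac_haplotypes([("x", "AB-")])
        assert haps[0][1] == "AN-"


class TestReport:
    def test_shape_and_pooled_rows(self, rng):
        dataset = []
        for locus in ("locA", "locB"):
            for pop in ("p1", "p2"):
                seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]
                dataset.append(_haps(seqs, locus, pop))
        frame = per_population_report(dataset)
        assert len(frame) == 4 + 2
        assert (frame.population == "pooled").sum() == 2

    def test_pooled_segregating_sites_at_least_max_per_population(self, rng):
        dataset = []
        for pop in ("p1", "p2"):
            seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)]
            dataset.append(_haps(seqs, "loc", pop))
        frame = per_population_report(dataset)
        pooled_S = int(frame.loc[frame.population == "pooled", "S"].iloc[0])
        per_pop_S = frame.loc[frame.population != "pooled", "S"].astype(int)
        assert pooled_S >= per_pop_S.max()

    def test_monomorphic_locus_reports_na_tajima(self):
        dataset = [
            _haps(["ACGT" * 10] * 5, "mono", "p1"),
            _haps(["ACGT" * 10] * 4 + ["ACGA" + "ACGT" * 9], "poly", "p1"),
        ]
        frame = per_population_report(dataset)
        mono = frame[(frame.locus == "mono") & (frame.population == "p1")]
        assert np.isnan(mono.tajima_D.iloc[0])
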