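import numpy as np
import pandas as pd
import pytest

from edsel.ancestry import SubstitutionMatrix
from edsel.io import Synonymy, Transcript
from edsel.stats import (
    binomial_resample_ci,
    codon_weights,
    directed_R_from,
    directed_R_to,
    dnds_edited_vs_unedited,
    el_binned,
    el_bins,
    mismatch_R,
    pair_table,
    pearson_f_test,
    q_backward,
    q_forward,
    r_syn_nonsyn_split,
)

# matrix alphabet order: A, E, C, G, T
A, E, C, G, T = range(5)


def matrix(counts, n_E=None, n_A=None):
    counts = np.asarray(counts, dtype=np.int64)
    m = SubstitutionMatrix(counts=counts)
    m.n_focal_E = int(counts[:, E].sum()) if n_E is None else n_E
    m.n_focal_A = int(counts[:, A].sum()) if n_A is None else n_A
    return m


def toy(e_row, a_row, g_row=None, y_rows=None):
    c = np.zeros((5, 5), dtype=np.int64)
    c[E] = e_row
    c[A] = a_row
    if g_row is not None:
        c[G] = g_row
    if y_rows is not None:
        c[C], c[T] = y_rows
    return c


class TestDirectedRTo:
    def test_worked_example(self):
        # E->G 8 of 100; A->G 2 of 100  ->  R_->G = 4
        m = matrix(toy([92, 0, 0, 8, 0], [98, 0, 0, 2, 0]))
        est = directed_R_to(m, "G", reps=1000, seed=0)
        assert est.value == pytest.approx(4.0)
        assert est.ci95[0] <= 4.0 <= est.ci95[1]

    def test_identical_rows_give_unity_for_all_targets(self):
        row = [90, 0, 3, 5, 2]
        m = matrix(toy(row, row))
        for N in ("G", "C", "T", "Y"):
            assert directed_R_to(m, N, reps=200, seed=0).value == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_raised(self):
        m = matrix(toy([92, 0, 0, 8, 0], [100, 0, 0, 0, 0]))
        est = directed_R_to(m, "G", reps=200, seed=0)
        assert est.undefined and np.isnan(est.value)

    def test_y_pools_counts_not_averages(self):
        # E->C 2, E->T 4 of 100; A->C 1, A->T 1 of 100 -> R_->Y = 6/2 = 3
        m = matrix(toy([94, 0, 2, 0, 4], [98, 0, 1, 0, 1]))
        assert directed_R_to(m, "Y", reps=200, seed=0).value == pytest.approx(3.0)


class TestDirectedRFrom:
    def test_worked_example_density_normalization(self):
        # p(G->E)=0.001, p(G->A)=0.099, #E/(#E+#A)=0.01 -> R_G-> = 1
        g_row = [99, 1, 0, 900, 0]
        m = matrix(toy([0] * 5, [0] * 5, g_row=g_row), n_E=10, n_A=990)
        est = directed_R_from(m, "G", reps=200, seed=0)
        assert est.value == pytest.approx(1.0)

    def test_scale_invariance_in_edited_counts(self):
        g_row = [99, 1, 0, 900, 0]
        m1 = matrix(toy([0] * 5, [0] * 5, g_row=g_row), n_E=10, n_A=990)
        # double #E and the G->E count proportionally
        g_row2 = [99, 2, 0, 899, 0]
        m2 = matrix(toy([0] * 5, [0] * 5, g_row=g_row2), n_E=20, n_A=990)
        v1 = directed_R_from(m1, "G", reps=200, seed=0).value
        v2 = directed_R_from(m2, "G", reps=200, seed=0).value
        assert v2 == pytest.approx(v1 * (2 / 1) * (10 / 20) * (99 / 99), rel=0.03)

    def test_zero_edited_pool_flagged(self):
        m = matrix(toy([0] * 5, [0] * 5, g_row=[99, 1, 0, 900, 0]), n_E=0, n_A=990)
        assert directed_R_from(m, "G", reps=200, seed=0).undefined


class TestQ:
    def test_arithmetic(self):
        # R_->G = 4, R_->Y = 0.5  ->  Q_->* = 8
        m = matrix(toy([91, 0, 0, 8, 1], [96, 0, 1, 2, 1]))
        est = q_forward(m, reps=500, seed=0)
        assert est.value == pytest.approx(8.0)

    def test_triple_ratio_identity(self, rng):
        """Q_->* as R_->G/R_->Y equals p(E->G)/p(E->Y) / [p(A->G)/p(A->Y)]
        exactly (algebraic identity)."""
        for _ in range(20):
            c = rng.integers(1, 500, size=(5, 5))
            m = matrix(c)
            q = q_forward(m, reps=10, seed=0).value
            pe = c[E] / c[E].sum()
            pa = c[A] / c[A].sum()
            alt = (pe[G] / (pe[C] + pe[T])) / (pa[G] / (pa[C] + pa[T]))
            assert q == pytest.approx(alt, rel=1e-12)

    def test_backward_density_normalization_cancels(self):
        c = toy([0] * 5, [0] * 5, g_row=[50, 5, 0, 945, 0],
                y_rows=([20, 2, 978, 0, 0], [20, 2, 0, 0, 978]))
        m = matrix(c, n_E=100, n_A=9900)
        est = q_backward(m, reps=500, seed=0)
        # (5/50) / (4/40) = 1
        assert est.value == pytest.approx(1.0)

    def test_undefined_component_propagates(self):
        m = matrix(toy([0] * 5, [0] * 5, g_row=[0, 0, 0, 100, 0]))
        assert q_backward(m, reps=100, seed=0).undefined


class TestScaleInvariance:
    def test_e_row_scaling_leaves_q_unchanged(self, rng):
        c = rng.integers(1, 300, size=(5, 5))
        m1 = matrix(c)
        c2 = c.copy()
        c2[E] *= 7
        m2 = matrix(c2)
        assert q_forward(m1, reps=10, seed=0).value == pytest.approx(
            q_forward(m2, reps=10, seed=0).value
        )


class TestBinomialResampleCI:
    def test_degenerate_zero_count(self):
        assert binomial_resample_ci(0, 50, reps=500, seed=1) == (0.0, 0.0)

    def test_degenerate_full_count(self):
        assert binomial_resample_ci(50, 50, reps=500, seed=1) == (1.0, 1.0)

    def test_deterministic_under_seed(self):
        a = binomial_resample_ci(10, 100, reps=2000, seed=7)
        b = binomial_resample_ci(10, 100, reps=2000, seed=7)
        assert a == b

    def test_plain_proportion_ci_brackets_phat(self):
        lo, hi = binomial_resample_ci(30, 100, reps=5000, seed=2)
        assert lo < 0.3 < hi
        assert 0.2 < lo and hi < 0.42

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_resample_ci(1, 0)
        with pytest.raises(ValueError):
            binomial_resample_ci(5, 3)


class TestMismatchR:
    @staticmethod
    def pairs_from_counts(n_e, e_hits, n_a, a_hits):
        st1 = ["E"] * n_e + ["A"] * n_a
        st2 = (
            ["G"] * e_hits + ["A"] * (n_e - e_hits)
            + ["G"] * a_hits + ["A"] * (n_a - a_hits)
        )
        return pd.DataFrame(
            {
                "state1": st1,
                "state2": st2,
                "el1": [0.5] * (n_e + n_a),
                "el2": np.nan,
                "syn1": -1,
                "syn2": -1,
                "four1": False,
                "four2": False,
            }
        )

    def test_worked_example(self):
        pairs = self.pairs_from_counts(1000, 40, 100_000, 1000)
        est = mismatch_R(pairs, "G", reps=500, seed=0)
        assert est.value == pytest.approx(4.0)

    def test_random_editing_labels_give_unity(self, rng):
        """Exchangeability: labels assigned independently of partner state."""
        n = 40_000
        st1 = rng.choice(["E", "A"], size=n, p=[0.1, 0.9])
        st2 = rng.choice(["A", "G", "C", "T"], size=n, p=[0.85, 0.05, 0.05, 0.05])
        pairs = pd.DataFrame(
            {"state1": st1, "state2": st2, "el1": 0.5, "el2": np.nan,
             "syn1": -1, "syn2": -1, "four1": False, "four2": False}
        )
        est = mismatch_R(pairs, "G", reps=2000, seed=3)
        assert est.ci95[0] <= 1.0 <= est.ci95[1]
        assert abs(est.value - 1.0) < 0.35

    def test_el_range_filters_numerator_only(self):
        pairs = self.pairs_from_counts(100, 10, 1000, 10)
        full = mismatch_R(pairs, "G", reps=100, seed=0)
        banded = mismatch_R(pairs, "G", el_range=(0.4, 0.6), reps=100, seed=0)
        assert banded.value == pytest.approx(full.value)
        empty = mismatch_R(pairs, "G", el_range=(0.8, 0.9), reps=100, seed=0)
        assert empty.undefined

    def test_recovers_planted_multiplier_within_ci_of_recount(self, rng):
        """Simulation with k_EG = 3: extant-pair R_G falls within the
        resampling CI of the value recounted from the true history."""
        from edsel.simulate import SimConfig, simulate_dataset

        ds = simulate_dataset(
            SimConfig(n_transcripts=250, mean_cds_len=900,
                      editing_density=0.04, k_EG=3.0, seed=42)
        )
        pairs = pair_table(ds.alignments, "focal", "sister")
        est = mismatch_R(pairs, "G", reps=3000, seed=1)
        assert est.value > 1.5
        # oracle recount from truth: E-in-focal vs G-in-sister mismatches
        ce = ne = ca = na = 0
        for tt in ds.truth.transcripts.values():
            f, s = tt.tip_states["focal"], tt.tip_states["sister"]
            is_site = np.zeros(len(f), dtype=bool)
            is_site[tt.site_pos] = True
            e_mask = is_site & (f == 0)
            a_mask = ~is_site & (f == 0)
            ce += int((e_mask & (s == 2)).sum())
            ne += int(e_mask.sum())
            ca += int((a_mask & (s == 2)).sum())
            na += int(a_mask.sum())
        recount = (ce / ne) / (ca / na)
        assert est.ci95[0] <= recount <= est.ci95[1]


class TestCodonWeights:
    def test_aaa_transcriptome_hand_check(self):
        trs = {"t1": Transcript("t1", "sp", "AAA" * 20)}
        w = codon_weights(trs)
        assert w.k_non["AAA"] == 2
        assert w.k_syn["AAA"] == 1
        assert w.xi_non == pytest.approx(0.5)
        assert w.xi_syn == pytest.approx(1.0)

    def test_codon_without_adenine_has_zero_opportunities(self):
        trs = {"t1": Transcript("t1", "sp", "GGGAAA" * 10)}
        w = codon_weights(trs)
        assert w.k_non["GGG"] == 0 and w.k_syn["GGG"] == 0

    def test_frequencies_sum_to_one(self, rng):
        cds = "".join(rng.choice(list("ACGT"), size=300))
        trs = {"t1": Transcript("t1", "sp", cds)}
        w = codon_weights(trs)
        assert sum(w.f.values()) == pytest.approx(1.0)

    def test_k_non_plus_k_syn_equals_adenine_count(self):
        trs = {"t1": Transcript("t1", "sp", "ATGAAACCCGTA")}
        w = codon_weights(trs)
        for codon in w.k_non:
            assert w.k_non[codon] + w.k_syn[codon] == codon.count("A")

    def test_no_complete_codons_error(self):
        with pytest.raises(ValueError):
            codon_weights({"t1": Transcript("t1", "sp", "AT")})


class TestSynNonsynSplit:
    def test_all_syn_dataset_leaves_nonsyn_undefined(self):
        by_class = {
            Synonymy.SYN: toy([92, 0, 0, 8, 0], [98, 0, 0, 2, 0]),
            Synonymy.NONSYN: np.zeros((5, 5), dtype=np.int64),
            Synonymy.NONCODING: np.zeros((5, 5), dtype=np.int64),
        }
        m = matrix(by_class[Synonymy.SYN])
        m.by_class = by_class
        split = r_syn_nonsyn_split(m, "to", "G", reps=200, seed=0)
        assert split[Synonymy.SYN].value == pytest.approx(4.0)
        assert split[Synonymy.NONSYN].undefined

    def test_unstratified_matrix_raises(self):
        m = matrix(toy([92, 0, 0, 8, 0], [98, 0, 0, 2, 0]))
        with pytest.raises(ValueError):
            r_syn_nonsyn_split(m, "to", "G", reps=10, seed=0)

    def test_hand_built_classes_match_hand_tally(self):
        """Six-column toy with known classes tallies per class."""
        syn = toy([8, 0, 0, 2, 0], [90, 0, 0, 10, 0])
        non = toy([5, 0, 0, 5, 0], [95, 0, 0, 5, 0])
        m = matrix(syn + non)
        m.by_class = {
            Synonymy.SYN: syn, Synonymy.NONSYN: non,
            Synonymy.NONCODING: np.zeros((5, 5), dtype=np.int64),
        }
        split = r_syn_nonsyn_split(m, "to", "G", reps=100, seed=0)
        assert split[Synonymy.SYN].value == pytest.approx((2 / 10) / (10 / 100))
        assert split[Synonymy.NONSYN].value == pytest.approx((5 / 10) / (5 / 100))


class TestDnDs:
    @staticmethod
    def hand_pairs(dn_e, dn_e_n, ds_e, ds_e_n, dn_a, dn_a_n, ds_a, ds_a_n, el=0.55):
        rows = []

        def add(state, syn, four, n, hits, level):
            for i in range(n):
                rows.append(
                    {"state1": state, "state2": "G" if i < hits else "A",
                     "el1": level, "el2": np.nan, "syn1": syn, "syn2": -1,
                     "four1": four, "four2": False}
                )

        add("E", 0, False, dn_e_n, dn_e, el)
        add("E", 1, True, ds_e_n, ds_e, el)
        add("A", 0, False, dn_a_n, dn_a, np.nan)
        add("A", 1, True, ds_a_n, ds_a, np.nan)
        return pd.DataFrame(rows)

    def test_hand_built_ratio_of_ratios(self):
        # dN_E = 4/100, dS_E = 1/100, dN_A = 1/100, dS_A = 1/100 -> 4
        pairs = self.hand_pairs(4, 100, 1, 100, 1, 100, 1, 100)
        ests, r, p = dnds_edited_vs_unedited(pairs, "G", reps=300, seed=0)
        defined = [e for e in ests if not e.undefined]
        assert len(defined) == 1
        assert defined[0].value == pytest.approx(4.0)
        assert defined[0].el_bin == (0.5, 0.6)

    def test_neutral_counts_give_unity_in_every_bin(self):
        frames = [
            self.hand_pairs(5, 500, 5, 500, 50, 5000, 50, 5000, el=el)
            for el in (0.05, 0.45, 0.95)
        ]
        ests, r, p = dnds_edited_vs_unedited(
            pd.concat(frames, ignore_index=True), "G", reps=300, seed=0
        )
        for e in ests:
            if not e.undefined:
                assert e.value == pytest.approx(1.0)

    def test_el_trend_detected_on_planted_gradient(self):
        """dN/dS increasing with EL yields positive r and small F-test p."""
        frames = []
        for el, dn in [(0.05, 5), (0.25, 10), (0.45, 20), (0.65, 40), (0.85, 80)]:
            frames.append(self.hand_pairs(dn, 1000, 10, 1000, 100, 10000, 100, 10000, el=el))
        ests, r, p = dnds_edited_vs_unedited(
            pd.concat(frames, ignore_index=True), "G", reps=200, seed=0
        )
        assert r > 0.8
        assert p < 0.05


class TestElBins:
    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            el_bins(0.15)

    def test_point_mass_populates_one_bin(self):
        from edsel.stats import StatEstimate

        def stat(bin_):
            if bin_[0] <= 0.05 < bin_[1]:
                return StatEstimate("s", 2.0, el_bin=bin_)
            return None

        ests, r, p = el_binned(stat)
        assert len(ests) == 1 and ests[0].el_bin == (0.0, 0.1)
        assert np.isnan(r)

    def test_constant_statistic_flagged_r(self):
        from edsel.stats import StatEstimate

        ests, r, p = el_binned(lambda b: StatEstimate("s", 1.0, el_bin=b))
        assert np.isnan(r)

    def test_planted_linear_trend_recovered(self):
        from edsel.stats import StatEstimate

        ests, r, p = el_binned(
            lambda b: StatEstimate("s", 1.0 + (b[0] + b[1]) / 2, el_bin=b)
        )
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_last_bin_includes_el_one(self):
        assert el_bins()[-1] == (0.9, 1.0)


class TestPearsonF:
    def test_matches_scipy_pearsonr(self, rng):
        from scipy import stats as sps

        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        r, p = pearson_f_test(x, y)
        r2, p2 = sps.pearsonr(x, y)
        assert r == pytest.approx(r2)
        assert p == pytest.approx(p2, rel=1e-6)
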