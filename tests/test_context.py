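import numpy as np
import pytest

from edsel.context import (
    ContextCounts,
    context_counts,
    context_mismatch_R,
    motif_bitscore,
    window_el_correlation,
)
from edsel.io import EditingSite, OrthoAlignment, Synonymy, Transcript


def make_sites(transcripts, el=0.5):
    sites = []
    for tid, tr in transcripts.items():
        for pos, b in enumerate(tr.cds):
            if b == "A" and 5 <= pos < len(tr.cds) - 5:
                sites.append(EditingSite(tid, pos, el, Synonymy.NONCODING))
    return sites


class TestMotifBitscore:
    def test_identical_flanks_give_two_bits(self):
        trs = {
            f"t{i}": Transcript(f"t{i}", "sp", "CCCGATAGGTCCC") for i in range(4)
        }
        sites = [EditingSite(f"t{i}", 6, 0.5, Synonymy.NONCODING) for i in range(4)]
        prof = motif_bitscore(sites, trs, k=3)
        for o in (-3, -2, -1, 1, 2, 3):
            assert prof.bits[o] == pytest.approx(2.0)

    def test_uniform_random_flanks_near_zero_bits(self, rng):
        trs = {}
        sites = []
        for i in range(400):
            cds = "".join(rng.choice(list("ACGT"), size=11))
            cds = cds[:5] + "A" + cds[6:]
            trs[f"t{i}"] = Transcript(f"t{i}", "sp", cds)
            sites.append(EditingSite(f"t{i}", 5, 0.5, Synonymy.NONCODING))
        prof = motif_bitscore(sites, trs, k=3)
        for o in prof.offsets:
            if o != 0:
                assert prof.bits[o] < 0.08

    def test_planted_preference_matches_closed_form_entropy(self, rng):
        """+1 G drawn with probability 0.7 (others 0.1): information
        content matches 2 - H(0.7, 0.1, 0.1, 0.1)."""
        trs, sites = {}, []
        for i in range(3000):
            plus1 = rng.choice(list("GACT"), p=[0.7, 0.1, 0.1, 0.1])
            cds = "CCCCCA" + plus1 + "CCCCC"
            trs[f"t{i}"] = Transcript(f"t{i}", "sp", cds)
            sites.append(EditingSite(f"t{i}", 5, 0.5, Synonymy.NONCODING))
        prof = motif_bitscore(sites, trs, k=1)
        h = -(0.7 * np.log2(0.7) + 3 * 0.1 * np.log2(0.1))
        assert prof.bits[1] == pytest.approx(2 - h, abs=0.07)

    def test_empty_stratum_is_error(self):
        trs = {"t": Transcript("t", "sp", "CCCCCACCCCC")}
        sites = [EditingSite("t", 5, 0.1, Synonymy.NONCODING)]
        with pytest.raises(ValueError):
            motif_bitscore(sites, trs, el_range=(0.8, 1.0))

    def test_el_stratification(self):
        trs = {"t": Transcript("t", "sp", "CCCCCACCCCC")}
        sites = [
            EditingSite("t", 5, 0.1, Synonymy.NONCODING),
            EditingSite("t", 5, 0.9, Synonymy.NONCODING),
        ]
        prof = motif_bitscore(sites, trs, el_range=(0.0, 0.5))
        assert prof.n_sites == 1


class TestContextMismatchR:
    def counts(self, c_ea=5, n_ea=100, c_aa=50, n_aa=1000):
        return ContextCounts(
            ea_mismatches={+1: {("G", "C"): c_ea}, -1: {}},
            aa_mismatches={+1: {("G", "C"): c_aa}, -1: {}},
            n_ea=n_ea,
            n_aa=n_aa,
        )

    def test_worked_example_unity(self):
        est = context_mismatch_R(self.counts(), "G", "C", side=+1)
        assert est.value == pytest.approx(1.0)

    def test_equal_proportions_give_p_one(self):
        est = context_mismatch_R(self.counts(50, 1000, 50, 1000), "G", "C")
        assert est.value == pytest.approx(1.0)
        assert est.extras["p_raw"] == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_bonferroni_scaling_reported(self):
        est = context_mismatch_R(self.counts(40, 100, 50, 1000), "G", "C", m=12)
        assert est.extras["bonferroni_m"] == 12
        assert est.p_value == pytest.approx(min(1.0, 12 * est.extras["p_raw"]))

    def test_zero_total_flagged(self):
        est = context_mismatch_R(self.counts(0, 0, 0, 0), "G", "C")
        assert est.undefined

    def test_enrichment_detected_at_scale(self):
        est = context_mismatch_R(self.counts(60, 500, 50, 5000), "G", "C")
        assert est.value == pytest.approx(12.0)
        assert est.p_value < 1e-6


class TestContextCounts:
    def build_alignment(self, seq_e, seq_u, edited_col):
        enc = lambda s: np.array(
            ["ACGTE-N".index(ch) for ch in s], dtype=np.int8
        )
        st1, st2 = enc(seq_e), enc(seq_u)
        els = {"s1": np.where(st1 == 4, 0.5, np.nan)}
        aln = OrthoAlignment(
            ["s1", "s2"],
            {"s1": st1, "s2": st2},
            els,
            transcript_ids={"s1": "t1", "s2": "t2"},
        )
        trs = {
            "s1": {"t1": Transcript("t1", "s1", seq_e.replace("E", "A").replace("-", ""))},
            "s2": {"t2": Transcript("t2", "s2", seq_u.replace("E", "A").replace("-", ""))},
        }
        return aln, trs

    def test_tallies_match_brute_force_scan(self):
        # column 2: E in s1, A in s2; +1 flank G vs C mismatch; -1 flanks equal
        aln, trs = self.build_alignment("CTEGA", "CTACA", 2)
        cc = context_counts([aln], "s1", "s2", trs)
        assert cc.n_ea == 1
        assert cc.ea_mismatches[+1] == {("G", "C"): 1}
        assert cc.ea_mismatches[-1] == {}
        # column 4: A-A pair, flanks G vs C at -1
        assert cc.n_aa == 2  # symmetrized totals
        assert cc.aa_mismatches[-1] == {("G", "C"): 1, ("C", "G"): 1}

    def test_swap_invariance_after_symmetrization(self):
        aln, trs = self.build_alignment("CTEGAGA", "CTACAGA", 2)
        cc12 = context_counts([aln], "s1", "s2", trs)
        cc21 = context_counts([aln], "s2", "s1", trs)
        # E-A orientation is fixed by which species is edited; A-A tallies
        # symmetric by construction
        assert cc12.ea_mismatches == cc21.ea_mismatches
        assert cc12.aa_mismatches == cc21.aa_mismatches
        assert (cc12.n_ea, cc12.n_aa) == (cc21.n_ea, cc21.n_aa)

    def test_sum_bounded_by_totals(self, neutral_ds):
        cc = context_counts(
            neutral_ds.alignments[:40], "focal", "sister", neutral_ds.transcripts
        )
        for side in (+1, -1):
            assert sum(cc.ea_mismatches[side].values()) <= cc.n_ea
            assert sum(cc.aa_mismatches[side].values()) <= cc.n_aa


class TestWindowElCorrelation:
    def test_too_few_pairs_error(self, neutral_ds):
        with pytest.raises(ValueError):
            window_el_correlation(
                neutral_ds.alignments[:1], "focal", "sister", window_sizes=[50],
                min_pairs=10_000,
            )

    def test_zero_variance_flagged_as_nan(self):
        enc = lambda s: np.array(["ACGTE-N".index(ch) for ch in s], dtype=np.int8)
        seq = "CCEACCEACCEA"
        st = enc(seq)
        els1 = np.where(st == 4, 0.5, np.nan)
        els2 = np.where(st == 4, 0.3, np.nan)
        aln = OrthoAlignment(
            ["s1", "s2"], {"s1": st, "s2": st.copy()},
            {"s1": els1, "s2": els2},
        )
        curve, argmax = window_el_correlation([aln], "s1", "s2", window_sizes=[6])
        assert np.isnan(curve["r"].iloc[0])
        assert argmax is None

    def test_recovery_of_planted_window(self):
        from edsel.simulate import SimConfig, plant_el_context_coupling

        ds = plant_el_context_coupling(
            SimConfig(n_transcripts=120, mean_cds_len=600,
                      editing_density=0.04, seed=33),
            window=80,
        )
        curve, argmax = window_el_correlation(
            ds.alignments, "focal", "sister", window_sizes=range(20, 161, 10)
        )
        assert 60 <= argmax <= 100

    def test_permutation_null_small(self, rng):
        """Shuffling ΔEL against the mismatch counts kills the signal."""
        from edsel.simulate import SimConfig, plant_el_context_coupling

        ds = plant_el_context_coupling(
            SimConfig(n_transcripts=80, mean_cds_len=600,
                      editing_density=0.04, seed=34),
            window=80,
        )
        # jointly permute the (focal, sister) EL pairs across conserved
        # sites, detaching |ΔEL| from each site's local context
        pool = []
        for aln in ds.alignments:
            both = (aln.states["focal"] == 4) & (aln.states["sister"] == 4)
            for c in np.nonzero(both)[0]:
                pool.append((aln.els["focal"][c], aln.els["sister"][c]))
        perm = [pool[j] for j in rng.permutation(len(pool))]
        i = 0
        for aln in ds.alignments:
            both = (aln.states["focal"] == 4) & (aln.states["sister"] == 4)
            for c in np.nonzero(both)[0]:
                aln.els["focal"][c], aln.els["sister"][c] = perm[i]
                i += 1
        curve, _ = window_el_correlation(
            ds.alignments, "focal", "sister", window_sizes=range(20, 161, 20)
        )
        assert curve["r"].abs().max() < 0.2
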