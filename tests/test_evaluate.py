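"""Screening metrics: base-pair F1, simulated reactivity, concordance,
design filtering, sequence preparation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paircraft import (
    DesignRecord,
    ReactivityProfile,
    SecondaryStructure,
    filter_designs,
    parse_dotbracket,
    prepend_leader,
    reactivity_concordance,
    simulate_reactivity,
    ss_f1,
)
from paircraft.errors import ValidationError
from paircraft.evaluate import records_from_table, records_to_table

from conftest import pair_sets


class TestF1:
    def test_identical(self):
        s = {(0, 5), (1, 4)}
        assert ss_f1(s, s) == (1.0, 1.0, 1.0)

    def test_disjoint(self):
        assert ss_f1({(0, 5)}, {(1, 4)}) == (0.0, 0.0, 0.0)

    def test_hand_counted_half(self):
        p, r, f1 = ss_f1({(0, 5), (1, 4)}, {(0, 5), (2, 3)})
        assert (p, r, f1) == (0.5, 0.5, 0.5)

    def test_both_empty(self):
        assert ss_f1(set(), set()) == (1.0, 1.0, 1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(pair_sets(), pair_sets())
    def test_symmetry_and_harmonic_mean(self, a, b):
        p1, r1, f1 = ss_f1(a.pairs, b.pairs)
        p2, r2, f2 = ss_f1(b.pairs, a.pairs)
        assert f1 == pytest.approx(f2)
        assert (p1, r1) == (r2, p2)
        if p1 > 0 and r1 > 0:
            assert f1 == pytest.approx(2 * p1 * r1 / (p1 + r1))


class TestSimulateReactivity:
    def test_zero_noise_exact_means(self):
        ss = parse_dotbracket("((..))")
        prof = simulate_reactivity(ss, mu_paired=0.2, mu_unpaired=1.0, sigma=0.0, seed=0)
        assert np.allclose(prof.values[[0, 1, 4, 5]], 0.2)
        assert np.allclose(prof.values[[2, 3]], 1.0)

    def test_seed_determinism(self):
        ss = parse_dotbracket("((((....))))")
        a = simulate_reactivity(ss, seed=42)
        b = simulate_reactivity(ss, seed=42)
        assert np.array_equal(a.values, b.values)
        c = simulate_reactivity(ss, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_sample_means_within_three_standard_errors(self):
        # large structure: half paired, half unpaired
        L = 10_000
        pairs = frozenset((i, L - 1 - i) for i in range(L // 4))
        ss = SecondaryStructure(length=L, pairs=pairs)
        mu_p, mu_u, sigma = 0.2, 1.0, 0.3
        prof = simulate_reactivity(ss, mu_p, mu_u, sigma, seed=7)
        paired_idx = sorted(ss.paired_indices())
        unpaired_idx = sorted(ss.unpaired_indices())
        # log-normal with E[x] = mu, Var[x] = mu^2 (exp(sigma^2) - 1)
        for mu, idx in ((mu_p, paired_idx), (mu_u, unpaired_idx)):
            sd = mu * np.sqrt(np.exp(sigma**2) - 1.0)
            se = sd / np.sqrt(len(idx))
            assert abs(prof.values[idx].mean() - mu) < 3 * se

    def test_parameter_validation(self):
        ss = parse_dotbracket("(.)")
        with pytest.raises(ValidationError):
            simulate_reactivity(ss, mu_paired=1.0, mu_unpaired=0.5)
        with pytest.raises(ValidationError):
            simulate_reactivity(ss, sigma=-0.1)


class TestConcordance:
    def test_perfect_at_zero_noise(self):
        ss = parse_dotbracket("((((....))))")
        prof = simulate_reactivity(ss, 0.2, 1.0, sigma=0.0, seed=0)
        assert reactivity_concordance(prof, ss, threshold=0.5) == 1.0

    def test_inverted_labels(self):
        ss = parse_dotbracket("((((....))))")
        # swap the class means: paired reads high, unpaired reads low
        paired = np.zeros(ss.length, bool)
        paired[list(ss.paired_indices())] = True
        vals = np.where(paired, 1.0, 0.2)
        assert reactivity_concordance(ReactivityProfile(vals), ss, 0.5) == 0.0

    def test_hand_built_confusion_case(self):
        # 2 paired (one misread high), 4 unpaired (all read high):
        # balanced accuracy (0.5 + 1.0) / 2 = 0.75
        ss = SecondaryStructure(length=6, pairs=frozenset({(0, 5)}))
        vals = np.array([0.1, 1.0, 1.0, 1.0, 1.0, 0.9])
        assert reactivity_concordance(ReactivityProfile(vals), ss, 0.5) == 0.75

    def test_degenerate_all_unpaired(self):
        ss = SecondaryStructure(length=4)
        prof = ReactivityProfile(np.array([1.0, 1.0, 0.1, 1.0]))
        assert reactivity_concordance(prof, ss, 0.5) == 0.75

    def test_noise_degrades_concordance(self):
        ss = parse_dotbracket("((((((....))))))" * 4)
        scores = []
        for sigma in (0.0, 0.6, 1.8):
            ensemble = [
                reactivity_concordance(
                    simulate_reactivity(ss, 0.2, 1.0, sigma, seed=s), ss, 0.5
                )
                for s in range(30)
            ]
            scores.append(np.mean(ensemble))
        assert scores[0] == 1.0
        assert scores[0] > scores[1] > scores[2]

    def test_length_mismatch(self):
        ss = parse_dotbracket("(.)")
        with pytest.raises(ValidationError, match="length"):
            reactivity_concordance(ReactivityProfile(np.ones(5)), ss, 0.5)


def test_profile_io_roundtrip(tmp_path):
    prof = ReactivityProfile(np.array([0.1, 2.5, 0.0]))
    path = tmp_path / "profile.tsv"
    prof.to_file(path)
    back = ReactivityProfile.from_file(path)
    assert np.allclose(back.values, prof.values)


class TestFilterDesigns:
    def rec(self, plddt=0.9, bb=2.0, aa=3.0, design_id="d"):
        return DesignRecord(
            design_id=design_id, plddt=plddt, backbone_rmsd=bb, allatom_rmsd=aa
        )

    def test_default_thresholds_keep_good_record(self):
        assert filter_designs([self.rec()]) == [self.rec()]

    def test_boundary_plddt_rejected(self):
        # strict inequality: confidence exactly at the bound fails
        assert filter_designs([self.rec(plddt=0.87)]) == []

    def test_boundary_rmsd_rejected(self):
        assert filter_designs([self.rec(bb=2.2)]) == []
        assert filter_designs([self.rec(aa=3.5)]) == []

    def test_empty_input(self):
        assert filter_designs([]) == []

    def test_no_bounds_is_identity(self):
        recs = [self.rec(plddt=0.1, bb=9.0, aa=9.0), self.rec()]
        assert filter_designs(recs, {}) == recs

    def test_anti_monotone_in_bounds(self):
        rng = np.random.default_rng(0)
        recs = [
            self.rec(
                plddt=float(rng.uniform(0.5, 1.0)),
                bb=float(rng.uniform(0, 5)),
                aa=float(rng.uniform(0, 6)),
                design_id=f"d{i}",
            )
            for i in range(50)
        ]
        bounds: dict = {}
        prev = len(recs)
        for extra in (("plddt", (">", 0.87)), ("backbone_rmsd", ("<", 2.2)),
                      ("allatom_rmsd", ("<", 3.5))):
            bounds[extra[0]] = extra[1]
            kept = filter_designs(recs, bounds)
            assert len(kept) <= prev
            assert [r.design_id for r in kept] == [
                r.design_id for r in recs if r in kept
            ]  # order preserved
            prev = len(kept)

    def test_missing_field_fails_only_its_bound(self):
        r = DesignRecord(design_id="x", plddt=0.95)
        assert filter_designs([r], {"plddt": (">", 0.87)}) == [r]
        assert filter_designs([r], {"backbone_rmsd": ("<", 2.2)}) == []

    def test_unknown_field(self):
        with pytest.raises(ValidationError, match="unknown filter field"):
            filter_designs([], {"banana": (">", 1.0)})

    def test_plddt_scale_normalized(self):
        assert DesignRecord(design_id="x", plddt=90.0).plddt == pytest.approx(0.9)

    def test_table_roundtrip(self, tmp_path):
        recs = [self.rec(design_id=f"d{i}", plddt=0.88 + 0.01 * i) for i in range(3)]
        path = tmp_path / "designs.tsv"
        records_to_table(recs).to_csv(path, sep="\t", index=False)
        back = records_from_table(path)
        assert [r.design_id for r in back] == ["d0", "d1", "d2"]
        assert back[1].plddt == pytest.approx(0.89)


class TestPrependLeader:
    @pytest.mark.parametrize("seq", ["AUGC", "GGAAA", "U"])
    def test_default_leader_adds_two(self, seq):
        out = prepend_leader(seq)
        assert out == "GG" + seq
        assert len(out) == len(seq) + 2

    def test_empty_leader_identity(self):
        assert prepend_leader("ACGU", leader="") == "ACGU"

    def test_no_dedup_against_existing_gg(self):
        assert prepend_leader("GGAC") == "GGGGAC"

    def test_alphabet_error(self):
        with pytest.raises(ValidationError, match="nucleotide"):
            prepend_leader("ACGX")
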