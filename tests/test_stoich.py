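import numpy as np
import pytest
from hypothesis import given, strategies as st

from metaboloq import (
    DigestionRules,
    PSMTable,
    ProteinEntry,
    complex_slope,
    effective_nop,
    stoichiometry_ratio,
    synth_protein,
    synth_psm_table,
    tryptic_peptides,
)
from metaboloq.stoich import EstimationError, SequenceError
from metaboloq.synth import make_synthetic_proteome


class TestTrypticPeptides:
    def test_two_clean_sites(self):
        assert tryptic_peptides("AAAAAAKAAAAAAAR") == ["AAAAAAK", "AAAAAAAR"]

    def test_proline_suppresses_cleavage(self):
        assert tryptic_peptides("AAAAAAKPAAAAAAR") == ["AAAAAAKPAAAAAAR"]

    def test_proline_rule_can_be_disabled(self):
        rules = DigestionRules(suppress_proline=False)
        assert tryptic_peptides("AAAAAAKPAAAAAAR", rules) == \
            ["AAAAAAK", "PAAAAAAR"]

    def test_empty_sequence(self):
        assert tryptic_peptides("") == []

    def test_length_window_filters(self):
        # the central fragment 'AAK' (3 residues) is below min_length
        assert tryptic_peptides("AAAAAAKAAKAAAAAAR") == ["AAAAAAK", "AAAAAAR"]

    def test_missed_cleavages_enumerated(self):
        rules = DigestionRules(missed_cleavages=1)
        peps = tryptic_peptides("AAAAAAKAAAAAAAR", rules)
        # hand enumeration: both fully cleaved peptides plus the 1-missed span
        assert sorted(peps) == sorted(
            ["AAAAAAK", "AAAAAAAR", "AAAAAAKAAAAAAAR"])

    def test_repeated_peptides_counted_separately(self):
        assert tryptic_peptides("AAAAAAKAAAAAAK") == ["AAAAAAK", "AAAAAAK"]

    def test_invalid_character_names_position(self):
        with pytest.raises(SequenceError, match="position 3"):
            tryptic_peptides("AAAXAA")

    @given(tail=st.text(alphabet="ACDE", min_size=0, max_size=6))
    def test_nop_invariant_under_short_tail(self, tail):
        base = "AAAAAAKAAAAAAAR"
        assert len(tryptic_peptides(base + tail)) == len(tryptic_peptides(base))


class TestEffectiveNop:
    def test_identity_response_factor(self):
        p = ProteinEntry("P", "AAAAAAKAAAAAAAR", "C")
        assert effective_nop(p) == 2.0

    def test_response_factor_scales(self):
        p = ProteinEntry("P", "AAAAAAKAAAAAAAR", "C", response_factor=0.5)
        assert effective_nop(p) == 1.0

    def test_generator_round_trip(self):
        p = synth_protein(8, "P", seed=0, complex_label="C")
        assert effective_nop(p) == 8.0


def _grid_refine_slope(nop, psm, lo=0, hi=10**4, iters=120):
    """Brute-force 1-D minimizer of sum (psm - b*nop)^2 by interval thirds.

    Exact rational arithmetic: float comparisons near a quadratic minimum
    stall at the sqrt(machine-epsilon) noise floor, rationals do not.
    """
    from fractions import Fraction

    nop = [Fraction(x) for x in nop]
    psm = [Fraction(x) for x in psm]
    lo, hi = Fraction(lo), Fraction(hi)

    def rss(b):
        return sum((p - b * n) ** 2 for p, n in zip(psm, nop))

    for _ in range(iters):
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        if rss(m1) <= rss(m2):
            hi = m2
        else:
            lo = m1
    return float((lo + hi) / 2)


def _table(pairs):
    return PSMTable({pid: c for pid, c in pairs})


def _proteins(spec):
    """spec: list of (id, nop, complex)."""
    return [synth_protein(nop, pid, seed=i, complex_label=cx)
            for i, (pid, nop, cx) in enumerate(spec)]


class TestComplexSlope:
    def test_exact_proportionality(self):
        proteins = _proteins([("P1", 2, "C"), ("P2", 5, "C"), ("P3", 10, "C")])
        fit = complex_slope(_table([("P1", 6), ("P2", 15), ("P3", 30)]),
                            proteins, "C")
        assert fit.slope == pytest.approx(3.0)
        assert all(abs(r) < 1e-9 for r in fit.residuals.values())

    def test_single_zero_count_protein(self):
        proteins = _proteins([("P1", 4, "C")])
        fit = complex_slope(_table([("P1", 0)]), proteins, "C")
        assert fit.slope == 0.0

    def test_matches_brute_force_minimizer(self):
        proteins = _proteins([("P1", 3, "C"), ("P2", 11, "C"), ("P3", 27, "C"),
                              ("P4", 8, "C")])
        table = _table([("P1", 14), ("P2", 41), ("P3", 99), ("P4", 35)])
        fit = complex_slope(table, proteins, "C")
        brute = _grid_refine_slope([3, 11, 27, 8], [14, 41, 99, 35], hi=100.0)
        assert fit.slope == pytest.approx(brute, rel=1e-9)

    def test_poisson_simulation_recovers_generating_slope(self):
        depth = 1e4
        proteome = make_synthetic_proteome({"C": 1.0}, proteins_per_complex=5,
                                           depth=depth, seed=3)
        table, truth = synth_psm_table(proteome)
        fit = complex_slope(table, proteome.proteins, "C")
        total_nop = sum(effective_nop(p) for p in proteome.proteins)
        generating = depth / total_nop
        assert fit.slope == pytest.approx(generating, rel=0.10)

    def test_no_usable_proteins_raises(self):
        proteins = _proteins([("P1", 4, "C")])
        with pytest.raises(EstimationError, match="no usable proteins"):
            complex_slope(_table([("P1", 5)]), proteins, "other")

    def test_orphan_psm_row_warned_and_skipped(self):
        proteins = _proteins([("P1", 4, "C")])
        with pytest.warns(UserWarning, match="ghost"):
            fit = complex_slope(_table([("P1", 8), ("ghost", 3)]), proteins, "C")
        assert fit.n_proteins == 1


class TestStoichiometryRatio:
    def test_exact_slopes_give_exact_ratio(self):
        proteins = _proteins([("A1", 2, "A"), ("A2", 4, "A"),
                              ("B1", 2, "B"), ("B2", 4, "B")])
        table = _table([("A1", 20), ("A2", 40), ("B1", 40), ("B2", 80)])
        res = stoichiometry_ratio(table, proteins, "A", "B", n_boot=100, seed=0)
        assert res.ratio == pytest.approx(0.5)
        assert not res.undefined

    def test_relabelled_data_gives_unit_ratio(self):
        proteins = _proteins([("A1", 3, "A"), ("A2", 9, "A"),
                              ("B1", 3, "B"), ("B2", 9, "B")])
        table = _table([("A1", 12), ("A2", 31), ("B1", 12), ("B2", 31)])
        res = stoichiometry_ratio(table, proteins, "A", "B", n_boot=500, seed=1)
        assert res.ratio == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_point_estimates_are_reciprocal(self):
        proteins = _proteins([("A1", 3, "A"), ("A2", 7, "A"),
                              ("B1", 5, "B"), ("B2", 11, "B")])
        table = _table([("A1", 10), ("A2", 25), ("B1", 30), ("B2", 61)])
        ab = stoichiometry_ratio(table, proteins, "A", "B", n_boot=10, seed=0)
        ba = stoichiometry_ratio(table, proteins, "B", "A", n_boot=10, seed=0)
        assert ab.ratio * ba.ratio == pytest.approx(1.0, rel=1e-12)

    def test_zero_denominator_flagged_not_raised(self):
        proteins = _proteins([("A1", 3, "A"), ("B1", 5, "B")])
        table = _table([("A1", 10), ("B1", 0)])
        res = stoichiometry_ratio(table, proteins, "A", "B", n_boot=10, seed=0)
        assert res.undefined and res.ratio is None

    def test_recovery_of_one_to_two_regime(self):
        """Short recovery check at the generating 1:2 molar regime."""
        errors = []
        for seed in range(5):
            proteome = make_synthetic_proteome({"ETF": 1.0, "CIII": 2.0},
                                               proteins_per_complex=4,
                                               depth=1e4, seed=seed)
            table, _ = synth_psm_table(proteome)
            res = stoichiometry_ratio(table, proteome.proteins, "ETF", "CIII",
                                      n_boot=200, seed=seed)
            errors.append(abs(res.ratio - 0.5) / 0.5)
        assert np.median(errors) <= 0.10
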