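import numpy as np
import pytest
from hypothesis import given, strategies as st

from neqpka.constants import GAS_CONSTANT, rt_ln10
from neqpka.coupling import (
    CoupledDyad,
    apparent_pka,
    conditional_pka,
    dyad_titration,
    hh_curve,
    hh_fit,
    interaction_energy,
    protonation_fractions,
    reduce_triad,
)
from neqpka.cycle import DEFAULT_REFERENCES
from neqpka.estimators import FreeEnergyEstimate
from neqpka.cycle import ddg_from_legs, pka_from_ddg

T = 298.15
PH = np.linspace(-2.0, 16.0, 1801)


def brute_force_dyad(pk_a, pk_b, w, ph, temperature=T):
    """Independent 4-state enumeration: explicit Boltzmann sums."""
    scale = GAS_CONSTANT * temperature * np.log(10.0)
    beta = 1.0 / (GAS_CONSTANT * temperature)
    g_a = scale * (pk_a - ph)
    g_b = scale * (pk_b - ph)
    z_hh = np.exp(-beta * 0.0)
    z_hd = np.exp(-beta * g_b)
    z_dh = np.exp(-beta * g_a)
    z_dd = np.exp(-beta * (g_a + g_b + w))
    z = z_hh + z_hd + z_dh + z_dd
    return (z_hh + z_hd) / z, (z_hh + z_dh) / z


class TestDyadTitration:
    def test_zero_coupling_reproduces_hh(self):
        curve = dyad_titration(CoupledDyad(4.0, 6.0, 0.0), PH)
        assert np.max(np.abs(curve.frac_a - hh_curve(PH, 4.0))) < 1e-12
        assert np.max(np.abs(curve.frac_b - hh_curve(PH, 6.0))) < 1e-12

    @pytest.mark.parametrize("pk_a,pk_b,w", [(4.0, 4.0, 10.0), (3.5, 5.0, 6.0), (4.2, 4.4, -3.0)])
    def test_matches_brute_force_enumeration(self, pk_a, pk_b, w):
        curve = dyad_titration(CoupledDyad(pk_a, pk_b, w), PH)
        fa, fb = brute_force_dyad(pk_a, pk_b, w, PH)
        assert np.max(np.abs(curve.frac_a - fa)) < 1e-10
        assert np.max(np.abs(curve.frac_b - fb)) < 1e-10

    def test_saturation_limits(self):
        curve = dyad_titration(CoupledDyad(4.0, 5.0, 8.0), np.linspace(-6, 20, 500))
        for frac in (curve.frac_a, curve.frac_b):
            assert frac[0] > 1 - 1e-9
            assert frac[-1] < 1e-9

    def test_repulsive_symmetric_dyad_splits_transitions(self):
        # total proton release happens in two separated steps straddling pk=4
        w = 3 * rt_ln10(T)  # 3 pK units of repulsion
        curve = dyad_titration(CoupledDyad(4.0, 4.0, w), PH)
        total = curve.frac_a + curve.frac_b
        ph_first = PH[np.argmin(np.abs(total - 1.5))]
        ph_second = PH[np.argmin(np.abs(total - 0.5))]
        assert ph_first < 4.0 < ph_second
        assert ph_second - ph_first > 2.0

    @given(
        pk_a=st.floats(2, 12),
        pk_b=st.floats(2, 12),
        w=st.floats(-15, 30),
    )
    def test_fractions_valid_and_protons_monotone(self, pk_a, pk_b, w):
        curve = dyad_titration(CoupledDyad(pk_a, pk_b, w), PH)
        for frac in (curve.frac_a, curve.frac_b):
            assert np.all(frac >= 0) and np.all(frac <= 1)
        total = curve.frac_a + curve.frac_b
        assert np.all(np.diff(total) <= 1e-12)

    def test_normalization_exact(self):
        # marginal of "A protonated" plus "A deprotonated" must be exactly 1
        d = CoupledDyad(4.0, 5.0, 40.0)
        fa, fb = protonation_fractions(d, PH)
        scale = rt_ln10(T)
        beta = 1.0 / (GAS_CONSTANT * T)
        g_a = scale * (4.0 - PH)
        g_b = scale * (5.0 - PH)
        g = np.stack([np.zeros_like(PH), g_b, g_a, g_a + g_b + 40.0])
        g -= g.min(axis=0)
        wts = np.exp(-beta * g)
        total = wts.sum(axis=0)
        deprot_a = (wts[2] + wts[3]) / total
        assert np.max(np.abs(fa + deprot_a - 1.0)) < 1e-12


class TestApparentPka:
    def test_one_site_hh_definition(self):
        curve = dyad_titration(CoupledDyad(4.0, 20.0, 0.0), np.linspace(0, 10, 1001))
        assert apparent_pka(curve, "a") == pytest.approx(4.0, abs=1e-6)

    def test_decoupled_dyad_apparent_equals_intrinsic(self):
        curve = dyad_titration(CoupledDyad(4.0, 6.0, 0.0), np.linspace(0, 14, 1401))
        assert apparent_pka(curve, "a") == pytest.approx(4.0, abs=1e-6)
        assert apparent_pka(curve, "b") == pytest.approx(6.0, abs=1e-6)

    def test_repulsive_coupling_raises_second_site(self):
        # with B titrating below A, repulsion pushes A's half-point above intrinsic
        grid = np.linspace(0, 14, 1401)
        coupled = dyad_titration(CoupledDyad(5.0, 4.0, 2 * rt_ln10(T)), grid)
        assert apparent_pka(coupled, "a") > 5.0 + 0.5

    def test_no_crossing_errors(self):
        curve = dyad_titration(CoupledDyad(4.0, 5.0, 0.0), np.linspace(8, 10, 50))
        with pytest.raises(ValueError, match="widen"):
            apparent_pka(curve, "a")


class TestReduceTriad:
    def test_decoupled_reduction(self):
        fixed, dyad = reduce_triad(
            [("s1", 3.0), ("s2", 4.0), ("s3", 5.0)],
            {("s1", "s2"): 0.0, ("s1", "s3"): 0.0, ("s2", "s3"): 0.0},
        )
        assert fixed == "s1"
        assert (dyad.pk_a, dyad.pk_b, dyad.w) == (4.0, 5.0, 0.0)

    def test_coupling_to_fixed_site_shifts_by_one_pk(self):
        w = rt_ln10(T)
        fixed, dyad = reduce_triad(
            [("s1", 3.0), ("s2", 4.0), ("s3", 5.0)],
            {("s1", "s2"): w, ("s1", "s3"): w, ("s2", "s3"): 1.5},
        )
        assert fixed == "s1"
        assert dyad.pk_a == pytest.approx(5.0)
        assert dyad.pk_b == pytest.approx(6.0)
        assert dyad.w == 1.5

    def test_permutation_invariant(self):
        sites = [("x", 4.5), ("y", 3.1), ("z", 6.0)]
        couplings = {("x", "y"): 1.0, ("y", "z"): 2.0, ("x", "z"): 3.0}
        a = reduce_triad(sites, couplings)
        b = reduce_triad(sites[::-1], couplings)
        assert a[0] == b[0]
        assert (a[1].pk_a, a[1].pk_b, a[1].w) == pytest.approx((b[1].pk_a, b[1].pk_b, b[1].w))

    def test_tie_is_explicit_error(self):
        with pytest.raises(ValueError, match="tie"):
            reduce_triad(
                [("s1", 4.0), ("s2", 4.0), ("s3", 5.0)],
                {("s1", "s2"): 0.0, ("s1", "s3"): 0.0, ("s2", "s3"): 0.0},
            )

    def test_conditional_marginals_match_eight_state_enumeration(self):
        # fixing the first-deprotonating site and titrating the rest must equal
        # the full 8-state model conditioned on that site being deprotonated
        sites = [("s1", 2.5), ("s2", 4.2), ("s3", 5.1)]
        couplings = {("s1", "s2"): 2.0, ("s1", "s3"): 4.0, ("s2", "s3"): 3.0}
        fixed, dyad = reduce_triad(sites, couplings)
        assert fixed == "s1"
        ph = np.linspace(0, 14, 701)
        curve = dyad_titration(dyad, ph)

        beta = 1.0 / (GAS_CONSTANT * T)
        scale = rt_ln10(T)
        pks = dict(sites)
        cmap = {frozenset(k): v for k, v in couplings.items()}
        ids = ["s1", "s2", "s3"]
        za = np.zeros_like(ph)
        zb = np.zeros_like(ph)
        z = np.zeros_like(ph)
        for state in range(8):  # bit i set = site i deprotonated
            bits = [(state >> i) & 1 for i in range(3)]
            if not bits[0]:
                continue  # condition on s1 deprotonated
            g = sum(bits[i] * scale * (pks[ids[i]] - ph) for i in range(3))
            for i in range(3):
                for j in range(i + 1, 3):
                    if bits[i] and bits[j]:
                        g = g + cmap[frozenset((ids[i], ids[j]))]
            wgt = np.exp(-beta * g)
            z += wgt
            if not bits[1]:
                za += wgt
            if not bits[2]:
                zb += wgt
        assert np.max(np.abs(curve.frac_a - za / z)) < 1e-10
        assert np.max(np.abs(curve.frac_b - zb / z)) < 1e-10


class TestHhFit:
    def test_noiseless_recovery(self):
        ph = np.linspace(1, 8, 40)
        pka, rss = hh_fit(ph, hh_curve(ph, 4.0))
        assert pka == pytest.approx(4.0, abs=1e-6)
        assert rss < 1e-12

    def test_noisy_recovery_seeded(self):
        rng = np.random.default_rng(21)
        ph = np.linspace(1, 8, 50)
        frac = np.clip(hh_curve(ph, 4.3) + rng.normal(0, 0.02, ph.size), 0, 1)
        pka, _ = hh_fit(ph, frac)
        assert abs(pka - 4.3) < 0.05

    def test_half_protonation_at_fitted_pka(self):
        ph = np.linspace(2, 7, 30)
        pka, _ = hh_fit(ph, hh_curve(ph, 4.1))
        assert hh_curve(np.array([pka]), pka)[0] == pytest.approx(0.5)

    def test_flat_curve_errors(self):
        with pytest.raises(ValueError, match="no titration"):
            hh_fit([3.0, 4.0, 5.0], [0.5, 0.5, 0.5])


class TestConditionalPka:
    @staticmethod
    def cycle(ddg):
        leg = FreeEnergyEstimate(ddg, 0.0, 5, 5, "BAR")
        ref_leg = FreeEnergyEstimate(0.0, 0.0, 5, 5, "BAR")
        return ddg_from_legs(leg, ref_leg, T)

    def test_same_number_different_kind(self):
        cyc = self.cycle(2.0)
        std = pka_from_ddg(cyc, DEFAULT_REFERENCES["ASP"])
        cond = conditional_pka(cyc, DEFAULT_REFERENCES["ASP"], "HIS+ neighbor")
        assert cond.pka == std.pka
        assert cond.kind == "conditional"

    def test_condition_string_propagates_verbatim(self):
        cond = conditional_pka(self.cycle(0.0), DEFAULT_REFERENCES["GLU"], "HIS42 doubly protonated")
        assert cond.condition == "HIS42 doubly protonated"

    def test_empty_condition_errors(self):
        with pytest.raises(ValueError, match="condition"):
            conditional_pka(self.cycle(0.0), DEFAULT_REFERENCES["GLU"], "")


def test_interaction_energy_second_difference():
    # w = dG(deprot A | B deprot) - dG(deprot A | B prot)
    assert interaction_energy(10.0, 13.5) == pytest.approx(3.5)
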