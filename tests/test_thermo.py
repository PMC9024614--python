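"""Redox thermodynamics: DeltaG = -nF DeltaE and the weighted cycle sum."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aomflux import confurcation_delta_g, default_couples, delta_g, redox_cycle_delta_g
from aomflux.model import ModelError
from aomflux.thermo import (
    FARADAY_KJ_PER_MV,
    DeltaGTable,
    RedoxCouple,
    couples_from_tsv,
    couples_to_tsv,
)

couple_st = st.builds(
    RedoxCouple,
    name=st.sampled_from(["A", "B", "C"]),
    e0_prime_mv=st.floats(-800, 800, allow_nan=False),
)


class TestDeltaG:
    def test_f420_to_menaquinone_pair(self):
        c = default_couples()
        assert delta_g(2, c["F420"], c["MQ"]) == pytest.approx(-57.888, abs=1e-9)

    def test_same_couple_zero(self):
        c = default_couples()
        assert delta_g(2, c["F420"], c["F420"]) == 0.0

    def test_f420_to_ferredoxin_uphill(self):
        c = default_couples()
        assert delta_g(2, c["F420"], c["Fd"]) == pytest.approx(+27.0144, abs=1e-6)

    def test_n_below_one_rejected(self):
        c = default_couples()
        with pytest.raises(ModelError, match="n must be"):
            delta_g(0, c["F420"], c["MQ"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(1, 8), donor=couple_st, acceptor=couple_st)
    def test_antisymmetry(self, n, donor, acceptor):
        assert delta_g(n, donor, acceptor) == pytest.approx(
            -delta_g(n, acceptor, donor), abs=1e-9
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(1, 8), a=couple_st, b=couple_st, c=couple_st)
    def test_additivity_of_two_step_transfer(self, n, a, b, c):
        assert delta_g(n, a, b) + delta_g(n, b, c) == pytest.approx(
            delta_g(n, a, c), abs=1e-9
        )


class TestDefaultCouples:
    def test_printed_midpoint_potentials(self):
        c = default_couples()
        assert c["Fd"].e0_prime_mv == -520
        assert c["CoM/CoB"].e0_prime_mv == -143
        assert c["F420"].e0_prime_mv == -380
        assert c["MQ"].e0_prime_mv == -80
        assert c["MPh"].e0_prime_mv == -165

    def test_nitrate_couple_flagged_as_package_adopted(self):
        c = default_couples()
        assert c["NO3/NO2"].e0_prime_mv == 433
        assert c["NO3/NO2"].source == "package-adopted"

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "couples.tsv"
        couples_to_tsv(default_couples(), str(path))
        back = couples_from_tsv(str(path))
        assert {c.name: c.e0_prime_mv for c in back.values()} == {
            c.name: c.e0_prime_mv for c in default_couples().values()
        }


class TestConfurcation:
    def test_positive_at_printed_potentials(self):
        # thiols->F420 (+45.732) plus Fd->F420 (-27.014)
        assert confurcation_delta_g() == pytest.approx(+18.71712, abs=1e-6)

    def test_zero_when_all_potentials_equal(self):
        flat = {name: RedoxCouple(name, -200.0) for name in ("CoM/CoB", "Fd", "F420")}
        assert confurcation_delta_g(flat) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_donor_potential(self):
        base = default_couples()
        lowered = dict(base)
        lowered["Fd"] = RedoxCouple("Fd", -700.0)
        assert confurcation_delta_g(lowered) < confurcation_delta_g(base)

    def test_missing_couple_named(self):
        with pytest.raises(ModelError, match="Fd"):
            confurcation_delta_g({"CoM/CoB": RedoxCouple("CoM/CoB", -143.0)})


class TestRedoxCycle:
    CYCLE = ("Mcr", "Mtr", "HdrDE", "HdrABC", "Fqo", "Nar")

    def table(self, values):
        t = DeltaGTable()
        for rid in self.CYCLE:
            t.set(rid, values.get(rid, 0.0))
        return t

    def test_all_zero_table_gives_zero(self):
        assert redox_cycle_delta_g(self.table({})) == 0.0

    def test_single_unweighted_term(self):
        assert redox_cycle_delta_g(self.table({"Mcr": 1.1})) == pytest.approx(1.1)

    def test_term_by_term_hand_summation(self):
        """Cycle sum with computed Fqo/Nar terms matches the by-hand total."""
        c = default_couples()
        t = DeltaGTable()
        t.set("Mcr", 30.0)  # user-supplied endergonic activation steps
        t.set("Mtr", 30.0)
        t.set_computed("HdrDE", 2, c["CoM/CoB"], c["MQ"])
        t.set("HdrABC", confurcation_delta_g(c), provenance="computed")
        t.set_computed("Fqo", 2, c["F420"], c["MQ"])
        t.set_computed("Nar", 2, c["MQ"], c["NO3/NO2"])
        w_de, w_abc = 0.183 / 1.1, 0.917 / 1.1
        by_hand = (
            30.0 + 30.0
            + w_de * (-2 * FARADAY_KJ_PER_MV * (-80 - -143) + -2 * FARADAY_KJ_PER_MV * (433 - -80))
            + w_abc * (
                18.71712
                + -2 * FARADAY_KJ_PER_MV * (-80 - -380)
                + -2 * FARADAY_KJ_PER_MV * (433 - -80)
            )
        )
        assert redox_cycle_delta_g(t, w_de, w_abc) == pytest.approx(by_hand, abs=1e-9)

    def test_default_weights_are_reference_flux_shares(self):
        t = self.table({"HdrDE": 1.0, "HdrABC": 1.0})
        expected = (0.183 / 1.1) * 1.0 + (0.917 / 1.1) * 1.0
        assert redox_cycle_delta_g(t) == pytest.approx(expected, abs=1e-12)

    def test_missing_entry_named(self):
        t = self.table({})
        t2 = DeltaGTable()
        for rid in self.CYCLE:
            if rid != "Fqo":
                t2.set(rid, t[rid])
        with pytest.raises(ModelError, match="Fqo"):
            redox_cycle_delta_g(t2)


class TestSignChecks:
    """Directional sanity of the electron-transport steps at standard potentials."""

    def test_confurcation_uphill(self):
        assert confurcation_delta_g() > 0

    def test_f420h2_to_ferredoxin_uphill(self):
        c = default_couples()
        assert delta_g(2, c["F420"], c["Fd"]) > 0

    def test_fqo_and_nar_downhill(self):
        c = default_couples()
        assert delta_g(2, c["F420"], c["MQ"]) < 0
        assert delta_g(2, c["MQ"], c["NO3/NO2"]) < 0


class TestDeltaGTableIO:
    def test_tsv_round_trip_with_provenance(self, tmp_path):
        t = DeltaGTable()
        t.set("Mcr", 30.0)
        c = default_couples()
        t.set_computed("Fqo", 2, c["F420"], c["MQ"])
        path = tmp_path / "dg.tsv"
        t.to_tsv(str(path))
        back = DeltaGTable.from_tsv(str(path))
        assert back["Mcr"] == pytest.approx(30.0)
        assert back["Fqo"] == pytest.approx(-57.888)
        assert back.provenance("Fqo") == "computed"

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ModelError, match="provenance"):
            DeltaGTable().set("Mcr", 1.0, provenance="guessed")
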