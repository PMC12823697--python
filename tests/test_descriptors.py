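"""Reactivity descriptors: printed-value reproduction and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqdsense import descriptors as d
from gqdsense.errors import DegenerateHardnessError, MissingPropertyError
from gqdsense.fixtures import REACTIVITY_TABLE, last_digit_tol
from gqdsense.records import SpeciesRecord
from gqdsense.units import round_half_away


@pytest.mark.parametrize(
    "func,args,expected",
    [
        (d.hlg, (-5.94, -2.05), 3.89),
        (d.hlg, (-4.34, -3.95), 0.39),
        (d.hlg, (-3.0, -3.0), 0.0),
        (d.hardness, (-5.26, -2.4), 1.43),
        (d.hardness, (-9.85, 0.62), 5.235),
        (d.hardness, (-3.0, -3.0), 0.0),
        (d.softness, (0.5,), 1.0),
        (d.softness, (1.94,), 0.2577),
        (d.chemical_potential, (-5.94, -2.05), -3.995),
        (d.chemical_potential, (-4.42, -3.22), -3.82),
        (d.chemical_potential, (-3.0, -3.0), -3.0),
        (d.delta_n_max, (-4.145, 0.195), 21.256),
        (d.delta_n_max, (-1.0, 1.0), 1.0),
    ],
)
def test_descriptor_point_values(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=5e-4)


def test_degenerate_hardness_rejected():
    with pytest.raises(DegenerateHardnessError):
        d.softness(0.0)
    with pytest.raises(DegenerateHardnessError):
        d.delta_n_max(-1.0, 0.0)


class TestECT:
    def test_gas_al_complex_from_unrounded_frontiers(self):
        sensor = d.delta_n_max(d.chemical_potential(-4.62, -2.53), d.hardness(-4.62, -2.53))
        complex_ = d.delta_n_max(d.chemical_potential(-4.26, -4.05), d.hardness(-4.26, -4.05))
        assert d.ect(sensor, complex_) == pytest.approx(-36.15, abs=0.01)

    def test_water_pristine_complex(self):
        sensor = d.delta_n_max(d.chemical_potential(-5.26, -2.4), d.hardness(-5.26, -2.4))
        complex_ = d.delta_n_max(d.chemical_potential(-5.3, -3.51), d.hardness(-5.3, -3.51))
        assert d.ect(sensor, complex_) == pytest.approx(-2.2435, abs=1e-3)

    def test_equal_inputs_give_zero(self):
        assert d.ect(1.5, 1.5) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            d.ect(math.nan, 1.0)


class TestResponse:
    def test_dipole_magnitude(self):
        assert d.dipole_magnitude((3, 4, 0)) == 5.0
        assert d.dipole_magnitude((0, 0, 0)) == 0.0

    def test_mean_polarizability(self):
        assert d.mean_polarizability((300, 300, 360)) == pytest.approx(320.0)
        assert d.mean_polarizability((7.5, 7.5, 7.5)) == pytest.approx(7.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=3))
    def test_dipole_matches_norm_oracle(self, xyz):
        oracle = math.sqrt(xyz[0] ** 2 + xyz[1] ** 2 + xyz[2] ** 2)
        assert d.dipole_magnitude(tuple(xyz)) == pytest.approx(oracle, abs=1e-12)

    def _rec(self, label, dip, pol):
        return SpeciesRecord(label=label, role="sensor", phase="water", functional="B97D",
                             e_homo=-5.0, e_lumo=-2.0, dipole_xyz=dip, polarizability_diag=pol)

    def test_adsorption_deltas_tabulated_direction(self):
        sensor = self._rec("Coronene", (0.0, 0.0, 0.0), (311.58,) * 3)
        complex_ = self._rec("Coronene@FA", (1.81, 0.0, 0.0), (323.86,) * 3)
        d_dip, d_pol = d.adsorption_deltas(sensor, complex_)
        assert d_dip == pytest.approx(1.81)
        assert d_pol == pytest.approx(12.28)

    def test_zn_polarizability_delta(self):
        sensor = self._rec("Zn.Coronene", (0.94, 0, 0), (344.39,) * 3)
        complex_ = self._rec("Zn.Coronene@FA", (3.62, 0, 0), (367.72,) * 3)
        assert d.adsorption_deltas(sensor, complex_)[1] == pytest.approx(23.33)

    def test_identical_records_give_zero(self):
        rec = self._rec("X", (1, 1, 1), (300,) * 3)
        assert d.adsorption_deltas(rec, rec) == (0.0, 0.0)

    def test_missing_fields_rejected(self):
        bare = SpeciesRecord(label="X", role="sensor", phase="water", functional="B97D",
                             e_homo=-5.0, e_lumo=-2.0)
        with pytest.raises(MissingPropertyError):
            d.adsorption_deltas(bare, bare)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    homo=st.floats(-12, -0.5),
    gap=st.floats(0.05, 12),
)
def test_descriptor_identities(homo, gap):
    """hlg = 2*eta; S*eta = 1/2; sign(dNmax) = -sign(mu)."""
    lumo = homo + gap
    eta = d.hardness(homo, lumo)
    assert d.hlg(homo, lumo) == pytest.approx(2 * eta, rel=1e-12)
    assert d.softness(eta) * eta == pytest.approx(0.5, rel=1e-12)
    mu = d.chemical_potential(homo, lumo)
    dn = d.delta_n_max(mu, eta)
    if mu != 0:
        assert math.copysign(1, dn) == -math.copysign(1, mu)


def _recompute_row(row):
    homo, lumo = float(row.homo), float(row.lumo)
    eta = d.hardness(homo, lumo)
    mu = d.chemical_potential(homo, lumo)
    return {
        "hlg": d.hlg(homo, lumo),
        "eta": eta,
        "s": d.softness(eta),
        "mu": mu,
        "dnmax": d.delta_n_max(mu, eta),
    }


def test_all_printed_derived_columns_recompute():
    """Every unflagged derived cell of the reactivity table matches the
    printed value within one unit of its last printed digit."""
    sensors = {}
    for row in REACTIVITY_TABLE:
        got = _recompute_row(row)
        key = (row.functional, row.phase)
        if not row.label.endswith("@FA"):
            sensors[(key, row.label)] = got["dnmax"]
        for col in ("hlg", "eta", "s", "mu", "dnmax"):
            printed = float(getattr(row, col))
            tol = last_digit_tol(getattr(row, col)) + 1e-9
            assert got[col] == pytest.approx(printed, abs=tol), (row.label, key, col)
        if row.ect is not None and "ect" not in row.flagged:
            sensor_dn = sensors[(key, row.label[: -len("@FA")])]
            recomputed = d.ect(sensor_dn, got["dnmax"])
            tol = last_digit_tol(row.ect) + 1e-9
            assert recomputed == pytest.approx(float(row.ect), abs=tol), (row.label, key)


def test_flagged_ect_cell_is_a_sign_artifact():
    """The water-phase Zn complex prints ECT=-0.02 but recomputes to +0.02."""
    rows = {r.label: r for r in REACTIVITY_TABLE if (r.functional, r.phase) == ("B97D", "water")}
    sensor = _recompute_row(rows["Zn.Coronene"])["dnmax"]
    complex_ = _recompute_row(rows["Zn.Coronene@FA"])["dnmax"]
    assert d.ect(sensor, complex_) == pytest.approx(0.022, abs=5e-3)
    assert float(rows["Zn.Coronene@FA"].ect) == -0.02


def test_reactivity_table_fills_ect_for_linked_complexes(golden):
    species = golden.species_blocks[("B97D", "gas")]
    links = golden.link_blocks[("B97D", "gas")]
    table = d.reactivity_table(species, links)
    assert list(table.columns) == ["label", "lumo", "homo", "hlg", "eta", "s", "mu", "dnmax", "ect"]
    al = table.set_index("label").loc["Al.Coronene@FA"]
    assert al.ect == pytest.approx(-36.15, abs=0.01)
    assert table.set_index("label").loc["FA"].isna()["ect"]


def test_rounding_is_half_away_from_zero():
    assert round_half_away(0.2577, 2) == 0.26
    assert round_half_away(-2.2435, 2) == -2.24
    assert round_half_away(-3.995, 2) == -4.0
    assert round_half_away(2.5, 0) == 3.0
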