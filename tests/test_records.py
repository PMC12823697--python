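"""Record model validation, interchange round-trips, geometry operators."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqdsense.errors import (
    DegenerateGeometryError,
    LinkageError,
    ParseError,
    RecordValidationError,
)
from gqdsense.records import (
    BCPRecord,
    ComplexLink,
    ExcitationLine,
    SpeciesRecord,
    TaggedEnergy,
    VibLine,
    bond_angle,
    bond_length,
    read_records,
    validate_minimum,
    write_records,
)

MINIMAL = {
    "species": [
        {"label": "Coronene", "role": "sensor", "phase": "water",
         "functional": "B97D", "e_homo": -5.26, "e_lumo": -2.4},
    ]
}


class TestReadRecords:
    def test_minimal_stream(self):
        species, links = read_records(MINIMAL)
        assert len(species) == 1 and not links
        assert species[0].e_homo == -5.26 and species[0].e_lumo == -2.4

    def test_empty_stream(self):
        assert read_records(io.StringIO("")) == ([], [])

    def test_inverted_frontier_rejected(self):
        bad = {"species": [dict(MINIMAL["species"][0], e_homo=-3.0, e_lumo=-4.0)]}
        with pytest.raises(RecordValidationError, match="e_homo"):
            read_records(bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_records({"species": MINIMAL["species"] * 2})

    def test_schema_violation_names_field_and_record(self):
        bad = {"species": [dict(MINIMAL["species"][0], phase="plasma")]}
        with pytest.raises(ParseError, match="Coronene"):
            read_records(bad)

    def test_dangling_link_rejected(self):
        doc = dict(MINIMAL)
        doc["complexes"] = [{"complex_label": "X", "host_label": "Coronene",
                             "guest_label": "FA", "bsse": {"value": 0.002, "unit": "hartree"}}]
        with pytest.raises(LinkageError, match="unresolved"):
            read_records(doc)

    def test_link_phase_mismatch_rejected(self):
        sp = MINIMAL["species"][0]
        doc = {
            "species": [sp,
                        dict(sp, label="FA", role="analyte", phase="gas"),
                        dict(sp, label="Coronene@FA", role="complex")],
            "complexes": [{"complex_label": "Coronene@FA", "host_label": "Coronene",
                           "guest_label": "FA", "bsse": {"value": 0.002, "unit": "hartree"}}],
        }
        with pytest.raises(LinkageError, match="mix"):
            read_records(doc)


def test_roundtrip_preserves_all_fields(synthetic_set):
    text = write_records(synthetic_set.species, synthetic_set.links)
    species, links = read_records(io.StringIO(text))
    assert species == synthetic_set.species
    assert links == synthetic_set.links


def test_golden_fixtures_validate(golden):
    """Every bundled table row loads into a validated record without error."""
    n = sum(len(block) for block in golden.species_blocks.values())
    assert n == 21  # 7 systems x 3 method blocks
    assert all(len(links) == 3 for links in golden.link_blocks.values())


def test_excitation_consistency_is_soft():
    line = ExcitationLine(lambda_nm=357.0, e_ex=3.30, f_osc=0.045)
    assert not line.energy_consistent(tol=0.03)
    assert line.energy_consistent(tol=0.2)


def test_physical_bcp_sign_enforcement():
    BCPRecord(rho=0.05, lap_rho=-0.06, v_r=-0.02, g_r=0.03, convention="physical")
    with pytest.raises(Exception):
        BCPRecord(rho=0.05, lap_rho=-0.06, v_r=0.02, g_r=-0.03, convention="physical")
    # printed convention accepts the tabulated (unphysical) sign pattern verbatim
    BCPRecord(rho=0.05, lap_rho=-0.06, v_r=0.0657, g_r=0.0061)


class TestGeometry:
    def test_axis_aligned_bond(self):
        assert bond_length((0, 0, 0), (0, 0, 1.43)) == pytest.approx(1.43)

    def test_identical_points(self):
        assert bond_length((1, 2, 3), (1, 2, 3)) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_length_matches_bruteforce_and_is_symmetric(self, xs):
        p, q = xs[:3], xs[3:]
        oracle = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        assert bond_length(p, q) == pytest.approx(oracle, abs=1e-12)
        assert bond_length(q, p) == bond_length(p, q)

    def test_collinear_is_180(self):
        assert bond_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_zero_arm_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            bond_angle((0, 0, 0), (0, 0, 0), (1, 1, 1))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_angle_matches_law_of_cosines(self, seed):
        rng = np.random.default_rng(seed)
        p1, v, p3 = rng.uniform(-5, 5, (3, 3))
        a = np.linalg.norm(p1 - v)
        b = np.linalg.norm(p3 - v)
        c = np.linalg.norm(p1 - p3)
        if a < 1e-6 or b < 1e-6:
            return
        cosg = np.clip((a * a + b * b - c * c) / (2 * a * b), -1, 1)
        assert bond_angle(p1, v, p3) == pytest.approx(math.degrees(math.acos(cosg)), abs=1e-9)


class TestValidateMinimum:
    def test_all_real_modes(self):
        modes = [VibLine(freq_cm1=f, intensity=1.0) for f in (120.0, 1600.0, 3050.0)]
        assert validate_minimum(modes) is True

    def test_imaginary_mode_detected(self):
        modes = [VibLine(freq_cm1=-45.0, intensity=0.0), VibLine(freq_cm1=1600.0, intensity=1.0)]
        assert validate_minimum(modes) is False

    def test_empty_list_rejected(self):
        with pytest.raises(RecordValidationError):
            validate_minimum([])
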