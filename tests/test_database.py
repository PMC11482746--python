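import math

import numpy as np
import pytest

import medoc as m
from medoc.database import DEPROTONATED, PROTONATED, site_delta_tables
from medoc.errors import DatabaseError
from medoc.thermo import LN10


def test_isolated_site_is_intrinsic_only(zero_db, thermo):
    rec = m.parse_sequence("s", "GGEGG")
    g = m.delta_E(zero_db, rec, 0, [])
    assert g == pytest.approx(thermo.pka_to_energy(4.34), rel=1e-12)


def test_zero_pair_terms_make_delta_e_context_free(flat_db):
    rec = m.parse_sequence("s", "EEE")
    vals = {m.delta_E(flat_db, rec, 2, [a, b]) for a in (0, 1) for b in (0, 1)}
    assert len(vals) == 1


def test_delta_e_finite_difference_matches_pair_terms(coupled_db):
    """On 'EE', toggling the left neighbor's state changes delta_E by exactly
    the difference of the corresponding pair terms."""
    rec = m.parse_sequence("s", "EE")
    diff = m.delta_E(coupled_db, rec, 1, [1]) - m.delta_E(coupled_db, rec, 1, [0])
    scale = coupled_db.rescale_for("E")[1]
    expected = scale * (
        coupled_db.pair("E", "E", DEPROTONATED, -1) - coupled_db.pair("E", "E", PROTONATED, -1)
    )
    assert diff == pytest.approx(expected, rel=1e-12)


def test_microstate_free_energy_reference_and_path(coupled_db):
    rec = m.parse_sequence("s", "EE")
    assert m.microstate_free_energy(coupled_db, rec, [0, 0]) == 0.0
    # single deprotonation: that site's delta_E with an all-protonated left context
    assert m.microstate_free_energy(coupled_db, rec, [0, 1]) == pytest.approx(
        m.delta_E(coupled_db, rec, 1, [0])
    )
    # doubly deprotonated EE: sum of the ee->Ee and Ee->EE transitions
    expected = m.delta_E(coupled_db, rec, 0, []) + m.delta_E(coupled_db, rec, 1, [1])
    assert m.microstate_free_energy(coupled_db, rec, [1, 1]) == pytest.approx(expected)


def test_missing_pair_term_names_the_key(coupled_db):
    db = m.ContextDatabase(
        window=1,
        intrinsic=dict(coupled_db.intrinsic),
        pair_terms={},
        config=coupled_db.config,
    )
    rec = m.parse_sequence("s", "GE")
    with pytest.raises(DatabaseError, match=r"central='E'.*neighbor='G'.*offset=-1"):
        m.delta_E(db, rec, 0, [])


def test_delta_e_window_locality(coupled_db):
    """Toggling the state of a left site beyond the window is bit-neutral."""
    rec = m.parse_sequence("s", "E" + "G" * (coupled_db.window + 1) + "E")
    a = m.delta_E(coupled_db, rec, 1, [0])
    b = m.delta_E(coupled_db, rec, 1, [1])
    assert a == b


def test_zero_coupling_free_energy_is_separable(flat_db, thermo):
    rec = m.parse_sequence("s", "DEKH")
    states = [1, 0, 1, 1]
    expected = sum(
        flat_db.intrinsic[s.residue_type] for s, x in zip(rec.sites, states) if x
    )
    assert m.microstate_free_energy(flat_db, rec, states) == pytest.approx(expected, rel=1e-12)


def test_zero_coupling_path_is_order_independent(flat_db):
    """Deprotonating in reverse (C-to-N) order with re-derived deltas gives the
    same microstate free energy when couplings vanish."""
    rec = m.parse_sequence("s", "EKDE")
    states = [1, 1, 0, 1]
    forward = m.microstate_free_energy(flat_db, rec, states)
    reverse = 0.0
    for i in reversed(range(rec.n_sites)):
        if states[i]:
            # in the reverse path every *left* neighbor is still protonated
            reverse += m.delta_E(flat_db, rec, i, [0] * i)
    assert reverse == pytest.approx(forward, rel=1e-12)


class TestSyntheticGenerator:
    def test_deterministic_given_seed(self):
        a = m.generate_synthetic_db(window=2, seed=42)
        b = m.generate_synthetic_db(window=2, seed=42)
        assert a.intrinsic == b.intrinsic
        assert a.pair_terms == b.pair_terms

    def test_zero_coupling_zeroes_charged_pair_terms(self):
        db = m.generate_synthetic_db(window=2, coupling_strength=0.0, seed=1)
        assert db.pair("E", "E", DEPROTONATED, -1) == 0.0
        assert db.pair("E", "K", PROTONATED, 1) == 0.0
        assert db.pair("E", "R", PROTONATED, -2) == 0.0

    def test_sign_rules(self):
        db = m.generate_synthetic_db(window=2, seed=1)
        # like-charge neighbor disfavors deprotonation, opposite charge favors it
        assert db.pair("E", "E", DEPROTONATED, -1) > 0
        assert db.pair("E", "K", PROTONATED, -1) < 0
        assert db.pair("K", "K", PROTONATED, -1) < 0  # removing +1 next to +1
        assert db.pair("E", "R", PROTONATED, 1) < 0  # fixed +1 charge
        # screening decays with distance
        assert db.pair("E", "E", DEPROTONATED, -2) < db.pair("E", "E", DEPROTONATED, -1)

    def test_intrinsic_terms_are_model_pkas(self, thermo):
        db = m.generate_synthetic_db(window=1, seed=0)
        pkas = m.load_model_pkas()
        assert db.intrinsic["D"] == pytest.approx(thermo.pka_to_energy(pkas["D"]))

    def test_rejects_negative_decay(self):
        with pytest.raises(DatabaseError):
            m.generate_synthetic_db(window=1, decay_length=-1.0)


class TestPersistence:
    def test_round_trip(self, tmp_path, coupled_db):
        path = tmp_path / "db.json"
        db = coupled_db.with_rescale({"E": (0.3, 1.2)})
        m.save_db(db, path)
        loaded = m.load_db(path)
        assert loaded.window == db.window
        assert loaded.intrinsic == db.intrinsic
        assert loaded.pair_terms == db.pair_terms
        assert loaded.rescale == db.rescale
        assert loaded.config == db.config

    def test_version_check(self, tmp_path, zero_db):
        path = tmp_path / "db.json"
        m.save_db(zero_db, path)
        doc = path.read_text().replace("medoc-db-1", "medoc-db-99")
        path.write_text(doc)
        with pytest.raises(DatabaseError, match="version"):
            m.load_db(path)

    def test_duplicate_pair_rows_rejected(self, tmp_path):
        import json

        db = m.generate_synthetic_db(window=1, seed=0)
        path = tmp_path / "db.json"
        m.save_db(db, path)
        doc = json.loads(path.read_text())
        doc["pair_terms"].append(dict(doc["pair_terms"][0]))
        path.write_text(json.dumps(doc))
        with pytest.raises(DatabaseError, match="duplicate"):
            m.load_db(path)

    def test_unknown_residue_type_rejected(self, tmp_path):
        import json

        db = m.generate_synthetic_db(window=1, seed=0)
        path = tmp_path / "db.json"
        m.save_db(db, path)
        doc = json.loads(path.read_text())
        doc["pair_terms"][0]["neighbor"] = "Z"
        path.write_text(json.dumps(doc))
        with pytest.raises(DatabaseError, match="unknown residue"):
            m.load_db(path)


def test_rescale_offset_shifts_intrinsic_and_scale_multiplies_pairs(coupled_db):
    rec = m.parse_sequence("s", "EE")
    base = m.delta_E(coupled_db, rec, 1, [1])
    plain_pairs = base - coupled_db.intrinsic["E"]
    db2 = coupled_db.with_rescale({"E": (0.7, 2.0)})
    shifted = m.delta_E(db2, rec, 1, [1])
    assert shifted == pytest.approx(coupled_db.intrinsic["E"] + 0.7 + 2.0 * plain_pairs)


def test_site_delta_tables_match_delta_e(coupled_db):
    rec = m.parse_sequence("s", "EDKGHE")
    tables = site_delta_tables(coupled_db, rec)
    for i, tab in enumerate(tables):
        for bits in range(2 ** len(tab.dep_sites)):
            ctx = [(bits >> (len(tab.dep_sites) - 1 - j)) & 1 for j in range(len(tab.dep_sites))]
            left = [0] * i
            for j, dep in enumerate(tab.dep_sites):
                left[dep] = ctx[j]
            assert tab.lookup(ctx) == pytest.approx(
                m.delta_E(coupled_db, rec, i, left), rel=1e-12
            )
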