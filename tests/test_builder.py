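import numpy as np
import pytest

from rnawaxs import (ConstructSpec, HelicalParams, build_a_form_helix,
                     build_uau12_construct, build_uau_triplex,
                     parse_construct_spec, sample_disordered_ensemble)
from rnawaxs.builder import ConstructParseError


def _chain_p_coords(model, n_res):
    """Phosphorus positions in residue order."""
    out = []
    for ri in range(1, n_res + 1):
        sel = (model.res_index == ri) & (model.atom_names == "P")
        out.append(model.coords[sel][0])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# construct parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text, length, seq_head", [
    ("12U-5C-12U-5C-12A", 46, "U" * 12 + "C" * 5),
    ("rU30", 30, "U" * 30),
    ("rA30", 30, "A" * 30),
    ("1A", 1, "A"),
])
def test_parse_construct_lengths(text, length, seq_head):
    spec = parse_construct_spec(text)
    assert len(spec) == length
    assert spec.sequence.startswith(seq_head)


def test_parse_round_trips_through_text_form():
    spec = parse_construct_spec("12U-5C-12U-5C-12A")
    assert parse_construct_spec(spec.to_text()) == spec


@pytest.mark.parametrize("bad", ["12X-5C", "0U", "12U-", "rZ30"])
def test_parse_rejects_bad_tokens(bad):
    with pytest.raises(ConstructParseError):
        parse_construct_spec(bad)


def test_zero_count_rejected_in_type():
    with pytest.raises(ValueError, match="count"):
        ConstructSpec((("U", 0),))


# ---------------------------------------------------------------------------
# helix builders
# ---------------------------------------------------------------------------

def test_printed_construct_sizes():
    """Every printed construct size is reproduced exactly."""
    assert len(parse_construct_spec("rU30")) == 30
    assert build_a_form_helix(29, 4).res_index.max() == 62
    hp29 = build_a_form_helix(parse_construct_spec("12U-5C-12A"), 5)
    assert hp29.res_index.max() == 29
    assert build_uau12_construct().res_index.max() == 46


def test_trivial_hairpin_arithmetic():
    assert build_a_form_helix(1, 4).res_index.max() == 6


def test_hairpin_stem_rise_and_twist_match_params(hairpin62):
    params = HelicalParams.a_form_duplex()
    p = _chain_p_coords(hairpin62, 29)          # 5' stem strand
    dz = np.diff(p[:, 2])
    np.testing.assert_allclose(dz, params.rise, rtol=0.01)
    ang = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    dtw = np.diff(np.unwrap(np.radians(ang))) * 180.0 / np.pi
    np.testing.assert_allclose(dtw, params.twist, rtol=0.01)


def test_hairpin_axial_extent_close_to_stem_length(hairpin62):
    params = HelicalParams.a_form_duplex()
    p = _chain_p_coords(hairpin62, 29)          # stem phosphates only
    extent = p[:, 2].max() - p[:, 2].min()
    assert abs(extent - 29 * params.rise) <= 1.5 * params.rise


def test_backbone_steps_within_physical_range(hairpin62):
    p = _chain_p_coords(hairpin62, 62)
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    assert d.min() >= 5.0 and d.max() <= 6.8


@pytest.mark.parametrize("loop", [1, 2])
def test_tiny_loops_rejected(loop):
    with pytest.raises(ValueError, match="loop"):
        build_a_form_helix(10, loop)


def test_non_complementary_stem_rejected():
    with pytest.raises(ValueError, match="complementary"):
        build_a_form_helix(parse_construct_spec("12U-5C-12U"), 5)


# ---------------------------------------------------------------------------
# triplex
# ---------------------------------------------------------------------------

def test_triplex_residue_count_and_spacing(triplex24):
    assert triplex24.res_index.max() == 24
    # 3 strands x 24 residues
    assert sum(triplex24.atom_names == "P") == 72
    params = HelicalParams.uau_triplex()
    for cid in "ABC":
        p = triplex24.phosphorus_coords(cid)
        dz = np.diff(np.sort(p[:, 2]))
        np.testing.assert_allclose(dz, params.rise, rtol=0.01)


def test_triple_plane_spacing_equals_rise():
    """Axial spacing between consecutive base-triple centroids."""
    params = HelicalParams.uau_triplex()
    m = build_uau_triplex(24, params)
    backbone = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                "O3'", "C2'", "O2'", "C1'"}
    cz = []
    for lvl in range(24):
        zs = []
        for cid in "ABC":
            ri = lvl + 1 if cid in "AC" else 24 - lvl
            sel = ((m.chain_id == cid) & (m.res_index == ri)
                   & ~np.isin(m.atom_names, list(backbone)))
            zs.append(m.coords[sel][:, 2].mean())
        cz.append(np.mean(zs))
    np.testing.assert_allclose(np.diff(sorted(cz)), params.rise, atol=0.04)


def test_triplex_degenerates_to_blunt_duplex():
    """fraction=0 gives the blunt duplex atom for atom."""
    params = HelicalParams.uau_triplex()
    t0 = build_uau_triplex(24, params, third_strand_fraction=0.0)
    dup = build_a_form_helix(parse_construct_spec("24U"), 0, params)
    assert len(t0) == len(dup)
    key_t = np.lexsort(t0.coords.T)
    key_d = np.lexsort(dup.coords.T)
    np.testing.assert_allclose(t0.coords[key_t], dup.coords[key_d], atol=1e-9)
    assert np.array_equal(t0.elements[key_t], dup.elements[key_d])


def test_partial_third_strand_fraction():
    m = build_uau_triplex(24, third_strand_fraction=0.5)
    assert sum((m.chain_id == "C") & (m.atom_names == "P")) == 12


def test_triplex_rejects_empty():
    with pytest.raises(ValueError):
        build_uau_triplex(0)


# ---------------------------------------------------------------------------
# disordered ensembles
# ---------------------------------------------------------------------------

def test_ensemble_determinism_and_diversity():
    spec = parse_construct_spec("rU30")
    e1 = sample_disordered_ensemble(spec, 10, seed=7)
    e2 = sample_disordered_ensemble(spec, 10, seed=7)
    for a, b in zip(e1.members, e2.members):
        np.testing.assert_array_equal(a.coords, b.coords)
    # all pairwise distinct conformations
    for i in range(10):
        for j in range(i + 1, 10):
            assert not np.allclose(e1.members[i].coords, e1.members[j].coords)


def test_stacking_propensity_bookkeeping():
    spec = parse_construct_spec("rA30")
    ens = sample_disordered_ensemble(spec, 100, seed=3,
                                     stacking_propensity=0.6)
    assert abs(ens.stacked_fraction - 0.6) < 0.05


def test_self_avoidance_exclusion_holds():
    spec = parse_construct_spec("rU30")
    ens = sample_disordered_ensemble(spec, 5, seed=11)
    for m in ens.members:
        p = m.phosphorus_coords()
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        iu = np.triu_indices(len(p), k=2)      # non-adjacent pairs
        assert d[iu].min() >= 4.0 - 1e-9


def test_pdb_round_trip(tmp_path, triplex24):
    path = tmp_path / "triplex.pdb"
    triplex24.to_pdb(path)
    from rnawaxs import AtomicModel
    back = AtomicModel.from_pdb(path)
    assert len(back) == len(triplex24)
    assert set(back.chain_id) == {"A", "B", "C"}
    np.testing.assert_allclose(
        np.sort(back.coords, axis=0), np.sort(triplex24.coords, axis=0),
        atol=1e-3)  # PDB stores 3 decimals
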