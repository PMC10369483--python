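"""Unit conversion of interaction parameters (AKMA -> GROMACS)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffport.model import LJParam, ParameterTables
from ffport.param_convert import (
    build_pairtypes,
    combine_lorentz_berthelot,
    convert_cmap,
    convert_dihedral,
    convert_harmonic,
    convert_lj,
    convert_nbfix_entry,
    convert_parameters,
    invert_harmonic,
    invert_lj,
)
from ffport.model import FFError


@pytest.mark.parametrize(
    "K, x0, kind, k_exp, x0_exp",
    [
        (300.0, 1.111, "bond", 2 * 300 * 4.184 * 100, 0.1111),
        (50.0, 109.5, "angle", 2 * 50 * 4.184, 109.5),
        (10.0, 2.5, "urey_bradley", 2 * 10 * 4.184 * 100, 0.25),
        (75.0, 0.0, "improper", 2 * 75 * 4.184, 0.0),
        (0.0, 1.0, "bond", 0.0, 0.1),
    ],
)
def test_harmonic_conversion_hand_values(K, x0, kind, k_exp, x0_exp):
    k, x = convert_harmonic(K, x0, kind)
    assert k == pytest.approx(k_exp, rel=1e-14)
    assert x == pytest.approx(x0_exp, rel=1e-14)


def test_negative_force_constant_rejected():
    with pytest.raises(FFError):
        convert_harmonic(-1.0, 1.0, "bond")


@pytest.mark.parametrize(
    "kchi, n, delta, expected",
    [
        (0.2, 3, 0.0, (0.0, 0.8368, 3)),
        (0.0, 1, 180.0, (180.0, 0.0, 1)),
        (1.0, 2, 180.0, (180.0, 4.184, 2)),
    ],
)
def test_dihedral_conversion_no_factor_of_two(kchi, n, delta, expected):
    delta_out, k_out, n_out = convert_dihedral(kchi, n, delta)
    assert (delta_out, n_out) == (expected[0], expected[2])
    assert k_out == pytest.approx(expected[1], rel=1e-14)


def test_dihedral_multiplicity_must_be_positive_integer():
    with pytest.raises(FFError):
        convert_dihedral(1.0, 0, 0.0)


def test_lj_hand_value():
    sigma, eps = convert_lj(-0.12, 2.0)
    assert eps == pytest.approx(0.50208, rel=1e-12)
    assert sigma == pytest.approx(4.0 / 2 ** (1 / 6) / 10.0, rel=1e-14)


def test_lj_constructed_inverse_gives_exact_sigma():
    rmin2 = 2 ** (1 / 6) / 2 * 10.0  # Angstrom, chosen so sigma = 1 nm
    sigma, eps = convert_lj(-1.0, rmin2)
    assert sigma == pytest.approx(1.0, rel=1e-14)
    assert eps == pytest.approx(4.184, rel=1e-14)


def test_lj_zero_epsilon():
    _sigma, eps = convert_lj(0.0, 1.0)
    assert eps == 0.0


def test_nbfix_uses_full_rmin():
    sigma, eps = convert_nbfix_entry(-0.075, 3.19)
    assert eps == pytest.approx(0.075 * 4.184, rel=1e-14)
    assert sigma == pytest.approx(3.19 / 2 ** (1 / 6) / 10.0, rel=1e-14)


def test_minimum_depth_identity():
    """LJ energy at r = R_min equals -epsilon after conversion."""
    eps_kcal, rmin2 = -0.2, 1.8
    sigma, eps = convert_lj(eps_kcal, rmin2)
    r = 2 * rmin2 * 0.1  # full R_min in nm
    sr6 = (sigma / r) ** 6
    e = 4 * eps * (sr6 * sr6 - sr6)
    assert e == pytest.approx(-abs(eps_kcal) * 4.184, rel=1e-12)


def test_cmap_elementwise_scaling():
    rng = np.random.default_rng(0)
    grid = rng.uniform(-2, 2, (24, 24))
    out = convert_cmap(grid)
    assert np.max(np.abs(out - 4.184 * grid)) == 0.0
    assert np.all(convert_cmap(np.zeros((8, 8))) == 0.0)


def test_cmap_non_square_rejected():
    with pytest.raises(FFError):
        convert_cmap(np.zeros((8, 9)))


# ---------------------------------------------------------------------------
# pairtypes
# ---------------------------------------------------------------------------


def _lj_table():
    return {
        "A": LJParam(-0.1, 2.0, epsilon14=-0.05, rmin2_14=1.9),
        "B": LJParam(-0.2, 1.5),
        "C": LJParam(-0.3, 1.0),
        "D": LJParam(-0.15, 1.2),
        "E": LJParam(-0.25, 1.7),
    }


def test_pairtypes_full_enumeration_count():
    pairs = build_pairtypes(_lj_table(), mode="full")
    assert len(pairs) == 5 * 6 // 2  # N(N+1)/2 with N=5


def test_pairtypes_override_uses_dedicated_14_values():
    pairs = build_pairtypes(_lj_table(), mode="overrides")
    # only pairs containing A (the sole type with a 1-4 set) are emitted
    assert set(pairs) == {("A", "A"), ("A", "B"), ("A", "C"), ("A", "D"), ("A", "E")}
    s_ab, e_ab = pairs[("A", "B")]
    sa14, ea14 = convert_lj(-0.05, 1.9)
    sb, eb = convert_lj(-0.2, 1.5)
    s_exp, e_exp = combine_lorentz_berthelot((sa14, ea14), (sb, eb))
    assert (s_ab, e_ab) == pytest.approx((s_exp, e_exp), rel=1e-14)


def test_pairtypes_no_override_reduces_to_combination_rule():
    table = {"B": LJParam(-0.2, 1.5), "C": LJParam(-0.3, 1.0)}
    pairs = build_pairtypes(table, mode="full")
    sb, eb = convert_lj(-0.2, 1.5)
    sc, ec = convert_lj(-0.3, 1.0)
    assert pairs[("B", "C")] == pytest.approx(
        combine_lorentz_berthelot((sb, eb), (sc, ec)), rel=1e-14
    )


# ---------------------------------------------------------------------------
# whole-table conversion properties
# ---------------------------------------------------------------------------


def test_count_conservation(merged, conversion):
    src_counts = merged.params.counts()
    gmx_counts = conversion.gmx.counts()
    assert gmx_counts["bondtypes"] == src_counts["bonds"]
    assert gmx_counts["angletypes"] == src_counts["angles"]
    assert gmx_counts["dihedraltypes"] == src_counts["dihedrals"]
    assert gmx_counts["impropertypes"] == src_counts["impropers"]
    assert gmx_counts["atomtypes"] == src_counts["lj"]
    assert gmx_counts["nonbond_params"] == src_counts["nbfix"]
    assert gmx_counts["cmaptypes"] == src_counts["cmaps"]


def test_all_converted_epsilons_nonneg_sigmas_positive(conversion):
    for at in conversion.gmx.atomtypes.values():
        assert at.epsilon >= 0 and at.sigma > 0
    for s, e in conversion.gmx.nonbond_params.values():
        assert e >= 0 and s > 0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    K=st.floats(0, 1e4, allow_nan=False),
    x0=st.floats(0.1, 10),
    kind=st.sampled_from(["bond", "angle", "urey_bradley", "improper"]),
)
def test_harmonic_inversion_recovers_input(K, x0, kind):
    k, x = convert_harmonic(K, x0, kind)
    K2, x02 = invert_harmonic(k, x, kind)
    assert K2 == pytest.approx(K, rel=1e-12, abs=1e-12)
    assert x02 == pytest.approx(x0, rel=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(eps=st.floats(-5, 0), rmin2=st.floats(0.05, 5))
def test_lj_inversion_recovers_input(eps, rmin2):
    sigma, e = convert_lj(eps, rmin2)
    eps2, rmin2_2 = invert_lj(sigma, e)
    assert eps2 == pytest.approx(eps if eps < 0 else -abs(eps), rel=1e-12, abs=1e-12)
    assert rmin2_2 == pytest.approx(rmin2, rel=1e-12)
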