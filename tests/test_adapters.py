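"""Unit and property tests for the micro-structure -> CTI adapters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ctisim import (
    cti_alpha_de,
    kappa_from_odi,
    noddi_to_cti,
    odi_from_kappa,
    sandi_to_cti,
    smt_to_cti,
    tau_from_kappa,
)
from ctisim.adapters import DomainError


def watson_tau_quadrature(kappa: float) -> float:
    """Independent oracle: E[cos^2 theta] under the Watson density by quadrature."""
    num = quad(lambda t: np.cos(t) ** 2 * np.exp(kappa * np.cos(t) ** 2) * np.sin(t), 0, np.pi)[0]
    den = quad(lambda t: np.exp(kappa * np.cos(t) ** 2) * np.sin(t), 0, np.pi)[0]
    return num / den


class TestKappaFromOdi:
    def test_half_dispersion_gives_unit_kappa(self):
        assert kappa_from_odi(0.5) == pytest.approx(1.0)

    def test_full_dispersion_gives_zero(self):
        assert kappa_from_odi(1.0) == 0.0

    def test_low_dispersion_value(self):
        # 1 / tan(0.05 * pi), high-precision reference
        assert kappa_from_odi(0.1) == pytest.approx(6.313751514675043, rel=1e-12)

    def test_zero_odi_returns_cap(self):
        assert kappa_from_odi(0.0) == 1.0e6

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_out_of_domain_raises(self, bad):
        with pytest.raises(DomainError):
            kappa_from_odi(bad)

    def test_strictly_decreasing_and_roundtrips(self):
        odi = np.linspace(1e-4, 1 - 1e-4, 500)
        k = kappa_from_odi(odi)
        assert np.all(np.diff(k) < 0)
        assert np.max(np.abs(odi_from_kappa(k) - odi)) < 1e-10


class TestTauFromKappa:
    @pytest.mark.parametrize("kappa", [0.01, 0.1, 1.0, 3.0, 10.0, 50.0])
    def test_matches_watson_quadrature(self, kappa):
        assert tau_from_kappa(kappa) == pytest.approx(
            watson_tau_quadrature(kappa), abs=1e-6
        )

    def test_isotropic_and_coherent_limits(self):
        assert tau_from_kappa(0.0) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert tau_from_kappa(1e-4) == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert tau_from_kappa(1e4) == pytest.approx(1.0, abs=1e-3)

    def test_nondecreasing_in_kappa(self):
        k = np.concatenate([np.linspace(0, 1, 500), np.logspace(0, 4, 500)])
        tau = tau_from_kappa(k)
        assert np.all(np.diff(tau) >= -1e-14)
        assert np.all((tau >= 1.0 / 3.0) & (tau <= 1.0))

    def test_negative_kappa_raises(self):
        with pytest.raises(DomainError):
            tau_from_kappa(-1.0)


class TestNoddiAdapter:
    def test_isotropic_only_voxel(self):
        cti = noddi_to_cti(0.4, 0.5, 1.0)
        assert cti.alpha == pytest.approx(1.0)
        assert cti.di == pytest.approx(0.0)
        assert cti.de == pytest.approx(3.0e-3)
        assert cti.valid_mask.all()

    def test_worked_example(self):
        # fi=0.7, fiso=0.1, odi=0.5 -> kappa=1, tau~0.42923; intermediate
        # decm ~ 0.5712e-3; all checked by hand through the conversion chain
        cti = noddi_to_cti(0.7, 0.5, 0.1)
        assert cti.alpha == pytest.approx(0.37, rel=1e-12)
        assert cti.di == pytest.approx(0.357e-3, rel=1e-4)
        assert cti.de == pytest.approx(1.2276e-3, rel=1e-4)

    def test_degenerate_all_intracellular_masked(self):
        cti = noddi_to_cti(1.0, 0.5, 0.0)
        assert not cti.valid_mask.any()

    def test_mixing_weights_sum_to_one(self, rng):
        fi = rng.uniform(0, 0.99, 1000)
        fiso = rng.uniform(0, 0.99, 1000)
        alpha = fiso + (1 - fiso) * (1 - fi)
        w1 = (1 - fiso) * (1 - fi) / alpha
        w2 = fiso / alpha
        assert np.allclose(w1 + w2, 1.0)

    def test_canonical_scaling_gives_larger_de(self, rng):
        fi = rng.uniform(0.3, 0.9, 200)
        odi = rng.uniform(0.1, 0.9, 200)
        fiso = rng.uniform(0.0, 0.3, 200)
        scaled = noddi_to_cti(fi, odi, fiso, noddi_scaling="scaled")
        canon = noddi_to_cti(fi, odi, fiso, noddi_scaling="canonical")
        # pre-scaling by fi*(1-fiso) < 1 shrinks the tortuosity base
        assert np.all(canon.de >= scaled.de - 1e-15)
        np.testing.assert_allclose(canon.alpha, scaled.alpha)

    def test_nan_propagates_to_mask(self):
        cti = noddi_to_cti(np.array([np.nan, 0.5]), np.array([0.5, 0.5]), np.array([0.1, 0.1]))
        assert not cti.valid_mask[0] and cti.valid_mask[1]

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            cti = noddi_to_cti(np.array([1.2, 0.5]), 0.5, 0.1)
        assert cti.alpha.min() >= 0


class TestSandiAdapter:
    def test_fully_extracellular(self):
        cti = sandi_to_cti(1.0, 0.6, 2e-3, 1.5e-3)
        assert cti.alpha == pytest.approx(1.0)
        assert cti.di == pytest.approx(0.0)
        assert cti.de == pytest.approx(1.5e-3)

    def test_worked_example(self):
        cti = sandi_to_cti(0.5, 0.6, 2e-3, 1.5e-3)
        assert cti.alpha == pytest.approx(0.5)
        assert cti.di == pytest.approx(1.2e-3, rel=1e-12)
        assert cti.de == pytest.approx(0.75e-3, rel=1e-12)

    def test_no_extracellular_space(self):
        cti = sandi_to_cti(0.0, 0.6, 2e-3, 1.5e-3)
        assert cti.alpha == pytest.approx(0.0)
        assert cti.de == pytest.approx(0.0)


class TestSmtAdapter:
    def test_no_neurites(self):
        cti = smt_to_cti(0.0, 2e-3, 1.1e-3)
        assert cti.alpha == pytest.approx(1.0)
        assert cti.di == pytest.approx(0.0)
        assert cti.de == pytest.approx(1.1e-3)

    def test_worked_example(self):
        cti = smt_to_cti(0.65, 2.0e-3, 1.1e-3)
        assert cti.alpha == pytest.approx(0.35)
        assert cti.di == pytest.approx(1.3e-3, rel=1e-12)
        assert cti.de == pytest.approx(1.1e-3)

    def test_all_neurite(self):
        assert smt_to_cti(1.0, 2e-3, 1.1e-3).alpha == pytest.approx(0.0)


class TestCtiAlphaDe:
    def test_single_compartment_weight(self):
        _, de = cti_alpha_de(0.4, 0.0, 0.6, 1.0e-3)
        assert de == pytest.approx(1.0e-3)

    def test_equal_weights(self):
        _, de = cti_alpha_de(0.2, 0.2, 0.6, 1.0e-3)
        assert de == pytest.approx((1.0e-3 + 3.0e-3) / 2)

    def test_worked_example(self):
        alpha, de = cti_alpha_de(0.3, 0.1, 0.6, 1.0e-3)
        assert alpha == pytest.approx(0.4)
        assert de == pytest.approx(1.5e-3)

    def test_no_extracellular_is_masked(self):
        alpha, de = cti_alpha_de(0.0, 0.0, 1.0, 1.0e-3)
        assert alpha == 0.0 and np.isnan(de)

    def test_negative_fraction_raises(self):
        with pytest.raises(DomainError):
            cti_alpha_de(-0.1, 0.2, 0.5, 1e-3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    fi=st.floats(0, 1),
    odi=st.floats(0.001, 1),
    fiso=st.floats(0, 1),
)
def test_noddi_invariants_hold_everywhere(fi, odi, fiso):
    """alpha in [0,1] and nonnegative diffusivities for any valid input."""
    cti = noddi_to_cti(fi, odi, fiso)
    assert 0.0 <= cti.alpha <= 1.0
    assert cti.di >= 0.0 and cti.de >= 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    fe=st.floats(0, 1),
    fin=st.floats(0, 1),
    din=st.floats(0, 3e-3),
    dx=st.floats(0, 3e-3),
)
def test_sandi_smt_invariants_hold_everywhere(fe, fin, din, dx):
    for cti in (sandi_to_cti(fe, fin, din, dx), smt_to_cti(fin, din, dx)):
        assert 0.0 <= cti.alpha <= 1.0
        assert cti.di >= 0.0 and cti.de >= 0.0
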