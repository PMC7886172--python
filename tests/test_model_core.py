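"""Gamete production and embryonic deposition against exhaustive oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivesim.model_core import (
    AlleleClass,
    DepositionParams,
    Exposure,
    FitnessTable,
    GermlineParams,
    IndividualState,
    available_strains,
    embryo_transform,
    gamete_distribution,
    genotype_key,
    load_params,
)

W, D, R1, R2 = AlleleClass.W, AlleleClass.D, AlleleClass.R1, AlleleClass.R2


def het(maternal=D, paternal=W):
    return IndividualState(maternal, paternal)


def germline(params, c, hdr, rho, sex="female"):
    g = GermlineParams(c, hdr, rho)
    return params.with_updates(
        **{("germline_female" if sex == "female" else "germline_male"): g})


def oracle_gametes(pair, c, hdr, rho):
    """Exhaustive enumeration over cut/repair outcomes, then Mendelian pick.

    Independent of the implementation: builds the post-repair cell genotype
    for every branch of the outcome tree and draws each allele with 1/2.
    """
    out = {a: 0.0 for a in AlleleClass}
    if D in pair and W in pair:
        branches = [((D, W), 1.0 - c),          # no cut
                    ((D, D), c * hdr),           # HDR: homing
                    ((D, R1), c * (1 - hdr) * rho),
                    ((D, R2), c * (1 - hdr) * (1 - rho))]
    else:
        branches = [(pair, 1.0)]
    for cell, p in branches:
        for allele in cell:
            out[allele] += p * 0.5
    return out


class TestGameteDistribution:
    def test_no_cleavage_is_mendelian(self, neutral):
        dist = gamete_distribution(het(), "female", neutral)
        assert dist[D] == pytest.approx(0.5)
        assert dist[W] == pytest.approx(0.5)

    def test_complete_homing(self, zpg):
        params = germline(zpg, c=1.0, hdr=1.0, rho=0.0)
        dist = gamete_distribution(het(), "female", params)
        assert dist[D] == pytest.approx(1.0)

    def test_printed_inheritance_rate_from_partial_homing(self, zpg):
        # homing of 20.4% of non-drive chromosomes -> 60.2% inheritance
        params = germline(zpg, c=0.204, hdr=1.0, rho=0.0)
        dist = gamete_distribution(het(), "female", params)
        assert dist[D] == pytest.approx(0.602)

    def test_full_four_class_distribution_matches_oracle(self, zpg):
        params = germline(zpg, c=0.9, hdr=0.8, rho=0.25)
        dist = gamete_distribution(het(), "female", params)
        expected = oracle_gametes((D, W), 0.9, 0.8, 0.25)
        for allele in AlleleClass:
            assert dist.get(allele, 0.0) == pytest.approx(
                expected[allele], abs=1e-12)

    def test_oracle_agreement_on_random_parameter_draws(self, zpg):
        rng = np.random.default_rng(20260929)
        pairs = [genotype_key(a, b) for a in AlleleClass for b in AlleleClass]
        for _ in range(120):
            c, hdr, rho = rng.random(3)
            params = germline(zpg, c, hdr, rho)
            pair = pairs[rng.integers(len(pairs))]
            ind = IndividualState(pair[0], pair[1])
            dist = gamete_distribution(ind, "female", params)
            expected = oracle_gametes(pair, c, hdr, rho)
            for allele in AlleleClass:
                assert dist.get(allele, 0.0) == pytest.approx(
                    expected[allele], abs=1e-12)

    @pytest.mark.parametrize("c,hdr,rho", list(itertools.product(
        (0.0, 0.5, 1.0), repeat=3)))
    def test_probability_distribution_at_parameter_corners(self, zpg, c, hdr, rho):
        params = germline(zpg, c, hdr, rho)
        for pair in [(D, W), (W, W), (D, R1), (R1, R2)]:
            dist = gamete_distribution(IndividualState(*pair), "female", params)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(p >= 0 for p in dist.values())

    def test_mosaic_germline_is_a_mixture(self, zpg):
        # half the germline carries an embryo-mutated (D,R2) pair: those
        # cells segregate Mendelianly, diluting transmission
        mixture = ((genotype_key(D, R2), 0.5), (genotype_key(D, W), 0.5))
        ind = IndividualState(D, W, Exposure.MATERNAL, mixture)
        full = gamete_distribution(het(), "male", zpg)
        mixed = gamete_distribution(ind, "male", zpg)
        assert mixed[D] == pytest.approx(0.5 * full[D] + 0.5 * 0.5)

    @given(c=st.floats(0, 1), hdr=st.floats(0, 1), rho=st.floats(0, 1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_distribution_property_over_parameter_space(self, c, hdr, rho):
        params = germline(load_params("zpg"), c, hdr, rho)
        for pair in [(D, W), (W, W), (D, R1)]:
            dist = gamete_distribution(IndividualState(*pair), "male", params)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
            assert min(dist.values()) >= 0.0
            if pair == (D, W):
                assert 0.5 - 1e-12 <= dist[D] <= 1.0 + 1e-12

    def test_transmission_homing_identity(self):
        # h = 2p - 1 recovers c*hdr from the implied transmission exactly
        for c, hdr in [(0.3, 0.9), (0.99784, 0.984126), (1.0, 0.5)]:
            g = GermlineParams(c, hdr, 0.3)
            assert 2 * g.transmission - 1 == pytest.approx(c * hdr, abs=1e-15)


def oracle_embryo(zygote, cut, dep):
    """Independent enumeration of per-allele embryonic fates."""
    def fates(allele, homologue):
        if allele is not W:
            return {allele: 1.0}
        out = {}
        out[W] = 1.0 - cut
        out[homologue] = out.get(homologue, 0.0) + cut * dep.hdr_frac
        ej = cut * (1.0 - dep.hdr_frac)
        out[R1] = out.get(R1, 0.0) + ej * dep.r1_frac
        out[R2] = out.get(R2, 0.0) + ej * (1.0 - dep.r1_frac)
        return out

    a, b = zygote
    result = {}
    for (x, px), (y, py) in itertools.product(
            fates(a, b).items(), fates(b, a).items()):
        key = genotype_key(x, y)
        result[key] = result.get(key, 0.0) + px * py
    return result


class TestEmbryoTransform:
    def test_no_deposition_is_identity(self, zpg):
        out = embryo_transform((W, W), True, False, zpg)
        assert len(out) == 1
        (state, p), = out.items()
        assert p == pytest.approx(1.0)
        assert state.exposure is Exposure.MATERNAL
        assert state.germline_mixture == ((genotype_key(W, W), 1.0),)

    def test_forced_single_outcome(self, zpg):
        dep = DepositionParams(cut_maternal=1.0, hdr_frac=0.0, r1_frac=0.0,
                               germline_mosaic_frac=1.0)
        out = embryo_transform((W, R1), True, False, zpg.with_updates(deposition=dep))
        (state, p), = out.items()
        assert p == pytest.approx(1.0)
        assert state.germline_mixture == ((genotype_key(R1, R2), 1.0),)

    def test_printed_maternal_conversion_rate(self, zpg):
        # 70% of nuclease-sensitive alleles converted to novel R classes
        dep = DepositionParams(cut_maternal=0.70, hdr_frac=0.0,
                               r1_frac=1 / 3, germline_mosaic_frac=1.0)
        out = embryo_transform((W, R1), True, False,
                               zpg.with_updates(deposition=dep))
        converted = sum(p for s, p in out.items()
                        if W not in dict(s.germline_mixture).popitem()[0])
        assert converted == pytest.approx(0.70, abs=1e-12)

    def test_full_mixture_matches_enumeration_oracle(self, zpg):
        dep = DepositionParams(cut_maternal=0.5, hdr_frac=0.2, r1_frac=0.1,
                               germline_mosaic_frac=0.5)
        params = zpg.with_updates(deposition=dep)
        out = embryo_transform((W, W), True, False, params)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        # aggregate the implementation's mixtures back to modified-pair mass
        got = {}
        for state, p in out.items():
            for pair, weight in state.germline_mixture:
                if pair == genotype_key(W, W):
                    continue
                got[pair] = got.get(pair, 0.0) + p * weight / dep.germline_mosaic_frac
        expected = oracle_embryo((W, W), 0.5, dep)
        for pair, mass in expected.items():
            if pair == genotype_key(W, W):
                continue
            assert got.get(pair, 0.0) == pytest.approx(mass, abs=1e-12)

    def test_both_parents_combine_independently(self, zpg):
        dep = DepositionParams(cut_maternal=0.6, cut_paternal=0.5,
                               hdr_frac=0.0, r1_frac=0.0,
                               germline_mosaic_frac=1.0)
        out = embryo_transform((W, R1), True, True,
                               zpg.with_updates(deposition=dep))
        uncut = sum(p for s, p in out.items()
                    if dict(s.germline_mixture).popitem()[0] == genotype_key(W, R1))
        assert uncut == pytest.approx((1 - 0.6) * (1 - 0.5), abs=1e-12)

    def test_deposition_without_carrier_parent_rejected(self, zpg):
        with pytest.raises(ValueError):
            embryo_transform((W, W), False, False, zpg, maternal_cut=0.5)

    @pytest.mark.parametrize("dm,dp,hdr", list(itertools.product(
        (0.0, 0.5, 1.0), repeat=3)))
    def test_distribution_at_parameter_corners(self, zpg, dm, dp, hdr):
        dep = DepositionParams(cut_maternal=dm, cut_paternal=dp, hdr_frac=hdr,
                               r1_frac=0.5, germline_mosaic_frac=0.5)
        params = zpg.with_updates(deposition=dep)
        for zygote in [(W, W), (W, D), (W, R1), (R1, R2)]:
            out = embryo_transform(zygote, True, True, params)
            assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(p >= 0 for p in out.values())
            for state in out:
                assert sum(w for _, w in state.germline_mixture) == \
                    pytest.approx(1.0, abs=1e-12)


class TestParameterContainers:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            GermlineParams(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            DepositionParams(cut_maternal=-0.1)

    def test_implied_transmission_in_valid_range(self):
        for strain in available_strains():
            params = load_params(strain)
            for sex in ("female", "male"):
                assert 0.5 <= params.germline(sex).transmission <= 1.0

    def test_sterile_genotypes_enforced_for_females(self):
        with pytest.raises(ValueError):
            FitnessTable(female_overrides={"D/D": 0.5})
        table = FitnessTable(female_overrides={"W/D": 0.5})
        assert table.female_fecundity((D, D)) == 0.0
        assert table.female_fecundity((W, W)) == 1.0  # wild-type reference

    def test_exposure_specific_override_takes_precedence(self):
        table = FitnessTable(female_overrides={"W/D": 0.6, "W/D|maternal": 0.4})
        assert table.female_fecundity((D, W), Exposure.MATERNAL) == 0.4
        assert table.female_fecundity((D, W), Exposure.PATERNAL) == 0.6

    def test_bundled_strains_load(self):
        assert set(available_strains()) >= {"zpg", "nos", "vas2"}
        nos = load_params("nos")
        assert nos.deposition.cut_maternal == pytest.approx(0.105)

    def test_germline_mixture_must_normalise(self):
        with pytest.raises(ValueError):
            IndividualState(D, W, Exposure.NONE,
                            ((genotype_key(D, W), 0.5),))
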