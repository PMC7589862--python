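"""Compositional machinery: closure, balances, distances, partitions."""

import numpy as np
import pytest
from skbio.stats.composition import clr as skbio_clr
from skbio.stats.composition import closure as skbio_closure

from berrywalk.compositions import (
    LEAF_PARTS,
    SOIL_PARTS,
    BalancePartition,
    Composition,
    IlrTransformer,
    aitchison_distance,
    close,
    ilr,
    ilr_array,
    ilr_inverse,
    leaf_partition,
    multiplicative_replacement,
    perturbation_ratio,
    soil_partition,
    with_filling_value,
)
from conftest import random_composition_values, random_sbp


class TestClosure:
    def test_symmetry_and_scaling(self):
        assert np.allclose(close([1, 1, 1, 1], 1).values, 0.25)
        assert np.allclose(close([2, 3, 5], 100).values, [20, 30, 50])

    def test_matches_direct_normalization(self, rng):
        for _ in range(20):
            x = random_composition_values(rng, 6)
            assert np.allclose(close(x, 1000).values, skbio_closure(x) * 1000)
            # re-closing is idempotent up to the constant
            assert np.allclose(
                close(close(x, 1).values, 1000).values, 1000 * close(x, 1).values
            )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="x2"):
            close([1.0, 0.0, 2.0], 1)
        with pytest.raises(ValueError, match="positive"):
            close([1.0, 2.0], -5)

    def test_composition_invariants(self):
        with pytest.raises(ValueError, match="unique"):
            Composition(("a", "a"), np.array([0.5, 0.5]), 1.0)
        with pytest.raises(ValueError, match="kappa"):
            Composition(("a", "b"), np.array([0.5, 0.6]), 1.0)


class TestFillingValue:
    def test_arithmetic(self):
        c = with_filling_value([20, 1, 5], ["N", "P", "K"], 1000)
        assert c["Fv"] == pytest.approx(974.0)
        assert c.values.sum() == pytest.approx(1000.0)

    def test_no_room_errors(self):
        with pytest.raises(ValueError, match="no room"):
            with_filling_value([600, 400], ["a", "b"], 1000)

    def test_random_vectors_close_to_kappa(self, rng):
        for _ in range(50):
            vals = rng.uniform(0.1, 10.0, size=5)
            c = with_filling_value(vals, list("abcde"), 100.0)
            assert c.values.sum() == pytest.approx(100.0)
            assert np.allclose(c.values[:-1], vals)


class TestIlr:
    def test_uniform_composition_is_origin(self):
        part = leaf_partition()
        c = close(np.ones(8), 1000, labels=LEAF_PARTS)
        assert np.allclose(ilr(c, part), 0.0)

    def test_two_part_closed_form(self):
        part = BalancePartition.from_contrasts(["a", "b"], [(["a"], ["b"])])
        c = close([np.e, 1.0], 1.0, labels=["a", "b"])
        assert ilr(c, part)[0] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_isometry_with_clr_oracle(self, rng):
        """ilr norm equals clr norm for any orthonormal basis (100 cases)."""
        for _ in range(100):
            d = int(rng.integers(3, 9))
            labels = [f"p{i}" for i in range(d)]
            part = random_sbp(rng, labels)
            x = random_composition_values(rng, d)
            bal = ilr(close(x, 1, labels=labels), part)
            assert np.linalg.norm(bal) == pytest.approx(
                np.linalg.norm(skbio_clr(skbio_closure(x))), abs=1e-9
            )

    def test_scale_invariance(self, rng):
        part = soil_partition()
        x = random_composition_values(rng, 5)
        b1 = ilr(close(x, 1, labels=SOIL_PARTS), part)
        b2 = ilr(close(x, 1e6, labels=SOIL_PARTS), part)
        assert np.allclose(b1, b2, atol=1e-10)

    def test_label_mismatch(self):
        part = soil_partition()
        c = close([1, 2, 3, 4, 5], 1, labels=["P", "K", "Ca", "Mg", "Na"])
        with pytest.raises(ValueError):
            ilr(c, part)


class TestIlrInverse:
    def test_zero_vector_gives_uniform(self):
        part = soil_partition()
        c = ilr_inverse(np.zeros(4), part, kappa=100.0)
        assert np.allclose(c.values, 20.0)

    def test_round_trip(self, rng):
        part = leaf_partition()
        worst = 0.0
        for _ in range(100):
            x = close(random_composition_values(rng, 8), 1000, labels=LEAF_PARTS)
            b = ilr(x, part)
            back = ilr_inverse(b, part, kappa=1000.0)
            worst = max(worst, np.abs(back.values - x.values).max())
            assert np.allclose(ilr(back, part), b, atol=1e-9)
        assert worst < 1e-9 * 1000

    def test_coordinate_bump_scales_group_ratio(self, rng):
        """Adding delta to coordinate j multiplies g(num)/g(den) by
        exp(delta * sqrt((r+s)/(r*s)))."""
        part = leaf_partition()
        b = rng.normal(0, 0.5, size=7)
        delta = 0.3
        for j in range(7):
            signs = part.signs[j]
            r, s = (signs > 0).sum(), (signs < 0).sum()
            b2 = b.copy()
            b2[j] += delta

            def group_ratio(coords):
                c = ilr_inverse(coords, part).values
                g_num = np.exp(np.mean(np.log(c[signs > 0])))
                g_den = np.exp(np.mean(np.log(c[signs < 0])))
                return g_num / g_den

            expect = np.exp(delta * np.sqrt((r + s) / (r * s)))
            assert group_ratio(b2) / group_ratio(b) == pytest.approx(expect, rel=1e-9)

    def test_wrong_length(self):
        with pytest.raises(ValueError, match="coordinates"):
            ilr_inverse(np.zeros(3), leaf_partition())


class TestAitchisonDistance:
    def test_identity(self, rng):
        x = close(random_composition_values(rng, 5), 1, labels=SOIL_PARTS)
        assert aitchison_distance(x, x) == 0.0

    def test_partition_invariance(self, rng):
        """Any valid SBP yields the same distance as the clr oracle."""
        labels = [f"p{i}" for i in range(6)]
        for _ in range(100):
            xv = random_composition_values(rng, 6)
            yv = random_composition_values(rng, 6)
            x = close(xv, 1, labels=labels)
            y = close(yv, 1, labels=labels)
            d_clr = np.linalg.norm(
                skbio_clr(skbio_closure(xv)) - skbio_clr(skbio_closure(yv))
            )
            assert aitchison_distance(x, y) == pytest.approx(d_clr, abs=1e-9)
            p1, p2 = random_sbp(rng, labels), random_sbp(rng, labels)
            d1 = np.linalg.norm(ilr(x, p1) - ilr(y, p1))
            d2 = np.linalg.norm(ilr(x, p2) - ilr(y, p2))
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_perturbation_invariance(self, rng):
        labels = list("abcde")
        for _ in range(20):
            x = close(random_composition_values(rng, 5), 1, labels=labels)
            y = close(random_composition_values(rng, 5), 1, labels=labels)
            p = random_composition_values(rng, 5)
            px = close(x.values * p, 1, labels=labels)
            py = close(y.values * p, 1, labels=labels)
            assert aitchison_distance(px, py) == pytest.approx(
                aitchison_distance(x, y), abs=1e-9
            )

    def test_kappa_invariance(self, rng):
        x = random_composition_values(rng, 5)
        y = random_composition_values(rng, 5)
        d1 = aitchison_distance(close(x, 1), close(y, 1))
        d2 = aitchison_distance(close(x, 1e6), close(y, 1e6))
        assert d1 == pytest.approx(d2, abs=1e-10)


class TestPerturbationRatio:
    def test_equal_compositions(self, rng):
        x = close(random_composition_values(rng, 5), 1000)
        assert np.allclose(list(perturbation_ratio(x, x).values()), 1.0)

    def test_closure_effect_spreads(self, rng):
        """Doubling one raw part before closure changes every ratio."""
        vals = random_composition_values(rng, 4)
        labels = list("abcd")
        target = close(vals, 1000, labels=labels)
        doubled = vals.copy()
        doubled[0] *= 2
        observed = close(doubled, 1000, labels=labels)
        ratios = perturbation_ratio(observed, target)
        expect = (doubled / doubled.sum()) / (vals / vals.sum())
        assert np.allclose(list(ratios.values()), expect)
        assert all(r != pytest.approx(1.0) for r in ratios.values())

    def test_kappa_invariance(self, rng):
        x = random_composition_values(rng, 5)
        y = random_composition_values(rng, 5)
        r1 = perturbation_ratio(close(x, 1), close(y, 1))
        r2 = perturbation_ratio(close(x, 100), close(y, 100))
        assert np.allclose(list(r1.values()), list(r2.values()))


class TestFixedPartitions:
    def test_shapes(self):
        assert leaf_partition().n_balances == 7
        assert soil_partition().n_balances == 4

    @pytest.mark.parametrize("factory", [leaf_partition, soil_partition])
    def test_orthonormality(self, factory):
        psi = factory().contrast_matrix()
        assert np.allclose(psi @ psi.T, np.eye(psi.shape[0]), atol=1e-10)

    def test_random_sbp_orthonormality(self, rng):
        for _ in range(25):
            d = int(rng.integers(3, 10))
            part = random_sbp(rng, [f"p{i}" for i in range(d)])
            psi = part.contrast_matrix()
            assert np.allclose(psi @ psi.T, np.eye(d - 1), atol=1e-10)

    def test_matches_skbio_sbp_basis(self):
        """The contrast matrix spans the same ilr basis as scikit-bio's."""
        from skbio.stats.composition import sbp_basis

        part = soil_partition()
        ours = part.contrast_matrix()
        theirs = sbp_basis(part.signs)
        # same rows up to numerical noise
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_boron_excess_lowers_boron_balance(self, rng):
        """More leaf B (pre-closure) lowers the [B | macronutrients] balance:
        B sits in the denominator group."""
        part = leaf_partition()
        names = part.balance_names()
        j = names.index("[B | Mg,Ca,K,N,P]")
        raw = random_composition_values(rng, 7) * [17, 1.2, 5, 4.2, 1.6, 0.03, 0.05]
        base = with_filling_value(raw, [p for p in LEAF_PARTS if p != "Fv"], 1000)
        doubled_raw = raw.copy()
        doubled_raw[5] *= 2  # B
        doubled = with_filling_value(doubled_raw, [p for p in LEAF_PARTS if p != "Fv"], 1000)
        assert ilr(doubled, part)[j] < ilr(base, part)[j]

    def test_invalid_sbp_rejected(self):
        # second contrast re-splits parts already separated
        with pytest.raises(ValueError):
            BalancePartition.from_contrasts(
                list("abc"), [(["a"], ["b", "c"]), (["a"], ["b"])]
            )
        with pytest.raises(ValueError, match="both sides"):
            BalancePartition.from_contrasts(list("ab"), [(["a", "b"], [])])

    def test_json_round_trip(self):
        part = leaf_partition()
        again = BalancePartition.from_json(part.to_json(), labels=part.labels)
        assert np.array_equal(part.signs, again.signs)
        assert part.balance_names() == again.balance_names()


class TestTransformer:
    def test_round_trip_and_names(self, rng):
        t = IlrTransformer(leaf_partition(), kappa=1000.0).fit()
        X = np.exp(rng.normal(0, 0.3, size=(10, 8)))
        B = t.transform(X)
        assert B.shape == (10, 7)
        back = t.inverse_transform(B)
        assert np.allclose(back.sum(axis=1), 1000.0)
        assert np.allclose(t.transform(back), B, atol=1e-9)
        assert t.feature_names_out_[0] == "[Fv | B,Al,Mg,Ca,K,P,N]"

    def test_get_set_params(self):
        t = IlrTransformer(soil_partition(), kappa=5.0)
        assert t.get_params()["kappa"] == 5.0
        t.set_params(kappa=7.0)
        assert t.kappa == 7.0


def test_multiplicative_replacement():
    table = np.array([[1.0, 0.0], [2.0, 4.0], [3.0, 8.0]])
    out, n = multiplicative_replacement(table)
    assert n == 1
    assert out[0, 1] == pytest.approx(0.65 * 4.0)
    assert np.array_equal(out[1:], table[1:])


# hypothesis property checks: closure scale-invariance of the ilr map
from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.01, 100.0), min_size=5, max_size=5),
    st.floats(0.1, 1e6),
)
def test_ilr_scale_invariance_property(values, kappa):
    part = soil_partition()
    b1 = ilr(close(values, 1.0, labels=SOIL_PARTS), part)
    b2 = ilr(close(values, kappa, labels=SOIL_PARTS), part)
    assert np.allclose(b1, b2, atol=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4), st.integers(0, 10))
def test_filling_value_closes_exactly(values, _):
    total = sum(values)
    c = with_filling_value(values, list("wxyz"), kappa=2 * total)
    assert c.values.sum() == pytest.approx(2 * total)
    assert c["Fv"] == pytest.approx(total)
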