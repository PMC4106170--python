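"""The acACS encoder against brute-force oracles, plus AAC/DC/fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acacs.alphabets import AA_ORDER, ATOM_ORDER
from acacs.features import (
    FeatureSpec,
    FeatureVector,
    MissingCellError,
    aac,
    autocovariance,
    dc,
    encode_acacs,
    encode_dataset,
    encode_sample,
    fuse,
    lookup_series,
    series_mean,
)
from acacs.star_io import ProteinSample

# ---------------------------------------------------------------- oracles


def brute_force_theta(values, lam):
    """Independent double-loop evaluation of the lagged mean-squared difference."""
    L = len(values)
    total = 0.0
    for l in range(L - lam):
        total += (values[l] - values[l + lam]) ** 2
    return total / (L - lam)


def brute_force_acacs(sample, table, atoms, lam_max):
    """Per-position re-lookup + double-loop lags, independent of the encoder."""
    out = []
    for atom in [a for a in ATOM_ORDER if a in atoms]:
        values = [
            table.mean(atom, j, k) for j, k in zip(sample.sequence, sample.ss)
        ]
        out.append(sum(values) / len(values))
        for lam in range(1, lam_max + 1):
            out.append(brute_force_theta(values, lam))
    return np.array(out)


def _random_sample(rng, L, pid="r"):
    seq = "".join(rng.choice([a for a in AA_ORDER if a != "P"], size=L))
    ss = "".join(rng.choice(list("HEC"), size=L))
    return ProteinSample(pid, seq, ss)


# ------------------------------------------------------------- lookup


class TestLookupSeries:
    def test_single_residue_lookup(self, fixture_table):
        sample = ProteinSample("p", "A", "H")
        series = lookup_series(sample, fixture_table, "H1A")
        assert series.values[0] == fixture_table.mean("H1A", "A", "H")

    def test_proline_amide_proton_error_policy(self, fixture_table):
        sample = ProteinSample("p", "AP", "HH")
        with pytest.raises(MissingCellError, match=r"H1N, P"):
            lookup_series(sample, fixture_table, "H1N", missing_policy="error")

    def test_proline_zero_policy_and_missing_positions(self, fixture_table):
        sample = ProteinSample("p", "APA", "HHH")
        series = lookup_series(sample, fixture_table, "H1N", missing_policy="zero")
        assert series.values[1] == 0.0
        assert series.missing_positions == frozenset({2})

    def test_cell_row_mean_policy_gives_weighted_row_mean(self, fixture_table):
        sample = ProteinSample("p", "P", "H")
        series = lookup_series(sample, fixture_table, "H1N", "cell_row_mean")
        # proline has no H1N data in any SS state, so the atom-wide
        # count-weighted mean applies
        frame = fixture_table.frame.xs("H1N", level="atom")
        ok = frame["count"] > 0
        expected = np.average(frame["mean_ppm"][ok], weights=frame["count"][ok])
        assert series.values[0] == pytest.approx(expected)

    def test_series_matches_positionwise_relookup(self, fixture_table):
        rng = np.random.default_rng(1)
        sample = _random_sample(rng, 50)
        for atom in ATOM_ORDER:
            series = lookup_series(sample, fixture_table, atom)
            expected = [
                fixture_table.mean(atom, j, k)
                for j, k in zip(sample.sequence, sample.ss)
            ]
            np.testing.assert_array_equal(series.values, expected)


# ------------------------------------------------------- autocovariance


class TestAutocovariance:
    def test_constant_series_is_zero_at_every_lag(self):
        for lam in (1, 2):
            assert autocovariance(np.array([5.0, 5.0, 5.0]), lam) == 0.0

    def test_hand_derived_values_for_1_3_5(self):
        series = np.array([1.0, 3.0, 5.0])
        assert autocovariance(series, 1) == pytest.approx(4.0)
        assert autocovariance(series, 2) == pytest.approx(16.0)

    @pytest.mark.parametrize("lam", [0, 3, 5, -1])
    def test_lag_outside_open_interval_raises(self, lam):
        with pytest.raises(ValueError):
            autocovariance(np.array([1.0, 2.0, 3.0]), lam)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-50, 150), min_size=3, max_size=40),
        st.floats(-10, 10),
        st.integers(1, 5),
    )
    def test_shift_invariance(self, values, c, lam):
        values = np.asarray(values)
        lam = min(lam, len(values) - 1)
        assert autocovariance(values + c, lam) == pytest.approx(
            autocovariance(values, lam), abs=1e-6
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-20, 20), min_size=3, max_size=40),
        st.floats(-4, 4),
        st.integers(1, 5),
    )
    def test_quadratic_scale_law(self, values, a, lam):
        values = np.asarray(values)
        lam = min(lam, len(values) - 1)
        assert autocovariance(a * values, lam) == pytest.approx(
            a * a * autocovariance(values, lam), abs=1e-8
        )

    def test_nonnegative_and_zero_iff_lag_matched(self):
        # period-2 series: zero exactly at even lags
        series = np.array([1.0, 9.0] * 5)
        assert autocovariance(series, 2) == 0.0
        assert autocovariance(series, 1) > 0


def test_series_mean_matches_direct_sum():
    values = np.array([4.0])
    assert series_mean(values) == 4.0
    assert series_mean(np.array([1.0, 3.0])) == 2.0
    rng = np.random.default_rng(2)
    v = rng.normal(size=31)
    assert series_mean(v) == pytest.approx(sum(v) / len(v))
    with pytest.raises(ValueError):
        series_mean(np.array([]))


# ------------------------------------------------------------- encoding


class TestEncodeAcacs:
    def test_dimensionality_one_atom(self, fixture_table):
        sample = ProteinSample("p", "MKV", "HEC")
        vec = encode_acacs(sample, fixture_table, atoms=("H1A",), lam_max=2)
        assert len(vec) == 3

    def test_server_default_two_atoms_lambda_12(self, fixture_table):
        rng = np.random.default_rng(3)
        sample = _random_sample(rng, 40)
        vec = encode_acacs(sample, fixture_table, atoms=("H1A", "H1N"), lam_max=12)
        assert len(vec) == 26
        np.testing.assert_allclose(
            vec.components,
            brute_force_acacs(sample, fixture_table, {"H1A", "H1N"}, 12),
            rtol=1e-10,
        )

    def test_constant_series_gives_mean_then_zeros(self, fixture_table):
        sample = ProteinSample("p", "AAAA", "HHHH")
        vec = encode_acacs(sample, fixture_table, atoms=("C13A",), lam_max=2)
        c = fixture_table.mean("C13A", "A", "H")
        np.testing.assert_allclose(vec.components, [c, 0.0, 0.0])

    def test_lam_max_at_least_length_names_protein(self, fixture_table):
        sample = ProteinSample("tiny", "MKV", "HEC")
        with pytest.raises(ValueError, match="tiny"):
            encode_acacs(sample, fixture_table, lam_max=3)

    def test_atom_blocks_follow_fixed_order(self, fixture_table):
        rng = np.random.default_rng(4)
        sample = _random_sample(rng, 30)
        vec = encode_acacs(sample, fixture_table, atoms=("H1N", "N15"), lam_max=1)
        assert vec.names[0].startswith("acACS_N15")
        assert vec.names[2].startswith("acACS_H1N")

    def test_oracle_equivalence_over_random_inputs(self, fixture_table):
        rng = np.random.default_rng(7)
        for _ in range(25):
            L = int(rng.integers(25, 80))
            lam = int(rng.integers(1, 21))
            sample = _random_sample(rng, L)
            vec = encode_acacs(sample, fixture_table, ATOM_ORDER, lam)
            expected = brute_force_acacs(sample, fixture_table, set(ATOM_ORDER), lam)
            np.testing.assert_allclose(vec.components, expected, rtol=1e-10)


class TestCompositions:
    def test_aac_small_example(self):
        vec = aac("AAC")
        assert vec.components[0] == pytest.approx(2 / 3)  # A
        assert vec.components[1] == pytest.approx(1 / 3)  # C
        assert vec.components[2:].sum() == 0

    def test_aac_homopolymer(self):
        assert aac("A" * 100).components[0] == 1.0

    def test_aac_random_sums_to_one(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list(AA_ORDER), size=211))
        assert aac(seq).components.sum() == pytest.approx(1.0, abs=1e-12)

    def test_aac_rejects_nonstandard_residue(self):
        with pytest.raises(ValueError, match="position 2"):
            aac("AXA")

    def test_dc_small_examples(self):
        vec = dc("AAC")
        nonzero = {n: v for n, v in zip(vec.names, vec.components) if v}
        assert nonzero == {"DC_AA": 0.5, "DC_AC": 0.5}
        assert dict(zip(dc("AC").names, dc("AC").components))["DC_AC"] == 1.0

    def test_dc_requires_length_two(self):
        with pytest.raises(ValueError):
            dc("A")

    def test_dc_random_sums_to_one_with_bounded_support(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(AA_ORDER), size=57))
        vec = dc(seq)
        assert vec.components.sum() == pytest.approx(1.0, abs=1e-12)
        assert (vec.components > 0).sum() <= 56


class TestFusion:
    def test_block_additivity_and_layout(self, fixture_table):
        rng = np.random.default_rng(10)
        sample = _random_sample(rng, 40)
        acacs_block = encode_acacs(sample, fixture_table, ("H1A", "H1N"), 12)
        fused = fuse([acacs_block, aac(sample.sequence), dc(sample.sequence)])
        assert len(fused) == 26 + 20 + 400
        # slicing back by name prefix recovers each block
        names = np.array(fused.names)
        for block in (acacs_block, aac(sample.sequence)):
            mask = np.isin(names, block.names)
            np.testing.assert_array_equal(fused.components[mask], block.components)

    def test_single_block_is_identity(self):
        block = aac("MKV")
        fused = fuse([block])
        np.testing.assert_array_equal(fused.components, block.components)

    def test_duplicate_block_kind_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            fuse([aac("MKV"), aac("MKV")])

    def test_layout_round_trips_through_csv_header(self, fixture_table, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(11)
        samples = [_random_sample(rng, 30, pid=f"p{i}") for i in range(3)]
        matrix = encode_dataset(samples, fixture_table, FeatureSpec(lam_max=5))
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        back = pd.read_csv(path, index_col="protein_id")
        pd.testing.assert_frame_equal(matrix, back)


def test_dimensional_law_across_configs(fixture_table):
    rng = np.random.default_rng(12)
    sample = _random_sample(rng, 45)
    for atoms in (("H1A",), ("H1A", "H1N"), ATOM_ORDER):
        for lam in (1, 5, 12):
            for use_aac in (False, True):
                for use_dc in (False, True):
                    spec = FeatureSpec(acacs=True, aac=use_aac, dc=use_dc,
                                       atoms=atoms, lam_max=lam)
                    vec = encode_sample(sample, fixture_table, spec)
                    expected = len(atoms) * (lam + 1) + 20 * use_aac + 400 * use_dc
                    assert len(vec) == expected


def test_feature_vector_rejects_name_length_mismatch():
    with pytest.raises(ValueError):
        FeatureVector(np.zeros(2), ("a",))
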