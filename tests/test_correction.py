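"""Natural isotope abundance correction: distributions, matrix, inversion.

The isotope-pattern implementation (closed-form multinomial products) is
checked against an independent brute-force oracle that convolves per-atom
generating polynomials keyed by substitution composition.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cometchem import DEFAULT_ATOMS, AtomTable, H3_18_26, Formula
from cometchem.constants import MONOISOTOPIC_MASS
from cometchem.correction import (
    ChannelSpec,
    build_correction_matrix,
    channels_for_peptide,
    correct_intensities,
    correct_table,
    natural_isotope_distribution,
    normalize_abundances,
)

C13 = MONOISOTOPIC_MASS["13C"] - MONOISOTOPIC_MASS["C"]
D_H = MONOISOTOPIC_MASS["2H"] - MONOISOTOPIC_MASS["H"]


def oracle_distribution(formula, max_shift, atoms=DEFAULT_ATOMS):
    """Independent oracle: enumerate substitution compositions, probabilities
    via scipy's multinomial pmf, offsets merged by exact mass."""
    from scipy.stats import multinomial

    per_element = []
    for elem, count in sorted(formula.unlabeled.items()):
        minors = atoms.minor_isotopes(elem)
        if not minors or count == 0:
            continue
        deltas = [d for _i, d, p in minors]
        probs = [p for _i, d, p in minors]
        base_p = 1.0 - sum(probs)
        options = []
        for ks in itertools.product(*(range(max_shift + 1) for _ in minors)):
            if sum(ks) > min(max_shift, count):
                continue
            pmf = multinomial.pmf(
                list(ks) + [count - sum(ks)], n=count, p=probs + [base_p]
            )
            options.append((sum(k * d for k, d in zip(ks, deltas)), sum(ks), float(pmf)))
        per_element.append(options)
    dist = {0.0: 1.0}
    shifts = {0.0: 0}
    for options in per_element:
        nxt, nshifts = {}, {}
        for off, prob in dist.items():
            for d, nsub, p in options:
                if shifts[off] + nsub > max_shift:
                    continue
                key = round(off + d, 9)
                nxt[key] = nxt.get(key, 0.0) + prob * p
                nshifts[key] = shifts[off] + nsub
        dist, shifts = nxt, nshifts
    return dist


class TestNaturalDistribution:
    def test_two_carbons_single_shift_is_binomial(self):
        p = DEFAULT_ATOMS.abundances["C"]["13C"]
        dist = natural_isotope_distribution(Formula({"C": 2}), max_shift=2)
        probs = {round(pk.mass_offset, 4): pk.probability for pk in dist}
        assert probs[round(C13, 4)] == pytest.approx(2 * p * (1 - p), rel=1e-12)
        assert probs[round(2 * C13, 4)] == pytest.approx(p * p, rel=1e-12)

    def test_empty_formula_is_monoisotopic_only(self):
        dist = natural_isotope_distribution(Formula({}), max_shift=5)
        assert len(dist) == 1
        assert dist[0].mass_offset == 0.0
        assert dist[0].probability == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            natural_isotope_distribution(Formula({"C": -2, "H": 4}), max_shift=2)

    def test_full_peptide_matches_convolution_oracle(self, h3_by_id):
        formula = h3_by_id["I"].formula()  # both sites chemically acetylated
        got = {
            round(pk.mass_offset, 9): pk.probability
            for pk in natural_isotope_distribution(formula, max_shift=3)
        }
        oracle = oracle_distribution(formula, max_shift=3)
        assert len(got) == len(oracle)
        oracle_keys = sorted(oracle)
        for off, prob in got.items():
            key = min(oracle_keys, key=lambda k: abs(k - off))
            assert abs(key - off) < 1e-6
            assert prob == pytest.approx(oracle[key], abs=1e-12)

    def test_probabilities_sum_to_one_at_large_max_shift(self, h3_by_id):
        for iso_id in ("I", "IV", "IX"):
            dist = natural_isotope_distribution(
                h3_by_id[iso_id].formula(), max_shift=10
            )
            assert sum(p.probability for p in dist) == pytest.approx(1.0, abs=1e-9)

    def test_labeled_atoms_excluded_from_natural_variation(self):
        # identical unlabeled content -> identical distribution regardless of labels
        f1 = Formula({"C": 10, "H": 20})
        f2 = Formula({"C": 10, "H": 20, "13C": 4, "2H": 6})
        d1 = natural_isotope_distribution(f1, max_shift=4)
        d2 = natural_isotope_distribution(f2, max_shift=4)
        assert [(p.mass_offset, p.probability) for p in d1] == [
            (p.mass_offset, p.probability) for p in d2
        ]

    def test_label_impurity_adds_negative_offsets(self):
        f = Formula({"13C": 2})
        dist = natural_isotope_distribution(f, max_shift=2, label_purity={"13C": 0.99})
        probs = {round(p.mass_offset, 4): p.probability for p in dist}
        assert probs[round(-C13, 4)] == pytest.approx(2 * 0.01 * 0.99, rel=1e-9)


def _two_channel_set(n_carbons, separation):
    f = Formula({"C": n_carbons})
    return [
        ChannelSpec("light", 1000.0, f),
        ChannelSpec("heavy", 1000.0 + separation, f),
    ]


class TestCorrectionMatrix:
    def test_single_channel_matrix(self):
        chans = [ChannelSpec("only", 500.0, Formula({"C": 3}))]
        cm = build_correction_matrix(chans, charge=1)
        assert cm.matrix.shape == (1, 1)
        assert 0 < cm.matrix[0, 0] <= 1

    def test_light_to_heavy_overlap_is_double_13c_term(self):
        # channels spaced by exactly two 13C substitutions; with a tight
        # tolerance only the 13C2 natural satellite lands on the heavy channel
        n, p = 30, DEFAULT_ATOMS.abundances["C"]["13C"]
        cm = build_correction_matrix(
            _two_channel_set(n, 2 * C13), coalescence_tol=0.0005, charge=1
        )
        expected = math.comb(n, 2) * p**2 * (1 - p) ** (n - 2)
        assert cm.matrix[1, 0] == pytest.approx(expected, rel=1e-12)

    def test_mass_defect_resolves_deuterium_from_carbon(self):
        # channels spaced by 3 x (2H-1H) = 3.0188; natural 3 x 13C sits at
        # 3.0101, outside a 3 mDa window -> no cross-talk
        cm = build_correction_matrix(
            _two_channel_set(40, 3 * D_H), coalescence_tol=0.003, charge=1
        )
        assert cm.matrix[1, 0] == 0.0

    def test_lower_triangular_and_column_sums(self, h3_groups):
        channels, _ = channels_for_peptide(H3_18_26)
        cm = build_correction_matrix(channels)
        assert cm.is_lower_triangular
        assert np.all(cm.matrix.sum(axis=0) <= 1 + 1e-12)
        assert np.all(np.diag(cm.matrix) > 0)

    def test_channels_too_close_rejected(self):
        chans = _two_channel_set(5, 0.001)
        with pytest.raises(ValueError, match="unresolvable"):
            build_correction_matrix(chans, coalescence_tol=0.003, charge=1)

    def test_zero_natural_abundance_gives_identity(self):
        atoms = AtomTable(abundances={})
        channels, _ = channels_for_peptide(H3_18_26, atoms=atoms)
        cm = build_correction_matrix(channels, atoms=atoms)
        assert np.allclose(cm.matrix, np.eye(6))


@pytest.fixture(scope="module")
def h3_cm():
    channels, _ = channels_for_peptide(H3_18_26)
    return build_correction_matrix(channels)


class TestCorrectIntensities:

    def test_identity_matrix_is_noop(self, h3_cm):
        from dataclasses import replace

        eye = replace(h3_cm, matrix=np.eye(6))
        y = np.arange(6, dtype=float)
        assert np.allclose(correct_intensities(y, eye), y)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_roundtrip_recovers_truth(self, h3_cm, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.0, 1e6, 6)
        measured = h3_cm.matrix @ x
        recovered = correct_intensities(measured, h3_cm)
        assert np.allclose(recovered, x, rtol=1e-9)

    def test_nnls_matches_triangular_solution(self, h3_cm):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.0, 1e5, 6)
        y = h3_cm.matrix @ x
        assert np.allclose(
            correct_intensities(y, h3_cm, method="nnls"),
            correct_intensities(y, h3_cm),
            rtol=1e-6,
        )

    def test_all_zero_measured(self, h3_cm):
        assert np.allclose(correct_intensities(np.zeros(6), h3_cm), 0.0)

    def test_negative_clamped_and_logged(self, h3_cm, caplog):
        # heavy channel lower than its satellite inflow -> negative solution
        y = np.array([1e6, 0.0, 0.0, 0.0, 0.0, 0.0])
        y[1] = 1.0  # less than the 13C2 satellite of channel 0
        with caplog.at_level("WARNING"):
            x = correct_intensities(y, h3_cm)
        assert np.all(x >= 0)
        assert any("clamped" in r.message for r in caplog.records)

    def test_lightest_channel_ignores_heavier_channels(self, h3_cm):
        y1 = np.array([1e5, 0.0, 0.0, 0.0, 0.0, 0.0])
        y2 = np.array([1e5, 5e5, 3e5, 2e5, 1e5, 9e5])
        x1 = correct_intensities(y1, h3_cm)
        x2 = correct_intensities(y2, h3_cm)
        assert x1[0] == pytest.approx(x2[0], rel=1e-12)

    def test_negative_input_rejected(self, h3_cm):
        with pytest.raises(ValueError, match="non-negative"):
            correct_intensities(np.array([-1.0, 0, 0, 0, 0, 0]), h3_cm)


class TestTables:
    def test_correct_table_roundtrip(self):
        channels, _ = channels_for_peptide(H3_18_26)
        cm = build_correction_matrix(channels)
        rng = np.random.default_rng(3)
        rows = []
        truth = {}
        for t in (0.0, 60.0):
            x = rng.uniform(1e3, 1e6, 6)
            truth[t] = dict(zip(cm.channel_ids, x))
            y = cm.matrix @ x
            for cid, v in zip(cm.channel_ids, y):
                rows.append({"time_min": t, "replicate": 1, "channel_id": cid, "intensity": v})
        out = correct_table(pd.DataFrame(rows), cm)
        for _, r in out.iterrows():
            assert r["intensity_corrected"] == pytest.approx(
                truth[r["time_min"]][r["channel_id"]], rel=1e-9
            )

    def test_missing_channel_rejected(self):
        channels, _ = channels_for_peptide(H3_18_26)
        cm = build_correction_matrix(channels)
        df = pd.DataFrame(
            [{"time_min": 0.0, "replicate": 1, "channel_id": cm.channel_ids[0], "intensity": 1.0}]
        )
        with pytest.raises(ValueError, match="missing channels"):
            correct_table(df, cm)

    @pytest.mark.parametrize(
        "values,expected",
        [([1.0, 1.0, 1.0, 1.0], [25.0] * 4), ([0.0, 7.0, 0.0, 0.0], [0.0, 100.0, 0.0, 0.0])],
    )
    def test_normalize_simple_cases(self, values, expected):
        df = pd.DataFrame({
            "time_min": 0.0, "replicate": 1,
            "channel_id": list("abcd"), "intensity_corrected": values,
        })
        out = normalize_abundances(df)
        assert out["abundance_pct"].tolist() == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=1e8), min_size=2, max_size=10))
    def test_normalize_matches_direct_computation(self, values):
        df = pd.DataFrame({
            "time_min": 0.0, "replicate": 1,
            "channel_id": [f"c{i}" for i in range(len(values))],
            "intensity_corrected": values,
        })
        out = normalize_abundances(df)
        expected = np.array(values) / sum(values) * 100.0
        assert np.allclose(out["abundance_pct"], expected)
        assert out["abundance_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_flagged_not_nan_poisoned(self):
        df = pd.DataFrame({
            "time_min": [0.0, 0.0, 60.0, 60.0], "replicate": 1,
            "channel_id": ["a", "b", "a", "b"],
            "intensity_corrected": [0.0, 0.0, 1.0, 3.0],
        })
        out = normalize_abundances(df)
        assert out.loc[out["time_min"] == 0.0, "missing"].all()
        assert out.loc[out["time_min"] == 60.0, "abundance_pct"].tolist() == [25.0, 75.0]
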