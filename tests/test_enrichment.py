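"""Normalization, medians, pseudocount, fold changes and calls.

The end of the file carries the independent straight-line oracle for
the whole quantitative chain: a pure-Python recomputation that shares
no code with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from modreaders.design import CONDITIONS, MODIFICATIONS
from modreaders.enrichment import (
    ConditionMedians,
    classify_candidates,
    compute_fold_changes,
    compute_pseudocount,
    median_by_condition,
    normalize_total_intensity,
    rank_candidates,
)
from modreaders.pipeline import call_candidates
from tests.conftest import make_records


def _uniform_records(design, rows):
    return make_records(rows, design)


class TestNormalization:
    def test_columns_are_stochastic_and_zeros_preserved(self, design18):
        rows = {"P1": [2.0] * 18, "P2": [2.0] * 18, "P3": [4.0] * 18}
        rows["P2"][0] = 0.0
        norm = normalize_total_intensity(make_records(rows, design18), design18)
        sums = norm.values.sum(axis=0)
        assert np.allclose(sums, 1.0, rtol=1e-9)
        assert norm.values.iloc[1, 0] == 0.0
        # untouched columns: (2, 2, 4) -> (0.25, 0.25, 0.5)
        assert norm.values.iloc[:, 1].tolist() == [0.25, 0.25, 0.5]

    def test_single_positive_entry_gets_full_mass(self, design18):
        rows = {"P1": [5.0] * 18, "P2": [0.0] * 18, "P3": [0.0] * 18}
        norm = normalize_total_intensity(make_records(rows, design18), design18)
        assert norm.values.iloc[:, 0].tolist() == [1.0, 0.0, 0.0]

    def test_all_zero_sample_column_names_the_sample(self, design18):
        rows = {"P1": [1.0] * 18, "P2": [1.0] * 18}
        for r in (rows["P1"], rows["P2"]):
            r[design18.sample_ids.index("f5C_2")] = 0.0
        with pytest.raises(ValueError, match="f5C_2"):
            normalize_total_intensity(make_records(rows, design18), design18)

    def test_scaling_one_sample_leaves_its_fractions_unchanged(self, design18):
        rng = np.random.default_rng(7)
        rows = {f"P{i}": rng.lognormal(0, 1, 18).tolist() for i in range(6)}
        scaled = {g: list(v) for g, v in rows.items()}
        for g in scaled:
            scaled[g][3] *= 10.0
        a = normalize_total_intensity(make_records(rows, design18), design18)
        b = normalize_total_intensity(make_records(scaled, design18), design18)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestMedians:
    @pytest.mark.parametrize(
        "replicate_values, expected",
        [((0.1, 0.2, 0.4), 0.2), ((0.0, 0.0, 0.3), 0.0)],
    )
    def test_odd_replicates(self, design18, replicate_values, expected):
        rows = {"P1": [1.0] * 18, "P2": [1.0] * 18}
        # place the triplet in m5C, keep column totals at 1 via P2
        for v, s in zip(replicate_values, design18.samples_of("m5C")):
            i = design18.sample_ids.index(s)
            rows["P1"][i] = v
            rows["P2"][i] = 1.0 - v
        norm = normalize_total_intensity(make_records(rows, design18), design18)
        med = median_by_condition(norm)
        assert med.values.at["P1", "m5C"] == pytest.approx(expected)

    def test_even_replicate_count_uses_midpoint(self):
        from modreaders.simulate import default_design

        design = default_design(replicates=2)
        rows = {"P1": [1.0] * 12, "P2": [1.0] * 12}
        for v, s in zip((0.1, 0.3), design.samples_of("hm5C")):
            i = design.sample_ids.index(s)
            rows["P1"][i] = v
            rows["P2"][i] = 1.0 - v
        norm = normalize_total_intensity(make_records(rows, design), design)
        med = median_by_condition(norm)
        assert med.values.at["P1", "hm5C"] == pytest.approx(0.2)


class TestPseudocount:
    def _medians(self, values):
        df = pd.DataFrame(
            {c: [values[i]] for i, c in enumerate(CONDITIONS)}, index=["P1"]
        )
        return ConditionMedians(values=df)

    def test_derived_is_min_positive_median_over_100(self):
        med = self._medians([1e-7, 0.0, 5e-6, 2e-5, 3e-4, 1e-3])
        assert compute_pseudocount(med).epsilon == pytest.approx(1e-9)

    def test_derived_excludes_zeros(self):
        med = self._medians([0.0, 0.0, 5e-6, 1e-5, 1e-4, 1e-3])
        assert compute_pseudocount(med).epsilon == pytest.approx(5e-8)

    def test_fixed_mode_is_identity(self):
        med = self._medians([1e-7] * 6)
        eps = compute_pseudocount(med, mode="fixed", value=1e-9)
        assert eps.epsilon == 1e-9

    def test_all_zero_medians_cannot_derive(self):
        med = self._medians([0.0] * 6)
        with pytest.raises(ValueError, match="all medians are zero"):
            compute_pseudocount(med)


class TestFoldChanges:
    def _medians(self, beads, C, m5C):
        df = pd.DataFrame(
            {
                "beads": [beads],
                "C": [C],
                "m5C": [m5C],
                "hm5C": [0.0],
                "hm5Cm": [0.0],
                "f5C": [0.0],
            },
            index=["P1"],
        )
        return ConditionMedians(values=df)

    def test_ratio_against_beads(self):
        fct = compute_fold_changes(self._medians(1e-6, 1e-6, 3e-6), 1e-9)
        assert fct.fc_beads.at["P1", "m5C"] == pytest.approx(3.0, rel=1e-3)

    def test_absent_control_gives_large_finite_ratio(self):
        fct = compute_fold_changes(self._medians(1e-6, 0.0, 1e-6), 1e-9)
        assert fct.fc_unmod.at["P1", "m5C"] == pytest.approx(1001.0, rel=1e-6)

    def test_doubly_absent_protein_sits_at_unity(self):
        fct = compute_fold_changes(self._medians(0.0, 0.0, 0.0), 1e-9)
        assert fct.fc_beads.at["P1", "m5C"] == 1.0
        assert fct.fc_unmod.at["P1", "m5C"] == 1.0

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_fold_changes(self._medians(1e-6, 1e-6, 1e-6), 0.0)


class TestClassification:
    def _fct(self, fc_beads, fc_unmod):
        from modreaders.enrichment import FoldChangeTable

        return FoldChangeTable(
            fc_beads=pd.DataFrame({m: [fc_beads] for m in MODIFICATIONS}, index=["P1"]),
            fc_unmod=pd.DataFrame({m: [fc_unmod] for m in MODIFICATIONS}, index=["P1"]),
        )

    @pytest.mark.parametrize(
        "fc_beads, fc_unmod, strict, expected",
        [
            (2.5, 1.6, False, True),
            (2.5, 1.4, False, False),
            (1.9, 1.6, False, False),
            (2.0, 1.5, False, True),  # inclusive boundary
            (2.0, 1.5, True, False),  # strict boundary
            (2.0 + 1e-12, 1.5 + 1e-12, True, True),
        ],
    )
    def test_dual_threshold_semantics(self, fc_beads, fc_unmod, strict, expected):
        calls = classify_candidates(self._fct(fc_beads, fc_unmod), strict=strict)
        assert bool(calls.at["P1", "m5C"]) is expected

    def test_raising_thresholds_never_adds_candidates(self, design18):
        rng = np.random.default_rng(11)
        rows = {f"P{i}": rng.lognormal(0, 1.5, 18).tolist() for i in range(40)}
        records = make_records(rows, design18)
        _, _, fct, loose, _ = call_candidates(records, design18, 2.0, 1.5)
        tight = classify_candidates(fct, 3.0, 2.0)
        assert ((~loose) & tight).to_numpy().sum() == 0


class TestRanking:
    def _setup(self, medians_m5C, fc_unmod_m5C):
        from modreaders.enrichment import FoldChangeTable

        ids = list(medians_m5C)
        med = pd.DataFrame(
            {c: [medians_m5C[g] if c == "m5C" else 0.0 for g in ids] for c in CONDITIONS},
            index=ids,
        )
        fct = FoldChangeTable(
            fc_beads=pd.DataFrame({m: [9.0] * len(ids) for m in MODIFICATIONS}, index=ids),
            fc_unmod=pd.DataFrame(
                {m: [fc_unmod_m5C[g] for g in ids] for m in MODIFICATIONS}, index=ids
            ),
        )
        calls = pd.DataFrame({m: [True] * len(ids) for m in MODIFICATIONS}, index=ids)
        return fct, calls, ConditionMedians(values=med)

    def test_descending_bait_median(self):
        fct, calls, med = self._setup({"A": 0.1, "B": 0.4}, {"A": 2.0, "B": 2.0})
        assert rank_candidates(fct, calls, med, "m5C") == ["B", "A"]

    def test_fold_change_breaks_median_ties(self):
        fct, calls, med = self._setup({"A": 0.2, "B": 0.2}, {"A": 2.0, "B": 3.0})
        assert rank_candidates(fct, calls, med, "m5C") == ["B", "A"]

    def test_group_id_breaks_remaining_ties(self):
        fct, calls, med = self._setup({"B": 0.2, "A": 0.2}, {"A": 2.0, "B": 2.0})
        assert rank_candidates(fct, calls, med, "m5C") == ["A", "B"]

    def test_empty_candidate_set(self):
        fct, calls, med = self._setup({"A": 0.1}, {"A": 2.0})
        calls[:] = False
        assert rank_candidates(fct, calls, med, "m5C") == []


def test_pseudocount_size_does_not_flip_calls_on_positive_tables(design18):
    """With all medians positive, calls converge as epsilon shrinks."""
    rng = np.random.default_rng(3)
    rows = {f"P{i}": (rng.lognormal(0, 1, 18) + 0.1).tolist() for i in range(20)}
    records = make_records(rows, design18)
    for eps in (1e-9, 1e-12):
        _, _, fct, calls, _ = call_candidates(
            records, design18, pseudocount_mode="fixed", pseudocount_value=eps
        )
        if eps == 1e-9:
            reference = calls
    pd.testing.assert_frame_equal(reference, calls)


# --- independent straight-line oracle (no shared code) -----------------

def straight_line_chain(raw: dict[str, list[float]], sample_conditions: list[str],
                        t_beads: float = 2.0, t_unmod: float = 1.5):
    """Pure-Python recomputation of the whole quantitative chain."""

    def median(xs):
        xs = sorted(xs)
        n = len(xs)
        mid = n // 2
        return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0

    n_samples = len(sample_conditions)
    totals = [sum(raw[g][j] for g in raw) for j in range(n_samples)]
    norm = {g: [raw[g][j] / totals[j] for j in range(n_samples)] for g in raw}
    conditions = ("beads", "C", "m5C", "hm5C", "hm5Cm", "f5C")
    med = {
        g: {
            c: median([norm[g][j] for j in range(n_samples) if sample_conditions[j] == c])
            for c in conditions
        }
        for g in raw
    }
    positives = [m for g in raw for m in med[g].values() if m > 0]
    eps = min(positives) / 100.0
    fc, calls = {}, {}
    for g in raw:
        fc[g] = {}
        calls[g] = {}
        for mod in ("m5C", "hm5C", "hm5Cm", "f5C"):
            fb = (med[g][mod] + eps) / (med[g]["beads"] + eps)
            fu = (med[g][mod] + eps) / (med[g]["C"] + eps)
            fc[g][mod] = (fb, fu)
            calls[g][mod] = fb >= t_beads and fu >= t_unmod
    return eps, fc, calls


def test_chain_matches_straight_line_oracle(design18):
    rng = np.random.default_rng(42)
    rows = {f"P{i}": rng.lognormal(0, 2, 18).tolist() for i in range(10)}
    conditions = [design18.condition_of(s) for s in design18.sample_ids]

    eps_o, fc_o, calls_o = straight_line_chain(rows, conditions)
    records = make_records(rows, design18)
    medians, eps, fct, calls, _ = call_candidates(records, design18)

    assert eps.epsilon == pytest.approx(eps_o, rel=1e-12)
    for g in rows:
        for mod in MODIFICATIONS:
            fb, fu = fc_o[g][mod]
            assert fct.fc_beads.at[g, mod] == pytest.approx(fb, rel=1e-12)
            assert fct.fc_unmod.at[g, mod] == pytest.approx(fu, rel=1e-12)
            assert bool(calls.at[g, mod]) is calls_o[g][mod]
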