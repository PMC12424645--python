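"""Wildtype normalization, dominant-negative rule, core-motif calling,
variant impact classification, titration fitting, and heatmap scaling."""

import numpy as np
import pandas as pd
import pytest

import abepitope as ab
from abepitope.analysis import DmsMatrix

from conftest import brute_force_core_positions


def make_matrix(ratio_rows, wt_sequence, abeta_start=None, antibody="ab"):
    """DmsMatrix from {position: {letter: ratio}} rows."""
    letters = sorted(ab.AMINO_ACIDS)
    idx = pd.RangeIndex(1, len(wt_sequence) + 1, name="position")
    ratios = pd.DataFrame(np.nan, index=idx, columns=letters)
    for pos, row in ratio_rows.items():
        for letter, r in row.items():
            ratios.at[pos, letter] = r
    return DmsMatrix(
        antibody=antibody,
        wt_sequence=wt_sequence,
        ratios=ratios,
        wt_mean=1000.0,
        abeta_start=abeta_start,
    )


def full_random_matrix(rng, length=6):
    wt = "".join(rng.choice(list(ab.AMINO_ACIDS), size=length))
    rows = {}
    for pos in range(1, length + 1):
        rows[pos] = {
            letter: float(rng.uniform(0, 1.5))
            for letter in ab.AMINO_ACIDS
            if letter != wt[pos - 1]
        }
    return rows, wt


class TestNormalization:
    def test_ratio_arithmetic(self):
        lib = ab.positional_scan("DA")
        sub_id = next(p.probe_id for p in lib if p.role == "substitution")
        rows = [
            {"probe_id": "scan:wt", "antibody": "ab", "replicate": 1, "intensity": 900},
            {"probe_id": "scan:wt", "antibody": "ab", "replicate": 2, "intensity": 1100},
        ]
        for p in lib:
            if p.role != "substitution":
                continue
            v = 400 if p.probe_id == sub_id else 800
            for rep in (1, 2):
                rows.append(
                    {"probe_id": p.probe_id, "antibody": "ab", "replicate": rep, "intensity": v}
                )
        table = pd.DataFrame(rows)
        m = ab.normalize_to_wildtype(table, lib, "ab")
        probe = lib[sub_id]
        assert m.ratio(probe.wt_position, probe.substitution) == pytest.approx(0.4)
        assert m.wt_mean == pytest.approx(1000.0)

    def test_wildtype_below_floor_refused(self):
        lib = ab.positional_scan("DA")
        rows = []
        for p in lib:
            v = 0.0 if p.role == "wildtype" else 1000.0
            rows.append(
                {"probe_id": p.probe_id, "antibody": "ab", "replicate": 1, "intensity": v}
            )
        with pytest.raises(ValueError, match="below floor"):
            ab.normalize_to_wildtype(pd.DataFrame(rows), lib, "ab")

    def test_negative_intensities_rejected(self):
        df = pd.DataFrame(
            [{"probe_id": "x", "antibody": "ab", "replicate": 1, "intensity": -1.0}]
        )
        with pytest.raises(ValueError):
            ab.normalize_to_wildtype(df, ab.positional_scan("DA"), "ab")

    def test_scale_invariance_of_downstream_calls(self, noiseless_dms):
        truth, table, library, _ = noiseless_dms
        m1 = ab.normalize_to_wildtype(table, library, "synthetic-ab")
        scaled = table.copy()
        scaled["intensity"] *= 37.5
        m2 = ab.normalize_to_wildtype(scaled, library, "synthetic-ab")
        pd.testing.assert_frame_equal(m1.ratios, m2.ratios)
        assert ab.call_core_motif(m1).to_dict() == ab.call_core_motif(m2).to_dict()


class TestDominantNegativeRule:
    def test_strict_threshold_boundary(self):
        m = make_matrix({1: {"V": 0.49, "T": 0.50, "G": 1.2}}, "A")
        flags = ab.call_dominant_negative(m)
        assert bool(flags.at[1, "V"]) is True  # reduced by more than 50%
        assert bool(flags.at[1, "T"]) is False  # exactly 50% is not "more than"
        assert bool(flags.at[1, "G"]) is False  # gain of binding never flagged

    def test_wildtype_cells_never_flagged(self):
        m = make_matrix({1: {l: 0.0 for l in ab.AMINO_ACIDS if l != "A"}}, "A")
        flags = ab.call_dominant_negative(m)
        assert not bool(flags.at[1, "A"])
        assert int(flags.sum().sum()) == 19

    def test_monotonicity_lower_ratios_only_add_flags(self):
        rng = np.random.default_rng(11)
        rows, wt = full_random_matrix(rng)
        m_hi = make_matrix(rows, wt)
        lowered = {p: {l: r * 0.5 for l, r in row.items()} for p, row in rows.items()}
        m_lo = make_matrix(lowered, wt)
        f_hi = ab.call_dominant_negative(m_hi)
        f_lo = ab.call_dominant_negative(m_lo)
        assert bool((f_lo | f_hi).equals(f_lo))  # flags(hi) subset of flags(lo)


class TestCoreMotif:
    def _matrix_with_counts(self, counts):
        """One-letter-wildtype matrix with a given dominant-negative count per position."""
        wt = "A" * len(counts)
        rows = {}
        for pos, n in enumerate(counts, start=1):
            letters = [l for l in ab.AMINO_ACIDS if l != "A"]
            rows[pos] = {l: (0.1 if i < n else 0.9) for i, l in enumerate(letters)}
        return make_matrix(rows, wt)

    def test_ten_of_nineteen_is_core_nine_is_not(self):
        m = self._matrix_with_counts([10, 9])
        motif = ab.call_core_motif(m)
        assert motif.core_positions == [1]
        assert motif.motif == "AX"
        assert motif.counts == [10, 9]

    def test_threshold_is_configurable(self):
        m = self._matrix_with_counts([10, 9])
        assert ab.call_core_motif(m, min_count=9).core_positions == [1, 2]
        assert ab.call_core_motif(m, min_count=11).core_positions == []

    def test_core_set_grows_as_count_threshold_decreases(self):
        rng = np.random.default_rng(5)
        rows, wt = full_random_matrix(rng, length=8)
        m = make_matrix(rows, wt)
        previous: set = set()
        for min_count in range(19, 0, -1):
            current = set(ab.call_core_motif(m, min_count=min_count).core_positions)
            assert previous <= current
            previous = current

    def test_planted_core_recovered_exactly_without_noise(self, noiseless_dms):
        truth, table, library, _ = noiseless_dms
        m = ab.normalize_to_wildtype(table, library, "synthetic-ab")
        motif = ab.call_core_motif(m)
        assert motif.coordinates == "abeta"
        assert motif.core_positions == sorted(truth.core_positions)
        expected = "".join(
            truth.wt_sequence[i] if (i + 1) in truth.core_positions else "X"
            for i in range(len(truth.wt_sequence))
        )
        assert motif.motif == expected

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            rows, wt = full_random_matrix(rng, length=int(rng.integers(2, 7)))
            m = make_matrix(rows, wt)
            assert ab.call_core_motif(m).core_positions == brute_force_core_positions(rows)


class TestVariantImpact:
    def test_known_variant_classifications(self):
        scan = {}
        wt = "DAEFRHDSGYEVHHQKLV"  # Abeta 1-18
        for pos in range(1, 19):
            scan[pos] = {
                l: 0.9 for l in ab.AMINO_ACIDS if l != wt[pos - 1]
            }
        scan[6]["R"] = 0.05  # the English mutation abolishes binding
        m = make_matrix(scan, wt, abeta_start=1)
        report = {e["variant"]: e for e in ab.variant_impact_report(m)}
        assert report["H6R"]["classification"] == "binding-reducing"
        assert report["R5G"]["classification"] == "tolerated"
        assert report["Y10F"]["classification"] == "tolerated"

    def test_variant_outside_scan_not_covered(self):
        wt = "DAEFRHDSGYEVHHQKLV"
        m = make_matrix(
            {p: {l: 0.9 for l in ab.AMINO_ACIDS if l != wt[p - 1]} for p in range(1, 19)},
            wt,
            abeta_start=1,
        )
        report = {e["variant"]: e for e in ab.variant_impact_report(m, variants={"X25A": (25, "A")})}
        assert report["X25A"]["classification"] == "not covered"

    def test_core_membership_annotated(self, noiseless_dms):
        truth, table, library, _ = noiseless_dms
        m = ab.normalize_to_wildtype(table, library, "synthetic-ab")
        motif = ab.call_core_motif(m)
        report = {e["variant"]: e for e in ab.variant_impact_report(m, motif)}
        assert report["H6R"]["in_core_motif"] is True  # position 6 is in the planted core
        assert report["K16Q"]["in_core_motif"] is False


class TestTitrationFit:
    def test_round_trip_on_noiseless_boltzmann(self):
        series, rec = ab.simulate_titration(
            [1e-12 * 10 ** (k / 2) for k in range(13)], bottom=0.1, top=0.9,
            ec50=3e-10, slope=0.4,
        )
        fit = ab.fit_titration(series["concentration"], series["response"])
        assert fit.converged and not fit.no_transition
        assert fit.ec50 == pytest.approx(3e-10, rel=0.01)
        assert fit.top == pytest.approx(0.9, rel=0.01)

    def test_midpoint_value_is_half_transition(self):
        series, _ = ab.simulate_titration(
            [1e-12 * 10 ** (k / 2) for k in range(13)], ec50=1e-9
        )
        fit = ab.fit_titration(series["concentration"], series["response"])
        assert fit.predict([fit.ec50])[0] == pytest.approx(
            (fit.top + fit.bottom) / 2, rel=1e-6
        )

    def test_flat_series_flagged_no_transition(self):
        conc = [1e-12 * 10 ** k for k in range(6)]
        fit = ab.fit_titration(conc, [0.7] * 6)
        assert fit.no_transition
        assert fit.ec50 is None

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ab.fit_titration([1e-9, 2e-9, 3e-9, 4e-9], [0, 1, 2, 3])  # too few
        with pytest.raises(ValueError):
            ab.fit_titration([1e-9, 2e-9, 3e-9, 4e-9, 5e-9], [0, 1, 2, 3, 4])  # < 1 decade

    def test_selectivity_ratio(self):
        grid = [1e-12 * 10 ** (k / 2) for k in range(13)]
        series_a, _ = ab.simulate_titration(grid, ec50=1e-8)
        series_b, _ = ab.simulate_titration(grid, ec50=1e-10)
        fit_a = ab.fit_titration(series_a["concentration"], series_a["response"])
        fit_b = ab.fit_titration(series_b["concentration"], series_b["response"])
        assert ab.selectivity_ratio(fit_a, fit_b) == pytest.approx(100.0, rel=0.02)


class TestHeatmap:
    def test_min_max_arithmetic(self):
        df = pd.DataFrame({"ab1": [0.0, 50.0, 100.0]})
        out = ab.heatmap_matrix(df)
        assert list(out["ab1"]) == [0.0, 0.5, 1.0]

    def test_scale_invariance(self):
        df = pd.DataFrame({"ab1": [1.0, 5.0, 9.0]})
        pd.testing.assert_frame_equal(ab.heatmap_matrix(df), ab.heatmap_matrix(df * 123.0))

    def test_antibodies_scaled_independently(self):
        df = pd.DataFrame({"weak": [0.0, 5.0, 10.0], "strong": [0.0, 5000.0, 10000.0]})
        out = ab.heatmap_matrix(df)
        pd.testing.assert_series_equal(out["weak"], out["strong"], check_names=False)

    def test_flat_profile_warns_and_zeros(self):
        df = pd.DataFrame({"flat": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning, match="flat profile"):
            out = ab.heatmap_matrix(df)
        assert (out["flat"] == 0.0).all()
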