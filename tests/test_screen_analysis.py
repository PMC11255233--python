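"""Replicate aggregation, ranked curve, extreme detection, property sums."""

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pepscreen.array_layout import GridSpec, build_layout
from pepscreen.constants import AMINO_ACIDS, BLANK_ID
from pepscreen.library_design import PeptideEntry
from pepscreen.quantification import SpotQuantification, quantifications_from_table
from pepscreen.scan_simulator import (
    assign_latent_adhesion,
    make_synthetic_screen,
    random_peptides,
    simulate_intensity_table,
)
from pepscreen.screen_analysis import (
    PeptideMeasurement,
    aggregate_replicates,
    blank_floor_threshold,
    compute_property_profile,
    correlate_properties,
    detect_extremes,
    rank_curve,
)

WATER = 18.0153


def quant(pid, value, spot="s"):
    return SpotQuantification(
        spot_id=spot, peptide_id=pid, median_intensity=float(value),
        pixel_count=16, background_estimate=0.0,
    )


def measurements_from(values_by_id):
    return [
        PeptideMeasurement.from_replicates(pid, vals) for pid, vals in values_by_id.items()
    ]


class TestAggregateReplicates:
    def test_median_is_robust_to_one_outlier(self):
        meas, _ = aggregate_replicates(
            [quant("p", 5, "a"), quant("p", 7, "b"), quant("p", 100, "c")]
        )
        assert meas[0].intensity == 7.0

    def test_even_count_uses_central_pair_mean(self):
        meas, _ = aggregate_replicates([quant("p", 4, "a"), quant("p", 6, "b")])
        assert meas[0].intensity == 5.0

    def test_blanks_pool_under_single_id(self):
        meas, _ = aggregate_replicates(
            [quant(BLANK_ID, 10, "a"), quant("BLK_1", 20, "b"), quant("x", 7, "c")],
            blank_ids=frozenset({"BLK_1"}),
        )
        by_id = {m.peptide_id: m for m in meas}
        assert by_id[BLANK_ID].replicate_intensities == (10.0, 20.0)

    def test_noise_free_simulation_identity(self):
        """With zero replicate noise, Int. equals background + latent adhesion."""
        lib = [
            PeptideEntry(peptide_id=f"N{i}", sequence=s, group="random", replicates=3)
            for i, s in enumerate(random_peptides(25, seed=1))
        ]
        layout = build_layout(lib, GridSpec(grid_rows=9, grid_cols=9, seed=2))
        model = assign_latent_adhesion(lib, sigma_rep=0.0, background=300.0, seed=3)
        meas, _ = aggregate_replicates(
            quantifications_from_table(simulate_intensity_table(layout, model))
        )
        for m in meas:
            expected = 300.0 if m.peptide_id == BLANK_ID else 300.0 + model.a[m.peptide_id]
            assert m.intensity == pytest.approx(expected)


class TestRankCurve:
    def test_sorted_non_decreasing_with_gradient(self):
        meas = measurements_from({"a": [3.0], "b": [1.0], "c": [2.0]})
        curve = rank_curve(meas)
        assert curve.peptide_ids == ["b", "c", "a"]
        assert np.all(np.diff(curve.intensities) >= 0)
        assert np.allclose(curve.gradient, [1.0, 1.0])

    def test_equal_intensities_give_zero_gradient_and_id_tiebreak(self):
        meas = measurements_from({"z": [5.0], "a": [5.0]})
        curve = rank_curve(meas)
        assert curve.peptide_ids == ["a", "z"]
        assert np.all(curve.gradient == 0)

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            rank_curve(measurements_from({"a": [1.0]}))

    def test_simulated_maximum_gradients_sit_in_the_edge_five_percent(self):
        _, layout, model = make_synthetic_screen(
            n_peptides=600, n_repulsive=30, n_adhesive=6, seed=17, sigma_rep=0.05
        )
        table = simulate_intensity_table(layout, model)
        meas, _ = aggregate_replicates(quantifications_from_table(table))
        curve = rank_curve([m for m in meas if m.peptide_id != BLANK_ID])
        top2 = np.argsort(curve.gradient)[-2:]
        n = len(curve)
        assert all(i < 0.05 * n or i > 0.95 * n - 1 for i in top2)


class TestDetectExtremes:
    def test_planted_floor_recovered_exactly(self):
        _, layout, model = make_synthetic_screen(
            n_peptides=1000, n_repulsive=20, n_adhesive=0, seed=19, sigma_rep=0.05
        )
        table = simulate_intensity_table(layout, model)
        meas, _ = aggregate_replicates(quantifications_from_table(table))
        curve = rank_curve([m for m in meas if m.peptide_id != BLANK_ID])
        calls, report = detect_extremes(curve)
        repulsive = {c.peptide_id for c in calls if c.side == "repulsive"}
        assert repulsive == set(model.planted_repulsive)
        assert report["boundary_low"] == 20

    def test_planted_top_set_is_recovered_on_the_adhesive_side(self):
        _, layout, model = make_synthetic_screen(
            n_peptides=1000, n_repulsive=0, n_adhesive=10, seed=23, sigma_rep=0.05
        )
        table = simulate_intensity_table(layout, model)
        meas, _ = aggregate_replicates(quantifications_from_table(table))
        curve = rank_curve([m for m in meas if m.peptide_id != BLANK_ID])
        calls, _ = detect_extremes(curve)
        adhesive = {c.peptide_id for c in calls if c.side == "adhesive"}
        assert set(model.planted_adhesive) <= adhesive

    def test_uniform_intensities_give_zero_calls_without_fallback(self):
        meas = measurements_from({f"u{i}": [7.0] for i in range(100)})
        calls, report = detect_extremes(rank_curve(meas), fallback="none")
        assert calls == []
        assert report["boundary_low"] == 0

    def test_quantile_method_is_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(8, 1, size=200)
        meas = measurements_from({f"m{i:03d}": [v] for i, v in enumerate(values)})
        c1, _ = detect_extremes(rank_curve(meas), method="quantile")
        transformed = measurements_from(
            {f"m{i:03d}": [np.expm1(v / values.max() * 4)] for i, v in enumerate(values)}
        )
        c2, _ = detect_extremes(rank_curve(transformed), method="quantile")
        assert {(c.peptide_id, c.side) for c in c1} == {(c.peptide_id, c.side) for c in c2}

    def test_too_few_peptides_for_window_is_an_error(self):
        meas = measurements_from({"a": [1.0], "b": [2.0], "c": [3.0]})
        with pytest.raises(ValueError, match="shorter than the edge windows"):
            detect_extremes(rank_curve(meas), q_low=0.05, q_high=0.95)


class TestPropertyProfile:
    def test_uncharged_sequence(self):
        assert compute_property_profile("GGG").total_charge == 0.0

    def test_parent_peptide_net_charge(self):
        # K + R + R (+3) and E + E (-2) -> net +1
        assert compute_property_profile("KEQWFGNRWHEGYR").total_charge == 1.0

    def test_hydropathy_sum_for_triple_isoleucine(self):
        assert compute_property_profile("III").sh == pytest.approx(13.5)

    def test_empty_sequence_is_all_zeros(self):
        prof = compute_property_profile("")
        assert (prof.total_charge, prof.total_mw, prof.sh, prof.hp) == (0, 0, 0, 0)

    def test_unknown_residue_is_an_error(self):
        with pytest.raises(ValueError, match="non-canonical"):
            compute_property_profile("ACX")

    def test_total_mw_matches_biopython(self):
        for seq in random_peptides(10, 12, seed=8):
            ours = compute_property_profile(seq).total_mw
            ref = molecular_weight(seq, seq_type="protein", monoisotopic=False)
            assert ours == pytest.approx(ref, rel=1e-4)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        s1=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=20),
        s2=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=20),
    )
    def test_additivity_under_concatenation(self, s1, s2):
        p1, p2, p12 = (compute_property_profile(s) for s in (s1, s2, s1 + s2))
        assert p12.total_charge == pytest.approx(p1.total_charge + p2.total_charge)
        assert p12.sh == pytest.approx(p1.sh + p2.sh)
        assert p12.hp == pytest.approx(p1.hp + p2.hp)
        # MW carries one water per peptide, so concatenation saves exactly one
        assert p12.total_mw == pytest.approx(p1.total_mw + p2.total_mw - WATER)


class TestCorrelateProperties:
    def test_profile_equal_to_intensity_gives_rho_one(self):
        meas = measurements_from({f"c{i}": [float(i)] for i in range(30)})
        profiles = [
            compute_property_profile("G" * (i + 1), peptide_id=f"c{i}") for i in range(30)
        ]
        # charge stays 0; use MW which grows with length, i.e. with intensity
        report, _ = correlate_properties(meas, profiles, n_permutations=99, seed=0)
        mw_row = report.set_index("property").loc["total_mw"]
        assert mw_row["spearman_rho"] == pytest.approx(1.0)
        assert mw_row["p_permutation"] <= 0.02

    def test_independent_profiles_have_small_rho(self):
        rng = np.random.default_rng(11)
        seqs = random_peptides(150, seed=12)
        meas = measurements_from({f"r{i}": [float(v)] for i, v in enumerate(rng.lognormal(8, 1, 150))})
        profiles = [compute_property_profile(s, peptide_id=f"r{i}") for i, s in enumerate(seqs)]
        report, scatter = correlate_properties(meas, profiles, n_permutations=199, seed=13)
        assert (report["spearman_rho"].abs() < 0.25).all()
        assert (report["p_permutation"] > 0.01).all()
        assert len(scatter) == 4 * 150

    def test_constructed_hydrophobicity_trend_reproduced(self):
        """Adhesion built to rise with SH (and fall with HP by construction)
        yields rho(SH) > 0 and rho(HP) < 0."""
        seqs = ["I" * k + "G" * (15 - k) for k in range(1, 15)]
        profiles = [compute_property_profile(s, peptide_id=s) for s in seqs]
        meas = measurements_from({p.peptide_id: [1000.0 + 100.0 * p.sh] for p in profiles})
        report, _ = correlate_properties(meas, profiles, n_permutations=199, seed=14)
        by_prop = report.set_index("property")
        assert by_prop.loc["sh", "spearman_rho"] > 0.9
        assert by_prop.loc["hp", "spearman_rho"] < -0.9

    def test_fewer_than_three_pairs_is_an_error(self):
        meas = measurements_from({"a": [1.0], "b": [2.0]})
        profiles = [compute_property_profile("AC", peptide_id=p) for p in ("a", "b")]
        with pytest.raises(ValueError, match=">= 3"):
            correlate_properties(meas, profiles)


def test_blank_floor_threshold_median_plus_two_mads():
    # median 13, absolute deviations {3, 1, 1, 87} -> MAD 2 -> 13 + 2*2
    assert blank_floor_threshold([10.0, 12.0, 14.0, 100.0]) == pytest.approx(17.0)
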