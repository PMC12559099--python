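import json

import numpy as np
import pandas as pd
import pytest

from huiharm import reference as ref
from huiharm.harmonization import (
    CohortTable,
    HarmonizationModel,
    ScannerCalibration,
    build_model,
    calibrate_scanners,
    choose_reference,
    commutability_report,
    derive_cf3,
    distribution_analysis,
    estimate_icg_pdr,
    harmonize_cohort,
    harmonize_hui,
)
from huiharm.simulate import ScannerSpec, SimulationConfig, simulate_cohort
from huiharm.stats import ci_overlap


def noiseless_config(gains, n=40, seed=0, route_ratio=ref.CF3):
    scanners = [ScannerSpec(f"S{i}", g, n) for i, g in enumerate(gains)]
    return SimulationConfig(
        scanners=scanners,
        reference_scanner_id="S0",
        noise_sd_icg=0.0,
        noise_sd_albi=0.0,
        noise_sd_hui_meas=0.0,
        route_ratio=route_ratio,
        seed=seed,
    )


@pytest.fixture
def noiseless_cohort():
    return simulate_cohort(noiseless_config([1.0, 2.0, 0.5])).cohort


class TestChooseReference:
    def test_largest_group_wins(self):
        df = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(227)],
                "scanner_id": ["A"] * 31 + ["T"] * 196,
                "hui": 1.0,
            }
        )
        assert choose_reference(CohortTable(df)) == "T"

    def test_single_scanner(self):
        df = pd.DataFrame({"patient_id": ["1"], "scanner_id": ["X"], "hui": [1.0]})
        assert choose_reference(CohortTable(df)) == "X"

    def test_lexicographic_tiebreak(self):
        df = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(10)],
                "scanner_id": ["B"] * 5 + ["A"] * 5,
                "hui": 1.0,
            }
        )
        assert choose_reference(CohortTable(df)) == "A"

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            choose_reference(CohortTable(pd.DataFrame(
                {"patient_id": [], "scanner_id": [], "hui": []})))


class TestCalibrateScanners:
    def test_zero_noise_gain_two(self, noiseless_cohort):
        cal = calibrate_scanners(noiseless_cohort, "S0")
        assert cal["S0"].fit_icg.slope == pytest.approx(ref.SLOPE1)
        # scanner gain 2 halves the slope and the conversion factor
        assert cal["S1"].fit_icg.slope == pytest.approx(ref.SLOPE1 / 2)
        assert cal["S1"].cf1 == pytest.approx(0.5)
        assert cal["S2"].cf1 == pytest.approx(2.0)

    def test_reference_has_unit_cfs(self, noiseless_cohort):
        cal = calibrate_scanners(noiseless_cohort, "S0")
        assert cal["S0"].cf1 == 1.0
        assert cal["S0"].cf2 == 1.0
        assert cal["S0"].is_reference

    def test_published_cf2_ratio(self):
        # Avanto ALBI-route slope over the reference slope
        assert round(-1.402 / ref.SLOPE1_PRIME, 3) == 0.984

    def test_small_scanner_marked_uncalibratable(self, noiseless_cohort):
        extra = pd.DataFrame(
            {
                "patient_id": ["x1", "x2", "x3"],
                "scanner_id": "tiny",
                "hui": [1.0, 1.1, 0.9],
                "icg_pdr": [-0.17, -0.18, -0.16],
                "albi_lp": [-1.4, -1.5, -1.3],
            }
        )
        cohort = CohortTable(pd.concat([noiseless_cohort.df, extra]))
        cal = calibrate_scanners(cohort, "S0", min_n=10)
        assert cal["tiny"].cf1 is None
        assert cal["tiny"].cf2 is None

    def test_missing_reference_errors(self, noiseless_cohort):
        with pytest.raises(ValueError, match="reference"):
            calibrate_scanners(noiseless_cohort, "nope")


def make_cal(sid, cf1, cf2, is_reference=False):
    return ScannerCalibration(sid, None, None, cf1, cf2, is_reference)


class TestDeriveCf3:
    def test_published_pairs(self):
        cf1s, cf2s = ref.non_reference_cf_pairs()
        cals = [make_cal(f"s{i}", a, b) for i, (a, b) in enumerate(zip(cf1s, cf2s))]
        cals.append(make_cal("ref", 1.0, 1.0, is_reference=True))
        cf3, fit = derive_cf3(cals)
        assert round(cf3, 3) == 0.955
        assert fit.p_value < 0.001
        # regression form differs from the mean-of-ratios estimator
        mean_ratio = np.mean([a / b for a, b in zip(cf1s, cf2s)])
        assert round(mean_ratio, 3) == 0.957
        assert cf3 != pytest.approx(mean_ratio, abs=1e-4)

    def test_identity_when_equal(self):
        cals = [make_cal(f"s{i}", v, v) for i, v in enumerate([0.7, 0.9, 1.1])]
        cf3, _ = derive_cf3(cals)
        assert cf3 == pytest.approx(1.0)

    def test_exact_proportionality(self):
        cals = [make_cal(f"s{i}", 0.9 * v, v) for i, v in enumerate([0.7, 0.9, 1.1])]
        cf3, _ = derive_cf3(cals)
        assert cf3 == pytest.approx(0.9)

    def test_reference_excluded(self):
        cals = [
            make_cal("ref", 1.0, 1.0, is_reference=True),
            make_cal("a", 0.45, 0.5),
            make_cal("b", 0.72, 0.8),
        ]
        cf3, _ = derive_cf3(cals)
        assert cf3 == pytest.approx(0.9)

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            derive_cf3([make_cal("a", 0.9, 1.0)])


def fixture_model(slope2_prime=-1.402):
    """Model with the published reference constants and one extra scanner."""
    cals = {
        "Trio Tim": ScannerCalibration("Trio Tim", None, None, 1.0, 1.0, True),
        "Avanto": ScannerCalibration(
            "Avanto", None, None, 0.930, slope2_prime / ref.SLOPE1_PRIME, False
        ),
        "NoIcg": ScannerCalibration("NoIcg", None, None, None, 0.8, False),
    }
    return HarmonizationModel(
        reference_scanner_id="Trio Tim",
        slope1=ref.SLOPE1,
        slope1_prime=ref.SLOPE1_PRIME,
        cf3=ref.CF3,
        calibrations=cals,
    )


class TestHarmonizeAndEstimate:
    def test_reference_icg_route_is_identity(self):
        model = fixture_model()
        assert harmonize_hui(0.8, "Trio Tim", model, route="icg") == pytest.approx(0.8)

    def test_albi_route_formula(self):
        model = fixture_model()
        got = harmonize_hui(1.0, "Avanto", model, route="albi")
        assert got == pytest.approx((-1.402 / -1.425) * 0.955)
        assert got == pytest.approx(0.984 * 0.955, abs=5e-4)

    def test_zero_hui(self):
        model = fixture_model()
        assert harmonize_hui(0.0, "Avanto", model, route="icg") == 0.0
        assert harmonize_hui(0.0, "Avanto", model, route="albi") == 0.0

    def test_missing_route_errors_name_scanner(self):
        model = fixture_model()
        with pytest.raises(ValueError, match="NoIcg"):
            harmonize_hui(1.0, "NoIcg", model, route="icg")
        # the ALBI route must still work for ICG-less scanners
        assert harmonize_hui(1.0, "NoIcg", model, route="albi") == pytest.approx(
            0.8 * ref.CF3
        )

    def test_unknown_scanner_and_route(self):
        model = fixture_model()
        with pytest.raises(KeyError):
            harmonize_hui(1.0, "ghost", model)
        with pytest.raises(ValueError, match="route"):
            harmonize_hui(1.0, "Avanto", model, route="xyz")

    def test_estimate_icg_pdr_constants(self):
        model = fixture_model()
        assert estimate_icg_pdr(1.0, model) == pytest.approx(-0.173)
        assert estimate_icg_pdr(0.0, model) == 0.0
        assert estimate_icg_pdr(0.925, model) == pytest.approx(-0.160, abs=5e-4)


class TestRoundTripProperties:
    def test_zero_noise_round_trip_recovers_reference_scale(self):
        syn = simulate_cohort(noiseless_config([1.0, 2.0, 0.5, 1.3]))
        model = build_model(syn.cohort, reference="S0", min_n=2)
        hdf = harmonize_cohort(syn.cohort, model, route="icg")
        latent = syn.truth.set_index("patient_id")["latent_hui"]
        np.testing.assert_allclose(
            hdf.set_index("patient_id")["h_hui"], latent[hdf["patient_id"]], rtol=1e-9
        )
        report = commutability_report(syn.cohort, model, route="icg")
        # CIs degenerate to points here, so only slope equality is meaningful
        for entry in report.values():
            assert entry["fit"].slope == pytest.approx(ref.SLOPE1, abs=1e-12)

    def test_route_consistency_when_cf1_equals_cf2_cf3(self):
        # premise cf1 == cf2 * cf3 for *every* scanner holds when the two
        # assay routes share one proportionality (route_ratio = 1)
        syn = simulate_cohort(noiseless_config([1.0, 2.0, 0.5], route_ratio=1.0))
        model = build_model(syn.cohort, reference="S0", min_n=2)
        for scanner, cal in model.calibrations.items():
            assert cal.cf1 == pytest.approx(cal.cf2 * model.cf3, rel=1e-9)
        icg = harmonize_cohort(syn.cohort, model, route="icg")["h_hui"]
        albi = harmonize_cohort(syn.cohort, model, route="albi")["h_hui"]
        np.testing.assert_allclose(icg, albi, rtol=1e-9)

    def test_albi_route_identity_for_non_reference_scanners(self):
        # with a route discrepancy, cf1 == cf2 * cf3 still holds off-reference
        syn = simulate_cohort(noiseless_config([1.0, 2.0, 0.5]))
        model = build_model(syn.cohort, reference="S0", min_n=2)
        for scanner, cal in model.calibrations.items():
            if not cal.is_reference:
                assert cal.cf1 == pytest.approx(cal.cf2 * model.cf3, rel=1e-9)
        hdf = harmonize_cohort(syn.cohort, model, route="albi")
        off_ref = hdf[hdf["scanner_id"] != "S0"]
        icg = harmonize_cohort(syn.cohort, model, route="icg")
        np.testing.assert_allclose(
            off_ref["h_hui"],
            icg[icg["scanner_id"] != "S0"]["h_hui"],
            rtol=1e-9,
        )

    def test_reference_invariance(self):
        syn = simulate_cohort(noiseless_config([1.0, 2.0]))
        model = build_model(syn.cohort, reference="S0", min_n=2)
        cal = model.calibrations["S0"]
        assert cal.cf1 == 1.0 and cal.cf2 == 1.0
        sub = harmonize_cohort(syn.cohort, model, route="icg")
        s0 = sub[sub["scanner_id"] == "S0"]
        np.testing.assert_allclose(s0["h_hui"], s0["hui"], rtol=1e-12)


class TestCommutabilityMonteCarlo:
    """Stochastic behaviour at realistic noise, over seeded replicates."""

    N_REP = 25

    def _replicates(self):
        from huiharm.simulate import paper_default_config

        for seed in range(self.N_REP):
            cfg = paper_default_config(seed=seed)
            yield simulate_cohort(cfg)

    def test_harmonized_cis_overlap_reference(self):
        ok = 0
        total = 0
        for syn in self._replicates():
            model = build_model(syn.cohort)
            report = commutability_report(syn.cohort, model, route="albi")
            for scanner, entry in report.items():
                if entry["is_reference"]:
                    continue
                total += 1
                ok += entry["overlaps_reference"]
        assert ok / total >= 0.90

    def test_non_harmonized_low_gain_scanners_flagged(self):
        # scanners whose cf1 <= 0.73 carry a strong multiplicative bias
        flagged = {"Vida": 0, "Prisma2": 0}
        for syn in self._replicates():
            model = build_model(syn.cohort)
            report = commutability_report(syn.cohort, model, route=None)
            for scanner in flagged:
                flagged[scanner] += not report[scanner]["overlaps_reference"]
        for scanner, count in flagged.items():
            assert count > self.N_REP / 2, f"{scanner} rarely flagged"


class TestDistributionAnalysis:
    def test_perfect_estimator_zero_summary(self):
        syn = simulate_cohort(noiseless_config([1.0, 1.5]))
        model = build_model(syn.cohort, reference="S0", min_n=2)
        rows = distribution_analysis(syn.cohort, model, n_boot=20, seed=0)
        by_label = {r.method_label: r for r in rows}
        icg_row = by_label["h-HUI by ICG-PDR"]
        assert icg_row.rmse.value == pytest.approx(0.0, abs=1e-12)
        assert icg_row.mu.value == pytest.approx(0.0, abs=1e-12)
        assert icg_row.sigma.value == pytest.approx(0.0, abs=1e-12)

    def test_method_rows_present(self):
        from huiharm.simulate import paper_default_config

        syn = simulate_cohort(paper_default_config(seed=3))
        model = build_model(syn.cohort)
        rows = distribution_analysis(syn.cohort, model, n_boot=100, seed=0)
        labels = {r.method_label for r in rows}
        assert {
            "h-HUI by ICG-PDR",
            "h-HUI by ALBI-LP",
            "Non-harmonized HUI (All)",
            "Trio Tim (reference)",
            "ALBI-LP",
        } <= labels
        # one per-scanner row for each of the six scanners
        assert {"Avanto", "Avanto Fit", "Vida", "Prisma1", "Prisma2"} <= labels

    def test_harmonized_sigma_not_worse_than_pooled(self):
        from huiharm.simulate import paper_default_config

        for seed in range(5):
            syn = simulate_cohort(paper_default_config(seed=seed))
            model = build_model(syn.cohort)
            rows = {
                r.method_label: r
                for r in distribution_analysis(syn.cohort, model, n_boot=50, seed=0)
            }
            assert (
                rows["h-HUI by ALBI-LP"].sigma.value
                <= rows["Non-harmonized HUI (All)"].sigma.value
            )

    def test_equal_gains_statistically_indistinguishable(self):
        cfg = SimulationConfig(
            scanners=[ScannerSpec(f"S{i}", 1.0, 80) for i in range(3)],
            reference_scanner_id="S0",
            route_ratio=1.0,
            seed=11,
        )
        syn = simulate_cohort(cfg)
        model = build_model(syn.cohort, min_n=2)
        rows = {
            r.method_label: r
            for r in distribution_analysis(syn.cohort, model, n_boot=500, seed=0)
        }
        harm = rows["h-HUI by ALBI-LP"]
        raw = rows["Non-harmonized HUI (All)"]
        assert ci_overlap(harm.sigma.ci, raw.sigma.ci)
        assert ci_overlap(harm.rmse.ci, raw.rmse.ci)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, noiseless_cohort):
        model = build_model(noiseless_cohort, reference="S0", min_n=2)
        path = tmp_path / "cal.json"
        model.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["schema"] == "huiharm-calibration-1"
        back = HarmonizationModel.from_json(path)
        assert back.reference_scanner_id == model.reference_scanner_id
        assert back.slope1 == pytest.approx(model.slope1)
        assert back.cf3 == pytest.approx(model.cf3)
        for sid, cal in model.calibrations.items():
            assert back.calibrations[sid].cf1 == pytest.approx(cal.cf1)
            assert back.calibrations[sid].cf2 == pytest.approx(cal.cf2)

    def test_bad_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema": "other"}))
        with pytest.raises(ValueError, match="schema"):
            HarmonizationModel.from_json(path)
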