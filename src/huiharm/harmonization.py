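"""Cross-scanner HUI harmonization.

The method: on a designated reference scanner, fit through-origin slopes of
ICG-PDR on HUI (Slope1) and of ALBI-LP on HUI (Slope1'). For every other
scanner, the analogous slopes (Slope2, Slope2') yield conversion factors

    CF1 = Slope2 / Slope1        (ICG route)
    CF2 = Slope2' / Slope1'      (ALBI route)

and a cross-route coefficient CF3, the through-origin regression slope of
CF1 on CF2 across non-reference scanners. Harmonized HUI is then

    h-HUI = HUI * CF1 = HUI * CF2 * CF3

so scanners lacking ICG clearance data can still be harmonized via the
blood-test route, and quantitative liver function is estimated as

    eICG-PDR = Slope1 * h-HUI.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (
    ResidualSummary,
    ZeroInterceptFit,
    ci_overlap,
    fit_residual_normal,
    fit_zero_intercept,
    rmse_with_ci,
)

__all__ = [
    "CohortTable",
    "ScannerCalibration",
    "HarmonizationModel",
    "choose_reference",
    "calibrate_scanners",
    "conversion_factor_ci",
    "derive_cf3",
    "build_model",
    "harmonize_hui",
    "estimate_icg_pdr",
    "harmonize_cohort",
    "commutability_report",
    "distribution_analysis",
    "DEFAULT_MIN_N",
    "CALIBRATION_SCHEMA",
]

logger = logging.getLogger(__name__)

#: Minimum per-scanner sample size for a route's calibration fit.
DEFAULT_MIN_N = 10

CALIBRATION_SCHEMA = "huiharm-calibration-1"

COHORT_COLUMNS = ("patient_id", "scanner_id", "hui", "icg_pdr", "albi_lp")


@dataclass
class CohortTable:
    """Per-patient cohort records: scanner id, HUI, and optional assays.

    ``icg_pdr`` and ``albi_lp`` may be missing (NaN) per record; rows
    missing an assay are simply excluded from that route's fits.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in ("patient_id", "scanner_id", "hui") if c not in df.columns]
        if missing:
            raise ValueError(f"cohort is missing required columns: {missing}")
        for col in ("icg_pdr", "albi_lp"):
            if col not in df.columns:
                df[col] = np.nan
        df["patient_id"] = df["patient_id"].astype(str)
        df["scanner_id"] = df["scanner_id"].astype(str)
        if (df["scanner_id"].str.len() == 0).any():
            raise ValueError("scanner_id must be non-empty")
        for col in ("hui", "icg_pdr", "albi_lp"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df["hui"].isna().any():
            raise ValueError("hui must be present for every record")
        self.df = df[list(COHORT_COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame.from_records(records))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def scanner_ids(self) -> list[str]:
        return sorted(self.df["scanner_id"].unique())

    def scanner_counts(self) -> dict[str, int]:
        return self.df["scanner_id"].value_counts().to_dict()

    def subset(self, scanner_id: str) -> pd.DataFrame:
        return self.df[self.df["scanner_id"] == scanner_id]


@dataclass(frozen=True)
class ScannerCalibration:
    """Per-scanner calibration: route fits and conversion factors.

    ``cf1`` is None when the scanner has no usable ICG data — the ALBI
    route (cf2 with the model-level CF3) still applies.
    """

    scanner_id: str
    fit_icg: ZeroInterceptFit | None
    fit_albi: ZeroInterceptFit | None
    cf1: float | None
    cf2: float | None
    is_reference: bool = False

    def to_dict(self) -> dict:
        d: dict = {"scanner_id": self.scanner_id, "is_reference": self.is_reference}
        if self.fit_icg is not None:
            d["slope2"] = self.fit_icg.slope
            d["slope2_ci"] = [self.fit_icg.ci_low, self.fit_icg.ci_high]
            d["n_icg"] = self.fit_icg.n
        else:
            d["slope2"] = None
            d["n_icg"] = 0
        if self.fit_albi is not None:
            d["slope2_prime"] = self.fit_albi.slope
            d["slope2_prime_ci"] = [self.fit_albi.ci_low, self.fit_albi.ci_high]
            d["n_albi"] = self.fit_albi.n
        else:
            d["slope2_prime"] = None
            d["n_albi"] = 0
        d["cf1"] = self.cf1
        d["cf2"] = self.cf2
        return d


@dataclass(frozen=True)
class HarmonizationModel:
    """Fitted harmonization model for a multi-scanner cohort."""

    reference_scanner_id: str
    slope1: float
    slope1_prime: float
    cf3: float
    calibrations: dict[str, ScannerCalibration]
    cf3_fit: ZeroInterceptFit | None = None

    def __post_init__(self) -> None:
        if self.cf3 <= 0:
            raise ValueError("cf3 must be positive")

    def calibration(self, scanner_id: str) -> ScannerCalibration:
        try:
            return self.calibrations[scanner_id]
        except KeyError:
            raise KeyError(f"no calibration for scanner {scanner_id!r}") from None

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": CALIBRATION_SCHEMA,
            "reference_scanner_id": self.reference_scanner_id,
            "slope1": self.slope1,
            "slope1_prime": self.slope1_prime,
            "cf3": self.cf3,
            "cf3_fit": self.cf3_fit.to_dict() if self.cf3_fit is not None else None,
            "scanners": [c.to_dict() for c in self.calibrations.values()],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonizationModel":
        if d.get("schema") != CALIBRATION_SCHEMA:
            raise ValueError(f"unsupported calibration schema: {d.get('schema')!r}")

        def _fit(entry: dict, slope_key: str, ci_key: str, n_key: str):
            if entry.get(slope_key) is None:
                return None
            lo, hi = entry[ci_key]
            slope = entry[slope_key]
            n = entry[n_key]
            # SE is reconstructed from the CI half-width for round-tripping.
            from scipy import stats as sps

            tcrit = sps.t.ppf(0.975, n - 1)
            se = (hi - lo) / 2 / tcrit if tcrit > 0 else 0.0
            p = 0.0 if se == 0 and slope != 0 else (
                2 * sps.t.sf(abs(slope / se), n - 1) if se > 0 else 1.0
            )
            return ZeroInterceptFit(slope, se, lo, hi, min(max(p, 0.0), 1.0), n)

        calibrations = {}
        for entry in d["scanners"]:
            calibrations[entry["scanner_id"]] = ScannerCalibration(
                scanner_id=entry["scanner_id"],
                fit_icg=_fit(entry, "slope2", "slope2_ci", "n_icg"),
                fit_albi=_fit(entry, "slope2_prime", "slope2_prime_ci", "n_albi"),
                cf1=entry.get("cf1"),
                cf2=entry.get("cf2"),
                is_reference=entry.get("is_reference", False),
            )
        return cls(
            reference_scanner_id=d["reference_scanner_id"],
            slope1=d["slope1"],
            slope1_prime=d["slope1_prime"],
            cf3=d["cf3"],
            calibrations=calibrations,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def choose_reference(cohort: CohortTable) -> str:
    """Scanner with the most records; ties broken lexicographically."""
    counts = cohort.scanner_counts()
    if not counts:
        raise ValueError("empty cohort: no scanner to choose as reference")
    return min(counts, key=lambda s: (-counts[s], s))


def _route_fit(sub: pd.DataFrame, ycol: str, min_n: int) -> ZeroInterceptFit | None:
    rows = sub.dropna(subset=["hui", ycol])
    if len(rows) < max(min_n, 2):
        return None
    return fit_zero_intercept(rows["hui"].to_numpy(), rows[ycol].to_numpy())


def calibrate_scanners(
    cohort: CohortTable,
    reference: str,
    min_n: int = DEFAULT_MIN_N,
) -> dict[str, ScannerCalibration]:
    """Fit both routes per scanner and derive CF1/CF2 against the reference.

    The reference scanner gets cf1 = cf2 = 1 exactly. A scanner whose
    route has fewer than ``min_n`` usable records is marked uncalibratable
    on that route (warning, not an error).
    """
    if reference not in cohort.scanner_ids:
        raise ValueError(f"reference scanner {reference!r} not present in cohort")

    ref_sub = cohort.subset(reference)
    ref_icg = _route_fit(ref_sub, "icg_pdr", min_n)
    ref_albi = _route_fit(ref_sub, "albi_lp", min_n)
    if ref_icg is None or ref_albi is None:
        raise ValueError(
            f"reference scanner {reference!r} must support both routes "
            f"with at least {min_n} records each"
        )

    calibrations: dict[str, ScannerCalibration] = {}
    for scanner in cohort.scanner_ids:
        if scanner == reference:
            calibrations[scanner] = ScannerCalibration(
                scanner_id=scanner,
                fit_icg=ref_icg,
                fit_albi=ref_albi,
                cf1=1.0,
                cf2=1.0,
                is_reference=True,
            )
            continue
        sub = cohort.subset(scanner)
        fit_icg = _route_fit(sub, "icg_pdr", min_n)
        fit_albi = _route_fit(sub, "albi_lp", min_n)
        if fit_icg is None:
            logger.warning(
                "scanner %s: ICG route uncalibratable (fewer than %d records)",
                scanner,
                min_n,
            )
        if fit_albi is None:
            logger.warning(
                "scanner %s: ALBI route uncalibratable (fewer than %d records)",
                scanner,
                min_n,
            )
        calibrations[scanner] = ScannerCalibration(
            scanner_id=scanner,
            fit_icg=fit_icg,
            fit_albi=fit_albi,
            cf1=fit_icg.slope / ref_icg.slope if fit_icg is not None else None,
            cf2=fit_albi.slope / ref_albi.slope if fit_albi is not None else None,
        )
    return calibrations


def conversion_factor_ci(
    fit: ZeroInterceptFit, ref_fit: ZeroInterceptFit
) -> tuple[float, float]:
    """Delta-method 95% CI for a conversion factor slope/ref_slope.

    Propagates the standard errors of both independent slope fits:
    se(cf) = |cf| * sqrt((se2/slope2)^2 + (se1/slope1)^2).
    """
    cf = fit.slope / ref_fit.slope
    rel = np.hypot(fit.se / fit.slope, ref_fit.se / ref_fit.slope)
    half = 1.959963984540054 * abs(cf) * rel
    return (cf - half, cf + half)


def derive_cf3(
    calibrations: dict[str, ScannerCalibration] | list[ScannerCalibration],
) -> tuple[float, ZeroInterceptFit]:
    """Cross-route coefficient: through-origin slope of CF1 on CF2.

    Fitted across non-reference scanners having both conversion factors;
    the reference scanner's (1, 1) point is excluded.
    """
    if isinstance(calibrations, dict):
        calibrations = list(calibrations.values())
    pairs = [
        (c.cf2, c.cf1)
        for c in calibrations
        if not c.is_reference and c.cf1 is not None and c.cf2 is not None
    ]
    if len(pairs) < 2:
        raise ValueError(
            "need at least 2 non-reference scanners with both CF1 and CF2 "
            "to derive CF3"
        )
    cf2s, cf1s = zip(*pairs)
    fit = fit_zero_intercept(np.asarray(cf2s), np.asarray(cf1s))
    return fit.slope, fit


def build_model(
    cohort: CohortTable,
    reference: str = "auto",
    min_n: int = DEFAULT_MIN_N,
    cf3: float | None = None,
) -> HarmonizationModel:
    """Full calibration: reference choice, per-scanner CFs, and CF3.

    ``cf3`` may be supplied externally (e.g. an established value) for
    cohorts without enough dual-route scanners to fit it.
    """
    ref = choose_reference(cohort) if reference == "auto" else reference
    calibrations = calibrate_scanners(cohort, ref, min_n=min_n)
    cf3_fit = None
    if cf3 is None:
        pairs = [
            c
            for c in calibrations.values()
            if not c.is_reference and c.cf1 is not None and c.cf2 is not None
        ]
        if len(pairs) >= 2:
            cf3, cf3_fit = derive_cf3(calibrations)
        elif len(pairs) == 1:
            cf3 = pairs[0].cf1 / pairs[0].cf2
            warnings.warn(
                "only one dual-route scanner: cf3 taken as its cf1/cf2 ratio",
                stacklevel=2,
            )
        else:
            raise ValueError(
                "cannot derive cf3: no non-reference scanner has both routes; "
                "supply cf3 explicitly"
            )
    ref_cal = calibrations[ref]
    assert ref_cal.fit_icg is not None and ref_cal.fit_albi is not None
    return HarmonizationModel(
        reference_scanner_id=ref,
        slope1=ref_cal.fit_icg.slope,
        slope1_prime=ref_cal.fit_albi.slope,
        cf3=cf3,
        calibrations=calibrations,
        cf3_fit=cf3_fit,
    )


def harmonize_hui(
    hui: float,
    scanner_id: str,
    model: HarmonizationModel,
    route: str = "albi",
) -> float:
    """h-HUI for one measurement: HUI*CF1 (icg) or HUI*CF2*CF3 (albi)."""
    cal = model.calibration(scanner_id)
    if route == "icg":
        if cal.cf1 is None:
            raise ValueError(f"scanner {scanner_id!r} has no ICG-route calibration")
        return hui * cal.cf1
    if route == "albi":
        if cal.cf2 is None:
            raise ValueError(f"scanner {scanner_id!r} has no ALBI-route calibration")
        return hui * cal.cf2 * model.cf3
    raise ValueError(f"unknown route {route!r}; expected 'icg' or 'albi'")


def estimate_icg_pdr(h_hui: float, model: HarmonizationModel) -> float:
    """eICG-PDR = Slope1 * h-HUI (per minute)."""
    return model.slope1 * h_hui


def harmonize_cohort(
    cohort: CohortTable,
    model: HarmonizationModel,
    route: str = "albi",
) -> pd.DataFrame:
    """Cohort table with added ``h_hui`` and ``eicg_pdr`` columns.

    Records on scanners lacking the requested route's CF get NaN with a
    warning rather than an error.
    """
    df = cohort.df.copy()
    h = np.full(len(df), np.nan)
    for scanner, idx in df.groupby("scanner_id").groups.items():
        try:
            h[np.asarray(idx)] = [
                harmonize_hui(v, str(scanner), model, route)
                for v in df.loc[idx, "hui"]
            ]
        except (ValueError, KeyError) as exc:
            warnings.warn(str(exc), stacklevel=2)
    df["h_hui"] = h
    df["eicg_pdr"] = model.slope1 * h
    return df


def commutability_report(
    cohort: CohortTable,
    model: HarmonizationModel,
    route: str = "albi",
) -> dict[str, dict]:
    """Per-scanner slope of observed ICG-PDR on h-HUI, with CI-overlap flags.

    A scanner is commutable with the reference when its post-harmonization
    slope CI overlaps the reference scanner's CI. ``route=None`` evaluates
    the non-harmonized HUI directly.
    """
    df = cohort.df.copy()
    if route is None:
        df["h_hui"] = df["hui"]
    else:
        df = harmonize_cohort(cohort, model, route)
    df = df.dropna(subset=["icg_pdr", "h_hui"])

    fits: dict[str, ZeroInterceptFit] = {}
    for scanner, sub in df.groupby("scanner_id"):
        if len(sub) < 2:
            warnings.warn(f"scanner {scanner}: too few ICG records", stacklevel=2)
            continue
        fits[str(scanner)] = fit_zero_intercept(
            sub["h_hui"].to_numpy(), sub["icg_pdr"].to_numpy()
        )
    ref = model.reference_scanner_id
    if ref not in fits:
        raise ValueError(f"reference scanner {ref!r} has no usable ICG records")
    report = {}
    for scanner, fit in fits.items():
        overlaps = ci_overlap(fit.ci, fits[ref].ci)
        report[scanner] = {
            "fit": fit,
            "overlaps_reference": overlaps,
            "significant_vs_reference": not overlaps,
            "is_reference": scanner == ref,
        }
    return report


def _summary(
    label: str,
    observed: np.ndarray,
    estimated: np.ndarray,
    n_boot: int,
    seed: int,
) -> ResidualSummary:
    rmse = rmse_with_ci(observed, estimated, n_boot=n_boot, seed=seed)
    mu, sigma = fit_residual_normal(observed - estimated)
    return ResidualSummary(
        method_label=label, rmse=rmse, mu=mu, sigma=sigma, n=observed.size
    )


def distribution_analysis(
    cohort: CohortTable,
    model: HarmonizationModel,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[ResidualSummary]:
    """Residual analysis of ICG-PDR estimation for every method.

    Methods: h-HUI by ICG-PDR, h-HUI by ALBI-LP, non-harmonized HUI
    (pooled and per scanner, the reference scanner doubling as the
    comparison baseline), and ALBI-LP mapped to the ICG-PDR scale via
    Slope1/Slope1'. Each summary carries significance flags (CI
    non-overlap vs the reference scanner's summary) for RMSE, mu, sigma.
    """
    df = cohort.df.dropna(subset=["icg_pdr"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no observed ICG-PDR records to analyze")
    summaries: list[ResidualSummary] = []

    def add(label: str, sub: pd.DataFrame, est: np.ndarray) -> None:
        obs = sub["icg_pdr"].to_numpy()
        ok = np.isfinite(est)
        if ok.sum() < 2:
            warnings.warn(f"method {label!r}: too few usable records", stacklevel=2)
            return
        summaries.append(_summary(label, obs[ok], est[ok], n_boot, seed))

    cohort_icg = CohortTable(df)

    for route, label in (("icg", "h-HUI by ICG-PDR"), ("albi", "h-HUI by ALBI-LP")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hdf = harmonize_cohort(cohort_icg, model, route)
        add(label, hdf, hdf["eicg_pdr"].to_numpy())

    # Non-harmonized: eICG-PDR computed from raw HUI.
    raw_est = model.slope1 * df["hui"].to_numpy()
    add("Non-harmonized HUI (All)", df, raw_est)
    ref = model.reference_scanner_id
    ref_label = f"{ref} (reference)"
    for scanner in cohort_icg.scanner_ids:
        sub = df[df["scanner_id"] == scanner]
        label = ref_label if scanner == ref else scanner
        add(label, sub, model.slope1 * sub["hui"].to_numpy())

    # ALBI-LP as a direct estimator, rescaled onto the ICG-PDR scale.
    albi_est = df["albi_lp"].to_numpy() * (model.slope1 / model.slope1_prime)
    add("ALBI-LP", df, albi_est)

    ref_summary = next((s for s in summaries if s.method_label == ref_label), None)
    if ref_summary is not None:
        flagged = []
        for s in summaries:
            flags = {
                key: not ci_overlap(getattr(s, key).ci, getattr(ref_summary, key).ci)
                for key in ("rmse", "mu", "sigma")
            }
            flagged.append(
                ResidualSummary(s.method_label, s.rmse, s.mu, s.sigma, s.n, flags)
            )
        summaries = flagged
    return summaries
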