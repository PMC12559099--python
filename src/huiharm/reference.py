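"""Reference values from a six-scanner gadoxetate liver-function cohort.

These constants describe the calibration study that established the
harmonization method: per-scanner through-origin slopes of ICG-PDR on HUI
(with 95% CIs) and of ALBI-LP on HUI, the derived conversion factors, and
per-scanner sample sizes. They serve as defaults for the cohort simulator
and as fixtures for validating the harmonization arithmetic.

Printed conversion factors were derived from unrounded slopes, so ratios
of the 3-decimal slopes below can differ from the printed CF by 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScannerReference",
    "REFERENCE_SCANNER_ID",
    "SLOPE1",
    "SLOPE1_PRIME",
    "CF3",
    "SCANNER_REFERENCES",
    "ICG_PDR_MEAN",
    "ICG_PDR_SD",
    "ALBI_LP_MEAN",
    "ALBI_LP_SD",
    "LATENT_HUI_MEAN",
    "REFERENCE_RESIDUAL_SIGMA",
    "non_reference_cf_pairs",
]


@dataclass(frozen=True)
class ScannerReference:
    """Published per-scanner calibration row."""

    scanner_id: str
    n_icg: int
    n_albi: int
    slope_icg: float  # ICG-PDR on HUI, through origin
    slope_icg_ci: tuple[float, float]
    slope_albi: float  # ALBI-LP on HUI, through origin
    slope_albi_ci: tuple[float, float]
    cf1: float  # slope_icg / reference slope_icg (printed value)
    cf2: float  # slope_albi / reference slope_albi (printed value)
    starred_icg: bool  # significantly different slope vs reference (ICG route)


REFERENCE_SCANNER_ID = "Trio Tim"

#: Reference-scanner slope of ICG-PDR on HUI (1/min per liter).
SLOPE1 = -0.173
#: Reference-scanner slope of ALBI-LP on HUI (per liter).
SLOPE1_PRIME = -1.425
#: Cross-route conversion coefficient: through-origin slope of CF1 on CF2.
CF3 = 0.955

SCANNER_REFERENCES: tuple[ScannerReference, ...] = (
    ScannerReference(
        "Avanto", 31, 31, -0.161, (-0.177, -0.144), -1.402, (-1.569, -1.235),
        0.930, 0.984, starred_icg=False,
    ),
    ScannerReference(
        "Avanto Fit", 38, 40, -0.141, (-0.158, -0.124), -1.216, (-1.367, -1.066),
        0.813, 0.854, starred_icg=True,
    ),
    ScannerReference(
        "Vida", 23, 24, -0.121, (-0.135, -0.108), -1.031, (-1.160, -0.902),
        0.702, 0.723, starred_icg=True,
    ),
    ScannerReference(
        "Prisma1", 174, 180, -0.153, (-0.162, -0.145), -1.324, (-1.401, -1.246),
        0.887, 0.929, starred_icg=True,
    ),
    ScannerReference(
        "Prisma2", 36, 38, -0.126, (-0.137, -0.114), -1.075, (-1.194, -0.956),
        0.727, 0.754, starred_icg=True,
    ),
    ScannerReference(
        "Trio Tim", 196, 201, -0.173, (-0.181, -0.165), -1.425, (-1.511, -1.338),
        1.0, 1.0, starred_icg=False,
    ),
)

# Cohort marginals (ICG subgroup, n = 498).
ICG_PDR_MEAN = -0.16
ICG_PDR_SD = 0.04
ALBI_LP_MEAN = -1.32
ALBI_LP_SD = 0.55

#: Cohort-mean latent HUI implied by ICG_PDR_MEAN / SLOPE1 (liters).
LATENT_HUI_MEAN = ICG_PDR_MEAN / SLOPE1  # ~0.925 L

#: Residual sigma of the reference scanner's ICG-PDR estimate.
REFERENCE_RESIDUAL_SIGMA = 0.049


def non_reference_cf_pairs() -> tuple[tuple[float, ...], tuple[float, ...]]:
    """(cf1 values, cf2 values) for the five non-reference scanners."""
    rows = [r for r in SCANNER_REFERENCES if r.scanner_id != REFERENCE_SCANNER_ID]
    return tuple(r.cf1 for r in rows), tuple(r.cf2 for r in rows)
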