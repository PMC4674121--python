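"""Allometric body-size estimation from a partial rostrum.

For a physeteroid known only from an incomplete rostrum, the one usable
body-length proxy is the width at the antorbital notch (AON, cm),
measured on the preserved right side and doubled for a minimum
estimate.  Two bivariate OLS pipelines convert AON into condylobasal
length (CBL, cm) and total length (TL, cm):

* Method 1:  CBL = a·AON + b, then TL = c·CBL + d
  (the TL step is fit on extant taxa with field-measured lengths).
* Method 2:  regress rostrum-corrected quantities on AON —
  (CBL − RL) = a'·AON + b' and (TL − CBL) = c'·AON + d' — then add the
  preserved rostrum length RL back in, which corrects for variable
  rostrum proportions and serves as the upper-bound method.

The default coefficients are the published values for the physeteroid
reference dataset; :func:`pipeline_from_data` refits all four
regressions from a reference table instead.  Unrounded intermediates
are carried throughout; rounding to 0.1 cm happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class RegressionModel:
    slope: float
    intercept: float
    n: int
    r2: float
    residual_sd: float
    x_name: str = "x"
    y_name: str = "y"

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class SpecimenMeasurements:
    """Cranial measurements of one specimen (cm)."""

    aon_width: float
    rostrum_length: float | None = None
    aon_half_width: float | None = None

    def __post_init__(self) -> None:
        if self.aon_width <= 0:
            raise ValueError("antorbital notch width must be positive")
        if self.rostrum_length is not None and self.rostrum_length <= 0:
            raise ValueError("rostrum length must be positive")

    @classmethod
    def from_half_width(
        cls, half_width: float, rostrum_length: float | None = None
    ) -> "SpecimenMeasurements":
        return cls(
            aon_width=derive_aon(half_width),
            rostrum_length=rostrum_length,
            aon_half_width=half_width,
        )


@dataclass(frozen=True)
class BodySizeCoefficients:
    """Four (slope, intercept) pairs driving the two methods."""

    m1_cbl: tuple[float, float]  # CBL ~ AON
    m2_cbl: tuple[float, float]  # (CBL - RL) ~ AON
    m1_tl: tuple[float, float]  # TL ~ CBL
    m2_tl: tuple[float, float]  # (TL - CBL) ~ AON


#: Published reference coefficients for the physeteroid dataset.
PRINTED_COEFFS = BodySizeCoefficients(
    m1_cbl=(2.51, 2.84),
    m2_cbl=(0.634, 31.2),
    m1_tl=(3.4, 161.0),
    m2_tl=(6.33, 31.2),
)


@dataclass
class BodySizeEstimate:
    cbl_lower: float  # Method 1
    cbl_upper: float | None  # Method 2 (needs rostrum length)
    tl_lower: float  # Method 1
    tl_upper: float | None  # Method 2
    equations_used: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 1) -> dict:
        """Report values at 0.1-cm precision."""
        out = {
            "cbl_lower_cm": round(self.cbl_lower, ndigits),
            "tl_lower_cm": round(self.tl_lower, ndigits),
        }
        if self.cbl_upper is not None:
            out["cbl_upper_cm"] = round(self.cbl_upper, ndigits)
        if self.tl_upper is not None:
            out["tl_upper_cm"] = round(self.tl_upper, ndigits)
        return out


def derive_aon(half_width: float) -> float:
    """Double a right-side half measurement into a minimum full AON."""
    if half_width <= 0:
        raise ValueError("half width must be positive")
    return 2.0 * half_width


def fit_ols(
    points: Sequence[tuple[float, float]],
    x_name: str = "x",
    y_name: str = "y",
) -> RegressionModel:
    """Ordinary least squares y = slope·x + intercept."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    n = len(pts)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    residual_sd = float(np.sqrt(model.ssr / (n - 2))) if n > 2 else 0.0
    r2 = float(model.rsquared) if np.ptp(y) > 0 else 1.0
    return RegressionModel(
        slope=float(slope),
        intercept=float(intercept),
        n=n,
        r2=r2,
        residual_sd=residual_sd,
        x_name=x_name,
        y_name=y_name,
    )


def estimate_body_size(
    m: SpecimenMeasurements,
    coeffs: BodySizeCoefficients = PRINTED_COEFFS,
    methods: tuple[int, ...] = (1, 2),
) -> BodySizeEstimate:
    """Apply the two-method pipeline to one specimen.

    Method 1: CBL then TL straight from the regressions (lower bounds).
    Method 2: rostrum-corrected regressions, adding the preserved
    rostrum length (CBL upper bound) and composing the TL equation as
    published: TL = (slope·AON + intercept) + CBL_upper.
    """
    aon = m.aon_width
    s1, i1 = coeffs.m1_cbl
    cbl_lower = s1 * aon + i1
    s3, i3 = coeffs.m1_tl
    tl_lower = s3 * cbl_lower + i3

    cbl_upper = tl_upper = None
    if 2 in methods:
        if m.rostrum_length is None:
            raise ValueError("Method 2 requires the preserved rostrum length")
        s2, i2 = coeffs.m2_cbl
        cbl_upper = (s2 * aon + i2) + m.rostrum_length
        s4, i4 = coeffs.m2_tl
        tl_upper = (s4 * aon + i4) + cbl_upper

    return BodySizeEstimate(
        cbl_lower=cbl_lower,
        cbl_upper=cbl_upper,
        tl_lower=tl_lower,
        tl_upper=tl_upper,
        equations_used={
            "m1_cbl": coeffs.m1_cbl,
            "m2_cbl": coeffs.m2_cbl,
            "m1_tl": coeffs.m1_tl,
            "m2_tl": coeffs.m2_tl,
            "aon_cm": aon,
            "rostrum_length_cm": m.rostrum_length,
            "methods": list(methods),
        },
    )


def fit_reference_regressions(table: pd.DataFrame) -> BodySizeCoefficients:
    """Fit the four pipeline regressions from a reference-specimen table.

    Expected columns: AON, CBL, RL, TL (TL may be missing/NaN for
    fossil taxa).  Raises if any regression has fewer than 3 usable rows.
    """
    def usable(cols: list[str]) -> pd.DataFrame:
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"reference table lacks column(s) {missing}")
        return table[cols].dropna()

    def fit(xcol_vals, ycol_vals, name: str) -> RegressionModel:
        pts = list(zip(xcol_vals, ycol_vals))
        if len(pts) < 3:
            raise ValueError(
                f"regression {name!r} has {len(pts)} usable rows; need >= 3"
            )
        return fit_ols(pts, name.split("~")[1], name.split("~")[0])

    d = usable(["AON", "CBL"])
    m1_cbl = fit(d["AON"], d["CBL"], "CBL~AON")
    d = usable(["AON", "CBL", "RL"])
    m2_cbl = fit(d["AON"], d["CBL"] - d["RL"], "CBL-RL~AON")
    d = usable(["CBL", "TL"])
    m1_tl = fit(d["CBL"], d["TL"], "TL~CBL")
    d = usable(["AON", "CBL", "TL"])
    m2_tl = fit(d["AON"], d["TL"] - d["CBL"], "TL-CBL~AON")
    return BodySizeCoefficients(
        m1_cbl=(m1_cbl.slope, m1_cbl.intercept),
        m2_cbl=(m2_cbl.slope, m2_cbl.intercept),
        m1_tl=(m1_tl.slope, m1_tl.intercept),
        m2_tl=(m2_tl.slope, m2_tl.intercept),
    )


def pipeline_from_data(
    table: pd.DataFrame, specimen: SpecimenMeasurements
) -> BodySizeEstimate:
    """Refit all four regressions from data, then estimate the specimen."""
    coeffs = fit_reference_regressions(table)
    est = estimate_body_size(specimen, coeffs)
    est.equations_used["fitted_from_n_rows"] = int(len(table))
    return est
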