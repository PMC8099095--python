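"""Enamel carbonate δ¹⁸O to drinking-water δ¹⁸O conversion chain.

Tooth enamel is usually analysed as structural carbonate on the VPDB scale,
while drinking-water (precipitation) isoscapes are on VSMOW. Comparing a
tooth to a precipitation isoscape therefore takes three affine steps:

1. VPDB -> VSMOW scale change (Coplen relation),
2. carbonate -> phosphate fraction (Iacumin-type calibration),
3. phosphate -> drinking water (Hoppe-type calibration).

Each step is a strictly increasing affine map and exactly invertible. The
combined calibration uncertainty of steps 2-3 is about 1 permil and is
folded into the precipitation isoscape SD (quadrature by default). An
analytic first-order propagation from the printed coefficient SDs is also
available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

VSMOW = "VSMOW"
VPDB = "VPDB"
CARBONATE = "carbonate"
PHOSPHATE = "phosphate"
WATER = "water"


class ScaleError(ValueError):
    """Input value carries the wrong scale or mineral-fraction tag."""


@dataclass(frozen=True)
class OxygenValue:
    """A δ¹⁸O value tagged with its reference scale and mineral fraction."""

    value: float
    scale: str
    fraction: str
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in (VSMOW, VPDB):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.fraction not in (CARBONATE, PHOSPHATE, WATER):
            raise ValueError(f"unknown fraction {self.fraction!r}")


@dataclass(frozen=True)
class ConversionParams:
    """Affine coefficients of the conversion chain, with their printed SDs.

    Defaults: carbonate->phosphate intercept 8.79 (±0.79) permil and slope
    1.015 (±0.043); phosphate->water intercept 21.28 (±0.51) permil and
    slope 0.68 (±0.04); summary chain uncertainty 1.0 permil; Coplen
    VPDB->VSMOW relation 1.03091 x + 30.91.
    """

    eq3_intercept: float = 8.79
    eq3_intercept_sd: float = 0.79
    eq3_slope: float = 1.015
    eq3_slope_sd: float = 0.043
    eq4_intercept: float = 21.28
    eq4_intercept_sd: float = 0.51
    eq4_slope: float = 0.68
    eq4_slope_sd: float = 0.04
    chain_sd: float = 1.0
    pdb_smow_slope: float = 1.03091
    pdb_smow_offset: float = 30.91

    def __post_init__(self) -> None:
        if self.eq3_slope == 0 or self.eq4_slope == 0 or self.pdb_smow_slope == 0:
            raise ValueError("slopes must be nonzero")


DEFAULT_PARAMS = ConversionParams()


def pdb_to_smow(v: OxygenValue, params: ConversionParams = DEFAULT_PARAMS) -> OxygenValue:
    """Rescale a VPDB value onto VSMOW; the mineral fraction is unchanged."""
    if v.scale != VPDB:
        raise ScaleError(f"pdb_to_smow expects a VPDB value, got {v.scale}")
    out = params.pdb_smow_slope * v.value + params.pdb_smow_offset
    sd = v.sd * params.pdb_smow_slope if v.sd is not None else None
    return OxygenValue(out, VSMOW, v.fraction, sd)


def smow_to_pdb(v: OxygenValue, params: ConversionParams = DEFAULT_PARAMS) -> OxygenValue:
    if v.scale != VSMOW:
        raise ScaleError(f"smow_to_pdb expects a VSMOW value, got {v.scale}")
    out = (v.value - params.pdb_smow_offset) / params.pdb_smow_slope
    sd = v.sd / params.pdb_smow_slope if v.sd is not None else None
    return OxygenValue(out, VPDB, v.fraction, sd)


def carbonate_to_phosphate(v: OxygenValue,
                           params: ConversionParams = DEFAULT_PARAMS,
                           propagate: str | None = None) -> OxygenValue:
    """δ¹⁸O_p = (δ¹⁸O_c − 8.79) / 1.015, on VSMOW."""
    if v.fraction != CARBONATE:
        raise ScaleError(f"expected a carbonate value, got {v.fraction}")
    if v.scale != VSMOW:
        raise ScaleError("carbonate_to_phosphate operates on the VSMOW scale; "
                         "convert with pdb_to_smow first")
    out = (v.value - params.eq3_intercept) / params.eq3_slope
    sd = _propagate_affine(v.sd, out, params.eq3_intercept_sd,
                           params.eq3_slope, params.eq3_slope_sd, propagate)
    return OxygenValue(out, VSMOW, PHOSPHATE, sd)


def phosphate_to_carbonate(v: OxygenValue,
                           params: ConversionParams = DEFAULT_PARAMS) -> OxygenValue:
    if v.fraction != PHOSPHATE:
        raise ScaleError(f"expected a phosphate value, got {v.fraction}")
    return OxygenValue(v.value * params.eq3_slope + params.eq3_intercept,
                       v.scale, CARBONATE, v.sd)


def phosphate_to_water(v: OxygenValue,
                       params: ConversionParams = DEFAULT_PARAMS,
                       propagate: str | None = None) -> OxygenValue:
    """δ¹⁸O_w = (δ¹⁸O_p − 21.28) / 0.68."""
    if v.fraction != PHOSPHATE:
        raise ScaleError(f"expected a phosphate value, got {v.fraction}")
    out = (v.value - params.eq4_intercept) / params.eq4_slope
    sd = _propagate_affine(v.sd, out, params.eq4_intercept_sd,
                           params.eq4_slope, params.eq4_slope_sd, propagate)
    return OxygenValue(out, v.scale, WATER, sd)


def water_to_phosphate(v: OxygenValue,
                       params: ConversionParams = DEFAULT_PARAMS) -> OxygenValue:
    if v.fraction != WATER:
        raise ScaleError(f"expected a water value, got {v.fraction}")
    return OxygenValue(v.value * params.eq4_slope + params.eq4_intercept,
                       v.scale, PHOSPHATE, v.sd)


def _propagate_affine(sd_in, out_value, intercept_sd, slope, slope_sd, propagate):
    """First-order SD of y = (x - a)/b given sd(x), sd(a), sd(b)."""
    if propagate != "analytic":
        return sd_in
    var_in = (sd_in or 0.0) ** 2
    return math.sqrt((var_in + intercept_sd ** 2) / slope ** 2
                     + (out_value * slope_sd / slope) ** 2)


def tissue_to_water(d18Oc_vpdb: float,
                    params: ConversionParams = DEFAULT_PARAMS,
                    assume_input_scale: str = VPDB,
                    propagate: str = "chain") -> OxygenValue:
    """Full chain: enamel carbonate δ¹⁸O to drinking-water equivalent.

    ``assume_input_scale`` controls whether the raw tooth value is taken as
    VPDB (default; a VPDB->VSMOW rescaling is applied first) or already
    VSMOW. With ``propagate="chain"`` the returned SD is the summary 1
    permil chain uncertainty; ``propagate="analytic"`` instead carries the
    printed coefficient SDs through both calibrations.
    """
    analytic = "analytic" if propagate == "analytic" else None
    if assume_input_scale == VPDB:
        v = pdb_to_smow(OxygenValue(d18Oc_vpdb, VPDB, CARBONATE), params)
    elif assume_input_scale == VSMOW:
        v = OxygenValue(d18Oc_vpdb, VSMOW, CARBONATE)
    else:
        raise ScaleError(f"unknown input scale {assume_input_scale!r}")
    v = carbonate_to_phosphate(v, params, propagate=analytic)
    v = phosphate_to_water(v, params, propagate=analytic)
    if propagate == "chain":
        v = replace(v, sd=params.chain_sd)
    return v


def combine_oxygen_uncertainty(precip_sd, chain_sd: float,
                               mode: str = "quadrature"):
    """Fold the conversion-chain SD into a precipitation isoscape SD grid.

    ``quadrature`` (default): sqrt(precip_sd^2 + chain_sd^2);
    ``additive``: precip_sd + chain_sd. Accepts scalars or arrays.
    """
    precip_sd = np.asarray(precip_sd, float)
    if mode == "quadrature":
        out = np.sqrt(precip_sd ** 2 + chain_sd ** 2)
    elif mode == "additive":
        out = precip_sd + chain_sd
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def convert_table(df: pd.DataFrame, value_column: str = "d18Oc",
                  params: ConversionParams = DEFAULT_PARAMS,
                  assume_input_scale: str = VPDB,
                  propagate: str = "chain") -> pd.DataFrame:
    """Batch conversion: add water-equivalent and SD columns to a table."""
    out = df.copy()
    waters, sds = [], []
    for v in out[value_column].astype(float):
        w = tissue_to_water(v, params, assume_input_scale, propagate)
        waters.append(w.value)
        sds.append(w.sd)
    out["d18Ow"] = waters
    out["d18Ow_sd"] = sds
    return out
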