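"""Poiseuille-flow estimate of cerebral blood flow from TCD velocity.

For laminar pipe flow with a parabolic (Poiseuille) profile, the mean
velocity is half the centerline velocity v measured by transcranial
Doppler, and the insonation angle theta between beam and vessel attenuates
the reading by cos(theta).  The estimator implemented here is

    CBF_TCD = pi * R^2 * M * v / (2 cos(theta)),

with R the MCA radius, M the mass of the perfused (MCA) territory and v
the TCD centerline velocity.  Written in terms of the diameter D = 2R this
is CBF_TCD = C * D^2 with C = (pi/4) * M * v / (2 cos(theta)); the
quadratic dependence on D means a relative diameter error Delta propagates
to a relative flow error of (1 + Delta)^2 - 1 = 2*Delta + Delta^2, so a
10% diameter error already moves the flow estimate by over 20%.

Units follow the cohort schema: v in cm/s, R (or D) in mm, M in g, theta
in degrees.  Mapping the literal product above onto the per-100-g scale
of perfusion MRI (ml/min/100g) has no unique dimensional reading, so the
schema-unit mode multiplies by a single configurable constant,
:data:`DEFAULT_CONVERSION`, calibrated at a reference territory mass of
230 g (an exact per-100g normalisation would divide by M^2 instead of
using a constant).  ``units="raw"`` bypasses all conversion and evaluates
the formula on the inputs as given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlowInput",
    "cbf_tcd",
    "cbf_tcd_table",
    "diameter_error_propagation",
    "angle_factor",
    "DEFAULT_CONVERSION",
    "REFERENCE_MASS_G",
]

#: Reference MCA-territory mass (g) used to calibrate the schema-unit
#: conversion constant.
REFERENCE_MASS_G = 230.0

#: Schema-unit conversion: mm^2 -> cm^2 (1/100), ml/s -> ml/min (60), and
#: per-100g normalisation at the reference mass
#: (100 / REFERENCE_MASS_G^2 per extra gram in the literal product):
#: 60 / 230^2 overall.
DEFAULT_CONVERSION = 60.0 / REFERENCE_MASS_G ** 2


@dataclass(frozen=True)
class FlowInput:
    """Inputs to the Poiseuille estimator: centerline velocity v (cm/s),
    vessel radius R (mm) or diameter D = 2R (mm), territory mass M (g),
    insonation angle theta in degrees with 0 <= theta < 90."""

    v: float
    R: float | None = None
    D: float | None = None
    M: float = REFERENCE_MASS_G
    theta: float = 0.0

    @property
    def radius(self) -> float:
        if self.R is not None:
            return self.R
        if self.D is not None:
            return self.D / 2.0
        raise ValueError("FlowInput needs R or D")


def _validate(v, R, M, theta):
    v = np.asarray(v, dtype=float)
    R = np.asarray(R, dtype=float)
    M = np.asarray(M, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if (v < 0).any():
        raise ValueError("velocity v must be >= 0")
    if (R <= 0).any():
        raise ValueError("radius R must be > 0")
    if (M <= 0).any():
        raise ValueError("territory mass M must be > 0")
    if ((theta < 0) | (theta >= 90)).any():
        raise ValueError("insonation angle must satisfy 0 <= theta < 90 "
                         "degrees (cos(theta) must be positive)")
    return v, R, M, theta


def cbf_tcd(input: FlowInput | None = None, *, v=None, R=None, D=None,
            M=REFERENCE_MASS_G, theta=0.0, units: str = "schema",
            conversion: float | None = None):
    """Poiseuille CBF estimate pi R^2 M v / (2 cos theta).

    Accepts either a :class:`FlowInput` or keyword scalars/arrays.
    ``units="schema"`` converts cohort-schema units (cm/s, mm, g, degrees)
    to ml/min/100g via ``conversion`` (default
    :data:`DEFAULT_CONVERSION`); ``units="raw"`` evaluates the bare
    formula on the inputs as given, e.g. v=2, R=1, M=1, theta=0 -> pi.
    """
    if input is not None:
        v, R, M, theta = input.v, input.radius, input.M, input.theta
    elif R is None:
        if D is None:
            raise ValueError("provide R or D")
        R = np.asarray(D, dtype=float) / 2.0
    v, R, M, theta = _validate(v, R, M, theta)
    core = math.pi * R ** 2 * M * v / (2.0 * np.cos(np.deg2rad(theta)))
    if units == "raw":
        out = core
    elif units == "schema":
        c = DEFAULT_CONVERSION if conversion is None else conversion
        out = c * core
    else:
        raise ValueError(f"units must be 'schema' or 'raw', got {units!r}")
    return float(out) if np.ndim(out) == 0 else out


def cbf_tcd_table(table: pd.DataFrame, conversion: float | None = None,
                  column: str = "cbf_tcd") -> pd.DataFrame:
    """Add the Poiseuille estimate for every row where ``bfv``,
    ``mca_diameter``, ``mass_M`` and ``insonation_angle`` are all
    observed; other rows get a missing estimate."""
    need = ["bfv", "mca_diameter", "mass_M", "insonation_angle"]
    out = table.copy()
    ok = out[need].notna().all(axis=1)
    est = np.full(len(out), np.nan)
    if ok.any():
        sub = out.loc[ok]
        est[np.asarray(ok)] = cbf_tcd(
            v=sub["bfv"].to_numpy(), D=sub["mca_diameter"].to_numpy(),
            M=sub["mass_M"].to_numpy(),
            theta=sub["insonation_angle"].to_numpy(),
            conversion=conversion)
    out[column] = est
    return out


def diameter_error_propagation(delta):
    """Relative flow error induced by a relative diameter error ``delta``:
    (1 + delta)^2 - 1 = 2*delta + delta^2 (quadratic dependence of flow on
    diameter).  ``delta`` must exceed -1 (positive diameter)."""
    delta = np.asarray(delta, dtype=float)
    if (delta <= -1).any():
        raise ValueError("relative diameter error must be > -1")
    out = (1.0 + delta) ** 2 - 1.0
    return float(out) if np.ndim(out) == 0 else out


def angle_factor(theta):
    """Geometric correction 1 / cos(theta) applied to the velocity reading
    for an insonation angle ``theta`` in degrees, 0 <= theta < 90."""
    theta = np.asarray(theta, dtype=float)
    if ((theta < 0) | (theta >= 90)).any():
        raise ValueError("insonation angle must satisfy 0 <= theta < 90")
    out = 1.0 / np.cos(np.deg2rad(theta))
    return float(out) if np.ndim(out) == 0 else out
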