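"""Synthetic cohorts of paired TCD / pCASL-MRI measurements.

Generates tables with one row per (patient, side, visit): the 11 clinical
predictors — hematocrit, intracranial volume, height, BMI, age, head
length, diabetes, hypertension, gender, TCD blood-flow velocity and MCA
diameter — plus the pCASL cerebral blood flow response, and optionally the
MCA-territory mass and insonation angle needed by the Poiseuille flow
estimator.  Defaults reproduce the published cohort structure: 88 older
patients contributing 261 left/right MCA measurements, ~32% healthy /
~47% hypertensive / ~2% diabetic / ~19% both, group- and side-specific
means and dispersions for every numeric variable, correlated left–right
CBF within a patient, and a missingness process calibrated to leave about
134 of the 261 rows complete.

The predictor→CBF relationship in real data is unknown; the generator
plants a configurable one.  Under ``mode="planted"`` the (standardised)
CBF is a weighted sum of standardised predictors plus a per-patient random
offset and residual noise, rescaled to the configured group/side CBF
moments; under ``mode="null"`` CBF is drawn independently of all
predictors given group and side, with left–right correlation induced by a
shared per-patient latent term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigError",
    "EffectSpec",
    "CohortConfig",
    "generate_cohort",
    "inject_missingness",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
    "PREDICTORS",
    "RESPONSE",
]

#: CSV schema, in order.  Predictor tie-breaking in the forest follows the
#: relative order of the predictor columns here.
COHORT_COLUMNS = [
    "patient_id", "side", "visit_id",
    "hct", "icv", "height", "bmi", "age", "head_length",
    "diabetes", "hypertension", "gender", "bfv", "mca_diameter",
    "mass_M", "insonation_angle", "cbf",
]

PREDICTORS = ["hct", "icv", "height", "bmi", "age", "head_length",
              "diabetes", "hypertension", "gender", "bfv", "mca_diameter"]
CATEGORICAL_PREDICTORS = ["diabetes", "hypertension", "gender"]
RESPONSE = "cbf"

GROUPS = ["healthy", "HTN", "DM", "DM-HTN"]

#: Measurements-per-patient distribution of the 88-patient cohort
#: (count of measurements -> number of patients); totals 261 measurements.
DEFAULT_MEASUREMENT_DISTRIBUTION = {1: 1, 2: 49, 3: 1, 4: 32, 5: 1, 6: 3,
                                    7: 0, 8: 1}

DEFAULT_GROUP_PROPORTIONS = {"healthy": 28 / 88, "HTN": 41 / 88,
                             "DM": 2 / 88, "DM-HTN": 17 / 88}

#: (mean, sd) of side-independent numeric covariates, healthy vs diseased.
#: Published tables pool the three diseased subgroups, so they share moments.
DEFAULT_SIDE_INDEPENDENT = {
    "height":      {"healthy": (1.67, 0.0954), "diseased": (1.65, 0.0934)},
    "bmi":         {"healthy": (25.9, 4.04),   "diseased": (27.3, 5.24)},
    "head_length": {"healthy": (1.90, 0.106),  "diseased": (1.92, 0.171)},
    "icv":         {"healthy": (1547.0, 211.0), "diseased": (1634.0, 248.0)},
    "hct":         {"healthy": (40.6, 3.50),   "diseased": (39.5, 3.12)},
    # age is only published overall (67.7 +/- 8.02 y); both groups share it
    "age":         {"healthy": (67.7, 8.02),   "diseased": (67.7, 8.02)},
}

#: (mean, sd) of side-dependent numeric variables by (health, side).
DEFAULT_SIDE_DEPENDENT = {
    "bfv": {("healthy", "L"): (40.6, 13.5), ("healthy", "R"): (38.9, 15.9),
            ("diseased", "L"): (41.9, 11.9), ("diseased", "R"): (39.2, 14.0)},
    "mca_diameter": {("healthy", "L"): (2.35, 0.388),
                     ("healthy", "R"): (2.33, 0.309),
                     ("diseased", "L"): (2.48, 0.261),
                     ("diseased", "R"): (2.50, 0.258)},
    "cbf": {("healthy", "L"): (40.7, 9.27), ("healthy", "R"): (40.3, 8.86),
            ("diseased", "L"): (37.8, 9.25), ("diseased", "R"): (37.0, 10.2)},
}

#: Default per-variable missing probability for the seven measured numeric
#: predictors, calibrated so that under independent cell-wise missingness
#: the expected number of complete rows is 261 * (1-q)^7 = 134.
_MEASURED_VARS = ["hct", "icv", "height", "bmi", "head_length",
                  "bfv", "mca_diameter"]
_Q_COMPLETE = 1.0 - (134.0 / 261.0) ** (1.0 / len(_MEASURED_VARS))
DEFAULT_MISSINGNESS = {v: _Q_COMPLETE for v in _MEASURED_VARS}


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class EffectSpec:
    """Planted predictor→CBF relationship.

    ``mode="null"`` draws CBF independently of all predictors given group
    and side.  ``mode="planted"`` builds standardised CBF as
    ``sum(coefficients[j] * z_j) + patient_offset + noise`` with
    ``patient_offset ~ N(0, patient_effect_sd^2)`` and
    ``noise ~ N(0, noise_sd^2)``, then rescales to the configured CBF
    moments.  The default plants a weak covariate signal under a strong
    per-patient offset, mirroring a cohort in which left and right CBF of
    one patient resemble each other far more than covariates predict CBF
    across patients.
    """

    mode: str = "planted"
    coefficients: Mapping[str, float] = field(default_factory=lambda: {
        "bfv": 0.20, "hct": 0.20, "age": -0.15, "icv": 0.10, "bmi": -0.10})
    patient_effect_sd: float = 0.85
    noise_sd: float = 0.45

    def validate(self) -> None:
        if self.mode not in ("null", "planted"):
            raise ConfigError(f"effect_spec.mode must be 'null' or "
                              f"'planted', got {self.mode!r}")
        if self.patient_effect_sd < 0:
            raise ConfigError("effect_spec.patient_effect_sd must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("effect_spec.noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults reproduce the published
    cohort structure (see module docstring).

    ``lr_cbf_correlation`` is the within-patient left–right CBF correlation
    under the null effect mode (the variance fraction of a shared
    per-patient latent term).  ``visit_variance_fraction`` is the share of
    a side-dependent variable's variance that is re-drawn at every visit;
    the rest sits in a per-(patient, side) latent, so repeat visits
    resemble each other.  ``angle_mass_rows`` bounds how many rows carry
    the optional territory mass / insonation angle columns.
    """

    n_patients: int = 88
    measurement_count_distribution: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_DISTRIBUTION))
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS))
    side_independent_params: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SIDE_INDEPENDENT.items()})
    side_dependent_params: Mapping[str, Mapping[tuple, tuple]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SIDE_DEPENDENT.items()})
    male_fraction: float = 38 / 88
    lr_cbf_correlation: float = 0.7
    visit_variance_fraction: float = 0.3
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    missingness_spec: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    angle_mass_rows: int = 98
    mass_params: tuple = (230.0, 30.0)
    angle_range_deg: tuple = (0.0, 40.0)
    seed: int = 0

    @classmethod
    def simple(cls, n_patients: int, measurements_per_patient: int = 2,
               **kwargs) -> "CohortConfig":
        """Uniform measurements-per-patient convenience constructor."""
        return cls(n_patients=n_patients,
                   measurement_count_distribution={
                       measurements_per_patient: n_patients},
                   **kwargs)

    @property
    def n_measurements(self) -> int:
        return sum(k * n for k, n in
                   self.measurement_count_distribution.items())

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        dist = self.measurement_count_distribution
        if any(k < 1 or n < 0 for k, n in dist.items()):
            raise ConfigError("measurement_count_distribution entries must "
                              "map positive counts to >= 0 patients")
        if sum(dist.values()) != self.n_patients:
            raise ConfigError(
                "measurement_count_distribution totals "
                f"{sum(dist.values())} patients, expected {self.n_patients}")
        tot = sum(self.group_proportions.get(g, 0.0) for g in GROUPS)
        if set(self.group_proportions) - set(GROUPS):
            raise ConfigError("group_proportions has unknown groups "
                              f"{set(self.group_proportions) - set(GROUPS)}")
        if abs(tot - 1.0) > 1e-12:
            raise ConfigError(f"group_proportions sum to {tot}, expected 1")
        for var, by in self.side_independent_params.items():
            for h, (mu, sd) in by.items():
                if sd < 0:
                    raise ConfigError(
                        f"side_independent_params[{var!r}][{h!r}] sd < 0")
        for var, by in self.side_dependent_params.items():
            for key, (mu, sd) in by.items():
                if sd < 0:
                    raise ConfigError(
                        f"side_dependent_params[{var!r}][{key!r}] sd < 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must be in [0, 1]")
        if not 0.0 <= self.lr_cbf_correlation <= 1.0:
            raise ConfigError("lr_cbf_correlation must be in [0, 1]")
        if not 0.0 <= self.visit_variance_fraction <= 1.0:
            raise ConfigError("visit_variance_fraction must be in [0, 1]")
        for var, q in self.missingness_spec.items():
            if not 0.0 <= q <= 1.0:
                raise ConfigError(
                    f"missingness_spec[{var!r}] = {q} outside [0, 1]")
        if self.angle_mass_rows < 0:
            raise ConfigError("angle_mass_rows must be >= 0")
        if self.mass_params[1] < 0:
            raise ConfigError("mass_params sd must be >= 0")
        lo, hi = self.angle_range_deg
        if not (0.0 <= lo <= hi < 90.0):
            raise ConfigError("angle_range_deg must satisfy 0 <= lo <= hi < 90")
        self.effect_spec.validate()


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated at zero; exact via scipy's truncnorm."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size).copy()
    out = mean.copy()
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(a, np.inf, loc=mean[pos],
                                       scale=sd[pos], random_state=rng)
    return out


def _group_counts(config) -> dict:
    """Integer group sizes by largest remainder, preserving the total."""
    P = config.n_patients
    raw = {g: config.group_proportions.get(g, 0.0) * P for g in GROUPS}
    base = {g: int(math.floor(v)) for g, v in raw.items()}
    short = P - sum(base.values())
    order = sorted(GROUPS, key=lambda g: raw[g] - base[g], reverse=True)
    for g in order[:short]:
        base[g] += 1
    return base


def _row_layout(config, rng):
    """Assign each patient a group and a (side, visit) layout.

    A patient with k measurements attends ceil(k/2) visits; each visit
    yields a left and a right measurement, except the last visit of a
    patient with odd k, which yields a single left one.
    """
    P = config.n_patients
    counts = _group_counts(config)
    groups = np.array([g for g in GROUPS for _ in range(counts[g])])
    rng.shuffle(groups)
    ks = np.repeat(
        list(config.measurement_count_distribution.keys()),
        list(config.measurement_count_distribution.values()))
    rng.shuffle(ks)
    pid, side, visit = [], [], []
    for i in range(P):
        k = int(ks[i])
        n_visits = (k + 1) // 2
        laid = 0
        for v in range(1, n_visits + 1):
            for s in ("L", "R"):
                if laid == k:
                    break
                pid.append(i)
                side.append(s)
                visit.append(v)
                laid += 1
    return groups, np.asarray(pid), np.asarray(side), np.asarray(visit)


def _positive_composite(rng, mean, latent_part, noise_sd, max_tries=200):
    """mean + latent + N(0, noise_sd) with the visit-level noise redrawn
    until the composite is positive (row-wise rejection, preserving the
    latent structure).  ``noise_sd`` may be scalar or per-row."""
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), mean.shape)
    noise = rng.standard_normal(mean.shape) * sd
    vals = mean + latent_part + noise
    for _ in range(max_tries):
        bad = vals <= 0
        if not bad.any():
            return vals, noise
        noise[bad] = rng.standard_normal(int(bad.sum())) * sd[bad]
        vals = mean + latent_part + noise
    return np.maximum(vals, np.finfo(float).tiny), noise


def _lookup_side_dep(params, health_row, side_row):
    mu = np.empty(len(health_row))
    sd = np.empty(len(health_row))
    for h in ("healthy", "diseased"):
        for s in ("L", "R"):
            m = (health_row == h) & (side_row == s)
            if m.any():
                mu[m], sd[m] = params[(h, s)]
    return mu, sd


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a fully observed cohort table per ``config``.

    Returns a frame in the :data:`COHORT_COLUMNS` schema (``mass_M`` and
    ``insonation_angle`` are populated only for ``config.angle_mass_rows``
    randomly chosen rows and left missing elsewhere; every other column is
    fully observed).  Identical config and seed give a bit-identical table.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_patients
    groups, pid, side, visit = _row_layout(config, rng)
    N = len(pid)
    health = np.where(groups == "healthy", "healthy", "diseased")
    health_row = health[pid]
    side_row = side

    # patient-level demographics
    gender = np.where(rng.random(P) < config.male_fraction, "M", "F")
    diabetes = np.where(np.isin(groups, ["DM", "DM-HTN"]), "Y", "N")
    hypertension = np.where(np.isin(groups, ["HTN", "DM-HTN"]), "Y", "N")

    # side-independent numeric covariates, one draw per patient
    si_vals = {}
    for var, by in config.side_independent_params.items():
        mu = np.where(health == "healthy", by["healthy"][0], by["diseased"][0])
        sd = np.where(health == "healthy", by["healthy"][1], by["diseased"][1])
        si_vals[var] = _truncated_normal(rng, mu, sd, (P,))

    f = config.visit_variance_fraction
    # per-(patient, side) latents for side-dependent predictors
    sd_vals = {}
    for var in ("bfv", "mca_diameter"):
        params = config.side_dependent_params[var]
        a_ps = rng.standard_normal((P, 2))
        mu_row, sd_row = _lookup_side_dep(params, health_row, side_row)
        s_idx = (side_row == "R").astype(int)
        latent = sd_row * math.sqrt(1.0 - f) * a_ps[pid, s_idx]
        vals, _ = _positive_composite(rng, mu_row, latent,
                                      sd_row * math.sqrt(f))
        sd_vals[var] = vals

    # response
    cbf_params = config.side_dependent_params["cbf"]
    mu_c, sd_c = _lookup_side_dep(cbf_params, health_row, side_row)
    s_idx = (side_row == "R").astype(int)
    spec = config.effect_spec
    if spec.mode == "null":
        rho = config.lr_cbf_correlation
        z_p = rng.standard_normal(P)
        b_ps = rng.standard_normal((P, 2))
        latent = sd_c * (math.sqrt(rho) * z_p[pid]
                         + math.sqrt((1.0 - rho) * (1.0 - f))
                         * b_ps[pid, s_idx])
        cbf, _ = _positive_composite(rng, mu_c, latent,
                                     sd_c * math.sqrt((1.0 - rho) * f))
    else:
        score = np.zeros(N)
        var_total = spec.patient_effect_sd ** 2 + spec.noise_sd ** 2
        for var, coef in spec.coefficients.items():
            z = _standardize_predictor(
                var, config, health_row, side_row,
                si_vals, sd_vals, pid, gender, diabetes, hypertension)
            score += coef * z
            var_total += coef ** 2
        if var_total <= 0:
            var_total = 1.0
        offset = rng.standard_normal(P) * spec.patient_effect_sd
        scale = sd_c / math.sqrt(var_total)
        latent = scale * (score + offset[pid])
        cbf, _ = _positive_composite(rng, mu_c, latent,
                                     scale * spec.noise_sd)

    # optional territory mass and insonation angle
    mass = np.full(N, np.nan)
    theta = np.full(N, np.nan)
    n_sub = min(config.angle_mass_rows, N)
    if n_sub > 0:
        subset = rng.choice(N, size=n_sub, replace=False)
        mass[subset] = _truncated_normal(
            rng, config.mass_params[0], config.mass_params[1], (n_sub,))
        lo, hi = config.angle_range_deg
        theta[subset] = rng.uniform(lo, hi, size=n_sub)

    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:03d}" for i in pid],
        "side": side_row,
        "visit_id": visit,
        "hct": si_vals["hct"][pid],
        "icv": si_vals["icv"][pid],
        "height": si_vals["height"][pid],
        "bmi": si_vals["bmi"][pid],
        "age": si_vals["age"][pid],
        "head_length": si_vals["head_length"][pid],
        "diabetes": diabetes[pid],
        "hypertension": hypertension[pid],
        "gender": gender[pid],
        "bfv": sd_vals["bfv"],
        "mca_diameter": sd_vals["mca_diameter"],
        "mass_M": mass,
        "insonation_angle": theta,
        "cbf": cbf,
    }, columns=COHORT_COLUMNS)
    return df


def _standardize_predictor(var, config, health_row, side_row, si_vals,
                           sd_vals, pid, gender, diabetes, hypertension):
    """z-score a predictor against its own generating moments (categorical
    predictors become standardised indicators)."""
    if var in si_vals:
        by = config.side_independent_params[var]
        mu = np.where(health_row == "healthy", by["healthy"][0],
                      by["diseased"][0])
        sd = np.where(health_row == "healthy", by["healthy"][1],
                      by["diseased"][1])
        vals = si_vals[var][pid]
    elif var in sd_vals:
        mu, sd = _lookup_side_dep(config.side_dependent_params[var],
                                  health_row, side_row)
        vals = sd_vals[var]
    elif var in ("diabetes", "hypertension", "gender"):
        raw = {"diabetes": diabetes, "hypertension": hypertension,
               "gender": gender}[var][pid]
        pos = {"diabetes": "Y", "hypertension": "Y", "gender": "M"}[var]
        if var == "gender":
            q = config.male_fraction
        elif var == "diabetes":
            q = (config.group_proportions.get("DM", 0.0)
                 + config.group_proportions.get("DM-HTN", 0.0))
        else:
            q = (config.group_proportions.get("HTN", 0.0)
                 + config.group_proportions.get("DM-HTN", 0.0))
        sd1 = math.sqrt(q * (1.0 - q)) or 1.0
        return ((raw == pos).astype(float) - q) / sd1
    else:
        raise ConfigError(f"effect_spec.coefficients names unknown "
                          f"predictor {var!r}")
    z = np.zeros(len(vals))
    nz = sd > 0
    z[nz] = (vals[nz] - mu[nz]) / sd[nz]
    return z


def inject_missingness(table: pd.DataFrame,
                       spec: Mapping[str, float] | None = None,
                       seed: int = 0,
                       exempt: tuple = (RESPONSE,),
                       mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Set cells missing, independently per cell with per-variable
    probability (missing completely at random).

    ``spec`` maps column name → missing probability; the default is
    calibrated so a 261-row default cohort keeps ≈134 complete rows.
    Columns in ``exempt`` are skipped even if listed.  A user-supplied
    boolean ``mask`` (True = set missing) overrides the MCAR mechanism and
    supports arbitrary missingness processes.  Observed cells are returned
    unchanged; the input table is not modified.
    """
    out = table.copy()
    if mask is not None:
        for c in mask.columns:
            if c in exempt or c not in out.columns:
                continue
            out.loc[np.asarray(mask[c], dtype=bool), c] = np.nan
        return out
    if spec is None:
        spec = DEFAULT_MISSINGNESS
    for var, q in spec.items():
        if not 0.0 <= q <= 1.0:
            raise ConfigError(f"missingness probability for {var!r} is {q}, "
                              "outside [0, 1]")
    rng = np.random.default_rng(seed)
    for var, q in spec.items():
        if var in exempt or var not in out.columns:
            continue
        hit = rng.random(len(out)) < q
        if hit.any():
            out.loc[hit, var] = np.nan
    return out


def expected_complete_rows(n_rows: int,
                           spec: Mapping[str, float] | None = None) -> float:
    """Expected number of fully observed rows under independent cell-wise
    missingness: n * prod_j (1 - q_j)."""
    if spec is None:
        spec = DEFAULT_MISSINGNESS
    p = 1.0
    for q in spec.values():
        p *= 1.0 - q
    return n_rows * p


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write the cohort schema CSV (missing cells empty)."""
    table.reindex(columns=COHORT_COLUMNS).to_csv(path, index=False,
                                                 na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort schema CSV back into the canonical dtypes."""
    df = pd.read_csv(path, dtype={"patient_id": str, "side": str,
                                  "diabetes": str, "hypertension": str,
                                  "gender": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks columns {missing}")
    return df[COHORT_COLUMNS]
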