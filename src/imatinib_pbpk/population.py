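"""Virtual individuals and virtual twins.

Generates the physiology the PBPK engine consumes: demographics, body
size, liver weight and hepatic blood flow (with age decline), MPPGL,
hepatic CYP3A4/CYP2C8 abundances drawn from truncated log-normals with a
Gaussian-copula rank correlation, gut CYP3A4, hepatobiliary transporter
abundances, AAG (ancestry- and sex-specific), serum creatinine and eGFR
(CKD-EPI 2009).  Special populations (cirrhosis Child-Pugh A/B/C, renal
impairment bands) are produced by multiplier tables, and real patient
covariate records map to "virtual twins": observed covariates fixed,
unobserved physiology sampled conditional on demographics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (ConfigurationError, DomainError, SystemDefaults,
                     ValidationError, ANCESTRIES, TRANSPORTERS, _Dist)
from .mechanisms import unbound_fraction

__all__ = [
    "Individual", "PatientRecord",
    "egfr_ckd_epi", "bsa_du_bois",
    "sample_individual", "apply_special_population", "make_virtual_twin",
    "read_cohort_csv", "write_cohort_csv", "records_from_frame",
]

UMOL_PER_MGDL_CREATININE = 88.42

# hard physiologic truncation for body size draws
WEIGHT_BOUNDS = (35.0, 200.0)
HEIGHT_BOUNDS = (140.0, 210.0)


@dataclass
class Individual:
    """One virtual subject's physiology."""
    id: str
    age: float                       # years
    sex: str                         # 'M' | 'F'
    ancestry: str
    weight: float                    # kg
    height: float                    # cm
    bsa: float                       # m2
    liver_weight: float              # g
    liver_weight_ref: float          # g (reference, for biliary scaling)
    mppgl: float                     # mg microsomal protein / g liver
    qh: float                        # L/h hepatic blood flow
    enzyme_abundance: dict           # hepatic pmol/mg; gut nmol total
    transporter_abundance: dict      # pmol / 1e6 hepatocytes
    aag: float                       # g/L
    serum_creatinine: float          # umol/L
    egfr: float                      # mL/min/1.73 m2
    cirrhosis_class: str = "none"
    renal_band: str = "normal"
    fu_baseline: Optional[float] = None  # dilute-drug unbound fraction

    def __post_init__(self):
        for name in ("age", "weight", "height", "bsa", "liver_weight",
                     "mppgl", "qh", "aag", "serum_creatinine"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValidationError(f"Individual.{name} must be positive, got {v!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")

    def replace(self, **kw) -> "Individual":
        return dataclasses.replace(self, **kw)


@dataclass
class PatientRecord:
    """One row of the (real or synthetic) patient covariate table."""
    id: str
    age: float
    sex: str
    ancestry: str
    dose_mg_per_day: float
    weight: Optional[float] = None
    height: Optional[float] = None
    serum_creatinine: Optional[float] = None
    cirrhosis_class: str = "none"
    comedications: list = field(default_factory=list)
    emr_evaluable: Optional[bool] = None
    emr_achieved: Optional[bool] = None
    adr_grade3: Optional[bool] = None

    def __post_init__(self):
        for name in ("age", "sex", "ancestry"):
            if getattr(self, name) in (None, ""):
                raise ValidationError(f"PatientRecord.{name} is mandatory")
        if self.dose_mg_per_day is None or self.dose_mg_per_day <= 0:
            raise ValidationError("PatientRecord.dose_mg_per_day must be positive")
        if self.ancestry not in ANCESTRIES:
            raise ConfigurationError(f"unknown ancestry {self.ancestry!r}")


# ---------------------------------------------------------------------------
# deterministic covariate equations
# ---------------------------------------------------------------------------

def bsa_du_bois(weight_kg: float, height_cm: float) -> float:
    """Du Bois & Du Bois body surface area, m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725


def egfr_ckd_epi(sex: str, age: float, serum_creatinine: float) -> float:
    """CKD-EPI 2009 creatinine equation, mL/min/1.73 m^2.

    Original published constants (no race coefficient applied); serum
    creatinine is taken in umol/L and converted to mg/dL internally.
    """
    if age <= 0 or serum_creatinine <= 0:
        raise DomainError("age and serum creatinine must be positive")
    if sex not in ("M", "F"):
        raise DomainError(f"sex must be 'M' or 'F', got {sex!r}")
    scr = serum_creatinine / UMOL_PER_MGDL_CREATININE
    kappa, alpha = (0.7, -0.329) if sex == "F" else (0.9, -0.411)
    egfr = (141.0 * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** -1.209 * 0.993 ** age)
    if sex == "F":
        egfr *= 1.018
    return egfr


def _creatinine_for_egfr(sex: str, age: float, egfr_target: float) -> float:
    """Invert CKD-EPI for the creatinine giving a target eGFR."""
    f = lambda scr: egfr_ckd_epi(sex, age, scr) - egfr_target
    return optimize.brentq(f, 10.0, 2000.0, xtol=1e-8)


def _liver_weight(defaults: SystemDefaults, bsa: float, age: float) -> float:
    decline = defaults.liver_age_decline_per_y * max(age - defaults.liver_age_onset_y, 0.0)
    return (defaults.liver_weight_coeff * bsa ** defaults.liver_weight_bsa_exponent
            * max(1.0 - decline, 0.4))


def _hepatic_flow(defaults: SystemDefaults, bsa: float, age: float) -> float:
    decline = defaults.qh_age_decline_per_y * max(age - defaults.qh_age_onset_y, 0.0)
    return (defaults.qh_ref * (bsa / defaults.bsa_ref) ** defaults.qh_bsa_exponent
            * max(1.0 - decline, 0.4))


# ---------------------------------------------------------------------------
# truncated distributions via inverse-CDF (keeps copula ranks intact)
# ---------------------------------------------------------------------------

def _lognorm_params(mean: float, cv: float):
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)

def _trunc_lognorm_ppf(u: float, dist: _Dist) -> float:
    mu, sigma = _lognorm_params(dist.mean, dist.cv)
    lo = stats.norm.cdf((math.log(max(dist.min, 1e-300)) - mu) / sigma) if dist.min > 0 else 0.0
    hi = stats.norm.cdf((math.log(dist.max) - mu) / sigma)
    z = stats.norm.ppf(lo + u * (hi - lo))
    return float(np.exp(mu + sigma * z))

def _trunc_normal_ppf(u: float, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def sample_individual(defaults: SystemDefaults, demographics: dict, seed,
                      drug=None, overrides: dict | None = None) -> Individual:
    """Draw one virtual individual.

    ``demographics`` fixes or bounds age / sex / ancestry (keys ``age``,
    ``sex``, ``ancestry``, ``age_range``, ``prop_female``); everything else
    is sampled from the configured population distributions.  Hepatic
    CYP3A4 and CYP2C8 are drawn through a Gaussian copula so their
    Spearman rank correlation matches the configured value while the
    truncated log-normal marginals are preserved exactly (inverse-CDF
    transform of the copula uniforms).

    ``overrides`` pins individual parameters after (or, for body size,
    before) the derived quantities are computed; used by the sensitivity
    sweeps.  Deterministic given ``seed``.
    """
    overrides = dict(overrides or {})
    rng = _rng_from(seed)
    ancestry = demographics.get("ancestry", "European")
    if ancestry not in ANCESTRIES:
        raise ConfigurationError(f"unknown ancestry {ancestry!r}")

    # fixed draw order keeps a given seed reproducible
    age_lo, age_hi = demographics.get("age_range", (20.0, 91.0))
    age = demographics.get("age")
    u_age = rng.uniform()
    if age is None:
        age = age_lo + u_age * (age_hi - age_lo)
    sex = demographics.get("sex")
    u_sex = rng.uniform()
    if sex is None:
        sex = "F" if u_sex < demographics.get("prop_female", 0.4) else "M"
    age = overrides.pop("age", age)
    sex = overrides.pop("sex", sex)

    size = defaults.body_size[ancestry][sex]
    weight = _trunc_normal_ppf(rng.uniform(), size["weight_mean"],
                               size["weight_sd"], *WEIGHT_BOUNDS)
    height = _trunc_normal_ppf(rng.uniform(), size["height_mean"],
                               size["height_sd"], *HEIGHT_BOUNDS)
    weight = overrides.pop("weight", weight)
    height = overrides.pop("height", height)

    mppgl = _trunc_lognorm_ppf(rng.uniform(), defaults.mppgl)

    # hepatic CYP3A4 / CYP2C8 through the Gaussian copula
    rs = defaults.cyp3a4_cyp2c8_rank_correlation
    rho = 2.0 * math.sin(math.pi * rs / 6.0)  # Spearman -> Pearson on normal scores
    z1, z2 = rng.standard_normal(2)
    z2 = rho * z1 + math.sqrt(max(1.0 - rho * rho, 0.0)) * z2
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    enzyme_abundance = {
        "CYP3A4_hepatic": _trunc_lognorm_ppf(u1, defaults.enzyme_abundance["CYP3A4_hepatic"]),
        "CYP2C8_hepatic": _trunc_lognorm_ppf(u2, defaults.enzyme_abundance["CYP2C8_hepatic"]),
        "CYP3A4_gut": _trunc_lognorm_ppf(rng.uniform(), defaults.enzyme_abundance["CYP3A4_gut"]),
    }
    transporter_abundance = {
        t: _trunc_lognorm_ppf(rng.uniform(), defaults.transporter_abundance[t])
        for t in TRANSPORTERS
    }

    aag_spec = defaults.aag[ancestry]
    aag_mean = aag_spec["male_mean"] if sex == "M" else aag_spec["female_mean"]
    aag = _trunc_lognorm_ppf(
        rng.uniform(),
        _Dist(mean=aag_mean, cv=aag_spec["cv"], min=aag_spec["min"], max=aag_spec["max"]))

    scr_spec = defaults.serum_creatinine
    scr_mean = scr_spec["male_mean"] if sex == "M" else scr_spec["female_mean"]
    scr_mean *= 1.0 + scr_spec["age_slope_per_y"] * max(age - scr_spec["age_onset_y"], 0.0)
    scr = _trunc_lognorm_ppf(
        rng.uniform(),
        _Dist(mean=scr_mean, cv=scr_spec["cv"], min=scr_spec["min"], max=scr_spec["max"]))
    scr = overrides.pop("serum_creatinine", scr)

    for key in ("CYP3A4_hepatic", "CYP2C8_hepatic", "CYP3A4_gut"):
        if key in overrides:
            enzyme_abundance[key] = max(float(overrides.pop(key)), 1e-12)
    for key in TRANSPORTERS:
        if key in overrides:
            transporter_abundance[key] = max(float(overrides.pop(key)), 1e-12)
    aag = overrides.pop("AAG", aag)
    if overrides:
        raise ConfigurationError(f"unknown override(s): {sorted(overrides)}")

    bsa = bsa_du_bois(weight, height)
    ind = Individual(
        id=demographics.get("id", "virtual"),
        age=age, sex=sex, ancestry=ancestry,
        weight=weight, height=height, bsa=bsa,
        liver_weight=_liver_weight(defaults, bsa, age),
        liver_weight_ref=defaults.liver_weight_ref,
        mppgl=mppgl,
        qh=_hepatic_flow(defaults, bsa, age),
        enzyme_abundance=enzyme_abundance,
        transporter_abundance=transporter_abundance,
        aag=aag,
        serum_creatinine=scr,
        egfr=egfr_ckd_epi(sex, age, scr),
    )
    if drug is not None:
        ind.fu_baseline = unbound_fraction(
            0.0, ind.aag, drug.kd_app, drug.binding_capacity_per_aag,
            drug.molecular_weight, drug.aag_molecular_weight)
    return ind


# ---------------------------------------------------------------------------
# special populations
# ---------------------------------------------------------------------------

def apply_special_population(ind: Individual, condition: str,
                             defaults: SystemDefaults,
                             modified_renal: bool = False) -> Individual:
    """Apply a disease multiplier table to a healthy individual.

    ``condition`` is ``"cirrhosis_A" | "cirrhosis_B" | "cirrhosis_C" |
    "renal_30to60" | "renal_lt30"``.  Cirrhosis reduces liver weight,
    hepatic blood flow, CYP abundances and AAG with severity A < B < C.
    Renal impairment raises AAG (acute-phase response) and, in the default
    mode, reduces CYP abundances; ``modified_renal`` keeps healthy CYP
    abundances.  Conditions cannot be stacked.
    """
    if ind.cirrhosis_class != "none" or ind.renal_band != "normal":
        raise ValidationError(
            "individual already carries a special-population condition; "
            "stacking is unsupported")
    if condition.startswith("cirrhosis_"):
        cls = condition.split("_", 1)[1]
        try:
            table = defaults.cirrhosis_multipliers[cls]
        except KeyError:
            raise ConfigurationError(f"no cirrhosis multipliers for {cls!r}") from None
        enz = dict(ind.enzyme_abundance)
        for e in ("CYP3A4_hepatic", "CYP2C8_hepatic"):
            enz[e] = enz[e] * table["cyp_abundance"]
        return ind.replace(
            liver_weight=ind.liver_weight * table["liver_weight"],
            qh=ind.qh * table["qh"],
            enzyme_abundance=enz,
            aag=ind.aag * table["aag"],
            fu_baseline=None,
            cirrhosis_class=cls,
        )
    if condition.startswith("renal_"):
        band = condition.split("_", 1)[1]
        try:
            table = defaults.renal_multipliers[band]
        except KeyError:
            raise ConfigurationError(f"no renal multipliers for {band!r}") from None
        enz = dict(ind.enzyme_abundance)
        if not modified_renal:
            for e in ("CYP3A4_hepatic", "CYP2C8_hepatic"):
                enz[e] = enz[e] * table["cyp_abundance"]
        egfr = table["egfr_target"]
        return ind.replace(
            enzyme_abundance=enz,
            aag=ind.aag * table["aag"],
            serum_creatinine=_creatinine_for_egfr(ind.sex, ind.age, egfr),
            egfr=egfr,
            fu_baseline=None,
            renal_band=band,
        )
    raise ConfigurationError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# virtual twins
# ---------------------------------------------------------------------------

def make_virtual_twin(rec: PatientRecord, defaults: SystemDefaults, seed,
                      drug=None) -> Individual:
    """Individual whose observed covariates match a patient record.

    Age, sex, ancestry, weight, height, serum creatinine and cirrhosis
    class are fixed to the record where present; missing weight/height are
    imputed with the ancestry/sex distribution medians; unobserved
    physiology (enzyme/transporter abundances, MPPGL, AAG) is sampled
    conditional on the demographics.  Deterministic given ``seed``.
    """
    demographics = {"id": rec.id, "age": rec.age, "sex": rec.sex,
                    "ancestry": rec.ancestry}
    overrides = {}
    size = defaults.body_size[rec.ancestry][rec.sex]
    overrides["weight"] = rec.weight if rec.weight else size["weight_mean"]
    overrides["height"] = rec.height if rec.height else size["height_mean"]
    if rec.serum_creatinine:
        overrides["serum_creatinine"] = rec.serum_creatinine
    ind = sample_individual(defaults, demographics, seed, drug=drug,
                            overrides=overrides)
    if rec.cirrhosis_class not in (None, "", "none"):
        ind = apply_special_population(ind, f"cirrhosis_{rec.cirrhosis_class}", defaults)
        if drug is not None:
            ind.fu_baseline = unbound_fraction(
                0.0, ind.aag, drug.kd_app, drug.binding_capacity_per_aag,
                drug.molecular_weight, drug.aag_molecular_weight)
    return ind


# ---------------------------------------------------------------------------
# cohort CSV schema
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id", "age_y", "sex", "ancestry", "weight_kg", "height_cm",
    "serum_creatinine_umol_l", "cirrhosis_class", "dose_mg_per_day",
    "comedications", "emr_evaluable", "emr_achieved", "adr_grade3",
]


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort frame missing columns {sorted(missing)}")
    frame.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort file missing columns {sorted(missing)}")
    return frame


def _opt_bool(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return bool(v)


def records_from_frame(frame: pd.DataFrame) -> list:
    """Parse cohort rows into validated PatientRecord objects."""
    records = []
    for _, row in frame.iterrows():
        comeds = row.get("comedications")
        if comeds is None or (isinstance(comeds, float) and math.isnan(comeds)) or comeds == "":
            comeds = []
        else:
            comeds = [c for c in str(comeds).split(";") if c]
        def _opt(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v
        cirr = row.get("cirrhosis_class")
        records.append(PatientRecord(
            id=str(row["id"]),
            age=float(row["age_y"]),
            sex=str(row["sex"]),
            ancestry=str(row["ancestry"]),
            dose_mg_per_day=float(row["dose_mg_per_day"]),
            weight=_opt(row.get("weight_kg")),
            height=_opt(row.get("height_cm")),
            serum_creatinine=_opt(row.get("serum_creatinine_umol_l")),
            cirrhosis_class="none" if _opt(cirr) is None else str(cirr),
            comedications=comeds,
            emr_evaluable=_opt_bool(row.get("emr_evaluable")),
            emr_achieved=_opt_bool(row.get("emr_achieved")),
            adr_grade3=_opt_bool(row.get("adr_grade3")),
        ))
    return records
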