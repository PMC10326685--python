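"""Virtual-trial exposure studies, sensitivity sweeps and DDI ratios.

Three study designs sit on top of the engine:

* ``run_virtual_trials`` — repeated trials of independently sampled
  virtual subjects, returning a long-format table of steady-state PK
  metrics (AUC over the final 24-h interval, peak, trough, CL/F).
* ``sensitivity_sweep`` — one-at-a-time parameter sweeps in matched
  subjects: the same virtual subjects (same seeds) are re-simulated at
  each level with only the target parameter overridden, so fold-changes
  between levels are nearly free of Monte-Carlo noise.
* ``ddi_study`` — paired with/without-perpetrator simulation of every
  subject (identical physiology in both arms), summarised as geometric
  mean ratios with 90% confidence intervals and flagged against the
  conventional 0.80–1.25 no-effect interval.

Group contrasts (e.g. by clinical outcome) use the Kruskal–Wallis rank
sum test on the raw metric and a two-sample t-test on the log metric,
two-sided at the 0.05 level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import (ConfigurationError, DomainError, DrugModel,
                     PerpetratorModel, SystemDefaults)
from .engine import DoseRegimen, IntegrationError, SolverOptions, simulate
from .population import (Individual, apply_special_population,
                         make_virtual_twin, sample_individual)

__all__ = [
    "TrialDesign", "GmrResult", "MetricsTable",
    "run_virtual_trials", "geomean_ci", "compare_groups",
    "sensitivity_sweep", "ddi_study", "simulate_cohort_records",
    "NO_EFFECT_INTERVAL", "METRICS",
]

log = logging.getLogger("imatinib_pbpk")

METRICS = ("auc_0_24_ss", "css_max", "css_min", "cl_over_f")
NO_EFFECT_INTERVAL = (0.80, 1.25)
SIGNIFICANCE_LEVEL = 0.05
MAX_FAILURE_FRACTION = 0.10

SWEEP_PARAMETERS = (
    "sex", "age", "weight", "egfr_band", "cirrhosis",
    "CYP3A4_hepatic", "CYP3A4_gut", "CYP2C8_hepatic", "P-gp", "BCRP", "AAG",
)


@dataclass
class TrialDesign:
    """Virtual-trial layout: trials x subjects with a demographic envelope."""
    n_trials: int = 10
    n_subjects: int = 10
    age_range: tuple = (20.0, 91.0)
    prop_female: float = 0.4
    ancestry: str = "European"
    condition: Optional[str] = None   # special population, e.g. "cirrhosis_B"
    modified_renal: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ConfigurationError("n_trials and n_subjects must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must lie in [0, 1]")

    def subject_seed(self, trial: int, subject: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=int(self.seed),
                                      spawn_key=(trial, subject))

    def subject_sex(self, subject: int) -> str:
        # fixed per-trial sex mix (e.g. 4 of 10 female), not Bernoulli draws
        n_female = round(self.prop_female * self.n_subjects)
        return "F" if subject < n_female else "M"


@dataclass
class GmrResult:
    metric: str
    ratio: float
    ci90: tuple
    clinically_significant: bool
    n: int


def _sample_subject(design: TrialDesign, defaults: SystemDefaults,
                    drug: DrugModel, trial: int, subject: int,
                    overrides: dict | None = None) -> Individual:
    demographics = {
        "id": f"t{trial:02d}s{subject:02d}",
        "sex": design.subject_sex(subject),
        "age_range": design.age_range,
        "ancestry": design.ancestry,
    }
    ind = sample_individual(defaults, demographics,
                            design.subject_seed(trial, subject),
                            drug=drug, overrides=overrides)
    if design.condition is not None:
        ind = apply_special_population(ind, design.condition, defaults,
                                       modified_renal=design.modified_renal)
    return ind


MetricsTable = pd.DataFrame  # long format: trial, subject, id, <metrics...>


def run_virtual_trials(design: TrialDesign, drug: DrugModel,
                       defaults: SystemDefaults, regimen: DoseRegimen,
                       scenario: dict | None = None,
                       perpetrator: Optional[PerpetratorModel] = None,
                       options: Optional[SolverOptions] = None) -> MetricsTable:
    """Simulate ``n_trials x n_subjects`` independent subjects.

    ``scenario`` optionally pins individual parameters (see
    ``sample_individual`` overrides).  Subjects that fail to integrate are
    excluded with a warning; more than 10% failures aborts the run.
    Reproducible: the subject at (trial, subject) is always drawn from the
    same seed substream of ``design.seed``.
    """
    options = options or SolverOptions.population()
    rows, failures = [], 0
    total = design.n_trials * design.n_subjects
    for trial in range(design.n_trials):
        for subject in range(design.n_subjects):
            ind = _sample_subject(design, defaults, drug, trial, subject,
                                  overrides=scenario)
            try:
                res = simulate(ind, drug, regimen, perpetrator=perpetrator,
                               options=options, kdeg=defaults.kdeg)
            except IntegrationError as exc:
                failures += 1
                log.warning("subject %s failed to simulate: %s", ind.id, exc)
                if failures > MAX_FAILURE_FRACTION * total:
                    raise RuntimeError(
                        f"{failures}/{total} subjects failed to simulate") from exc
                continue
            row = {"trial": trial, "subject": subject, "id": ind.id}
            row.update(res.metrics)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def geomean_ci(values, level: float = 0.95) -> dict:
    """Geometric mean with a t-based confidence interval on the log scale."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("need at least two values")
    if np.any(x <= 0):
        raise DomainError("geometric statistics require positive values")
    if level not in (0.90, 0.95):
        raise DomainError("confidence level must be 0.90 or 0.95")
    logs = np.log(x)
    gm = math.exp(logs.mean())
    se = logs.std(ddof=1) / math.sqrt(x.size)
    tq = stats.t.ppf(0.5 + level / 2.0, df=x.size - 1)
    half = tq * se
    return {"gm": gm, "ci": (gm * math.exp(-half), gm * math.exp(half)),
            "level": level, "n": int(x.size)}


def compare_groups(table: MetricsTable, labels, metrics=METRICS) -> dict:
    """Contrast PK metrics between two labelled groups.

    ``labels`` is a boolean array-like aligned to the table rows (True =
    index group).  Returns, per metric: geometric means with 95% CIs per
    group, their ratio, the Kruskal–Wallis p-value on the raw metric and
    the two-sample t-test p-value on the log metric (both two-sided).
    """
    lab = np.asarray(labels, dtype=bool)
    if lab.size != len(table):
        raise DomainError("labels must align with the metrics table")
    out = {}
    for metric in metrics:
        x1 = table.loc[lab, metric].to_numpy(dtype=float)
        x0 = table.loc[~lab, metric].to_numpy(dtype=float)
        if x1.size < 2 or x0.size < 2:
            raise DomainError(f"each group needs n >= 2 for {metric}")
        kw = stats.kruskal(x1, x0)
        tt = stats.ttest_ind(np.log(x1), np.log(x0), equal_var=False)
        g1, g0 = geomean_ci(x1), geomean_ci(x0)
        out[metric] = {
            "group1": g1, "group0": g0,
            "gm_ratio": g1["gm"] / g0["gm"],
            "p_kruskal_wallis": float(kw.pvalue),
            "p_t_test": float(tt.pvalue),
            "significant": bool(kw.pvalue < SIGNIFICANCE_LEVEL),
        }
    return out


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------

def _level_design_and_scenario(parameter: str, value, design: TrialDesign):
    """Translate a sweep level into a design/scenario pair."""
    if parameter in ("CYP3A4_hepatic", "CYP2C8_hepatic", "CYP3A4_gut",
                     "P-gp", "BCRP", "AAG", "weight", "age"):
        return design, {parameter: value}
    if parameter == "sex":
        if value not in ("M", "F"):
            raise ConfigurationError(f"sex level must be M or F, got {value!r}")
        return dc_replace(design, prop_female=1.0 if value == "F" else 0.0), None
    if parameter == "cirrhosis":
        cond = None if value in (None, "none") else f"cirrhosis_{value}"
        return dc_replace(design, condition=cond), None
    if parameter == "egfr_band":
        cond = None if value in (None, "normal") else f"renal_{value}"
        return dc_replace(design, condition=cond), None
    raise ConfigurationError(
        f"unknown sweep parameter {parameter!r}; expected one of {SWEEP_PARAMETERS}")


def sensitivity_sweep(parameter: str, values, design: TrialDesign,
                      drug: DrugModel, defaults: SystemDefaults,
                      regimen: DoseRegimen,
                      options: Optional[SolverOptions] = None) -> dict:
    """One-at-a-time sensitivity analysis over ``values`` of one parameter.

    Each level re-simulates the same matched virtual subjects (same seed
    substreams) with only the target parameter overridden.  Reports the
    per-level geometric means, the fold-change of each metric between the
    extreme levels (last / first), Kruskal–Wallis across all levels and a
    Wilcoxon–Mann–Whitney test between the extremes.
    """
    if parameter not in SWEEP_PARAMETERS:
        raise ConfigurationError(
            f"unknown sweep parameter {parameter!r}; expected one of {SWEEP_PARAMETERS}")
    values = list(values)
    if not values:
        raise ConfigurationError("need at least one sweep level")
    tables = []
    for value in values:
        lv_design, scenario = _level_design_and_scenario(parameter, value, design)
        t = run_virtual_trials(lv_design, drug, defaults, regimen,
                               scenario=scenario, options=options)
        t.insert(0, "level", [value] * len(t))
        tables.append(t)
    long = pd.concat(tables, ignore_index=True)

    summary, fold, pct = {}, {}, {}
    for metric in METRICS:
        per_level = [geomean_ci(t[metric]) for t in tables]
        summary[metric] = {str(v): g for v, g in zip(values, per_level)}
        f = per_level[-1]["gm"] / per_level[0]["gm"]
        fold[metric] = f
        pct[metric] = 100.0 * (f - 1.0)
    if len(values) >= 2:
        groups = [t["auc_0_24_ss"].to_numpy(dtype=float) for t in tables]
        p_kw = float(stats.kruskal(*groups).pvalue)
        p_ext = float(stats.mannwhitneyu(groups[0], groups[-1],
                                         alternative="two-sided").pvalue)
    else:
        p_kw = p_ext = float("nan")
    return {
        "parameter": parameter, "values": values, "table": long,
        "summary": summary, "fold_change": fold, "percent_change": pct,
        "p_kruskal_wallis_auc": p_kw, "p_extremes_auc": p_ext,
    }


# ---------------------------------------------------------------------------
# DDI studies
# ---------------------------------------------------------------------------

def ddi_study(drug: DrugModel, defaults: SystemDefaults,
              victim_regimen: DoseRegimen, perpetrator: PerpetratorModel,
              design: TrialDesign,
              options: Optional[SolverOptions] = None,
              baseline: Optional[MetricsTable] = None) -> dict:
    """Paired with/without-perpetrator study.

    Every subject is simulated twice with identical physiology (same seed
    substream), once with and once without the perpetrator, which removes
    between-subject Monte-Carlo noise from the geometric mean ratio.  A
    pre-computed ``baseline`` table from ``run_virtual_trials`` with the
    same design may be supplied to avoid re-simulating the control arm.
    Returns ``GmrResult`` per metric with 90% CIs (t-quantiles on the log
    ratio, subjects pooled over trials) and the 0.80–1.25 no-effect flag.
    """
    options = options or SolverOptions.population()
    if baseline is None:
        baseline = run_virtual_trials(design, drug, defaults, victim_regimen,
                                      options=options)
    with_perp = run_virtual_trials(design, drug, defaults, victim_regimen,
                                   perpetrator=perpetrator, options=options)
    merged = baseline.merge(with_perp, on=["trial", "subject", "id"],
                            suffixes=("_ctrl", "_perp"))
    if len(merged) < 2:
        raise RuntimeError("not enough paired subjects for a GMR")
    results = {}
    for metric in METRICS:
        ratios = (merged[f"{metric}_perp"] / merged[f"{metric}_ctrl"]).to_numpy(dtype=float)
        g = geomean_ci(ratios, level=0.90)
        lo, hi = g["ci"]
        inside = NO_EFFECT_INTERVAL[0] <= lo and hi <= NO_EFFECT_INTERVAL[1]
        results[metric] = GmrResult(metric=metric, ratio=g["gm"], ci90=(lo, hi),
                                    clinically_significant=not inside,
                                    n=g["n"])
    return {"perpetrator": perpetrator.name, "gmr": results,
            "baseline": baseline, "with_perpetrator": with_perp}


# ---------------------------------------------------------------------------
# cohort exposure simulation (virtual twins)
# ---------------------------------------------------------------------------

def simulate_cohort_records(records, drug: DrugModel, defaults: SystemDefaults,
                            seed: int, n_days: int = 14,
                            perpetrators: dict | None = None,
                            options: Optional[SolverOptions] = None) -> pd.DataFrame:
    """Steady-state exposure for a list of patient records via virtual twins.

    Each record's once-daily dose is simulated for ``n_days``; a listed
    comedication (first match against ``perpetrators`` by name) is applied
    as the interaction perpetrator.  Returns one row per record with the
    steady-state metrics.
    """
    options = options or SolverOptions.population()
    perpetrators = perpetrators or {}
    rows = []
    for i, rec in enumerate(records):
        twin = make_virtual_twin(
            rec, defaults, np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)),
            drug=drug)
        regimen = DoseRegimen(dose=rec.dose_mg_per_day, interval=24.0, n_doses=n_days)
        perp = None
        for name in rec.comedications:
            if name in perpetrators:
                perp = perpetrators[name]
                break
        if perp is not None:
            # clip the comedication's regimen to the victim's dosing window
            reg = perp.regimen
            n_max = int((regimen.duration - reg.start_offset) // reg.interval)
            if n_max < 1:
                perp = None
            elif reg.n_doses > n_max:
                perp = dc_replace(perp, regimen=dc_replace(reg, n_doses=n_max))
        res = simulate(twin, drug, regimen, perpetrator=perp, options=options,
                       kdeg=defaults.kdeg)
        row = {"id": rec.id, "dose_mg_per_day": rec.dose_mg_per_day}
        row.update(res.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
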