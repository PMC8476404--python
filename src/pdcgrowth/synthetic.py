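"""Seeded synthetic EMR cohorts with the statistical structure the audits
and difference-in-difference analysis assume.

The generator emulates a paediatric-development-clinic programme:

* four exposure cells (control/intervention arm x pre/post calendar period),
  each enrolling its own children at hospital and health-centre facilities;
* a preterm/low-birthweight case mix (gestational age from a truncated
  normal, birthweight regressed on gestational age);
* the standard visit schedule at 1, 2 and 3 weeks and 1, 2, 4, 6, 9 and 12
  months of age, attended with a fixed probability — late visits of
  pre-period enrollees naturally spill into the post window, producing the
  contaminated visits the cohort filter must drop;
* latent growth: per-child z-score intercepts around a malnourished mean
  with AR(1) visit-to-visit noise; true measurements are produced by
  inverting the LMS reference at the child's corrected age, then measurement
  noise is added;
* nurse recording behaviour: per-metric completion probabilities and
  misclassification probabilities per exposure cell, occasional continuous
  (uncategorised) interval-growth entries, and rare implausible data-entry
  errors.

Everything is deterministic for a fixed seed: one global seed sequence is
split into per-child streams, so output is byte-identical across runs.

A synthetic LMS reference set (documented non-WHO; smooth, plausible curves)
is provided so the whole pipeline runs with no external tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assessment import Child, Visit, assess_visit, interval_threshold
from .errors import ConfigError
from .ingest import DEFAULT_WINDOWS, StudyWindows
from .records import EXPOSURE_GROUPS, INTERVAL_CLASSES, Z_CLASSES
from .reference import (LMSRecord, ReferenceSet, ReferenceTable, inverse_zscore)

# ---------------------------------------------------------------------------
# synthetic reference tables

def _table(indicator: str, sex: str, grid: np.ndarray, L: np.ndarray,
           M: np.ndarray, S: np.ndarray) -> ReferenceTable:
    recs = [LMSRecord(float(x), float(l), float(m), float(s))
            for x, l, m, s in zip(grid, L, M, S)]
    return ReferenceTable(indicator=indicator, sex=sex, records=recs)


def synthetic_reference_set() -> ReferenceSet:
    """Smooth synthetic LMS tables for all three indicators and both sexes.

    These are *not* the WHO 2006 standards — they are invented curves with
    realistic magnitudes (birth weight ~3.3 kg, birth length ~49.9 cm,
    infant growth flattening over the first two years) so that tests and
    simulations exercise the machinery end to end.  Real WHO tables in the
    same file dialect are drop-in replacements.
    """
    rs = ReferenceSet()
    age = np.arange(0.0, 731.0, 5.0)
    length = np.arange(45.0, 110.5, 0.5)
    for sex, f in (("male", 1.0), ("female", 0.96)):
        m_wfa = f * (3.4 + 6.6 * (1.0 - np.exp(-age / 160.0)))
        rs.add(_table("weight_for_age", sex, age,
                      np.full_like(age, 0.3), m_wfa, np.full_like(age, 0.12)))
        m_lfa = f * (49.9 + 35.0 * (1.0 - np.exp(-age / 255.0)))
        rs.add(_table("length_for_age", sex, age,
                      np.ones_like(age), m_lfa, np.full_like(age, 0.035)))
        m_wfl = f * 3.3 * (length / 50.0) ** 2.45
        rs.add(_table("weight_for_length", sex, length,
                      np.full_like(length, 0.2), m_wfl, np.full_like(length, 0.09)))
    return rs


def synthetic_birthweight_percentiles() -> pd.DataFrame:
    """Synthetic (sex, gestational age) -> 10th-percentile birthweight table.

    A stand-in for a user-supplied standard (e.g. INTERGROWTH-21st), built
    from the same birthweight model the cohort generator uses.
    """
    rows = []
    for sex, f in (("male", 1.0), ("female", 0.96)):
        for ga in np.arange(24.0, 43.0, 1.0):
            mean = f * (3300.0 - 170.0 * (40.0 - ga))
            rows.append({"sex": sex, "ga_weeks": ga,
                         "p10_g": max(mean - 1.2816 * 350.0, 300.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation configuration

COMPLETION_METRICS = ("weight", "length", "corrected_age", "lhfa", "wflh",
                      "wfa", "interval_growth")
MISCLASS_METRICS = ("lhfa", "wflh", "wfa", "interval_growth")

# defaults emulate the recording behaviour magnitudes of the programme the
# generator models (high completion of raw measurements, patchy corrected
# age, 60-90% category completion, 10-36% misclassification)
DEFAULT_COMPLETION = {
    ("control", "pre"): {"weight": 1.0, "length": 0.99, "corrected_age": 0.51,
                         "lhfa": 0.77, "wflh": 0.76, "wfa": 0.77, "interval_growth": 0.81},
    ("control", "post"): {"weight": 1.0, "length": 0.99, "corrected_age": 0.55,
                          "lhfa": 0.57, "wflh": 0.59, "wfa": 0.67, "interval_growth": 0.81},
    ("intervention", "pre"): {"weight": 1.0, "length": 1.0, "corrected_age": 0.06,
                              "lhfa": 0.79, "wflh": 0.78, "wfa": 0.79, "interval_growth": 0.82},
    ("intervention", "post"): {"weight": 1.0, "length": 0.99, "corrected_age": 0.65,
                               "lhfa": 0.82, "wflh": 0.90, "wfa": 0.93, "interval_growth": 0.90},
}
DEFAULT_MISCLASSIFICATION = {
    ("control", "pre"): {"lhfa": 0.36, "wflh": 0.26, "wfa": 0.33, "interval_growth": 0.23},
    ("control", "post"): {"lhfa": 0.36, "wflh": 0.25, "wfa": 0.36, "interval_growth": 0.28},
    ("intervention", "pre"): {"lhfa": 0.23, "wflh": 0.15, "wfa": 0.19, "interval_growth": 0.10},
    ("intervention", "post"): {"lhfa": 0.28, "wflh": 0.17, "wfa": 0.25, "interval_growth": 0.13},
}
# latent-growth improvement in the intervention-post cell (and mild decline
# under control-post), emulating the programme-effect structure
DEFAULT_Z_SHIFT = {("control", "pre"): 0.0, ("control", "post"): -0.2,
                   ("intervention", "pre"): 0.0, ("intervention", "post"): 0.45}


@dataclass
class SimConfig:
    """Cohort-generator configuration; defaults are the emulated study
    conditions (~900 children, ~4000 visits, ~50% baseline stunting)."""

    seed: int = 0
    n_children_per_cell: int = 220
    n_hospitals_per_arm: int = 1
    n_health_centres_per_arm: int = 3
    preterm_fraction: float = 0.57
    #: (mean, sd, low, high) weeks for preterm and term gestational ages
    ga_preterm: tuple = (33.0, 2.5, 26.0, 36.86)
    ga_term: tuple = (39.0, 1.0, 37.0, 42.0)
    #: birthweight ~ N(intercept - slope*(40 - GA), sd), floored (grams)
    bw_intercept_g: float = 3300.0
    bw_slope_g_per_week: float = 170.0
    bw_sd_g: float = 350.0
    ga_missing_prob: float = 0.06
    #: standard visit schedule in days of (chronological) age
    schedule: tuple = (7, 14, 21, 30.4, 60.9, 121.8, 182.6, 273.9, 365.25)
    attendance_prob: float = 0.65
    other_visit_prob: float = 0.08
    #: latent z-trajectory model: child intercept ~ N(mu, sd), AR(1) noise
    mu_z_lhfa: float = -2.0
    mu_z_wfa: float = -1.8
    sd_z_child: float = 1.1
    ar1_rho: float = 0.7
    ar1_sd: float = 0.35
    cell_z_shift: dict = field(default_factory=lambda: dict(DEFAULT_Z_SHIFT))
    #: nurse behaviour per exposure cell
    completion: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPLETION.items()})
    misclassification: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISCLASSIFICATION.items()})
    continuous_interval_prob: float = 0.3
    implausible_prob: float = 0.003
    #: measurement noise (recorded = true + noise)
    noise_weight_g: float = 30.0
    noise_length_cm: float = 0.4
    windows: StudyWindows = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        for cell in EXPOSURE_GROUPS:
            for m, p in self.completion[cell].items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"completion[{cell}][{m}]={p} outside [0,1]")
            for m, q in self.misclassification[cell].items():
                if not 0.0 <= q <= 1.0:
                    raise ConfigError(f"misclassification[{cell}][{m}]={q} outside [0,1]")
        for p in (self.preterm_fraction, self.attendance_prob,
                  self.continuous_interval_prob, self.implausible_prob,
                  self.ga_missing_prob, self.other_visit_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0,1]")
        if not all(b > a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ConfigError("visit schedule must be strictly increasing")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    # rejection sampling keeps the per-child stream simple and exact
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _facilities(cfg: SimConfig, arm: str) -> list[tuple[str, str]]:
    out = [(f"{arm}_hosp_{i + 1}", "hospital") for i in range(cfg.n_hospitals_per_arm)]
    out += [(f"{arm}_hc_{i + 1}", "health_centre")
            for i in range(cfg.n_health_centres_per_arm)]
    return out


def _wrong_category(rng: np.random.Generator, gold: str | None,
                    categories: tuple) -> str:
    pool = [c for c in categories if c != gold]
    return pool[int(rng.integers(len(pool)))]


def simulate_cohort(config: SimConfig, references: ReferenceSet
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (children, visits, truth) tables for one synthetic cohort.

    Deterministic for a fixed seed.  ``truth`` keeps the generating labels
    (latent z-scores, gold classifications, injected corruption flags) for
    recovery tests; it is not part of the EMR surface the audits see.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = 4 * config.n_children_per_cell
    child_seeds = root.spawn(n_total)

    children_rows, visit_rows, truth_rows = [], [], []
    w = config.windows

    def behaviour_period(date: dt.date) -> str:
        # recording behaviour and care effects follow the calendar: the
        # intervention rolls out right after the pre window closes
        return "pre" if date <= w.pre_end else "post"

    k = 0
    for arm, period in EXPOSURE_GROUPS:
        facs = _facilities(config, arm)
        if period == "pre":
            w_start, w_end = w.pre_start, w.pre_end
        else:
            # "post" enrollment spans the inter-window gap too: children who
            # enrol between the windows reach their target ages during the
            # post window and are exactly the post-period outcome cohort
            w_start, w_end = w.pre_end + dt.timedelta(days=1), w.post_end
        window_days = (w_end - w_start).days

        for j in range(config.n_children_per_cell):
            rng = np.random.default_rng(child_seeds[k])
            cid = f"{arm[:1]}{period[:2]}_{j:04d}"
            k += 1

            preterm = rng.random() < config.preterm_fraction
            # GA is charted to 0.1 weeks; use the charted value throughout
            ga = round(_truncnorm(rng, *(config.ga_preterm if preterm else config.ga_term)), 1)
            bw = max(rng.normal(
                config.bw_intercept_g - config.bw_slope_g_per_week * (40.0 - ga),
                config.bw_sd_g), 600.0)
            ga_missing = rng.random() < config.ga_missing_prob
            sex = "male" if rng.random() < 0.5 else "female"
            fac_id, fac_type = facs[int(rng.integers(len(facs)))]

            enroll = w_start + dt.timedelta(days=int(rng.integers(window_days + 1)))
            birth = enroll - dt.timedelta(days=int(rng.integers(3, 11)))

            child = Child(
                child_id=cid, birth_date=birth, sex=sex, enrollment_date=enroll,
                facility_id=fac_id, facility_type=fac_type, arm=arm,
                gestational_age_weeks=None if ga_missing else ga,
                referred_as_preterm=bool(preterm),
                birthweight_g=round(bw),
            )
            children_rows.append({
                "child_id": cid, "birth_date": pd.Timestamp(birth), "sex": sex,
                "gestational_age_weeks": None if ga_missing else ga,
                "referred_as_preterm": int(preterm),
                "birthweight_g": round(bw),
                "enrollment_date": pd.Timestamp(enroll),
                "facility_id": fac_id, "facility_type": fac_type, "arm": arm,
                "enrollment_period": period,
            })

            # latent growth trajectories (cell z-shift applied per visit date)
            zi_lhfa = rng.normal(config.mu_z_lhfa, config.sd_z_child)
            zi_wfa = rng.normal(config.mu_z_wfa, config.sd_z_child)
            e_lhfa = e_wfa = 0.0
            innov = np.sqrt(1.0 - config.ar1_rho ** 2) * config.ar1_sd

            prev_weighed: Visit | None = None
            for day in config.schedule:
                e_lhfa = config.ar1_rho * e_lhfa + innov * rng.normal()
                e_wfa = config.ar1_rho * e_wfa + innov * rng.normal()
                if rng.random() >= config.attendance_prob:
                    continue
                # high-risk follow-up is scheduled on corrected age; a little
                # calendar jitter emulates real appointment slippage
                early = 0 if ga >= 37.0 else int(round(7.0 * (40.0 - ga)))
                jitter = int(rng.integers(-3, 4))
                vdate = birth + dt.timedelta(days=int(round(day)) + early + jitter)
                ca = (vdate - birth).days - early
                gen_age = float(max(ca, 0))

                bp = behaviour_period(vdate)
                comp = config.completion[(arm, bp)]
                misc = config.misclassification[(arm, bp)]
                # nutrition effects lag the rollout; they bind to the post
                # window proper, not the inter-window gap
                bp_nut = "post" if vdate >= w.post_start else "pre"
                zshift = config.cell_z_shift.get((arm, bp_nut), 0.0)

                z_lhfa = zi_lhfa + e_lhfa + zshift
                z_wfa = zi_wfa + e_wfa + zshift
                t_l = references.get("length_for_age", sex)
                t_w = references.get("weight_for_age", sex)
                Ll, Ml, Sl = t_l.lms_at(min(gen_age, t_l.span[1]))
                Lw, Mw, Sw = t_w.lms_at(min(gen_age, t_w.span[1]))
                true_len = inverse_zscore(z_lhfa, Ll, Ml, Sl)
                true_wt = inverse_zscore(z_wfa, Lw, Mw, Sw) * 1000.0

                rec_len = round(true_len + rng.normal(0.0, config.noise_length_cm), 1)
                rec_wt = float(round(true_wt + rng.normal(0.0, config.noise_weight_g)))
                implausible_injected = rng.random() < config.implausible_prob
                if implausible_injected:
                    rec_wt = float(round(rec_wt * 4))

                wt_recorded = rng.random() < comp["weight"]
                len_recorded = rng.random() < comp["length"]
                visit = Visit(
                    child_id=cid, visit_date=vdate,
                    visit_type="other" if rng.random() < config.other_visit_prob
                               else "standard_growth",
                    weight_g=rec_wt if wt_recorded else None,
                    length_cm=rec_len if len_recorded else None,
                )
                gold = assess_visit(child, visit, prev_weighed, references)

                nurse: dict[str, object] = {}
                miscls: dict[str, bool] = {}
                for metric, gold_cls in (("lhfa", gold.class_lhfa),
                                         ("wflh", gold.class_wflh),
                                         ("wfa", gold.class_wfa)):
                    if rng.random() >= comp[metric]:
                        nurse[metric] = None
                        miscls[metric] = False
                        continue
                    wrong = rng.random() < misc[metric]
                    miscls[metric] = wrong
                    if wrong or gold_cls is None:
                        nurse[metric] = _wrong_category(rng, gold_cls, Z_CLASSES)
                    else:
                        nurse[metric] = gold_cls

                if rng.random() >= comp["interval_growth"]:
                    nurse_ig: object = None
                    miscls["interval_growth"] = False
                else:
                    wrong = rng.random() < misc["interval_growth"]
                    miscls["interval_growth"] = wrong
                    gold_ig = gold.class_interval
                    continuous = (rng.random() < config.continuous_interval_prob
                                  and gold.interval_growth_g_per_day is not None
                                  and gold_ig in ("adequate", "inadequate"))
                    if continuous:
                        rate = gold.interval_growth_g_per_day
                        if wrong:
                            # a numeric entry on the wrong side of the band
                            thr = interval_threshold(float(gold.corrected_age_days)) or 10.0
                            rate = max(2.0 * thr - rate + (0.5 if rate < thr else -0.5), 0.0)
                        nurse_ig = round(float(rate), 1)
                    elif wrong or gold_ig is None:
                        nurse_ig = _wrong_category(rng, gold_ig, INTERVAL_CLASSES)
                    else:
                        nurse_ig = gold_ig

                ca_recorded = (child.referred_as_preterm or
                               (child.gestational_age_weeks or 40.0) < 37.0)
                ca_recorded = ca_recorded and rng.random() < comp["corrected_age"]

                visit_rows.append({
                    "child_id": cid, "visit_date": pd.Timestamp(vdate),
                    "visit_type": visit.visit_type,
                    "weight_g": visit.weight_g, "length_cm": visit.length_cm,
                    "nurse_corrected_age_recorded": int(ca_recorded),
                    "nurse_lhfa": nurse["lhfa"], "nurse_wflh": nurse["wflh"],
                    "nurse_wfa": nurse["wfa"], "nurse_interval_growth": nurse_ig,
                })
                truth_rows.append({
                    "child_id": cid, "visit_date": pd.Timestamp(vdate),
                    "arm": arm, "period_cell": period,
                    "corrected_age_true_days": ca,
                    "z_lhfa_true": z_lhfa, "z_wfa_true": z_wfa,
                    "true_length_cm": true_len, "true_weight_g": true_wt,
                    "gold_class_lhfa": gold.class_lhfa,
                    "gold_class_wflh": gold.class_wflh,
                    "gold_class_wfa": gold.class_wfa,
                    "gold_class_interval": gold.class_interval,
                    "implausible_injected": implausible_injected,
                    "misclassified_lhfa": miscls["lhfa"],
                    "misclassified_wflh": miscls["wflh"],
                    "misclassified_wfa": miscls["wfa"],
                    "misclassified_interval_growth": miscls["interval_growth"],
                })
                if visit.weight_g is not None:
                    prev_weighed = visit

    children = pd.DataFrame(children_rows)
    visits = pd.DataFrame(visit_rows)
    truth = pd.DataFrame(truth_rows)
    return children, visits, truth


# ---------------------------------------------------------------------------
# DiD scenario generator

@dataclass
class DidScenarioConfig:
    """Child-level binary-outcome scenario with facility random intercepts."""

    seed: int = 0
    n_facilities_per_arm: int = 10
    n_children: int = 4000
    p_control_pre: float = 0.4
    period_effect: float = 0.05
    arm_effect: float = 0.0
    facility_sd: float = 0.05


def simulate_did_scenario(config: DidScenarioConfig,
                          interaction_effect: float) -> pd.DataFrame:
    """Rows for :func:`pdcgrowth.did.did_fit` with a known true interaction.

    Cell probabilities are ``p_control_pre`` plus additive arm, period and
    interaction effects, plus a facility-level normal intercept (clipped to
    keep probabilities valid).  Raises :class:`ConfigError` when the
    deterministic cell probabilities leave [0, 1].
    """
    cells = {}
    for arm, period in EXPOSURE_GROUPS:
        p = (config.p_control_pre
             + (config.period_effect if period == "post" else 0.0)
             + (config.arm_effect if arm == "intervention" else 0.0)
             + (interaction_effect if (arm, period) == ("intervention", "post") else 0.0))
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"cell probability {p:.3f} for {(arm, period)} outside [0,1]")
        cells[(arm, period)] = p

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    fac_effects = {}
    facilities = {}
    for arm in ("control", "intervention"):
        ids = [f"{arm}_f{i + 1}" for i in range(config.n_facilities_per_arm)]
        facilities[arm] = ids
        for fid in ids:
            fac_effects[fid] = rng.normal(0.0, config.facility_sd)

    n_cell = config.n_children // 4
    rows = []
    for arm, period in EXPOSURE_GROUPS:
        for i in range(n_cell):
            fid = facilities[arm][i % len(facilities[arm])]
            p = float(np.clip(cells[(arm, period)] + fac_effects[fid], 0.0, 1.0))
            rows.append({
                "outcome": int(rng.random() < p),
                "arm": arm, "period": period,
                "facility_id": fid,
                "facility_type": "hospital" if fid.endswith("f1") else "health_centre",
            })
    return pd.DataFrame(rows)
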