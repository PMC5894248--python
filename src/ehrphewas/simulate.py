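"""Seeded synthetic EHR generator with planted effects.

The generator emulates the statistical structure a coded-EHR lupus
comorbidity scan assumes, at desk scale:

* race/sex/age-structured subjects with uniform follow-up windows ending
  at a common index date;
* SLE labels with race-dependent prevalence (African American subjects
  at roughly 1.6× the Caucasian rate, calibrated so the default 20,000-
  subject population yields cohorts of a few hundred cases per race);
* algorithm-concordant coding for SLE subjects — 710.0 on 4+Poisson
  distinct dates plus an ANA titer ≥1:160 with configurable
  sensitivity — together with the noise that makes rule-based
  phenotyping imperfect: SLE subjects carrying a scleroderma rule-out
  code (false negatives) and lupus-like non-SLE subjects meeting the
  full algorithm (false positives);
* non-SLE subjects with 1–3 710.0 dates or 710.1/714.0/M32.9 codes to
  exercise the control-pool exclusions;
* per-phecode comorbidity indicators drawn from a logistic model with
  planted log-odds for SLE status, race, age, and sex; diseased
  subjects emit 1+Poisson(event_rate) distinct-date coded events,
  non-diseased subjects emit a single "rule-out" date with a small
  probability (these land in the excluded stratum downstream);
* outpatient visit histories dense enough that most subjects satisfy
  the three-visits-in-five-years medical-home rule, with a sparse
  minority that does not.

Every random draw flows from one ``numpy`` Generator seeded from the
config, so identical configs produce byte-identical CSV output.

``simulate_statuses`` is a reduced-form sampler drawing per-phecode
case/control/excluded statuses from the identical probabilistic model
without materializing event tables; Monte-Carlo experiments use it to
keep replicate counts high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .phecode_map import PhecodeMap, load_phecode_map, fixture_map_path

INDEX_DATE = np.datetime64("2017-12-31")
AGE_CENTER = 50.0  # comorbidity age effects are per year relative to this

RACES = ("african_american", "caucasian")
SEXES = ("female", "male")


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class ComorbiditySpec:
    """Planted logistic model for one phecode's disease indicator."""

    phecode: str
    baseline_logit: float
    beta_sle: float = 0.0
    beta_race: float = 0.0  # african_american vs caucasian
    beta_age_per_year: float = 0.0  # per year of (age - AGE_CENTER)
    beta_sex: float = 0.0  # female vs male


#: Phecodes carrying planted SLE effects in the default scenario, echoing
#: the tiered hypertension / renal-dialysis / pneumonia signal shape.
#: All three are hierarchy leaves, so parent-code case counting (which
#: includes descendant events) cannot dilute a planted effect with a
#: sibling's null events.
PLANTED_DEFAULTS = {"401.1": 4.0, "585.31": 8.0, "480.1": 3.5}


def default_comorbidity_specs(
    pmap: PhecodeMap | None = None,
    planted: dict[str, float] | None = None,
) -> list[ComorbiditySpec]:
    """One spec per fixture phecode: ~4% baseline prevalence, a mild age
    gradient, and planted SLE odds ratios on three phecodes."""
    pmap = pmap or load_phecode_map(fixture_map_path())
    planted = PLANTED_DEFAULTS if planted is None else planted
    specs = []
    for p in pmap.phecodes:
        specs.append(
            ComorbiditySpec(
                phecode=p,
                baseline_logit=_logit(0.04),
                beta_sle=math.log(planted.get(p, 1.0)),
                beta_age_per_year=0.01,
            )
        )
    return specs


@dataclass
class SimConfig:
    """Study-condition knobs for one synthetic population."""

    n_subjects: int = 20_000
    race_prob: float = 0.19  # P(african_american); source EHR is 81% Caucasian
    female_prob: float = 0.5
    age_range: tuple[float, float] = (18.0, 85.0)
    followup_range: tuple[float, float] = (1.0, 19.0)  # years; mean ~10
    sle_prevalence_by_race: dict[str, float] = field(
        default_factory=lambda: {"african_american": 0.071, "caucasian": 0.044}
    )
    sle_beta_age: float = 0.0  # optional per-year log-odds on SLE itself
    ana_positive_given_sle: float = 0.95
    ana_titer_distribution: dict[int, float] = field(
        default_factory=lambda: {160: 0.20, 320: 0.25, 640: 0.25, 1280: 0.20, 2560: 0.10}
    )
    comorbidity_specs: list[ComorbiditySpec] = field(default_factory=default_comorbidity_specs)
    event_rate: float = 2.0  # mean extra coded dates per diseased subject
    rule_out_prob: float = 0.05  # non-diseased single-instance code probability
    sle_rule_out_frac: float = 0.02  # non-SLE subjects with 1-3 710.0 dates
    connective_tissue_frac: float = 0.01  # non-SLE with a 710.1/714.0/M32.9 code
    sle_scleroderma_frac: float = 0.02  # SLE subjects also coded 710.1 (false negatives)
    pseudo_sle_frac: float = 0.004  # non-SLE meeting the full algorithm (false positives)
    sparse_visit_frac: float = 0.02  # subjects failing the medical-home rule
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.race_prob, self.female_prob, self.ana_positive_given_sle,
            self.rule_out_prob, self.sle_rule_out_frac, self.connective_tissue_frac,
            self.sle_scleroderma_frac, self.pseudo_sle_frac, self.sparse_visit_frac,
            *self.sle_prevalence_by_race.values(),
        ]
        if any(not (0.0 <= q <= 1.0) for q in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, (lo, hi) in (("age_range", self.age_range), ("followup_range", self.followup_range)):
            if not lo < hi:
                raise ValueError(f"{name} must be non-degenerate (lo < hi)")
        if set(self.sle_prevalence_by_race) != set(RACES):
            raise ValueError(f"sle_prevalence_by_race must cover {RACES}")
        if abs(sum(self.ana_titer_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("ana_titer_distribution must sum to 1")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")


@dataclass
class Population:
    """One realized synthetic population plus its ground truth."""

    subjects: pd.DataFrame  # subject_id, sex, race, birth_year, age, followup_years, sle
    events: pd.DataFrame  # subject_id, code, vocabulary, date, setting
    labs: pd.DataFrame  # subject_id, test, date, titer, titer_text
    disease: pd.DataFrame  # subjects x phecodes bool truth matrix
    config: SimConfig

    def write(self, outdir) -> None:
        """Write deterministic CSVs (row order and formats fixed)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.csv", index=False, float_format="%.17g")
        ev = self.events.sort_values(
            ["subject_id", "date", "vocabulary", "code", "setting"], kind="stable"
        )
        ev.to_csv(outdir / "events.csv", index=False)
        self.labs.sort_values(["subject_id", "date"], kind="stable").to_csv(
            outdir / "labs.csv", index=False
        )
        truth = self.disease.astype(int).reset_index()
        truth.to_csv(outdir / "truth_disease.csv", index=False)
        self.subjects[["subject_id", "sle"]].assign(sle=self.subjects["sle"].astype(int)).to_csv(
            outdir / "truth_sle.csv", index=False
        )
        planted_effect_table(self.config).to_csv(
            outdir / "truth_effects.csv", index=False, float_format="%.17g"
        )


def planted_effect_table(config: SimConfig) -> pd.DataFrame:
    """Exponentiated planted coefficients, one row per configured phecode."""
    return pd.DataFrame(
        [
            {
                "phecode": s.phecode,
                "true_or_sle": math.exp(s.beta_sle),
                "true_or_race": math.exp(s.beta_race),
            }
            for s in config.comorbidity_specs
        ],
        columns=["phecode", "true_or_sle", "true_or_race"],
    )


# ---------------------------------------------------------------------------
# shared latent draws
# ---------------------------------------------------------------------------

def _draw_subjects(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    race = np.where(rng.random(n) < config.race_prob, RACES[0], RACES[1])
    sex = np.where(rng.random(n) < config.female_prob, SEXES[0], SEXES[1])
    age = rng.integers(int(config.age_range[0]), int(config.age_range[1]) + 1, size=n)
    followup = np.round(rng.uniform(*config.followup_range, size=n), 2)
    base = np.array([config.sle_prevalence_by_race[r] for r in race])
    logit = np.log(base / (1 - base)) + config.sle_beta_age * (age - AGE_CENTER)
    sle = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "race": race,
            "birth_year": 2017 - age,
            "age": age.astype(float),
            "followup_years": followup,
            "sle": sle,
        }
    )


def _draw_disease(
    config: SimConfig, subjects: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(subjects)
    aa = (subjects["race"] == RACES[0]).to_numpy(dtype=float)
    female = (subjects["sex"] == SEXES[0]).to_numpy(dtype=float)
    age_c = subjects["age"].to_numpy(dtype=float) - AGE_CENTER
    sle = subjects["sle"].to_numpy(dtype=float)
    cols = {}
    for s in config.comorbidity_specs:
        eta = (
            s.baseline_logit
            + s.beta_sle * sle
            + s.beta_race * aa
            + s.beta_age_per_year * age_c
            + s.beta_sex * female
        )
        cols[s.phecode] = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    disease = pd.DataFrame(cols, index=subjects["subject_id"])
    disease.index.name = "subject_id"
    return disease


def _date_count_and_ruleout(
    config: SimConfig,
    disease: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct-date counts per (subject, phecode): diseased subjects get
    1+Poisson(event_rate) dates, non-diseased get one date with
    probability rule_out_prob (else zero)."""
    d = disease.to_numpy()
    counts = np.zeros(d.shape, dtype=np.int64)
    counts[d] = 1 + rng.poisson(config.event_rate, size=int(d.sum()))
    ruleout = (~d) & (rng.random(d.shape) < config.rule_out_prob)
    counts[ruleout] = 1
    frame = pd.DataFrame(counts, index=disease.index, columns=disease.columns)
    return frame, pd.DataFrame(ruleout, index=disease.index, columns=disease.columns)


# ---------------------------------------------------------------------------
# reduced-form sampler
# ---------------------------------------------------------------------------

def simulate_statuses(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-phecode phenotype statuses directly.

    Returns ``(subjects, statuses, disease)`` where ``statuses`` is the
    subjects × phecodes int8 frame the PheWAS engine consumes (1 case /
    0 control / -1 excluded).  A diseased subject whose drawn date count
    is 1 is excluded (single-instance rule), as is a non-diseased
    subject receiving a rule-out code; cross-phecode exclusion-range
    interactions are not simulated here (the event-level path exercises
    those).
    """
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    disease = _draw_disease(config, subjects, rng)
    counts, _ = _date_count_and_ruleout(config, disease, rng)
    c = counts.to_numpy()
    status = np.zeros(c.shape, dtype="int8")
    status[c >= 2] = 1
    status[c == 1] = -1
    statuses = pd.DataFrame(status, index=disease.index, columns=disease.columns)
    return subjects.set_index("subject_id", drop=False), statuses, disease


# ---------------------------------------------------------------------------
# full event-level generator
# ---------------------------------------------------------------------------

def _distinct_offsets(
    rng: np.random.Generator, spans: np.ndarray, counts: np.ndarray, keys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Random day offsets within each subject's span, distinct within key.

    ``spans``/``counts``/``keys`` are per-group arrays; returns
    (row_keys, offsets) with duplicates resampled away.
    """
    row_keys = np.repeat(keys, counts)
    row_spans = np.repeat(spans, counts)
    offsets = rng.integers(0, np.maximum(row_spans, 1))
    for _ in range(20):
        df = pd.DataFrame({"k": row_keys, "o": offsets})
        dup = df.duplicated().to_numpy()
        if not dup.any():
            break
        offsets[dup] = rng.integers(0, np.maximum(row_spans[dup], 1))
    return row_keys, offsets


def generate_population(config: SimConfig) -> Population:
    """Generate a full event-level synthetic population.

    All sampling is driven by ``config.seed``; calling twice with the
    same config yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    disease = _draw_disease(config, subjects, rng)
    counts, _ = _date_count_and_ruleout(config, disease, rng)

    pmap = load_phecode_map(fixture_map_path())
    icd_for_phecode = {}
    for e in pmap.entries:
        icd_for_phecode.setdefault(e.phecode, e.icd9_code)

    n = len(subjects)
    span_days = np.maximum((subjects["followup_years"].to_numpy() * 365.25).astype(int), 2)
    start = INDEX_DATE - span_days.astype("timedelta64[D]")
    sid = subjects["subject_id"].to_numpy()
    sle = subjects["sle"].to_numpy()
    idx_all = np.arange(n)

    ev_sid: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []
    ev_vocab: list[np.ndarray] = []
    ev_off: list[np.ndarray] = []
    ev_setting: list[np.ndarray] = []

    def emit(subj_idx, offsets, code, vocab, setting):
        ev_sid.append(sid[subj_idx])
        ev_code.append(np.full(len(subj_idx), code, dtype=object))
        ev_vocab.append(np.full(len(subj_idx), vocab, dtype=object))
        ev_off.append(offsets)
        ev_setting.append(setting)

    # --- comorbidity events -------------------------------------------------
    for spec in config.comorbidity_specs:
        c = counts[spec.phecode].to_numpy()
        has = c > 0
        if not has.any():
            continue
        keys, offs = _distinct_offsets(rng, span_days[has], c[has], idx_all[has])
        settings = np.where(rng.random(len(keys)) < 0.3, "inpatient", "outpatient")
        emit(keys, offs, icd_for_phecode[spec.phecode], "ICD9CM", settings)

    # --- SLE coding ---------------------------------------------------------
    sle_idx = idx_all[sle]
    not_sle_idx = idx_all[~sle]
    pseudo = not_sle_idx[rng.random(len(not_sle_idx)) < config.pseudo_sle_frac]
    coded_like_sle = np.concatenate([sle_idx, pseudo])
    n710 = 4 + rng.poisson(config.event_rate, size=len(coded_like_sle))
    keys, offs = _distinct_offsets(rng, span_days[coded_like_sle], n710, coded_like_sle)
    settings = np.where(rng.random(len(keys)) < 0.3, "inpatient", "outpatient")
    emit(keys, offs, "710.0", "ICD9CM", settings)

    remaining = not_sle_idx[~np.isin(not_sle_idx, pseudo)]
    ruleout_sle = remaining[rng.random(len(remaining)) < config.sle_rule_out_frac]
    n_ro = rng.integers(1, 4, size=len(ruleout_sle))
    keys, offs = _distinct_offsets(rng, span_days[ruleout_sle], n_ro, ruleout_sle)
    emit(keys, offs, "710.0", "ICD9CM", np.full(len(keys), "outpatient", dtype=object))

    ct = remaining[rng.random(len(remaining)) < config.connective_tissue_frac]
    ct_codes = rng.choice(["710.1", "714.0", "M32.9"], size=len(ct))
    ct_off = rng.integers(0, np.maximum(span_days[ct], 1))
    for code, vocab in (("710.1", "ICD9CM"), ("714.0", "ICD9CM"), ("M32.9", "ICD10CM")):
        m = ct_codes == code
        emit(ct[m], ct_off[m], code, vocab, np.full(int(m.sum()), "outpatient", dtype=object))

    scl = sle_idx[rng.random(len(sle_idx)) < config.sle_scleroderma_frac]
    emit(
        scl,
        rng.integers(0, np.maximum(span_days[scl], 1)),
        "710.1",
        "ICD9CM",
        np.full(len(scl), "outpatient", dtype=object),
    )

    # --- visits -------------------------------------------------------------
    sparse = rng.random(n) < config.sparse_visit_frac
    n_visits = np.where(
        sparse,
        rng.integers(1, 3, size=n),
        3 + rng.poisson(np.maximum(subjects["followup_years"].to_numpy(), 1.0)),
    )
    keys, offs = _distinct_offsets(rng, span_days, n_visits, idx_all)
    emit(keys, offs, "V70.0", "ICD9CM", np.full(len(keys), "outpatient", dtype=object))

    subj_rows = np.concatenate(ev_sid)
    offsets = np.concatenate(ev_off)
    sid_to_row = {s: i for i, s in enumerate(sid)}
    subj_row_idx = np.fromiter((sid_to_row[s] for s in subj_rows), dtype=int, count=len(subj_rows))
    dates = start[subj_row_idx] + offsets.astype("timedelta64[D]")

    events = pd.DataFrame(
        {
            "subject_id": subj_rows,
            "code": np.concatenate(ev_code),
            "vocabulary": np.concatenate(ev_vocab),
            "date": pd.to_datetime(dates).strftime("%Y-%m-%d"),
            "setting": np.concatenate(ev_setting),
        }
    )

    # --- ANA labs -----------------------------------------------------------
    titers = np.array(sorted(config.ana_titer_distribution))
    titer_p = np.array([config.ana_titer_distribution[t] for t in titers])
    lab_rows = []
    pos_draw = rng.random(len(sle_idx)) < config.ana_positive_given_sle
    sle_titers = np.where(
        pos_draw, titers[rng.choice(len(titers), size=len(sle_idx), p=titer_p)], 80
    )
    pseudo_titers = titers[rng.choice(len(titers), size=len(pseudo), p=titer_p)]
    other = remaining[rng.random(len(remaining)) < 0.10]
    other_titers = rng.choice([40, 80], size=len(other))
    for group_idx, group_titers in ((sle_idx, sle_titers), (pseudo, pseudo_titers), (other, other_titers)):
        if len(group_idx) == 0:
            continue
        lab_off = rng.integers(0, np.maximum(span_days[group_idx], 1))
        lab_dates = pd.to_datetime(start[group_idx] + lab_off.astype("timedelta64[D]"))
        for s_i, t, d in zip(group_idx, group_titers, lab_dates.strftime("%Y-%m-%d")):
            lab_rows.append(
                {
                    "subject_id": sid[s_i],
                    "test": "ANA",
                    "date": d,
                    "titer": int(t),
                    "titer_text": f"1:{int(t)}",
                }
            )
    labs = pd.DataFrame(lab_rows, columns=["subject_id", "test", "date", "titer", "titer_text"])

    return Population(subjects=subjects, events=events, labs=labs, disease=disease, config=config)


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

def default_scenario(n_subjects: int = 20_000, seed: int = 0) -> SimConfig:
    """Three planted SLE odds ratios {4.0, 8.0, 3.5} among 27 nulls."""
    return SimConfig(n_subjects=n_subjects, seed=seed)


def null_scenario(n_subjects: int = 5_000, seed: int = 0) -> SimConfig:
    """All comorbidity beta_sle = 0 (FDR calibration scenario)."""
    cfg = SimConfig(n_subjects=n_subjects, seed=seed)
    return replace(
        cfg,
        comorbidity_specs=[replace(s, beta_sle=0.0) for s in cfg.comorbidity_specs],
    )


def confounded_scenario(n_subjects: int = 5_000, seed: int = 0) -> SimConfig:
    """Race-driven comorbidity with no SLE effect.

    SLE prevalence differs strongly by race and each phecode carries a
    race OR of 4 on an 8% baseline, sized so the crude SLE–phenotype
    association is reliably detectable at the default n while the
    race-adjusted and matched-conditional estimates are null.  Five
    phecodes keep replicate loops fast.
    """
    cfg = SimConfig(
        n_subjects=n_subjects,
        seed=seed,
        sle_prevalence_by_race={"african_american": 0.15, "caucasian": 0.02},
    )
    phecodes = [s.phecode for s in cfg.comorbidity_specs][:5]
    specs = [
        ComorbiditySpec(
            phecode=p,
            baseline_logit=_logit(0.08),
            beta_sle=0.0,
            beta_race=math.log(4.0),
            beta_age_per_year=0.01,
        )
        for p in phecodes
    ]
    return replace(cfg, comorbidity_specs=specs)


def age_confounded_scenario(n_subjects: int = 20_000, seed: int = 0) -> SimConfig:
    """Exposure–phenotype association flowing only through age."""
    cfg = SimConfig(
        n_subjects=n_subjects,
        seed=seed,
        sle_beta_age=0.06,
        sle_prevalence_by_race={"african_american": 0.06, "caucasian": 0.06},
    )
    specs = [
        ComorbiditySpec(
            phecode=s.phecode,
            baseline_logit=_logit(0.05),
            beta_sle=0.0,
            beta_age_per_year=0.05,
        )
        for s in cfg.comorbidity_specs[:5]
    ]
    return replace(cfg, comorbidity_specs=specs)
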