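"""SLE phenotyping, control-pool selection, and matched-control sampling.

The case-finding rule is a validated rule-based EHR algorithm for
systemic lupus erythematosus: at least four distinct-date occurrences of
ICD-9 710.0, a positive anti-nuclear antibody (ANA) titer of at least
1:160, and no codes for systemic sclerosis (710.1) or dermatomyositis
(710.3).  Control eligibility excludes the whole 710.* and 714.* ICD-9
headings and the ICD-10 M05/M06/M32–M36 families, and requires
"medical home" care density: three outpatient visits inside a five-year
window.  Controls are then matched to cases on sex, race, and age
(within a window, default ±5 years) at a target ratio (default 5:1),
sampled without replacement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SLE_CODE = "710.0"
SLE_RULEOUT_CODES = ("710.1", "710.3")  # systemic sclerosis, dermatomyositis
CONTROL_EXCLUDED_ICD9_HEADINGS = ("710", "714")
CONTROL_EXCLUDED_ICD10_PREFIXES = ("M05", "M06", "M32", "M33", "M34", "M35", "M36")
ANA_POSITIVE_TITER = 160
MIN_SLE_CODE_DATES = 4
MEDICAL_HOME_VISITS = 3
MEDICAL_HOME_WINDOW_DAYS = 1826  # five years, leap-inclusive

_TITER_RE = re.compile(r"^\s*1\s*:\s*(\d+)\s*$")


class TiterParseError(ValueError):
    pass


def parse_titer(text: str) -> int:
    """Parse an ANA titer string ``"1:N"`` to its integer denominator N."""
    m = _TITER_RE.match(str(text))
    if not m or int(m.group(1)) <= 0:
        raise TiterParseError(f"malformed titer {text!r}; expected '1:<positive int>'")
    return int(m.group(1))


@dataclass
class MatchedSet:
    """One conditional-regression stratum: a case and its matched controls."""

    stratum_id: int
    case_id: str
    control_ids: list[str] = field(default_factory=list)

    @property
    def achieved_ratio(self) -> int:
        return len(self.control_ids)


def _as_dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series).dt.normalize()


def identify_sle_cases(events: pd.DataFrame, labs: pd.DataFrame) -> set[str]:
    """Apply the rule-based SLE algorithm.

    Parameters
    ----------
    events : DataFrame with columns subject_id, code, vocabulary, date.
    labs : DataFrame with columns subject_id, test, date, and either an
        integer ``titer`` column or a ``titer_text`` column of "1:N"
        strings.

    Returns
    -------
    set of subject_id meeting all three criteria: 710.0 on >=4 distinct
    dates, maximum ANA titer >=160, and zero 710.1/710.3 events.
    Subjects with no ANA result simply fail the titer criterion.
    """
    ev = events
    icd9 = ev[ev["vocabulary"] == "ICD9CM"]
    sle_ev = icd9[icd9["code"] == SLE_CODE]
    if len(sle_ev):
        date_counts = sle_ev.groupby("subject_id")["date"].apply(
            lambda s: _as_dates(s).nunique()
        )
        enough_codes = set(date_counts[date_counts >= MIN_SLE_CODE_DATES].index)
    else:
        enough_codes = set()

    ruled_out = set(icd9[icd9["code"].isin(SLE_RULEOUT_CODES)]["subject_id"])

    ana = labs[labs["test"] == "ANA"] if len(labs) else labs
    if len(ana):
        if "titer" in ana.columns:
            titers = pd.to_numeric(ana["titer"])
        else:
            titers = ana["titer_text"].map(parse_titer)
        max_titer = titers.groupby(ana["subject_id"]).max()
        ana_positive = set(max_titer[max_titer >= ANA_POSITIVE_TITER].index)
    else:
        ana_positive = set()

    cases = (enough_codes & ana_positive) - ruled_out
    logger.info(
        "SLE algorithm: %d with >=%d coded dates, %d ANA-positive, %d ruled out -> %d cases",
        len(enough_codes), MIN_SLE_CODE_DATES, len(ana_positive), len(ruled_out), len(cases),
    )
    return cases


def _has_excluded_codes(events: pd.DataFrame) -> pd.Series:
    """Boolean per-row mask of control-disqualifying connective-tissue codes."""
    code = events["code"].astype(str)
    vocab = events["vocabulary"]
    icd9_hit = (vocab == "ICD9CM") & (
        code.isin(CONTROL_EXCLUDED_ICD9_HEADINGS)
        | code.str.startswith(tuple(h + "." for h in CONTROL_EXCLUDED_ICD9_HEADINGS))
    )
    icd10_hit = (vocab == "ICD10CM") & code.str.startswith(CONTROL_EXCLUDED_ICD10_PREFIXES)
    return icd9_hit | icd10_hit


def _meets_medical_home(dates: np.ndarray) -> bool:
    """>=3 distinct outpatient dates inside some 1826-day window."""
    d = np.unique(dates)
    if len(d) < MEDICAL_HOME_VISITS:
        return False
    span = (d[MEDICAL_HOME_VISITS - 1 :] - d[: len(d) - MEDICAL_HOME_VISITS + 1]).astype(
        "timedelta64[D]"
    )
    return bool((span < np.timedelta64(MEDICAL_HOME_WINDOW_DAYS, "D")).any())


def select_control_pool(events: pd.DataFrame) -> set[str]:
    """Subjects eligible as non-SLE controls.

    Eligibility: no ICD-9 codes under the 710.* or 714.* headings, no
    ICD-10 codes under M05/M06/M32/M33/M34/M35/M36, and at least three
    distinct outpatient visit dates within some five-year (1826-day)
    window.
    """
    excluded = set(events.loc[_has_excluded_codes(events), "subject_id"])
    outpt = events[events["setting"] == "outpatient"]
    dates = _as_dates(outpt["date"]).to_numpy(dtype="datetime64[D]")
    pool = set()
    for sid, idx in outpt.groupby("subject_id").indices.items():
        if sid in excluded:
            continue
        if _meets_medical_home(dates[idx]):
            pool.add(sid)
    logger.info(
        "control pool: %d eligible (%d excluded by connective-tissue codes)",
        len(pool), len(excluded),
    )
    return pool


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 5,
    age_window: float = 5.0,
    seed: int = 0,
) -> tuple[list[MatchedSet], pd.DataFrame]:
    """Draw sex/race-exact, age-window controls for each case without replacement.

    Cases are visited in seeded random order; each case's eligible
    controls are ranked by absolute age difference (ties broken uniformly
    at random under the seed) and the nearest ``ratio`` are taken.  A
    case with no eligible control yields a stratum with an empty control
    list and a warning; downstream conditional regression drops it.

    Parameters
    ----------
    cases, pool : DataFrames with columns subject_id, sex, race, age.
        The pool must be disjoint from the cases.
    ratio : target controls per case.
    age_window : maximum |case age - control age| in years.
    seed : RNG seed; fixes visit order and tie-breaks.

    Returns
    -------
    (strata, report) : the matched sets plus a per-case DataFrame with
    the achieved control ratio.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if age_window < 0:
        raise ValueError("age_window must be >= 0")
    overlap = set(cases["subject_id"]) & set(pool["subject_id"])
    if overlap:
        raise ValueError(f"pool overlaps cases: {sorted(overlap)[:5]}")

    rng = np.random.default_rng(seed)
    cases = cases.reset_index(drop=True).sort_values("subject_id").reset_index(drop=True)
    pool = pool.reset_index(drop=True).sort_values("subject_id").reset_index(drop=True)
    order = rng.permutation(len(cases))

    pool_sex = pool["sex"].to_numpy()
    pool_race = pool["race"].to_numpy()
    pool_age = pool["age"].to_numpy(dtype=float)
    pool_ids = pool["subject_id"].to_numpy()
    available = np.ones(len(pool), dtype=bool)

    strata: list[MatchedSet] = []
    rows = []
    for stratum_id, i in enumerate(order):
        case = cases.iloc[i]
        eligible = (
            available
            & (pool_sex == case["sex"])
            & (pool_race == case["race"])
            & (np.abs(pool_age - float(case["age"])) <= age_window)
        )
        idx = np.flatnonzero(eligible)
        if len(idx) == 0:
            logger.warning("case %s: no eligible controls", case["subject_id"])
            chosen = np.empty(0, dtype=int)
        else:
            diffs = np.abs(pool_age[idx] - float(case["age"]))
            tiebreak = rng.random(len(idx))
            take = np.lexsort((tiebreak, diffs))[:ratio]
            chosen = idx[take]
            available[chosen] = False
        strata.append(
            MatchedSet(
                stratum_id=stratum_id,
                case_id=case["subject_id"],
                control_ids=list(pool_ids[chosen]),
            )
        )
        rows.append(
            {
                "stratum_id": stratum_id,
                "case_id": case["subject_id"],
                "achieved_ratio": len(chosen),
            }
        )
    report = pd.DataFrame(rows, columns=["stratum_id", "case_id", "achieved_ratio"])
    logger.info(
        "matched %d cases; mean achieved ratio %.2f (target %d)",
        len(strata), report["achieved_ratio"].mean() if len(report) else float("nan"), ratio,
    )
    return strata, report


def matched_sets_frame(strata: list[MatchedSet]) -> pd.DataFrame:
    """Long-format (stratum_id, role, subject_id) table for matched sets."""
    rows = []
    for s in strata:
        rows.append({"stratum_id": s.stratum_id, "role": "case", "subject_id": s.case_id})
        for cid in s.control_ids:
            rows.append({"stratum_id": s.stratum_id, "role": "control", "subject_id": cid})
    return pd.DataFrame(rows, columns=["stratum_id", "role", "subject_id"])


def strata_from_frame(df: pd.DataFrame) -> list[MatchedSet]:
    """Inverse of :func:`matched_sets_frame`."""
    strata = []
    for sid, grp in df.groupby("stratum_id", sort=True):
        case_rows = grp[grp["role"] == "case"]
        if len(case_rows) != 1:
            raise ValueError(f"stratum {sid}: expected exactly one case")
        strata.append(
            MatchedSet(
                stratum_id=int(sid),
                case_id=case_rows["subject_id"].iloc[0],
                control_ids=list(grp.loc[grp["role"] == "control", "subject_id"]),
            )
        )
    return strata
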