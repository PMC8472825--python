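"""Subject classification, baseline preference and cohort summaries.

A subject is *suppressive* when at least one scalp cluster shows a
significant mu desynchronization during action execution (adjusted p <
0.05 with negative median) for at least one of the two baselines; otherwise
*non-suppressive*.  For suppressive subjects the *preferred baseline* is
decided from the paired cluster tests: among clusters with a significant
paired BL1-vs-BL2 difference, the baseline whose median ERD is more
negative in a strict majority of those clusters wins; no significant
cluster, or a tie, means no preference.  The same rule applied to action
observation checks whether the preference replicates.

These rules run identically on pipeline output and on the packaged
summary-table transcriptions (`table2.csv` for AE, `table3.csv` for AO),
which allows the headline cohort rates to be recomputed without raw EEG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLUSTERS, ConfigurationError, PipelineConfig, round_pct
from .stats import TestResult, rank_sum

__all__ = [
    "CohortSummary",
    "SubjectResult",
    "SubjectTests",
    "classify_subject",
    "confirm_preference_ao",
    "determine_preference",
    "evaluate_subject",
    "export_summary_table",
    "fixture_path",
    "ingest_summary_table",
    "subject_tests_from_results",
    "summarize_cohort",
]


# ---------------------------------------------------------------------------
# per-subject test container (common to pipeline output and fixtures)
# ---------------------------------------------------------------------------


@dataclass
class SubjectTests:
    """Everything the classification/preference rules need for one subject.

    ``onesample[(condition, baseline)]`` maps cluster -> (median, iqr,
    significant); ``paired_p[condition]`` maps cluster -> adjusted paired
    p-value (NaN when the paired test was not run / not reported).
    """

    subject_id: str
    onesample: dict[tuple[str, str], dict[str, tuple[float, float, bool]]]
    paired_p: dict[str, dict[str, float]]
    n_epochs: dict[str, int] = field(default_factory=dict)
    stated_preference: dict[str, str] = field(default_factory=dict)
    stated_group: str = ""

    def medians(self, condition: str, baseline: str) -> dict[str, float]:
        return {cl: v[0] for cl, v in self.onesample[(condition, baseline)].items()}

    def any_significant(self, condition: str) -> bool:
        return any(
            v[2]
            for (cond, _), d in self.onesample.items()
            if cond == condition
            for v in d.values()
        )


def subject_tests_from_results(
    subject_id: str,
    onesample: dict[tuple[str, str], list[TestResult]],
    paired: dict[str, list[TestResult]],
    n_epochs: dict[str, int],
) -> SubjectTests:
    """Adapt stats-module family results into a :class:`SubjectTests`."""
    return SubjectTests(
        subject_id=subject_id,
        onesample={
            key: {r.cluster: (r.median, r.iqr, r.significant) for r in results}
            for key, results in onesample.items()
        },
        paired_p={
            cond: {r.cluster: r.p_adjusted for r in results}
            for cond, results in paired.items()
        },
        n_epochs=dict(n_epochs),
    )


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


def classify_subject(tests: SubjectTests,
                     condition: str = "AE") -> tuple[str, bool]:
    """(group, both_baselines): suppressive iff >= 1 significant cluster for
    either baseline; ``both_baselines`` is True when each baseline
    individually yields >= 1 significant cluster."""
    per_base = {}
    for base in ("BL1", "BL2"):
        key = (condition, base)
        if key not in tests.onesample:
            raise ConfigurationError(
                f"{tests.subject_id}: missing {condition}/{base} test family"
            )
        per_base[base] = any(v[2] for v in tests.onesample[key].values())
    group = "suppressive" if any(per_base.values()) else "non_suppressive"
    return group, all(per_base.values())


def determine_preference(
    paired_p: dict[str, float],
    medians_bl1: dict[str, float],
    medians_bl2: dict[str, float],
    alpha: float = 0.050,
) -> str:
    """Majority direction among clusters with a significant paired
    difference; a strict majority of more-negative medians decides, zero
    significant clusters or an exact tie mean ``"none"``."""
    n_bl1 = n_bl2 = 0
    for cl in CLUSTERS:
        p = paired_p.get(cl, math.nan)
        if not (p == p and p < alpha):  # NaN-safe significance check
            continue
        m1, m2 = medians_bl1[cl], medians_bl2[cl]
        if m1 < m2:
            n_bl1 += 1
        elif m2 < m1:
            n_bl2 += 1
    if n_bl1 > n_bl2:
        return "BL1"
    if n_bl2 > n_bl1:
        return "BL2"
    return "none"


def _condition_preference(tests: SubjectTests, condition: str,
                          alpha: float = 0.050) -> str:
    """Preference for one condition; gated on that condition showing at
    least one significant one-sample cluster (paired tests were only run
    for conditions with a significant desynchronization)."""
    if not tests.any_significant(condition):
        return "none"
    return determine_preference(
        tests.paired_p.get(condition, {}),
        tests.medians(condition, "BL1"),
        tests.medians(condition, "BL2"),
        alpha,
    )


def confirm_preference_ao(ae_pref: str, tests: SubjectTests,
                          alpha: float = 0.050) -> str:
    """Replication of the AE preference in AO: ``confirmed`` when AO yields
    the same baseline, ``undetermined`` when AO yields none, else
    ``switched``."""
    ao_pref = _condition_preference(tests, "AO", alpha)
    if ao_pref == "none":
        return "undetermined"
    return "confirmed" if ao_pref == ae_pref else "switched"


# ---------------------------------------------------------------------------
# per-subject result and cohort summary
# ---------------------------------------------------------------------------


@dataclass
class SubjectResult:
    subject_id: str
    group: str  # suppressive / non_suppressive / insufficient_data
    both_baselines: bool = False
    preference: str = "NA"  # BL1 / BL2 / none / NA
    ao_confirmation: str = "NA"  # confirmed / switched / undetermined / NA
    ae_epoch_count: int = 0
    ao_epoch_count: int = 0
    lateralized_score: float = math.nan
    mu_band_center: dict[str, int] = field(default_factory=dict)


def evaluate_subject(tests: SubjectTests, alpha: float = 0.050,
                     ao_tests: SubjectTests | None = None) -> SubjectResult:
    """Apply all rules to one subject's AE tests (and AO tests when
    available; they may live in the same SubjectTests or a separate one,
    as with the two summary tables)."""
    group, both = classify_subject(tests, "AE")
    pref = "NA"
    confirmation = "NA"
    if group == "suppressive":
        pref = _condition_preference(tests, "AE", alpha)
        ao_src = ao_tests if ao_tests is not None else tests
        if ("AO", "BL1") in ao_src.onesample:
            confirmation = confirm_preference_ao(pref, ao_src, alpha)
    return SubjectResult(
        subject_id=tests.subject_id,
        group=group,
        both_baselines=both,
        preference=pref,
        ao_confirmation=confirmation,
        ae_epoch_count=tests.n_epochs.get("AE", 0),
        ao_epoch_count=(ao_tests or tests).n_epochs.get("AO", 0),
    )


@dataclass
class CohortSummary:
    n_total: int
    n_insufficient: int
    n_suppressive: int
    n_non_suppressive: int
    pct_suppressive: float
    pct_non_suppressive: float
    n_both_baselines: int
    pct_both_baselines: float
    preference_counts: dict[str, int]
    preference_pcts: dict[str, float]
    n_ao_confirmed: int
    pct_ao_confirmed: float
    ae_epoch_median: dict[str, float]
    epoch_count_ranksum_p: float

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_insufficient": self.n_insufficient,
            "n_suppressive": self.n_suppressive,
            "n_non_suppressive": self.n_non_suppressive,
            "pct_suppressive": self.pct_suppressive,
            "pct_non_suppressive": self.pct_non_suppressive,
            "n_both_baselines": self.n_both_baselines,
            "pct_both_baselines": self.pct_both_baselines,
            "preference_counts": self.preference_counts,
            "preference_pcts": self.preference_pcts,
            "n_ao_confirmed": self.n_ao_confirmed,
            "pct_ao_confirmed": self.pct_ao_confirmed,
            "ae_epoch_median": self.ae_epoch_median,
            "epoch_count_ranksum_p": self.epoch_count_ranksum_p,
        }


def summarize_cohort(results: list[SubjectResult]) -> CohortSummary:
    """Headline rates: group percentages over the included subjects,
    preference and AO-confirmation percentages over the suppressive
    group.  Subjects flagged insufficient-data are excluded from all
    denominators."""
    if not results:
        raise ConfigurationError("cannot summarize an empty cohort")
    included = [r for r in results if r.group != "insufficient_data"]
    n = len(included)
    supp = [r for r in included if r.group == "suppressive"]
    nonsupp = [r for r in included if r.group == "non_suppressive"]
    n_s = len(supp)
    pref_counts = {
        "BL1": sum(1 for r in supp if r.preference == "BL1"),
        "BL2": sum(1 for r in supp if r.preference == "BL2"),
        "none": sum(1 for r in supp if r.preference == "none"),
    }
    n_conf = sum(1 for r in supp if r.ao_confirmation == "confirmed")
    n_both = sum(1 for r in included if r.both_baselines)

    med = lambda rs: float(np.median([r.ae_epoch_count for r in rs])) if rs else math.nan
    if len(supp) >= 2 and len(nonsupp) >= 2:
        _, p_counts = rank_sum([r.ae_epoch_count for r in supp],
                               [r.ae_epoch_count for r in nonsupp])
    else:
        p_counts = math.nan
    pct = lambda k, d: round_pct(100.0 * k / d) if d else math.nan
    return CohortSummary(
        n_total=n,
        n_insufficient=len(results) - n,
        n_suppressive=n_s,
        n_non_suppressive=len(nonsupp),
        pct_suppressive=pct(n_s, n),
        pct_non_suppressive=pct(len(nonsupp), n),
        n_both_baselines=n_both,
        pct_both_baselines=pct(n_both, n),
        preference_counts=pref_counts,
        preference_pcts={k: pct(v, n_s) for k, v in pref_counts.items()},
        n_ao_confirmed=n_conf,
        pct_ao_confirmed=pct(n_conf, n_s),
        ae_epoch_median={"suppressive": med(supp), "non_suppressive": med(nonsupp)},
        epoch_count_ranksum_p=float(p_counts),
    )


# ---------------------------------------------------------------------------
# summary-table fixtures
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "subject", "group", "n_epochs", "cluster", "baseline", "median", "iqr",
    "significant", "paired_adjusted_p", "stated_preference",
)


def export_summary_table(tests: list[SubjectTests], condition: str,
                         path: str | Path) -> None:
    """Write SubjectTests to the summary-table CSV schema, so pipeline
    output can be re-ingested by :func:`ingest_summary_table`."""
    rows = []
    for st in tests:
        group, _ = classify_subject(st, condition) if condition == "AE" else ("", None)
        grp = {"suppressive": 1, "non_suppressive": 2}.get(group, "")
        pref = st.stated_preference.get(condition, "")
        for base in ("BL1", "BL2"):
            for cl in CLUSTERS:
                med, iqr, sig = st.onesample[(condition, base)][cl]
                p = st.paired_p.get(condition, {}).get(cl, math.nan)
                rows.append(
                    [st.subject_id, grp, st.n_epochs.get(condition, 0), cl, base,
                     med, iqr, int(sig), "" if p != p else repr(p), pref]
                )
    pd.DataFrame(rows, columns=list(_TABLE_COLUMNS)).to_csv(path, index=False)


def fixture_path(name: str) -> Path:
    """Path to a packaged summary-table fixture (``table2`` or ``table3``)."""
    return Path(resources.files("muerd").joinpath(f"data/{name}.csv"))


def _parse_p(text: str, row: int) -> float:
    """Parse a printed adjusted p-value; inequality strings map to a value
    on the certain side of the cut (e.g. '<0.001' -> 0.0005)."""
    s = str(text).strip()
    if s in ("", "nan", "NA"):
        return math.nan
    try:
        if s.startswith("<"):
            return float(s[1:]) / 2
        if s.startswith(">"):
            return (1 + float(s[1:])) / 2
        return float(s)
    except ValueError as exc:
        raise ConfigurationError(f"row {row}: bad p-value {text!r}") from exc


def ingest_summary_table(path: str | Path, condition: str) -> dict[str, SubjectTests]:
    """Load a summary table (one row per subject x cluster x baseline) into
    :class:`SubjectTests` keyed by subject id.

    ``condition`` names the event condition the table describes ("AE" for
    the execution table, "AO" for the observation table).
    """
    df = pd.read_csv(path, dtype={"paired_adjusted_p": str})
    if df.empty:
        raise ConfigurationError(f"{path}: empty summary table")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")

    out: dict[str, SubjectTests] = {}
    for row_i, row in df.iterrows():
        sid = str(row["subject"])
        cl = str(row["cluster"])
        base = str(row["baseline"])
        if cl not in CLUSTERS or base not in ("BL1", "BL2"):
            raise ConfigurationError(f"row {row_i}: bad cluster/baseline "
                                     f"{cl!r}/{base!r}")
        st = out.get(sid)
        if st is None:
            st = SubjectTests(
                subject_id=sid,
                onesample={(condition, "BL1"): {}, (condition, "BL2"): {}},
                paired_p={condition: {}},
                n_epochs={condition: int(row["n_epochs"])},
                stated_group=str(row["group"]),
            )
            out[sid] = st
        try:
            med = float(row["median"])
            iqr = float(row["iqr"])
            sig = bool(int(row["significant"]))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"row {row_i}: malformed values") from exc
        st.onesample[(condition, base)][cl] = (med, iqr, sig)
        p = _parse_p(row["paired_adjusted_p"], row_i)
        if p == p:  # keep first non-NaN (duplicated across baseline rows)
            st.paired_p[condition][cl] = p
        sp = str(row.get("stated_preference", "")).strip()
        if sp and sp != "nan":
            st.stated_preference[condition] = sp

    for sid, st in out.items():
        for base in ("BL1", "BL2"):
            have = set(st.onesample[(condition, base)])
            if have != set(CLUSTERS):
                raise ConfigurationError(
                    f"{sid}: incomplete {base} cluster set {sorted(have)}"
                )
    return out
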