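"""Dichotic-listening trial scoring: stimulus set, QC, and the laterality index.

The task presents consonant-vowel syllable pairs, one syllable per ear, and the
listener reports the single syllable heard best.  The six stop-consonant
syllables split into two voice-onset-time (VOT) classes: voiced stops
(ba, da, ga) have a short VOT, voiceless stops (ta, ka, pa) a long VOT.  All
ordered combinations give 36 pairs: 30 dichotic (different syllables) and 6
homonyms (same syllable to both ears).

The laterality index (LI) is computed only from the 12 dichotic pairs whose
two syllables share a VOT class (LL and SS), because on mixed pairs (LS / SL)
listeners overwhelmingly report the short-VOT syllable regardless of ear,
which would confound ear attribution:

    LI = 100 * (n_correct_right - n_correct_left) / n_correct_total

Positive LI denotes a right-ear advantage (left-hemisphere language
dominance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SYLLABLES",
    "SHORT_VOT",
    "LONG_VOT",
    "EQUAL_VOT_CATEGORIES",
    "StimulusPair",
    "SetupAnswers",
    "LateralityResult",
    "build_stimulus_set",
    "classify_vot",
    "check_setup",
    "apply_error_rate_qc",
    "category_accuracies",
    "compute_laterality_index",
    "score_subject",
    "score_cohort",
    "read_trial_table",
    "read_setup_table",
]

#: The six CV syllables, short-VOT (voiced) first.
SYLLABLES: tuple[str, ...] = ("ba", "da", "ga", "ta", "ka", "pa")
SHORT_VOT: frozenset[str] = frozenset({"ba", "da", "ga"})
LONG_VOT: frozenset[str] = frozenset({"ta", "ka", "pa"})

#: VOT categories whose trials enter the laterality index.
EQUAL_VOT_CATEGORIES: tuple[str, str] = ("LL", "SS")

#: Sentinel for a trial with no response within the response window.
MISSING = ""

#: Inclusive bounds for the balance-slider setup question (0 = left, 100 = right).
SLIDER_BOUNDS = (30, 70)

#: Expected perceived locations for the three tone setup questions.
DEFAULT_EXPECTED_LOCATIONS = ("left", "right", "both")

#: Exclusion thresholds (strict inequalities) for per-subject error rates.
DICHOTIC_ERROR_MAX = 0.80
HOMONYM_ERROR_MAX = 0.50


def classify_vot(left: str, right: str) -> str:
    """Classify an ordered syllable pair by VOT category.

    Returns one of ``HOM`` (identical syllables), ``LL`` (long VOT to both
    ears), ``SS`` (short to both), ``LS`` (long left / short right) or ``SL``
    (short left / long right).
    """
    for s in (left, right):
        if s not in SHORT_VOT and s not in LONG_VOT:
            raise ValueError(f"unknown syllable: {s!r}")
    if left == right:
        return "HOM"
    left_long = left in LONG_VOT
    right_long = right in LONG_VOT
    if left_long and right_long:
        return "LL"
    if not left_long and not right_long:
        return "SS"
    return "LS" if left_long else "SL"


@dataclass(frozen=True)
class StimulusPair:
    """One ordered stimulus pair: ``left_syllable`` to the left ear, ``right_syllable`` to the right."""

    left_syllable: str
    right_syllable: str

    @property
    def vot_category(self) -> str:
        return classify_vot(self.left_syllable, self.right_syllable)

    @property
    def is_homonym(self) -> bool:
        return self.left_syllable == self.right_syllable

    @property
    def short_vot_member(self) -> str | None:
        """The short-VOT syllable of a mixed (LS/SL) pair, else None."""
        cat = self.vot_category
        if cat == "LS":
            return self.right_syllable
        if cat == "SL":
            return self.left_syllable
        return None


def build_stimulus_set() -> list[StimulusPair]:
    """All 36 ordered syllable pairs: 30 dichotic plus 6 homonyms.

    Deterministic order (left syllable outer loop, right inner).  Category
    sizes are HOM=6, LL=6, SS=6, LS=9, SL=9.
    """
    return [StimulusPair(l, r) for l in SYLLABLES for r in SYLLABLES]


@dataclass(frozen=True)
class SetupAnswers:
    """Answers to the four headphone-setup questions.

    ``q1``-``q3`` are the perceived locations of three test tones
    (``left``/``right``/``both``); ``q4_slider`` is the 0-100 balance slider
    for a tone presented equally to both ears (0 = fully left).
    """

    q1: str | None
    q2: str | None
    q3: str | None
    q4_slider: int | float | None


def check_setup(
    answers: SetupAnswers,
    expected_locations: tuple[str, str, str] = DEFAULT_EXPECTED_LOCATIONS,
) -> tuple[bool, list[str]]:
    """Validate the headphone-setup answers.

    Passes iff each tone-location answer matches the presented ear and the
    slider lies within the accepted band (inclusive).  Returns
    ``(passed, reasons)`` where ``reasons`` names each failed question.
    """
    reasons: list[str] = []
    given = (answers.q1, answers.q2, answers.q3)
    if any(g is None for g in given) or answers.q4_slider is None:
        return False, ["incomplete setup"]
    for i, (got, exp) in enumerate(zip(given, expected_locations), start=1):
        if got != exp:
            reasons.append(f"q{i} answered {got!r}, expected {exp!r}")
    lo, hi = SLIDER_BOUNDS
    if not (lo <= answers.q4_slider <= hi):
        reasons.append(f"q4 slider {answers.q4_slider} outside [{lo}, {hi}]")
    return (not reasons), reasons


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a single subject's trial table covers the 36-pair set exactly once."""
    required = {"left_syllable", "right_syllable", "response"}
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise ValueError(f"trial table missing columns: {sorted(missing_cols)}")
    pairs = list(zip(trials["left_syllable"], trials["right_syllable"]))
    if len(pairs) != len(set(pairs)):
        raise ValueError("malformed trial table: duplicated pair presentations")
    expected = {(p.left_syllable, p.right_syllable) for p in build_stimulus_set()}
    if set(pairs) != expected:
        raise ValueError(
            "malformed trial table: does not cover the 36-pair stimulus set"
        )
    return trials


def _is_correct(row: pd.Series) -> bool:
    resp = row["response"]
    if resp is None or (isinstance(resp, float) and np.isnan(resp)) or resp == MISSING:
        return False
    return resp == row["left_syllable"] or resp == row["right_syllable"]


def _annotate(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    out["response"] = out["response"].fillna(MISSING)
    out["vot_category"] = [
        classify_vot(l, r)
        for l, r in zip(out["left_syllable"], out["right_syllable"])
    ]
    out["correct"] = out.apply(_is_correct, axis=1)
    return out


def apply_error_rate_qc(trials: pd.DataFrame) -> tuple[bool, list[str]]:
    """Per-subject exclusion on error rates, with missing responses counted as errors.

    A subject is excluded iff the dichotic error rate exceeds 80% or the
    homonym error rate exceeds 50% (both strict inequalities).
    """
    t = _annotate(_validate_trials(trials))
    dichotic = t[t["vot_category"] != "HOM"]
    homonym = t[t["vot_category"] == "HOM"]
    reasons = []
    dich_err = 1.0 - dichotic["correct"].mean()
    hom_err = 1.0 - homonym["correct"].mean()
    if dich_err > DICHOTIC_ERROR_MAX:
        reasons.append(f"dichotic error rate {dich_err:.3f} > {DICHOTIC_ERROR_MAX}")
    if hom_err > HOMONYM_ERROR_MAX:
        reasons.append(f"homonym error rate {hom_err:.3f} > {HOMONYM_ERROR_MAX}")
    return (not reasons), reasons


def category_accuracies(trials: pd.DataFrame) -> dict[str, float]:
    """Proportion of correct responses per VOT category.

    For the mixed categories LS and SL, additionally reports
    ``LS_short_share`` / ``SL_short_share``: among correct responses, the
    share that named the short-VOT member of the pair.  (Empirically listeners
    report the short-VOT syllable on mixed pairs regardless of ear; this
    statistic lets that phenomenon be checked rather than assumed.)
    """
    t = _annotate(_validate_trials(trials))
    out: dict[str, float] = {}
    for cat in ("LL", "SS", "LS", "SL", "HOM"):
        sub = t[t["vot_category"] == cat]
        out[cat] = float(sub["correct"].mean())
    for cat in ("LS", "SL"):
        sub = t[(t["vot_category"] == cat) & t["correct"]]
        if len(sub) == 0:
            out[f"{cat}_short_share"] = float("nan")
        else:
            short = [
                StimulusPair(l, r).short_vot_member
                for l, r in zip(sub["left_syllable"], sub["right_syllable"])
            ]
            out[f"{cat}_short_share"] = float(
                np.mean(np.asarray(sub["response"]) == np.asarray(short))
            )
    return out


@dataclass
class LateralityResult:
    """Per-subject scoring outcome."""

    subject_id: str
    n_correct_right: int
    n_correct_left: int
    n_correct_total: int
    li: float  # percentage points in [-100, 100]; NaN when undefined
    category_accuracy: dict[str, float]
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)


def compute_laterality_index(trials: pd.DataFrame) -> tuple[int, int, float]:
    """Laterality index from the 12 equal-VOT dichotic pairs.

    A correct response is credited to the ear whose syllable was reported
    (unambiguous on dichotic trials).  Returns ``(n_right, n_left, li)`` with
    ``li = 100 * (nR - nL) / (nR + nL)``; ``li`` is NaN when no equal-VOT
    response was correct.
    """
    t = _annotate(_validate_trials(trials))
    eq = t[t["vot_category"].isin(EQUAL_VOT_CATEGORIES)]
    n_right = int((eq["response"] == eq["right_syllable"]).sum())
    n_left = int((eq["response"] == eq["left_syllable"]).sum())
    total = n_right + n_left
    li = float("nan") if total == 0 else 100.0 * (n_right - n_left) / total
    return n_right, n_left, li


def score_subject(
    subject_id: str,
    trials: pd.DataFrame,
    setup: SetupAnswers | None = None,
) -> LateralityResult:
    """Full per-subject pipeline: setup QC, error-rate QC, accuracies, LI."""
    reasons: list[str] = []
    if setup is not None:
        ok, setup_reasons = check_setup(setup)
        if not ok:
            reasons.extend(setup_reasons)
    qc_ok, err_reasons = apply_error_rate_qc(trials)
    reasons.extend(err_reasons)
    n_right, n_left, li = compute_laterality_index(trials)
    if n_right + n_left == 0:
        reasons.append("no correct equal-VOT responses; LI undefined")
    return LateralityResult(
        subject_id=subject_id,
        n_correct_right=n_right,
        n_correct_left=n_left,
        n_correct_total=n_right + n_left,
        li=li,
        category_accuracy=category_accuracies(trials),
        qc_pass=not reasons,
        qc_reasons=reasons,
    )


def score_cohort(
    trial_table: pd.DataFrame,
    setup_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every subject in a long-format trial table.

    ``trial_table`` has one row per presentation with columns ``subject_id``,
    ``left_syllable``, ``right_syllable``, ``response``.  ``setup_table``
    (optional) has one row per subject with columns ``subject_id``, ``q1``,
    ``q2``, ``q3``, ``q4_slider``.  Returns one row per subject with LI,
    category accuracies and QC outcome.
    """
    setup_by_subject: dict[str, SetupAnswers] = {}
    if setup_table is not None:
        for _, row in setup_table.iterrows():
            setup_by_subject[str(row["subject_id"])] = SetupAnswers(
                row["q1"], row["q2"], row["q3"], row["q4_slider"]
            )
    rows = []
    for subject_id, trials in trial_table.groupby("subject_id", sort=True):
        res = score_subject(
            str(subject_id), trials, setup_by_subject.get(str(subject_id))
        )
        row = {
            "subject_id": res.subject_id,
            "n_correct_right": res.n_correct_right,
            "n_correct_left": res.n_correct_left,
            "n_correct_total": res.n_correct_total,
            "li": res.li,
            "qc_pass": res.qc_pass,
            "qc_reasons": "; ".join(res.qc_reasons),
        }
        for k, v in res.category_accuracy.items():
            row[f"acc_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table TSV (subject_id, trial_index, left/right syllables, response)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str}, keep_default_na=False
    )
    df["response"] = df["response"].replace({"": MISSING})
    return df


def read_setup_table(path) -> pd.DataFrame:
    """Read a setup-answers TSV (subject_id, q1, q2, q3, q4_slider)."""
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})
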