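"""Anesthesia episode records: parsing, quality control, and phenotype features.

An *episode* is one anesthesia record for one patient: a set of
phenylephrine infusion segments (constant prescribed rate per segment, in
mcg/min), a timestamped series of systolic blood pressure (SBP) readings
with their measurement modality, bolus drug events, and demographics.

The QC rules implemented here mirror standard practice for deriving a
clean infusion-rate phenotype from raw operative records: episodes with a
short total infusion (< 10 min), too few SBP readings in the infusion
window (< 3), confounding phenylephrine/ephedrine boluses during the
infusion, inconsistent BP measurement modality, implausible infusion-rate
units, or missing body weight are excluded; individual SBP values outside
the physiologically plausible open interval (20, 200) mmHg are treated as
artifacts (arterial-line flushes, disconnections) and removed at the
value level before any counting rule is applied.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "SbpReading",
    "Bolus",
    "Episode",
    "EpisodeFeatures",
    "QCRules",
    "Exclusion",
    "EpisodeParseError",
    "REASON_CODES",
    "read_episodes",
    "write_episodes",
    "qc_filter",
    "valid_readings",
    "compute_features",
    "aggregate_patients",
    "write_exclusion_log",
]

#: Vocabulary of episode-level exclusion reason codes.
REASON_CODES = (
    "short_infusion",
    "few_sbp",
    "bolus_during_infusion",
    "mixed_modality",
    "bad_unit",
    "missing_weight",
    "no_infusion",
)

MISSING = "."


@dataclass(frozen=True)
class Segment:
    """One infusion segment: constant prescribed rate over [t_start, t_end)."""

    t_start: float  # minutes from episode start
    t_end: float
    rate: float  # mcg/min
    unit: str = "mcg/min"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SbpReading:
    t: float  # minutes
    value: float  # mmHg
    modality: str  # "invasive" | "noninvasive"


@dataclass(frozen=True)
class Bolus:
    drug: str
    t: float


@dataclass
class Episode:
    """One anesthesia record. Segments and readings are kept time-sorted."""

    patient_id: str
    episode_id: str
    age: float
    sex: str  # "F" | "M"
    weight: float | None  # kg; None when missing
    anesthesia_type: str  # "general" | "spinal" | "other"
    infusion_segments: list[Segment] = field(default_factory=list)
    sbp_readings: list[SbpReading] = field(default_factory=list)
    bolus_events: list[Bolus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.infusion_segments = sorted(
            self.infusion_segments, key=lambda s: (s.t_start, s.t_end)
        )
        self.sbp_readings = sorted(self.sbp_readings, key=lambda r: r.t)
        self.bolus_events = sorted(self.bolus_events, key=lambda b: b.t)
        for seg in self.infusion_segments:
            if not seg.t_start < seg.t_end:
                raise ValueError(
                    f"{self.episode_id}: segment t_start must be < t_end "
                    f"({seg.t_start} >= {seg.t_end})"
                )
            if seg.rate < 0:
                raise ValueError(f"{self.episode_id}: negative infusion rate")
        for a, b in zip(self.infusion_segments, self.infusion_segments[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError(
                    f"{self.episode_id}: overlapping segments at t={b.t_start}"
                )

    @property
    def infusion_window(self) -> tuple[float, float] | None:
        """[first segment start, last segment end], or None without segments."""
        if not self.infusion_segments:
            return None
        return (self.infusion_segments[0].t_start, self.infusion_segments[-1].t_end)

    @property
    def infusion_duration(self) -> float:
        """Total infused time: the sum of segment durations, minutes."""
        return sum(s.duration for s in self.infusion_segments)


@dataclass(frozen=True)
class EpisodeFeatures:
    """Per-episode phenotype features used for response clustering."""

    avg_rate: float  # mcg/min, duration-weighted over segments
    mean_sbp: float  # mmHg
    sd_sbp: float  # mmHg, sample SD (n-1)
    infusion_duration: float  # min
    n_sbp: int


@dataclass(frozen=True)
class QCRules:
    """Episode QC thresholds; defaults are the study rules."""

    min_duration: float = 10.0  # minutes
    min_sbp_readings: int = 3
    sbp_bounds: tuple[float, float] = (20.0, 200.0)  # open interval, mmHg
    allowed_units: tuple[str, ...] = ("mcg/min",)
    confounding_bolus_drugs: tuple[str, ...] = ("phenylephrine", "ephedrine")


@dataclass(frozen=True)
class Exclusion:
    episode_id: str
    reason_code: str
    detail: str = ""


class EpisodeParseError(ValueError):
    """Raised when the episode TSV contains malformed rows (strict mode)."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__(
            f"{len(issues)} malformed row(s); first: {issues[0] if issues else ''}"
        )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

COLUMNS = [
    "patient_id",
    "episode_id",
    "event_type",
    "t_start",
    "t_end",
    "value",
    "unit",
    "modality",
    "drug",
    "age",
    "sex",
    "weight",
    "anesthesia_type",
]


def _fmt(x) -> str:
    if x is None:
        return MISSING
    if isinstance(x, float):
        if math.isnan(x):
            return MISSING
        return format(x, ".10g")
    return str(x)


def write_episodes(episodes: Iterable[Episode], path) -> None:
    """Write episodes in the long TSV dialect: one row per (episode, event)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COLUMNS)
        for ep in episodes:
            base = [ep.patient_id, ep.episode_id]
            w.writerow(
                base
                + ["demo", MISSING, MISSING, MISSING, MISSING, MISSING, MISSING]
                + [_fmt(ep.age), ep.sex, _fmt(ep.weight), ep.anesthesia_type]
            )
            for s in ep.infusion_segments:
                w.writerow(
                    base
                    + ["segment", _fmt(s.t_start), _fmt(s.t_end), _fmt(s.rate), s.unit]
                    + [MISSING] * 6
                )
            for r in ep.sbp_readings:
                w.writerow(
                    base
                    + ["sbp", _fmt(r.t), MISSING, _fmt(r.value), MISSING, r.modality]
                    + [MISSING] * 5
                )
            for b in ep.bolus_events:
                w.writerow(
                    base
                    + ["bolus", _fmt(b.t), MISSING, MISSING, MISSING, MISSING, b.drug]
                    + [MISSING] * 4
                )


def _parse_float(s: str, what: str):
    if s == MISSING or s == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable {what}: {s!r}") from exc


def read_episodes(path, errors: str = "strict"):
    """Read episodes from the TSV dialect.

    Parameters
    ----------
    path
        TSV file with the 13 dialect columns; ``.`` marks a missing value.
    errors
        ``"strict"`` (default) raises :class:`EpisodeParseError` listing every
        malformed row; ``"collect"`` returns ``(episodes, issues)`` instead so
        callers can report malformed rows without losing the clean ones.
    """
    raw: dict[str, dict] = {}
    issues: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header")
        missing_cols = [c for c in COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"{path}: missing mandatory column(s) {missing_cols}")
        idx = {c: header.index(c) for c in COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            try:
                get = lambda c: row[idx[c]]  # noqa: E731
                pid, eid, etype = get("patient_id"), get("episode_id"), get("event_type")
                rec = raw.setdefault(
                    eid,
                    {
                        "patient_id": pid,
                        "demo": None,
                        "segments": [],
                        "sbp": [],
                        "bolus": [],
                    },
                )
                if etype == "demo":
                    rec["demo"] = {
                        "age": _parse_float(get("age"), "age"),
                        "sex": get("sex"),
                        "weight": _parse_float(get("weight"), "weight"),
                        "anesthesia_type": get("anesthesia_type"),
                    }
                elif etype == "segment":
                    rec["segments"].append(
                        Segment(
                            t_start=_parse_float(get("t_start"), "t_start"),
                            t_end=_parse_float(get("t_end"), "t_end"),
                            rate=_parse_float(get("value"), "rate"),
                            unit=get("unit"),
                        )
                    )
                elif etype == "sbp":
                    rec["sbp"].append(
                        SbpReading(
                            t=_parse_float(get("t_start"), "t"),
                            value=_parse_float(get("value"), "sbp value"),
                            modality=get("modality"),
                        )
                    )
                elif etype == "bolus":
                    rec["bolus"].append(
                        Bolus(drug=get("drug"), t=_parse_float(get("t_start"), "t"))
                    )
                else:
                    raise ValueError(f"unknown event_type {etype!r}")
            except (ValueError, TypeError, IndexError) as exc:
                issues.append(f"line {lineno}: {exc}")

    out: list[Episode] = []
    for eid, rec in raw.items():
        demo = rec["demo"]
        if demo is None:
            issues.append(f"episode {eid}: no demo row")
            continue
        try:
            out.append(
                Episode(
                    patient_id=rec["patient_id"],
                    episode_id=eid,
                    age=demo["age"],
                    sex=demo["sex"],
                    weight=demo["weight"],
                    anesthesia_type=demo["anesthesia_type"],
                    infusion_segments=rec["segments"],
                    sbp_readings=rec["sbp"],
                    bolus_events=rec["bolus"],
                )
            )
        except ValueError as exc:
            issues.append(f"episode {eid}: {exc}")

    if errors == "collect":
        return out, issues
    if issues:
        raise EpisodeParseError(issues)
    return out


def write_exclusion_log(log: Sequence[Exclusion], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["episode_id", "reason_code", "detail"])
        for e in log:
            w.writerow([e.episode_id, e.reason_code, e.detail])


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def valid_readings(ep: Episode, rules: QCRules = QCRules()) -> list[SbpReading]:
    """SBP readings inside the infusion window with in-bounds values.

    The window is [first segment start, last segment end], inclusive at both
    ends; the value bounds are the *open* interval ``rules.sbp_bounds``, so a
    reading of exactly 20 or 200 mmHg is discarded as an artifact.
    """
    window = ep.infusion_window
    if window is None:
        return []
    lo, hi = rules.sbp_bounds
    t0, t1 = window
    return [
        r
        for r in ep.sbp_readings
        if t0 <= r.t <= t1 and lo < r.value < hi
    ]


def _failure_reasons(ep: Episode, rules: QCRules) -> list[Exclusion]:
    reasons: list[Exclusion] = []
    eid = ep.episode_id
    if not ep.infusion_segments:
        return [Exclusion(eid, "no_infusion", "no infusion segments")]
    bad_units = {s.unit for s in ep.infusion_segments} - set(rules.allowed_units)
    if bad_units:
        reasons.append(Exclusion(eid, "bad_unit", ",".join(sorted(bad_units))))
    if ep.weight is None or (isinstance(ep.weight, float) and math.isnan(ep.weight)):
        reasons.append(Exclusion(eid, "missing_weight", ""))
    if ep.infusion_duration < rules.min_duration:
        reasons.append(
            Exclusion(eid, "short_infusion", f"{ep.infusion_duration:.1f} min")
        )
    vr = valid_readings(ep, rules)
    if len(vr) < rules.min_sbp_readings:
        reasons.append(Exclusion(eid, "few_sbp", f"{len(vr)} valid readings"))
    else:
        modalities = {r.modality for r in vr}
        if len(modalities) > 1:
            reasons.append(
                Exclusion(eid, "mixed_modality", ",".join(sorted(modalities)))
            )
    t0, t1 = ep.infusion_window
    drugs = {d.lower() for d in rules.confounding_bolus_drugs}
    offending = [
        b for b in ep.bolus_events if b.drug.lower() in drugs and t0 <= b.t <= t1
    ]
    if offending:
        reasons.append(
            Exclusion(
                eid,
                "bolus_during_infusion",
                ";".join(f"{b.drug}@{b.t:.0f}" for b in offending),
            )
        )
    return reasons


def qc_filter(
    episodes: Sequence[Episode], rules: QCRules = QCRules()
) -> tuple[list[Episode], list[Exclusion]]:
    """Apply the episode exclusion rules.

    Returns the kept episodes and an exhaustive exclusion log: every failing
    rule of every excluded episode gets one entry, so an episode may appear
    under several reason codes. Kept episodes plus distinct excluded episodes
    partition the input. Out-of-bounds SBP values are removed *before* the
    reading-count and modality rules are evaluated, so a single artifactual
    reading never costs an otherwise clean episode.
    """
    kept: list[Episode] = []
    log: list[Exclusion] = []
    for ep in episodes:
        reasons = _failure_reasons(ep, rules)
        if reasons:
            log.extend(reasons)
        else:
            kept.append(ep)
    return kept, log


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def compute_features(
    ep: Episode, rules: QCRules = QCRules(), rate_method: str = "duration_weighted"
) -> EpisodeFeatures:
    """Derive the clustering features for a QC-passing episode.

    avg_rate is the duration-weighted mean of segment rates (the physical
    average dose rate); set ``rate_method="arithmetic"`` for the unweighted
    mean of recorded settings. mean_sbp / sd_sbp are the mean and sample SD
    (n-1 denominator) of the valid readings inside the infusion window.
    """
    if not ep.infusion_segments:
        raise ValueError(f"{ep.episode_id}: no infusion segments")
    durations = np.array([s.duration for s in ep.infusion_segments])
    rates = np.array([s.rate for s in ep.infusion_segments])
    if rate_method == "duration_weighted":
        avg_rate = float(np.average(rates, weights=durations))
    elif rate_method == "arithmetic":
        avg_rate = float(rates.mean())
    else:
        raise ValueError(f"unknown rate_method {rate_method!r}")
    vr = valid_readings(ep, rules)
    if not vr:
        raise ValueError(
            f"{ep.episode_id}: no valid SBP readings in window (QC-order bug?)"
        )
    values = np.array([r.value for r in vr], dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return EpisodeFeatures(
        avg_rate=avg_rate,
        mean_sbp=float(values.mean()),
        sd_sbp=sd,
        infusion_duration=float(ep.infusion_duration),
        n_sbp=len(values),
    )


def features_table(
    episodes: Sequence[Episode],
    rules: QCRules = QCRules(),
    rate_method: str = "duration_weighted",
) -> pd.DataFrame:
    """Episode-level feature/covariate table for downstream clustering."""
    rows = []
    for ep in episodes:
        f = compute_features(ep, rules, rate_method)
        rows.append(
            {
                "patient_id": ep.patient_id,
                "episode_id": ep.episode_id,
                "avg_rate": f.avg_rate,
                "mean_sbp": f.mean_sbp,
                "sd_sbp": f.sd_sbp,
                "infusion_duration": f.infusion_duration,
                "n_sbp": f.n_sbp,
                "age": ep.age,
                "sex": ep.sex,
                "weight": ep.weight,
                "anesthesia_type": ep.anesthesia_type,
            }
        )
    return pd.DataFrame(rows)


def aggregate_patients(
    episode_table: pd.DataFrame, label_col: str = "label"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse episode-level rows to one row per patient.

    Patients whose episodes received discordant cluster labels are dropped
    (their response subtype is ambiguous — likely reflecting unmeasured
    surgical or pharmacological context); concordant multi-episode patients
    contribute the mean of avg_rate, mean_sbp, sd_sbp, age, weight.

    Returns ``(patient_table, dropped_table)``; the dropped table carries the
    patient_id and the set of conflicting labels.
    """
    if episode_table[label_col].isna().any():
        bad = episode_table.loc[episode_table[label_col].isna(), "episode_id"].tolist()
        raise ValueError(f"episodes without a cluster label: {bad[:5]}")
    numeric = ["avg_rate", "mean_sbp", "sd_sbp", "age", "weight"]
    patients, dropped = [], []
    for pid, grp in episode_table.groupby("patient_id", sort=True):
        labels = grp[label_col].unique()
        if len(labels) > 1:
            dropped.append(
                {
                    "patient_id": pid,
                    "reason": "discordant_cluster",
                    "labels": ",".join(sorted(map(str, labels))),
                    "n_episodes": len(grp),
                }
            )
            continue
        row = {"patient_id": pid, label_col: labels[0], "n_episodes": len(grp)}
        for c in numeric:
            row[c] = float(grp[c].mean())
        row["sex"] = grp["sex"].iloc[0]
        row["anesthesia_type"] = grp["anesthesia_type"].iloc[0]
        patients.append(row)
    return pd.DataFrame(patients), pd.DataFrame(
        dropped, columns=["patient_id", "reason", "labels", "n_episodes"]
    )
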