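"""Longitudinal surveillance evaluation of MRD calls.

Per-patient timelines combine the scalar sample summaries (timepoint,
maxAF, MethylMean) with the deconvolution fits and the clinical relapse
annotation. On top of those this module computes:

* lead time — days between the first positive postoperative call and
  radiological confirmation of relapse;
* horizon confusion — sensitivity/specificity/PPV/NPV of an assay
  evaluated at the last sample at or before ``relapse_day - horizon``
  (non-relapsed patients contribute their last follow-up sample);
* ROC / AUC over the continuous score at the same horizon samples;
* Fisher exact tests for the 2x2 contingency comparisons;
* survival-ready export tables (patient_id, dfs_days, event, group) for
  standard Kaplan-Meier / Cox tooling, which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import TimmrdFit
from .errors import UndefinedResultError, ValidationError
from .panel_io import SampleSummary


@dataclass
class TimelineRecord:
    summary: SampleSummary
    fit: TimmrdFit | None = None

    @property
    def day(self) -> int:
        return self.summary.day_from_surgery


@dataclass
class PatientTimeline:
    """Day-ordered sample records plus the relapse annotation."""

    patient_id: str
    records: list[TimelineRecord]
    relapsed: bool
    relapse_day: int | None
    dfs_days: int

    def postoperative(self) -> list[TimelineRecord]:
        return [r for r in self.records if r.day > 0]


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def build_timeline(
    samples: Sequence[SampleSummary],
    fits: dict[str, TimmrdFit],
    clinical: dict,
) -> PatientTimeline:
    """Merge sample summaries, fits, and the clinical row into one timeline."""
    patient_id = clinical["patient_id"]
    relapsed = bool(clinical["relapsed"])
    relapse_day = clinical.get("relapse_day")
    if relapsed and relapse_day is None:
        raise ValidationError(f"patient {patient_id}: relapsed without relapse_day")
    if not relapsed and relapse_day is not None:
        raise ValidationError(f"patient {patient_id}: relapse_day without relapse flag")
    dfs_days = int(clinical["dfs_days"])
    if dfs_days < 0:
        raise ValidationError(f"patient {patient_id}: negative dfs_days")
    for s in samples:
        fit = fits.get(s.sample_id)
        if fit is not None and fit.patient_id not in (None, patient_id):
            raise ValidationError(
                f"fit for sample {s.sample_id} belongs to {fit.patient_id}, "
                f"not {patient_id}"
            )
    records = sorted(
        (TimelineRecord(s, fits.get(s.sample_id)) for s in samples),
        key=lambda r: r.day,
    )
    return PatientTimeline(patient_id, records, relapsed, relapse_day, dfs_days)


def _is_positive(record: TimelineRecord, assay: str) -> bool:
    if assay == "timmrd":
        return record.fit is not None and record.fit.call == "high"
    if assay == "mutation":
        return record.summary.max_af is not None and record.summary.max_af > 0
    raise ValidationError(f"unknown assay {assay!r}")


def lead_time(timeline: PatientTimeline, rule: str = "first_positive",
              assay: str = "timmrd") -> int | None:
    """Days between blood-based detection and confirmed relapse.

    ``first_positive`` (default): relapse_day minus the day of the
    earliest postoperative positive sample at or before relapse; ``None``
    when the patient was never positive before relapse (such patients are
    excluded from average lead times). ``last_negative_to_relapse``:
    relapse_day minus the day of the last negative sample before relapse,
    an upper bound on how late detection could have begun.
    """
    if not timeline.relapsed or timeline.relapse_day is None:
        raise ValidationError(f"patient {timeline.patient_id} did not relapse")
    post = [r for r in timeline.postoperative() if r.day <= timeline.relapse_day]
    if rule == "first_positive":
        for r in post:
            if _is_positive(r, assay):
                return timeline.relapse_day - r.day
        return None
    if rule == "last_negative_to_relapse":
        negatives = [r for r in post if not _is_positive(r, assay)]
        if not negatives:
            return None
        return timeline.relapse_day - negatives[-1].day
    raise ValidationError(f"unknown lead-time rule {rule!r}")


def _horizon_record(
    timeline: PatientTimeline, horizon_days: int
) -> TimelineRecord | None:
    post = timeline.postoperative()
    if not post:
        return None
    if timeline.relapsed and timeline.relapse_day is not None:
        cutoff = timeline.relapse_day - horizon_days
        eligible = [r for r in post if r.day <= cutoff]
        return eligible[-1] if eligible else None
    return post[-1]


def horizon_confusion(
    timelines: Iterable[PatientTimeline],
    horizon_days: int = 120,
    assay: str = "timmrd",
) -> ConfusionSummary:
    """Patient-level 2x2 at a fixed horizon before relapse.

    Relapsed patients are evaluated at their last sample at or before
    ``relapse_day - horizon_days`` (skipped when no such sample exists);
    non-relapsed patients at their last follow-up sample.
    """
    tp = fp = tn = fn = 0
    for t in timelines:
        record = _horizon_record(t, horizon_days)
        if record is None:
            continue
        positive = _is_positive(record, assay)
        if t.relapsed:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    summary = ConfusionSummary(tp, fp, tn, fn)
    if summary.n == 0:
        raise UndefinedResultError("no evaluable patient at this horizon")
    return summary


def roc_over_thresholds(
    timelines: Iterable[PatientTimeline], horizon_days: int = 120
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and trapezoidal AUC of the score at the horizon samples.

    Sweeps the MRD-call threshold over every observed score. Returns the
    (1 - specificity, sensitivity) point list and the AUC.
    """
    scores, labels = [], []
    for t in timelines:
        record = _horizon_record(t, horizon_days)
        if record is None or record.fit is None:
            continue
        scores.append(record.fit.score)
        labels.append(t.relapsed)
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels, dtype=bool)
    n_pos = int(labels_arr.sum())
    n_neg = int((~labels_arr).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one relapsed and one non-relapsed patient")
    thresholds = np.unique(scores_arr)[::-1]
    points = [(0.0, 0.0)]  # threshold above every observed score
    for thr in thresholds:
        pred = scores_arr >= thr
        sens = float(np.sum(pred & labels_arr) / n_pos)
        fpr = float(np.sum(pred & ~labels_arr) / n_neg)
        points.append((fpr, sens))
    points.append((1.0, 1.0))
    points = sorted(set(points))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValidationError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("empty contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def export_survival_table(
    timelines: Iterable[PatientTimeline],
    grouping: str = "timmrd_call",
    at: str = "plasma_bc",
    path=None,
) -> list[dict]:
    """Survival-ready rows (patient_id, dfs_days, event, group).

    ``grouping='timmrd_call'`` labels a patient ``high`` when the worse of
    the requested samples is MRD-high; ``'mutation_status'`` labels
    ``positive`` when any requested sample has maxAF > 0. ``at`` selects
    the samples: ``plasma_bc`` (timepoints B and C) or ``last_followup``.
    """
    if grouping not in ("timmrd_call", "mutation_status"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    if at not in ("plasma_bc", "last_followup"):
        raise ValidationError(f"unknown timepoint rule {at!r}")
    rows = []
    for t in timelines:
        if at == "plasma_bc":
            records = [r for r in t.records if r.summary.timepoint_label in ("B", "C")]
        else:
            post = t.postoperative()
            records = post[-1:] if post else []
        if not records:
            continue
        if grouping == "timmrd_call":
            positive = any(_is_positive(r, "timmrd") for r in records)
            group = "high" if positive else "low"
        else:
            positive = any(_is_positive(r, "mutation") for r in records)
            group = "positive" if positive else "negative"
        rows.append(
            {
                "patient_id": t.patient_id,
                "dfs_days": t.dfs_days,
                "event": int(t.relapsed),
                "group": group,
            }
        )
    if path is not None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("#patient_id\tdfs_days\tevent\tgroup\n")
            for r in rows:
                handle.write(
                    f"{r['patient_id']}\t{r['dfs_days']}\t{r['event']}\t{r['group']}\n"
                )
    return rows
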