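"""Error metrics and cheap-baseline comparisons for the distilled model.

Provides the five error measures used to assess the student against the
teacher (RMS error, mean absolute error, 99th percentile and maximum of
the absolute error, and prediction bias, all in phons), plus the two
conventional low-cost loudness proxies it is compared with:

* A-weighted SPL, computed from the 61-band spectrum with the standard
  analytic A-weighting curve evaluated at the band centres, bias-corrected
  per test set before its RMS error is taken;
* stationary loudness from the long-term average spectrum: each sound's
  band spectra are averaged in the power domain, the teacher is run once
  on the average, and the result is compared with the teacher's overall
  (maximum long-term) loudness for the time-varying run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dnn import MLPParams, forward
from .frontend import AudioSignal, HOP_TRACE, band_spectra
from .soundgen import LabelledDataset
from .teacher import Teacher

METRIC_COLUMNS = ("rms", "mean_absolute", "p99_absolute", "max_absolute", "bias")


@dataclass
class ErrorReport:
    """Error measures (phons) between a prediction and a reference series."""

    rms: float
    mean_absolute: float
    p99_absolute: float
    max_absolute: float
    bias: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def error_report(pred, ref) -> ErrorReport:
    """Five-way error summary of ``pred - ref`` (both in phons).

    The 99th percentile uses linear interpolation between order
    statistics.
    """
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("prediction and reference must be equal-length series")
    diff = pred - ref
    adiff = np.abs(diff)
    return ErrorReport(
        rms=float(np.sqrt(np.mean(diff**2))),
        mean_absolute=float(np.mean(adiff)),
        p99_absolute=float(np.percentile(adiff, 99.0)),
        max_absolute=float(np.max(adiff)),
        bias=float(np.mean(diff)),
    )


# ---------------------------------------------------------------------------
# A-weighting baseline
# ---------------------------------------------------------------------------


def a_weight_db(f_hz) -> np.ndarray:
    """Standard A-weighting curve in dB (0 dB at 1 kHz)."""
    f = np.asarray(f_hz, dtype=np.float64)
    f2 = f**2
    ra = (12194.0**2 * f2**2) / (
        (f2 + 20.6**2)
        * np.sqrt((f2 + 107.7**2) * (f2 + 737.9**2))
        * (f2 + 12194.0**2)
    )
    out = 20.0 * np.log10(ra) + 2.0
    return float(out) if np.isscalar(f_hz) else out


def a_weighted_level(levels: np.ndarray, centers_hz: np.ndarray) -> np.ndarray:
    """A-weighted SPL (dBA) of 61-band spectra, power-summed over bands."""
    L = np.atleast_2d(np.asarray(levels, dtype=np.float64))
    w = a_weight_db(centers_hz)
    dba = 10.0 * np.log10(np.sum(10.0 ** ((L + w[None, :]) / 10.0), axis=-1))
    if np.asarray(levels).ndim == 1:
        return float(dba[0])
    return dba


# ---------------------------------------------------------------------------
# Dataset-level baselines
# ---------------------------------------------------------------------------

BASELINE_TAGS = ("a_weighted", "stationary_average_spectrum", "student_dnn")


def baseline_error(
    test: LabelledDataset,
    tag: str,
    teacher: Teacher | None = None,
    student: MLPParams | None = None,
) -> ErrorReport:
    """Error of a loudness estimator against the teacher labels.

    ``a_weighted``: per-row A-weighted SPL with the set's mean offset from
    the labels removed before computing errors (the bias correction the
    assessment protocol applies to this proxy).

    ``stationary_average_spectrum``: per sound, the teacher applied once
    to the power-averaged band spectrum versus the teacher's overall
    loudness of the time-varying run (labels are per-frame, so the
    time-varying overall loudness is recomputed from the stored rows).

    ``student_dnn``: the trained network's per-row predictions.
    """
    if tag not in BASELINE_TAGS:
        raise ValueError(f"unknown baseline tag {tag!r}")
    if len(test) == 0:
        raise ValueError("empty test set")
    if teacher is None:
        teacher = Teacher()

    if tag == "a_weighted":
        dba = a_weighted_level(test.inputs, teacher.bands.centers_hz)
        bias = float(np.mean(dba - test.labels))
        return error_report(dba - bias, test.labels)

    if tag == "student_dnn":
        if student is None:
            raise ValueError("student_dnn baseline needs trained parameters")
        return error_report(forward(student, test.inputs), test.labels)

    # stationary loudness from the average spectrum, per sound; the
    # time-varying reference needs the true 1-ms hop, so the sounds are
    # re-synthesized from the manifest
    from .soundgen import synthesize

    preds, refs = [], []
    for sid in np.unique(test.sound_id):
        sig = synthesize(test.manifest.specs[int(sid)])
        times, levels = band_spectra(sig, teacher.bands, hop=HOP_TRACE)
        mean_power = np.mean(10.0 ** (levels / 10.0), axis=0)
        avg_spectrum = 10.0 * np.log10(mean_power)
        preds.append(float(teacher.phons_from_levels(avg_spectrum)))
        inst = np.asarray(teacher.phons_from_levels(levels))
        refs.append(teacher.smooth_trace(times, inst).overall)
    return error_report(np.asarray(preds), np.asarray(refs))


# ---------------------------------------------------------------------------
# Trace-level comparison (instantaneous / short / long / overall)
# ---------------------------------------------------------------------------


def _smoothed_error_reports(
    teacher: Teacher,
    inst_pred: list[np.ndarray],
    inst_ref: list[np.ndarray],
) -> dict[str, ErrorReport]:
    """Apply the teacher's smoothing identically to both series per sound
    and pool the errors at every stage."""
    pooled = {k: ([], []) for k in ("instantaneous", "short_term", "long_term")}
    overall_p, overall_r = [], []
    for p, r in zip(inst_pred, inst_ref):
        times = np.arange(len(p)) * 1e-3
        tp = teacher.smooth_trace(times, p)
        tr = teacher.smooth_trace(times, r)
        pooled["instantaneous"][0].append(tp.instantaneous)
        pooled["instantaneous"][1].append(tr.instantaneous)
        pooled["short_term"][0].append(tp.short_term)
        pooled["short_term"][1].append(tr.short_term)
        pooled["long_term"][0].append(tp.long_term)
        pooled["long_term"][1].append(tr.long_term)
        overall_p.append(tp.overall)
        overall_r.append(tr.overall)
    out = {
        k: error_report(np.concatenate(v[0]), np.concatenate(v[1]))
        for k, v in pooled.items()
    }
    out["overall"] = error_report(np.asarray(overall_p), np.asarray(overall_r))
    return out


def trace_errors(
    student: MLPParams,
    sounds: list[AudioSignal],
    teacher: Teacher | None = None,
) -> dict[str, ErrorReport]:
    """Student-versus-teacher errors for the four loudness kinds.

    Both models are run at the 1-ms hop; the teacher's smoothing formula
    is applied to both instantaneous series, and errors are reported for
    instantaneous, short-term, long-term (pooled over time) and overall
    loudness (one value per sound).
    """
    if teacher is None:
        teacher = Teacher()
    inst_pred, inst_ref = [], []
    for sig in sounds:
        _, levels = band_spectra(sig, teacher.bands, hop=HOP_TRACE)
        inst_ref.append(np.asarray(teacher.phons_from_levels(levels)))
        inst_pred.append(np.asarray(forward(student, levels)))
    return _smoothed_error_reports(teacher, inst_pred, inst_ref)


def report_table(reports: dict[str, ErrorReport]) -> pd.DataFrame:
    """Reports as a table: rows = sets or loudness kinds, the five metrics."""
    return pd.DataFrame(
        {name: rep.as_dict() for name, rep in reports.items()}
    ).T[list(METRIC_COLUMNS)]
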