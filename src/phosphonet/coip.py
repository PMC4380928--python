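"""Luminescence co-IP hit calling and validation-rate summaries.

A pair's signal is compared against background binding measured in the same
run with the same firefly-tagged protein and a non-related partner:

* ``fold`` = mean(signal) / mean(background)
* ``Z``    = (mean(signal) - mean(background)) / sd(background), with the
  sample (n-1) standard deviation of the background triplicate.

A measurement is **positive** when both fold and Z reach their thresholds
(default 2 for both). The published rule is worded both as "at least two"
and as "larger than two"; the default here is inclusive (>=), with
``strict=True`` switching both comparisons to strict (>), and calls landing
exactly on a threshold are flagged as boundary cases so the difference stays
auditable. Both statistics are ratios of readings from one luminometer, so
calls are invariant under any rescaling of the instrument's units.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .types import CoIPMeasurement

POSITIVE = "positive"
NEGATIVE = "negative"
INVALID = "invalid"


@dataclass
class CoIPCall:
    """Result of calling one co-IP measurement."""

    pair_id: str
    fold: float
    log2_fold: float
    z: float  # nan when sd(background) = 0
    call: str  # positive | negative | invalid
    boundary: bool = False  # a statistic sits exactly on its threshold
    z_undefined: bool = False  # sd(background) = 0; call fell back to fold only


def coip_call(
    m: CoIPMeasurement,
    fold_threshold: float = 2.0,
    z_threshold: float = 2.0,
    strict: bool = False,
) -> CoIPCall:
    """Call one measurement positive/negative/invalid under the fold & Z rule."""
    mean_s = statistics.fmean(m.signal)
    mean_b = statistics.fmean(m.background)
    fold = mean_s / mean_b
    sd_b = statistics.stdev(m.background)  # sample SD, n-1
    z_undefined = sd_b == 0.0
    z = math.nan if z_undefined else (mean_s - mean_b) / sd_b

    if not m.valid:
        return CoIPCall(m.pair_id, fold, math.log2(fold), z, INVALID,
                        z_undefined=z_undefined)

    def meets(value: float, threshold: float) -> bool:
        return value > threshold if strict else value >= threshold

    fold_ok = meets(fold, fold_threshold)
    z_ok = True if z_undefined else meets(z, z_threshold)
    call = POSITIVE if (fold_ok and z_ok) else NEGATIVE
    boundary = fold == fold_threshold or (not z_undefined and z == z_threshold)
    return CoIPCall(m.pair_id, fold, math.log2(fold), z, call, boundary, z_undefined)


def call_measurements(
    measurements: Iterable[CoIPMeasurement],
    fold_threshold: float = 2.0,
    z_threshold: float = 2.0,
    strict: bool = False,
) -> list[CoIPCall]:
    return [coip_call(m, fold_threshold, z_threshold, strict) for m in measurements]


def validation_summary(
    calls: Sequence[CoIPCall],
    dependence_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class counts of tested/valid/positive pairs and the validation rate.

    ``rate`` = positive / valid; invalid measurements are excluded from the
    denominator, and a class with no valid measurement reports ``nan``. With
    no labels given, a single "all" row is returned.
    """
    labels = ["all"] * len(calls) if dependence_labels is None else list(dependence_labels)
    if len(labels) != len(calls):
        raise ValueError("calls and dependence_labels must align")
    rows: dict[str, dict[str, int]] = {}
    for call, label in zip(calls, labels):
        row = rows.setdefault(label, {"n_tested": 0, "n_valid": 0, "n_positive": 0})
        row["n_tested"] += 1
        if call.call != INVALID:
            row["n_valid"] += 1
            row["n_positive"] += int(call.call == POSITIVE)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df["rate"] = df["n_positive"] / df["n_valid"].where(df["n_valid"] > 0)
    return df


def kinase_induction_contrast(
    m_induced: CoIPMeasurement,
    m_uninduced: CoIPMeasurement,
    flag_threshold: float = 2.0,
) -> tuple[float, bool]:
    """Fold-change of fold-changes between induced and uninduced kinase states.

    Returns the ratio of the induced pair's fold over the uninduced pair's
    fold and whether it exceeds ``flag_threshold`` (strictly) — the criterion
    for a strong binding increase upon kinase induction.
    """
    fold_induced = coip_call(m_induced).fold
    fold_uninduced = coip_call(m_uninduced).fold
    ratio = fold_induced / fold_uninduced
    return ratio, ratio > flag_threshold
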