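"""Per-probe dose-response classification against a reference perturbation.

Each probe is placed in exactly one category by comparing its reference fold
change with its query fold change at the top dose (lower doses feed only the
monotone-trend call):

``mimicked_full``
    strong reference response reproduced by the query at >= ``full_ratio``
    of the reference log2 magnitude, same direction (the EGR3-type case);
``mimicked_attenuated``
    same direction but weaker (the GREB1-type case);
``not_mimicked``
    strong reference response with no query response (MYBL1/RET-type);
``discordant``
    reference and query respond in opposite directions (CYP1A1-type);
``query_specific``
    query responds but the reference does not (the dose-dependent
    query-only cluster);
``unaffected``
    neither responds.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .matrix import ContrastTable

logger = logging.getLogger(__name__)

CATEGORIES = (
    "mimicked_full",
    "mimicked_attenuated",
    "not_mimicked",
    "discordant",
    "query_specific",
    "unaffected",
)


def dose_trend(
    query_fc_by_dose: Mapping[float, float] | Sequence[float],
    min_top_fold: float = 1.5,
) -> str:
    """Monotone trend call over an increasing dose series of fold changes.

    ``monotone_up`` iff log2 fold change strictly increases across doses and
    the top dose reaches at least ``min_top_fold``; ``monotone_down`` is
    symmetric (strictly decreasing, top-dose fc <= 1/min_top_fold); anything
    else is ``none``.
    """
    fcs = _dose_series(query_fc_by_dose)
    if len(fcs) < 2:
        raise ValidationError("dose_trend requires at least two doses")
    lfc = np.log2(fcs)
    if np.all(np.diff(lfc) > 0) and fcs[-1] >= min_top_fold:
        return "monotone_up"
    if np.all(np.diff(lfc) < 0) and fcs[-1] <= 1.0 / min_top_fold:
        return "monotone_down"
    return "none"


def _dose_series(query_fc_by_dose: Mapping[float, float] | Sequence[float]) -> np.ndarray:
    if isinstance(query_fc_by_dose, Mapping):
        fcs = np.asarray([query_fc_by_dose[d] for d in sorted(query_fc_by_dose)], dtype=float)
    else:
        fcs = np.asarray(list(query_fc_by_dose), dtype=float)
    if fcs.size == 0:
        raise ValidationError("empty dose series")
    if np.any(fcs <= 0) or not np.isfinite(fcs).all():
        raise ValidationError("fold changes must be positive and finite")
    return fcs


def classify_probe(
    reference_fc: float,
    query_fc_by_dose: Mapping[float, float] | Sequence[float],
    respond_min: float = 1.5,
    full_ratio: float = 0.8,
    reference_respond_min: float = 2.5,
) -> str:
    """Classify one probe's response pattern; see module docstring.

    ``reference_fc`` and the dose series are fold changes (positive). The
    reference counts as responsive when |log2 fc| >= log2
    ``reference_respond_min`` (default 2.5-fold, the scale of the stringent
    signature filter's down cutoff); the query when the top-dose
    |log2 fc| >= log2 ``respond_min``. Any query-responsive probe whose
    reference response is below the reference threshold is
    ``query_specific``, keeping the categories exhaustive.
    """
    if reference_fc <= 0 or not np.isfinite(reference_fc):
        raise ValidationError("reference fold change must be positive and finite")
    if respond_min <= 1 or reference_respond_min <= 1:
        raise ValidationError("respond_min thresholds must exceed 1")
    fcs = _dose_series(query_fc_by_dose)
    R = np.log2(reference_fc)
    Q = np.log2(fcs[-1])
    r = np.log2(respond_min)
    ref_responsive = abs(R) >= np.log2(reference_respond_min)
    query_responsive = abs(Q) >= r
    if ref_responsive and query_responsive:
        if np.sign(R) != np.sign(Q):
            return "discordant"
        if abs(Q) >= full_ratio * abs(R):
            return "mimicked_full"
        return "mimicked_attenuated"
    if ref_responsive:
        return "not_mimicked"
    if query_responsive:
        return "query_specific"
    return "unaffected"


def classify_all(
    probe_ids: Sequence[str],
    reference: ContrastTable,
    dose_contrasts: Mapping[float, ContrastTable],
    respond_min: float = 1.5,
    full_ratio: float = 0.8,
    reference_respond_min: float = 2.5,
    min_top_fold: float = 1.5,
) -> tuple[pd.DataFrame, Counter]:
    """Classify every probe in a set across the reference and dose series.

    ``dose_contrasts`` maps numeric dose -> contrast table; doses are used in
    increasing order. Probes missing from any contrast are dropped with a
    warning. Returns a per-probe table (category, reference fc, per-dose fc,
    dose trend) and a Counter of category totals.
    """
    doses = sorted(dose_contrasts)
    if not doses:
        raise ValidationError("classify_all requires at least one dose contrast")
    rows = []
    dropped = []
    for pid in probe_ids:
        if pid not in reference.table.index or any(
            pid not in dose_contrasts[d].table.index for d in doses
        ):
            dropped.append(pid)
            continue
        ref_fc = float(reference.table.at[pid, "fc"])
        fc_by_dose = {d: float(dose_contrasts[d].table.at[pid, "fc"]) for d in doses}
        category = classify_probe(ref_fc, fc_by_dose, respond_min, full_ratio, reference_respond_min)
        trend = dose_trend(fc_by_dose, min_top_fold) if len(doses) >= 2 else "none"
        row = {"probe_id": pid, "category": category, "reference_fc": ref_fc,
               "dose_trend": trend}
        row.update({f"fc_dose_{d:g}": fc_by_dose[d] for d in doses})
        rows.append(row)
    if dropped:
        logger.warning("classify_all: dropped %d probes missing from a contrast: %s",
                       len(dropped), dropped[:10])
    columns = ["probe_id", "category", "reference_fc", "dose_trend"] + [
        f"fc_dose_{d:g}" for d in doses
    ]
    table = pd.DataFrame(rows, columns=columns).set_index("probe_id") if rows else (
        pd.DataFrame(columns=columns[1:], index=pd.Index([], name="probe_id"))
    )
    counts = Counter(table["category"]) if len(table) else Counter()
    logger.info("classification: %s", dict(counts))
    return table, counts
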