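"""Per-probe differential expression: fold change, two-sample t, BH-FDR, filters.

The contrast statistics follow classic two-colour/Affymetrix microarray
practice: probe-wise pooled-variance Student's t on log2 intensities, fold
change as 2**(difference of group means), and Benjamini-Hochberg step-up
q-values across all probes of a contrast. A Welch (unequal-variance) option
is available but off by default.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .matrix import ContrastTable, ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


def fold_change(treatment_log2: Sequence[float], control_log2: Sequence[float]) -> tuple[float, float]:
    """Fold change of a probe between two groups of log2 intensities.

    Returns ``(log2_fc, fc)`` where ``log2_fc`` is the difference of group
    means on the log2 scale and ``fc = 2**log2_fc`` (treatment over control
    on the intensity scale).
    """
    t = np.asarray(treatment_log2, dtype=float)
    c = np.asarray(control_log2, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValidationError("fold_change requires at least one value per group")
    if not (np.isfinite(t).all() and np.isfinite(c).all()):
        raise ValidationError("fold_change requires finite values")
    log2_fc = float(t.mean() - c.mean())
    return log2_fc, float(2.0 ** log2_fc)


def two_sample_t(
    treatment_log2: Sequence[float],
    control_log2: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on log2 intensities.

    Pooled-variance Student's t by default (``welch=True`` switches to the
    unequal-variance form). Two-sided p from the t distribution. Degenerate
    zero-variance inputs are resolved deterministically: equal means give
    ``(0, 1)``; unequal means give ``(+/-inf, 0)`` with a warning.
    """
    t_vals = np.asarray(treatment_log2, dtype=float)
    c_vals = np.asarray(control_log2, dtype=float)
    if t_vals.size < 2 or c_vals.size < 2:
        raise ValidationError("two_sample_t requires at least two values per group")
    pooled_var = _pooled_variance(t_vals, c_vals, welch)
    diff = t_vals.mean() - c_vals.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means; p set to 0", stacklevel=2)
        return float(np.sign(diff) * np.inf), 0.0
    res = stats.ttest_ind(t_vals, c_vals, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def _pooled_variance(t_vals: np.ndarray, c_vals: np.ndarray, welch: bool) -> float:
    vt = t_vals.var(ddof=1)
    vc = c_vals.var(ddof=1)
    if welch:
        return float(vt / t_vals.size + vc / c_vals.size)
    n1, n2 = t_vals.size, c_vals.size
    return float(((n1 - 1) * vt + (n2 - 1) * vc) / (n1 + n2 - 2))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_table(
    matrix: ExpressionMatrix,
    treatment_group: str,
    control_group: str,
    welch: bool = False,
    name: str | None = None,
) -> ContrastTable:
    """Vectorised per-probe contrast statistics for treatment vs control.

    Probes with any missing intensity in either group are dropped with a
    logged count. q-values are BH-adjusted across the retained probes.
    """
    t_block = matrix.group_values(treatment_group).to_numpy(dtype=float)
    c_block = matrix.group_values(control_group).to_numpy(dtype=float)
    keep = np.isfinite(t_block).all(axis=1) & np.isfinite(c_block).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("contrast %s vs %s: dropped %d probes with missing intensities",
                    treatment_group, control_group, n_dropped)
    probes = matrix.probe_ids[keep]
    t_block = t_block[keep]
    c_block = c_block[keep]

    mean_t = t_block.mean(axis=1)
    mean_c = c_block.mean(axis=1)
    log2_fc = mean_t - mean_c
    n1, n2 = t_block.shape[1], c_block.shape[1]
    vt = t_block.var(axis=1, ddof=1)
    vc = c_block.var(axis=1, ddof=1)
    if welch:
        se2 = vt / n1 + vc / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((vt / n1) ** 2 / (n1 - 1) + (vc / n2) ** 2 / (n2 - 1))
    else:
        pooled = ((n1 - 1) * vt + (n2 - 1) * vc) / (n1 + n2 - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = log2_fc / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    # zero-variance degenerates: equal means -> (0, 1); unequal -> (inf, 0)
    zero_var = se2 == 0
    if zero_var.any():
        flat = zero_var & (log2_fc == 0)
        moved = zero_var & (log2_fc != 0)
        t_stat[flat], p[flat] = 0.0, 1.0
        t_stat[moved], p[moved] = np.sign(log2_fc[moved]) * np.inf, 0.0

    table = pd.DataFrame(
        {
            "mean_log2_treatment": mean_t,
            "mean_log2_control": mean_c,
            "log2_fc": log2_fc,
            "fc": 2.0**log2_fc,
            "t_statistic": t_stat,
            "p_value": p,
        },
        index=probes,
    )
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    contrast_name = name or f"{treatment_group}_vs_{control_group}"
    logger.info("contrast %s: %d probes, %d at p<0.05", contrast_name, len(table),
                int((table["p_value"] < 0.05).sum()))
    return ContrastTable(contrast_name, table, treatment_group, control_group)


def initial_filter(table: ContrastTable, p_max: float = 0.05, fc_min: float = 1.5) -> pd.Index:
    """First-tier differential-expression filter: p < p_max and |fold| > fc_min.

    The fold threshold is applied symmetrically: a probe is retained when
    fc > fc_min (up) or fc < 1/fc_min (down).
    """
    if fc_min <= 1:
        raise ValidationError(f"fc_min must exceed 1, got {fc_min}")
    t = table.table
    mask = (t["p_value"] < p_max) & ((t["fc"] > fc_min) | (t["fc"] < 1.0 / fc_min))
    selected = t.index[mask]
    logger.info("initial filter (p<%g, fold>%g): %d of %d probes", p_max, fc_min,
                len(selected), len(t))
    return selected


def collapse_to_genes(
    probe_ids: Iterable[str],
    annotation: ProbeAnnotation,
) -> tuple[int, list[str], list[str]]:
    """Collapse a probe set to unique nonempty gene symbols.

    Returns ``(n_genes, sorted gene symbols, unannotated probe ids)``.
    Probes without a symbol are reported separately and never counted as
    genes — several probe sets may interrogate the same gene, and some
    interrogate transcripts with no assigned symbol.
    """
    genes: set[str] = set()
    unannotated: list[str] = []
    for pid in probe_ids:
        sym = annotation.gene_symbol(pid)
        if sym:
            genes.add(sym)
        else:
            unannotated.append(pid)
    logger.info("collapse: %d genes, %d unannotated probes", len(genes), len(unannotated))
    return len(genes), sorted(genes), unannotated
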