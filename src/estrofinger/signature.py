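"""Reference-perturbation signature derivation.

The signature is the ordered set of probes passing the stringent filter on
the reference contrast — strong up-regulation (fold change above ``fc_up``),
strong down-regulation (below ``fc_down``) and a q-value below ``fdr_max`` —
with a fixed per-probe direction. A cross-study concordance filter can then
drop probes whose direction is not reproduced (at a minimum fold) in
external fold-change profiles from independent experiments on the same
platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .matrix import ContrastTable, ProbeAnnotation

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Ordered probe set with direction labels derived from one contrast.

    ``probes`` is indexed by probe id with columns ``direction`` ("up" or
    "down"), ``reference_fc`` and ``gene_symbol``; up probes come first in
    descending fold change, then down probes in ascending fold change.
    ``thresholds`` records the filter provenance.
    """

    probes: pd.DataFrame
    contrast_name: str = ""
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("direction", "reference_fc", "gene_symbol"):
            if col not in self.probes.columns:
                raise ValidationError(f"signature missing column {col!r}")
        bad = set(self.probes["direction"]) - {"up", "down"}
        if bad:
            raise ValidationError(f"invalid directions: {sorted(bad)}")
        if self.probes.index.has_duplicates:
            raise ValidationError("duplicate probes in signature")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    @property
    def up_probes(self) -> pd.Index:
        return self.probes.index[self.probes["direction"] == "up"]

    @property
    def down_probes(self) -> pd.Index:
        return self.probes.index[self.probes["direction"] == "down"]

    def __len__(self) -> int:
        return len(self.probes)


def _order_signature(frame: pd.DataFrame) -> pd.DataFrame:
    up = frame[frame["direction"] == "up"].sort_values("reference_fc", ascending=False, kind="stable")
    down = frame[frame["direction"] == "down"].sort_values("reference_fc", ascending=True, kind="stable")
    return pd.concat([up, down])


def stringent_filter(
    table: ContrastTable,
    annotation: ProbeAnnotation | None = None,
    fc_up: float = 4.0,
    fc_down: float = 0.4,
    fdr_max: float = 0.01,
) -> Signature:
    """Derive a signature from a contrast by the stringent fold/FDR filter.

    Retains probes with q < ``fdr_max`` whose fold change exceeds ``fc_up``
    (direction "up") or falls below ``fc_down`` (direction "down"). Output is
    ordered by descending fold change within the up block, then ascending
    within the down block.
    """
    if fc_up <= 1:
        raise ConfigurationError(f"fc_up must exceed 1, got {fc_up}")
    if fc_down >= 1:
        raise ConfigurationError(f"fc_down must be below 1, got {fc_down}")
    if not table.has_q_values:
        raise ValidationError("stringent_filter requires q values; run bh_fdr first")
    t = table.table
    passing = t[t["q_value"] < fdr_max]
    up = passing[passing["fc"] > fc_up]
    down = passing[passing["fc"] < fc_down]
    frame = pd.DataFrame(
        {
            "direction": ["up"] * len(up) + ["down"] * len(down),
            "reference_fc": np.concatenate([up["fc"].to_numpy(), down["fc"].to_numpy()]),
        },
        index=up.index.append(down.index),
    )
    frame["gene_symbol"] = [annotation.gene_symbol(p) if annotation else "" for p in frame.index]
    frame = _order_signature(frame)
    logger.info("stringent filter (fold>%g / fold<%g, FDR<%g) on %s: %d up, %d down",
                fc_up, fc_down, fdr_max, table.name, len(up), len(down))
    return Signature(frame, table.name,
                     {"fc_up": fc_up, "fc_down": fc_down, "fdr_max": fdr_max})


def concordance_filter(
    sig: Signature,
    external_profiles: Sequence[Mapping[str, float]],
    min_fold: float = 2.0,
) -> Signature:
    """Cross-study concordance check on a signature.

    ``external_profiles`` are probe -> log2 fold-change maps from independent
    experiments. A probe is kept iff every profile containing it changes at
    least ``min_fold``-fold in the signature's direction (up: fc >= min_fold;
    down: fc <= 1/min_fold). Probes absent from all profiles are kept with a
    warning, since absence is no evidence of discordance.
    """
    if not external_profiles:
        raise ValidationError("concordance_filter requires at least one external profile")
    log_min = np.log2(min_fold)
    keep: list[str] = []
    unseen: list[str] = []
    for pid, row in sig.probes.iterrows():
        seen = False
        concordant = True
        for profile in external_profiles:
            if pid not in profile:
                continue
            seen = True
            lfc = profile[pid]
            if row["direction"] == "up" and lfc < log_min:
                concordant = False
            if row["direction"] == "down" and lfc > -log_min:
                concordant = False
        if not seen:
            unseen.append(pid)
            keep.append(pid)
        elif concordant:
            keep.append(pid)
    if unseen:
        logger.warning("concordance filter: %d probes absent from all external profiles, kept: %s",
                       len(unseen), unseen[:10])
    logger.info("concordance filter (>=%g-fold in %d profiles): %d of %d probes kept",
                min_fold, len(external_profiles), len(keep), len(sig))
    thresholds = dict(sig.thresholds, concordance_min_fold=min_fold,
                      n_external_profiles=len(external_profiles))
    return Signature(sig.probes.loc[keep], sig.contrast_name, thresholds)


def query_responsive_set(
    table: ContrastTable,
    annotation: ProbeAnnotation | None = None,
    fc_up: float = 4.0,
    fc_down: float = 0.4,
    fdr_max: float | None = None,
) -> Signature:
    """Strongly query-responsive probes from the top-dose contrast.

    Same machinery as :func:`stringent_filter` but fold-change-only by
    default (``fdr_max=None`` disables the FDR clause); the selection
    difference is logged.
    """
    effective_fdr = 1.1 if fdr_max is None else fdr_max
    if fdr_max is None and not table.has_q_values:
        t = table.table.copy()
        t["q_value"] = 0.0
        table = ContrastTable(table.name, t, table.treatment_group, table.control_group)
    result = stringent_filter(table, annotation, fc_up=fc_up, fc_down=fc_down, fdr_max=effective_fdr)
    if fdr_max is None:
        with_fdr = stringent_filter(table, annotation, fc_up=fc_up, fc_down=fc_down, fdr_max=0.01)
        logger.info("query-responsive set: FDR clause off; %d probes (vs %d with FDR<0.01)",
                    len(result), len(with_fdr))
        result.thresholds["fdr_max"] = None
    return result
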