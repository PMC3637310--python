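"""Core in-memory containers: expression matrix, probe annotation, contrast table.

All intensities are log2-transformed. An :class:`ExpressionMatrix` couples a
probes x samples value table with per-sample metadata (treatment group,
numeric dose where applicable, replicate index); every downstream statistic
is computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "dose_mg_ml", "replicate")


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensity matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``group`` (str),
        ``dose_mg_ml`` (float, NaN for groups without a numeric dose such as
        vehicle control or the reference perturbation) and ``replicate``
        (int, 1-based).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        matrix_samples = set(self.values.columns)
        sheet_samples = set(self.samples.index)
        missing = sorted(matrix_samples - sheet_samples)
        if missing:
            raise ValidationError(f"samples in matrix missing from sample sheet: {missing}")
        extra = sorted(sheet_samples - matrix_samples)
        if extra:
            raise ValidationError(f"samples in sample sheet missing from matrix: {extra}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        # sample order follows the sheet
        self.values = self.values.loc[:, self.samples.index]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["group"]))

    def group_sample_ids(self, group: str) -> list[str]:
        ids = self.samples.index[self.samples["group"] == group].tolist()
        if not ids:
            raise ValidationError(f"no samples in group {group!r}")
        return ids

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of replicates belonging to one treatment group."""
        return self.values[self.group_sample_ids(group)]

    def group_dose(self, group: str) -> float:
        """Numeric dose shared by a group's samples (NaN if undosed)."""
        doses = self.samples.loc[self.samples["group"] == group, "dose_mg_ml"]
        return float(doses.iloc[0]) if len(doses) else float("nan")


@dataclass
class ProbeAnnotation:
    """Mapping probe id -> (gene symbol, free-text description).

    Gene symbols may be empty strings: some array probe sets interrogate
    transcripts with no assigned symbol. Probe ids must be unique.
    """

    table: pd.DataFrame  # index probe_id, columns gene_symbol, description

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids in annotation: {dups[:10]}")
        for col in ("gene_symbol", "description"):
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        self.table = self.table.fillna({"gene_symbol": "", "description": ""})

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, str]]) -> "ProbeAnnotation":
        df = pd.DataFrame.from_dict(mapping, orient="index", columns=["gene_symbol", "description"])
        df.index.name = "probe_id"
        return cls(df)

    def gene_symbol(self, probe_id: str) -> str:
        if probe_id not in self.table.index:
            return ""
        return str(self.table.at[probe_id, "gene_symbol"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ContrastTable:
    """Per-probe statistics for one treatment-versus-control contrast.

    ``table`` is indexed by probe id with columns ``mean_log2_treatment``,
    ``mean_log2_control``, ``log2_fc``, ``fc``, ``t_statistic``, ``p_value``
    and (after FDR adjustment) ``q_value``. Fold change is
    2**(mean log2 treatment - mean log2 control), so fc > 0 always.
    """

    name: str
    table: pd.DataFrame
    treatment_group: str = ""
    control_group: str = ""

    REQUIRED = ("mean_log2_treatment", "mean_log2_control", "log2_fc", "fc", "t_statistic", "p_value")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"contrast table missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate probe ids in contrast table")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def has_q_values(self) -> bool:
        return "q_value" in self.table.columns

    def log2_fc_map(self, probes: Iterable[str] | None = None) -> pd.Series:
        """log2 fold-change profile, optionally restricted to a probe subset."""
        s = self.table["log2_fc"]
        if probes is not None:
            s = s.loc[list(probes)]
        return s
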