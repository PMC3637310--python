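"""Synthetic replicated perturbation experiments with planted effects.

The generator reproduces the study design the pipeline targets: three
replicates each of a vehicle control (C), a reference perturbation (EM,
estradiol 0.1 uM) and a query perturbation at three increasing doses
(SL/SM/SH at 0.0256/0.256/2.56 mg/ml). Three probe blocks are planted on an
otherwise null background:

* a signature block strongly responsive to the reference (up effects of
  4-16-fold, down effects of at least ~2.5-fold), partially mimicked by the
  query with a dose-dependent attenuation coefficient in [0, 1];
* a query-specific block with a monotone dose-dependent query effect and no
  reference effect;
* null probes with baseline intensity only.

Effects are additive on the log2 scale; replicate noise is i.i.d. Gaussian
on the log2 scale. Ground truth (per-probe category and planted per-group
effects) is returned alongside the matrix so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._table1 import TABLE1_ROWS
from .exceptions import ConfigurationError
from .matrix import ContrastTable, ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

CATEGORY_NULL = "null"
CATEGORY_UP = "signature_up"
CATEGORY_DOWN = "signature_down"
CATEGORY_QUERY = "query_specific"


def _default_doses() -> dict[str, float]:
    return {"SL": 0.0256, "SM": 0.256, "SH": 2.56}


def _default_mimicry() -> dict[str, float]:
    return {"SL": 0.2, "SM": 0.4, "SH": 0.7}


def _default_query_effects() -> dict[str, float]:
    return {"SL": 0.5, "SM": 1.2, "SH": 2.5}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults mirror the study design: 20,000 probes of which 36 are planted
    strongly up and 9 strongly down in the reference group (the scale of the
    published estrogen-responsive probe set) and 60 respond only to the
    query; log2 up effects uniform in [2, 4] (4-16-fold), down effects in
    [-2.5, -1.3]; dose-wise mimicry coefficients 0.2/0.4/0.7; query-specific
    log2 effects 0.5/1.2/2.5; baseline log2 intensity N(8, 1.5^2); replicate
    noise sd 0.25 on the log2 scale.
    """

    n_probes: int = 20000
    n_signature_up: int = 36
    n_signature_down: int = 9
    n_query_specific: int = 60
    replicates_per_group: int = 3
    dose_labels: Mapping[str, float] = field(default_factory=_default_doses)
    reference_label: str = "EM"
    control_label: str = "C"
    up_log2fc_range: tuple[float, float] = (2.0, 4.0)
    down_log2fc_range: tuple[float, float] = (-2.5, -1.3)
    mimicry_by_dose: Mapping[str, float] = field(default_factory=_default_mimicry)
    query_specific_log2fc_by_dose: Mapping[str, float] = field(default_factory=_default_query_effects)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    seed: int = 0
    unannotated_fraction: float = 0.05

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be positive")
        if self.replicates_per_group < 2:
            raise ConfigurationError("replicates_per_group must be at least 2 (t-tests need replication)")
        for name in ("n_signature_up", "n_signature_down", "n_query_specific"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        planted = self.n_signature_up + self.n_signature_down + self.n_query_specific
        if planted > self.n_probes:
            raise ConfigurationError(
                f"planted probes ({planted}) exceed n_probes ({self.n_probes})")
        if not self.dose_labels:
            raise ConfigurationError("dose_labels must not be empty")
        doses = list(self.dose_labels.values())
        if any(d <= 0 for d in doses):
            raise ConfigurationError("dose_labels doses must be positive")
        if sorted(doses) != doses or len(set(doses)) != len(doses):
            raise ConfigurationError("dose_labels must be strictly ordered by numeric dose")
        for label in self.dose_labels:
            if label not in self.mimicry_by_dose:
                raise ConfigurationError(f"mimicry_by_dose missing dose label {label!r}")
            if label not in self.query_specific_log2fc_by_dose:
                raise ConfigurationError(f"query_specific_log2fc_by_dose missing dose label {label!r}")
            m = self.mimicry_by_dose[label]
            if not (0.0 <= m <= 1.0):
                raise ConfigurationError(f"mimicry_by_dose[{label!r}] must lie in [0, 1], got {m}")
        if self.up_log2fc_range[0] > self.up_log2fc_range[1] or self.up_log2fc_range[0] <= 0:
            raise ConfigurationError("up_log2fc_range must be a positive increasing interval")
        if self.down_log2fc_range[0] > self.down_log2fc_range[1] or self.down_log2fc_range[1] >= 0:
            raise ConfigurationError("down_log2fc_range must be a negative increasing interval")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigurationError("noise_sd and baseline_sd must be non-negative")
        if not (0.0 <= self.unannotated_fraction <= 1.0):
            raise ConfigurationError("unannotated_fraction must lie in [0, 1]")
        if self.reference_label == self.control_label:
            raise ConfigurationError("reference_label must differ from control_label")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def group_labels(self) -> list[str]:
        return [self.control_label, self.reference_label, *self.dose_labels]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment.

    ``table`` is indexed by probe id with a ``category`` column
    (signature_up / signature_down / query_specific / null) and one
    ``effect_<group>`` column per non-control group holding the planted log2
    effect added to that probe's baseline in that group.
    """

    table: pd.DataFrame

    def probes_in(self, category: str) -> pd.Index:
        return self.table.index[self.table["category"] == category]

    @property
    def signature_probes(self) -> pd.Index:
        return self.table.index[self.table["category"].isin([CATEGORY_UP, CATEGORY_DOWN])]


def generate_experiment(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a replicated multi-group experiment from a config.

    Group means are baseline + planted effect (reference group: the full
    signature effect; dose groups: mimicry coefficient x signature effect
    for signature probes, the dose's query-specific effect for query-only
    probes); replicates add i.i.d. N(0, noise_sd^2) on the log2 scale.
    Identical configs (including seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    width = len(str(n))
    probe_ids = [f"SIMP{i + 1:0{width}d}_at" for i in range(n)]

    categories = np.array([CATEGORY_NULL] * n, dtype=object)
    n_up, n_down, n_q = config.n_signature_up, config.n_signature_down, config.n_query_specific
    categories[:n_up] = CATEGORY_UP
    categories[n_up:n_up + n_down] = CATEGORY_DOWN
    categories[n_up + n_down:n_up + n_down + n_q] = CATEGORY_QUERY

    ref_effect = np.zeros(n)
    ref_effect[:n_up] = rng.uniform(*config.up_log2fc_range, size=n_up)
    ref_effect[n_up:n_up + n_down] = rng.uniform(*config.down_log2fc_range, size=n_down)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    groups = config.group_labels
    effects: dict[str, np.ndarray] = {config.control_label: np.zeros(n)}
    effects[config.reference_label] = ref_effect
    is_query = categories == CATEGORY_QUERY
    for label in config.dose_labels:
        e = config.mimicry_by_dose[label] * ref_effect
        e[is_query] = config.query_specific_log2fc_by_dose[label]
        effects[label] = e

    reps = config.replicates_per_group
    sample_ids, columns, meta = [], [], []
    for group in groups:
        mean = baseline + effects[group]
        dose = config.dose_labels.get(group, np.nan)
        for r in range(1, reps + 1):
            sid = f"{group}_{r}"
            sample_ids.append(sid)
            noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
            columns.append(mean + noise)
            meta.append({"sample_id": sid, "group": group, "dose_mg_ml": dose, "replicate": r})

    values = pd.DataFrame(np.column_stack(columns), index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    samples = pd.DataFrame(meta).set_index("sample_id")
    matrix = ExpressionMatrix(values, samples)

    truth_table = pd.DataFrame({"category": categories}, index=values.index)
    for group in groups[1:]:
        truth_table[f"effect_{group}"] = effects[group]
    truth = SimulationTruth(truth_table)
    logger.info("simulated %d probes x %d samples (%d up, %d down, %d query-specific planted)",
                n, len(sample_ids), n_up, n_down, n_q)
    return matrix, truth


def generate_annotation(config: SimulationConfig) -> ProbeAnnotation:
    """Synthetic probe annotation matching :func:`generate_experiment`.

    Assigns symbols GENE000001... with a configured fraction of probes left
    unannotated (empty symbol), exercising the gene-collapse rules. Uses a
    seed derived from the config's so annotation and matrix stay paired.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = config.n_probes
    width = len(str(n))
    probe_ids = [f"SIMP{i + 1:0{width}d}_at" for i in range(n)]
    blank = rng.random(n) < config.unannotated_fraction
    table = pd.DataFrame(
        {
            "gene_symbol": ["" if blank[i] else f"GENE{i + 1:06d}" for i in range(n)],
            "description": ["" if blank[i] else f"simulated gene {i + 1}" for i in range(n)],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(table)


def table1_fixture() -> tuple[ContrastTable, ContrastTable, ContrastTable]:
    """Packaged worked-example contrasts (reference E2, query doses SH and SM).

    Returns three :class:`ContrastTable` objects over the 44 published
    estrogen-responsive probes, carrying the printed two-decimal fold
    changes. Mean intensities are not published and are reconstructed as
    log2 fc over a zero control baseline; p/q are recorded as 0.0 because
    the printed probes were selected at FDR < 0.01 and no finer values were
    printed. The published text describes 45 probes (9 down-regulated) but
    prints 44 rows (8 down); the fixture carries the printed rows.
    """
    index = pd.Index([r[0] for r in TABLE1_ROWS], name="probe_id")

    def build(name: str, col: int) -> ContrastTable:
        fc = np.array([r[col] for r in TABLE1_ROWS], dtype=float)
        log2_fc = np.log2(fc)
        table = pd.DataFrame(
            {
                "mean_log2_treatment": log2_fc,
                "mean_log2_control": np.zeros_like(fc),
                "log2_fc": log2_fc,
                "fc": fc,
                "t_statistic": np.full_like(fc, np.nan),
                "p_value": np.zeros_like(fc),
                "q_value": np.zeros_like(fc),
            },
            index=index,
        )
        return ContrastTable(name, table)

    return build("E2", 3), build("SH", 4), build("SM", 5)


def table1_annotation() -> ProbeAnnotation:
    """Probe annotation (gene symbol, description) for the packaged fixture."""
    table = pd.DataFrame(
        {
            "gene_symbol": [r[1] for r in TABLE1_ROWS],
            "description": [r[2] for r in TABLE1_ROWS],
        },
        index=pd.Index([r[0] for r in TABLE1_ROWS], name="probe_id"),
    )
    return ProbeAnnotation(table)


def table1_directions() -> pd.Series:
    """Published per-probe direction labels ("up"/"down") for the fixture."""
    return pd.Series({r[0]: r[6] for r in TABLE1_ROWS}, name="direction")
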