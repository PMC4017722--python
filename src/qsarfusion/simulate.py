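"""Synthetic study generator with the statistical structure the fusion
analysis assumes.

True activities are drawn log-uniform over a configurable span of orders of
magnitude (matching the split rule that training activities span at least 4
orders; uniform in log10 makes the span exact by construction, where a
log-normal would only control it in distribution). Each of m prediction
systems reports

    predicted log10 IC50 = true log10 IC50 + bias_k + eps_k,

with (eps_1 … eps_m) jointly Gaussian: per-system standard deviations
``noise_sd`` and pairwise correlation matrix ``noise_corr``. Dialling
``noise_sd`` controls individual accuracy; dialling ``noise_corr`` controls
how *diverse* the systems are — independent noise gives maximally diverse
systems whose fusion helps, perfectly correlated noise gives redundant
systems whose fusion is a no-op. That is exactly the accuracy/diversity
trade-off the selection heuristics are built on.

Everything is reproducible from the single integer ``seed``: one
``numpy.random.Generator`` is threaded through all draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError
from .io import ActivityTable, InhibitorRecord, ScoreTable, ScreeningRecord

__all__ = [
    "SimulationConfig",
    "simulate_study",
    "simulate_screening",
    "recover_noise_sd",
    "recover_bias",
]


def _as_per_system(value, m: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (m,)).copy()
    return arr


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``noise_sd`` and ``bias`` may be scalars (shared by all systems) or
    length-m sequences, in log10 units. ``noise_corr`` is an m x m symmetric
    positive-semidefinite matrix with unit diagonal; ``None`` means
    independent noise.
    """

    n_train: int = 25
    n_test: int = 133
    span_orders: float = 4.6
    m: int = 2
    noise_sd: float | tuple = 0.5
    bias: float | tuple = 0.0
    noise_corr: np.ndarray | None = None
    base_log10_nM: float = 0.5  # lower edge of the activity range
    seed: int = 0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_train < 0 or self.n_test < 0 or self.m < 1:
            raise ValueError("counts must be non-negative and m >= 1")
        if self.span_orders < 0:
            raise ValueError("span_orders must be >= 0")
        sd = _as_per_system(self.noise_sd, self.m, "noise_sd")
        if np.any(sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.noise_corr is not None:
            corr = np.asarray(self.noise_corr, dtype=float)
            if corr.shape != (self.m, self.m):
                raise ValueError(f"noise_corr must be {self.m}x{self.m}")
            if not np.allclose(corr, corr.T):
                raise ValueError("noise_corr must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("noise_corr must have unit diagonal")
            if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
                raise ValueError("noise_corr must be positive semidefinite")
        if self.labels is not None and len(self.labels) != self.m:
            raise ValueError("labels must have length m")

    @property
    def system_labels(self) -> tuple[str, ...]:
        return self.labels or tuple(f"S{k + 1}" for k in range(self.m))


def simulate_study(
    config: SimulationConfig,
) -> tuple[ActivityTable, ActivityTable, list[ScoreTable]]:
    """Generate a train table, a test table, and m prediction systems.

    Prediction systems cover both tables (train ids then test ids, which are
    disjoint). Identical configs produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    sd = _as_per_system(config.noise_sd, config.m, "noise_sd")
    bias = _as_per_system(config.bias, config.m, "bias")
    corr = (
        np.eye(config.m)
        if config.noise_corr is None
        else np.asarray(config.noise_corr, dtype=float)
    )
    cov = np.outer(sd, sd) * corr

    n = config.n_train + config.n_test
    log_truth = config.base_log10_nM + config.span_orders * rng.random(n)
    eps = rng.multivariate_normal(
        np.zeros(config.m), cov, size=n, method="svd"
    )  # (n, m)
    log_pred = log_truth[:, None] + bias[None, :] + eps

    ids = [f"TRN{i + 1:05d}" for i in range(config.n_train)] + [
        f"TST{i + 1:05d}" for i in range(config.n_test)
    ]
    train = ActivityTable(
        name="sim_train",
        records=[
            InhibitorRecord(ids[i], float(10 ** log_truth[i]), set_label="train")
            for i in range(config.n_train)
        ],
    )
    test = ActivityTable(
        name="sim_test",
        records=[
            InhibitorRecord(ids[i], float(10 ** log_truth[i]), set_label="test")
            for i in range(config.n_train, n)
        ],
    )
    systems = [
        ScoreTable(
            label=config.system_labels[k],
            scores={ids[i]: float(10 ** log_pred[i, k]) for i in range(n)},
        )
        for k in range(config.m)
    ]
    return train, test, systems


def simulate_screening(
    n: int,
    seed: int = 0,
    ic50_range_nM: tuple[float, float] = (1.0, 10.0),
    energy_mean: float = 45.0,
    energy_sd: float = 8.0,
) -> list[ScreeningRecord]:
    """Independent screening candidates for exercising the triage filters.

    Estimated IC50 is log-uniform over ``ic50_range_nM``; docking energy is
    Gaussian and independent of potency (docking scores are not modelled as
    informative here — this only feeds filter logic).
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(ic50_range_nM[0]), np.log10(ic50_range_nM[1])
    return [
        ScreeningRecord(
            id=f"SCR{i + 1:05d}",
            est_ic50_nM=float(10 ** (lo + (hi - lo) * rng.random())),
            energy_kcal_mol=float(rng.normal(energy_mean, energy_sd)),
        )
        for i in range(n)
    ]


def _residuals(truth: ActivityTable, pred: ScoreTable) -> np.ndarray:
    absent = pred.covers(truth.ids)
    if absent:
        raise CoverageError(
            f"system {pred.label!r} is missing ids: {absent[:10]}", missing=absent
        )
    if truth.t < 2:
        raise ValueError("need at least 2 records")
    return np.array(
        [np.log10(pred[i]) - np.log10(truth.activities[i]) for i in truth.ids]
    )


def recover_noise_sd(truth: ActivityTable, pred: ScoreTable) -> float:
    """Sample SD (ddof=1) of predicted-minus-true log10 activities."""
    return float(np.std(_residuals(truth, pred), ddof=1))


def recover_bias(truth: ActivityTable, pred: ScoreTable) -> float:
    """Mean of predicted-minus-true log10 activities."""
    return float(np.mean(_residuals(truth, pred)))
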