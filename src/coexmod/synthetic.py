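"""Multi-condition synthetic time-series benchmark with known class structure.

Emulates the classic sine/linear benchmark used to validate cross-condition
module discovery: six gene classes measured over 20 time points in each of
K conditions.  Four classes follow ``sin(2*pi*t/10 - w)`` with a phase ``w``
drawn fresh for every (class, condition) pair, so the same genes show
different patterns in different conditions; the remaining two classes follow
the linear ramps ``t/20`` and ``-t/20``.  Replicated measurements are the
noiseless pattern plus Gaussian noise with standard deviation
``noise_factor * sigma_it``, where ``sigma_it`` is a per-(gene, time)
heteroscedastic scale drawn from a configurable pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "LabeledDataset",
    "pattern_value",
    "default_noise_scale_pool",
    "generate_dataset",
    "write_dataset",
]

N_SINE_CLASSES = 4


def default_noise_scale_pool(size: int = 1000, seed: int = 0) -> np.ndarray:
    """Pool of per-measurement noise scales sigma_it.

    Log-normal with median 0.05 and log-scale 0.5 — a stand-in for the
    heteroscedastic measurement-error scales observed on real arrays.
    """
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=math.log(0.05), sigma=0.5, size=size)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    Defaults are the benchmark's stated conditions: 400 genes in 6 classes,
    20 time points, 5 conditions, high-noise multiplier ``noise_factor=6``.
    """

    n_genes: int = 400
    n_classes: int = 6
    n_timepoints: int = 20
    n_conditions: int = 5
    n_replicates: int = 3
    noise_factor: float = 6.0
    noise_scale_pool: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_classes", "n_timepoints", "n_conditions", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be >= 0")
        if self.noise_scale_pool is not None:
            pool = np.asarray(self.noise_scale_pool, dtype=float)
            if pool.ndim != 1 or pool.size == 0:
                raise ValueError("noise_scale_pool must be a non-empty 1-D array")
            if np.any(pool <= 0):
                raise ValueError("noise_scale_pool entries must be positive")
            self.noise_scale_pool = pool

    def class_sizes(self) -> list[int]:
        """Partition n_genes into n_classes as evenly as possible.

        The first ``n_genes % n_classes`` classes get one extra gene
        (400/6 -> 67,67,67,67,66,66).
        """
        base, extra = divmod(self.n_genes, self.n_classes)
        return [base + (1 if c < extra else 0) for c in range(self.n_classes)]


@dataclass
class LabeledDataset:
    """Generated benchmark: per-condition tensors plus ground-truth labels."""

    values: list[np.ndarray]  # one (n_genes, n_timepoints, n_replicates) tensor per condition
    class_labels: np.ndarray  # (n_genes,) int class ids, 1-based
    condition_ids: list[str]
    gene_ids: list[str] = field(default_factory=list)
    phases: np.ndarray | None = None  # (n_conditions, n_classes) phases used, NaN for linear classes

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(len(self.class_labels))]

    @property
    def timepoints(self) -> np.ndarray:
        return np.arange(1, self.values[0].shape[1] + 1, dtype=float)


def pattern_value(class_id: int, t: float, phase: float = 0.0) -> float:
    """Noiseless pattern for one class at time ``t``.

    Classes 1-4: ``sin(2*pi*t/10 - phase)``; class 5: ``t/20``;
    class 6: ``-t/20``.
    """
    if not 1 <= class_id <= 6:
        raise ValueError(f"invalid class id {class_id}: must be in 1..6")
    if class_id == 5:
        return t / 20.0
    if class_id == 6:
        return -t / 20.0
    return math.sin(2.0 * math.pi * t / 10.0 - phase)


def _pattern_matrix(class_id: int, timepoints: np.ndarray, phase: float) -> np.ndarray:
    if class_id == 5:
        return timepoints / 20.0
    if class_id == 6:
        return -timepoints / 20.0
    return np.sin(2.0 * np.pi * timepoints / 10.0 - phase)


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate the benchmark described by ``spec``.

    Each condition draws a fresh phase per sine class, so the class partition
    is shared across conditions while the patterns are not.  Reproducible:
    the same spec (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pool = spec.noise_scale_pool
    if pool is None:
        if spec.noise_factor > 0:
            pool = default_noise_scale_pool(seed=spec.seed)
        else:
            pool = np.array([1.0])
    elif pool.size == 0:  # pragma: no cover - guarded in __post_init__
        raise ValueError("noise_scale_pool is empty")

    sizes = spec.class_sizes()
    labels = np.repeat(np.arange(1, spec.n_classes + 1), sizes)
    timepoints = np.arange(1, spec.n_timepoints + 1, dtype=float)

    values: list[np.ndarray] = []
    phases = np.full((spec.n_conditions, spec.n_classes), np.nan)
    for _k in range(spec.n_conditions):
        tensor = np.empty((spec.n_genes, spec.n_timepoints, spec.n_replicates))
        start = 0
        for c, size in enumerate(sizes, start=1):
            phase = 0.0
            if c <= min(N_SINE_CLASSES, spec.n_classes) or c > 6:
                phase = rng.uniform(0.0, 2.0 * math.pi)
                phases[_k, c - 1] = phase
            mu = _pattern_matrix(c, timepoints, phase)  # (T,)
            # sigma_it: one heteroscedastic scale per (gene, time), shared by replicates
            sigma = spec.noise_factor * rng.choice(pool, size=(size, spec.n_timepoints))
            noise = rng.normal(0.0, 1.0, size=(size, spec.n_timepoints, spec.n_replicates))
            tensor[start : start + size] = mu[None, :, None] + sigma[:, :, None] * noise
            start += size
        values.append(tensor)

    condition_ids = [f"condition_{k + 1}" for k in range(spec.n_conditions)]
    return LabeledDataset(values=values, class_labels=labels, condition_ids=condition_ids, phases=phases)


def write_dataset(ds: LabeledDataset, out_dir) -> None:
    """Write one wide TSV per condition (columns ``t<j>_r<k>``) plus labels."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_t, n_r = ds.values[0].shape[1], ds.values[0].shape[2]
    columns = [f"t{j + 1}_r{k + 1}" for j in range(n_t) for k in range(n_r)]
    for cid, tensor in zip(ds.condition_ids, ds.values):
        flat = tensor.reshape(tensor.shape[0], -1)
        pd.DataFrame(flat, index=pd.Index(ds.gene_ids, name="gene_id"), columns=columns).to_csv(
            out / f"{cid}.tsv", sep="\t"
        )
    pd.DataFrame({"gene_id": ds.gene_ids, "class": ds.class_labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
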