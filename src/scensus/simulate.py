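"""Synthetic scRNA-seq-like fixtures: ground-truth partitions, expression
matrices with cluster structure, and perturbed base clusterings.

The generator draws, for each of C clusters, a mean expression profile
(shared positive baseline plus a cluster-specific location shift), adds
Gaussian within-cluster noise, floors at zero and optionally zero-inflates a
fixed fraction of entries — emulating the high dropout rate of droplet
scRNA-seq.  Base clusterings are derived from the truth by structural
merge/split operations followed by independent per-cell label noise, which
mimics how real base clusterers disagree with the truth in both cluster
count and membership.  It is a location-shift emulation, not a count-level
scRNA-seq simulator: the downstream method consumes only a feature space and
base labels, so separation structure is what matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import ExpressionMatrix, PartitionLabels

__all__ = [
    "SimulationScenario",
    "simulate_truth",
    "perturb_partition",
    "simulate_ensemble",
]

# merge/split directives: ("merge", label_a, label_b) relabels b into a;
# ("split", label_a) splits a uniformly into a and a new cluster.
StructuralOp = tuple


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic ensemble-clustering experiment.

    Defaults describe the standard small test scenario: 200 cells in 5
    equally sized, well-separated clusters over 50 genes, 10% zero
    inflation, and M = 4 base methods whose label-noise rates span
    0.05-0.20.
    """

    n_cells: int = 200
    n_genes: int = 50
    n_true_clusters: int = 5
    cluster_proportions: list[float] | None = None
    between_cluster_separation: float = 3.0
    within_cluster_noise_sd: float = 1.0
    zero_inflation_rate: float = 0.10
    n_base_methods: int = 4
    label_noise_rates: list[float] = field(
        default_factory=lambda: [0.05, 0.10, 0.15, 0.20]
    )
    structural_ops: list[list[StructuralOp]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        if not 0.0 <= self.zero_inflation_rate < 1.0:
            raise ValueError("zero_inflation_rate must be in [0, 1)")
        if self.cluster_proportions is not None:
            props = np.asarray(self.cluster_proportions, dtype=float)
            if len(props) != self.n_true_clusters:
                raise ValueError("one proportion per cluster required")
            if np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
                raise ValueError("proportions must be positive and sum to 1")
        if len(self.label_noise_rates) != self.n_base_methods:
            raise ValueError("one label-noise rate per base method required")
        if any(not 0.0 <= r < 1.0 for r in self.label_noise_rates):
            raise ValueError("label-noise rates must be in [0, 1)")
        if self.structural_ops is not None and len(self.structural_ops) != self.n_base_methods:
            raise ValueError("one structural-op list per base method required")

    def to_dict(self) -> dict:
        return asdict(self)


def _cluster_sizes(s: SimulationScenario) -> np.ndarray:
    c = s.n_true_clusters
    if s.cluster_proportions is None:
        props = np.full(c, 1.0 / c)
    else:
        props = np.asarray(s.cluster_proportions, dtype=float)
    sizes = np.floor(props * s.n_cells).astype(int)
    sizes[: s.n_cells - sizes.sum()] += 1  # deterministic remainder allocation
    if np.any(sizes == 0):
        raise ValueError("a cluster received zero cells; adjust proportions")
    return sizes


def simulate_truth(s: SimulationScenario) -> tuple[ExpressionMatrix, PartitionLabels]:
    """Draw the expression matrix and its generating partition."""
    rng = np.random.default_rng(s.seed)
    sizes = _cluster_sizes(s)
    codes = np.repeat(np.arange(s.n_true_clusters), sizes)
    # signed location shifts: a gene whose shifted mean falls below zero is
    # consistently floored to zero for that cluster, giving cluster-specific
    # marker on/off patterns in addition to level differences (so flooring
    # adds zeros beyond zero_inflation_rate whenever separation is
    # comparable to the baseline)
    baseline = rng.uniform(1.0, 3.0, size=s.n_genes)
    shifts = rng.normal(0.0, 1.0, size=(s.n_true_clusters, s.n_genes))
    means = baseline[None, :] + s.between_cluster_separation * shifts
    values = means[codes] + rng.normal(
        0.0, s.within_cluster_noise_sd, size=(s.n_cells, s.n_genes)
    )
    values = np.maximum(values, 0.0)
    if s.zero_inflation_rate > 0.0:
        dropout = rng.random(values.shape) < s.zero_inflation_rate
        values[dropout] = 0.0
    cell_ids = [f"cell_{i:05d}" for i in range(s.n_cells)]
    gene_ids = [f"gene_{j:04d}" for j in range(s.n_genes)]
    x = ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)
    truth = PartitionLabels(
        cell_ids=cell_ids,
        labels=[f"type_{c + 1}" for c in codes],
        method_name="truth",
    )
    return x, truth


def perturb_partition(
    truth: PartitionLabels,
    label_noise_rate: float = 0.0,
    structural_ops: list[StructuralOp] | None = None,
    seed: int = 0,
    method_name: str = "perturbed",
) -> PartitionLabels:
    """Derive a base-clustering surrogate from the truth.

    Structural merge/split directives are applied first (changing the
    cluster count, as real base clusterers do), then each cell is
    independently reassigned with probability ``label_noise_rate`` to a
    uniformly random existing cluster.
    """
    if not 0.0 <= label_noise_rate < 1.0:
        raise ValueError("label_noise_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = list(truth.labels)
    for op in structural_ops or []:
        kind = op[0]
        if kind == "merge":
            _, a, b = op
            present = set(labels)
            if a not in present or b not in present:
                raise ValueError(f"merge references missing cluster(s): {a!r}, {b!r}")
            labels = [a if lab == b else lab for lab in labels]
        elif kind == "split":
            _, a = op
            if a not in set(labels):
                raise ValueError(f"split references missing cluster: {a!r}")
            new = f"{a}_split"
            while new in set(labels):
                new += "_"
            labels = [
                (new if lab == a and rng.random() < 0.5 else lab) for lab in labels
            ]
        else:
            raise ValueError(f"unknown structural op {kind!r}")
    if label_noise_rate > 0.0:
        pool = sorted(set(labels))
        flip = rng.random(len(labels)) < label_noise_rate
        draws = rng.integers(0, len(pool), size=len(labels))
        labels = [
            pool[draws[i]] if flip[i] else labels[i] for i in range(len(labels))
        ]
    return PartitionLabels(
        cell_ids=list(truth.cell_ids), labels=labels, method_name=method_name
    )


def random_partition(
    cell_ids: list[str], n_clusters: int, seed: int, method_name: str = "random"
) -> PartitionLabels:
    """Uniformly random labels — a worthless base method for robustness tests."""
    rng = np.random.default_rng(seed)
    labels = [f"r{z}" for z in rng.integers(0, n_clusters, size=len(cell_ids))]
    return PartitionLabels(cell_ids=list(cell_ids), labels=labels, method_name=method_name)


def simulate_ensemble(
    s: SimulationScenario,
) -> tuple[ExpressionMatrix, PartitionLabels, list[PartitionLabels]]:
    """Truth plus M perturbed base partitions, all reproducible from the seed."""
    x, truth = simulate_truth(s)
    bases: list[PartitionLabels] = []
    for m in range(s.n_base_methods):
        ops = s.structural_ops[m] if s.structural_ops is not None else None
        bases.append(
            perturb_partition(
                truth,
                label_noise_rate=s.label_noise_rates[m],
                structural_ops=ops,
                seed=(s.seed + 7919 * (m + 1)) % (2**31),
                method_name=f"base_{m + 1}",
            )
        )
    return x, truth, bases
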