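"""Run-level configuration: fit hyperparameters plus pipeline choices.

Configs round-trip through flat YAML files whose keys match the CLI flag
names (dashes replaced by underscores).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .model import FitConfig

__all__ = ["RunConfig"]


def _default_b_grid() -> list[float]:
    return [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]


def _default_alpha_grid() -> list[float]:
    return [float(a) for a in range(50, 1000, 100)]  # 50, 150, ..., 950


@dataclass
class RunConfig:
    """End-to-end pipeline settings with field-standard defaults.

    ``wt`` is the consensus binarization threshold ("more than half of the
    methods agree" at 0.5); ``knn_k`` the neighbor count of the expression
    graph; ``b_grid``/``alpha_grid`` the hyperparameter sweep ranges.
    """

    q_max: int = 25
    alpha: float = 100.0
    hyper_a: float = 1.0
    hyper_b: float = 0.3
    wt: float = 0.5
    knn_k: int = 10
    rho: float = 1e-5
    max_iter: int = 100
    n_restarts: int = 50
    seed: int = 0
    prune_tol: float = 1e-4
    ch_variant: str = "standard"
    use_pca: bool = False
    n_pcs: int = 20
    use_weighted_consensus: bool = False
    b_grid: list[float] = field(default_factory=_default_b_grid)
    alpha_grid: list[float] = field(default_factory=_default_alpha_grid)
    sweep_restarts: int = 5

    def fit_config(self, alpha: float | None = None, hyper_b: float | None = None,
                   n_restarts: int | None = None) -> FitConfig:
        return FitConfig(
            q_max=self.q_max,
            alpha=self.alpha if alpha is None else alpha,
            hyper_a=self.hyper_a,
            hyper_b=self.hyper_b if hyper_b is None else hyper_b,
            rho=self.rho,
            max_iter=self.max_iter,
            n_restarts=self.n_restarts if n_restarts is None else n_restarts,
            seed=self.seed,
            prune_tol=self.prune_tol,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
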