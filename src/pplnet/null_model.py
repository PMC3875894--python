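"""Size-matched random pathway population used as the statistical control.

Each random network's gene count is drawn from a Normal calibrated on the
real pathway sizes (mean and sample standard deviation of gene-node
counts), rounded to the nearest integer, redrawn while non-positive; its
genes are sampled uniformly without replacement from the gene universe.
Random networks contain only gene nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pathways import Pathway, PathwayNode

_MAX_REDRAWS = 1000


@dataclass
class NullModelConfig:
    n_networks: int = 100
    mu_size: float = 0.0
    sigma_size: float = 0.0
    seed: int = 0
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.sigma_size < 0:
            raise ValueError("sigma_size must be >= 0")
        if not self.gene_universe:
            raise ValueError("gene_universe must be non-empty")


def estimate_size_distribution(pathways: list[Pathway]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of pathway gene counts."""
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways to estimate a size spread")
    sizes = np.array([len(p.gene_ids) for p in pathways], dtype=float)
    return float(sizes.mean()), float(sizes.std(ddof=1))


def draw_sizes(
    rng: np.random.Generator, n: int, mu: float, sigma: float, max_size: int
) -> list[int]:
    """Draw n integer sizes from N(mu, sigma), rejecting draws < 1 or
    beyond the universe size; bounded retries keep infeasible configs from
    spinning forever."""
    sizes: list[int] = []
    for _ in range(n):
        for _attempt in range(_MAX_REDRAWS):
            size = int(round(rng.normal(mu, sigma)))
            if 1 <= size <= max_size:
                sizes.append(size)
                break
        else:
            raise ValueError(
                f"could not draw a feasible network size <= {max_size} "
                f"from N({mu}, {sigma}) in {_MAX_REDRAWS} attempts"
            )
    return sizes


def generate_random_networks(config: NullModelConfig) -> list[Pathway]:
    """Generate ``config.n_networks`` random pathways (group ``random``),
    fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    universe = np.asarray(config.gene_universe, dtype=object)
    sizes = draw_sizes(
        rng, config.n_networks, config.mu_size, config.sigma_size, len(universe)
    )
    width = max(3, int(math.log10(config.n_networks)) + 1)
    pathways: list[Pathway] = []
    for i, size in enumerate(sizes, start=1):
        genes = rng.choice(universe, size=size, replace=False)
        nodes = tuple(
            PathwayNode(node_kind="gene", label=str(g), gene_id=str(g))
            for g in genes
        )
        pid = f"rand{i:0{width}d}"
        pathways.append(
            Pathway(pathway_id=pid, name=f"random network {i}", group="random", nodes=nodes)
        )
    return pathways
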