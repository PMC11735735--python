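"""Synthetic hashtag count datasets with ground truth.

Each simulated dataset mimics a pooled cell-hashing experiment with two kinds
of background noise layered on top of a clean signal:

* **signal** — every cell draws a uniform integer read count in
  ``[signal_low, signal_high]`` for its own tag (each tag of a doublet draws
  independently) and zero for all other tags;
* **cell-bound contamination** — contaminating reads physically attached to
  the cell. A fraction ``f = cell_bound_fraction`` of each cell's total bound
  reads is contamination, implemented by adding ``round(f/(1-f) * signal)``
  reads distributed multinomially over the non-own tags in proportion to
  their ambient levels;
* **ambient contamination** — cell-free tag background. Each tag *i* has an
  ambient level λ_i; per cell and tag, Poisson(λ_i) reads are added. One tag
  is pinned at ``ambient_max`` and the remaining levels are log-uniform in
  ``[ambient_min, ambient_max]``.

Exactly ``round(doublet_rate * total_cells)`` cells are doublets, replacing
singlets evenly across tags; each doublet carries an unordered pair of
distinct tags drawn uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd

from .graph_cluster import ParameterError
from .io_formats import DOUBLET, TagCountMatrix

CELL_BOUND_LEVELS = (0.02, 0.05, 0.14, 0.37)
AMBIENT_MAX_LEVELS = tuple(range(100, 2000, 200))  # 100, 300, ..., 1900
SCALABILITY_TAGS = (5, 10, 20, 40)
SCALABILITY_CELLS_PER_TAG = (100, 200, 400, 800)


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset (all recorded in the output)."""

    n_tags: int = 5
    cells_per_tag: int = 1000
    doublet_rate: float = 0.10
    signal_low: int = 10
    signal_high: int = 1000
    cell_bound_fraction: float = 0.02
    ambient_max: float = 100.0
    ambient_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tags < 2:
            raise ParameterError("need at least 2 tags")
        if not (0 <= self.doublet_rate < 1):
            raise ParameterError("doublet_rate must lie in [0, 1)")
        if self.signal_low > self.signal_high:
            raise ParameterError("signal_low must not exceed signal_high")
        if not (0 <= self.cell_bound_fraction < 1):
            raise ParameterError("cell_bound_fraction must lie in [0, 1)")
        if self.ambient_max > 0 and self.ambient_min > self.ambient_max:
            raise ParameterError("ambient_min must not exceed ambient_max")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    """A TagCountMatrix with per-cell ground truth and the generating config.

    ``truth[j]`` is a tag name for a singlet or a sorted tuple of two distinct
    tag names for a doublet. ``ambient_levels[i]`` is tag i's Poisson mean.
    """

    matrix: TagCountMatrix
    truth: list
    config: SimulationConfig
    ambient_levels: np.ndarray

    def truth_labels(self) -> pd.DataFrame:
        """Ground truth as a label table (doublet pairs collapsed to 'Doublet')."""
        labels = [t if isinstance(t, str) else DOUBLET for t in self.truth]
        return pd.DataFrame(
            {
                "barcode": self.matrix.barcodes,
                "label": labels,
                "confidence": 1.0,
            }
        )

    @property
    def doublet_fraction(self) -> float:
        return sum(1 for t in self.truth if not isinstance(t, str)) / len(self.truth)


def _draw_ambient_levels(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.ambient_max <= 0:
        return np.zeros(config.n_tags)
    levels = np.empty(config.n_tags)
    levels[0] = config.ambient_max  # one tag pinned at the maximum
    if config.n_tags > 1:
        levels[1:] = np.exp(
            rng.uniform(
                np.log(config.ambient_min), np.log(config.ambient_max),
                size=config.n_tags - 1,
            )
        )
    return levels


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    T = config.n_tags
    total = T * config.cells_per_tag
    tags = [f"HTO{i + 1}" for i in range(T)]
    barcodes = [f"cell_{j:06d}" for j in range(total)]

    # initial singlet assignment: cells_per_tag cells per tag, in tag blocks
    own_tag = np.repeat(np.arange(T), config.cells_per_tag)

    # convert round(rate * total) singlets into doublets, spread evenly over
    # the initial tag blocks; each doublet gets a uniform unordered tag pair
    n_doublets = int(round(config.doublet_rate * total))
    if n_doublets and T < 2:
        raise ParameterError("doublets need at least 2 tags")
    per_tag = np.full(T, n_doublets // T)
    per_tag[: n_doublets % T] += 1
    doublet_cells = np.concatenate(
        [
            rng.choice(np.where(own_tag == t)[0], size=per_tag[t], replace=False)
            for t in range(T)
        ]
    ).astype(np.int64) if n_doublets else np.empty(0, dtype=np.int64)

    ambient = _draw_ambient_levels(config, rng)

    # per-cell set of own tags (1 for singlets, 2 for doublets)
    is_doublet = np.zeros(total, dtype=bool)
    is_doublet[doublet_cells] = True
    truth: list = [tags[t] for t in own_tag]
    membership = np.zeros((T, total), dtype=bool)
    membership[own_tag, np.arange(total)] = True
    if n_doublets:
        pairs = np.array(
            [rng.choice(T, size=2, replace=False) for _ in range(n_doublets)]
        )
        for cell, (a, b) in zip(doublet_cells, pairs):
            membership[:, cell] = False
            membership[[a, b], cell] = True
            truth[cell] = tuple(sorted((tags[a], tags[b])))

    # own-tag signal
    counts = np.zeros((T, total), dtype=np.int64)
    n_signal_draws = int(membership.sum())
    signal = rng.integers(
        config.signal_low, config.signal_high + 1, size=n_signal_draws
    )
    counts[membership] = signal

    # cell-bound contamination: fraction f of each cell's bound reads,
    # multinomial over non-own tags proportional to ambient levels
    f = config.cell_bound_fraction
    if f > 0:
        own_signal = counts.sum(axis=0)
        n_contam = np.round(f / (1.0 - f) * own_signal).astype(np.int64)
        # group cells by their own-tag set so pvals are shared within a group
        keys = {}
        for j in range(total):
            keys.setdefault(tuple(np.where(membership[:, j])[0]), []).append(j)
        for own, cells in keys.items():
            other = np.setdiff1d(np.arange(T), own)
            weights = ambient[other]
            if weights.sum() <= 0:
                weights = np.ones_like(weights, dtype=float)
            pvals = weights / weights.sum()
            draws = rng.multinomial(n_contam[cells], pvals)
            counts[np.ix_(other, cells)] += draws.T
    # ambient contamination: Poisson per (tag, cell)
    if config.ambient_max > 0:
        counts += rng.poisson(ambient[:, None], size=(T, total))

    matrix = TagCountMatrix(counts, tags, barcodes)
    return SimulatedDataset(matrix, truth, config, ambient)


def paper_noise_grid(
    replicates: int = 3, base_seed: int = 0, **overrides
) -> list[SimulatedDataset]:
    """The high-background-noise benchmark grid.

    Cartesian product of 4 cell-bound contamination levels {2%, 5%, 14%, 37%}
    and 10 maximum ambient levels {100, 300, ..., 1900}, times ``replicates``
    datasets each (40 x replicates total); every dataset has 5 tags, 1000
    cells per tag and a 10% doublet rate.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    datasets = []
    seed = base_seed
    for cell_bound, ambient_max in product(CELL_BOUND_LEVELS, AMBIENT_MAX_LEVELS):
        for _ in range(replicates):
            config = SimulationConfig(
                cell_bound_fraction=cell_bound,
                ambient_max=float(ambient_max),
                seed=seed,
                **overrides,
            )
            datasets.append(simulate_dataset(config))
            seed += 1
    return datasets


def scalability_grid(base_seed: int = 0) -> list[SimulationConfig]:
    """Configs for the runtime-scaling benchmark: {5,10,20,40} tags x
    {100,200,400,800} cells per tag, low contamination (2% cell-bound,
    ambient_max 100), 10% doublets."""
    configs = []
    seed = base_seed
    for n_tags, cells_per_tag in product(SCALABILITY_TAGS, SCALABILITY_CELLS_PER_TAG):
        configs.append(
            SimulationConfig(
                n_tags=n_tags,
                cells_per_tag=cells_per_tag,
                doublet_rate=0.10,
                cell_bound_fraction=0.02,
                ambient_max=100.0,
                seed=seed,
            )
        )
        seed += 1
    return configs
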