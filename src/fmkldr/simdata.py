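"""Synthetic multi-view cohorts and region-measure tables.

The generator emulates the structure of a multi-omic / imaging cohort:
several views (feature matrices) over one set of samples that share a
class partition, where each view carries its own amount of class signal
(a Gaussian mean shift on a subset of features, expressed in units of
the noise standard deviation), its own magnitude scale, and occasional
features that are missing for some samples. Class-conditional Gaussians
are the simplest structure under which a discriminant embedding is
Bayes-consistent, which keeps recovery experiments analytically
interpretable.

Missingness is injected at the feature level: a feature is hit with
probability ``missing_rate`` and then has one or more of its cells
blanked, mirroring measurements that fail for some subjects — the
downstream policy removes any feature missing in any subject, so the
hit rate is (approximately) the fraction of features dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureMatrix
from .roi_graph import RegionMeasureTable

__all__ = ["SimSpec", "make_multiview_cohort", "make_region_measures"]


@dataclass
class SimSpec:
    """Parameters of a synthetic multi-view cohort.

    ``effect_size`` is the between-class mean shift on informative
    features, in units of ``noise_sd``; ``scale`` multiplies each view to
    create heterogeneous magnitudes across views.
    """

    class_sizes: tuple[int, ...] = (30, 30)
    n_views: int = 2
    dims: tuple[int, ...] = (20, 20)
    effect_size: tuple[float, ...] = (4.0, 0.0)
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    scale: tuple[float, ...] = (1.0, 1.0)
    informative_frac: float = 0.3
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes))

    def __post_init__(self) -> None:
        if len(self.class_sizes) < 2 or any(s < 1 for s in self.class_sizes):
            raise ValueError("need >= 2 classes with positive sizes")
        for name in ("dims", "effect_size", "scale"):
            if len(getattr(self, name)) != self.n_views:
                raise ValueError(f"{name} must have one entry per view")
        if any(e < 0 for e in self.effect_size):
            raise ValueError("effect sizes must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def make_multiview_cohort(spec: SimSpec) -> tuple[list[FeatureMatrix], np.ndarray]:
    """Draw a multi-view cohort; reproducible from ``spec.seed``.

    Each view is class-conditional Gaussian noise with the view's mean
    shift applied to a random subset (``informative_frac``) of features
    for every class beyond the first, then multiplied by the view scale.
    Returns the views and the label vector (strings ``c0``, ``c1``, ...).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.concatenate(
        [np.full(sz, f"c{k}") for k, sz in enumerate(spec.class_sizes)]
    )
    class_index = np.concatenate(
        [np.full(sz, k) for k, sz in enumerate(spec.class_sizes)]
    )
    sample_ids = [f"s{i:04d}" for i in range(n)]

    views: list[FeatureMatrix] = []
    for v in range(spec.n_views):
        d = spec.dims[v]
        X = rng.normal(0.0, spec.noise_sd, size=(n, d))
        shift = spec.effect_size[v] * spec.noise_sd
        if shift > 0:
            n_inf = max(1, int(round(spec.informative_frac * d)))
            inf_cols = rng.choice(d, size=n_inf, replace=False)
            # classes spread along one direction: class k shifted by k * shift
            X[:, inf_cols] += np.outer(class_index, np.full(n_inf, shift))
        X *= spec.scale[v]

        mask = np.zeros((n, d), dtype=bool)
        if spec.missing_rate > 0:
            hit = rng.random(d) < spec.missing_rate
            for j in np.flatnonzero(hit):
                n_cells = 1 + rng.binomial(n - 1, 0.05)
                rows = rng.choice(n, size=n_cells, replace=False)
                mask[rows, j] = True
        X = X.copy()
        X[mask] = np.nan
        views.append(
            FeatureMatrix(X, sample_ids, [f"v{v}_f{j}" for j in range(d)], mask)
        )
    return views, labels


def make_region_measures(
    n_subjects: int,
    n_regions: int,
    class_shift: float = 0.0,
    seed: int = 0,
    class_sizes: tuple[int, int] | None = None,
    informative_frac: float = 0.3,
) -> tuple[RegionMeasureTable, np.ndarray]:
    """Synthetic per-region anatomical measures for two subject groups.

    Each region has its own baseline level; subjects in the second group
    are shifted by ``class_shift`` (in noise-sd units) on a random subset
    of regions. With ``class_shift`` 0 the groups are exchangeable.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if class_sizes is None:
        class_sizes = (n_subjects // 2, n_subjects - n_subjects // 2)
    if sum(class_sizes) != n_subjects:
        raise ValueError("class sizes must sum to n_subjects")
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(1.0, 5.0, size=n_regions)
    X = baseline + rng.normal(0.0, 1.0, size=(n_subjects, n_regions))
    labels = np.concatenate([np.full(class_sizes[0], "c0"), np.full(class_sizes[1], "c1")])
    if class_shift > 0:
        n_inf = max(1, int(round(informative_frac * n_regions)))
        cols = rng.choice(n_regions, size=n_inf, replace=False)
        X[np.ix_(labels == "c1", cols)] += class_shift
    table = RegionMeasureTable(
        X,
        [f"s{i:04d}" for i in range(n_subjects)],
        [f"r{j:03d}" for j in range(n_regions)],
        measure_name="synthetic",
    )
    return table, labels
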