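"""Synthetic layered datasets with planted cross-layer cluster structure.

Planted clusters are coherent in every layer: each cluster gets its own
numeric center per attribute (centers one `signal` step of `noise_sd`
apart) and a preferred category per nominal attribute.  Noise examples
draw each attribute independently from the pooled marginals, so they
carry no joint structure — the same property the shuffled negatives of
the EST construction exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AttributeSpec, DataLayer, LayeredDataset, NOMINAL, NUMERIC

#: Probability that a cluster member shows its cluster's preferred category.
PREFERRED_CATEGORY_P = 0.8


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one layered dataset.

    ``signal`` is the separation of adjacent cluster centers in units of
    ``noise_sd`` (the within-cluster spread); ``attrs_per_layer`` lists
    (numeric count, nominal count) per layer; noise examples get label 0.
    """

    cluster_sizes: tuple[int, ...] = (15, 15, 15)
    n_noise: int = 0
    attrs_per_layer: tuple[tuple[int, int], ...] = ((10, 0), (10, 0))
    signal: float = 4.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if not self.attrs_per_layer:
            raise ValueError("need at least one layer")
        if any(nn + nc < 1 for nn, nc in self.attrs_per_layer):
            raise ValueError("every layer needs at least one attribute")
        if self.signal < 0 or self.noise_sd <= 0:
            raise ValueError("signal must be >= 0 and noise_sd > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.cluster_sizes == () and self.n_noise == 0:
            raise ValueError("dataset would be empty")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_examples(self) -> int:
        return sum(self.cluster_sizes) + self.n_noise


def generate_layered(spec: SynthSpec) -> tuple[LayeredDataset, np.ndarray]:
    """Generate a layered dataset and its planted labels.

    Returns the dataset and an integer label vector: 1..K for members of
    the K planted clusters, 0 for noise examples.  The same seed always
    yields the same dataset.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_clusters
    n = spec.n_examples
    labels = np.concatenate(
        [np.full(s, c + 1) for c, s in enumerate(spec.cluster_sizes)]
        + [np.zeros(spec.n_noise, dtype=int)]
    ).astype(int) if n else np.zeros(0, dtype=int)
    ids = [f"e{j + 1:04d}" for j in range(n)]
    clustered = labels > 0

    layers = []
    for li, (n_num, n_nom) in enumerate(spec.attrs_per_layer):
        cols: dict[str, np.ndarray] = {}
        specs: list[AttributeSpec] = []
        for a in range(n_num):
            name = f"L{li + 1}_num{a + 1}"
            vals = np.empty(n, dtype=float)
            if k:
                # a random assignment of equally spaced centers per attribute
                centers = rng.permutation(k) * spec.signal * spec.noise_sd
                for c in range(k):
                    sel = labels == c + 1
                    vals[sel] = rng.normal(centers[c], spec.noise_sd, sel.sum())
                if spec.n_noise:
                    pool = vals[clustered]
                    vals[~clustered] = rng.choice(pool, size=spec.n_noise)
            else:
                vals[:] = rng.normal(0.0, spec.noise_sd, n)
            cols[name] = vals
            specs.append(AttributeSpec(name, NUMERIC))
        n_categories = max(3, k)
        categories = np.array([f"cat{j + 1}" for j in range(n_categories)], dtype=object)
        for a in range(n_nom):
            name = f"L{li + 1}_nom{a + 1}"
            vals = np.empty(n, dtype=object)
            if k:
                preferred = rng.permutation(n_categories)[:k]
                for c in range(k):
                    sel = np.flatnonzero(labels == c + 1)
                    pref = categories[preferred[c]]
                    others = categories[categories != pref]
                    pick = rng.random(len(sel)) < PREFERRED_CATEGORY_P
                    vals[sel[pick]] = pref
                    vals[sel[~pick]] = rng.choice(others, size=(~pick).sum())
                if spec.n_noise:
                    pool = vals[clustered]
                    vals[~clustered] = rng.choice(pool, size=spec.n_noise)
            else:
                vals[:] = rng.choice(categories, size=n)
            cols[name] = vals
            specs.append(AttributeSpec(name, NOMINAL))
        frame = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
        if spec.missing_rate:
            mask = rng.random(frame.shape) < spec.missing_rate
            frame = frame.mask(mask)
        layers.append(DataLayer(f"layer{li + 1}", frame, specs))
    return LayeredDataset(layers), labels
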