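"""Small built-in fixtures for documentation and tests.

The six-example similarity table is a hand-checkable miniature: two very
similar examples (ex2, ex5), three similar ones (ex1, ex3, ex4), and one
outlier (ex6).  The raw co-coverage counts have maximum 97 (a diagonal
entry), and the normalized table is given at two decimals.
"""

from __future__ import annotations

import numpy as np

from .est import CountMatrix, SimilarityTable

SIX_EXAMPLE_IDS = ["ex1", "ex2", "ex3", "ex4", "ex5", "ex6"]

_COUNTS = np.array(
    [
        [38, 0, 27, 28, 0, 7],
        [0, 97, 3, 1, 97, 3],
        [27, 3, 47, 16, 3, 1],
        [28, 1, 16, 45, 1, 4],
        [0, 97, 3, 1, 97, 3],
        [7, 3, 1, 4, 3, 39],
    ],
    dtype=np.int64,
)

_EST = np.array(
    [
        [0.39, 0.00, 0.28, 0.29, 0.00, 0.07],
        [0.00, 1.00, 0.03, 0.01, 1.00, 0.03],
        [0.28, 0.03, 0.48, 0.16, 0.03, 0.01],
        [0.29, 0.01, 0.16, 0.46, 0.01, 0.04],
        [0.00, 1.00, 0.03, 0.01, 1.00, 0.03],
        [0.07, 0.03, 0.01, 0.04, 0.03, 0.40],
    ]
)


def six_example_counts() -> CountMatrix:
    """Rule co-coverage counts of the six-example miniature."""
    return CountMatrix(_COUNTS.copy(), list(SIX_EXAMPLE_IDS))


def six_example_est() -> SimilarityTable:
    """The six-example similarity table, stated at two-decimal precision."""
    return SimilarityTable(_EST.copy(), list(SIX_EXAMPLE_IDS))
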