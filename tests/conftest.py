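"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
connected components by an explicit stack-based flood fill, sequential
ANOVA by nested design-matrix least squares, and the pooled t-test by
its textbook closed form.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps


# ---------------------------------------------------------------------------
# flood-fill labeling oracle


def flood_fill_partition(mask: np.ndarray, connectivity: int) -> frozenset:
    """Partition of foreground pixels into maximal connected sets."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    parts = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = []
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                parts.append(frozenset(comp))
    return frozenset(parts)


def labeling_partition(labels: np.ndarray) -> frozenset:
    """Partition induced by a label image (ignores label numbering)."""
    labels = np.asarray(labels)
    parts = {}
    for r, c in zip(*np.nonzero(labels)):
        parts.setdefault(int(labels[r, c]), []).append((int(r), int(c)))
    return frozenset(frozenset(p) for p in parts.values())


# ---------------------------------------------------------------------------
# sequential-ANOVA design-matrix oracle


def _dummies(values) -> np.ndarray:
    levels = sorted(set(values))
    cols = [np.asarray([v == lv for v in values], dtype=float) for lv in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def sequential_anova_oracle(day, genotype, y) -> dict:
    """Type I (sequential) two-way ANOVA by nested least squares.

    Fits the nested models 1, 1+day, 1+day+genotype, full, and takes
    each term's sum of squares as the drop in residual sum of squares.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    d = _dummies(day)
    g = _dummies(genotype)
    inter = np.column_stack(
        [d[:, i] * g[:, j] for i in range(d.shape[1]) for j in range(g.shape[1])]
    ) if d.shape[1] and g.shape[1] else np.empty((n, 0))
    ones = np.ones((n, 1))
    blocks = [ones, np.hstack([ones, d]), np.hstack([ones, d, g]),
              np.hstack([ones, d, g, inter])]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), int(np.linalg.matrix_rank(X))

    rs = [rss(X) for X in blocks]
    terms = {}
    names = ["day", "genotype", "day:genotype"]
    df_res = n - rs[-1][1]
    ms_res = rs[-1][0] / df_res
    for k, name in enumerate(names):
        ss = rs[k][0] - rs[k + 1][0]
        df = rs[k + 1][1] - rs[k][1]
        F = (ss / df) / ms_res
        terms[name] = {"df": df, "ss": ss, "F": F,
                       "p": float(sps.f.sf(F, df, df_res))}
    terms["residual"] = {"df": df_res, "ss": rs[-1][0]}
    return terms


def pooled_t_oracle(x1, x2) -> tuple:
    """Textbook pooled-variance two-sample t statistic and two-sided p."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    t = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def simple_leaf():
    """One noise-free synthetic cotyledon with a single tip lesion."""
    from cotyquant import synthetic as syn

    leaf = syn.LeafSpec()
    record, truth = syn.make_leaf_image(
        leaf, [syn.Lesion((0.0, 0.7), 22.0)], noise_sd=0.0, seed=1
    )
    return leaf, record, truth
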