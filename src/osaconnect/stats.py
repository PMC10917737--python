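"""Nonparametric group comparison and per-node t-maps.

The Mann-Whitney-Wilcoxon test is implemented from the U statistic: midranks,
exact two-sided p by counting rank assignments for small tie-free samples,
otherwise a normal approximation with tie-corrected variance and continuity
correction.  Node-degree contrasts use Welch's two-sample t per node, a
deliberately separate parametric map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "mann_whitney",
    "exact_u_counts",
    "compare_bands",
    "NodeTMap",
    "degree_t_map",
    "correlate_t_with_network",
    "benjamini_hochberg",
]

ALPHA = 0.05  # conventional significance level

#: largest n1*n2 for which the exact null distribution is enumerated
EXACT_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided Mann-Whitney-Wilcoxon test."""

    statistic_U: float
    statistic_z: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        if not 0 <= self.statistic_U <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")
        if not 0 <= self.p_two_sided <= 1:
            raise ValueError("p outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_two_sided < ALPHA


def exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments yielding each U value, U = 0..n1*n2.

    Uses the standard recurrence f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u)
    over the choice of which group supplies the largest remaining rank.
    Counts fit exactly in float64 for n1*n2 <= 400 (max C(40, 20) < 2^53).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("sample sizes must be non-negative")
    u_max = n1 * n2
    f = np.zeros((n1 + 1, n2 + 1, u_max + 1))
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            f[a, b] = f[a, b - 1]
            f[a, b, b:] += f[a - 1, b, : u_max + 1 - b]
    return f[n1, n2]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon test of two independent samples.

    ``statistic_U`` is U of the first sample.  The exact method (enumeration
    of the null distribution) is used for tie-free data with
    ``n1 * n2 <= EXACT_LIMIT``; otherwise the normal approximation with
    tie-corrected variance and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    mean = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)

    if not has_ties and n1 * n2 <= EXACT_LIMIT:
        counts = exact_u_counts(n1, n2)
        total = counts.sum()
        u_min = int(round(min(u1, u2)))
        p = min(1.0, 2.0 * float(counts[: u_min + 1].sum()) / total)
        z = (u1 - mean) / np.sqrt(var) if var > 0 else 0.0
        return TestResult(u1, float(z), p, n1, n2, "exact")

    if var <= 0:  # all observations identical
        return TestResult(u1, 0.0, 1.0, n1, n2, "normal_approx")
    z_abs = max(0.0, abs(u1 - mean) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z_abs)))
    z = float(np.sign(u1 - mean) * z_abs)
    return TestResult(u1, z, p, n1, n2, "normal_approx")


def compare_bands(
    band_values: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, TestResult]:
    """One Mann-Whitney test per band on per-subject scalar summaries.

    ``band_values`` maps band name to the (group-1, group-2) value vectors —
    e.g. each subject's mean absolute wavelet coefficient, or mean positive
    correlation, in that band.
    """
    return {band: mann_whitney(g1, g2) for band, (g1, g2) in band_values.items()}


@dataclass
class NodeTMap:
    """Welch two-sample t statistic per node; NaN where undefined."""

    labels: list[str]
    t: np.ndarray
    df: np.ndarray

    def defined(self) -> np.ndarray:
        return np.isfinite(self.t)


def degree_t_map(
    degrees_group1: np.ndarray,
    degrees_group2: np.ndarray,
    labels: Sequence[str] | None = None,
) -> NodeTMap:
    """Welch t statistic of group-1 minus group-2 node degree, per node.

    Inputs are subjects x nodes matrices.  Nodes where both groups have zero
    variance get NaN (t undefined), reported as missing rather than raising.
    """
    d1 = np.asarray(degrees_group1, dtype=float)
    d2 = np.asarray(degrees_group2, dtype=float)
    if d1.ndim != 2 or d2.ndim != 2 or d1.shape[1] != d2.shape[1]:
        raise ValueError("inputs must be subjects x nodes with equal node counts")
    if d1.shape[0] < 2 or d2.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    n1, n2 = d1.shape[0], d2.shape[0]
    m1, m2 = d1.mean(axis=0), d2.mean(axis=0)
    v1, v2 = d1.var(axis=0, ddof=1), d2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (m1 - m2) / np.sqrt(se2), np.nan)
        df = np.where(
            se2 > 0,
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)),
            np.nan,
        )
    if labels is None:
        labels = [f"node{i}" for i in range(d1.shape[1])]
    return NodeTMap(labels=list(labels), t=t, df=df)


def correlate_t_with_network(
    t_map: NodeTMap, network_map: Sequence[float]
) -> float:
    """Pearson correlation of the node t-map with a reference network map."""
    from .connectivity import pearson

    ref = np.asarray(network_map, dtype=float)
    if ref.shape != t_map.t.shape:
        raise ValueError("network map length must match the t-map")
    mask = t_map.defined() & np.isfinite(ref)
    if mask.sum() < 3:
        raise ValueError("need at least 3 nodes with a defined t statistic")
    return pearson(t_map.t[mask], ref[mask])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional switch, default off)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
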