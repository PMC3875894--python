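"""Statistical battery for loop occurrence and loop counts.

Two questions are asked of the pathway groups (metabolic, non-metabolic,
random):

* do groups differ in the *frequency* of pathways showing at least one
  loop?  — omnibus Pearson chi-square on the groups x {L, NL} contingency
  matrix (no continuity correction), followed by pairwise 2x2 chi-square
  tests *with* Yates continuity correction and Holm step-down adjustment of
  the pairwise p-values;
* do groups differ in the *number* of loops per pathway? — Lilliefors
  normality check first (loop counts are far from Normal), then
  Kruskal-Wallis rank ANOVA and pairwise two-sided Mann-Whitney U tests,
  again Holm-adjusted.

Chi-square, Kruskal-Wallis and Mann-Whitney are delegated to scipy; Holm to
statsmodels.  The Lilliefors statistic is computed here, with the null
distribution of D obtained by seeded Monte-Carlo simulation (default) or by
the statsmodels table approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUP_ORDER = ("metabolic", "non_metabolic", "random")


@dataclass(frozen=True)
class ContingencyMatrix:
    """Ordered group labels with per-group counts of pathways with (L) and
    without (NL) at least one loop."""

    groups: tuple[str, ...]
    loops: tuple[int, ...]  # L column
    no_loops: tuple[int, ...]  # NL column

    def __post_init__(self) -> None:
        if not (len(self.groups) == len(self.loops) == len(self.no_loops)):
            raise ValueError("groups, loops and no_loops must align")
        if any(v < 0 for v in self.loops + self.no_loops):
            raise ValueError("counts must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.loops, self.no_loops]).astype(int)

    def pair(self, i: int, j: int) -> "ContingencyMatrix":
        return ContingencyMatrix(
            groups=(self.groups[i], self.groups[j]),
            loops=(self.loops[i], self.loops[j]),
            no_loops=(self.no_loops[i], self.no_loops[j]),
        )

    def render(self) -> str:
        """Counts with row percentages and column percentages, one group
        per line, mirroring the 'count (row %), [col %]' table style."""
        arr = self.to_array().astype(float)
        col_tot = arr.sum(axis=0)
        lines = ["group\tL\tNL\ttotal"]
        for g, row in zip(self.groups, arr):
            tot = row.sum()
            cells = []
            for j, v in enumerate(row):
                rp = 100 * v / tot if tot else 0.0
                cp = 100 * v / col_tot[j] if col_tot[j] else 0.0
                cells.append(f"{int(v)} ({rp:.1f}), [{cp:.1f}]")
            lines.append(f"{g}\t" + "\t".join(cells) + f"\t{int(tot)}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    continuity_corrected: bool
    p_adjusted: float | None = None


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    df: int | None = None
    method: str = ""
    p_adjusted: float | None = None


@dataclass(frozen=True)
class GroupSamples:
    """Per-group vectors of per-pathway loop counts."""

    samples: dict[str, np.ndarray] = field(default_factory=dict)

    @staticmethod
    def from_results(results) -> "GroupSamples":
        by_group: dict[str, list[int]] = {}
        for r in results:
            by_group.setdefault(r.group, []).append(r.n_loops)
        order = [g for g in GROUP_ORDER if g in by_group] + sorted(
            set(by_group) - set(GROUP_ORDER)
        )
        return GroupSamples(
            samples={g: np.asarray(by_group[g], dtype=float) for g in order}
        )

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.samples.values()))


def build_contingency(results) -> ContingencyMatrix:
    """Tabulate PathwayResults into the groups x {L, NL} matrix, group order
    fixed as (metabolic, non_metabolic, random); absent groups dropped."""
    if not results:
        raise ValueError("no pathway results to tabulate")
    counts: dict[str, list[int]] = {}
    for r in results:
        row = counts.setdefault(r.group, [0, 0])
        row[0 if r.has_loop else 1] += 1
    order = [g for g in GROUP_ORDER if g in counts] + sorted(
        set(counts) - set(GROUP_ORDER)
    )
    return ContingencyMatrix(
        groups=tuple(order),
        loops=tuple(counts[g][0] for g in order),
        no_loops=tuple(counts[g][1] for g in order),
    )


def chi_square(
    matrix: ContingencyMatrix, continuity_corrected: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on the contingency matrix; Yates correction only
    meaningful (and only applied by scipy) for 2x2 tables."""
    arr = matrix.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency matrix has a zero marginal")
    res = sps.chi2_contingency(arr, correction=continuity_corrected)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        continuity_corrected=continuity_corrected and arr.shape == (2, 2),
    )


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment: the i-th smallest of m p-values is
    multiplied by (m - i + 1), running maxima enforce monotonicity, values
    cap at 1; returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="holm")[1]]


def pairwise_chi_square_holm(
    matrix: ContingencyMatrix,
) -> dict[tuple[str, str], ChiSquareResult]:
    """Continuity-corrected 2x2 chi-square for every unordered group pair,
    p-values Holm-adjusted jointly across the pairs."""
    k = len(matrix.groups)
    if k < 2:
        raise ValueError("need at least 2 groups for pairwise tests")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = [chi_square(matrix.pair(i, j), continuity_corrected=True) for i, j in pairs]
    adjusted = holm_adjust([r.p_value for r in raw])
    return {
        (matrix.groups[i], matrix.groups[j]): ChiSquareResult(
            statistic=r.statistic,
            df=r.df,
            p_value=r.p_value,
            continuity_corrected=True,
            p_adjusted=adj,
        )
        for (i, j), r, adj in zip(pairs, raw, adjusted)
    }


def _lilliefors_d(x: np.ndarray) -> float:
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max((ecdf_hi - cdf).max(), (cdf - ecdf_lo).max()))


def lilliefors(
    values,
    method: str = "mc",
    n_reps: int = 100_000,
    seed: int = 0,
) -> RankTestResult:
    """Lilliefors test of Normality (Kolmogorov-Smirnov with estimated mean
    and standard deviation).

    ``method='mc'`` (default) draws the null distribution of D by
    simulating ``n_reps`` standard-normal samples of the same size with a
    seeded generator; ``method='approx'`` uses the statsmodels table/
    approximation p-value.  Requires n >= 4 and a non-constant sample.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 4:
        raise ValueError("Lilliefors test requires n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("sample is constant; normality test undefined")
    d = _lilliefors_d(x)
    if method == "mc":
        rng = np.random.default_rng(seed)
        n = x.size
        # vectorized null: simulate in blocks to bound memory
        block = max(1, min(n_reps, int(2e7) // n))
        exceed = 0
        done = 0
        while done < n_reps:
            b = min(block, n_reps - done)
            sims = rng.standard_normal((b, n))
            sims = np.sort(sims, axis=1)
            means = sims.mean(axis=1, keepdims=True)
            sds = sims.std(axis=1, ddof=1, keepdims=True)
            cdf = sps.norm.cdf((sims - means) / sds)
            hi = (np.arange(1, n + 1) / n - cdf).max(axis=1)
            lo = (cdf - np.arange(0, n) / n).max(axis=1)
            exceed += int((np.maximum(hi, lo) >= d).sum())
            done += b
        p = (exceed + 1) / (n_reps + 1)
        return RankTestResult(statistic=d, p_value=float(p), method="lilliefors-mc")
    if method == "approx":
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        _, p = sm_lilliefors(x, dist="norm", pvalmethod="table")
        return RankTestResult(statistic=d, p_value=float(p), method="lilliefors-approx")
    raise ValueError(f"unknown Lilliefors p-value method {method!r}")


def kruskal_wallis(samples: GroupSamples) -> RankTestResult:
    """Kruskal-Wallis rank ANOVA (tie-corrected H, chi-square p)."""
    groups = list(samples.samples.values())
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return RankTestResult(
            statistic=0.0, p_value=1.0, df=len(groups) - 1, method="kruskal-wallis"
        )
    h, p = sps.kruskal(*groups)
    return RankTestResult(
        statistic=float(h), p_value=float(p), df=len(groups) - 1,
        method="kruskal-wallis",
    )


def mann_whitney(
    x, y, exact_threshold: int = 8
) -> RankTestResult:
    """Two-sided Mann-Whitney U.  Exact enumeration when both samples are
    small and tie-free, normal approximation with tie correction otherwise;
    the method used is recorded in the result."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    use_exact = (len(x) <= exact_threshold and len(y) <= exact_threshold and not ties)
    method = "exact" if use_exact else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        statistic=float(u), p_value=float(min(p, 1.0)), method=f"mann-whitney-{method}"
    )


def pairwise_mann_whitney_holm(
    samples: GroupSamples,
) -> dict[tuple[str, str], RankTestResult]:
    """Two-sided Mann-Whitney U for every unordered group pair with Holm
    adjustment across the pairs."""
    names = list(samples.samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    raw = [
        mann_whitney(samples.samples[a], samples.samples[b]) for a, b in pairs
    ]
    adjusted = holm_adjust([r.p_value for r in raw])
    return {
        pair: RankTestResult(
            statistic=r.statistic,
            p_value=r.p_value,
            method=r.method,
            p_adjusted=adj,
        )
        for pair, r, adj in zip(pairs, raw, adjusted)
    }
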