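"""Inter-rater agreement statistics with image-level bootstrap CIs.

The statistical protocol for comparing two graders:

* continuous per-image scores (percent hypoperfusion, nonperfusion area):
  descriptives (mean, SD, Tukey five-number summary), Bland-Altman bias and
  95% limits of agreement, and Kendall's tau-b rank correlation;
* categorical per-cell grades: cross-tabulation and Cohen's (weighted)
  kappa over the ordered categories perfused < hypoperfused < nonperfused
  (optionally including ungradable as a fourth, unordered category);
* confidence intervals by the image-level percentile bootstrap: whole
  images are resampled with replacement so the within-image correlation of
  cells is respected.

Degenerate inputs (constant rankings, a single occupied category) raise
typed errors instead of returning NaN, so a bootstrap distribution can
never silently absorb undefined replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BootstrapFailureError,
    DegenerateStatisticError,
    UndefinedStatisticError,
)

__all__ = [
    "Descriptives",
    "descriptives",
    "BlandAltmanResult",
    "bland_altman",
    "TauResult",
    "kendall_tau_b",
    "cross_tabulate",
    "KappaResult",
    "cohen_kappa",
    "BootstrapCI",
    "bootstrap_ci",
]


# ---------------------------------------------------------------------------
# Descriptives


@dataclass(frozen=True)
class Descriptives:
    """Mean, SD and Tukey five-number summary of a sample."""

    n: int
    mean: float
    sd: float
    minimum: float
    lower_hinge: float
    median: float
    upper_hinge: float
    maximum: float


def descriptives(values: Sequence[float]) -> Descriptives:
    """Summary statistics with Tukey hinges.

    Hinges are medians of the lower/upper halves of the sorted sample, each
    half including the overall median when n is odd (Tukey's convention),
    e.g. 1..9 has hinges 3 and 7.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n == 0:
        raise ValueError("descriptives requires at least one value")
    half = (n + 1) // 2
    return Descriptives(
        n=int(n),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if n > 1 else 0.0,
        minimum=float(x[0]),
        lower_hinge=float(np.median(x[:half])),
        median=float(np.median(x)),
        upper_hinge=float(np.median(x[n - half :])),
        maximum=float(x[-1]),
    )


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    """Paired-difference bias and 95% limits of agreement.

    Differences are grader 1 minus grader 2, so a negative bias means
    grader 2 measured more of the quantity. ``plot_data`` carries the
    (pair mean, difference) points ordered by pair mean.
    """

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    plot_data: pd.DataFrame


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman analysis of paired per-image scores (x = grader 1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bland_altman requires two equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    diff = x - y
    mean = (x + y) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    order = np.argsort(mean, kind="stable")
    plot = pd.DataFrame({"mean": mean[order], "difference": diff[order]})
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=int(x.size),
        plot_data=plot,
    )


# ---------------------------------------------------------------------------
# Kendall tau-b


@dataclass(frozen=True)
class TauResult:
    tau: float
    variant: str
    n: int


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TauResult:
    """Kendall's tau-b (tie-corrected) rank correlation of paired scores."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("kendall_tau_b requires two equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("kendall_tau_b requires at least 2 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("tau-b undefined: a ranking is constant")
    tau = stats.kendalltau(x, y, variant="b").statistic
    if not np.isfinite(tau):
        raise UndefinedStatisticError("tau-b undefined for this input")
    return TauResult(tau=float(tau), variant="tau-b", n=int(x.size))


# ---------------------------------------------------------------------------
# Cross-tabulation and Cohen's kappa


def cross_tabulate(
    cats_1: Sequence, cats_2: Sequence, categories: Sequence
) -> pd.DataFrame:
    """K x K contingency table; cell (i, j) counts grader-1 = i, grader-2 = j.

    Margins (row/column sums) reproduce each grader's category counts.
    Values outside ``categories`` raise an error.
    """
    categories = list(categories)
    lut = {c: i for i, c in enumerate(categories)}
    k = len(categories)

    def encode(seq, who):
        try:
            return np.array([lut[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"grader {who} category {exc.args[0]!r} not in category list")

    a = encode(cats_1, 1)
    b = encode(cats_2, 2)
    if a.shape != b.shape:
        raise ValueError("category sequences must be paired (equal length)")
    table = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    labels = [getattr(c, "value", c) for c in categories]
    return pd.DataFrame(table, index=labels, columns=labels)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weight_scheme: str
    categories: tuple
    n: int


def _weight_matrix(k: int, scheme: str) -> np.ndarray:
    i = np.arange(k)
    d = np.abs(i[:, None] - i[None, :]).astype(np.float64)
    if scheme == "none":
        return (d > 0).astype(np.float64)
    if scheme == "linear":
        return d / (k - 1)
    if scheme == "quadratic":
        return (d / (k - 1)) ** 2
    raise ValueError(f"unknown weight scheme {scheme!r} (none|linear|quadratic)")


def cohen_kappa(table, weights: str = "linear") -> KappaResult:
    """Cohen's kappa with disagreement weights on an ordered K x K table.

    ``kappa = 1 - sum(w * p_obs) / sum(w * p_exp)`` with ``w[i, j]``
    proportional to ``|i - j|`` (linear), its square (quadratic), or the 0/1
    disagreement indicator (none, the unweighted kappa). A table whose mass
    sits in a single category has zero expected disagreement and raises
    :class:`DegenerateStatisticError`.
    """
    if isinstance(table, pd.DataFrame):
        categories = tuple(table.index)
        t = table.to_numpy(dtype=np.float64)
    else:
        t = np.asarray(table, dtype=np.float64)
        categories = tuple(range(t.shape[0]))
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise ValueError("table must be square with K >= 2 categories")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    n = t.sum()
    if n < 1:
        raise ValueError("table must contain at least one observation")
    p = t / n
    w = _weight_matrix(t.shape[0], weights)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = float((w * np.outer(row, col)).sum())
    if expected <= 0.0:
        raise DegenerateStatisticError(
            "expected disagreement is zero (single occupied category); kappa undefined"
        )
    kappa = 1.0 - float((w * p).sum()) / expected
    return KappaResult(
        kappa=kappa, weight_scheme=weights, categories=categories, n=int(round(n))
    )


# ---------------------------------------------------------------------------
# Image-level bootstrap


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap CI from resampling whole images (clusters)."""

    level: float
    low: float
    high: float
    point: float
    replicates: int
    n_failed: int
    seed: int
    resampling_unit: str = "image"

    @property
    def excludes_point(self) -> bool:
        """Percentile CIs can rarely exclude the point estimate; flagged, not an error."""
        return not (self.low <= self.point <= self.high)


def bootstrap_ci(
    items: Sequence,
    statistic: Callable[[Sequence], float],
    B: int = 2000,
    seed: Optional[int] = None,
    level: float = 0.95,
    max_failure_fraction: float = 0.10,
) -> BootstrapCI:
    """Image-level percentile bootstrap of ``statistic``.

    ``items`` holds one entry per image (all cells of an image move
    together); each replicate draws ``len(items)`` images with replacement
    and recomputes ``statistic`` on the resampled list. Replicates on which
    the statistic is undefined (typed degeneracy errors) are dropped; more
    than ``max_failure_fraction`` of them aborts with an error naming the
    failure mode. Fully reproducible for a fixed ``seed``.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("bootstrap requires at least 2 images")
    if B < 100:
        raise ValueError("bootstrap requires B >= 100 replicates")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap CIs")
    point = float(statistic(items))
    rng = np.random.default_rng(seed)
    n = len(items)
    values = []
    failures: dict[str, int] = {}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = [items[i] for i in idx]
        try:
            values.append(float(statistic(sample)))
        except (UndefinedStatisticError, DegenerateStatisticError) as exc:
            key = type(exc).__name__
            failures[key] = failures.get(key, 0) + 1
    n_failed = sum(failures.values())
    if n_failed > max_failure_fraction * B:
        detail = ", ".join(f"{k}: {v}" for k, v in sorted(failures.items()))
        raise BootstrapFailureError(
            f"statistic undefined on {n_failed}/{B} replicates ({detail})"
        )
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        level=level,
        low=float(low),
        high=float(high),
        point=point,
        replicates=B,
        n_failed=n_failed,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Full two-grader report


def _pair_categories(pair, region, include_ungradable: bool):
    """Paired category arrays for one image, filtered to a region."""
    from .grading import Category, GradeLevel, category_of, region_rings

    rings = region_rings(region, pair.grid)
    sub = pair.table[pair.table["ring"].isin(rings)]
    c1 = [category_of(g) for g in sub["grade_1"]]
    c2 = [category_of(g) for g in sub["grade_2"]]
    if not include_ungradable:
        keep = [
            a is not Category.UNGRADABLE and b is not Category.UNGRADABLE
            for a, b in zip(c1, c2)
        ]
        c1 = [a for a, k in zip(c1, keep) if k]
        c2 = [b for b, k in zip(c2, keep) if k]
    return c1, c2


def _pooled_kappa(pairs, region, include_ungradable: bool, weights: str) -> KappaResult:
    from .grading import ORDERED_CATEGORIES, Category

    cats = list(ORDERED_CATEGORIES) + (
        [Category.UNGRADABLE] if include_ungradable else []
    )
    c1, c2 = [], []
    for p in pairs:
        a, b = _pair_categories(p, region, include_ungradable)
        c1.extend(a)
        c2.extend(b)
    if not c1:
        raise UndefinedStatisticError("no gradable cell pairs in region")
    return cohen_kappa(cross_tabulate(c1, c2, cats), weights=weights)


@dataclass
class AgreementReport:
    """Agreement statistics for one region of a paired two-grader study.

    The cell-level kappa is reported in two labeled variants: over the three
    ordinal categories with the chosen disagreement weights after dropping
    cells either grader found ungradable, and over four categories
    (ungradable included, unweighted) — the protocols differ in whether an
    ungradable call counts as a grading decision.
    """

    region: object
    n_images: int
    crosstab_excluding: pd.DataFrame
    crosstab_including: pd.DataFrame
    kappa_excluding: KappaResult
    kappa_excluding_ci: Optional[BootstrapCI]
    kappa_including: KappaResult
    kappa_including_ci: Optional[BootstrapCI]
    tau: TauResult
    bland_altman: BlandAltmanResult
    per_image_scores: pd.DataFrame  # image_id, score_1, score_2 (% hypoperfusion)


def agreement_report(
    pairs,
    region,
    weights: str = "linear",
    B: int = 2000,
    seed: Optional[int] = None,
) -> AgreementReport:
    """Run the full agreement protocol on per-image paired sessions.

    Per-image continuous scores are each grader's percent hypoperfusion over
    the region's gradable cells; they feed Bland-Altman and Kendall tau-b.
    Cell-level categories feed cross-tabulation and Cohen's kappa, with
    image-level bootstrap CIs when ``seed`` is given (B replicates).
    """
    from .grading import (
        GRADABLE_LEVELS,
        GradeLevel,
        ORDERED_CATEGORIES,
        Category,
        score_of,
    )

    pairs = list(pairs)
    if not pairs:
        raise ValueError("agreement_report requires at least one paired image")

    def pct_hypo(grades) -> float:
        scores = [score_of(g) for g in grades if g is not GradeLevel.UNGRADABLE]
        return 100.0 * (1.0 - float(np.mean(scores))) if scores else np.nan

    from .grading import region_rings

    rows = []
    for p in pairs:
        rings = region_rings(region, p.grid)
        sub = p.table[p.table["ring"].isin(rings)]
        rows.append(
            {
                "image_id": p.image_id,
                "score_1": pct_hypo(sub["grade_1"]),
                "score_2": pct_hypo(sub["grade_2"]),
            }
        )
    scores = pd.DataFrame(rows)
    ok = scores.dropna()
    tau = kendall_tau_b(ok["score_1"], ok["score_2"])
    ba = bland_altman(ok["score_1"], ok["score_2"])

    cats3 = list(ORDERED_CATEGORIES)
    cats4 = cats3 + [Category.UNGRADABLE]
    excl = [_pair_categories(p, region, include_ungradable=False) for p in pairs]
    incl = [_pair_categories(p, region, include_ungradable=True) for p in pairs]
    ct_excl = cross_tabulate(
        [c for a, _ in excl for c in a], [c for _, b in excl for c in b], cats3
    )
    ct_incl = cross_tabulate(
        [c for a, _ in incl for c in a], [c for _, b in incl for c in b], cats4
    )
    kappa_excl = cohen_kappa(ct_excl, weights=weights)
    kappa_incl = cohen_kappa(ct_incl, weights="none")

    ci_excl = ci_incl = None
    if seed is not None:
        ci_excl = bootstrap_ci(
            pairs,
            lambda sample: _pooled_kappa(sample, region, False, weights).kappa,
            B=B,
            seed=seed,
        )
        ci_incl = bootstrap_ci(
            pairs,
            lambda sample: _pooled_kappa(sample, region, True, "none").kappa,
            B=B,
            seed=seed + 1,
        )
    return AgreementReport(
        region=region,
        n_images=len(pairs),
        crosstab_excluding=ct_excl,
        crosstab_including=ct_incl,
        kappa_excluding=kappa_excl,
        kappa_excluding_ci=ci_excl,
        kappa_including=kappa_incl,
        kappa_including_ci=ci_incl,
        tau=tau,
        bland_altman=ba,
        per_image_scores=scores,
    )
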