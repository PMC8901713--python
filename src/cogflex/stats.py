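"""Permutation-based paired inference and effect sizes.

All condition comparisons in the pipeline funnel through the same two
primitives: a two-tailed paired-samples permutation t-test (sign-flipping
of paired differences) and McNemar's chi-squared test for paired
presence/absence designs.  Effect sizes are Cohen's d (d_z variant,
``mean(diff)/sd(diff)``) for the permutation test and phi
(``sqrt(chi2/n)``) for McNemar.

The permutation p-value uses the add-one convention
``(1 + #{|t_perm| >= |t_obs|}) / (n_iter + 1)`` so that p is never
exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "ContingencyCounts",
    "permutation_paired_ttest",
    "cohens_d_paired",
    "mcnemar_test",
    "phi_from_chi2",
    "compare_per_item",
    "paired_sample_from_long",
]


@dataclass(frozen=True)
class PairedSample:
    """Two within-unit measurement vectors paired by ``unit_ids``.

    Units may be participants, removed network nodes, or resampling
    iteration indices -- anything that provides the pairing of the
    two-condition within-subject design.
    """

    values_a: np.ndarray
    values_b: np.ndarray
    unit_ids: Sequence

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("paired values must be 1-D vectors")
        if not (len(a) == len(b) == len(self.unit_ids)):
            raise ValueError(
                f"length mismatch: a={len(a)}, b={len(b)}, ids={len(self.unit_ids)}"
            )
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("paired samples must not contain missing values")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    def swapped(self) -> "PairedSample":
        return PairedSample(self.values_b, self.values_a, self.unit_ids)


@dataclass
class TestResult:
    """Statistic, p-value and effect size of one paired comparison."""

    test: str
    statistic: float
    p_value: float
    effect_d: Optional[float] = None
    effect_phi: Optional[float] = None
    n_iterations: int = 0
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.effect_phi is not None and not (0.0 <= self.effect_phi <= 1.0):
            raise ValueError(f"phi out of [0, 1]: {self.effect_phi}")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, default=float)


@dataclass(frozen=True)
class ContingencyCounts:
    """Discordant/concordant counts of a paired presence/absence design.

    The unique-response universe is built from responses present in at
    least one condition, so there is no both-absent cell: ``n_total`` is
    the sum of the three remaining cells.
    """

    discordant_a_only: int
    discordant_b_only: int
    concordant_both: int

    def __post_init__(self):
        for name in ("discordant_a_only", "discordant_b_only", "concordant_both"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.discordant_a_only + self.discordant_b_only + self.concordant_both


def _t_statistic(diff: np.ndarray) -> float:
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return 0.0 if diff.mean() == 0.0 else np.inf * np.sign(diff.mean())
    return float(diff.mean() / (sd / np.sqrt(n)))


def permutation_paired_ttest(
    sample: PairedSample, n_iter: int = 10_000, seed: int = 0
) -> TestResult:
    """Two-tailed paired-samples permutation t-test by sign flipping.

    The observed paired t is computed from the differences
    ``d_i = a_i - b_i``; the null distribution flips the sign of each
    difference independently per iteration.  If all differences are
    exactly zero the comparison is degenerate and ``p = 1, t = 0`` is
    returned so that resampling loops never abort.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    diff = sample.differences
    if diff.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(diff == 0.0):
        return TestResult("permutation_paired_t", 0.0, 1.0,
                          effect_d=None, n_iterations=n_iter, seed=seed)

    t_obs = _t_statistic(diff)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_iter, diff.size)) * 2 - 1
    perm = signs * diff[None, :]
    means = perm.mean(axis=1)
    sds = perm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / (sds / np.sqrt(diff.size))
    # zero-sd iterations (all flipped diffs equal): t is +-inf unless the
    # mean is also zero, which cannot happen here since diff != 0 somewhere
    zero_sd = sds == 0.0
    if zero_sd.any():
        t_perm[zero_sd] = np.sign(means[zero_sd]) * np.inf
    k = int(np.count_nonzero(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + k) / (n_iter + 1)
    try:
        d = cohens_d_paired(sample)
    except ValueError:
        d = None
    return TestResult("permutation_paired_t", t_obs, p,
                      effect_d=d, n_iterations=n_iter, seed=seed)


def cohens_d_paired(sample: PairedSample) -> float:
    """Cohen's d for paired data, d_z = mean(diff) / sd(diff) (n-1 sd).

    The d_av variant (difference of means over the mean of the two
    condition standard deviations) is available via ``variant='av'``
    on :func:`cohens_d`.
    """
    diff = sample.differences
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: Cohen's d undefined")
    return float(diff.mean() / sd)


def cohens_d(sample: PairedSample, variant: str = "z") -> float:
    if variant == "z":
        return cohens_d_paired(sample)
    if variant == "av":
        sd_a = sample.values_a.std(ddof=1)
        sd_b = sample.values_b.std(ddof=1)
        denom = (sd_a + sd_b) / 2.0
        if denom == 0.0:
            raise ValueError("zero-variance conditions: Cohen's d undefined")
        return float((sample.values_a.mean() - sample.values_b.mean()) / denom)
    raise ValueError(f"unknown Cohen's d variant: {variant!r}")


def mcnemar_test(counts: ContingencyCounts, continuity: bool = True) -> TestResult:
    """McNemar's chi-squared test on the discordant cells.

    With the continuity correction (default),
    ``chi2 = (max(|b - c| - 1, 0))^2 / (b + c)``; the correction is
    clamped at zero so b == c gives chi2 = 0.  phi = sqrt(chi2 / n) with
    n the total of the three paired cells.
    """
    b = counts.discordant_a_only
    c = counts.discordant_b_only
    if b + c == 0:
        raise ValueError("both discordant counts are zero: McNemar undefined")
    dev = abs(b - c) - 1.0 if continuity else abs(b - c)
    dev = max(dev, 0.0)
    chi2 = dev * dev / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    phi = phi_from_chi2(chi2, counts.n_total) if counts.n_total > 0 else None
    return TestResult("mcnemar", float(chi2), p, effect_phi=phi,
                      extra={"continuity": continuity, "n": counts.n_total})


def phi_from_chi2(chi2: float, n: int) -> float:
    """Phi effect size, sqrt(chi2 / n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    return float(np.sqrt(chi2 / n))


def compare_per_item(
    samples: Sequence[PairedSample], n_iter: int = 10_000, seed: int = 0
) -> list[TestResult]:
    """One permutation t-test per item, raw p-values (no adjustment)."""
    results = []
    for i, s in enumerate(samples):
        # independent stream per item so item order does not couple tests
        results.append(permutation_paired_ttest(s, n_iter=n_iter, seed=seed + i))
    return results


def paired_sample_from_long(
    df: pd.DataFrame,
    unit_col: str = "unit_id",
    condition_col: str = "condition",
    value_col: str = "value",
    conditions: Optional[tuple[str, str]] = None,
) -> PairedSample:
    """Pivot a long (unit, condition, value) table into a PairedSample."""
    wide = df.pivot_table(index=unit_col, columns=condition_col,
                          values=value_col, aggfunc="mean")
    if conditions is None:
        if wide.shape[1] != 2:
            raise ValueError(
                f"expected exactly 2 conditions, found {list(wide.columns)}"
            )
        conditions = tuple(wide.columns)
    wide = wide[list(conditions)].dropna()
    return PairedSample(wide[conditions[0]].to_numpy(),
                        wide[conditions[1]].to_numpy(),
                        list(wide.index))
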