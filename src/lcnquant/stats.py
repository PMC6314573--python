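"""Pipeline-uncertainty reports and group statistics.

Two concerns live here. First, quantifying the processing pipeline against
a reference skeleton: per-metric signed relative errors, reported as
nearest-integer percentages, with and without the lacuna mask. Second, the
group comparison used in ex vivo studies: one-way ANOVA over per-animal
network metrics, the two-sample normal-approximation sample-size formula,
and a Monte-Carlo oracle that verifies the achieved power of a proposed
group size by simulating Welch t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .skeleton import NetworkMetrics

#: metrics compared against a reference skeleton, in reporting order
ERROR_METRICS = (
    ("n_canaliculi", "canaliculi_number"),
    ("cav_tv_pct", "canalicular_density_pct"),
    ("n_connections", "connections_number"),
    ("junction_voxel_fraction_pct", "connection_density_pct"),
)


def relative_error(test: float, reference: float) -> int:
    """Signed percent error round(100·(test − reference)/reference).

    Rounding is half-away-from-zero so that printed uncertainty tables can
    be reproduced exactly.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    x = 100.0 * (test - reference) / reference
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def compare_skeletons(test: NetworkMetrics, reference: NetworkMetrics,
                      variant: str = "vesselness") -> pd.DataFrame:
    """Error report: one row per metric with reference, test and % error."""
    if not np.isclose(test.tv_um3, reference.tv_um3):
        raise ValueError(
            f"TV mismatch: test {test.tv_um3} vs reference {reference.tv_um3} µm³"
        )
    rows = []
    for attr, name in ERROR_METRICS:
        ref = getattr(reference, attr)
        val = getattr(test, attr)
        rows.append(
            {
                "variant": variant,
                "metric": name,
                "reference": ref,
                "test": val,
                "error_pct": relative_error(val, ref) if ref != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def oneway_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA on raw group samples."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least two observations")
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError("degenerate input: zero variance within every group")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def anova_oneway(records: pd.DataFrame, metric: str, group_col: str = "group",
                 quadrants: list[str] | None = None,
                 quadrant_col: str = "quadrant") -> dict:
    """One-way ANOVA of a network metric across groups.

    ``quadrants`` restricts the analysis to an anatomical region pool
    (e.g. ["anterior", "posterior"]); by default all records are used.
    """
    df = records
    if quadrants is not None:
        df = df[df[quadrant_col].isin(quadrants)]
    groups = [g[metric].to_numpy() for _, g in df.groupby(group_col)]
    f, p = oneway_f(groups)
    return {"metric": metric, "F": f, "p": p,
            "groups": sorted(df[group_col].unique().tolist()),
            "n_per_group": [len(g) for g in groups]}


@dataclass
class PowerCalcParams:
    """Inputs for the two-sample sample-size computation.

    The effect is either an absolute difference ``delta`` or a fraction of
    ``baseline_mean`` (e.g. 0.10 for a 10% change). ``sd1``/``sd2`` are the
    group standard deviations; significance is two-sided.
    """

    sd1: float
    sd2: float
    delta: float | None = None
    effect_fraction: float | None = None
    baseline_mean: float | None = None
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.delta is None:
            if self.effect_fraction is None or self.baseline_mean is None:
                raise ValueError("give delta, or effect_fraction with baseline_mean")
            self.delta = self.effect_fraction * self.baseline_mean
        if self.delta <= 0:
            raise ValueError("effect size delta must be positive")


def required_group_size(p: PowerCalcParams) -> int:
    """Per-group n for a two-sample comparison, normal approximation.

    n = ceil[ (z_{1−α/2} + z_{power})² (σ₁² + σ₂²) / δ² ]

    Unequal variances are allowed; with both SDs equal this reduces to the
    familiar 2σ² form.
    """
    z_alpha = sps.norm.ppf(1.0 - p.alpha / 2.0)
    z_power = sps.norm.ppf(p.power)
    n = (z_alpha + z_power) ** 2 * (p.sd1 ** 2 + p.sd2 ** 2) / p.delta ** 2
    return max(1, math.ceil(n))


def empirical_power(n: int, mean1: float, mean2: float, sd1: float, sd2: float,
                    alpha: float = 0.05, reps: int = 5000, seed: int = 0) -> float:
    """Monte-Carlo achieved power of a Welch two-sample t-test.

    Simulates ``reps`` experiments with ``n`` normal observations per group
    and returns the fraction rejecting at level ``alpha`` (two-sided).
    """
    if n < 2:
        raise ValueError("need n >= 2 per group")
    if reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    a = rng.normal(mean1, sd1, size=(reps, n))
    b = rng.normal(mean2, sd2, size=(reps, n))
    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    return float(np.mean(res.pvalue < alpha))
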