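"""Mixture-proportion estimation from per-marker f4 ratios.

For an admixed ancestry X formed from sources proxied by B (proportion
alpha) and C (proportion 1 - alpha), with A a sibling of B and O an
outgroup, the classical f4-ratio identity gives

    alpha = f4(A, O; X, C) / f4(A, O; B, C),

estimated per marker as

    r_m = [(pA - pO)(pX - pC)] / [(pA - pO)(pB - pC)]   (full mode)
        = (pX - pC) / (pB - pC)                          (simplified mode),

the two agreeing at every marker where pA != pO.  Summed over markers,
numerator and denominator are each asymptotically normal and strongly
dependent, so the aggregate ratio — and equally each per-marker ratio — is
a ratio of dependent normals with a Cauchy-like (heavy-tailed) law that
has no finite mean or variance.  A ratio-of-sums or mean-of-ratios
estimator is therefore inconsistent; this module instead summarizes the
per-marker ratios by their sample median (the location parameter) and
interquartile range (twice the scale parameter for a Cauchy law).

Markers with a (numerically) zero denominator are dropped and counted;
dropping is data, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fstats import f4_per_marker
from .simulate import Demography, sample_counts, simulate_frequencies
from .tables import FrequencyTable

__all__ = [
    "F4RatioConfig",
    "F4RatioResult",
    "ratio_per_marker",
    "estimate_mixture",
    "compare_mean_vs_median",
    "weighted_mixture_weights",
]

#: below this absolute denominator a per-marker ratio is treated as
#: undefined and dropped (frequencies are O(1), so absolute ~ relative)
DENOM_TOL = 1e-12


@dataclass(frozen=True)
class F4RatioConfig:
    """Labels for an f4-ratio estimate of the B-proportion in admixed X.

    ``sibling_a`` and ``outgroup`` may be omitted in simplified mode, which
    assumes pX = alpha pB + (1 - alpha) pC directly.
    """

    admixed: str
    parent_proxy_b: str
    parent_proxy_c: str
    sibling_a: str | None = None
    outgroup: str | None = None

    def __post_init__(self) -> None:
        labels = [x for x in (
            self.admixed, self.parent_proxy_b, self.parent_proxy_c,
            self.sibling_a, self.outgroup,
        ) if x is not None]
        if len(set(labels)) != len(labels):
            raise ValueError("configuration labels must be distinct")

    def require_full(self) -> None:
        if self.sibling_a is None or self.outgroup is None:
            raise ValueError("full mode needs sibling_a and outgroup labels")


@dataclass
class F4RatioResult:
    """Median/IQR summary of per-marker mixture-proportion ratios."""

    config: F4RatioConfig
    mode: str
    per_marker_ratios: np.ndarray = field(repr=False)
    n_dropped: int
    median_alpha: float
    iqr: float

    @property
    def n_used(self) -> int:
        return len(self.per_marker_ratios)

    @property
    def scale(self) -> float:
        """Cauchy scale implied by the IQR (half the IQR)."""
        return self.iqr / 2.0

    @property
    def pct_b(self) -> float:
        return 100.0 * self.median_alpha

    @property
    def pct_c(self) -> float:
        return 100.0 - self.pct_b

    def display_percentages(self) -> tuple[float, float]:
        """Percentages rounded to one decimal, complement-consistent.

        The complement is taken after rounding so the displayed pair sums
        to 100.0 exactly, matching the reporting convention.
        """
        pb = round(self.pct_b, 1)
        return pb, round(100.0 - pb, 1)


def ratio_per_marker(
    config: F4RatioConfig,
    table: FrequencyTable,
    mode: str = "full",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker mixture-proportion ratios and a usability mask.

    Returns ``(ratios, used)`` where ``ratios`` has one entry per marker
    (NaN where dropped) and ``used`` flags markers with a nonzero
    denominator.
    """
    if mode not in ("full", "simplified"):
        raise ValueError("mode must be 'full' or 'simplified'")
    pX = table.column(config.admixed)
    pB = table.column(config.parent_proxy_b)
    pC = table.column(config.parent_proxy_c)
    if mode == "full":
        config.require_full()
        pA = table.column(config.sibling_a)
        pO = table.column(config.outgroup)
        num = f4_per_marker(pA, pO, pX, pC)
        den = f4_per_marker(pA, pO, pB, pC)
    else:
        num = pX - pC
        den = pB - pC
    used = np.abs(den) > DENOM_TOL
    ratios = np.full(len(num), np.nan)
    ratios[used] = num[used] / den[used]
    return ratios, used


def estimate_mixture(
    config: F4RatioConfig,
    table: FrequencyTable,
    mode: str = "full",
) -> F4RatioResult:
    """Median/IQR mixture-proportion estimate over usable markers.

    The median uses the midpoint convention for even counts; quartiles use
    linear interpolation (quartile conventions vary — this one is fixed
    and documented).
    """
    ratios, used = ratio_per_marker(config, table, mode)
    r = ratios[used]
    if len(r) == 0:
        raise ValueError("no usable markers: every denominator is zero")
    q25, q75 = np.percentile(r, [25.0, 75.0])
    return F4RatioResult(
        config=config,
        mode=mode,
        per_marker_ratios=r,
        n_dropped=int((~used).sum()),
        median_alpha=float(np.median(r)),
        iqr=float(q75 - q25),
    )


def mixture_report(results: list[F4RatioResult]) -> pd.DataFrame:
    """Tabular report: one row per configuration, reporting-precision columns."""
    rows = []
    for res in results:
        pb, pc = res.display_percentages()
        rows.append(
            {
                "admixed": res.config.admixed,
                "proxy_b": res.config.parent_proxy_b,
                "proxy_c": res.config.parent_proxy_c,
                "mode": res.mode,
                "n_used": res.n_used,
                "n_dropped": res.n_dropped,
                "median": res.median_alpha,
                "iqr": res.iqr,
                "pct_b": pb,
                "pct_c": pc,
            }
        )
    return pd.DataFrame(rows)


def compare_mean_vs_median(
    config: F4RatioConfig,
    demography: Demography,
    n_markers: int,
    n_replicates: int,
    seed: int,
    counts: float | None = 200.0,
    mode: str = "full",
) -> pd.DataFrame:
    """Replicate comparison of three mixture-proportion estimators.

    For each replicate simulation the ratio is estimated by (a) the
    ratio-of-sums (sum of f4 numerators over sum of denominators), (b) the
    mean of per-marker ratios, and (c) the median of per-marker ratios.
    The returned table reports each estimator's across-replicate median and
    IQR.  Because per-marker ratios are Cauchy-like, the mean's replicate
    spread does not shrink with more markers while the median's does —
    the practical reason this pipeline reports medians.
    """
    rng = np.random.default_rng(seed)
    estimates: dict[str, list[float]] = {
        "ratio_of_sums": [],
        "per_marker_mean": [],
        "per_marker_median": [],
    }
    for _ in range(n_replicates):
        sim_seed = int(rng.integers(2**31 - 1))
        table = simulate_frequencies(demography, n_markers, sim_seed, counts=counts)
        if counts is not None:
            table = sample_counts(table, int(rng.integers(2**31 - 1)))
        ratios, used = ratio_per_marker(config, table, mode)
        r = ratios[used]
        if mode == "full":
            pA, pO = table.column(config.sibling_a), table.column(config.outgroup)
            num = f4_per_marker(pA, pO, table.column(config.admixed),
                                table.column(config.parent_proxy_c))
            den = f4_per_marker(pA, pO, table.column(config.parent_proxy_b),
                                table.column(config.parent_proxy_c))
        else:
            num = table.column(config.admixed) - table.column(config.parent_proxy_c)
            den = table.column(config.parent_proxy_b) - table.column(config.parent_proxy_c)
        estimates["ratio_of_sums"].append(float(num.sum() / den.sum()))
        estimates["per_marker_mean"].append(float(np.mean(r)))
        estimates["per_marker_median"].append(float(np.median(r)))
    rows = []
    for name, vals in estimates.items():
        arr = np.asarray(vals)
        q25, q75 = np.percentile(arr, [25.0, 75.0])
        rows.append(
            {
                "estimator": name,
                "replicate_median": float(np.median(arr)),
                "replicate_iqr": float(q75 - q25),
                "n_replicates": n_replicates,
                "n_markers": n_markers,
            }
        )
    return pd.DataFrame(rows)


def weighted_mixture_weights(weights, frequencies) -> tuple[float, float]:
    """Combine migration-edge weights across tree topologies.

    ``weights`` are per-topology mixture percentages for the same edge;
    ``frequencies`` are how often each topology was observed.  Returns the
    frequency-weighted mean and its complement to 100, both full precision
    (round to one decimal for display).
    """
    w = np.asarray(weights, float)
    f = np.asarray(frequencies, float)
    if w.shape != f.shape or w.ndim != 1 or len(w) == 0:
        raise ValueError("weights and frequencies must be equal-length 1-D sequences")
    if np.any(f < 0):
        raise ValueError("tree frequencies must be nonnegative")
    if f.sum() == 0:
        raise ValueError("tree frequencies must not all be zero")
    combined = float((f * w).sum() / f.sum())
    return combined, 100.0 - combined
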