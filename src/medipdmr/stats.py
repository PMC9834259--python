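"""Per-window differential-coverage statistics.

The statistical core is the classic count-based two-group workflow for
enrichment sequencing: trimmed-mean-of-M-values (TMM) scaling factors,
a single common negative-binomial dispersion estimated by conditional
maximum likelihood, and the two-sided NB conditional exact test on
per-window group totals, followed by Benjamini–Hochberg adjustment.

The NB is parameterized by mean mu and dispersion phi with
``variance = mu + phi * mu**2`` so phi = 0 recovers the Poisson.  For a
group of n exchangeable samples with common per-sample mean, the group
total is NB with shape ``r = n / phi``; conditioning the case total on
the pooled total makes the mean cancel and leaves a beta-binomial
(Dirichlet-multinomial) distribution — the exact test sums the
probabilities of all outcomes no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .windows import CountMatrix

__all__ = [
    "NormalizationFactors",
    "DispersionEstimate",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_test",
    "bh_fdr",
    "nb_conditional_pvalue",
    "resolve_groups",
]

# Relative tolerance when comparing outcome probabilities in the
# minimum-likelihood two-sided rule; protects mathematically tied
# outcomes (the symmetric design) from float noise.
_TIE_RTOL = 1e-10


class NormalizationError(ValueError):
    pass


class PValueError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM scaling factors, geometric mean 1."""

    samples: tuple[str, ...]
    factors: np.ndarray  # positive, geometric mean 1

    def effective_library_sizes(self, library_sizes: np.ndarray) -> np.ndarray:
        return np.asarray(library_sizes, dtype=float) * self.factors


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion phi (variance = mu + phi mu^2)."""

    phi: float
    log_likelihood: float = float("nan")
    method: str = "qCML"

    def __post_init__(self):
        if not np.isfinite(self.phi) or self.phi < 0:
            raise ValueError(f"dispersion must be finite and >= 0, got {self.phi}")


# --------------------------------------------------------------------- TMM


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the across-sample mean of those fractions.  For each
    sample, log ratios M and log abundances A are computed over windows
    with positive counts in both the sample and the reference; the top
    and bottom ``trim_m`` of M and ``trim_a`` of A are discarded, and the
    factor is two to the precision-weighted mean of the surviving M
    values.  Factors are rescaled to geometric mean one.
    """
    if matrix.n_samples < 2:
        raise NormalizationError("TMM needs at least two samples")
    counts = matrix.counts.astype(float)
    libs = matrix.library_sizes.astype(float)
    if (libs <= 0).any():
        raise NormalizationError("all library sizes must be positive")

    frac75 = np.array(
        [np.quantile(counts[:, j], 0.75) / libs[j] for j in range(matrix.n_samples)]
    )
    ref = int(np.argmin(np.abs(frac75 - frac75.mean())))

    factors = np.ones(matrix.n_samples)
    y_r, n_r = counts[:, ref], libs[ref]
    for j in range(matrix.n_samples):
        if j == ref:
            continue
        y_s, n_s = counts[:, j], libs[j]
        ok = (y_s > 0) & (y_r > 0)
        if not ok.any():
            raise NormalizationError(
                f"no window with positive counts in both {matrix.samples[j]} "
                f"and the reference {matrix.samples[ref]}"
            )
        ys, yr = y_s[ok], y_r[ok]
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
        # delta-method variance of M for weighting; floored so the
        # degenerate y == N case keeps finite weights
        v = np.maximum((n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr), 1e-12)

        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            factors[j] = 1.0
            continue
        w = 1.0 / v[keep]
        f = np.sum(w * m[keep]) / np.sum(w)
        factors[j] = 2.0 ** f if np.isfinite(f) else 1.0

    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(samples=tuple(matrix.samples), factors=factors)


# -------------------------------------------------------- group resolution


def resolve_groups(
    matrix: CountMatrix,
    case_group: str | None = None,
    control_group: str | None = None,
) -> tuple[str, str]:
    """Determine the (case, control) pair of group labels.

    If not given explicitly, the design must contain exactly two labels;
    a label equal to "control" (case-insensitive) is taken as the control,
    otherwise the alphabetically second label is.
    """
    labels = sorted(set(matrix.design.values()))
    if case_group is not None and control_group is not None:
        for g in (case_group, control_group):
            if g not in labels:
                raise ValueError(f"group {g!r} not present in design {labels}")
        return case_group, control_group
    if len(labels) != 2:
        raise ValueError(
            f"design has groups {labels}; pass case_group/control_group explicitly"
        )
    lowered = [g.lower() for g in labels]
    if "control" in lowered:
        control = labels[lowered.index("control")]
        case = labels[1 - lowered.index("control")]
    else:
        case, control = labels[0], labels[1]
    return case, control


def _pseudo_counts(
    matrix: CountMatrix, factors: NormalizationFactors
) -> tuple[np.ndarray, float]:
    """Counts rescaled to the geometric-mean effective library size."""
    eff = factors.effective_library_sizes(matrix.library_sizes)
    common = float(np.exp(np.mean(np.log(eff))))
    return matrix.counts * (common / eff), common


# --------------------------------------------------- common dispersion (qCML)


def estimate_common_dispersion(
    matrix: CountMatrix,
    factors: NormalizationFactors | None = None,
    case_group: str | None = None,
    control_group: str | None = None,
    bounds: tuple[float, float] = (1e-6, 5.0),
) -> DispersionEstimate:
    """Common dispersion by maximizing the conditional NB log-likelihood.

    Counts are scaled to a common effective library size; within each
    group the conditional distribution of the counts given their total
    is Dirichlet-multinomial with per-sample shape ``1/phi``, whose
    log-likelihood is summed over windows and groups and maximized over
    ``phi`` on ``bounds`` (log-scale golden-section search).  Falls back
    to a method-of-moments estimate with a warning if the optimizer
    fails.
    """
    if factors is None:
        factors = tmm_factors(matrix)
    case, control = resolve_groups(matrix, case_group, control_group)
    pseudo, _ = _pseudo_counts(matrix, factors)
    group_cols = [matrix.group_columns(case), matrix.group_columns(control)]
    if any(len(c) == 0 for c in group_cols):
        raise ValueError("both groups must be nonempty")

    blocks = [pseudo[:, cols] for cols in group_cols]

    def neg_cll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        r = 1.0 / phi
        total = 0.0
        for y in blocks:
            n = y.shape[1]
            s = y.sum(axis=1)
            ll = (
                gammaln(y + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(s + n * r)
            )
            total += ll.sum()
        return -total

    try:
        res = minimize_scalar(
            neg_cll,
            bounds=(np.log(bounds[0]), np.log(bounds[1])),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError(res.message)
        phi = float(np.exp(res.x))
        return DispersionEstimate(phi=phi, log_likelihood=-res.fun, method="qCML")
    except Exception:  # pragma: no cover - defensive fallback
        import warnings

        warnings.warn("qCML optimization failed; using method-of-moments dispersion")
        mu = pseudo.mean(axis=1)
        var = pseudo.var(axis=1, ddof=1)
        ok = mu > 0
        phi_mm = np.clip(np.median((var[ok] - mu[ok]) / mu[ok] ** 2), 0.0, bounds[1])
        return DispersionEstimate(phi=float(phi_mm), method="moments")


# ---------------------------------------------------------- exact NB test


def _conditional_logpmf(s: int, r1: float, r2: float) -> np.ndarray:
    """Log pmf of the case total given pooled total s, NB shapes r1, r2.

    With phi -> 0 (r -> inf) callers should use the binomial limit
    instead; here both shapes are finite.
    """
    o = np.arange(s + 1)
    lp = (
        gammaln(o + r1)
        - gammaln(o + 1)
        + gammaln(s - o + r2)
        - gammaln(s - o + 1)
    )
    return lp - logsumexp(lp)


def _binomial_logpmf(s: int, p1: float) -> np.ndarray:
    o = np.arange(s + 1)
    return (
        gammaln(s + 1)
        - gammaln(o + 1)
        - gammaln(s - o + 1)
        + o * np.log(p1)
        + (s - o) * np.log1p(-p1)
    )


def nb_conditional_pvalue(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p for case total y1 vs control total y2.

    Group totals are modelled as NB with means proportional to the group
    sizes (library sizes already equalized) and dispersion ``phi / n`` for
    a group of n samples, i.e. shape ``n / phi``.  The p value is the sum
    of conditional probabilities of all outcomes whose probability does
    not exceed the observed outcome's (minimum-likelihood two-sided rule,
    with a tiny relative tolerance so symmetric ties are kept together).
    """
    if min(n1, n2) < 1:
        raise ValueError("both groups must be nonempty")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    s = y1 + y2
    if s == 0:
        return 1.0
    if phi == 0:
        logpmf = _binomial_logpmf(s, n1 / (n1 + n2))
    else:
        logpmf = _conditional_logpmf(s, n1 / phi, n2 / phi)
    pmf = np.exp(logpmf)
    observed = pmf[y1]
    p = float(pmf[pmf <= observed * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def _pvalues_for_totals(
    y1: np.ndarray, s: np.ndarray, n1: int, n2: int, phi: float
) -> np.ndarray:
    """Vectorized exact p values, sharing work across windows with equal s."""
    p_out = np.ones(len(s), dtype=float)
    order = np.argsort(s)
    i = 0
    while i < len(order):
        j = i
        si = int(s[order[i]])
        while j < len(order) and int(s[order[j]]) == si:
            j += 1
        idx = order[i:j]
        if si > 0:
            if phi == 0:
                logpmf = _binomial_logpmf(si, n1 / (n1 + n2))
            else:
                logpmf = _conditional_logpmf(si, n1 / phi, n2 / phi)
            pmf = np.exp(logpmf)
            sort_idx = np.argsort(pmf)
            sorted_pmf = pmf[sort_idx]
            cum = np.cumsum(sorted_pmf)
            obs = pmf[y1[idx].astype(int)]
            pos = np.searchsorted(sorted_pmf, obs * (1.0 + _TIE_RTOL), side="right")
            p_out[idx] = np.minimum(cum[pos - 1], 1.0)
        i = j
    return p_out


def exact_test(
    matrix: CountMatrix,
    factors: NormalizationFactors | None = None,
    phi: float | DispersionEstimate | None = None,
    case_group: str | None = None,
    control_group: str | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-window two-group NB exact test.

    Returns a DataFrame with one row per window: ``chromosome, start,
    end, index, mean_case, mean_control, log2fc, p_value, fdr``.  A
    positive ``log2fc`` means higher methylation signal (MeDIP coverage)
    in the case group.  Counts are first scaled to a common effective
    library size; each window's rounded group totals feed the conditional
    test.  ``fdr`` is the Benjamini–Hochberg adjustment across all tested
    windows.
    """
    if factors is None:
        factors = tmm_factors(matrix)
    if phi is None:
        phi = estimate_common_dispersion(matrix, factors, case_group, control_group)
    if isinstance(phi, DispersionEstimate):
        phi = phi.phi
    case, control = resolve_groups(matrix, case_group, control_group)
    cols1 = matrix.group_columns(case)
    cols2 = matrix.group_columns(control)
    if len(cols1) == 0 or len(cols2) == 0:
        raise ValueError("both groups must be nonempty")
    pseudo, _ = _pseudo_counts(matrix, factors)
    y1 = np.rint(pseudo[:, cols1].sum(axis=1)).astype(np.int64)
    y2 = np.rint(pseudo[:, cols2].sum(axis=1)).astype(np.int64)
    s = y1 + y2
    p = _pvalues_for_totals(y1, s, len(cols1), len(cols2), phi)

    mean_case = pseudo[:, cols1].mean(axis=1)
    mean_control = pseudo[:, cols2].mean(axis=1)
    log2fc = np.log2((mean_case + prior_count) / (mean_control + prior_count))
    log2fc[s == 0] = 0.0

    df = pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in matrix.windows],
            "start": [w.start for w in matrix.windows],
            "end": [w.end for w in matrix.windows],
            "index": [w.index for w in matrix.windows],
            "mean_case": mean_case,
            "mean_control": mean_control,
            "log2fc": log2fc,
            "p_value": p,
        }
    )
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise PValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "start", "end", "p_value", "log2fc"}
    missing = required - set(df.columns)
    if missing:
        raise PValueError(f"results TSV missing columns: {sorted(missing)}")
    return df
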