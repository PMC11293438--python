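"""Downstream assay analyses: PEG-precipitation fits and amylase activity.

PEG precipitation measures relative solubility: soluble protein remaining in
the supernatant is read out over a ramp of PEG concentrations (% w/v),
normalized to the 0%-PEG wells, and fitted with a decreasing 3-parameter
logistic

    f(c) = a / (1 + exp(k · (c − PEG₁/₂)))

whose midpoint PEG₁/₂ is the relative-solubility proxy (higher = more
soluble).  The 95% confidence interval on PEG₁/₂ comes from a percentile
bootstrap that resamples wells with replacement within each concentration.

Colorimetric amylase activity follows the kit formula

    activity = (B × D) / (T_rxn × V)   [nmole·min⁻¹·ml⁻¹]

with B the nitrophenol generated (nmole) over the reaction window, D the
dilution factor, T_rxn the reaction time (min) and V the sample volume (ml);
one enzyme unit U = 1 nmole/min, and specific activity is U per mg protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit


class FitError(RuntimeError):
    """Raised when a sigmoid fit fails or too many bootstrap refits fail."""


@dataclass(frozen=True)
class PegAssay:
    """Well-level PEG-precipitation readings.

    ``peg`` and ``value`` are parallel arrays, one entry per well; ``value``
    is the soluble-fraction readout (raw absorbance-derived units before
    normalization, dimensionless fraction after).
    """

    peg: np.ndarray
    value: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.peg.shape != self.value.shape or self.peg.ndim != 1:
            raise ValueError("peg and value must be parallel 1-D arrays")
        if len(self.peg) == 0:
            raise ValueError("empty assay")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite well values")
        if 0.0 not in np.unique(self.peg):
            raise ValueError("assay must include a 0% PEG condition")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PegAssay":
        """Read a plate CSV with columns ``peg_percent, replicate, value``."""
        df = pd.read_csv(path)
        required = {"peg_percent", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: need columns {sorted(required)}")
        return cls(
            peg=df["peg_percent"].to_numpy(dtype=float),
            value=df["value"].to_numpy(dtype=float),
        )

    def concentrations(self) -> np.ndarray:
        return np.unique(self.peg)

    def wells_at(self, conc: float) -> np.ndarray:
        return self.value[self.peg == conc]


@dataclass(frozen=True)
class SigmoidFit:
    """A fitted solubility curve: midpoint PEG₁/₂, slope k, asymptote a."""

    peg_half: float
    k: float
    a: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    n_failed: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.ci_high:
                raise ValueError("CI bounds out of order")


@dataclass(frozen=True)
class ActivityMeasurement:
    """Inputs to the colorimetric activity formula (kit conventions)."""

    nmole_nitrophenol: float  # B
    dilution: float  # D
    reaction_time_min: float  # T_rxn
    sample_volume_ml: float  # V
    protein_mg_per_ml: float | None = None

    def __post_init__(self) -> None:
        if self.reaction_time_min <= 0 or self.sample_volume_ml <= 0:
            raise ValueError("reaction time and sample volume must be > 0")


def logistic(c: np.ndarray, a: float, k: float, peg_half: float) -> np.ndarray:
    """Decreasing 3-parameter logistic used for all PEG fits."""
    return a / (1.0 + np.exp(k * (c - peg_half)))


def normalize_peg(assay: PegAssay) -> PegAssay:
    """Divide every well by the mean of the 0%-PEG wells.

    After normalization the 0% wells average exactly 1.  A non-positive
    0%-mean is an error (nothing soluble at baseline means the curve is
    uninterpretable).
    """
    baseline = float(np.mean(assay.wells_at(0.0)))
    if baseline <= 0:
        raise ValueError(f"mean of 0% PEG wells must be > 0 (got {baseline:g})")
    return PegAssay(peg=assay.peg, value=assay.value / baseline, normalized=True)


def _initial_guess(peg: np.ndarray, frac: np.ndarray) -> tuple[float, float, float]:
    """Documented initialization: a = 1, PEG₁/₂ = concentration whose mean
    fraction is nearest 0.5, k = 1."""
    concs = np.unique(peg)
    means = np.array([np.mean(frac[peg == c]) for c in concs])
    half = float(concs[int(np.argmin(np.abs(means - 0.5)))])
    return 1.0, 1.0, half


def fit_sigmoid(assay: PegAssay, max_extrapolation: float = 10.0) -> SigmoidFit:
    """Least-squares logistic fit to the well-level normalized fractions.

    Fits a, k and PEG₁/₂ simultaneously.  The fit is ``flagged`` (not an
    exception) when the optimizer fails, the curve is not decreasing
    (k ≤ 0), or PEG₁/₂ falls outside [0, max concentration +
    ``max_extrapolation``] — such a midpoint is extrapolation, not
    measurement.
    """
    if not assay.normalized:
        assay = normalize_peg(assay)
    if len(assay.concentrations()) < 4:
        raise ValueError("need >= 4 distinct PEG concentrations to fit")
    a0, k0, h0 = _initial_guess(assay.peg, assay.value)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                logistic,
                assay.peg,
                assay.value,
                p0=(a0, k0, h0),
                maxfev=10000,
            )
    except RuntimeError:
        return SigmoidFit(peg_half=float("nan"), k=float("nan"), a=float("nan"), flagged=True)
    a, k, peg_half = (float(v) for v in popt)
    flagged = (
        not np.isfinite(peg_half)
        or k <= 0
        or not 0.0 <= peg_half <= float(assay.peg.max()) + max_extrapolation
    )
    return SigmoidFit(peg_half=peg_half, k=k, a=a, flagged=flagged)


def bootstrap_ci(
    assay: PegAssay,
    n_boot: int = 1000,
    seed: int | None = None,
    max_failure_rate: float = 0.2,
) -> SigmoidFit:
    """Percentile-bootstrap CI95 on PEG₁/₂.

    Wells are resampled with replacement *within* each concentration, the
    curve is refitted, and the 2.5/97.5 percentiles of the refitted PEG₁/₂
    values form the interval.  Failed or flagged refits are dropped and
    counted; more than ``max_failure_rate`` of them is an error.  The result
    is deterministic for a given seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    if not assay.normalized:
        assay = normalize_peg(assay)
    base = fit_sigmoid(assay)
    if base.flagged:
        raise FitError("base fit is flagged; no meaningful CI")

    rng = np.random.default_rng(seed)
    concs = assay.concentrations()
    groups = {c: np.nonzero(assay.peg == c)[0] for c in concs}
    estimates: list[float] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(groups[c], size=len(groups[c]), replace=True) for c in concs]
        )
        sample = PegAssay(peg=assay.peg[idx], value=assay.value[idx], normalized=True)
        fit = fit_sigmoid(sample)
        if fit.flagged:
            n_failed += 1
        else:
            estimates.append(fit.peg_half)
    if n_failed > max_failure_rate * n_boot:
        raise FitError(
            f"{n_failed}/{n_boot} bootstrap refits failed "
            f"({100 * n_failed / n_boot:.1f}% > {100 * max_failure_rate:.0f}%)"
        )
    lo, hi = np.percentile(np.array(estimates), [2.5, 97.5])
    # clamp so the point estimate always lies inside its own interval
    return replace(
        base,
        ci_low=float(min(lo, base.peg_half)),
        ci_high=float(max(hi, base.peg_half)),
        n_boot=n_boot,
        seed=seed,
        n_failed=n_failed,
    )


def amylase_activity(m: ActivityMeasurement) -> tuple[float, float | None]:
    """Activity in nmole·min⁻¹·ml⁻¹ and, when possible, specific activity U/mg.

    activity = (B × D) / (T_rxn × V); specific activity divides by the
    protein mass concentration (mg/ml) when provided, else returns None for
    that element.
    """
    activity = (m.nmole_nitrophenol * m.dilution) / (
        m.reaction_time_min * m.sample_volume_ml
    )
    if m.protein_mg_per_ml is None:
        return activity, None
    if m.protein_mg_per_ml <= 0:
        raise ValueError("protein concentration must be > 0")
    return activity, activity / m.protein_mg_per_ml


def specific_activity(m: ActivityMeasurement) -> float:
    """U/mg; raises when the protein concentration is absent."""
    _, per_mg = amylase_activity(m)
    if per_mg is None:
        raise ValueError("protein_mg_per_ml required for specific activity")
    return per_mg


def fit_standard_curve(a405: np.ndarray, nmole: np.ndarray) -> tuple[float, float]:
    """Linear nitrophenol standard curve: returns (slope, intercept) mapping
    A405 → nmole."""
    a405 = np.asarray(a405, dtype=float)
    nmole = np.asarray(nmole, dtype=float)
    slope, intercept = np.polyfit(a405, nmole, 1)
    return float(slope), float(intercept)


def activity_table(path: str | Path) -> pd.DataFrame:
    """Read an activity CSV (columns B, D, T_rxn, V[, protein_mg_per_ml]) and
    append computed activity and U/mg columns."""
    df = pd.read_csv(path)
    required = {"B", "D", "T_rxn", "V"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    activities = []
    per_mg = []
    for _, row in df.iterrows():
        m = ActivityMeasurement(
            nmole_nitrophenol=float(row["B"]),
            dilution=float(row["D"]),
            reaction_time_min=float(row["T_rxn"]),
            sample_volume_ml=float(row["V"]),
            protein_mg_per_ml=(
                float(row["protein_mg_per_ml"])
                if "protein_mg_per_ml" in df.columns and pd.notna(row["protein_mg_per_ml"])
                else None
            ),
        )
        act, spec = amylase_activity(m)
        activities.append(act)
        per_mg.append(spec)
    out = df.copy()
    out["activity_nmole_min_ml"] = activities
    out["specific_activity_U_mg"] = per_mg
    return out
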