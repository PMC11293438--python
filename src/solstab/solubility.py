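"""Per-residue solubility profiles and the global intrinsic score.

A propensity scale assigns each amino acid a dimensionless intrinsic
solubility propensity s(a) (zero mean over the 20 residues; charged D/E/K/R
strictly above the aliphatic/aromatic hydrophobics V/I/L/F/W).  For a
sequence, the raw profile s_i = s(residue_i) is smoothed with a running mean
of odd window w (shrinking at the termini), giving p_i; the global intrinsic
score is S = mean(p).  Mutations with ΔS > 0 are predicted solubilizing.

The structure-corrected profile gates each position by its solvent exposure
and averages the smoothed profile over the spatial neighbourhood:

    q_i = exposure_i · Σ_{j ∈ N(i) ∪ {i}} p_j e^{−d_ij/λ} / Σ e^{−d_ij/λ}

so buried residues contribute little to site identification.  The default
scale is a documented composite (see data/propensity_default.tsv); the
pipeline depends only on score orderings, and any two-column residue/value
file can be substituted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from solstab.sequence_msa import AMINO_ACIDS, SequenceRecord
from solstab.structure import ExposureTable, StructureModel, residue_centers

CHARGED = frozenset("DEKR")
HYDROPHOBIC = frozenset("VILFW")


@dataclass(frozen=True)
class PropensityScale:
    """Per-amino-acid intrinsic solubility propensities, zero mean, labelled."""

    values: dict[str, float]
    provenance: str

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError("scale must cover exactly the 20 amino acids")
        mean = sum(self.values.values()) / 20.0
        if abs(mean) > 1e-9:
            raise ValueError(f"scale must have zero mean (got {mean:.3g})")
        lo_charged = min(self.values[a] for a in CHARGED)
        hi_phobic = max(self.values[a] for a in HYDROPHOBIC)
        if lo_charged <= hi_phobic:
            raise ValueError(
                "charged residues (D/E/K/R) must all score above the "
                "hydrophobics (V/I/L/F/W)"
            )

    def __call__(self, residue: str) -> float:
        return self.values[residue]


def load_scale(path: str | Path, provenance: str | None = None) -> PropensityScale:
    """Load a two-column (residue, propensity) TSV; values are re-centred."""
    path = Path(path)
    raw: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        raw[aa] = float(value)
    mean = sum(raw.values()) / len(raw)
    centred = {a: v - mean for a, v in raw.items()}
    return PropensityScale(centred, provenance or str(path))


def default_scale() -> PropensityScale:
    """The packaged composite scale (inverted hydropathy + charge bonus)."""
    with resources.as_file(
        resources.files("solstab.data").joinpath("propensity_default.tsv")
    ) as p:
        return load_scale(p, provenance="composite-v1 (packaged default)")


@dataclass(frozen=True)
class SolubilityProfile:
    """Raw (s), smoothed (p) and optionally structure-corrected (q) profiles.

    All arrays are indexed by position−1.  ``corrected`` entries are NaN for
    residues without structural coverage; ``score`` is the global intrinsic
    score S = mean(p).
    """

    sequence: SequenceRecord
    raw: np.ndarray
    smoothed: np.ndarray
    window: int
    score: float
    corrected: np.ndarray | None = None

    def q(self, site: int) -> float:
        if self.corrected is None:
            raise ValueError("profile has no structural correction")
        return float(self.corrected[site - 1])

    def to_tsv(self, path: str | Path, exposure: ExposureTable | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("position\twt\ts\tp\tq\texposure\n")
            for i in range(len(self.sequence)):
                q = (
                    f"{self.corrected[i]:.6f}"
                    if self.corrected is not None and not math.isnan(self.corrected[i])
                    else "NA"
                )
                expo = "NA"
                if exposure is not None and (i + 1) in exposure.relative:
                    expo = f"{exposure.relative[i + 1]:.4f}"
                fh.write(
                    f"{i + 1}\t{self.sequence.residues[i]}\t"
                    f"{self.raw[i]:.6f}\t{self.smoothed[i]:.6f}\t{q}\t{expo}\n"
                )


def _window_mean(s: np.ndarray, i: int, half: int) -> float:
    """Mean of s over the window centred at i, shrunk at the termini.

    Both the full profile and the local Δ-update call this, so the two are
    bit-identical by construction.
    """
    lo = max(0, i - half)
    hi = min(len(s), i + half + 1)
    return float(np.sum(s[lo:hi]) / (hi - lo))


def _smooth(s: np.ndarray, window: int) -> np.ndarray:
    half = (window - 1) // 2
    return np.array([_window_mean(s, i, half) for i in range(len(s))])


def intrinsic_profile(
    seq: SequenceRecord, scale: PropensityScale | None = None, window: int = 7
) -> SolubilityProfile:
    """Raw and smoothed intrinsic solubility profile plus global score S."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if scale is None:
        scale = default_scale()
    s = np.array([scale(c) for c in seq.residues], dtype=float)
    p = _smooth(s, window)
    return SolubilityProfile(
        sequence=seq, raw=s, smoothed=p, window=window, score=float(np.mean(p))
    )


def mutate_sequence(seq: SequenceRecord, site: int, substitute: str) -> SequenceRecord:
    """Return a copy of ``seq`` with 1-based ``site`` replaced by ``substitute``."""
    if substitute not in AMINO_ACIDS:
        raise ValueError(f"substitute {substitute!r} is not canonical")
    residues = seq.residues[: site - 1] + substitute + seq.residues[site:]
    return SequenceRecord(f"{seq.identifier}|{seq[site]}{site}{substitute}", residues)


def intrinsic_score_delta(
    seq: SequenceRecord,
    site: int,
    substitute: str,
    scale: PropensityScale | None = None,
    window: int = 7,
) -> float:
    """ΔS = S(mutant) − S(WT) via a local update around the mutated site.

    Only smoothed values within one half-window of the site change, so the
    update touches O(window) positions yet matches a full recomputation
    bit-for-bit (both paths share the same window-summation routine).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if scale is None:
        scale = default_scale()
    wt = seq[site]
    if substitute not in AMINO_ACIDS:
        raise ValueError(f"substitute {substitute!r} is not canonical")
    if substitute == wt:
        warnings.warn(
            f"identity mutation {wt}{site}{substitute}: ΔS = 0", stacklevel=2
        )
        return 0.0
    L = len(seq)
    half = (window - 1) // 2
    s_wt = np.array([scale(c) for c in seq.residues], dtype=float)
    s_mut = s_wt.copy()
    s_mut[site - 1] = scale(substitute)
    p_wt = _smooth(s_wt, window)
    # only window means overlapping the site change; patch them into a copy
    # and take the same mean, so the result is bit-identical to recomputing
    # the whole mutant profile
    p_mut = p_wt.copy()
    lo = max(0, site - 1 - half)
    hi = min(L, site - 1 + half + 1)
    for i in range(lo, hi):
        p_mut[i] = _window_mean(s_mut, i, half)
    return float(np.mean(p_mut)) - float(np.mean(p_wt))


def structural_correction(
    profile: SolubilityProfile,
    model: StructureModel,
    exposure: ExposureTable,
    neighbours: dict[int, frozenset[int]],
    lam: float = 4.0,
) -> SolubilityProfile:
    """Exposure-gated, distance-weighted neighbourhood average of p.

    q_i = exposure_i · Σ_{j∈N(i)∪{i}} p_j e^{−d_ij/λ} / Σ e^{−d_ij/λ} with
    d_ii = 0; λ in Å (default 4).  Unresolved residues get q_i = NaN and are
    excluded from site identification downstream.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if model.seqres.residues != profile.sequence.residues:
        raise ValueError("profile sequence does not match structure SEQRES")
    centers = residue_centers(model)
    L = len(profile.sequence)
    q = np.full(L, np.nan)
    p = profile.smoothed
    for site in sorted(centers):
        members = [site] + sorted(neighbours.get(site, frozenset()))
        weights = []
        values = []
        for j in members:
            d = 0.0 if j == site else float(
                np.linalg.norm(centers[site] - centers[j])
            )
            weights.append(math.exp(-d / lam))
            values.append(p[j - 1])
        wsum = sum(weights)
        avg = sum(w * v for w, v in zip(weights, values)) / wsum
        q[site - 1] = exposure.rel(site) * avg
    return SolubilityProfile(
        sequence=profile.sequence,
        raw=profile.raw,
        smoothed=profile.smoothed,
        window=profile.window,
        score=profile.score,
        corrected=q,
    )
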