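"""Per-mutation folding-stability changes (ΔΔG, kcal/mol).

ΔΔG values normally arrive as a table of externally computed replicate
predictions (e.g. three FoldX runs per mutation); this module parses and
aggregates them.  Sign convention throughout: positive ΔΔG = destabilizing.
The decision statistic used downstream is the replicate mean; the standard
deviation is carried along for reporting.  A deterministic structural
surrogate is provided so the pipeline can be exercised end-to-end without a
physics predictor; it is clearly flagged as such and is not of predictive
accuracy.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass
from pathlib import Path

from solstab.sequence_msa import AMINO_ACIDS
from solstab.structure import ExposureTable, StructureModel, compute_exposure

#: Kyte–Doolittle hydropathy, used by the surrogate's hydrophobicity-loss term
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_MUTATION_TOKEN = re.compile(
    r"^([A-Z])([A-Z]?)(\d+)([A-Z])$"  # wt, optional chain letter, site, substitute
)


@dataclass(frozen=True)
class DdgRecord:
    """One substitution with its replicate ΔΔG predictions (kcal/mol)."""

    wt: str
    site: int
    substitute: str
    replicates: tuple[float, ...]
    surrogate: bool = False

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate required")

    @property
    def mean(self) -> float:
        return sum(self.replicates) / len(self.replicates)

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1); 0 for a single replicate."""
        if len(self.replicates) < 2:
            return 0.0
        return statistics.stdev(self.replicates)

    @property
    def mutation_str(self) -> str:
        return f"{self.wt}{self.site}{self.substitute}"


def parse_mutation_token(token: str) -> tuple[str, int, str]:
    """Parse ``G81E`` or FoldX-style ``GA81E`` (wt, chain, site, sub) tokens."""
    m = _MUTATION_TOKEN.match(token.strip())
    if not m:
        raise ValueError(f"unparseable mutation token {token!r}")
    wt, chain, site, sub = m.groups()
    if wt not in AMINO_ACIDS or sub not in AMINO_ACIDS:
        raise ValueError(f"mutation token {token!r}: non-canonical residue")
    return wt, int(site), sub


def read_ddg_table(path: str | Path) -> list[DdgRecord]:
    """Read a delimited ΔΔG table: one mutation token, then one column per replicate.

    Accepts comma- or tab-separated text with a ``mutation,rep1,...`` header
    and tolerates FoldX ``Dif_*.fxout``-style banners: lines before the first
    row whose leading field parses as a mutation token are skipped (a header
    line mentioning "mutation" is also recognized and skipped).  Duplicate
    (site, substitute) rows are an error.
    """
    path = Path(path)
    records: list[DdgRecord] = []
    seen: set[tuple[int, str]] = set()
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in re.split(r"[\t,;]", line) if f.strip()]
        if not fields:
            continue
        if not header_seen and "mutation" in fields[0].lower():
            header_seen = True
            continue
        try:
            wt, site, sub = parse_mutation_token(fields[0])
        except ValueError:
            if not records:
                continue  # banner line before the data block
            raise ValueError(
                f"{path} line {lineno}: unparseable mutation token {fields[0]!r}"
            ) from None
        try:
            reps = tuple(float(f) for f in fields[1:])
        except ValueError:
            raise ValueError(
                f"{path} line {lineno}: non-numeric replicate value"
            ) from None
        if not reps:
            raise ValueError(f"{path} line {lineno}: no replicate values")
        if (site, sub) in seen:
            raise ValueError(
                f"{path} line {lineno}: duplicate mutation {wt}{site}{sub}"
            )
        seen.add((site, sub))
        records.append(DdgRecord(wt=wt, site=site, substitute=sub, replicates=reps))
    if not records:
        raise ValueError(f"{path}: no ΔΔG records found")
    return records


def ddg_lookup(records: list[DdgRecord]) -> dict[tuple[int, str], DdgRecord]:
    """Index records by (site, substitute)."""
    return {(r.site, r.substitute): r for r in records}


def surrogate_ddg(
    model: StructureModel,
    site: int,
    substitute: str,
    exposure: ExposureTable | None = None,
) -> DdgRecord:
    """Deterministic structural stand-in for a physics ΔΔG predictor.

    ΔΔG = Δh · (2·b − 0.25·(1 − b)) where Δh is the normalized hydropathy
    loss (KD_wt − KD_sub)/9 and b = 1 − relative exposure (burial).  Removing
    hydrophobicity from a buried site is penalized; replacing an exposed
    hydrophobic by a polar residue is mildly favourable.  Identity mutations
    give exactly 0.  Flagged ``surrogate=True`` in provenance; same mutation
    and structure always yield the identical value.
    """
    if exposure is None:
        exposure = compute_exposure(model)
    wt = model.seqres[site]
    if substitute not in AMINO_ACIDS:
        raise ValueError(f"substitute {substitute!r} is not canonical")
    burial = 1.0 - exposure.rel(site)  # raises UnresolvedResidueError if needed
    dh = (_KD[wt] - _KD[substitute]) / 9.0
    value = dh * (2.0 * burial - 0.25 * (1.0 - burial))
    if substitute == wt:
        value = 0.0
    return DdgRecord(
        wt=wt, site=site, substitute=substitute, replicates=(value,), surrogate=True
    )


class SurrogateDdgSource:
    """Callable (site, substitute) → DdgRecord backed by :func:`surrogate_ddg`.

    Computes the exposure table once and reuses it, so scans over many
    mutations stay cheap and deterministic.
    """

    def __init__(self, model: StructureModel, exposure: ExposureTable | None = None):
        self.model = model
        self.exposure = exposure if exposure is not None else compute_exposure(model)

    def __call__(self, site: int, substitute: str) -> DdgRecord:
        return surrogate_ddg(self.model, site, substitute, exposure=self.exposure)
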