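"""Seed-deterministic generators for every synthetic input the suite needs.

Toy MSAs with controlled column compositions (so PSSM tests have exact
ground-truth counts), toy PDB structures with controlled burial, ΔΔG tables,
and simulated PEG-precipitation plates.  Generators write real files in the
standard formats (A3M/FASTA/PDB/CSV) so the I/O paths are exercised, and
each emits a machine-readable truth sidecar.  They emulate the *shape* of
real inputs, not realistic protein evolution or geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from solstab.assay_analysis import PegAssay, logistic
from solstab.sequence_msa import AA_INDEX, AMINO_ACIDS, QueryAlignment, SequenceRecord

STRUCTURE_PRESETS = ("extended", "caged", "two-shell", "buried-exposed")


@dataclass(frozen=True)
class FixtureSpec:
    """Bundle of generator knobs; the seed is mandatory.

    ``compositions`` maps 1-based columns to {symbol: probability} drawn for
    homologue rows ('-' allowed for gaps); unlisted columns match the query
    with probability ``match_prob`` and are otherwise uniform over the other
    19 residues.
    """

    seed: int
    length: int = 30
    depth: int = 20
    query: str | None = None
    compositions: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    match_prob: float = 0.7
    peg_half: float = 9.4
    peg_k: float = 1.0
    peg_a: float = 1.0
    noise_sd: float = 0.05
    replicates: int = 4


# ---------------------------------------------------------------------------
# MSA


@dataclass(frozen=True)
class MsaFixture:
    """A generated alignment plus the exact per-column residue tallies."""

    alignment: QueryAlignment
    counts: np.ndarray  # (L, 20), query row included, gaps excluded
    seed: int

    def write_a3m(self, path: str | Path, insertion_rate: float = 0.1) -> Path:
        """Write the alignment as A3M, salting homologue rows with lower-case
        insertion columns (which carry no query column and must be dropped
        by the reader)."""
        path = Path(path)
        rng = np.random.default_rng(self.seed + 10_007)
        lower = "acdefghiklmnpqrstvwy"
        with open(path, "w") as fh:
            for k, (rid, row) in enumerate(
                zip(self.alignment.row_ids, self.alignment.rows)
            ):
                out = []
                for c in row:
                    if k > 0 and rng.random() < insertion_rate:
                        out.append(lower[rng.integers(20)])
                    out.append(c)
                fh.write(f">{rid}\n{''.join(out)}\n")
        return path


def _validate_composition(col: int, comp: Mapping[str, float]) -> None:
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"column {col}: composition sums to {total:g}, not 1")
    bad = set(comp) - set(AMINO_ACIDS) - {"-"}
    if bad:
        raise ValueError(f"column {col}: unknown symbols {sorted(bad)}")


def make_msa(spec: FixtureSpec) -> MsaFixture:
    """Generate a query-anchored alignment with known column statistics.

    Row 0 is the query itself; the remaining ``depth - 1`` rows draw each
    column independently from the column's composition.  The returned
    ``counts`` are the generator's exact tallies (query included), giving
    PSSM tests independent ground truth.
    """
    if spec.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if spec.query is not None:
        query_seq = spec.query
    else:
        query_seq = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=spec.length)
        )
    L = len(query_seq)
    for col, comp in spec.compositions.items():
        if not 1 <= col <= L:
            raise ValueError(f"composition column {col} outside 1..{L}")
        _validate_composition(col, comp)

    rows = [query_seq]
    row_ids = ["query"]
    for r in range(1, spec.depth):
        symbols = []
        for i in range(L):
            comp = spec.compositions.get(i + 1)
            if comp is not None:
                keys = sorted(comp)
                probs = np.array([comp[k] for k in keys])
                symbols.append(keys[rng.choice(len(keys), p=probs / probs.sum())])
            else:
                if rng.random() < spec.match_prob:
                    symbols.append(query_seq[i])
                else:
                    others = [a for a in AMINO_ACIDS if a != query_seq[i]]
                    symbols.append(others[rng.integers(19)])
        rows.append("".join(symbols))
        row_ids.append(f"hom{r:03d}")

    counts = np.zeros((L, 20))
    for row in rows:
        for i, c in enumerate(row):
            if c != "-":
                counts[i, AA_INDEX[c]] += 1.0

    aln = QueryAlignment(
        query=SequenceRecord("query", query_seq),
        rows=tuple(rows),
        row_ids=tuple(row_ids),
    )
    return MsaFixture(alignment=aln, counts=counts, seed=spec.seed)


# ---------------------------------------------------------------------------
# structures


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Near-uniform points on a sphere (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return radius * np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


_SEQ3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _backbone(ca: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """A small rigid atom cloud around a Cα (name, element, coord)."""
    return [
        ("N", "N", ca + np.array([-1.20, 0.80, 0.00])),
        ("CA", "C", ca),
        ("C", "C", ca + np.array([1.20, 0.80, 0.00])),
        ("O", "O", ca + np.array([1.25, 1.90, 0.40])),
    ]


def _pdb_lines(
    chain: str,
    residues: list[tuple[int, str, list[tuple[str, str, np.ndarray]]]],
    seqres: str,
) -> str:
    lines: list[str] = []
    for ser, start in enumerate(range(0, len(seqres), 13), start=1):
        block = " ".join(_SEQ3[c] for c in seqres[start : start + 13])
        lines.append(f"SEQRES {ser:3d} {chain} {len(seqres):4d}  {block}")
    serial = 1
    for resnum, aa, atoms in residues:
        for name, element, coord in atoms:
            pdb_name = f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{_SEQ3[aa]:>3s} {chain}"
                f"{resnum:4d}    "
                f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_structure(
    preset: str,
    seed: int,
    path: str | Path,
    length: int = 10,
    chain: str = "A",
    sequence: str | None = None,
) -> Path:
    """Write a toy PDB file with controlled burial; returns the path.

    Presets: ``extended`` — a straight chain, every residue well exposed;
    ``caged`` — a central residue enclosed by one dense shell; ``two-shell``
    — the same with two concentric shells (tighter burial); both burial
    presets include a distant free residue (relative exposure > 0.9).
    ``buried-exposed`` — one caged valine and one free valine, for
    burial-ordering checks.  Identical (preset, seed) → identical bytes.
    """
    if preset not in STRUCTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {STRUCTURE_PRESETS}")
    path = Path(path)
    rng = np.random.default_rng(seed)

    residues: list[tuple[int, str, list[tuple[str, str, np.ndarray]]]] = []
    if preset == "extended":
        if sequence is not None:
            seq = sequence
        else:
            seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
        for i, aa in enumerate(seq):
            ca = np.array([3.8 * i, 0.6 * (i % 2), 0.0])
            residues.append((i + 1, aa, _backbone(ca)))
    else:
        center_aa = "V" if preset == "buried-exposed" else "G"
        free_aa = "V" if preset == "buried-exposed" else "G"
        residues.append((1, center_aa, [("CA", "C", np.zeros(3))]))
        shells = [(6.0, 300)] if preset == "caged" else [(5.5, 260), (7.0, 420)]
        num = 2
        for radius, n in shells:
            # tiny seeded rotation so distinct seeds give distinct files
            angle = float(rng.uniform(0, 2 * math.pi))
            rot = np.array(
                [
                    [math.cos(angle), -math.sin(angle), 0.0],
                    [math.sin(angle), math.cos(angle), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            for pt in _fibonacci_sphere(n, radius) @ rot.T:
                residues.append((num, "G", [("CA", "C", pt)]))
                num += 1
        residues.append((num, free_aa, _backbone(np.array([40.0, 0.0, 0.0]))))

    seqres = "".join(aa for _, aa, _ in residues)
    coords = np.array([c for _, _, atoms in residues for _, _, c in atoms])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1)) + np.eye(len(coords)) * 99.0
    if dist.min() < 1.0:
        raise AssertionError(f"generated atoms closer than 1 Å ({dist.min():.2f})")

    path.write_text(_pdb_lines(chain, residues, seqres))
    return path


# ---------------------------------------------------------------------------
# ΔΔG tables


def make_ddg_table(
    mutations: list[tuple[str, int, str]],
    seed: int,
    path: str | Path,
    n_replicates: int = 3,
    mean_range: tuple[float, float] = (-1.5, 1.5),
    replicate_sd: float = 0.1,
) -> Path:
    """Write a replicate ΔΔG CSV for the given (wt, site, sub) mutations,
    with a JSON truth sidecar recording each mutation's true mean."""
    path = Path(path)
    rng = np.random.default_rng(seed)
    truth: dict[str, float] = {}
    with open(path, "w") as fh:
        fh.write("mutation," + ",".join(f"rep{i+1}" for i in range(n_replicates)) + "\n")
        for wt, site, sub in mutations:
            mu = float(rng.uniform(*mean_range))
            reps = mu + rng.normal(0.0, replicate_sd, size=n_replicates)
            truth[f"{wt}{site}{sub}"] = mu
            fh.write(f"{wt}{site}{sub}," + ",".join(f"{v:.4f}" for v in reps) + "\n")
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# PEG plates


def make_peg_plate(
    seed: int,
    peg_half: float = 9.4,
    k: float = 1.0,
    a: float = 1.0,
    noise_sd: float = 0.05,
    replicates: int = 4,
    max_conc: float = 30.0,
    step: float = 2.0,
    baseline: float = 1.0,
    path: str | Path | None = None,
) -> PegAssay:
    """Simulate a PEG-precipitation plate from known sigmoid truth.

    Concentrations run 0 → ``max_conc`` % w/v in ``step`` increments with
    ``replicates`` wells each (quadruplicate by default); well values are
    baseline · (f(c) + N(0, noise_sd)).  When ``path`` is given the plate is
    written as CSV with a ``.truth.json`` sidecar.  Same seed → same plate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    concs = np.arange(0.0, max_conc + step / 2, step)
    peg = np.repeat(concs, replicates)
    clean = logistic(peg, a, k, peg_half)
    value = baseline * (clean + rng.normal(0.0, noise_sd, size=peg.shape))
    assay = PegAssay(peg=peg, value=value)

    if path is not None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("peg_percent,replicate,value\n")
            rep_counter: dict[float, int] = {}
            for c, v in zip(peg, value):
                rep_counter[c] = rep_counter.get(c, 0) + 1
                fh.write(f"{c:g},{rep_counter[c]},{v:.6f}\n")
        truth = {
            "peg_half": peg_half, "k": k, "a": a, "noise_sd": noise_sd,
            "replicates": replicates, "baseline": baseline, "seed": seed,
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )
    return assay
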