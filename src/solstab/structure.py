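"""Structure parsing, solvent exposure and sequence↔structure numbering.

All user-facing positions are 1-based indices into the SEQRES sequence;
author residue numbers (which may start anywhere and skip) are kept only in
the numbering map for reporting.  Solvent exposure is Shrake–Rupley SASA
normalized by a per-residue-type theoretical maximum, giving a relative
exposure in [0, 1] (0 = buried, 1 = fully exposed).

To make exposure reproducible under rigid motion of the input coordinates,
the structure is rotated into a canonical principal-axis frame before the
sphere-point sampling; see docs/methods.md for the limitation this implies
for highly symmetric (degenerate-inertia) structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1
from Bio import SeqIO

from solstab.sequence_msa import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger(__name__)


class UnresolvedResidueError(KeyError):
    """Lookup of a seqres position with no resolved coordinates."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")


@dataclass(frozen=True)
class Residue:
    author_number: int
    aa: str
    atoms: tuple[Atom, ...]


@dataclass(frozen=True)
class StructureModel:
    """One chain of a structure with its SEQRES sequence and numbering map."""

    chain_id: str
    residues: tuple[Residue, ...]  # resolved residues, author-number order
    seqres: SequenceRecord
    seqres_to_author: dict[int, int]
    author_to_seqres: dict[int, int]

    def resolved_sites(self) -> tuple[int, ...]:
        """Seqres indices (1-based) with resolved coordinates, ascending."""
        return tuple(sorted(self.seqres_to_author))

    def author_number(self, site: int) -> int:
        """Author residue number for 1-based seqres ``site``."""
        try:
            return self.seqres_to_author[site]
        except KeyError:
            raise UnresolvedResidueError(
                f"unresolved residue at seqres position {site}"
            ) from None

    def residue_at(self, site: int) -> Residue:
        author = self.author_number(site)
        return self._by_author[author]

    @property
    def _by_author(self) -> dict[int, Residue]:
        return {r.author_number: r for r in self.residues}


@dataclass(frozen=True)
class ExposureTable:
    """Per-residue absolute SASA (Å²) and relative exposure in [0, 1].

    Keyed by 1-based seqres index; residues without coordinates (or without
    heavy atoms) are absent and listed in ``excluded``.
    """

    absolute: dict[int, float]
    relative: dict[int, float]
    probe_radius: float
    n_points: int
    excluded: tuple[int, ...] = ()

    def rel(self, site: int) -> float:
        try:
            return self.relative[site]
        except KeyError:
            raise UnresolvedResidueError(
                f"no exposure for seqres position {site}"
            ) from None

    def to_tsv(self, path: str | Path, model: StructureModel) -> None:
        with open(path, "w") as fh:
            fh.write("position\twt\tsasa_abs\tsasa_rel\n")
            for site in sorted(self.absolute):
                fh.write(
                    f"{site}\t{model.seqres[site]}\t"
                    f"{self.absolute[site]:.3f}\t{self.relative[site]:.4f}\n"
                )


def load_max_sasa() -> dict[str, float]:
    """Theoretical maximum SASA (Å²) per residue type (Gly-X-Gly reference)."""
    table: dict[str, float] = {}
    text = resources.files("solstab.data").joinpath("max_sasa.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    if set(table) != set(AMINO_ACIDS):
        raise ValueError("max-SASA table must cover exactly the 20 amino acids")
    return table


# ---------------------------------------------------------------------------
# reading


def _read_seqres(path: Path, chain: str) -> str | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            records = list(SeqIO.parse(str(path), "pdb-seqres"))
        except Exception:
            return None
    for rec in records:
        if rec.annotations.get("chain") == chain:
            return str(rec.seq).upper() if len(rec.seq) else None
    return None


def read_structure(path: str | Path, chain: str = "A") -> StructureModel:
    """Parse one chain of a PDB file into a :class:`StructureModel`.

    The SEQRES record supplies the reference sequence when present, else the
    resolved residues do.  Hydrogens, waters and heteroatoms are dropped;
    alternate locations resolve to the highest-occupancy conformer (ties go
    to the first listed).  The numbering map pairs seqres indices with author
    numbers by scanning the resolved residues through the SEQRES sequence in
    order, tolerating unresolved stretches.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model0 = next(structure.get_models())
    if chain not in [c.id for c in model0]:
        raise ValueError(f"chain {chain!r} not present in {path}")

    residues: list[Residue] = []
    for res in model0[chain]:
        if not is_aa(res, standard=True):
            continue
        aa = seq1(res.get_resname())
        if aa not in AMINO_ACIDS:
            continue
        atoms = tuple(
            Atom(a.get_name(), (a.element or "C").strip().upper(), np.array(a.coord, dtype=float))
            for a in res.get_atoms()
            if (a.element or "").strip().upper() != "H"
        )
        if not atoms:
            logger.warning(
                "residue %s%d has no heavy atoms; excluded", aa, res.id[1]
            )
            continue
        residues.append(Residue(author_number=res.id[1], aa=aa, atoms=atoms))
    if not residues:
        raise ValueError(f"chain {chain!r} in {path} has no standard residues")
    residues.sort(key=lambda r: r.author_number)
    if len({r.author_number for r in residues}) != len(residues):
        raise ValueError(f"duplicate author residue numbers in chain {chain!r}")

    seqres_str = _read_seqres(path, chain)
    resolved_seq = "".join(r.aa for r in residues)
    if seqres_str is None:
        seqres_str = resolved_seq

    seqres = SequenceRecord(f"{path.stem}:{chain}", seqres_str)
    s2a, a2s = _build_numbering_map(seqres_str, residues)
    return StructureModel(
        chain_id=chain,
        residues=tuple(residues),
        seqres=seqres,
        seqres_to_author=s2a,
        author_to_seqres=a2s,
    )


def _build_numbering_map(
    seqres_str: str, residues: list[Residue]
) -> tuple[dict[int, int], dict[int, int]]:
    """Greedy in-order match of resolved residues into the SEQRES sequence."""
    s2a: dict[int, int] = {}
    a2s: dict[int, int] = {}
    j = 0  # pointer into residues
    for i, aa in enumerate(seqres_str, start=1):
        if j < len(residues) and residues[j].aa == aa:
            s2a[i] = residues[j].author_number
            a2s[residues[j].author_number] = i
            j += 1
    if j != len(residues):
        raise ValueError(
            f"could not map {len(residues) - j} resolved residues onto SEQRES; "
            "sequence/structure mismatch"
        )
    return s2a, a2s


# ---------------------------------------------------------------------------
# exposure


def _canonical_coords(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into the principal-axis frame with fixed axis signs.

    Makes the sphere-point SASA sampling invariant under rigid motion of the
    input: any rotation/translation of the atoms lands in the same frame (up
    to numerical precision) provided the principal moments are distinct.
    Axis signs are fixed by the third moment along each axis (skewness);
    a vanishing third moment leaves that sign as computed.
    """
    center = coords.mean(axis=0)
    X = coords - center
    cov = X.T @ X
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    V = eigvecs[:, order]
    Y = X @ V
    for k in range(3):
        skew = float(np.sum(Y[:, k] ** 3))
        if skew < 0:
            Y[:, k] = -Y[:, k]
    return Y


def _as_biopdb_chain(model: StructureModel, coords: np.ndarray):
    """Build a minimal Bio.PDB entity carrying the given atom coordinates."""
    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_chain(model.chain_id)
    builder.init_seg("    ")
    k = 0
    for res in model.residues:
        builder.init_residue("GLY", " ", res.author_number, " ")
        for atom in res.atoms:
            builder.init_atom(
                atom.name, coords[k], 0.0, 1.0, " ", atom.name, element=atom.element
            )
            k += 1
    return builder.get_structure()[0][model.chain_id]


def compute_exposure(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    max_sasa: dict[str, float] | None = None,
) -> ExposureTable:
    """Shrake–Rupley SASA and relative exposure for every resolved residue.

    ``probe_radius`` in Å (default 1.4, water); ``n_points`` sphere points per
    atom (default 960).  Relative exposure = absolute SASA / theoretical
    maximum for that residue type, clipped to [0, 1].
    """
    if max_sasa is None:
        max_sasa = load_max_sasa()
    all_coords = np.array(
        [a.coord for res in model.residues for a in res.atoms], dtype=float
    )
    canon = _canonical_coords(all_coords)
    chain = _as_biopdb_chain(model, canon)
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(
        chain, level="R"
    )
    sasa_by_author = {res.id[1]: float(res.sasa) for res in chain}

    absolute: dict[int, float] = {}
    relative: dict[int, float] = {}
    for res in model.residues:
        site = model.author_to_seqres[res.author_number]
        abs_sasa = sasa_by_author[res.author_number]
        absolute[site] = abs_sasa
        relative[site] = float(np.clip(abs_sasa / max_sasa[res.aa], 0.0, 1.0))
    excluded = tuple(
        i for i in range(1, len(model.seqres) + 1) if i not in absolute
    )
    return ExposureTable(
        absolute=absolute,
        relative=relative,
        probe_radius=probe_radius,
        n_points=n_points,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# geometry


def residue_centers(model: StructureModel) -> dict[int, np.ndarray]:
    """Cα coordinate per resolved seqres index; centroid fallback when absent."""
    centers: dict[int, np.ndarray] = {}
    for res in model.residues:
        site = model.author_to_seqres[res.author_number]
        ca = [a for a in res.atoms if a.name == "CA"]
        if ca:
            centers[site] = ca[0].coord
        else:
            logger.warning(
                "residue at seqres %d has no CA; using atom centroid", site
            )
            centers[site] = np.mean([a.coord for a in res.atoms], axis=0)
    return centers


def contact_neighbours(
    model: StructureModel, cutoff: float = 10.0
) -> dict[int, frozenset[int]]:
    """Per-residue neighbour sets: Cα–Cα distance ≤ cutoff, excluding self."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    centers = residue_centers(model)
    sites = sorted(centers)
    coords = np.array([centers[s] for s in sites])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    out: dict[int, frozenset[int]] = {}
    for i, s in enumerate(sites):
        mask = (dist[i] <= cutoff) & (np.arange(len(sites)) != i)
        out[s] = frozenset(sites[j] for j in np.nonzero(mask)[0])
    return out
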