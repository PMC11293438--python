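"""Pipeline core: site identification, mutational scanning, ranking, assembly.

The funnel runs: candidate *sites* are positions that are solvent-exposed and
either evolutionarily depleted (wild type has LL < 0 in the PSSM) or sit in
the worst band of the structure-corrected solubility profile.  At each site,
every PSSM-allowed substitution is scored for its intrinsic-solubility change
ΔS and its stability change ΔΔG; a candidate survives the *shortlist* iff
ΔS > 0 and mean ΔΔG is below the threshold (default 0, i.e. predicted
non-destabilizing).  Shortlisted candidates are ranked by a z-score
combination of the two criteria and greedily assembled into multi-mutation
design models (one mutation per site, at most ``budget`` mutations, model ΔS
recomputed on the full combined mutant sequence).

Everything here is deterministic: identical inputs and configuration yield
byte-identical reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np

from solstab.sequence_msa import (
    DEFAULT_EXCLUDED_SUBSTITUTIONS,
    PSSM,
    QueryAlignment,
    SequenceRecord,
    allowed_substitutions,
    compute_pssm,
    flag_mutable_sites,
    write_fasta,
)
from solstab.solubility import (
    PropensityScale,
    SolubilityProfile,
    default_scale,
    intrinsic_profile,
    intrinsic_score_delta,
    mutate_sequence,
    structural_correction,
)
from solstab.stability import DdgRecord
from solstab.structure import (
    ExposureTable,
    StructureModel,
    compute_exposure,
    contact_neighbours,
)


class Mutation(NamedTuple):
    wt: str
    site: int
    substitute: str

    def __str__(self) -> str:
        return f"{self.wt}{self.site}{self.substitute}"


#: a ΔΔG source is a mapping or callable over (site, substitute)
DdgSource = Mapping[tuple[int, str], DdgRecord] | Callable[[int, str], DdgRecord]


@dataclass(frozen=True)
class SiteSelectionConfig:
    """Thresholds gating which positions become candidate mutation sites.

    ``exposure_threshold``: minimum relative exposure (default 0.15 — buried
    residues are never touched).  ``profile_percentile``: positions whose
    corrected profile q falls in this lowest percentile band count as poorly
    soluble (default 30).  ``conservation_ceiling``: a site also qualifies
    when LL(i, wt) is below this ceiling (default 0, i.e. the wild type is
    depleted in the alignment).  ``excluded_positions`` removes sites (e.g.
    a known active site) outright.
    """

    exposure_threshold: float = 0.15
    profile_percentile: float = 30.0
    conservation_ceiling: float = 0.0
    excluded_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposure_threshold <= 1.0:
            raise ValueError("exposure_threshold must be in [0, 1]")
        if not 0.0 <= self.profile_percentile <= 100.0:
            raise ValueError("profile_percentile must be in [0, 100]")


@dataclass(frozen=True)
class MutationCandidate:
    """A single substitution with all the scores the pipeline attaches to it."""

    site: int
    wt: str
    substitute: str
    delta_s: float
    ddg_mean: float
    ddg_sd: float
    delta_ll: float
    rank_score: float = float("nan")

    @property
    def mutation(self) -> Mutation:
        return Mutation(self.wt, self.site, self.substitute)


@dataclass(frozen=True)
class DesignModel:
    """A set of compatible mutations combined into one multi-mutant design.

    ``delta_s`` is recomputed on the full combined mutant sequence (not the
    sum of single-mutation ΔS values), so overlapping smoothing windows
    interact correctly; ``sum_ddg`` is the sum of the members' mean ΔΔG.
    """

    members: tuple[MutationCandidate, ...]  # ordered by site
    delta_s: float
    sum_ddg: float
    rank: int

    @property
    def mutations(self) -> tuple[Mutation, ...]:
        return tuple(m.mutation for m in self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def mutation_string(self) -> str:
        return "+".join(str(m) for m in self.mutations) if self.members else "WT"

    def apply_to(self, seq: SequenceRecord) -> SequenceRecord:
        mutant = seq.residues
        for m in self.members:
            if mutant[m.site - 1] != m.wt:
                raise ValueError(f"sequence mismatch at site {m.site}")
            mutant = mutant[: m.site - 1] + m.substitute + mutant[m.site :]
        name = f"{seq.identifier}|{self.mutation_string()}"
        return SequenceRecord(name, mutant)


# ---------------------------------------------------------------------------
# funnel stages


def identify_sites(
    profile: SolubilityProfile,
    exposure: ExposureTable,
    pssm: PSSM,
    config: SiteSelectionConfig = SiteSelectionConfig(),
) -> list[int]:
    """Candidate mutation sites, ordered by ascending corrected profile q
    (worst predicted solubility first, ties by position).

    A site qualifies iff it is resolved with relative exposure ≥ threshold,
    AND it is either conservation-flagged (LL(i, wt) < ceiling) or its q lies
    in the lowest ``profile_percentile`` band, AND it is not excluded.
    Returns an empty list (with a warning) when nothing qualifies.
    """
    if profile.corrected is None:
        raise ValueError("identify_sites requires a structure-corrected profile")
    q = profile.corrected
    defined = ~np.isnan(q)
    if not defined.any():
        warnings.warn("no residues with structural coverage", stacklevel=2)
        return []
    q_cut = float(np.percentile(q[defined], config.profile_percentile))

    sites: list[int] = []
    for i in range(len(profile.sequence)):
        site = i + 1
        if not defined[i] or site in config.excluded_positions:
            continue
        if site not in exposure.relative:
            continue
        if exposure.relative[site] < config.exposure_threshold:
            continue
        conserved_flag = pssm.wt_ll(site) < config.conservation_ceiling
        poorly_soluble = q[i] <= q_cut
        if conserved_flag or poorly_soluble:
            sites.append(site)
    if not sites:
        warnings.warn("no candidate mutation sites identified", stacklevel=2)
    sites.sort(key=lambda s: (q[s - 1], s))
    return sites


def _ddg_for(source: DdgSource, site: int, substitute: str) -> DdgRecord | None:
    if callable(source):
        try:
            return source(site, substitute)
        except KeyError:
            return None
    return source.get((site, substitute))


def scan_mutations(
    sites: Sequence[int],
    pssm: PSSM,
    seq: SequenceRecord,
    ddg_source: DdgSource,
    scale: PropensityScale | None = None,
    window: int = 7,
    ddg_threshold: float = 0.0,
    excluded_substitutions: frozenset[str] = DEFAULT_EXCLUDED_SUBSTITUTIONS,
    pssm_mode: str = "strong",
) -> tuple[list[MutationCandidate], list[Mutation]]:
    """Score every PSSM-allowed substitution at the candidate sites.

    Keeps a candidate iff ΔS > 0 AND mean ΔΔG < ``ddg_threshold``.  Pairs
    with no ΔΔG available are returned in the second element ("not
    evaluated") rather than silently dropped.
    """
    if scale is None:
        scale = default_scale()
    allowed = allowed_substitutions(pssm, mode=pssm_mode, excluded=excluded_substitutions)
    shortlisted: list[MutationCandidate] = []
    not_evaluated: list[Mutation] = []
    for site in sites:
        wt = seq[site]
        for sub in sorted(allowed.get(site, frozenset())):
            rec = _ddg_for(ddg_source, site, sub)
            if rec is None:
                not_evaluated.append(Mutation(wt, site, sub))
                continue
            delta_s = intrinsic_score_delta(seq, site, sub, scale=scale, window=window)
            if delta_s > 0 and rec.mean < ddg_threshold:
                shortlisted.append(
                    MutationCandidate(
                        site=site,
                        wt=wt,
                        substitute=sub,
                        delta_s=delta_s,
                        ddg_mean=rec.mean,
                        ddg_sd=rec.sd,
                        delta_ll=pssm.get_delta_ll(site, sub),
                    )
                )
    return shortlisted, not_evaluated


def rank_candidates(
    candidates: Sequence[MutationCandidate],
    w_sol: float = 1.0,
    w_stab: float = 1.0,
) -> list[MutationCandidate]:
    """Rank by w_sol·z(ΔS) − w_stab·z(ΔΔG), descending.

    z-scores are taken within the candidate set (population sd; a zero sd
    maps the whole column to z = 0).  Ties break on (site, substitute) so
    the ordering is total and deterministic.
    """
    if w_sol < 0 or w_stab < 0 or (w_sol == 0 and w_stab == 0):
        raise ValueError("weights must be >= 0 and not both zero")
    if not candidates:
        return []

    def zscores(values: np.ndarray) -> np.ndarray:
        sd = float(np.std(values))
        if sd == 0.0:
            return np.zeros_like(values)
        return (values - float(np.mean(values))) / sd

    ds = zscores(np.array([c.delta_s for c in candidates], dtype=float))
    dg = zscores(np.array([c.ddg_mean for c in candidates], dtype=float))
    scored = [
        replace(c, rank_score=float(w_sol * ds[i] - w_stab * dg[i]))
        for i, c in enumerate(candidates)
    ]
    scored.sort(key=lambda c: (-c.rank_score, c.site, c.substitute))
    return scored


def _greedy_fill(
    ranked: Sequence[MutationCandidate],
    budget: int,
    min_separation: int,
    forced_first: MutationCandidate | None = None,
) -> list[MutationCandidate]:
    chosen: list[MutationCandidate] = []
    used_sites: list[int] = []

    def compatible(site: int) -> bool:
        for u in used_sites:
            if site == u:
                return False
            if min_separation > 0 and abs(site - u) < min_separation:
                return False
        return True

    def take(c: MutationCandidate) -> None:
        chosen.append(c)
        used_sites.append(c.site)

    if forced_first is not None:
        take(forced_first)
    for c in ranked:
        if len(chosen) >= budget:
            break
        if forced_first is not None and c == forced_first:
            continue
        if compatible(c.site):
            take(c)
    return chosen


def _build_model(
    members: Sequence[MutationCandidate],
    seq: SequenceRecord,
    scale: PropensityScale,
    window: int,
    rank: int,
) -> DesignModel:
    ordered = tuple(sorted(members, key=lambda c: c.site))
    if not ordered:
        return DesignModel(members=(), delta_s=0.0, sum_ddg=0.0, rank=rank)
    base = DesignModel(members=ordered, delta_s=0.0, sum_ddg=0.0, rank=rank)
    mutant = base.apply_to(seq)
    s_wt = intrinsic_profile(seq, scale=scale, window=window).score
    s_mut = intrinsic_profile(mutant, scale=scale, window=window).score
    return DesignModel(
        members=ordered,
        delta_s=s_mut - s_wt,
        sum_ddg=float(sum(c.ddg_mean for c in ordered)),
        rank=rank,
    )


def assemble_models(
    ranked: Sequence[MutationCandidate],
    seq: SequenceRecord,
    budget: int = 9,
    n_models: int = 3,
    min_separation: int = 0,
    scale: PropensityScale | None = None,
    window: int = 7,
) -> list[DesignModel]:
    """Greedy assembly of up to ``n_models`` distinct multi-mutation designs.

    The primary model takes candidates in rank order, skipping a candidate
    when its site is already used (or within ``min_separation`` residues of a
    used site), up to ``budget`` mutations.  Alternates force the best
    not-yet-used candidate first and greedily fill the rest.  Models whose
    recomputed combined ΔS is not positive are discarded; duplicates are
    de-duplicated.  Models may hold fewer mutations than the budget.
    """
    if budget < 1 or n_models < 1:
        raise ValueError("budget and n_models must be >= 1")
    if scale is None:
        scale = default_scale()
    if not ranked:
        warnings.warn("no shortlisted candidates: no design models", stacklevel=2)
        return []

    models: list[DesignModel] = []
    seen: set[frozenset[Mutation]] = set()

    def admit(members: list[MutationCandidate]) -> None:
        if not members or len(models) >= n_models:
            return
        key = frozenset(c.mutation for c in members)
        if key in seen:
            return
        model = _build_model(members, seq, scale, window, rank=len(models) + 1)
        if model.delta_s <= 0:
            return
        seen.add(key)
        models.append(model)

    admit(_greedy_fill(ranked, budget, min_separation))
    used_anywhere = {c.mutation for m in models for c in m.members}
    for c in ranked:
        if len(models) >= n_models:
            break
        if c.mutation in used_anywhere:
            continue
        admit(_greedy_fill(ranked, budget, min_separation, forced_first=c))
        used_anywhere = {cc.mutation for m in models for cc in m.members}
    return models


def remove_mutation(
    model: DesignModel,
    mutation: Mutation | str,
    seq: SequenceRecord,
    scale: PropensityScale | None = None,
    window: int = 7,
) -> DesignModel:
    """Drop one mutation from a model and recompute all model-level scores.

    Mirrors the manual curation step where a designed mutation is withdrawn
    after single-mutant testing; the result equals rebuilding the model from
    the remaining mutation set.  Removing the last mutation yields the
    wild-type model (ΔS = 0).
    """
    if scale is None:
        scale = default_scale()
    target = str(mutation)
    remaining = [c for c in model.members if str(c.mutation) != target]
    if len(remaining) == len(model.members):
        raise ValueError(f"mutation {target} not present in model")
    return _build_model(remaining, seq, scale, window, rank=model.rank)


# ---------------------------------------------------------------------------
# end-to-end driver and reports


@dataclass(frozen=True)
class PipelineResult:
    sequence: SequenceRecord
    pssm: PSSM
    profile: SolubilityProfile
    exposure: ExposureTable
    sites: list[int]
    candidates: list[MutationCandidate]  # ranked
    not_evaluated: list[Mutation]
    models: list[DesignModel]
    config: SiteSelectionConfig
    parameters: dict


def run_pipeline(
    seq: SequenceRecord,
    alignment: QueryAlignment,
    structure: StructureModel,
    ddg_source: DdgSource,
    config: SiteSelectionConfig = SiteSelectionConfig(),
    scale: PropensityScale | None = None,
    window: int = 7,
    pseudocount: float = 1.0,
    contact_cutoff: float = 10.0,
    lam: float = 4.0,
    ddg_threshold: float = 0.0,
    budget: int = 9,
    n_models: int = 3,
    min_separation: int = 0,
    w_sol: float = 1.0,
    w_stab: float = 1.0,
) -> PipelineResult:
    """Run the full design funnel from parsed inputs to ranked models."""
    if scale is None:
        scale = default_scale()
    if structure.seqres.residues != seq.residues:
        raise ValueError("query sequence does not match structure SEQRES")
    pssm = compute_pssm(alignment, pseudocount=pseudocount)
    exposure = compute_exposure(structure)
    neighbours = contact_neighbours(structure, cutoff=contact_cutoff)
    profile = intrinsic_profile(seq, scale=scale, window=window)
    profile = structural_correction(profile, structure, exposure, neighbours, lam=lam)
    sites = identify_sites(profile, exposure, pssm, config)
    shortlisted, not_evaluated = scan_mutations(
        sites, pssm, seq, ddg_source, scale=scale, window=window,
        ddg_threshold=ddg_threshold,
    )
    ranked = rank_candidates(shortlisted, w_sol=w_sol, w_stab=w_stab)
    models = assemble_models(
        ranked, seq, budget=budget, n_models=n_models,
        min_separation=min_separation, scale=scale, window=window,
    )
    parameters = {
        "window": window,
        "pseudocount": pseudocount,
        "contact_cutoff_A": contact_cutoff,
        "lambda_A": lam,
        "ddg_threshold": ddg_threshold,
        "budget": budget,
        "n_models": n_models,
        "min_separation": min_separation,
        "w_sol": w_sol,
        "w_stab": w_stab,
        "scale_provenance": scale.provenance,
    }
    return PipelineResult(
        sequence=seq,
        pssm=pssm,
        profile=profile,
        exposure=exposure,
        sites=sites,
        candidates=ranked,
        not_evaluated=not_evaluated,
        models=models,
        config=config,
        parameters=parameters,
    )


def write_report(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the candidate/model TSVs, mutant FASTA and JSON sidecar.

    Output is byte-deterministic for identical inputs and configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": outdir / "candidates.tsv",
        "models": outdir / "models.tsv",
        "sequences": outdir / "designs.fasta",
        "metadata": outdir / "run_metadata.json",
    }

    with open(paths["candidates"], "w") as fh:
        fh.write("site\twt\tsubstitute\tdelta_s\tddg_mean\tddg_sd\tdelta_ll\trank_score\n")
        for c in result.candidates:
            fh.write(
                f"{c.site}\t{c.wt}\t{c.substitute}\t{c.delta_s:.6f}\t"
                f"{c.ddg_mean:.4f}\t{c.ddg_sd:.4f}\t{c.delta_ll:.4f}\t"
                f"{c.rank_score:.6f}\n"
            )

    with open(paths["models"], "w") as fh:
        fh.write("model\tn_mutations\tmutations\tdelta_s\tsum_ddg\n")
        for m in result.models:
            fh.write(
                f"M{m.rank}\t{m.size}\t{m.mutation_string()}\t"
                f"{m.delta_s:.6f}\t{m.sum_ddg:.4f}\n"
            )

    write_fasta(
        paths["sequences"],
        [m.apply_to(result.sequence) for m in result.models],
    )

    meta = {
        "query": result.sequence.identifier,
        "length": len(result.sequence),
        "n_candidate_sites": len(result.sites),
        "candidate_sites": result.sites,
        "n_shortlisted": len(result.candidates),
        "n_not_evaluated": len(result.not_evaluated),
        "not_evaluated": [str(m) for m in result.not_evaluated],
        "n_models": len(result.models),
        "site_selection": {
            "exposure_threshold": result.config.exposure_threshold,
            "profile_percentile": result.config.profile_percentile,
            "conservation_ceiling": result.config.conservation_ceiling,
            "excluded_positions": sorted(result.config.excluded_positions),
        },
        "parameters": result.parameters,
        "scoring_note": (
            "intrinsic/corrected profiles use the packaged surrogate "
            "propensity scale unless overridden"
        ),
    }
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
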