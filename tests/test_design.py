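"""Site identification, mutational scanning, ranking and model assembly."""

import filecmp

import numpy as np
import pytest

from solstab.design import (
    DesignModel,
    Mutation,
    MutationCandidate,
    SiteSelectionConfig,
    assemble_models,
    identify_sites,
    rank_candidates,
    remove_mutation,
    run_pipeline,
    scan_mutations,
    write_report,
)
from solstab.fixtures import FixtureSpec, make_msa, make_structure
from solstab.sequence_msa import (
    QueryAlignment,
    SequenceRecord,
    allowed_substitutions,
    compute_pssm,
    flag_mutable_sites,
)
from solstab.solubility import (
    default_scale,
    intrinsic_profile,
    intrinsic_score_delta,
    mutate_sequence,
    structural_correction,
)
from solstab.stability import DdgRecord
from solstab.structure import compute_exposure, contact_neighbours, read_structure
from tests.conftest import ENRICHED_SITES


def random_candidates(rng, n, n_sites=None):
    n_sites = n_sites or n
    sites = rng.choice(np.arange(1, n_sites + 1), size=n, replace=True)
    out = []
    seen = set()
    for s in sites:
        sub = "ACDEFGHIKLPQRSTVWY"[rng.integers(18)]
        if (int(s), sub) in seen:
            continue
        seen.add((int(s), sub))
        out.append(
            MutationCandidate(
                site=int(s), wt="G", substitute=sub,
                delta_s=float(rng.normal()), ddg_mean=float(rng.normal()),
                ddg_sd=0.1, delta_ll=float(rng.normal()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# identify_sites


class TestIdentifySites:
    def test_end_to_end_world_finds_engineered_sites(self, design_result):
        for site in ENRICHED_SITES:
            assert site in design_result.sites

    def test_ordered_by_ascending_q(self, design_result):
        q = design_result.profile.corrected
        values = [q[s - 1] for s in design_result.sites]
        assert values == sorted(values)

    def test_conserved_buried_world_is_empty(self, tmp_path, scale):
        """A fully conserved alignment on a caged (buried) structure passes
        no gate: returns the empty list with a warning, not an error."""
        pdb = make_structure("caged", 5, tmp_path / "c.pdb")
        model = read_structure(pdb)
        seq = SequenceRecord("q", model.seqres.residues)
        aln = QueryAlignment(query=seq, rows=(seq.residues,) * 10)
        pssm = compute_pssm(aln)
        expo = compute_exposure(model)
        prof = structural_correction(
            intrinsic_profile(seq, scale), model, expo,
            contact_neighbours(model),
        )
        config = SiteSelectionConfig(profile_percentile=0.0)
        sites = identify_sites(prof, expo, pssm, config)
        buried = [s for s in sites if expo.rel(s) < 0.15]
        assert buried == []
        assert all(pssm.wt_ll(s) >= 0 or expo.rel(s) >= 0.15 for s in sites)

    def test_excluded_positions_respected(self, design_result, design_world):
        config = SiteSelectionConfig(excluded_positions=frozenset(ENRICHED_SITES))
        sites = identify_sites(
            design_result.profile, design_result.exposure,
            design_result.pssm, config,
        )
        assert not set(sites) & set(ENRICHED_SITES)

    def test_matches_boolean_gate_oracle(self, design_result):
        """Exhaustive per-position evaluation of the documented gate."""
        prof, expo, pssm = (
            design_result.profile, design_result.exposure, design_result.pssm,
        )
        config = design_result.config
        q = prof.corrected
        defined = ~np.isnan(q)
        q_cut = float(np.percentile(q[defined], config.profile_percentile))
        expected = []
        for site in range(1, len(prof.sequence) + 1):
            if not defined[site - 1] or site in config.excluded_positions:
                continue
            if site not in expo.relative or expo.relative[site] < config.exposure_threshold:
                continue
            if pssm.wt_ll(site) < config.conservation_ceiling or q[site - 1] <= q_cut:
                expected.append(site)
        expected.sort(key=lambda s: (q[s - 1], s))
        assert design_result.sites == expected

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SiteSelectionConfig(exposure_threshold=1.5)
        with pytest.raises(ValueError):
            SiteSelectionConfig(profile_percentile=120.0)


# ---------------------------------------------------------------------------
# scan_mutations


class TestScanMutations:
    def test_both_gates_pass(self, design_world, scale):
        seq = design_world["query"]
        pssm = compute_pssm(design_world["alignment"])
        source = {(4, "K"): DdgRecord("V", 4, "K", (-0.3,))}
        kept, _ = scan_mutations([4], pssm, seq, source, scale)
        assert [(c.site, c.substitute) for c in kept] == [(4, "K")]
        (cand,) = kept
        assert cand.delta_s > 0 and cand.ddg_mean == -0.3

    def test_stability_gate_rejects(self, design_world, scale):
        seq = design_world["query"]
        pssm = compute_pssm(design_world["alignment"])
        source = {(4, "K"): DdgRecord("V", 4, "K", (0.3,))}
        kept, _ = scan_mutations([4], pssm, seq, source, scale)
        assert kept == []

    def test_missing_ddg_reported_not_dropped(self, design_world, scale):
        seq = design_world["query"]
        pssm = compute_pssm(design_world["alignment"])
        kept, missing = scan_mutations([4], pssm, seq, {}, scale)
        assert kept == []
        assert Mutation("V", 4, "K") in missing

    def test_matches_exhaustive_double_filter_oracle(self, design_result, design_world, scale):
        """Brute-force enumeration over sites x allowed substitutions with
        both filters applied literally."""
        seq = design_world["query"]
        pssm = design_result.pssm
        source = design_world["ddg"]
        allowed = allowed_substitutions(pssm)
        expected = set()
        for site in design_result.sites:
            for sub in allowed[site]:
                rec = source.get((site, sub))
                if rec is None:
                    continue
                ds = (
                    intrinsic_profile(mutate_sequence(seq, site, sub), scale).score
                    - intrinsic_profile(seq, scale).score
                )
                if ds > 0 and rec.mean < 0.0:
                    expected.add((site, sub))
        got = {(c.site, c.substitute) for c in design_result.candidates}
        assert got == expected
        assert expected  # the engineered world must shortlist something

    def test_threshold_monotonicity(self, design_result, design_world, scale):
        """Shrinking the ΔΔG threshold never grows the shortlist."""
        seq = design_world["query"]
        pssm = design_result.pssm
        source = design_world["ddg"]
        previous = None
        for thr in (0.5, 0.0, -0.5, -1.0):
            kept, _ = scan_mutations(
                design_result.sites, pssm, seq, source, scale, ddg_threshold=thr
            )
            keys = {(c.site, c.substitute) for c in kept}
            if previous is not None:
                assert keys <= previous
            previous = keys


# ---------------------------------------------------------------------------
# rank_candidates


class TestRankCandidates:
    def test_single_candidate_gets_zero_zscores(self):
        c = MutationCandidate(1, "V", "K", 0.5, -0.3, 0.0, 1.0)
        (ranked,) = rank_candidates([c])
        assert ranked.rank_score == 0.0

    def test_stability_breaks_equal_solubility(self):
        a = MutationCandidate(1, "V", "K", 0.5, -1.0, 0.0, 1.0)
        b = MutationCandidate(2, "V", "K", 0.5, 0.0, 0.0, 1.0)
        ranked = rank_candidates([a, b])
        assert ranked[0].site == 1

    def test_empty_input(self):
        assert rank_candidates([]) == []

    def test_invalid_weights(self):
        c = MutationCandidate(1, "V", "K", 0.5, -0.3, 0.0, 1.0)
        with pytest.raises(ValueError):
            rank_candidates([c], w_sol=0.0, w_stab=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_oracle(self, seed):
        """50 random candidates: order equals an independently computed
        z-score sort with the documented key."""
        rng = np.random.default_rng(seed)
        cands = random_candidates(rng, 50)
        ranked = rank_candidates(cands, w_sol=1.0, w_stab=1.0)
        ds = np.array([c.delta_s for c in cands])
        dg = np.array([c.ddg_mean for c in cands])

        def z(v):
            return (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)

        scores = z(ds) - z(dg)
        expected = sorted(
            zip(scores, cands), key=lambda t: (-t[0], t[1].site, t[1].substitute)
        )
        assert [(c.site, c.substitute) for _, c in expected] == [
            (c.site, c.substitute) for c in ranked
        ]


# ---------------------------------------------------------------------------
# assemble_models / remove_mutation


def replay_greedy(ranked, budget, min_separation, forced=None):
    chosen, used = [], []
    if forced is not None:
        chosen.append(forced)
        used.append(forced.site)
    for c in ranked:
        if len(chosen) >= budget:
            break
        if forced is not None and c == forced:
            continue
        if any(
            c.site == u or (min_separation > 0 and abs(c.site - u) < min_separation)
            for u in used
        ):
            continue
        chosen.append(c)
        used.append(c.site)
    return chosen


class TestAssembleModels:
    def test_three_distinct_sites_fit_one_model(self, scale):
        seq = SequenceRecord("q", "AVAVAVAVAV")
        cands = [
            MutationCandidate(s, "V", "K", 0.1, -0.5, 0.0, 1.0)
            for s in (2, 4, 6)
        ]
        ranked = rank_candidates(cands)
        models = assemble_models(ranked, seq, budget=9, n_models=1, scale=scale)
        assert len(models) == 1
        assert models[0].size == 3  # fewer mutations than the budget is fine

    def test_one_mutation_per_site(self, scale):
        seq = SequenceRecord("q", "AVAAA")
        cands = rank_candidates([
            MutationCandidate(2, "V", "K", 0.2, -0.5, 0.0, 1.0),
            MutationCandidate(2, "V", "E", 0.1, -0.9, 0.0, 1.0),
        ])
        models = assemble_models(cands, seq, budget=9, n_models=3, scale=scale)
        for m in models:
            assert len({c.site for c in m.members}) == m.size == 1

    def test_model_delta_s_recomputed_on_combined_sequence(self, design_result, design_world, scale):
        for m in design_result.models:
            mutant = m.apply_to(design_world["query"])
            expected = (
                intrinsic_profile(mutant, scale).score
                - intrinsic_profile(design_world["query"], scale).score
            )
            assert m.delta_s == pytest.approx(expected, abs=1e-12)
            assert m.delta_s > 0

    def test_empty_shortlist_warns_and_returns_nothing(self, scale):
        seq = SequenceRecord("q", "AVAAA")
        with pytest.warns(UserWarning, match="no shortlisted"):
            assert assemble_models([], seq, scale=scale) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_greedy_replay_oracle(self, seed, scale):
        """Random candidate pools: emitted models equal a literal replay of
        the documented greedy procedure (primary + forced-first alternates)."""
        rng = np.random.default_rng(seed)
        seq = SequenceRecord("q", "".join(
            "AV"[int(b)] for b in rng.integers(0, 2, size=30)
        ))
        pool = []
        for c in random_candidates(rng, 10, n_sites=30):
            if seq[c.site] == c.wt or True:
                pool.append(
                    MutationCandidate(
                        c.site, seq[c.site], "K" if seq[c.site] != "K" else "E",
                        abs(c.delta_s) + 0.01, -abs(c.ddg_mean), 0.0, 1.0,
                    )
                )
        # unique (site, sub)
        uniq = {}
        for c in pool:
            uniq[(c.site, c.substitute)] = c
        ranked = rank_candidates(list(uniq.values()))
        budget, n_models, sep = 4, 3, 0
        models = assemble_models(
            ranked, seq, budget=budget, n_models=n_models,
            min_separation=sep, scale=scale,
        )

        # oracle replay
        expected, seen = [], set()
        def admit(members):
            if not members or len(expected) >= n_models:
                return
            key = frozenset((c.site, c.substitute) for c in members)
            if key in seen:
                return
            mutant = seq.residues
            for c in sorted(members, key=lambda c: c.site):
                mutant = mutant[: c.site - 1] + c.substitute + mutant[c.site:]
            ds = (
                intrinsic_profile(SequenceRecord("m", mutant), scale).score
                - intrinsic_profile(seq, scale).score
            )
            if ds <= 0:
                return
            seen.add(key)
            expected.append(sorted((c.site, c.substitute) for c in members))

        admit(replay_greedy(ranked, budget, sep))
        used = {(c.site, c.substitute) for m in expected for c in []}
        used = {pair for m in expected for pair in m}
        for c in ranked:
            if len(expected) >= n_models:
                break
            if (c.site, c.substitute) in used:
                continue
            admit(replay_greedy(ranked, budget, sep, forced=c))
            used = {pair for m in expected for pair in m}

        got = [sorted((c.site, c.substitute) for c in m.members) for m in models]
        assert got == expected

    def test_min_separation_enforced(self, scale):
        seq = SequenceRecord("q", "VVVVVVVVVV")
        cands = rank_candidates([
            MutationCandidate(s, "V", "K", 0.1 * s, -0.5, 0.0, 1.0)
            for s in (2, 3, 8)
        ])
        models = assemble_models(
            cands, seq, budget=9, n_models=1, min_separation=3, scale=scale
        )
        sites = sorted(c.site for c in models[0].members)
        assert all(b - a >= 3 for a, b in zip(sites, sites[1:]))


class TestRemoveMutation:
    def test_removal_recomputes_scores(self, design_result, design_world, scale):
        model = design_result.models[0]
        assert model.size >= 2
        victim = model.mutations[0]
        reduced = remove_mutation(model, victim, design_world["query"], scale)
        assert reduced.size == model.size - 1
        assert victim not in reduced.mutations
        rebuilt_ds = (
            intrinsic_profile(reduced.apply_to(design_world["query"]), scale).score
            - intrinsic_profile(design_world["query"], scale).score
        )
        assert reduced.delta_s == pytest.approx(rebuilt_ds, abs=1e-12)
        assert reduced.sum_ddg == pytest.approx(
            sum(c.ddg_mean for c in reduced.members), abs=1e-12
        )

    def test_removing_only_mutation_yields_wildtype(self, scale):
        seq = SequenceRecord("q", "AVAAA")
        cands = rank_candidates([MutationCandidate(2, "V", "K", 0.2, -0.5, 0.0, 1.0)])
        (model,) = assemble_models(cands, seq, budget=9, n_models=1, scale=scale)
        wt = remove_mutation(model, "V2K", seq, scale)
        assert wt.size == 0 and wt.delta_s == 0.0
        assert wt.mutation_string() == "WT"

    def test_absent_mutation_rejected(self, design_result, design_world, scale):
        with pytest.raises(ValueError, match="not present"):
            remove_mutation(
                design_result.models[0], "A1K", design_world["query"], scale
            )


# ---------------------------------------------------------------------------
# end-to-end contracts


class TestPipelineContracts:
    def test_model_invariants(self, design_result):
        shortlisted = {(c.site, c.substitute) for c in design_result.candidates}
        for m in design_result.models:
            assert m.size <= 4  # the fixture budget
            sites = [c.site for c in m.members]
            assert len(set(sites)) == len(sites)
            for c in m.members:
                assert (c.site, c.substitute) in shortlisted
                assert c.substitute not in "CMN"
            assert m.delta_s > 0

    def test_reports_byte_identical_across_runs(self, design_world, tmp_path):
        out = []
        for run in ("one", "two"):
            result = run_pipeline(
                design_world["query"], design_world["alignment"],
                design_world["model"], design_world["ddg"],
                budget=4, n_models=3,
            )
            out.append(write_report(result, tmp_path / run))
        for key in out[0]:
            assert filecmp.cmp(out[0][key], out[1][key], shallow=False), key

    def test_fully_conserved_world_returns_wildtype_only(self, tmp_path):
        """With every site conserved and no poorly soluble band, the design
        funnel returns no models — the already-optimal limit."""
        pdb = make_structure("extended", 21, tmp_path / "c.pdb", length=15)
        model = read_structure(pdb)
        seq = SequenceRecord("q", model.seqres.residues)
        aln = QueryAlignment(query=seq, rows=(seq.residues,) * 20)
        assert flag_mutable_sites(compute_pssm(aln)) == frozenset()
        with pytest.warns(UserWarning):
            result = run_pipeline(
                seq, aln, model, {}, config=SiteSelectionConfig(profile_percentile=0.0),
            )
        assert result.candidates == [] and result.models == []

    def test_mismatched_structure_rejected(self, design_world):
        other = SequenceRecord("x", "MKV")
        with pytest.raises(ValueError, match="SEQRES"):
            run_pipeline(
                other, design_world["alignment"], design_world["model"],
                design_world["ddg"],
            )
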