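"""Shared fixtures: small deterministic worlds built by solstab.fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from solstab.design import SiteSelectionConfig, run_pipeline
from solstab.fixtures import FixtureSpec, make_ddg_table, make_msa, make_structure
from solstab.sequence_msa import SequenceRecord
from solstab.solubility import default_scale
from solstab.stability import ddg_lookup, read_ddg_table
from solstab.structure import compute_exposure, contact_neighbours, read_structure

# An extended-chain world where three hydrophobic, exposed, alignment-depleted
# sites (4, 10, 16) have K/E strongly enriched, and the ΔΔG table favours
# exactly those substitutions.  Guarantees a non-empty shortlist.
DESIGN_QUERY = "STAVNDQGHIKLQTYVESDAGTHK"  # length 24
ENRICHED_SITES = (4, 10, 16)


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def design_world(tmp_path_factory):
    """Structure + alignment + ΔΔG table wired so the funnel produces designs."""
    tmp = tmp_path_factory.mktemp("design_world")
    query = DESIGN_QUERY
    pdb = make_structure(
        "extended", seed=101, path=tmp / "toy.pdb",
        length=len(query), sequence=query,
    )
    model = read_structure(pdb)

    # wt probability 0.02 keeps the wt frequency below the uniform background
    # (1/20), so LL(wt) < 0 and the site is conservation-flagged
    comps = {
        site: {"K": 0.60, "E": 0.38, query[site - 1]: 0.02}
        for site in ENRICHED_SITES
    }
    msa = make_msa(
        FixtureSpec(seed=202, length=len(query), depth=60,
                    query=query, compositions=comps)
    )

    muts = []
    for site in range(1, len(query) + 1):
        for sub in "KE":
            if sub != query[site - 1]:
                muts.append((query[site - 1], site, sub))
    ddg_path = make_ddg_table(
        muts, seed=303, path=tmp / "ddg.csv",
        mean_range=(-1.2, -0.2), replicate_sd=0.05,
    )

    return {
        "tmp": tmp,
        "query": SequenceRecord("toy", query),
        "pdb": pdb,
        "model": model,
        "alignment": msa.alignment,
        "msa": msa,
        "ddg_path": ddg_path,
        "ddg": ddg_lookup(read_ddg_table(ddg_path)),
    }


@pytest.fixture(scope="session")
def design_result(design_world):
    return run_pipeline(
        design_world["query"],
        design_world["alignment"],
        design_world["model"],
        design_world["ddg"],
        config=SiteSelectionConfig(),
        budget=4,
        n_models=3,
    )


@pytest.fixture(scope="session")
def extended_model(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("extended")
    pdb = make_structure("extended", seed=42, path=tmp / "ext.pdb", length=10)
    return read_structure(pdb)


@pytest.fixture(scope="session")
def extended_exposure(extended_model):
    return compute_exposure(extended_model)


@pytest.fixture(scope="session")
def caged_model(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("caged")
    pdb = make_structure("caged", seed=42, path=tmp / "caged.pdb")
    return read_structure(pdb)
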