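"""Shared fixtures: small synthetic workspaces built once per session."""

import pandas as pd
import pytest

from subpheno import growth, simulate


@pytest.fixture(scope="session")
def flat_reference():
    """Reference table with constant mean 50, sd 2 at every age (both sexes),
    so z-scores are controlled exactly: value = 50 + 2*z."""
    rows = []
    for sex in ("M", "F"):
        for age in (48.0, 96.0, 144.0, 204.0):
            rows.append({"sex": sex, "age_months": age, "mean": 50.0, "sd": 2.0})
    return growth.GrowthReferenceTable(pd.DataFrame(rows), measure="flat")


@pytest.fixture(scope="session")
def trio_workspace(tmp_path_factory):
    cfg = simulate.TrioConfig(n_families=2, n_inherited=500, n_denovo=25)
    outdir = tmp_path_factory.mktemp("trios")
    return simulate.gen_trio_vcf(cfg, outdir, seed=11)


@pytest.fixture(scope="session")
def network_morpho_workspace(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("netmorpho")
    return simulate.gen_edges_and_morpho(
        simulate.EdgeConfig(n_genes=150, n_seeds=10),
        simulate.MorphoConfig(),
        outdir, seed=13)


@pytest.fixture(scope="session")
def sc_workspace(tmp_path_factory):
    cfg = simulate.ScConfig(n_cells_per_condition=300, n_genes=500,
                            n_clusters=3, target_set_size=30)
    outdir = tmp_path_factory.mktemp("sc")
    return simulate.gen_sc_counts(cfg, outdir, seed=17)


@pytest.fixture(scope="session")
def sc_adata(sc_workspace):
    import anndata as ad

    from subpheno import scshift

    parts = [
        scshift.read_condition_mtx(v["counts"], v["cells"], v["genes"])
        for v in sc_workspace["conditions"].values()
    ]
    return ad.concat(parts, merge="same")
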