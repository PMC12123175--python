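"""Single-cell expression-shift analysis of knockdown/overexpression models.

Stages, in pipeline order:

* QC filtering on mitochondrial/ribosomal percentages and per-cell feature
  counts (absolute floor plus a per-sample mean + 2 SD ceiling);
* depth normalization to the median depth with natural-log1p transform and
  selection of the most variable genes (optional linear residualization on
  mito/ribo percentages);
* PCA followed by Ward hierarchical clustering of cells with the tree cut
  into *k* flat clusters;
* downsampling of test cells to the control total while preserving the
  test cluster distribution;
* per-gene two-sided Wilcoxon rank-sum differential expression with
  detection and log2-fold-change floors and BH correction;
* Fisher-exact enrichment of a target gene set (e.g. FMRP targets) among
  the differentially expressed genes;
* paired/unpaired t-tests on per-gene average log2 fold changes between and
  within models.

Counts live in an :class:`anndata.AnnData` (cells x genes, sparse); the
log-normalized expression is stored as the ``lognorm`` layer.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ensure_qc_fields",
    "qc_filter",
    "normalize",
    "cluster_cells",
    "downsample_to_match",
    "de_wilcoxon",
    "find_markers",
    "target_set_enrichment",
    "ortholog_map",
    "average_log2fc",
    "build_shift_table",
    "geneset_shift_test",
    "read_condition_mtx",
]

LOG2FC_EPS = 1e-9


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def ensure_qc_fields(adata: ad.AnnData) -> ad.AnnData:
    """Populate ``n_features`` (genes with count > 0 per cell) if absent."""
    if "n_features" not in adata.obs:
        X = adata.X
        nf = (X > 0).sum(axis=1)
        adata.obs["n_features"] = np.asarray(nf).ravel().astype(int)
    return adata


def qc_filter(
    adata: ad.AnnData,
    mito_ribo_max: float = 5.0,
    min_features: int = 200,
    nfeat_sd: float = 2.0,
    sample_col: str = "sample_id",
) -> ad.AnnData:
    """Remove low-quality cells; the removal report lands in ``uns['qc_report']``.

    A cell is removed when its mitochondrial *or* ribosomal percentage
    exceeds ``mito_ribo_max``, its feature count is strictly below
    ``min_features``, or its feature count exceeds the per-sample
    pre-filter mean + ``nfeat_sd``·SD. Samples left with fewer than 10
    cells trigger a warning.
    """
    ensure_qc_fields(adata)
    obs = adata.obs
    nfeat = obs["n_features"].to_numpy(dtype=float)
    high = np.zeros(adata.n_obs, dtype=bool)
    for sample, idx in obs.groupby(sample_col, observed=True).indices.items():
        mu, sd = nfeat[idx].mean(), nfeat[idx].std(ddof=0)
        high[idx] = nfeat[idx] > mu + nfeat_sd * sd
    rules = {
        "percent_mito": obs["percent_mito"].to_numpy() > mito_ribo_max,
        "percent_ribo": obs["percent_ribo"].to_numpy() > mito_ribo_max,
        "low_features": nfeat < min_features,
        "high_features": high,
    }
    if "is_doublet" in obs:
        rules["doublet"] = obs["is_doublet"].to_numpy(dtype=bool)
    removed = np.zeros(adata.n_obs, dtype=bool)
    report = {}
    for name, mask in rules.items():
        report[name] = int(mask.sum())
        removed |= mask
    report["removed_total"] = int(removed.sum())
    report["removed_cells"] = sorted(adata.obs_names[removed])
    out = adata[~removed].copy()
    out.uns["qc_report"] = report
    for sample, grp in out.obs.groupby(sample_col, observed=True):
        if len(grp) < 10:
            warnings.warn(f"sample {sample} has {len(grp)} cells after QC")
    return out


def normalize(
    adata: ad.AnnData,
    n_variable: int = 5000,
    regress_mito_ribo: bool = False,
) -> ad.AnnData:
    """Depth-scale to the median depth, log1p, and flag variable genes.

    Each cell's counts are scaled to the pre-filter median total count and
    natural-log1p transformed into the ``lognorm`` layer. The
    ``n_variable`` genes with the largest variance of the normalized
    expression get ``var['highly_variable'] = True`` (constant genes are
    never selected); clustering uses only those. Optional per-gene linear
    residualization on mito/ribo percentages replaces the layer with
    residuals shifted back to the gene mean.
    """
    X = adata.X.astype(np.float64)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("zero-depth cell encountered; run qc_filter first")
    target = float(np.median(depth))
    scale = target / depth
    if sparse.issparse(X):
        lognorm = sparse.diags(scale) @ X.tocsr()
        lognorm.data = np.log1p(lognorm.data)
    else:
        lognorm = np.log1p(X * scale[:, None])
    adata.layers["lognorm"] = lognorm
    dense = _dense(lognorm)
    var = dense.var(axis=0)
    order = np.argsort(-var, kind="stable")
    n_nonconst = int((var > 0).sum())
    chosen = order[: min(n_variable, n_nonconst)]
    hv = np.zeros(adata.n_vars, dtype=bool)
    hv[chosen] = True
    adata.var["highly_variable"] = hv
    adata.var["lognorm_variance"] = var
    if regress_mito_ribo:
        design = np.column_stack([
            np.ones(adata.n_obs),
            adata.obs["percent_mito"].to_numpy(dtype=float),
            adata.obs["percent_ribo"].to_numpy(dtype=float),
        ])
        beta, *_ = np.linalg.lstsq(design, dense, rcond=None)
        resid = dense - design @ beta + dense.mean(axis=0)
        adata.layers["lognorm"] = resid
    return adata


def cluster_cells(
    adata: ad.AnnData,
    n_pcs: int = 30,
    k: int = 10,
    linkage_method: str = "ward",
    cluster_col: str = "cluster",
) -> ad.AnnData:
    """PCA then agglomerative clustering of cells, tree cut into ``k`` clusters.

    Principal components are computed on the variable genes of the
    ``lognorm`` layer (deterministic full SVD; component signs fixed by
    forcing each component's largest-magnitude loading positive), pairwise
    Euclidean distances on the first ``n_pcs`` components feed a Ward-linkage
    dendrogram cut into ``k`` flat clusters (labels '1'..'k').
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > adata.n_obs:
        raise ValueError(f"k={k} exceeds the number of cells ({adata.n_obs})")
    dense = _dense(adata.layers["lognorm"])[:, adata.var["highly_variable"].to_numpy()]
    n_comp = min(n_pcs, min(dense.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    emb = pca.fit_transform(dense)
    # fix the sign indeterminacy of each component
    signs = np.sign(pca.components_[np.arange(n_comp),
                                    np.abs(pca.components_).argmax(axis=1)])
    signs[signs == 0] = 1.0
    emb = emb * signs
    adata.obsm["X_pca"] = emb
    if k == 1:
        labels = np.ones(adata.n_obs, dtype=int)
    else:
        Z = linkage(emb, method=linkage_method)
        labels = fcluster(Z, t=k, criterion="maxclust")
    adata.obs[cluster_col] = pd.Categorical(labels.astype(str))
    return adata


def downsample_to_match(
    adata: ad.AnnData,
    test_condition: str,
    control_condition: str,
    seed: int,
    condition_col: str = "condition",
    cluster_col: str = "cluster",
    mode: str = "proportional",
) -> ad.AnnData:
    """Subsample test cells to the control total, cluster-aware.

    ``mode='proportional'`` (default) allocates the control-group total
    across clusters proportionally to the *test* cluster distribution
    (largest-remainder rounding) and keeps ``min(available, target)`` test
    cells per cluster, sampled without replacement. ``mode='per_cluster'``
    instead matches the control per-cluster counts directly. Control cells
    and cells of other conditions are untouched; output is deterministic
    under ``seed``.
    """
    obs = adata.obs
    is_test = (obs[condition_col] == test_condition).to_numpy()
    is_ctl = (obs[condition_col] == control_condition).to_numpy()
    n_ctl = int(is_ctl.sum())
    test_idx = np.flatnonzero(is_test)
    clusters = obs[cluster_col].to_numpy()
    uniq = sorted(set(clusters[test_idx]))
    avail = {c: np.flatnonzero(is_test & (clusters == c)) for c in uniq}
    n_test = len(test_idx)
    if mode == "proportional":
        raw = {c: n_ctl * len(avail[c]) / n_test for c in uniq}
        target = {c: int(np.floor(raw[c])) for c in uniq}
        short = n_ctl - sum(target.values())
        for c in sorted(uniq, key=lambda c: (-(raw[c] - target[c]), c))[:short]:
            target[c] += 1
    elif mode == "per_cluster":
        target = {c: int((is_ctl & (clusters == c)).sum()) for c in uniq}
    else:
        raise ValueError(f"unknown downsampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    keep = np.ones(adata.n_obs, dtype=bool)
    keep[test_idx] = False
    for c in uniq:
        pool = avail[c]
        take = min(len(pool), target[c])
        if take < target[c]:
            logger.info("cluster %s: only %d of %d target test cells", c, len(pool), target[c])
        chosen = rng.choice(pool, size=take, replace=False)
        keep[np.sort(chosen)] = True
    return adata[keep].copy()


def _group_matrix(adata, mask, layer):
    return _dense(adata.layers[layer][mask] if layer else adata.X[mask])


def de_wilcoxon(
    adata: ad.AnnData,
    group_test: str,
    group_control: str,
    groupby: str = "condition",
    logfc_floor: float = 0.1,
    min_pct: float = 0.01,
    mode: str = "two_group",
    return_thresh: float = 0.01,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum differential expression.

    Genes detected (normalized expression > 0) in at least ``min_pct`` of
    cells of either group are eligible; of those, genes whose
    log2 fold change — ``log2((mean(expm1 x_test)+eps) / (mean(expm1
    x_control)+eps))`` — clears ``logfc_floor`` in magnitude are tested
    with midrank-based rank sums and BH-adjusted. ``mode='one_vs_rest'``
    keeps positive fold changes only and applies the raw-p
    ``return_thresh`` (marker-finding convention).
    """
    grp = adata.obs[groupby].astype(str)
    mask_t = (grp == str(group_test)).to_numpy()
    mask_c = (grp == str(group_control)).to_numpy() if mode == "two_group" \
        else ~mask_t
    if mask_t.sum() == 0 or mask_c.sum() == 0:
        raise ValueError("both groups must contain cells")
    Xt = _group_matrix(adata, mask_t, layer)
    Xc = _group_matrix(adata, mask_c, layer)
    pct_t = (Xt > 0).mean(axis=0)
    pct_c = (Xc > 0).mean(axis=0)
    detected = np.maximum(pct_t, pct_c) >= min_pct
    mean_t = np.expm1(Xt).mean(axis=0)
    mean_c = np.expm1(Xc).mean(axis=0)
    log2fc = np.log2((mean_t + LOG2FC_EPS) / (mean_c + LOG2FC_EPS))
    tested = detected & (np.abs(log2fc) >= logfc_floor)
    if mode == "one_vs_rest":
        tested &= log2fc > 0
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene", "log2fc", "pct_test", "pct_control", "p", "p_adj", "direction"]
        )
    res = stats.mannwhitneyu(
        Xt[:, idx], Xc[:, idx], alternative="two-sided", method="asymptotic", axis=0
    )
    p = np.atleast_1d(res.pvalue)
    df = pd.DataFrame({
        "gene": adata.var_names[idx],
        "log2fc": log2fc[idx],
        "pct_test": pct_t[idx],
        "pct_control": pct_c[idx],
        "p": p,
    })
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    if mode == "one_vs_rest":
        df = df[df["p"] <= return_thresh]
    return df.sort_values(["p", "gene"]).reset_index(drop=True)


def find_markers(
    adata: ad.AnnData,
    groupby: str = "cluster",
    logfc_floor: float = 0.1,
    min_pct: float = 0.2,
    return_thresh: float = 0.01,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Positive one-vs-rest markers per group (marker-finding convention)."""
    frames = []
    for group in sorted(adata.obs[groupby].astype(str).unique()):
        df = de_wilcoxon(
            adata, group, "__rest__", groupby=groupby, logfc_floor=logfc_floor,
            min_pct=min_pct, mode="one_vs_rest", return_thresh=return_thresh,
            layer=layer,
        )
        df.insert(0, groupby, group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def target_set_enrichment(
    de_results: pd.DataFrame,
    target_genes,
    expressed_background,
    alpha: float = 0.05,
    family_ps: list[float] | None = None,
) -> dict:
    """Fisher-exact enrichment of a target gene set among the DEGs.

    The 2x2 table crosses DEG status (BH-adjusted p <= ``alpha`` among
    ``de_results``) with target membership over ``expressed_background``.
    ``family_ps`` supplies the other raw p-values of the enrichment family
    for BH adjustment (the reported test is appended to that family).
    """
    targets = set(target_genes)
    if not targets:
        raise ValueError("target gene set is empty")
    background = set(expressed_background)
    targets &= background
    degs = set(de_results.loc[de_results["p_adj"] <= alpha, "gene"]) & background
    expected_frac = len(targets) / len(background)
    if not degs:
        warnings.warn("empty DEG set; enrichment p set to 1")
        observed_frac, odds, p = 0.0, np.nan, 1.0
    else:
        a = len(degs & targets)
        b = len(degs - targets)
        c = len(targets - degs)
        d = len(background - targets - degs)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        observed_frac = a / len(degs)
    family = list(family_ps or []) + [p]
    p_bh = float(multipletests(family, method="fdr_bh")[1][-1])
    return {
        "observed_frac": float(observed_frac),
        "expected_frac": float(expected_frac),
        "odds_ratio": float(odds) if np.isfinite(odds) else None,
        "p": float(p),
        "p_bh": p_bh,
        "n_degs": len(degs),
        "n_targets_in_background": len(targets),
        "n_background": len(background),
    }


def ortholog_map(genes, map_table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Map gene symbols across species using a two-column lookup table.

    ``map_table`` has columns ``human_symbol`` and ``zebrafish_symbol``;
    one-to-many expansions are kept, outputs deduplicated preserving first
    occurrence. Returns ``(mapped, unmapped_inputs)``.
    """
    lut: dict[str, list[str]] = {}
    for h, z in zip(map_table["human_symbol"], map_table["zebrafish_symbol"]):
        lut.setdefault(str(h), []).append(str(z))
    mapped: list[str] = []
    seen = set()
    unmapped = []
    for g in genes:
        if g not in lut:
            unmapped.append(g)
            continue
        for z in lut[g]:
            if z not in seen:
                seen.add(z)
                mapped.append(z)
    return mapped, unmapped


def average_log2fc(
    adata: ad.AnnData,
    group_test: str,
    group_control: str,
    groupby: str = "condition",
    expression_floor: float = 0.0001,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Per-gene average log2 fold change over genes expressed in both groups.

    A gene qualifies when detected in at least ``expression_floor``
    (fraction, default 0.01% of cells) of *both* groups; the fold change is
    the group-mean ratio used by :func:`de_wilcoxon`, with no magnitude
    floor.
    """
    grp = adata.obs[groupby].astype(str)
    Xt = _group_matrix(adata, (grp == str(group_test)).to_numpy(), layer)
    Xc = _group_matrix(adata, (grp == str(group_control)).to_numpy(), layer)
    pct_t = (Xt > 0).mean(axis=0)
    pct_c = (Xc > 0).mean(axis=0)
    ok = (pct_t >= expression_floor) & (pct_c >= expression_floor)
    log2fc = np.log2(
        (np.expm1(Xt).mean(axis=0) + LOG2FC_EPS)
        / (np.expm1(Xc).mean(axis=0) + LOG2FC_EPS)
    )
    return pd.DataFrame({"gene": adata.var_names[ok], "avg_log2fc": log2fc[ok]})


def build_shift_table(
    kd_fc: pd.DataFrame,
    oe_fc: pd.DataFrame,
    target_genes,
    scope: str = "all_cells",
) -> pd.DataFrame:
    """Join the knockdown and overexpression per-gene fold changes.

    Only genes present (i.e. passing the expression floor) in both models
    are kept; ``in_target_set`` flags membership of ``target_genes``.
    """
    targets = set(target_genes)
    merged = kd_fc.merge(oe_fc, on="gene", suffixes=("_kd", "_oe"))
    merged = merged.rename(
        columns={"avg_log2fc_kd": "avg_log2fc_kd", "avg_log2fc_oe": "avg_log2fc_oe"}
    )
    merged["scope"] = scope
    merged["in_target_set"] = merged["gene"].isin(targets)
    return merged


def geneset_shift_test(shift_table: pd.DataFrame) -> dict:
    """Paired and unpaired t-tests on per-gene average log2 fold changes.

    Between models: paired two-sided t-test of the overexpression versus
    knockdown fold change over the shared target genes. Within each model:
    unpaired two-sided t-test of target versus non-target genes. Medians
    are reported per group; each group must contain at least 3 genes.
    """
    tgt = shift_table[shift_table["in_target_set"]]
    non = shift_table[~shift_table["in_target_set"]]
    if len(tgt) < 3:
        raise ValueError("need >= 3 target genes")
    diffs = (tgt["avg_log2fc_oe"] - tgt["avg_log2fc_kd"]).to_numpy()
    if np.allclose(diffs, 0.0):
        paired_t, paired_p = 0.0, 1.0  # degenerate: no shift at all
    else:
        paired = stats.ttest_rel(tgt["avg_log2fc_oe"], tgt["avg_log2fc_kd"])
        paired_t, paired_p = float(paired.statistic), float(paired.pvalue)
    out = {
        "paired_t": paired_t,
        "paired_p": paired_p,
        "median_target_kd": float(tgt["avg_log2fc_kd"].median()),
        "median_target_oe": float(tgt["avg_log2fc_oe"].median()),
        "n_target": int(len(tgt)),
        "n_non_target": int(len(non)),
    }
    for model in ("kd", "oe"):
        col = f"avg_log2fc_{model}"
        if len(non) >= 3:
            res = stats.ttest_ind(tgt[col], non[col])
            out[f"unpaired_t_{model}"] = float(res.statistic)
            out[f"unpaired_p_{model}"] = float(res.pvalue)
            out[f"median_non_target_{model}"] = float(non[col].median())
    return out


def read_condition_mtx(counts_mtx, cells_tsv, genes_tsv) -> ad.AnnData:
    """Assemble an AnnData from Matrix Market counts plus cell/gene TSVs.

    The matrix is stored genes x cells on disk (the common exchange
    convention) and transposed to cells x genes in memory.
    """
    from scipy.io import mmread

    X = sparse.csr_matrix(mmread(str(counts_mtx)).T)
    cells = pd.read_csv(cells_tsv, sep="\t").set_index("cell_id")
    genes = pd.read_csv(genes_tsv, sep="\t").set_index("gene_id")
    adata = ad.AnnData(X=X, obs=cells, var=genes)
    return ensure_qc_fields(adata)
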