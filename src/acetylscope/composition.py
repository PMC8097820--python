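"""Cell-type marker sites and Marker Site Profiles (MSPs).

Bulk brain chromatin data mixes cell types, and cell composition is often
the dominant source of between-sample variance.  The MSP approach estimates
relative cell-type abundance from the bulk signal itself: reference data from
sorted nuclei (NeuN+ neurons vs NeuN− glia) defines strongly cell-type
-specific acetylation sites, marker gene lists assign those sites to specific
cell types, and the first principal component of each type's marker-site
log-CPM across bulk samples serves as a relative-abundance proxy used as a
covariate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: which reference class each cell type's marker sites must be "up" in:
#: neuronal types come from the NeuN+ class, glial types from NeuN−.
DEFAULT_CELL_TYPE_DIRECTION = {
    "neuron": "+",
    "oligodendrocyte": "-",
    "astrocyte": "-",
    "microglia": "-",
}


@dataclass
class MarkerSiteSet:
    cell_type: str
    site_ids: list
    provenance: dict  # site id -> licensing gene symbols/ids


@dataclass
class MSPResult:
    cell_type: str
    scores: pd.Series          # raw PC1 scores, sign-oriented
    scores_scaled: pd.Series   # rescaled to [0, 1] over the analyzed samples
    explained_variance_share: float
    orientation_sign: int


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million over each sample's total reads-in-peaks."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return counts.div(totals, axis=1) * 1e6


def reference_dars(
    ref_counts: pd.DataFrame,
    ref_labels: pd.Series,
    fc_threshold: float = 4.0,
    mean_threshold: float = 1000.0,
) -> pd.DataFrame:
    """Differential sites between two sorted-cell reference classes.

    Normalizes to CPM, then keeps sites with |class-mean fold change| > 4 and
    overall mean normalized count > 1000.  Fold change is the positive-class
    over negative-class mean; zero class means get a +0.5 floor (flagged).
    Returns one row per site with fold_change, mean_count, direction and the
    kept flag for every site (filter downstream on ``kept``).
    """
    classes = sorted(set(ref_labels))
    if len(classes) != 2:
        raise ValueError(f"expected two reference classes, got {classes}")
    for c in classes:
        if (ref_labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    pos = classes[0] if "+" in classes[0] else classes[1]
    neg = classes[1] if pos == classes[0] else classes[0]
    norm = cpm(ref_counts)
    mean_pos = norm.loc[:, ref_labels == pos].mean(axis=1)
    mean_neg = norm.loc[:, ref_labels == neg].mean(axis=1)
    floored = (mean_pos == 0) | (mean_neg == 0)
    fc = (mean_pos + 0.5 * (mean_pos == 0)) / (mean_neg + 0.5 * (mean_neg == 0))
    overall = norm.mean(axis=1)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "mean_count": overall,
            "direction": np.where(fc >= 1.0, "+", "-"),
            "zero_mean_floored": floored,
        },
        index=ref_counts.index,
    )
    out["kept"] = (
        (np.maximum(fc, 1.0 / fc) > fc_threshold) & (overall > mean_threshold)
    )
    return out


def assign_marker_sites(
    dars: pd.DataFrame,
    annotations: pd.DataFrame,
    marker_genes: pd.DataFrame,
    cell_type_direction: dict | None = None,
) -> dict[str, MarkerSiteSet]:
    """Assign reference DARs to cell types via marker-gene annotation.

    ``annotations`` are msp_window records (peak_id, gene_id); ``marker_genes``
    has columns cell_type and gene_id (or symbol).  A DAR annotated to marker
    genes of exactly one cell type joins that type's set; DARs touching marker
    genes of more than one type are dropped, keeping the per-type sets
    disjoint.  Direction consistency is enforced: a cell type mapped to the
    "+" reference class only accepts positive-class-up sites, and vice versa.
    """
    direction = dict(DEFAULT_CELL_TYPE_DIRECTION)
    direction.update(cell_type_direction or {})
    gene_col = "gene_id" if "gene_id" in marker_genes.columns else "symbol"
    gene_to_type = {}
    ambiguous_genes = set()
    for row in marker_genes.itertuples():
        g, ct = getattr(row, gene_col), row.cell_type
        if g in gene_to_type and gene_to_type[g] != ct:
            ambiguous_genes.add(g)
        gene_to_type[g] = ct
    kept = dars[dars["kept"]] if "kept" in dars.columns else dars
    site_types: dict[str, set] = {}
    site_genes: dict[str, set] = {}
    ann = annotations.dropna(subset=["gene_id"])
    for row in ann[ann["peak_id"].isin(kept.index)].itertuples():
        if row.gene_id in ambiguous_genes:
            site_types.setdefault(row.peak_id, set()).update({"_ambiguous"})
            continue
        ct = gene_to_type.get(row.gene_id)
        if ct is not None:
            site_types.setdefault(row.peak_id, set()).add(ct)
            site_genes.setdefault(row.peak_id, set()).add(row.gene_id)
    out: dict[str, MarkerSiteSet] = {}
    for ct in sorted(set(marker_genes["cell_type"])):
        want = direction.get(ct)
        if want is None:
            raise ValueError(f"no reference direction known for cell type {ct!r}")
        sites = []
        provenance = {}
        for pid, types in site_types.items():
            if types != {ct}:
                continue
            if kept.loc[pid, "direction"] != want:
                continue
            sites.append(pid)
            provenance[pid] = sorted(site_genes[pid])
        if not sites:
            import warnings

            warnings.warn(f"no marker sites for cell type {ct!r}; type skipped")
            continue
        out[ct] = MarkerSiteSet(ct, sorted(sites), provenance)
    return out


def compute_msp(bulk_counts: pd.DataFrame, marker_set: MarkerSiteSet) -> MSPResult:
    """Marker Site Profile: PC1 of log2(CPM+1) over one type's marker sites.

    CPM uses each sample's total reads-in-peaks over the full matrix.  The
    PC1 sample scores are sign-oriented to correlate positively with the mean
    marker-site signal and returned both raw and min–max rescaled to [0, 1].
    """
    sites = [s for s in marker_set.site_ids if s in bulk_counts.index]
    if len(sites) < 2:
        raise ValueError(
            f"{marker_set.cell_type}: need >=2 marker sites in the count matrix"
        )
    if bulk_counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    log_cpm = np.log2(cpm(bulk_counts) + 1.0)
    mat = log_cpm.loc[sites].to_numpy().T  # samples x sites
    if np.allclose(mat.var(axis=0).sum(), 0.0):
        raise ValueError("marker-site matrix has zero variance; PCA degenerate")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(mat - mat.mean(axis=0))[:, 0]
    mean_signal = mat.mean(axis=1)
    corr = np.corrcoef(scores, mean_signal)[0, 1]
    sign = -1 if corr < 0 else 1
    scores = sign * scores
    span = scores.max() - scores.min()
    scaled = (scores - scores.min()) / span if span > 0 else np.zeros_like(scores)
    return MSPResult(
        cell_type=marker_set.cell_type,
        scores=pd.Series(scores, index=bulk_counts.columns, name=marker_set.cell_type),
        scores_scaled=pd.Series(scaled, index=bulk_counts.columns,
                                name=marker_set.cell_type),
        explained_variance_share=float(pca.explained_variance_ratio_[0]),
        orientation_sign=sign,
    )


def compute_mgp(expression_counts: pd.DataFrame, marker_genes,
                cell_type: str = "marker") -> MSPResult:
    """Marker Gene Profile: the MSP algorithm on expression log-CPM.

    ``marker_genes`` is a list of gene ids present in the expression matrix;
    used to derive the RNA-side cell-composition covariate.
    """
    marker_set = MarkerSiteSet(cell_type, list(marker_genes), {})
    return compute_msp(expression_counts, marker_set)


def msp_table(bulk_counts: pd.DataFrame,
              marker_sets: dict[str, MarkerSiteSet],
              scaled: bool = False) -> pd.DataFrame:
    """Sample x cell-type MSP matrix (raw scores by default)."""
    cols = {}
    for ct, ms in sorted(marker_sets.items()):
        res = compute_msp(bulk_counts, ms)
        cols[ct] = res.scores_scaled if scaled else res.scores
    return pd.DataFrame(cols)
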