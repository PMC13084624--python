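"""Downstream statistics on discovered adduct peptides: hydrolysis-pair
detection, site distribution, Ward clustering with anonymized adducts,
the three-correlation volcano for agent attribution, the
enrichment-vs-binding volcano, and LOD-based detection calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .cohort import IntensityMatrix
from .selection import PreprocessConfig, preprocess

__all__ = [
    "find_hydrolysis_pairs",
    "site_distribution",
    "anonymize_adducts",
    "ward_cluster",
    "three_way_volcano",
    "enrichment_volcano",
    "detection_call",
    "detection_grid",
]

# Orthonormal basis of the zero-sum plane x+y+z=0 used to project the
# fold-change triple of the three-way volcano to 2-D.
_PLANE_BASIS = np.array(
    [
        [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
        [1.0 / np.sqrt(6.0), 1.0 / np.sqrt(6.0), -2.0 / np.sqrt(6.0)],
    ]
)


def find_hydrolysis_pairs(features: pd.DataFrame) -> pd.DataFrame:
    """Sites carrying both the HETETE adduct and its HETE hydrolysis shadow.

    ``features`` must be annotated with ``protein``, ``position`` and
    ``adduct`` columns (feature id index).  Each (protein, position) site
    is listed once, with one representative feature per adduct type.
    """
    mod = features[features["adduct"].isin(["HETETE", "HETE"])]
    rows = []
    for (protein, position), grp in mod.groupby(["protein", "position"], sort=True):
        adducts = set(grp["adduct"])
        if {"HETETE", "HETE"} <= adducts:
            rows.append(
                {
                    "protein": protein,
                    "position": position,
                    "hetete_feature": grp.index[grp["adduct"] == "HETETE"][0],
                    "hete_feature": grp.index[grp["adduct"] == "HETE"][0],
                }
            )
    return pd.DataFrame(rows, columns=["protein", "position", "hetete_feature", "hete_feature"])


def site_distribution(features: pd.DataFrame) -> pd.DataFrame:
    """Unique modification sites counted by protein x alkylated residue.

    Duplicate peptides covering the same (protein, position) count once.
    The table total equals the number of unique sites.
    """
    mod = features[features["adduct"].astype(str) != ""]
    if mod.empty:
        return pd.DataFrame()
    sites = mod.reset_index()[["protein", "position", "residue"]].drop_duplicates(
        subset=["protein", "position"]
    )
    return (
        sites.pivot_table(
            index="protein", columns="residue", aggfunc="size", fill_value=0
        )
        .rename_axis(columns=None)
        .sort_index()
    )


def anonymize_adducts(matrix: IntensityMatrix) -> IntensityMatrix:
    """Merge adduct forms of the same site by summing raw intensities.

    Features sharing (protein, position, sequence) but differing in alkyl
    chain collapse to one row; the chain identity is anonymized so only
    the peptide and site remain.  Values are log2, so summation happens on
    the linear scale; a sample missing every constituent stays missing.
    Background (unmodified) features pass through untouched.
    """
    feats = matrix.features
    is_mod = feats["adduct"].astype(str) != ""
    bg_ids = list(feats.index[~is_mod])
    mod = feats[is_mod]
    lin = 2.0 ** matrix.values
    new_cols = {}
    new_rows = []
    for (protein, position, sequence), grp in mod.groupby(
        ["protein", "position", "sequence"], sort=True
    ):
        fid = f"{protein}_{position}_anon"
        merged = lin[grp.index].sum(axis=1, min_count=1)
        new_cols[fid] = np.log2(merged)
        first = grp.iloc[0]
        new_rows.append(
            {
                "feature_id": fid,
                "kind": "anonymized",
                "protein": protein,
                "position": position,
                "residue": first["residue"],
                "adduct": "anonymized",
                "agent": "",
                "site": first.get("site", ""),
                "sequence": sequence,
            }
        )
    values = pd.concat(
        [matrix.values[bg_ids], pd.DataFrame(new_cols, index=matrix.values.index)],
        axis=1,
    )
    features = pd.concat(
        [
            feats.loc[bg_ids],
            pd.DataFrame(new_rows).set_index("feature_id")
            if new_rows
            else pd.DataFrame(),
        ]
    )
    features = features.reindex(values.columns)
    return IntensityMatrix(values=values, samples=matrix.samples.copy(), features=features)


def ward_cluster(
    X: pd.DataFrame, k: int, sample_labels=None
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Ward-linkage agglomerative clustering of samples, cut at k clusters.

    ``X`` is a preprocessed (log2, z-scored) sample x feature matrix.
    Returns (cluster labels, scipy linkage matrix, purity); purity -- the
    fraction of samples whose cluster's majority label matches their own --
    is None when no labels are given.
    """
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    Z = linkage(X.to_numpy(dtype=float), method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    purity = None
    if sample_labels is not None:
        sample_labels = np.asarray(sample_labels)
        correct = 0
        for c in np.unique(labels):
            members = sample_labels[labels == c]
            vals, counts = np.unique(members, return_counts=True)
            correct += counts.max()
        purity = correct / n
    return labels, Z, purity


def three_way_volcano(
    X: pd.DataFrame, agent_labels, alpha: float = 0.05
) -> pd.DataFrame:
    """Three-correlation volcano over exactly three agent groups.

    Per feature: pairwise Welch t-tests and log2 fold changes between
    group means for the three agent pairs (A-B, B-C, C-A in sorted agent
    order, so the triple sums to zero), Benjamini-Hochberg adjustment
    across all tests, a 7-way class (one of three primary colors when a
    feature is significantly higher in exactly one agent than both others,
    a secondary color when higher in exactly two, else none), and 2-D
    coordinates from projecting the zero-sum triple onto a fixed
    orthonormal basis of the plane x+y+z = 0.
    """
    agent_labels = np.asarray(agent_labels)
    agents = sorted(np.unique(agent_labels))
    if len(agents) != 3:
        raise ValueError(f"need exactly three groups, got {agents}")
    groups = {a: X.loc[agent_labels == a] for a in agents}
    for a, g in groups.items():
        if g.shape[0] < 2:
            raise ValueError(f"group {a} has fewer than 2 replicates")
    pairs = [(agents[0], agents[1]), (agents[1], agents[2]), (agents[2], agents[0])]
    fcs, ps = [], []
    for a, b in pairs:
        A, B = groups[a].to_numpy(float), groups[b].to_numpy(float)
        res = sps.ttest_ind(A, B, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        fcs.append(A.mean(axis=0) - B.mean(axis=0))
        ps.append(p)
    fcs = np.vstack(fcs)  # 3 x features; columns sum to 0 identically
    ps = np.vstack(ps)
    adj = multipletests(ps.ravel(), method="fdr_bh")[1].reshape(ps.shape)
    sig = adj < alpha

    classes = []
    for j in range(X.shape[1]):
        higher = {a: 0 for a in agents}
        for k, (a, b) in enumerate(pairs):
            if sig[k, j]:
                if fcs[k, j] > 0:
                    higher[a] += 1
                elif fcs[k, j] < 0:
                    higher[b] += 1
        winners = [a for a in agents if higher[a] == 2]
        partial = [a for a in agents if higher[a] >= 1]
        if len(winners) == 1:
            classes.append(f"{winners[0]}_primary")
        elif len(partial) == 2 and not winners:
            classes.append("+".join(partial) + "_secondary")
        else:
            classes.append("none")

    coords = _PLANE_BASIS @ fcs
    out = pd.DataFrame(
        {
            f"log2fc_{a}_vs_{b}": fcs[k] for k, (a, b) in enumerate(pairs)
        },
        index=X.columns,
    )
    for k, (a, b) in enumerate(pairs):
        out[f"p_{a}_vs_{b}"] = ps[k]
        out[f"padj_{a}_vs_{b}"] = adj[k]
    out["volcano_class"] = classes
    out["proj_x"] = coords[0]
    out["proj_y"] = coords[1]
    return out


def enrichment_volcano(
    eluate: pd.DataFrame,
    binding: pd.DataFrame,
    alpha: float = 0.05,
    full_protein_count: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-protein eluate-vs-binding comparison plus protein-count reduction.

    Inputs are protein x replicate log2 matrices (NaN = not detected).
    Proteins absent on both sides are excluded; proteins absent only from
    the eluate count toward the reduction.  Per shared protein: log2 FC of
    means, Welch t-test, BH adjustment, enriched/depleted call at adjusted
    p < alpha.  Reduction = 1 - detected-in-eluate / all proteins.
    """
    proteins = binding.index.union(eluate.index)
    n_total = full_protein_count if full_protein_count is not None else len(proteins)
    detected_eluate = eluate.dropna(how="all").index
    reduction = 1.0 - len(detected_eluate) / n_total

    rows = []
    for p in proteins:
        e = eluate.loc[p].dropna() if p in eluate.index else pd.Series(dtype=float)
        b = binding.loc[p].dropna() if p in binding.index else pd.Series(dtype=float)
        if e.empty and b.empty:
            continue
        if len(e) >= 2 and len(b) >= 2:
            fc = e.mean() - b.mean()
            if np.allclose(e.to_numpy(), b.to_numpy()[: len(e)]) and e.std() == 0:
                pval = 1.0
            else:
                pval = float(sps.ttest_ind(e, b, equal_var=False).pvalue)
                if np.isnan(pval):
                    pval = 1.0
            rows.append({"protein": p, "log2fc": fc, "p": pval, "status": "shared"})
        elif e.empty:
            rows.append({"protein": p, "log2fc": -np.inf, "p": np.nan, "status": "eluate_absent"})
        else:
            rows.append({"protein": p, "log2fc": np.inf, "p": np.nan, "status": "binding_absent"})
    df = pd.DataFrame(rows).set_index("protein")
    shared = df["status"] == "shared"
    padj = pd.Series(np.nan, index=df.index)
    if shared.any():
        padj.loc[shared] = multipletests(df.loc[shared, "p"], method="fdr_bh")[1]
    df["padj"] = padj
    call = pd.Series("unchanged", index=df.index)
    call[(df["padj"] < alpha) & (df["log2fc"] > 0)] = "enriched"
    call[(df["padj"] < alpha) & (df["log2fc"] < 0)] = "depleted"
    call[df["status"] == "eluate_absent"] = "lost_in_eluate"
    df["call"] = call
    return df, reduction


def detection_call(condition: np.ndarray, blank: np.ndarray) -> bool:
    """Detected iff mean(condition) > mean(blank) + 3 sd(blank).

    Missing values are treated as absent (excluded); a condition with no
    observed value is not detected.  At least 3 blank observations are
    required so the blank spread is estimable.
    """
    blank = np.asarray(blank, dtype=float)
    blank = blank[~np.isnan(blank)]
    if blank.size < 3:
        raise ValueError("need at least 3 blank observations")
    condition = np.asarray(condition, dtype=float)
    condition = condition[~np.isnan(condition)]
    if condition.size == 0:
        return False
    return bool(condition.mean() > blank.mean() + 3.0 * blank.std(ddof=1))


def detection_grid(
    matrix: IntensityMatrix,
    feature_ids,
    blank_agent: str = "control",
    floor_value: float | None = None,
) -> pd.DataFrame:
    """Detection calls per (feature, exposure condition) against blanks.

    Blank observations are the control samples' values with missing
    entries set to ``floor_value`` (default: the matrix-wide observed
    minimum, an LOD proxy) so the blank mean/spread are defined even when
    a feature is never seen in blanks.  Emits a detection-grid table over
    (agent, dose) cells -- the gray-cell layout of an exposure series.
    """
    samples = matrix.samples
    blanks = samples.index[samples["agent"] == blank_agent]
    if len(blanks) < 3:
        raise ValueError("need at least 3 blank samples")
    if floor_value is None:
        floor_value = float(np.nanmin(matrix.values.to_numpy()))
    conds = (
        samples[samples["agent"] != blank_agent][["agent", "dose_m"]]
        .drop_duplicates()
        .sort_values(["agent", "dose_m"], ascending=[True, False])
    )
    rows = []
    for fid in feature_ids:
        blank_vals = matrix.values.loc[blanks, fid].fillna(floor_value).to_numpy()
        for _, cond in conds.iterrows():
            mask = (samples["agent"] == cond["agent"]) & (
                samples["dose_m"] == cond["dose_m"]
            )
            vals = matrix.values.loc[mask.to_numpy(), fid].to_numpy()
            rows.append(
                {
                    "feature_id": fid,
                    "agent": cond["agent"],
                    "dose_m": cond["dose_m"],
                    "detected": detection_call(vals, blank_vals),
                }
            )
    return pd.DataFrame(rows)
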