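"""Candidate-gene nomination from two-replicate FPKM time courses.

The procedure: expression-level and fold-change filters (biotype-specific),
a TSS isolation filter for lncRNAs, per-replicate k-means clustering of
z-scored log10 profiles, automated classification of cluster centroids into
peaking / upregulated / other, and intersection of the peaking-or-upregulated
gene sets between replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .annotation import GeneModel

VALID_BIOTYPES = ("protein_coding", "lncRNA")


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the nomination procedure.

    Expression filters: mean >= 1 FPKM and >= 4-fold change for protein-coding
    genes; mean >= 0.1 FPKM, >= 2-fold and a 1-FPKM peak for lncRNAs. lncRNA
    TSS isolation: no gene body within 5 kb on the same strand nor 50 bp on
    the opposite strand. Profile classification thresholds (z-units) replace
    the original visual inspection and are deliberately explicit.
    """

    min_mean_fpkm: Mapping[str, float] = field(
        default_factory=lambda: {"protein_coding": 1.0, "lncRNA": 0.1}
    )
    min_fold: Mapping[str, float] = field(
        default_factory=lambda: {"protein_coding": 4.0, "lncRNA": 2.0}
    )
    lnc_min_peak_fpkm: float = 1.0
    k_clusters: Mapping[str, int] = field(
        default_factory=lambda: {"protein_coding": 36, "lncRNA": 16}
    )
    same_strand_bp: int = 5000
    opposite_strand_bp: int = 50
    fpkm_log_pseudocount: float = 0.01
    delta_up: float = 1.0
    delta_down: float = 1.0
    max_tol: float = 0.1  # slack for "last timepoint is the maximum"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 1 for f in self.min_fold.values()):
            raise ValueError("fold thresholds must exceed 1")
        if self.same_strand_bp < 0 or self.opposite_strand_bp < 0:
            raise ValueError("isolation windows must be non-negative")


def _timepoint_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in ("gene_id", "biotype")]


def select_expressed(matrix: pd.DataFrame, params: SelectionParams) -> set[str]:
    """Gene ids passing the biotype-specific expression filters.

    Fold change is max/min along the profile, with min clamped to the log
    pseudocount when zero. lncRNAs must additionally reach 1 FPKM in at
    least one timepoint.
    """
    cols = _timepoint_columns(matrix)
    unknown = set(matrix["biotype"]) - set(VALID_BIOTYPES)
    if unknown:
        raise ValueError(f"unknown biotype(s): {sorted(unknown)}")
    vals = matrix[cols].to_numpy(float)
    if (vals < 0).any():
        raise ValueError("FPKM values must be non-negative")
    mean = vals.mean(axis=1)
    vmax = vals.max(axis=1)
    vmin = np.maximum(vals.min(axis=1), params.fpkm_log_pseudocount)
    fold = vmax / vmin

    keep = np.zeros(len(matrix), dtype=bool)
    for bt in VALID_BIOTYPES:
        sel = (matrix["biotype"] == bt).to_numpy()
        ok = (mean >= params.min_mean_fpkm[bt]) & (fold >= params.min_fold[bt])
        if bt == "lncRNA":
            ok &= vmax >= params.lnc_min_peak_fpkm
        keep |= sel & ok
    return set(matrix.loc[keep, "gene_id"])


def lnc_isolation_filter(
    models: Sequence[GeneModel], params: SelectionParams
) -> set[str]:
    """lncRNA ids whose TSS neighbourhood is free of other genes.

    A lncRNA is retained iff no other gene body overlaps the closed window
    [TSS - 5000, TSS + 5000] on the same strand nor [TSS - 50, TSS + 50] on
    the opposite strand.
    """
    retained = set()
    for g in models:
        if g.biotype != "lncRNA":
            continue
        tss = g.tss
        isolated = True
        for other in models:
            if other.gene_id == g.gene_id or other.chrom != g.chrom:
                continue
            w = (
                params.same_strand_bp
                if other.strand == g.strand
                else params.opposite_strand_bp
            )
            # closed window [tss - w, tss + w] vs half-open gene body
            if other.start <= tss + w and other.end > tss - w:
                isolated = False
                break
        if isolated:
            retained.add(g.gene_id)
    return retained


def zscore_profiles(
    matrix: pd.DataFrame, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Per-gene z-score of log10(FPKM + pseudocount) across timepoints.

    Genes with zero variance (z-score undefined) are dropped with a warning.
    """
    cols = _timepoint_columns(matrix)
    logv = np.log10(matrix[cols].to_numpy(float) + pseudocount)
    sd = logv.std(axis=1)
    flat = sd < 1e-12  # numerically constant profiles: z-score undefined
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} constant-profile gene(s) before clustering"
        )
    z = (logv[~flat] - logv[~flat].mean(axis=1, keepdims=True)) / sd[~flat, None]
    return pd.DataFrame(z, index=matrix.loc[~flat, "gene_id"], columns=cols)


def cluster_profiles(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    pseudocount: float = 0.01,
    n_init: int = 10,
) -> tuple[pd.Series, np.ndarray]:
    """k-means over z-scored log10 profiles (fixed seed, >= 10 restarts).

    Returns (per-gene cluster assignment, k x n_timepoints centroid array).
    """
    z = zscore_profiles(matrix, pseudocount)
    if k > len(z):
        raise ValueError(f"k={k} exceeds the {len(z)} clusterable genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels, index=z.index, name="cluster"), km.cluster_centers_


def classify_profiles(
    centroids: np.ndarray,
    timepoints: Sequence[float] | None = None,
    delta_up: float = 1.0,
    delta_down: float = 1.0,
    tol: float = 0.1,
) -> list[str]:
    """Label each cluster centroid as upregulated / peaking / other.

    Upregulated: z(last) - z(first) >= delta_up and the last timepoint is the
    maximum within ``tol``. Peaking: the argmax is internal, with a rise of at
    least ``delta_up`` before the peak and a fall of at least ``delta_down``
    after it.
    """
    labels = []
    for c in np.atleast_2d(centroids):
        imax = int(np.argmax(c))
        if c[-1] - c[0] >= delta_up and c[-1] >= c.max() - tol:
            labels.append("upregulated")
        elif (
            0 < imax < len(c) - 1
            and c[imax] - c[: imax + 1].min() >= delta_up
            and c[imax] - c[imax:].min() >= delta_down
        ):
            labels.append("peaking")
        else:
            labels.append("other")
    return labels


def cluster_report(
    matrix: pd.DataFrame,
    models: Sequence[GeneModel] | None,
    params: SelectionParams,
) -> dict[str, tuple[pd.Series, np.ndarray, list[str]]]:
    """One replicate's filter + per-biotype clustering + centroid labels.

    Returns, per biotype with retained genes, the per-gene cluster
    assignments, the k x timepoints centroid array and the per-cluster
    profile labels. ``models`` may be None to skip the lncRNA isolation
    filter (e.g. when only protein-coding genes are analysed).
    """
    expressed = select_expressed(matrix, params)
    if models is not None and (matrix["biotype"] == "lncRNA").any():
        isolated = lnc_isolation_filter(models, params)
        lnc_ids = set(matrix.loc[matrix["biotype"] == "lncRNA", "gene_id"])
        expressed -= lnc_ids - isolated
    out = {}
    for bt in VALID_BIOTYPES:
        sub = matrix[(matrix["biotype"] == bt) & matrix["gene_id"].isin(expressed)]
        if sub.empty:
            continue
        k = min(params.k_clusters[bt], len(sub))
        assign, centroids = cluster_profiles(
            sub, k, seed=params.seed, pseudocount=params.fpkm_log_pseudocount
        )
        labels = classify_profiles(
            centroids,
            delta_up=params.delta_up,
            delta_down=params.delta_down,
            tol=params.max_tol,
        )
        out[bt] = (assign, centroids, labels)
    return out


def label_genes(
    matrix: pd.DataFrame,
    models: Sequence[GeneModel] | None,
    params: SelectionParams,
) -> pd.Series:
    """One replicate's full pipeline: gene_id -> profile label over the
    genes retained by the filters."""
    out: dict[str, str] = {}
    for bt, (assign, _, labels) in cluster_report(matrix, models, params).items():
        for gene, cl in assign.items():
            out[gene] = labels[cl]
    return pd.Series(out, name="label")


def finalize_candidates(
    labels_rep1: pd.Series, labels_rep2: pd.Series, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Intersect peaking-or-upregulated genes between replicates.

    Returns a table gene_id / biotype / label_rep1 / label_rep2 restricted to
    genes selected in both replicates; empty (with a warning) if none.
    """
    wanted = {"peaking", "upregulated"}
    s1 = {g for g, l in labels_rep1.items() if l in wanted}
    s2 = {g for g, l in labels_rep2.items() if l in wanted}
    both = s1 & s2
    if not both:
        warnings.warn("no gene selected in both replicates")
    bt = matrix.set_index("gene_id")["biotype"]
    rows = sorted(both)
    return pd.DataFrame(
        {
            "gene_id": rows,
            "biotype": [bt.get(g, "") for g in rows],
            "label_rep1": [labels_rep1[g] for g in rows],
            "label_rep2": [labels_rep2[g] for g in rows],
        }
    )


def select_targets(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    models: Sequence[GeneModel] | None = None,
    params: SelectionParams | None = None,
) -> pd.DataFrame:
    """End-to-end nomination from two replicate matrices."""
    params = params or SelectionParams()
    l1 = label_genes(rep1, models, params)
    l2 = label_genes(rep2, models, params)
    return finalize_candidates(l1, l2, rep1)
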