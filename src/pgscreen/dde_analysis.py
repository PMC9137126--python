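"""Differentiation-delaying effect (DDE) analysis and candidate calling.

DDE is the per-construct ratio of sequencing counts in the FACS-sorted
delayed fraction over the differentiated fraction, computed independently per
replicate at T3 and T6. Constructs need >= 5 counts in the replicate's T0
sample to enter the analysis; hits are constructs strictly above the 90th
percentile of their (replicate, timepoint) stratum; a target is called at a
timepoint when at least two *identical* constructs are hits in both
replicates, and the final call unions the two timepoints.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_quant import GuideCountMatrix

TIMEPOINTS = ("T3", "T6")


def _t0_sample(samples: pd.DataFrame, replicate: int) -> str:
    t0 = samples[samples["timepoint"] == "T0"]
    if t0.empty:
        raise ValueError("no T0/initial sample in the sample sheet")
    own = t0[t0["replicate"] == replicate]
    # a single pooled T0 may be applied to both replicates
    return (own if len(own) else t0).iloc[0]["sample_id"]


def t0_filter(counts: GuideCountMatrix, min_t0: int = 5) -> dict[int, set[str]]:
    """Constructs with at least ``min_t0`` counts in each replicate's own T0."""
    out = {}
    for rep in sorted(counts.samples["replicate"].unique()):
        if rep == 0:
            continue
        sid = _t0_sample(counts.samples, rep)
        col = counts.counts[sid]
        out[int(rep)] = set(col.index[col >= min_t0])
    return out


def compute_dde(
    counts: GuideCountMatrix,
    retained: Mapping[int, set[str]] | None = None,
    zero_policy: str = "raw",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-construct DDE table over every (replicate, timepoint) stratum.

    ``zero_policy="raw"`` reports del/0 as +inf (excluded later from
    percentile computation but still reported and always a hit);
    ``"pseudocount"`` adds ``pseudocount`` to both numerator and denominator.
    The policy is recorded in ``df.attrs["zero_policy"]``.
    """
    if zero_policy not in ("raw", "pseudocount"):
        raise ValueError("zero_policy must be 'raw' or 'pseudocount'")
    if retained is None:
        retained = t0_filter(counts)
    meta = counts.samples.set_index("sample_id")
    rows = []
    for tp in TIMEPOINTS:
        for rep in sorted(retained):
            sel = meta[(meta["timepoint"] == tp) & (meta["replicate"] == rep)]
            try:
                s_del = sel[sel["fraction"] == "delayed"].index[0]
                s_dif = sel[sel["fraction"] == "differentiated"].index[0]
            except IndexError:
                raise ValueError(
                    f"missing delayed/differentiated sample for {tp} replicate {rep}"
                ) from None
            keep = sorted(retained[rep])
            dele = counts.counts.loc[keep, s_del].to_numpy()
            dif = counts.counts.loc[keep, s_dif].to_numpy()
            if (dele < 0).any() or (dif < 0).any():
                raise ValueError("counts must be non-negative")
            if zero_policy == "pseudocount":
                dde = (dele + pseudocount) / (dif + pseudocount)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    dde = np.where(dif > 0, dele / np.maximum(dif, 1), np.inf)
                    dde = np.where((dif == 0) & (dele == 0), np.inf, dde)
            rows.append(
                pd.DataFrame(
                    {
                        "construct_id": keep,
                        "replicate": rep,
                        "timepoint": tp,
                        "del_count": dele,
                        "dif_count": dif,
                        "dde": dde,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.attrs["zero_policy"] = zero_policy
    return df


def decile_hits(
    dde_table: pd.DataFrame, pct: float = 90.0, min_finite: int = 10
) -> dict[tuple[int, str], tuple[float, set[str]]]:
    """Per-stratum percentile threshold and hit set.

    The threshold is the linear-interpolation ``pct`` percentile of the
    stratum's finite DDE values; hits are constructs strictly above it, plus
    every +inf construct. Strata with fewer than ``min_finite`` finite values
    are skipped with a warning.
    """
    out: dict[tuple[int, str], tuple[float, set[str]]] = {}
    for (rep, tp), sub in dde_table.groupby(["replicate", "timepoint"]):
        finite = sub.loc[np.isfinite(sub["dde"]), "dde"].to_numpy()
        if len(finite) < min_finite:
            warnings.warn(
                f"stratum (rep {rep}, {tp}): only {len(finite)} finite DDE values, skipped"
            )
            continue
        thr = float(np.percentile(finite, pct))
        hit = sub.loc[(sub["dde"] > thr) | ~np.isfinite(sub["dde"]), "construct_id"]
        out[(int(rep), tp)] = (thr, set(hit))
    return out


def replicate_mean_thresholds(
    dde_table: pd.DataFrame, pct: float = 90.0
) -> dict[str, float]:
    """Percentile thresholds of replicate-mean DDE per timepoint (the scale on
    which the screen's headline decile cut-offs are quoted)."""
    out = {}
    for tp, sub in dde_table.groupby("timepoint"):
        mean = sub.groupby("construct_id")["dde"].mean()
        finite = mean[np.isfinite(mean)]
        out[str(tp)] = float(np.percentile(finite, pct))
    return out


def _construct_targets(library: pd.DataFrame) -> dict[str, str]:
    return dict(zip(library["construct_id"].astype(str), library["target_id"].astype(str)))


def _record_targets(record_id: str, c2t: Mapping[str, str]) -> set[str]:
    # merged duplicate records carry '|'-joined source construct ids
    out = set()
    for cid in str(record_id).split("|"):
        if cid in c2t:
            out.add(c2t[cid])
    return out


def call_candidates(
    hits: Mapping[tuple[int, str], tuple[float, set[str]]],
    library: pd.DataFrame,
    min_designs: int = 2,
    timepoints: Sequence[str] = TIMEPOINTS,
    replicates: Sequence[int] = (1, 2),
    mode: str = "union",
) -> pd.DataFrame:
    """Target-level calls from per-stratum hit sets.

    A target is called at timepoint t when the *same* >= ``min_designs``
    constructs are hits in every replicate at t. ``mode="union"`` (default)
    makes the final call the union over timepoints; ``"intersection"``
    requires every timepoint.
    """
    c2t = _construct_targets(library)
    known_targets = sorted(set(c2t.values()))
    cls_of = dict(zip(library["target_id"].astype(str), library["class"].astype(str)))

    per_tp_shared: dict[str, dict[str, set[str]]] = {}
    per_stratum_counts: dict[tuple[int, str], dict[str, int]] = {}
    for tp in timepoints:
        shared: dict[str, set[str]] = {t: None for t in known_targets}  # type: ignore[misc]
        for rep in replicates:
            if (rep, tp) not in hits:
                raise ValueError(f"hits missing for stratum (rep {rep}, {tp})")
            _, hitset = hits[(rep, tp)]
            per_target: dict[str, set[str]] = {t: set() for t in known_targets}
            for rid in hitset:
                for t in _record_targets(rid, c2t):
                    per_target[t].add(rid)
            per_stratum_counts[(rep, tp)] = {t: len(v) for t, v in per_target.items()}
            for t in known_targets:
                shared[t] = (
                    per_target[t] if shared[t] is None else shared[t] & per_target[t]
                )
        per_tp_shared[tp] = {t: (v or set()) for t, v in shared.items()}

    rows = []
    for t in known_targets:
        called_at = [
            tp for tp in timepoints if len(per_tp_shared[tp][t]) >= min_designs
        ]
        final = bool(called_at) if mode == "union" else set(called_at) == set(timepoints)
        row = {"target_id": t, "class": cls_of.get(t, "")}
        for (rep, tp), cnt in per_stratum_counts.items():
            row[f"hits_{tp}_rep{rep}"] = cnt[t]
        for tp in timepoints:
            row[f"shared_hits_{tp}"] = len(per_tp_shared[tp][t])
        row["called_at"] = ",".join(called_at)
        row["final_call"] = final
        rows.append(row)
    return pd.DataFrame(rows)


def control_concordance(
    dde_table: pd.DataFrame,
    control_sets: Mapping[str, Sequence[str]],
    min_constructs: int = 3,
) -> pd.DataFrame:
    """Between-replicate Spearman correlation of DDE within control sets.

    One row per (set, timepoint) with the correlation over constructs present
    in both replicates (ties and +inf handled by ranks) and the per-replicate
    median DDE. Sets with fewer than ``min_constructs`` paired constructs get
    NaN correlation.
    """
    rows = []
    for name, ids in control_sets.items():
        ids = set(map(str, ids))
        sub = dde_table[dde_table["construct_id"].astype(str).isin(ids)]
        for tp, tps in sub.groupby("timepoint"):
            wide = tps.pivot_table(
                index="construct_id", columns="replicate", values="dde", aggfunc="first"
            )
            wide = wide.dropna()
            n = len(wide)
            if n >= min_constructs and wide.shape[1] >= 2:
                rho = float(stats.spearmanr(wide.iloc[:, 0], wide.iloc[:, 1]).statistic)
            else:
                rho = float("nan")
            med = wide.replace(np.inf, np.nan).median()
            rows.append(
                {
                    "set": name,
                    "timepoint": tp,
                    "n": n,
                    "spearman_rho": rho,
                    "median_dde_rep1": float(med.iloc[0]) if len(med) else np.nan,
                    "median_dde_rep2": float(med.iloc[1]) if len(med) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def qc_scatter(dde_table: pd.DataFrame, control_sets, path) -> None:
    """Replicate-vs-replicate DDE scatter per control set (QC figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sets = list(control_sets)
    tps = sorted(dde_table["timepoint"].unique())
    fig, axes = plt.subplots(
        len(tps), len(sets), figsize=(4 * len(sets), 4 * len(tps)), squeeze=False
    )
    for i, tp in enumerate(tps):
        for j, name in enumerate(sets):
            ids = set(map(str, control_sets[name]))
            sub = dde_table[
                (dde_table["timepoint"] == tp)
                & dde_table["construct_id"].astype(str).isin(ids)
            ]
            wide = sub.pivot_table(
                index="construct_id", columns="replicate", values="dde", aggfunc="first"
            ).replace(np.inf, np.nan).dropna()
            ax = axes[i][j]
            if len(wide):
                ax.loglog(wide.iloc[:, 0] + 1e-3, wide.iloc[:, 1] + 1e-3, ".", ms=4)
            ax.set_title(f"{name} {tp}")
            ax.set_xlabel("DDE rep1")
            ax.set_ylabel("DDE rep2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_dde_analysis(
    counts: GuideCountMatrix,
    library: pd.DataFrame,
    min_t0: int = 5,
    pct: float = 90.0,
    min_designs: int = 2,
    zero_policy: str = "raw",
    mode: str = "union",
) -> dict:
    """Full analysis: T0 filter -> DDE -> decile hits -> candidate calls."""
    retained = t0_filter(counts, min_t0)
    dde = compute_dde(counts, retained, zero_policy=zero_policy)
    hits = decile_hits(dde, pct)
    calls = call_candidates(hits, library, min_designs=min_designs, mode=mode)
    return {
        "retained": retained,
        "dde": dde,
        "hits": hits,
        "thresholds": {k: v[0] for k, v in hits.items()},
        "mean_thresholds": replicate_mean_thresholds(dde, pct),
        "calls": calls,
    }
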