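"""Repair-pathway balance from scar count tables.

For the LBR2 target the signature outcomes are a 7 bp deletion flanked by
3 bp microhomologies (MMEJ) and a +1 insertion (NHEJ); the balance statistic
is MMEJ/(MMEJ+NHEJ). Wild-type reads are excluded from every indel
denominator — an intact sequence can be uncut or perfectly repaired and is
not informative about pathway usage. NHEJ membership of an indel class can
also be established empirically: classes whose ratio drops significantly
under DNA-PK inhibition (one-sided Wilcoxon rank-sum, BH-adjusted) are NHEJ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineParams

log = logging.getLogger(__name__)


@dataclass
class PathwayRules:
    """Signature indel classes per pathway.

    ``mmej_signatures`` pairs an indel size with a required microhomology
    length (used only when scar details are available; None accepts any).
    Defaults carry the LBR2 signatures: -7/MH3 for MMEJ, +1 for NHEJ, with
    the additional known MMEJ deletions -14/MH3 and -22/MH6.
    """

    mmej_signatures: list[tuple[int, Optional[int]]] = field(
        default_factory=lambda: [(-7, 3)]
    )
    nhej_signatures: list[int] = field(default_factory=lambda: [1])
    extra_mmej_signatures: list[tuple[int, Optional[int]]] = field(
        default_factory=lambda: [(-14, 3), (-22, 6)]
    )

    def __post_init__(self) -> None:
        mmej_sizes = {s for s, _ in self.mmej_signatures}
        if mmej_sizes & set(self.nhej_signatures):
            raise ValueError("MMEJ and NHEJ signature sizes overlap")


def not_clear_fraction(counts: pd.DataFrame) -> float:
    total = counts["reads"].sum()
    if total == 0:
        return 0.0
    return float(counts.loc[counts["call"] == "not_clear", "reads"].sum() / total)


def filter_not_clear(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop not_clear rows; the removed read fraction is logged."""
    frac = not_clear_fraction(counts)
    removed = int(counts.loc[counts["call"] == "not_clear", "reads"].sum())
    log.info("filter_not_clear: removed %d reads (%.1f%%)", removed, 100 * frac)
    return counts[counts["call"] != "not_clear"].reset_index(drop=True)


def estimate_cells(counts: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    """Abundance-based per-barcode cell estimate.

    estimated_cells = (barcode reads / total reads) * total_cells_assumed *
    mean_barcodes_per_cell; with the default pool assumptions (100,000 cells,
    6 barcodes/cell) a barcode holding every read maps to 600,000 cells.
    A barcode is kept when estimated_cells >= min_cells. Estimates sum to
    total_cells_assumed * mean_barcodes_per_cell by construction.
    """
    total = counts["reads"].sum()
    if total == 0:
        raise ValueError("estimate_cells: scar count table holds no reads")
    per_bc = counts.groupby("barcode")["reads"].sum()
    scale = params.total_cells_assumed * params.mean_barcodes_per_cell
    est = per_bc / total * scale
    return pd.DataFrame(
        {
            "barcode": est.index,
            "estimated_cells": est.to_numpy(float),
            "kept": (est >= params.min_cells).to_numpy(),
        }
    ).reset_index(drop=True)


def normalize_replicates(replicate_counts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Library-size normalization and replicate averaging.

    Each replicate is scaled to counts-per-million of its library total,
    scaled values are averaged per (barcode, call, indel_size) — a class
    absent from a replicate contributes 0 — and per-barcode proportions are
    computed on the averages. Replicates with zero total are excluded with
    a warning.
    """
    usable = []
    for i, rep in enumerate(replicate_counts):
        total = rep["reads"].sum()
        if total == 0:
            log.warning("normalize_replicates: replicate %d has zero total; excluded", i)
            continue
        cpm = rep.copy()
        cpm["cpm"] = cpm["reads"] / total * 1e6
        usable.append(cpm[["barcode", "call", "indel_size", "cpm"]])
    if not usable:
        raise ValueError("normalize_replicates: no usable replicates")
    n = len(usable)
    stacked = pd.concat(usable, ignore_index=True)
    mean = (
        stacked.groupby(["barcode", "call", "indel_size"], dropna=False)["cpm"]
        .sum()
        .div(n)
        .rename("mean_cpm")
        .reset_index()
    )
    per_bc_total = mean.groupby("barcode")["mean_cpm"].transform("sum")
    mean["proportion"] = mean["mean_cpm"] / per_bc_total
    return mean


def _is_indel(df: pd.DataFrame) -> pd.Series:
    size = df["indel_size"]
    return (df["call"] != "wt") & size.notna() & (size != 0)


def classify_pathways(
    counts: pd.DataFrame,
    rules: Optional[PathwayRules] = None,
    details: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-barcode MMEJ/NHEJ/other read counts and the balance statistic.

    In count mode, classification is by indel size alone. When a scar-detail
    table (from the alignment mode) is supplied, MMEJ signatures additionally
    require the matching microhomology length, so e.g. a -7 deletion without
    flanking homology is routed to "other". Wild-type reads (call "wt" or
    indel size 0) are excluded from all denominators. mmej_fraction =
    MMEJ/(MMEJ+NHEJ), NaN when that denominator is zero.
    """
    rules = rules or PathwayRules()
    mmej_rules = list(rules.mmej_signatures) + list(rules.extra_mmej_signatures)
    mmej_sizes = {s for s, _ in mmej_rules}
    mh_required = {s: mh for s, mh in mmej_rules}
    nhej_sizes = set(rules.nhej_signatures)

    df = counts.copy()
    indel = _is_indel(df)
    size = df["indel_size"]

    is_mmej = indel & size.isin(mmej_sizes)
    if details is not None and not details.empty:
        # fraction of detailed reads per (barcode, size) with the required MH
        det = details[details["indel_size"].notna()].copy()
        det["indel_size"] = det["indel_size"].astype(int)
        mh_ok = []
        for s, mh in mh_required.items():
            sub = det[det["indel_size"] == s]
            if mh is None or sub.empty:
                continue
            ok = sub.groupby("barcode")["microhomology_len"].agg(
                lambda v: (v == mh).mean() >= 0.5
            )
            mh_ok.append((s, ok))
        for s, ok in mh_ok:
            bad_bc = set(ok[~ok].index)
            seen_bc = set(ok.index)
            mask = is_mmej & (size == s) & (
                df["barcode"].isin(bad_bc) | ~df["barcode"].isin(seen_bc)
            )
            is_mmej = is_mmej & ~mask
    is_nhej = indel & size.isin(nhej_sizes) & ~is_mmej

    df["_class"] = "excluded"
    df.loc[indel, "_class"] = "other"
    df.loc[is_mmej, "_class"] = "mmej"
    df.loc[is_nhej, "_class"] = "nhej"

    columns = [
        "barcode", "total_reads", "total_indel_reads",
        "mmej_count", "nhej_count", "other_count", "mmej_fraction",
    ]
    if df.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for barcode, grp in df.groupby("barcode"):
        mmej = int(grp.loc[grp["_class"] == "mmej", "reads"].sum())
        nhej = int(grp.loc[grp["_class"] == "nhej", "reads"].sum())
        other = int(grp.loc[grp["_class"] == "other", "reads"].sum())
        total_indel = mmej + nhej + other
        denom = mmej + nhej
        rows.append(
            {
                "barcode": barcode,
                "total_reads": int(grp["reads"].sum()),
                "total_indel_reads": total_indel,
                "mmej_count": mmej,
                "nhej_count": nhej,
                "other_count": other,
                "mmej_fraction": mmej / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def classify_nhej_by_inhibitor(
    dmso: pd.DataFrame,
    inhibited: pd.DataFrame,
    params: PipelineParams,
    min_values: int = 3,
) -> pd.DataFrame:
    """Label indel classes as NHEJ from inhibitor response.

    ``dmso`` and ``inhibited`` hold one row per observation (per barcode or
    per replicate) with columns ``indel`` (class label) and ``ratio`` (the
    class's proportion of reads). Classes with pooled DMSO mean ratio >=
    dmso_min_ratio are tested with a one-sided Wilcoxon rank-sum test
    (inhibited < DMSO); p-values are Benjamini-Hochberg adjusted across the
    tested classes and a class is NHEJ iff adjusted p < alpha_adj. Classes
    with fewer than ``min_values`` observations in either condition are
    reported as untested, never guessed.
    """
    labels = sorted(set(dmso["indel"]) | set(inhibited["indel"]), key=str)
    recs = []
    for lab in labels:
        d = dmso.loc[dmso["indel"] == lab, "ratio"].to_numpy(float)
        m = inhibited.loc[inhibited["indel"] == lab, "ratio"].to_numpy(float)
        mean_dmso = float(d.mean()) if d.size else 0.0
        rec = {
            "indel": lab,
            "dmso_mean_ratio": mean_dmso,
            "n_dmso": d.size,
            "n_inhibited": m.size,
            "tested": False,
            "p_value": np.nan,
            "p_adj": np.nan,
            "nhej": False,
        }
        if mean_dmso >= params.dmso_min_ratio and d.size >= min_values and m.size >= min_values:
            p = stats.mannwhitneyu(m, d, alternative="less").pvalue
            rec.update(tested=True, p_value=float(p))
        recs.append(rec)
    out = pd.DataFrame(recs)
    tested = out["tested"].to_numpy()
    if tested.any():
        rej, p_adj, _, _ = multipletests(
            out.loc[tested, "p_value"], alpha=params.alpha_adj, method="fdr_bh"
        )
        out.loc[tested, "p_adj"] = p_adj
        out.loc[tested, "nhej"] = p_adj < params.alpha_adj
    return out


def summarize_pool(
    pathway: pd.DataFrame, integrations: pd.DataFrame
) -> pd.DataFrame:
    """Join pass-filtered integration calls with per-barcode pathway summaries.

    Inner join on barcode; barcodes present in only one table are logged.
    """
    passing = integrations[integrations["status"] == "pass"]
    joined = passing.merge(pathway, on="barcode", how="inner")
    only_map = set(passing["barcode"]) - set(pathway["barcode"])
    only_scar = set(pathway["barcode"]) - set(passing["barcode"])
    if only_map or only_scar:
        log.info(
            "summarize_pool: %d barcodes mapped-only, %d scar-only",
            len(only_map), len(only_scar),
        )
    return joined.reset_index(drop=True)
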