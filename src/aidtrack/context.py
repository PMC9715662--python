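"""Genomic distribution analyses of tagged mutations.

Covers the spatial profile of c-AID activity: mutation load per chromatin
domain class (normalized by domain length), strand-oriented profiles around
transcription start sites, overlap with R-loop (G-skew) regions, rainfall
(inter-mutation) distances, and the per-tumor-type correlation between a
gene's c-AID mutation count and its own expression.

Interval containment uses half-open [start, end) intervals throughout and is
implemented with sorted-array bisection (the domain/region sets are
non-overlapping within a contig).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

DOMAIN_CLASSES = ("heterochromatin", "inactive", "repressed", "low-active", "active")


def _assign_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Index of the containing interval for each position, -1 when outside.

    Intervals must be sorted and non-overlapping within the arrays given.
    """
    idx = np.searchsorted(starts, pos, side="right") - 1
    idx = np.clip(idx, 0, max(len(starts) - 1, 0))
    inside = (len(starts) > 0) & (pos >= starts[idx]) & (pos < ends[idx])
    return np.where(inside, idx, -1)


def label_in_regions(mutations: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean per-mutation label: inside any region interval (half-open)."""
    out = np.zeros(len(mutations), dtype=bool)
    pos_all = mutations["pos"].to_numpy(int)
    for contig, idx in mutations.groupby("contig").indices.items():
        sub = regions[regions["contig"] == contig].sort_values("start")
        if sub.empty:
            continue
        hit = _assign_intervals(pos_all[idx], sub["start"].to_numpy(), sub["end"].to_numpy())
        out[idx] = hit >= 0
    return out


# ---------------------------------------------------------------------------
# TAD / chromatin-domain load

def domain_load(
    mutations: pd.DataFrame, domains: pd.DataFrame, bin_size: int = 25_000
) -> dict:
    """Mutation load per chromatin-domain class, length-normalized.

    Mutations are first counted in ``bin_size`` non-overlapping windows;
    each window is assigned to the domain covering the majority of it (ties
    to the leftward domain).  Per-class load = total mutations in the
    class's windows / total class length; the active/inactive ratio uses the
    "active" and "inactive" classes.  Windows outside every domain
    contribute to ``unassigned``.
    """
    bad = set(domains["class"]) - set(DOMAIN_CLASSES)
    if bad:
        raise ValueError(f"unknown domain class(es): {sorted(bad)}")
    counts = {c: 0 for c in DOMAIN_CLASSES}
    lengths = (
        domains.assign(length=domains["end"] - domains["start"])
        .groupby("class")["length"].sum().reindex(DOMAIN_CLASSES, fill_value=0)
    )
    unassigned = 0
    per_bin_rows = []
    pos_all = mutations["pos"].to_numpy(int)
    for contig, idx in mutations.groupby("contig").indices.items():
        dom = domains[domains["contig"] == contig].sort_values("start").reset_index(drop=True)
        pos = pos_all[idx]
        bins = pos // bin_size
        uniq, bin_counts = np.unique(bins, return_counts=True)
        for b, n in zip(uniq, bin_counts):
            lo, hi = b * bin_size, (b + 1) * bin_size
            if dom.empty:
                unassigned += int(n)
                continue
            overlap = np.minimum(dom["end"], hi) - np.maximum(dom["start"], lo)
            overlap = np.maximum(overlap.to_numpy(), 0)
            if overlap.max() == 0:
                unassigned += int(n)
                continue
            winner = int(np.argmax(overlap))  # argmax takes the leftward domain on ties
            cls = dom.loc[winner, "class"]
            counts[cls] += int(n)
            per_bin_rows.append({"contig": contig, "start": lo, "end": hi,
                                 "class": cls, "count": int(n)})
    loads = {c: counts[c] / lengths[c] if lengths[c] > 0 else np.nan for c in DOMAIN_CLASSES}
    active, inactive = loads["active"], loads["inactive"]
    ratio = np.inf if inactive == 0 else active / inactive
    return {
        "counts": counts,
        "class_lengths": lengths.to_dict(),
        "loads": loads,
        "active_inactive_ratio": ratio,
        "unassigned": unassigned,
        "per_bin": pd.DataFrame(per_bin_rows),
    }


# ---------------------------------------------------------------------------
# TSS-centered profiles

def tss_profile(
    mutations: pd.DataFrame,
    genes: pd.DataFrame,
    span: int = 500_000,
    bin_size: int = 10_000,
    equal_gene_weight: bool = True,
) -> dict:
    """Strand-oriented mutation profile around transcription start sites.

    For a plus-strand gene the TSS is its ``start``; for a minus-strand gene
    its ``end`` (and the axis is flipped so positive bins always point
    downstream of transcription).  Bin 0 is centered on the TSS; with the
    defaults there are 2K+1 = 101 bins of 10 kb covering +-500 kb.  Loads
    are mutation counts per bin divided by the number of contributing genes
    of that strand class (or raw pooled counts when ``equal_gene_weight`` is
    False).  Also returns per-gene loads at bin 0 and at +-K for rank-sum
    contrasts.
    """
    K = span // bin_size
    bins = np.arange(-K, K + 1)
    profiles = {s: np.zeros(2 * K + 1) for s in "+-"}
    n_genes = {s: 0 for s in "+-"}
    per_gene_bins = {s: {b: [] for b in (-K, 0, K)} for s in "+-"}
    pos_all = mutations["pos"].to_numpy(int)
    by_contig = {c: pos_all[idx] for c, idx in mutations.groupby("contig").indices.items()}

    for _, gene in genes.iterrows():
        strand = gene["strand"]
        tss = int(gene["start"]) if strand == "+" else int(gene["end"])
        pos = by_contig.get(gene["contig"])
        counts = np.zeros(2 * K + 1)
        if pos is not None:
            d = pos - tss
            if strand == "-":
                d = -d
            b = np.floor((d + bin_size / 2) / bin_size).astype(int)
            ok = (b >= -K) & (b <= K)
            if ok.any():
                counts = np.bincount(b[ok] + K, minlength=2 * K + 1).astype(float)
        profiles[strand] += counts
        n_genes[strand] += 1
        for b in (-K, 0, K):
            per_gene_bins[strand][b].append(counts[b + K])

    loads = {}
    for s in "+-":
        loads[s] = profiles[s] / n_genes[s] if (equal_gene_weight and n_genes[s]) else profiles[s]
    contrasts = {}
    for s in "+-":
        center = np.asarray(per_gene_bins[s][0])
        for b in (-K, K):
            flank_loads = np.asarray(per_gene_bins[s][b])
            if center.size and flank_loads.size and (center.std() + flank_loads.std()) > 0:
                stat, p = mannwhitneyu(center, flank_loads, alternative="two-sided")
            else:
                stat, p = np.nan, np.nan
            contrasts[(s, b)] = {"statistic": stat, "p": p}
    return {"bins": bins, "bin_size": bin_size, "loads": loads,
            "n_genes": n_genes, "contrasts": contrasts}


# ---------------------------------------------------------------------------
# R-loop overlap

def region_overlap_test(
    mutations: pd.DataFrame, regions: pd.DataFrame, process_col: str = "process"
) -> dict:
    """In/out-region labeling per mutational process plus pairwise Fisher tests.

    Each mutation is labeled "in" when its position falls inside a region
    interval.  For every pair of process labels a two-sided Fisher exact
    test compares [[inA, outA], [inB, outB]].
    """
    labels = mutations[process_col].astype(str)
    processes = sorted(labels.unique())
    if len(processes) < 2:
        raise ValueError("need at least two process labels")
    inside = label_in_regions(mutations, regions)
    counts = {}
    for p in processes:
        sel = (labels == p).to_numpy()
        counts[p] = (int(inside[sel].sum()), int((~inside[sel]).sum()))
    tests = {}
    for a, b in combinations(processes, 2):
        if counts[a][0] + counts[a][1] == 0 or counts[b][0] + counts[b][1] == 0:
            continue
        table = [list(counts[a]), list(counts[b])]
        orv, p = fisher_exact(table, alternative="two-sided")
        tests[(a, b)] = {"odds_ratio": orv, "p": p, "table": table}
    return {"counts": counts, "tests": tests, "in_labels": inside}


def fisher_in_out(in_a: int, out_a: int, in_b: int, out_b: int) -> float:
    """Two-sided Fisher p for two processes' in/out-region counts."""
    return float(fisher_exact([[in_a, out_a], [in_b, out_b]])[1])


# ---------------------------------------------------------------------------
# rainfall / inter-mutation distance

def intermutation_distance(mutations: pd.DataFrame, density_window: int = 1_000_000) -> dict:
    """Distances to the previous mutation on the same contig, plus per-Mb density.

    The first mutation of each contig has no distance.  Output dataframe
    keeps the sorted mutation order with a ``dist`` column (NaN for firsts).
    """
    df = mutations.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    dist = df.groupby("contig")["pos"].diff()
    df["dist"] = dist
    dens_rows = []
    for contig, sub in df.groupby("contig"):
        pos = sub["pos"].to_numpy(int)
        if pos.size == 0:
            continue
        edges = np.arange(0, pos.max() + density_window + 1, density_window)
        counts = np.histogram(pos, bins=edges)[0]
        for s, c in zip(edges[:-1], counts):
            dens_rows.append({"contig": contig, "start": int(s),
                              "end": int(s + density_window), "count": int(c)})
    return {"distances": df, "density": pd.DataFrame(dens_rows)}


# ---------------------------------------------------------------------------
# expression association

def expression_association(
    aid_counts: pd.DataFrame,
    expression: pd.DataFrame,
    tumor_types: pd.Series | None = None,
    alpha: float = 0.05,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Spearman association of per-gene c-AID counts with the gene's expression.

    ``aid_counts`` and ``expression`` are genes x samples frames on the same
    axes; ``tumor_types`` maps sample -> tumor type (a single pooled type
    when None).  Within each tumor type and gene, Spearman rho between the
    per-sample AID count and expression; BH adjustment within tumor type;
    a gene is associated when adjusted p < alpha and rho > 0.  Genes with a
    constant vector on either side are skipped and reported with NaN rho.
    """
    common = [s for s in aid_counts.columns if s in expression.columns]
    if not common:
        raise ValueError("no shared samples between counts and expression")
    if tumor_types is None:
        tumor_types = pd.Series("all", index=pd.Index(common))
    rows = []
    for ttype in sorted(tumor_types.loc[common].unique()):
        cols = [s for s in common if tumor_types[s] == ttype]
        if len(cols) < min_samples:
            continue
        for gene in aid_counts.index:
            if gene not in expression.index:
                continue
            x = aid_counts.loc[gene, cols].to_numpy(float)
            y = expression.loc[gene, cols].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_samples:
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rows.append({"tumor_type": ttype, "gene": gene, "rho": np.nan,
                             "p": np.nan, "n": int(ok.sum())})
                continue
            rho, p = spearmanr(x[ok], y[ok])
            rows.append({"tumor_type": ttype, "gene": gene, "rho": float(rho),
                         "p": float(p), "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], associated=[])
    out["q"] = np.nan
    for ttype, idx in out.groupby("tumor_type").groups.items():
        p = out.loc[idx, "p"]
        ok = p.notna()
        if ok.any():
            out.loc[p[ok].index, "q"] = multipletests(p[ok], method="fdr_bh")[1]
    out["associated"] = (out["q"] < alpha) & (out["rho"] > 0)
    return out
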