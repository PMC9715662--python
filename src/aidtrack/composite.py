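"""Composite-mutation detection and AID-composite enrichment statistics.

A composite mutation is two or more nonsynonymous somatic mutations hitting
the same gene in the same tumor sample.  This module detects composites,
builds a permutation null for the number of composite-carrying samples,
models the expected AID-composite count per gene with negative-binomial
regression over genomic covariates, tests genes (one-sided binomial) and
residues (right-sided Fisher) for AID-composite enrichment with BH-FDR at
q < 0.01, computes hotspot-utilization curves, and orders composite pairs
in molecular time via clonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest, fisher_exact
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

#: MAF variant classifications counted as nonsynonymous
NONSYNONYMOUS = {
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Splice_Site", "Translation_Start_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
}


def _nonsyn_mask(variants: pd.DataFrame) -> pd.Series:
    if "classification" not in variants.columns or variants["classification"].isna().all():
        return pd.Series(True, index=variants.index)
    return variants["classification"].isin(NONSYNONYMOUS)


# ---------------------------------------------------------------------------
# detection

def detect_composites(variants: pd.DataFrame, gene_classes: pd.Series | None = None) -> dict:
    """Composite events: (sample, gene) pairs with >=2 nonsynonymous SNVs.

    Returns the event table (one row per event, with member indices, an
    ``aid_composite`` flag set when any member is AID-flagged) and summary
    rates per gene class when ``gene_classes`` (gene -> oncogene/TSG) is
    given.
    """
    v = variants[_nonsyn_mask(variants) & variants["gene"].notna()]
    rows = []
    for (sample, gene), idx in v.groupby(["sample", "gene"]).groups.items():
        if len(idx) < 2:
            continue
        members = v.loc[idx]
        rows.append({
            "sample": sample,
            "gene": gene,
            "n_mutations": len(idx),
            "member_index": list(idx),
            "aid_composite": bool(members.get("aid", pd.Series(False, index=idx)).any()),
            "residues": [r if pd.notna(r) else None for r in members.get(
                "protein_pos", pd.Series(np.nan, index=idx))],
        })
    events = pd.DataFrame(rows, columns=[
        "sample", "gene", "n_mutations", "member_index", "aid_composite", "residues"])
    summary = {"n_events": len(events),
               "n_samples_with_composite": events["sample"].nunique() if len(events) else 0}
    if gene_classes is not None and len(events):
        cls = events["gene"].map(gene_classes)
        per_class = events.groupby(cls.fillna("unclassified")).size()
        gene_totals = gene_classes.value_counts()
        summary["events_per_class"] = per_class.to_dict()
        summary["rate_per_gene_in_class"] = {
            c: per_class.get(c, 0) / gene_totals[c] for c in gene_totals.index}
    return {"events": events, "summary": summary}


# ---------------------------------------------------------------------------
# permutation null

@dataclass
class PermutationNull:
    observed: int          # n_pos: samples carrying >=2 same-gene mutations
    replicates: np.ndarray  # n_i per permutation
    p_value: float          # add-one convention (1 + #{n_i >= n_pos}) / (N + 1)


def _n_composite_samples(samples: np.ndarray, genes: np.ndarray) -> int:
    pairs = pd.MultiIndex.from_arrays([samples, genes])
    dup = pairs[pairs.duplicated()]
    return len(set(d[0] for d in dup))


def permutation_expected(
    variants: pd.DataFrame, n_perm: int = 10_000, seed: int = 0,
    shuffle: str = "gene",
) -> PermutationNull:
    """Permutation null for the number of composite-carrying samples.

    Each replicate shuffles the gene labels across all nonsynonymous
    mutations (per-sample burden preserved; ``shuffle="sample"`` shuffles
    the sample labels instead, the equivalent rewiring) and recounts samples
    with >=2 same-gene mutations.  Deterministic given ``seed``.
    """
    v = variants[_nonsyn_mask(variants) & variants["gene"].notna()]
    if len(v) < 2:
        raise ValueError("need at least two mutations")
    samples = v["sample"].to_numpy()
    genes = v["gene"].to_numpy()
    observed = _n_composite_samples(samples, genes)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        if shuffle == "gene":
            reps[i] = _n_composite_samples(samples, rng.permutation(genes))
        else:
            reps[i] = _n_composite_samples(rng.permutation(samples), genes)
    p = (1 + int((reps >= observed).sum())) / (n_perm + 1)
    return PermutationNull(observed=observed, replicates=reps, p_value=p)


# ---------------------------------------------------------------------------
# expected counts by negative-binomial regression

def fit_expected_counts(counts: pd.DataFrame, min_genes: int = 20) -> dict:
    """Expected AID-composite sample count per gene from NB regression.

    ``counts`` has one row per gene with columns ``count`` (observed
    AID-composite samples), ``cds_length`` (bp, entered as log), ``gc``
    (percent), ``reptime``, ``chromatin`` (categorical), ``assay_version``
    (categorical), ``mean_cn``, and ``n_mutated`` (samples mutated in the
    gene; its log is the offset).  Missing numeric covariates are imputed by
    the median (reported).  Dispersion is estimated by maximum likelihood;
    on non-convergence the fit falls back to Poisson with a warning flag.
    """
    df = counts.copy()
    if len(df) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(df)}")
    numeric = ["cds_length", "gc", "reptime", "mean_cn"]
    imputed = {}
    for col in numeric:
        if col in df.columns and df[col].isna().any():
            med = df[col].median()
            imputed[col] = int(df[col].isna().sum())
            df[col] = df[col].fillna(med)
    if (df["cds_length"] <= 0).any():
        raise ValueError("cds_length must be positive")

    X = pd.DataFrame({
        "log_cds_length": np.log(df["cds_length"].to_numpy(float)),
        "gc": df["gc"].to_numpy(float),
        "reptime": df["reptime"].to_numpy(float),
        "mean_cn": df["mean_cn"].to_numpy(float),
    }, index=df.index)
    # constant covariates carry no information; keep the fit intercept-only
    # in the degenerate all-identical case instead of failing on rank
    X = X.loc[:, X.nunique() > 1]
    for cat in ("chromatin", "assay_version"):
        if cat in df.columns and df[cat].nunique() > 1:
            ref = df[cat].mode().iloc[0]  # most frequent level as reference
            dummies = pd.get_dummies(df[cat], prefix=cat, dtype=float)
            X = pd.concat([X, dummies.drop(columns=f"{cat}_{ref}")], axis=1)
    X = sm.add_constant(X, has_constant="add")
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        seen: list[int] = []
        for j, col in enumerate(X.columns):
            trial = arr[:, [*seen, j]]
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                seen.append(j)
            else:
                raise ValueError(f"singular design: covariate {col!r} is collinear")
    offset = np.log(df["n_mutated"].to_numpy(float))
    y = df["count"].to_numpy(float)

    family_used = "negative_binomial"
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            nb = sm.NegativeBinomial(y, X, offset=offset)
            res = nb.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("NB fit did not converge")
        mu = res.predict(X, offset=offset, which="mean")
        params = res.params
        conf = res.conf_int()
        alpha_disp = float(params.get("alpha", np.nan))
    except Exception:
        family_used = "poisson"
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = res.predict(X, offset=offset)
        params = res.params
        conf = res.conf_int()
        alpha_disp = np.nan
    coef = pd.DataFrame({"coef": params, "ci_low": conf[0], "ci_high": conf[1]})
    return {
        "expected": pd.Series(np.asarray(mu), index=df.index, name="expected"),
        "coefficients": coef,
        "dispersion": alpha_disp,
        "family": family_used,
        "imputed": imputed,
    }


# ---------------------------------------------------------------------------
# gene- and residue-level tests

def gene_enrichment(
    observed: pd.Series, expected: pd.Series, n_mutated: pd.Series,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One-sided binomial enrichment test per gene.

    Observed AID-composite samples out of ``n_mutated`` against the chance
    rate expected/n_mutated (capped just below 1 when the regression
    over-predicts); BH across genes; significant iff q < ``fdr``.
    """
    genes = observed.index
    rows = []
    for g in genes:
        n = int(n_mutated[g])
        rate = float(expected[g]) / n if n > 0 else 0.0
        capped = False
        if rate >= 1.0:
            rate, capped = 1.0 - 1e-9, True
        p = binomtest(int(observed[g]), n, rate, alternative="greater").pvalue if n else 1.0
        rows.append({"gene": g, "observed": int(observed[g]), "expected": float(expected[g]),
                     "n_mutated": n, "rate": rate, "p": p, "rate_capped": capped})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out


def residue_enrichment(variants: pd.DataFrame, events: pd.DataFrame,
                       fdr: float = 0.01) -> pd.DataFrame:
    """Right-sided Fisher test per mutated residue for AID-composite excess.

    Within each gene, every residue's 2x2 table contrasts AID-composite
    mutations at the residue vs at other residues against all other
    mutations; BH across all tested residues; significant iff q < ``fdr``.
    Mutations without a protein position are excluded and counted.
    """
    v = variants[variants["gene"].notna()].copy()
    has_res = v["protein_pos"].notna()
    n_excluded = int((~has_res).sum())
    v = v[has_res]
    aid_comp_idx: set = set()
    for _, ev in events.iterrows():
        if ev["aid_composite"]:
            aid_comp_idx.update(ev["member_index"])
    v["is_aid_composite"] = [i in aid_comp_idx for i in v.index]
    rows = []
    for gene, sub in v.groupby("gene"):
        residues = sub["protein_pos"].astype(int)
        if residues.nunique() < 2:
            for r in residues.unique():
                rows.append({"gene": gene, "residue": int(r), "p": 1.0,
                             "table": None})
            continue
        for r in sorted(residues.unique()):
            at = residues == r
            a = int((sub["is_aid_composite"] & at).sum())
            b = int((sub["is_aid_composite"] & ~at).sum())
            c = int((~sub["is_aid_composite"] & at).sum())
            d = int((~sub["is_aid_composite"] & ~at).sum())
            p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            rows.append({"gene": gene, "residue": int(r), "p": float(p),
                         "table": [[a, b], [c, d]]})
    out = pd.DataFrame(rows, columns=["gene", "residue", "p", "table"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr
    out.attrs["n_excluded_no_residue"] = n_excluded
    return out


# ---------------------------------------------------------------------------
# hotspot utilization and molecular timing

def hotspot_utilization(variants: pd.DataFrame, events: pd.DataFrame) -> dict:
    """Cumulative hotspot-utilization curves by mutation group.

    Residues (gene + protein position) are ranked by decreasing population
    frequency (unique samples mutated); for each of the four groups
    (AID-composite, AID-singleton, other-composite, other-singleton) the
    curve gives the cumulative fraction of the group's mutations at the
    top-k residues.  Pairwise composite-vs-singleton two-proportion
    contrasts at the top residue are reported with 95% binomial CIs.
    """
    v = variants[variants["gene"].notna() & variants["protein_pos"].notna()].copy()
    v["residue_key"] = v["gene"].astype(str) + ":" + v["protein_pos"].astype(int).astype(str)
    composite_idx: set = set()
    for _, ev in events.iterrows():
        composite_idx.update(ev["member_index"])
    aid = v.get("aid", pd.Series(False, index=v.index)).fillna(False).astype(bool)
    comp = pd.Series([i in composite_idx for i in v.index], index=v.index)
    group = np.where(aid & comp, "aid_composite",
             np.where(aid & ~comp, "aid_singleton",
              np.where(~aid & comp, "other_composite", "other_singleton")))
    v["group"] = group
    freq = v.groupby("residue_key")["sample"].nunique().sort_values(ascending=False)
    ranked = list(freq.index)
    pos = {r: k for k, r in enumerate(ranked)}
    curves = {}
    for g, sub in v.groupby("group"):
        ranks = np.sort([pos[r] for r in sub["residue_key"]])
        cum = np.searchsorted(ranks, np.arange(len(ranked)), side="right") / len(sub)
        curves[g] = cum
    contrasts = {}
    top = ranked[0] if ranked else None
    for a, b in (("aid_composite", "aid_singleton"), ("other_composite", "other_singleton")):
        if top is None or a not in curves or b not in curves:
            continue
        na = int((v["group"] == a).sum()); ka = int(((v["group"] == a) & (v["residue_key"] == top)).sum())
        nb = int((v["group"] == b).sum()); kb = int(((v["group"] == b) & (v["residue_key"] == top)).sum())
        ci_a = proportion_confint(ka, na, method="beta") if na else (np.nan, np.nan)
        ci_b = proportion_confint(kb, nb, method="beta") if nb else (np.nan, np.nan)
        p = fisher_exact([[ka, na - ka], [kb, nb - kb]])[1] if na and nb else np.nan
        contrasts[(a, b)] = {"prop_a": ka / na if na else np.nan, "ci_a": ci_a,
                             "prop_b": kb / nb if nb else np.nan, "ci_b": ci_b, "p": p}
    return {"ranked_residues": ranked, "frequencies": freq, "curves": curves,
            "contrasts": contrasts, "groups": v["group"]}


def timing_test(events: pd.DataFrame, variants: pd.DataFrame,
                min_events: int = 5) -> dict:
    """Binomial tests of mutation order within composite pairs.

    An event is orderable when exactly one member is clonal and one
    subclonal (the clonal mutation arose first) or when an explicit
    ``timing_order`` column ranks the members.  Globally: two-sided binomial
    test of "the more population-frequent residue came first" against 0.5.
    Per residue: one-sided binomial test that the residue arrives second.
    Fewer than ``min_events`` orderable events skips the test.
    """
    v = variants
    freq = v[v["gene"].notna() & v["protein_pos"].notna()].copy()
    freq["residue_key"] = freq["gene"].astype(str) + ":" + freq["protein_pos"].astype(int).astype(str)
    residue_freq = freq.groupby("residue_key")["sample"].nunique()

    ordered = []  # (first_residue_key, second_residue_key)
    for _, ev in events.iterrows():
        members = v.loc[ev["member_index"]]
        first = second = None
        if "timing_order" in members.columns and members["timing_order"].notna().all():
            ranked = members.sort_values("timing_order")
            first, second = ranked.iloc[0], ranked.iloc[-1]
        elif "clonality" in members.columns:
            clonal = members[members["clonality"] == "clonal"]
            sub = members[members["clonality"] == "subclonal"]
            if len(clonal) == 1 and len(sub) == 1:
                first, second = clonal.iloc[0], sub.iloc[0]
        if first is None or pd.isna(first["protein_pos"]) or pd.isna(second["protein_pos"]):
            continue
        k1 = f"{first['gene']}:{int(first['protein_pos'])}"
        k2 = f"{second['gene']}:{int(second['protein_pos'])}"
        if k1 == k2:
            continue
        ordered.append((k1, k2))

    if len(ordered) < min_events:
        return {"n_orderable": len(ordered), "skipped": True}
    hot_first = sum(residue_freq.get(k1, 0) >= residue_freq.get(k2, 0) for k1, k2 in ordered)
    n = len(ordered)
    global_test = binomtest(hot_first, n, 0.5, alternative="two-sided")
    per_residue = {}
    seconds = pd.Series([k2 for _, k2 in ordered])
    involved = pd.Series([k for pair in ordered for k in pair])
    for res in involved.unique():
        n_inv = int((involved == res).sum())
        n_second = int((seconds == res).sum())
        per_residue[res] = {
            "n_involved": n_inv, "n_second": n_second,
            "p": binomtest(n_second, n_inv, 0.5, alternative="greater").pvalue,
        }
    return {
        "n_orderable": n, "skipped": False,
        "frac_hotspot_first": hot_first / n,
        "p_global": global_test.pvalue,
        "per_residue": per_residue,
    }
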