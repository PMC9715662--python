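"""Neoepitope filtering, immunogenicity classification, and ICN contrasts.

Consumes precomputed neoepitope tables (peptide, HLA allele, immunogenicity
%rank) joined to source mutations.  A neoepitope is immunogenic when its
%rank is at or below 0.5; an immunogenic clonal neoepitope (ICN) further
requires its source mutation to be clonal.  Samples are "Presence" for a
mutational process when they carry at least one ICN attributed to it, and
presence proportions are compared between processes with a pooled
two-proportion Z-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

#: antigen-presentation genes whose damage/copy-loss excludes a sample
ANTIGEN_PRESENTATION_GENES = (
    "HLA-A", "HLA-B", "HLA-C", "CIITA", "IRF1", "PSME1", "PSME2", "PSME3",
    "ERAP1", "ERAP2", "HSPA", "HSPC", "TAP1", "TAP2", "TAPBP", "CALR",
    "CNX", "PDIA3", "B2M",
)


def filter_samples(metadata: pd.DataFrame) -> dict:
    """Sample-level exclusions: incomplete HLA, MSI, damaged antigen presentation.

    ``metadata`` is indexed by sample with boolean columns ``hla_complete``,
    ``msi`` and ``antigen_presentation_damaged`` (precomputed from damaging
    PolyPhen/SIFT predictions or copy loss over the antigen-presentation
    gene list).  Returns eligible sample index plus per-criterion exclusion
    counts.
    """
    required = ["hla_complete", "msi", "antigen_presentation_damaged"]
    for col in required:
        if col not in metadata.columns:
            raise ValueError(f"sample metadata lacks column {col!r}")
    excl_hla = ~metadata["hla_complete"].astype(bool)
    excl_msi = metadata["msi"].astype(bool)
    excl_ap = metadata["antigen_presentation_damaged"].astype(bool)
    eligible = metadata.index[~(excl_hla | excl_msi | excl_ap)]
    return {
        "eligible": eligible,
        "n_eligible": len(eligible),
        "excluded_incomplete_hla": int(excl_hla.sum()),
        "excluded_msi": int(excl_msi.sum()),
        "excluded_antigen_presentation": int(excl_ap.sum()),
    }


def classify_neoepitopes(
    records: pd.DataFrame,
    expression_threshold: float = 1.0,
    rank_threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag immunogenic and ICN neoepitopes.

    Drops records whose source-gene FPKM is at or below the expression
    threshold, flags ``immunogenic`` when %rank <= ``rank_threshold``
    (inclusive), and ``icn`` when additionally the source mutation's
    ``clonality`` is "clonal".  Records with missing %rank are dropped and
    counted; records with unknown clonality keep ``icn`` as NA and are
    excluded from presence counts downstream.
    """
    df = records.copy()
    n_no_rank = int(df["rank_score"].isna().sum())
    df = df[df["rank_score"].notna()]
    df = df[pd.to_numeric(df["fpkm"], errors="coerce") > expression_threshold]
    df["immunogenic"] = df["rank_score"].astype(float) <= rank_threshold
    clon = df.get("clonality", pd.Series("unknown", index=df.index)).fillna("unknown")
    icn = np.where(clon == "unknown", pd.NA, df["immunogenic"] & (clon == "clonal"))
    df["icn"] = pd.array(icn, dtype="boolean")
    df.attrs["n_dropped_no_rank"] = n_no_rank
    return df


def sample_presence(
    records: pd.DataFrame, eligible_samples, process_col: str = "process"
) -> pd.DataFrame:
    """Per-sample Presence/Absence of ICNs for every mutational process.

    Output is eligible samples x processes, boolean; a sample is Present
    for a process when at least one of its classified records has a
    determinate ICN=True flag attributed to that process.
    """
    df = records[records["icn"].notna()]
    df = df[df["sample"].isin(eligible_samples)]
    processes = sorted(df[process_col].fillna("other").astype(str).unique())
    out = pd.DataFrame(False, index=pd.Index(eligible_samples, name="sample"),
                       columns=processes if processes else ["none"])
    hits = df[df["icn"].astype(bool)]
    for (sample, proc), _ in hits.groupby(["sample", process_col]).groups.items():
        out.loc[sample, str(proc)] = True
    return out


def presence_contrast(
    presence: pd.DataFrame, process_a: str, process_b: str
) -> dict:
    """Two-sided pooled two-proportion Z-test of Presence between processes.

    Both proportions are computed over the same eligible-sample basis; 95%
    exact binomial CIs accompany each.
    """
    n = len(presence)
    if n == 0:
        raise ValueError("no eligible samples")
    ka = int(presence[process_a].sum()) if process_a in presence.columns else 0
    kb = int(presence[process_b].sum()) if process_b in presence.columns else 0
    if ka == kb:
        z, p = 0.0, 1.0
    else:
        z, p = proportions_ztest([ka, kb], [n, n], alternative="two-sided")
    ci_a = proportion_confint(ka, n, method="beta")
    ci_b = proportion_confint(kb, n, method="beta")
    return {
        "process_a": process_a, "process_b": process_b,
        "n_samples": n,
        "prop_a": ka / n, "ci_a": (float(ci_a[0]), float(ci_a[1])),
        "prop_b": kb / n, "ci_b": (float(ci_b[0]), float(ci_b[1])),
        "z": float(z), "p": float(p),
    }
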