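"""c-AID mutation tagging, the 768-channel substitution matrix, and
per-sample motif enrichment.

A somatic SNV is a canonical-AID (c-AID) candidate when it hits the cytosine
of a WRCY tetranucleotide with C>T or C>G — or, equivalently on the other
strand, the guanine of an RGYW tetranucleotide with G>A or G>C.  Enrichment
per sample contrasts the fraction of cytosine mutations falling at motifs
with the motif/cytosine content of the local sequence context, the
fold-enrichment construction standard in the APOBEC-signature literature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genome import WRCY, GenomeSequence, MotifSet, kmer_code, reverse_complement
from .variant_io import Cohort

PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")

# ---------------------------------------------------------------------------
# classification

def motif_target_mask(genome: GenomeSequence, contig: str, motifs: MotifSet = WRCY) -> np.ndarray:
    """Boolean mask over a contig: True at every mutable motif base.

    Marks the plus-strand C of each WRCY match and the plus-strand G of each
    RGYW (minus-strand WRCY) match.
    """
    codes = genome.codes(contig)
    n = codes.size
    mask = np.zeros(n, dtype=bool)
    k = motifs.length
    if n < k:
        return mask
    from .genome import _kmer_codes  # internal helper shared with the scanner

    kmers = _kmer_codes(codes, k)
    fwd = np.isin(kmers, [kmer_code(m) for m in motifs.motifs])
    rev = np.isin(kmers, [kmer_code(m) for m in motifs.rc_motifs])
    starts = np.flatnonzero(fwd)
    mask[starts + motifs.offset] = True
    starts = np.flatnonzero(rev)
    mask[starts + motifs.rc_offset] = True
    return mask


def classify_aid(cohort: Cohort, genome: GenomeSequence, motifs: MotifSet = WRCY) -> Cohort:
    """Tag every variant with its c-AID status.

    Adds two columns to the variant table: ``aid`` (bool) and ``aid_motif``
    (the matched motif in WRCY orientation, NA when not AID).  A variant out
    of context bounds is tagged False.  Returns the same cohort (modified in
    place) for chaining.
    """
    v = cohort.variants
    aid = np.zeros(len(v), dtype=bool)
    motif = np.full(len(v), None, dtype=object)
    fwd_codes = {kmer_code(m): m for m in motifs.motifs}
    rev_codes = {kmer_code(reverse_complement(m)): m for m in motifs.motifs}

    refs = v["ref"].to_numpy()
    alts = v["alt"].to_numpy()
    pos_all = v["pos"].to_numpy(int)
    for contig, idx in v.groupby("contig").indices.items():
        if contig not in genome.contig_names:
            continue
        codes = genome.codes(contig)
        n = codes.size
        pos = pos_all[idx]
        # plus-strand cytosine frame: 4-mer [pos-2, pos+2)
        c_case = (refs[idx] == "C") & np.isin(alts[idx], ["T", "G"])
        c_case &= (pos >= 2) & (pos + 2 <= n)
        # minus-strand (guanine) frame: 4-mer [pos-1, pos+3)
        g_case = (refs[idx] == "G") & np.isin(alts[idx], ["A", "C"])
        g_case &= (pos >= 1) & (pos + 3 <= n)
        for case, lo, table in ((c_case, 2, fwd_codes), (g_case, 1, rev_codes)):
            sub = idx[case]
            if sub.size == 0:
                continue
            p = pos_all[sub] - lo
            w = (
                np.minimum(codes[p], 3).astype(np.int64) * 64
                + np.minimum(codes[p + 1], 3) * 16
                + np.minimum(codes[p + 2], 3) * 4
                + np.minimum(codes[p + 3], 3)
            )
            has_n = (codes[p] >= 4) | (codes[p + 1] >= 4) | (codes[p + 2] >= 4) | (codes[p + 3] >= 4)
            for j, code, bad in zip(sub, w, has_n):
                if not bad and code in table:
                    aid[j] = True
                    motif[j] = table[code]
    v["aid"] = aid
    v["aid_motif"] = motif
    return cohort


def extract_aid_maf(cohort: Cohort) -> Cohort:
    """Subset of the cohort carrying only AID-flagged variants."""
    if "aid" not in cohort.variants.columns:
        raise ValueError("run classify_aid first")
    return cohort.subset(cohort.variants["aid"].to_numpy())


# ---------------------------------------------------------------------------
# 768-channel tetranucleotide substitution matrix

def channel_labels() -> list[str]:
    """The 768 tetranucleotide substitution channels, in canonical order.

    12 uncollapsed substitution types x 64 single-base contexts.  Pyrimidine
    references use the frame (-2, -1, X, +1); purine references the mirrored
    frame (-1, X, +1, +2), so that reverse complementation maps purine
    channels one-to-one onto pyrimidine channels.  Labels look like
    ``AG[C]T>G`` (pyrimidine) or ``A[G]CT>C`` (purine).
    """
    labels = []
    bases = "ACGT"
    for ref in bases:
        for alt in bases:
            if alt == ref:
                continue
            for a in bases:
                for b in bases:
                    for c in bases:
                        if ref in PYRIMIDINES:
                            labels.append(f"{a}{b}[{ref}]{c}>{alt}")
                        else:
                            labels.append(f"{a}[{ref}]{b}{c}>{alt}")
    return labels


def channel_of(context5: str, ref: str, alt: str) -> str:
    """Channel label for one SNV given its 5-mer reference context."""
    if len(context5) != 5 or context5[2] != ref:
        raise ValueError(f"context {context5!r} does not center ref {ref!r}")
    if ref in PYRIMIDINES:
        return f"{context5[0]}{context5[1]}[{ref}]{context5[3]}>{alt}"
    return f"{context5[1]}[{ref}]{context5[3]}{context5[4]}>{alt}"


def build_substitution_matrix(cohort: Cohort, genome: GenomeSequence) -> pd.DataFrame:
    """Samples x 768 counts of tetranucleotide substitutions.

    SNVs whose context leaves the contig or contains N are excluded; the
    exclusion count is attached as ``df.attrs["n_excluded"]``.
    """
    labels = channel_labels()
    col_index = {lab: i for i, lab in enumerate(labels)}
    samples = list(cohort.samples.index)
    row_index = {s: i for i, s in enumerate(samples)}
    mat = np.zeros((len(samples), 768), dtype=np.int64)

    v = cohort.variants
    n_excluded = 0
    for contig, idx in v.groupby("contig").indices.items():
        if contig not in genome.contig_names:
            n_excluded += idx.size
            continue
        codes = genome.codes(contig)
        seq = None
        for j in idx:
            pos = int(v["pos"].iloc[j])
            if pos < 2 or pos + 2 >= codes.size or np.any(codes[pos - 2 : pos + 3] >= 4):
                n_excluded += 1
                continue
            if seq is None:
                seq = genome.sequence(contig, 0, codes.size)
            ctx = seq[pos - 2 : pos + 3]
            lab = channel_of(ctx, v["ref"].iloc[j], v["alt"].iloc[j])
            mat[row_index[v["sample"].iloc[j]], col_index[lab]] += 1
    df = pd.DataFrame(mat, index=pd.Index(samples, name="sample"), columns=labels)
    df.attrs["n_excluded"] = n_excluded
    return df


# ---------------------------------------------------------------------------
# enrichment

def compute_enrichment(
    cohort: Cohort,
    genome: GenomeSequence,
    flank: int = 20,
    motifs: MotifSet = WRCY,
) -> pd.DataFrame:
    """Per-sample c-AID enrichment over the local cytosine background.

    For each sample: M_motif = C>T/G mutations at the motif (strand
    symmetric), M_C = all C>T/G mutations; Motif_ctx and C_ctx are the motif
    target positions and cytosine positions (C or G on the plus strand)
    inside +-``flank`` bp of every eligible mutation.  The enrichment score
    is ``E = (M_motif * C_ctx) / (M_C * Motif_ctx)``; the one-sided Fisher
    p-value tests the same 2x2 table toward enrichment; q is
    Benjamini-Hochberg across samples.  ``aid_fraction`` is AID mutations
    over all SNVs of the sample.
    """
    v = cohort.variants
    if "aid" not in v.columns:
        raise ValueError("run classify_aid first")

    # prefix sums per contig for O(1) window content counts
    cum_cg: dict[str, np.ndarray] = {}
    cum_motif: dict[str, np.ndarray] = {}
    for contig in v["contig"].unique():
        if contig not in genome.contig_names:
            continue
        codes = genome.codes(contig)
        is_cg = (codes == 1) | (codes == 2)
        cum_cg[contig] = np.concatenate([[0], np.cumsum(is_cg)])
        cum_motif[contig] = np.concatenate(
            [[0], np.cumsum(motif_target_mask(genome, contig, motifs))]
        )

    eligible = ((v["ref"] == "C") & v["alt"].isin(["T", "G"])) | (
        (v["ref"] == "G") & v["alt"].isin(["A", "C"])
    )
    rows = []
    for sample, idx in v.groupby("sample").indices.items():
        sub = v.iloc[idx]
        elig = sub[eligible.iloc[idx].to_numpy()]
        m_c = len(elig)
        m_motif = int(elig["aid"].sum())
        motif_ctx = c_ctx = 0
        for contig, cidx in elig.groupby("contig").indices.items():
            if contig not in cum_cg:
                continue
            n = cum_cg[contig].size - 1
            pos = elig["pos"].iloc[cidx].to_numpy(int)
            lo = np.clip(pos - flank, 0, n)
            hi = np.clip(pos + flank + 1, 0, n)
            c_ctx += int((cum_cg[contig][hi] - cum_cg[contig][lo]).sum())
            motif_ctx += int((cum_motif[contig][hi] - cum_motif[contig][lo]).sum())
        if m_c == 0 or motif_ctx == 0 or c_ctx == 0:
            e, p = (0.0 if m_motif == 0 else np.nan), 1.0
        else:
            e = (m_motif * c_ctx) / (m_c * motif_ctx)
            table = [[m_motif, m_c - m_motif], [motif_ctx, c_ctx - motif_ctx]]
            p = fisher_exact(table, alternative="greater")[1]
        rows.append(
            {
                "sample": sample,
                "n_snv": len(sub),
                "m_aid": int(sub["aid"].sum()),
                "m_motif": m_motif,
                "m_c": m_c,
                "motif_ctx": motif_ctx,
                "c_ctx": c_ctx,
                "enrichment": e,
                "p": p,
                "aid_fraction": float(sub["aid"].mean()) if len(sub) else 0.0,
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    out["q"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1] if len(out) else []
    return out


def profile_cosine(a, b) -> float:
    """Cosine similarity of two non-negative mutational profiles in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero profile has no direction")
    return float(np.dot(a, b) / (na * nb))
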