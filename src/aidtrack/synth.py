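"""Synthetic genomes, annotations, and tumor cohorts with known ground truth.

Every pipeline stage in this package is exercised on data from this module:
an i.i.d. random genome with a target GC content, tiled chromatin domains
and uniformly placed genes, and a cohort whose somatic SNVs are planted by
process — c-AID mutations at WRCY/RGYW target cytosines (C>T/G), APOBEC-like
mutations at TCW, and uniform background — with planted clonal/subclonal
cancer-cell fractions realized as binomial read counts, expression coupled
to per-gene AID counts by a Gaussian copula, and neoepitope %rank scores
drawn so a configured fraction of each process's clonal mutations is
immunogenic.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .genome import WRCY, TCW, GenomeSequence, MotifSet, scan_genome
from .variant_io import Cohort
from .context import DOMAIN_CLASSES

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthGenomeConfig:
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"1": 200_000})
    gc: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must lie in (0, 1)")
        if any(l <= 10_000 for l in self.contig_lengths.values()):
            raise ValueError("contig lengths must exceed 10 kb")


@dataclass
class SynthCohortConfig:
    n_samples: int = 20
    muts_per_sample: float = 500.0
    muts_dispersion: float = 0.1      # NB dispersion (0 -> Poisson)
    mix: dict = field(default_factory=lambda: {"aid": 0.1, "apobec": 0.1, "background": 0.8})
    aid_transition_prob: float = 0.7  # P(C>T) vs C>G at planted motif mutations
    clonal_fraction: float = 0.7
    subclonal_ccf: tuple[float, float] = (0.2, 0.7)
    purity_range: tuple[float, float] = (0.6, 1.0)
    depth: int = 80
    n_coupled_genes: int = 5
    coupled_rho: float = 0.8
    #: scalar, or dict keyed by process label (e.g. {"aid": 0.3, "apobec": 0.1})
    neo_immunogenic_fraction: float | dict = 0.5
    seed: int = 0

    def __post_init__(self):
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"process mix must sum to 1, got {total}")
        if self.depth < 20:
            raise ValueError("sequencing depth must be >= 20")


def generate_genome(config: SynthGenomeConfig) -> GenomeSequence:
    """Random genome with i.i.d. bases at the target GC fraction."""
    rng = np.random.default_rng(config.seed)
    p_gc = config.gc / 2
    p_at = (1 - config.gc) / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A, C, G, T
    contigs = {}
    for name, length in config.contig_lengths.items():
        draws = rng.choice(4, size=length, p=probs)
        contigs[name] = "".join(np.array(list("ACGT"))[draws])
    return GenomeSequence(contigs)


def write_genome_fasta(genome: GenomeSequence, path: str | Path) -> Path:
    """Write FASTA with a sidecar .fai index."""
    path = Path(path)
    with open(path, "w") as fh:
        for name in genome.contig_names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name, 0, genome.contig_lengths[name])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    from pyfaidx import Faidx

    Faidx(str(path))
    return path


def generate_annotations(
    genome: GenomeSequence,
    seed: int = 0,
    n_genes_per_contig: int = 20,
    gene_length: int = 3_000,
    domain_mean_length: int = 40_000,
    n_rloops_per_contig: int = 10,
    rloop_length: int = 600,
) -> dict:
    """Domains tiling each contig, uniformly placed genes, R-loop regions,
    and a gene covariate table for composite testing."""
    rng = np.random.default_rng(seed)
    domain_rows, gene_rows, rloop_rows = [], [], []
    for contig, clen in genome.contig_lengths.items():
        pos = 0
        while pos < clen:
            length = int(rng.exponential(domain_mean_length)) + 5_000
            end = min(pos + length, clen)
            domain_rows.append({"contig": contig, "start": pos, "end": end,
                                "class": rng.choice(DOMAIN_CLASSES)})
            pos = end
        starts = rng.integers(0, max(clen - gene_length, 1), size=n_genes_per_contig)
        for i, s in enumerate(sorted(starts)):
            gene_rows.append({"contig": contig, "start": int(s), "end": int(s + gene_length),
                              "gene": f"G{contig}_{i}", "strand": rng.choice(["+", "-"])})
        rstarts = rng.integers(0, max(clen - rloop_length, 1), size=n_rloops_per_contig)
        for s in sorted(set(rstarts)):
            rloop_rows.append({"contig": contig, "start": int(s), "end": int(s + rloop_length)})
    genes = pd.DataFrame(gene_rows)
    panel = pd.DataFrame({
        "gene": genes["gene"],
        "cds_length": rng.lognormal(np.log(1_500), 0.5, size=len(genes)).round().astype(int),
        "gc": rng.uniform(30, 70, size=len(genes)),
        "reptime": rng.uniform(0, 100, size=len(genes)),
        "chromatin": rng.choice(["open", "closed", "mixed"], size=len(genes)),
        "assay_version": rng.choice(["v1", "v2"], size=len(genes)),
        "mean_cn": rng.normal(2.0, 0.2, size=len(genes)).clip(1.0),
    }).set_index("gene")
    return {
        "domains": pd.DataFrame(domain_rows),
        "genes": genes,
        "rloops": pd.DataFrame(rloop_rows),
        "panel": panel,
    }


def _draw_counts(rng, n, mean, dispersion):
    if dispersion <= 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=n)


def generate_cohort(
    genome: GenomeSequence,
    annotations: dict,
    config: SynthCohortConfig,
) -> dict:
    """Cohort with planted processes, clonality, expression and neoepitopes.

    Returns a dict with the :class:`~aidtrack.variant_io.Cohort`, the
    per-sample purity table, the genes x samples expression frame, the
    neoepitope table, and the per-mutation ground-truth frame.  All
    placement and read-count draws are vectorized so cohorts of 10^5
    mutations generate in seconds.
    """
    rng = np.random.default_rng(config.seed)
    wrcy_sites = scan_genome(genome, WRCY)
    tcw_sites = scan_genome(genome, TCW)
    if config.mix.get("aid", 0) > 0 and wrcy_sites.empty:
        raise ValueError("AID fraction > 0 but the genome has no WRCY sites")
    if config.mix.get("apobec", 0) > 0 and tcw_sites.empty:
        raise ValueError("APOBEC fraction > 0 but the genome has no TCW sites")

    lengths = genome.contig_lengths
    contig_names = list(lengths)
    total_len = sum(lengths.values())
    contig_p = np.array([lengths[c] / total_len for c in contig_names])
    genes = annotations["genes"]

    processes = list(config.mix)
    probs = [config.mix[p] for p in processes]
    purities = rng.uniform(*config.purity_range, size=config.n_samples)
    n_muts = _draw_counts(rng, config.n_samples, config.muts_per_sample,
                          config.muts_dispersion).clip(1)

    n_total = int(n_muts.sum())
    sample_of = np.repeat([f"S{si:03d}" for si in range(config.n_samples)], n_muts)
    purity_of = np.repeat(purities, n_muts)
    proc_idx = rng.choice(len(processes), size=n_total, p=probs)
    proc = np.array(processes, dtype=object)[proc_idx]

    contig_arr = np.empty(n_total, dtype=object)
    pos_arr = np.zeros(n_total, dtype=np.int64)
    ref_arr = np.empty(n_total, dtype=object)
    alt_arr = np.empty(n_total, dtype=object)
    motif_arr = np.full(n_total, None, dtype=object)

    def _plant_at_sites(sel: np.ndarray, sites: pd.DataFrame) -> None:
        k = int(sel.sum())
        if k == 0:
            return
        rows = rng.integers(0, len(sites), size=k)
        contig_arr[sel] = sites["contig"].to_numpy()[rows]
        pos_arr[sel] = sites["mutable_pos"].to_numpy()[rows]
        motif_arr[sel] = sites["motif"].to_numpy()[rows]
        plus = sites["strand"].to_numpy()[rows] == "+"
        to_t = rng.random(k) < config.aid_transition_prob
        ref_arr[sel] = np.where(plus, "C", "G")
        alt_arr[sel] = np.where(plus, np.where(to_t, "T", "G"), np.where(to_t, "A", "C"))

    _plant_at_sites(proc == "aid", wrcy_sites)
    _plant_at_sites(proc == "apobec", tcw_sites)

    bg = proc == "background"
    k = int(bg.sum())
    if k:
        picks = rng.choice(len(contig_names), size=k, p=contig_p)
        bpos = np.zeros(k, dtype=np.int64)
        bref = np.empty(k, dtype=object)
        for ci, contig in enumerate(contig_names):
            m = picks == ci
            n_c = int(m.sum())
            if n_c == 0:
                continue
            codes = genome.codes(contig)
            p = rng.integers(2, codes.size - 2, size=n_c)
            bad = codes[p] >= 4
            while bad.any():  # resample the rare N hits
                p[bad] = rng.integers(2, codes.size - 2, size=int(bad.sum()))
                bad = codes[p] >= 4
            bpos[m] = p
            bref[m] = np.array(list("ACGT"), dtype=object)[codes[p]]
        contig_arr[bg] = np.array(contig_names, dtype=object)[picks]
        pos_arr[bg] = bpos
        ref_arr[bg] = bref
        # alt: uniform over the three non-reference bases
        shift = rng.integers(1, 4, size=k)
        base_idx = np.array(["ACGT".find(r) for r in bref])
        alt_arr[bg] = np.array(list("ACGT"), dtype=object)[(base_idx + shift) % 4]

    clonal = rng.random(n_total) < config.clonal_fraction
    ccf = np.where(clonal, 1.0, rng.uniform(*config.subclonal_ccf, size=n_total))
    # diploid, multiplicity 1: expected VAF = ccf * purity / 2
    vaf = ccf * purity_of / 2
    alt_count = rng.binomial(config.depth, vaf).clip(1)  # observed => >= 1 alt read

    # gene assignment by interval bisection per contig
    gene_arr = np.full(n_total, None, dtype=object)
    ppos_arr = np.full(n_total, np.nan)
    for contig in contig_names:
        sub = genes[genes["contig"] == contig].sort_values("start")
        m = contig_arr == contig
        if sub.empty or not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["gene"].to_numpy()
        pos = pos_arr[m]
        gi = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(starts) - 1)
        inside = (pos >= starts[gi]) & (pos < ends[gi])
        vals = np.full(pos.size, None, dtype=object)
        vals[inside] = names[gi[inside]]
        gene_arr[m] = vals
        pp = np.full(pos.size, np.nan)
        pp[inside] = (pos[inside] - starts[gi[inside]]) // 3 + 1
        ppos_arr[m] = pp

    variants = pd.DataFrame({
        "sample": sample_of, "contig": contig_arr, "pos": pos_arr,
        "ref": ref_arr, "alt": alt_arr, "gene": gene_arr,
        "protein_pos": ppos_arr,
        "classification": np.where(pd.notna(gene_arr), "Missense_Mutation", None),
        "t_alt_count": alt_count, "t_ref_count": config.depth - alt_count,
    })
    truth = pd.DataFrame({
        "sample": sample_of, "contig": contig_arr, "pos": pos_arr,
        "process": proc, "ccf": ccf,
        "clonality": np.where(clonal, "clonal", "subclonal"), "motif": motif_arr,
    })
    samples = pd.DataFrame({
        "purity": purities,
        "tumor_type": "SYNTH",
        "hla_complete": True,
        "msi": False,
        "antigen_presentation_damaged": False,
    }, index=pd.Index([f"S{si:03d}" for si in range(config.n_samples)], name="sample"))
    cohort = Cohort(variants, samples, provenance="aidtrack.synth")

    expression = _generate_expression(rng, cohort, truth, genes, config)
    neo = _generate_neoepitopes(rng, cohort, truth, expression, config)
    return {"cohort": cohort, "truth": truth, "expression": expression,
            "neoepitopes": neo, "samples": samples,
            "wrcy_sites": wrcy_sites, "tcw_sites": tcw_sites}


def _generate_expression(rng, cohort, truth, genes, config) -> pd.DataFrame:
    """Genes x samples FPKM-like expression; the first ``n_coupled_genes``
    genes track their own per-sample AID mutation count at the target
    Spearman rho via a Gaussian copula."""
    sample_ids = list(cohort.samples.index)
    gene_ids = list(genes["gene"])
    expr = pd.DataFrame(
        rng.lognormal(np.log(8), 1.0, size=(len(gene_ids), len(sample_ids))),
        index=pd.Index(gene_ids, name="gene"), columns=sample_ids,
    )
    aid_mask = (truth["process"] == "aid").to_numpy()
    v = cohort.variants
    aid_counts = (
        v[aid_mask & v["gene"].notna()].groupby(["gene", "sample"]).size()
        if aid_mask.any() else pd.Series(dtype=int)
    )
    # couple expression to the genes whose AID count actually varies across
    # samples (a constant count carries no rank signal to target)
    variances = {}
    for gene in gene_ids:
        counts = np.array([aid_counts.get((gene, s), 0) for s in sample_ids], float)
        variances[gene] = counts.var()
    coupled = sorted(gene_ids, key=lambda g: -variances[g])[: config.n_coupled_genes]
    rho = config.coupled_rho
    for gene in coupled:
        counts = np.array([aid_counts.get((gene, s), 0) for s in sample_ids], float)
        counts += rng.uniform(0, 1e-6, size=len(counts))  # break rank ties
        z1 = norm.ppf((rankdata(counts) - 0.5) / len(counts))
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(len(counts))
        expr.loc[gene] = np.exp(np.log(8) + z2)
    expr.attrs["coupled_genes"] = coupled
    return expr


def _generate_neoepitopes(rng, cohort, truth, expression, config) -> pd.DataFrame:
    """One neoepitope record per coding mutation, %rank drawn so that the
    configured fraction of each process's mutations is immunogenic."""
    v = cohort.variants
    coding = v["gene"].notna().to_numpy()
    idx = np.flatnonzero(coding)
    n = idx.size
    if n == 0:
        return pd.DataFrame(columns=["sample", "peptide", "hla", "rank_score", "gene",
                                     "fpkm", "mutation_index", "process", "clonality"])
    proc = truth["process"].to_numpy()[idx]
    frac_cfg = config.neo_immunogenic_fraction
    if isinstance(frac_cfg, dict):
        frac = np.array([frac_cfg.get(p, 0.0) for p in proc])
    else:
        frac = np.full(n, float(frac_cfg))
    immuno = rng.random(n) < frac
    rank = np.where(immuno, rng.uniform(0.0, 0.5, size=n), rng.uniform(0.6, 50.0, size=n))
    genes_v = v["gene"].to_numpy()[idx]
    samples_v = v["sample"].to_numpy()[idx]
    expr_lookup = expression.stack()
    fpkm = np.array([
        float(expr_lookup.get((g, s), 10.0)) for g, s in zip(genes_v, samples_v)
    ])
    peptides = ["".join(p) for p in rng.choice(list(AA), size=(n, 9))]
    return pd.DataFrame({
        "sample": samples_v,
        "peptide": peptides,
        "hla": "HLA-A*02:01",
        "rank_score": rank,
        "gene": genes_v,
        "fpkm": fpkm,
        "mutation_index": idx,
        "process": proc,
        "clonality": truth["clonality"].to_numpy()[idx],
    })


# ---------------------------------------------------------------------------
# composite-panel generator (counts from a known NB model)

def random_panel(n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Stand-alone gene covariate table (no genome needed), same columns as
    the annotation panel."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "gene": [f"P{i:04d}" for i in range(n_genes)],
        "cds_length": rng.lognormal(np.log(1_500), 0.5, size=n_genes).round().astype(int),
        "gc": rng.uniform(30, 70, size=n_genes),
        "reptime": rng.uniform(0, 100, size=n_genes),
        "chromatin": rng.choice(["open", "closed", "mixed"], size=n_genes),
        "assay_version": rng.choice(["v1", "v2"], size=n_genes),
        "mean_cn": rng.normal(2.0, 0.2, size=n_genes).clip(1.0),
    }).set_index("gene")


def generate_panel_counts(
    panel: pd.DataFrame,
    beta_log_cds: float = 1.0,
    intercept: float = -10.0,
    dispersion: float = 0.5,
    n_mutated_range: tuple[int, int] = (20, 200),
    enriched_genes: tuple[str, ...] = (),
    enrichment_fold: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene AID-composite sample counts from an NB model with a known
    log-CDS-length coefficient; planted enriched genes get ``fold`` times
    their model rate.  Used for regression-recovery and gene-test checks.
    """
    rng = np.random.default_rng(seed)
    df = panel.copy()
    df["n_mutated"] = rng.integers(*n_mutated_range, size=len(df))
    eta = intercept + beta_log_cds * np.log(df["cds_length"].to_numpy(float)) + np.log(
        df["n_mutated"].to_numpy(float))
    mu = np.exp(eta)
    enriched = df.index.isin(enriched_genes)
    mu = np.where(enriched, mu * enrichment_fold, mu)
    if dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    df["count"] = np.minimum(counts, df["n_mutated"])
    df["true_mu"] = mu
    df["enriched"] = enriched
    return df
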