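"""Context-preserving mutation shuffling and the c-AID null distribution.

Each replicate reassigns every somatic SNV of a sample, within its own
chromosome, to a uniformly drawn position sharing the same reference context
(the k-mer centered on the mutated base; substituted base and alt allele
preserved).  Counting c-AID mutations in each replicate yields a per-sample
null distribution against which the observed count is tested with per-
replicate two-sided Fisher exact tests and their odds-ratio confidence
intervals.

Resolution caveat: the WRCY/RGYW determinant lies entirely inside the +-2 bp
window around the mutated base, so a pentanucleotide-preserving shuffle
(``flank=2``) reproduces the observed c-AID count identically and the
enrichment ratio is 1 by construction.  Testing for motif excess requires a
coarser context (``flank=1``, trinucleotide), which preserves the immediate
neighbours but lets the -2 base (the W of WRCY) vary.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio

from .genome import GenomeSequence, MotifSet, WRCY, _kmer_codes
from .tracker import motif_target_mask


class ContextIndex:
    """Per-contig map from centered k-mer context to genomic positions.

    ``flank`` bases on each side of the mutated base define the context
    (flank=2 -> pentanucleotide, the SBS-1536 resolution; flank=1 ->
    trinucleotide, SBS-96).  Positions whose window contains N or leaves the
    contig are not indexed; the keys partition all indexable positions.
    """

    def __init__(self, genome: GenomeSequence, flank: int = 2):
        if flank < 1:
            raise ValueError("flank must be >= 1")
        self.genome = genome
        self.flank = flank
        self.k = 2 * flank + 1
        self._index: dict[str, dict[int, np.ndarray]] = {}
        self._codes_cache: dict[str, np.ndarray] = {}
        for contig in genome.contig_names:
            codes = genome.codes(contig)
            kmers = _kmer_codes(codes, self.k)
            centers = np.arange(kmers.size) + flank
            ok = kmers >= 0
            km, ct = kmers[ok], centers[ok]
            order = np.argsort(km, kind="mergesort")
            km, ct = km[order], ct[order]
            bounds = np.searchsorted(km, np.arange(4**self.k + 1))
            table = {}
            for key in np.unique(km):
                lo, hi = bounds[key], bounds[key + 1]
                table[int(key)] = ct[lo:hi].astype(np.int64)
            self._index[contig] = table
            ctx = np.full(codes.size, -1, dtype=np.int64)
            ctx[centers[ok]] = kmers[ok]
            self._codes_cache[contig] = ctx

    def positions(self, contig: str, key: int) -> np.ndarray:
        """All indexed positions on ``contig`` whose context code is ``key``."""
        return self._index.get(contig, {}).get(int(key), np.empty(0, dtype=np.int64))

    def context_code(self, contig: str, pos: int) -> int:
        """Context code of a position (-1 when not indexable)."""
        arr = self._codes_cache.get(contig)
        if arr is None or pos < 0 or pos >= arr.size:
            return -1
        return int(arr[pos])

    def keys(self, contig: str) -> list[int]:
        return list(self._index.get(contig, {}))


@dataclass
class NullDistribution:
    """Per-sample replicate c-AID counts from the context-preserving shuffle."""

    sample: str
    n_mutations: int
    observed_aid: int
    sim_counts: np.ndarray  # (R,)
    odds_ratios: np.ndarray  # per-replicate OR of observed vs simulated
    p_values: np.ndarray  # per-replicate two-sided Fisher p
    n_unplaceable: int = 0
    placements: list | None = None

    @property
    def R(self) -> int:
        return self.sim_counts.size

    @property
    def observed_non_aid(self) -> int:
        return self.n_mutations - self.observed_aid

    @property
    def expected_aid(self) -> float:
        return float(self.sim_counts.mean())

    @property
    def enrichment_ratio(self) -> float:
        exp = self.expected_aid
        return float(self.observed_aid / exp) if exp > 0 else np.inf


def _eligibility(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """AID-eligible substitution type: C>T/G on plus or G>A/C (minus strand)."""
    return ((ref == "C") & np.isin(alt, ["T", "G"])) | (
        (ref == "G") & np.isin(alt, ["A", "C"])
    )


def simulate_sample(
    variants: pd.DataFrame,
    index: ContextIndex,
    genome: GenomeSequence,
    R: int = 1000,
    seed: int = 0,
    motifs: MotifSet = WRCY,
    keep_placements: bool = False,
) -> NullDistribution:
    """Null distribution of c-AID counts for one sample's variants.

    Every replicate keeps the per-chromosome burden and every mutation's
    reference context and alt allele; only positions move.  A mutation whose
    context class offers no position (unindexable context) stays in place
    and is counted in ``n_unplaceable``.  Deterministic given ``seed``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    masks = {c: motif_target_mask(genome, c, motifs) for c in variants["contig"].unique()
             if c in genome.contig_names}

    refs = variants["ref"].to_numpy()
    alts = variants["alt"].to_numpy()
    eligible = _eligibility(refs, alts)
    pos_all = variants["pos"].to_numpy(int)
    contigs = variants["contig"].to_numpy()

    observed_aid = 0
    sims = np.zeros(R, dtype=np.int64)
    n_unplaceable = 0
    placements = [np.array(pos_all, copy=True) for _ in range(R)] if keep_placements else None

    order = np.argsort([f"{c}:{index.context_code(c, p)}" for c, p in zip(contigs, pos_all)],
                       kind="mergesort")
    groups: dict[tuple[str, int], list[int]] = {}
    for j in order:
        key = (contigs[j], index.context_code(contigs[j], pos_all[j]))
        groups.setdefault(key, []).append(j)

    for (contig, key), members in groups.items():
        members = np.asarray(members)
        mask = masks.get(contig)
        obs_flags = (
            mask[pos_all[members]] & eligible[members] if mask is not None
            else np.zeros(members.size, bool)
        )
        observed_aid += int(obs_flags.sum())
        pool = index.positions(contig, key) if key >= 0 else np.empty(0, np.int64)
        if key < 0 or pool.size == 0:
            n_unplaceable += members.size
            sims += int(obs_flags.sum())  # stays in place in every replicate
            continue
        draws = rng.integers(0, pool.size, size=(R, members.size))
        new_pos = pool[draws]
        if mask is not None:
            sims += (mask[new_pos] & eligible[members][None, :]).sum(axis=1)
        if keep_placements:
            for r in range(R):
                placements[r][members] = new_pos[r]

    m = len(variants)
    ors = np.full(R, np.nan)
    pvals = np.full(R, np.nan)
    cache: dict[int, tuple[float, float]] = {}
    for r in range(R):
        s = int(sims[r])
        if s not in cache:
            table = [[observed_aid, m - observed_aid], [s, m - s]]
            res = fisher_exact(table, alternative="two-sided")
            cache[s] = (res[0], res[1])
        ors[r], pvals[r] = cache[s]
    return NullDistribution(
        sample=str(variants["sample"].iloc[0]) if m else "",
        n_mutations=m,
        observed_aid=observed_aid,
        sim_counts=sims,
        odds_ratios=ors,
        p_values=pvals,
        n_unplaceable=n_unplaceable,
        placements=placements,
    )


def analytic_expected_aid(
    variants: pd.DataFrame,
    index: ContextIndex,
    genome: GenomeSequence,
    motifs: MotifSet = WRCY,
) -> float:
    """Closed-form mean simulated c-AID count: sum over mutations of the
    motif fraction of each mutation's context class (eligible types only)."""
    masks: dict[str, np.ndarray] = {}
    refs = variants["ref"].to_numpy()
    alts = variants["alt"].to_numpy()
    eligible = _eligibility(refs, alts)
    total = 0.0
    for j, (contig, pos) in enumerate(zip(variants["contig"], variants["pos"])):
        if contig not in genome.contig_names:
            continue
        if contig not in masks:
            masks[contig] = motif_target_mask(genome, contig, motifs)
        key = index.context_code(contig, int(pos))
        pool = index.positions(contig, key) if key >= 0 else np.empty(0, np.int64)
        if pool.size == 0:
            total += float(masks[contig][int(pos)] & bool(eligible[j]))
        elif eligible[j]:
            total += float(masks[contig][pool].mean())
    return total


def test_sample_significance(null: NullDistribution, alpha: float = 0.05) -> dict:
    """Per-sample significance by odds-ratio interval coverage.

    For each replicate the conditional-MLE 95% CI of the odds ratio of
    [[observed AID, observed non-AID], [simulated AID, simulated non-AID]]
    is computed; the sample is significant when fewer than ``alpha`` of the
    replicates' intervals contain 1.  Needs R >= 20, else the flag is None.
    Degenerate tables (a zero margin) are skipped and reported.
    """
    m = null.n_mutations
    n_cover = n_used = n_skipped = 0
    cache: dict[int, bool] = {}
    for s in null.sim_counts:
        s = int(s)
        if s in cache:
            covered = cache[s]
        else:
            table = np.array([[null.observed_aid, m - null.observed_aid], [s, m - s]])
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                cache[s] = None
                covered = None
            else:
                ci = odds_ratio(table).confidence_interval(1 - alpha)
                covered = bool(ci.low <= 1.0 <= ci.high)
                cache[s] = covered
        if covered is None:
            n_skipped += 1
        else:
            n_used += 1
            n_cover += covered
    frac_cover = n_cover / n_used if n_used else np.nan
    finite = null.odds_ratios[np.isfinite(null.odds_ratios)]
    direction = "enrichment" if finite.size and np.median(finite) > 1 else "depletion"
    flag = None if null.R < 20 or n_used == 0 else bool(frac_cover < alpha)
    return {
        "sample": null.sample,
        "significant": flag,
        "frac_or_ci_covering_1": frac_cover,
        "direction": direction,
        "n_replicates_used": n_used,
        "n_replicates_skipped": n_skipped,
        "observed": null.observed_aid,
        "expected": null.expected_aid,
        "enrichment_ratio": null.enrichment_ratio,
    }


def cohort_enrichment_ratio(
    nulls: list[NullDistribution], n_boot: int = 1000, seed: int = 0
) -> dict:
    """Cohort observed/expected c-AID ratio with a bootstrap 95% CI.

    ratio = (sum of observed counts) / (sum of per-sample mean simulated
    counts); the CI resamples samples with replacement.
    """
    if not nulls:
        raise ValueError("no samples")
    obs = np.array([n.observed_aid for n in nulls], dtype=float)
    exp = np.array([n.expected_aid for n in nulls], dtype=float)
    if exp.sum() <= 0:
        raise ValueError("zero expected c-AID count across the cohort")
    ratio = obs.sum() / exp.sum()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(nulls), size=(n_boot, len(nulls)))
    boot = obs[idx].sum(axis=1) / np.maximum(exp[idx].sum(axis=1), 1e-12)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"ratio": float(ratio), "ci_low": float(lo), "ci_high": float(hi),
            "n_samples": len(nulls)}
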