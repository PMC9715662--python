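"""MAF-style somatic SNV I/O and the cohort data model.

A cohort is a pair of tables: a variant table (one row per somatic SNV) and a
sample table (tumor type, purity).  Positions are converted from the 1-based
inclusive MAF convention to 0-based on read and back on write; internal code
only ever sees 0-based coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

#: internal column names for the variant table
VARIANT_COLUMNS = [
    "sample", "contig", "pos", "ref", "alt",
    "gene", "protein_pos", "classification",
    "t_alt_count", "t_ref_count",
]

#: default MAF header -> internal name
DEFAULT_DIALECT = {
    "Tumor_Sample_Barcode": "sample",
    "Chromosome": "contig",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Hugo_Symbol": "gene",
    "Protein_position": "protein_pos",
    "Variant_Classification": "classification",
    "t_alt_count": "t_alt_count",
    "t_ref_count": "t_ref_count",
}

MANDATORY = ["sample", "contig", "pos", "ref", "alt"]

AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass
class Cohort:
    """Somatic SNVs plus per-sample metadata.

    ``variants`` carries at least the :data:`VARIANT_COLUMNS`; derived
    columns (``aid``, ``process``, ``clonality``, ...) are appended by the
    analysis stages.  ``samples`` is indexed by sample barcode with optional
    ``tumor_type`` and ``purity`` columns.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame = None
    provenance: str = ""

    def __post_init__(self):
        if self.samples is None:
            barcodes = pd.unique(self.variants["sample"])
            self.samples = pd.DataFrame(index=pd.Index(barcodes, name="sample"))
        missing = set(self.variants["sample"]) - set(self.samples.index)
        if missing:
            raise ValueError(f"variants reference samples absent from metadata: {sorted(missing)[:5]}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.variants.loc[mask].reset_index(drop=True),
                      self.samples.copy(), self.provenance)


def _is_snv(ref: pd.Series, alt: pd.Series) -> pd.Series:
    ok = ref.isin(list("ACGT")) & alt.isin(list("ACGT"))
    return ok & (ref != alt)


def read_maf(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    chr_prefix: bool | None = False,
    autosomes_only: bool = False,
    strict: bool = False,
) -> Cohort:
    """Read a MAF-style TSV into a :class:`Cohort`.

    Only single-nucleotide substitutions are retained; indels and MNVs are
    dropped (counted in the log, or a hard error when ``strict``).
    ``chr_prefix`` normalizes contig names: False strips a leading "chr",
    True adds one, None leaves names untouched.
    """
    dialect = dialect or DEFAULT_DIALECT
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    rename = {src: dst for src, dst in dialect.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} lacks mandatory column(s): {missing}")

    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    bad = df["pos"].isna()
    if bad.any():
        if strict:
            raise ValueError(f"{bad.sum()} rows with unparsable positions in {path}")
        log.warning("dropping %d rows with unparsable positions", bad.sum())
        df = df[~bad]
    df["pos"] = df["pos"].astype(int) - 1  # 1-based inclusive -> 0-based

    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    snv = _is_snv(df["ref"], df["alt"])
    n_dropped = int((~snv).sum())
    if n_dropped:
        if strict:
            raise ValueError(f"{n_dropped} non-SNV rows in {path}")
        log.info("dropped %d non-SNV rows (indels/MNVs)", n_dropped)
    df = df[snv].copy()

    df["contig"] = df["contig"].astype(str)
    if chr_prefix is False:
        df["contig"] = df["contig"].str.replace("^chr", "", regex=True)
    elif chr_prefix is True:
        df["contig"] = "chr" + df["contig"].str.replace("^chr", "", regex=True)
    if autosomes_only:
        core = df["contig"].str.replace("^chr", "", regex=True)
        df = df[core.isin(AUTOSOMES)]

    for col in ("t_alt_count", "t_ref_count", "protein_pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[VARIANT_COLUMNS].reset_index(drop=True)
    return Cohort(df, provenance=str(path))


def write_maf(cohort: Cohort, path: str | Path, dialect: dict[str, str] | None = None) -> None:
    """Write a cohort back to MAF-style TSV (1-based inclusive positions)."""
    dialect = dialect or DEFAULT_DIALECT
    inv = {dst: src for src, dst in dialect.items()}
    out = cohort.variants.copy()
    out["pos"] = out["pos"].astype(int) + 1
    extra = [c for c in out.columns if c not in VARIANT_COLUMNS]
    out = out[VARIANT_COLUMNS + extra].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def validate_against_reference(cohort: Cohort, genome) -> dict:
    """Check every variant's ref allele against the genome base at its position.

    Returns a report dict with match/mismatch counts and the mismatching
    rows; never raises (use the counts in strict callers).
    """
    v = cohort.variants
    matches = pd.Series(False, index=v.index)
    for contig, idx in v.groupby("contig").groups.items():
        if contig not in genome.contig_names:
            continue
        codes = genome.codes(contig)
        pos = v.loc[idx, "pos"].to_numpy(int)
        in_bounds = (pos >= 0) & (pos < codes.size)
        ref_codes = pd.Series([ "ACGT".find(r) for r in v.loc[idx, "ref"]], index=idx)
        ok = in_bounds & (codes[pos.clip(0, codes.size - 1)] == ref_codes.to_numpy())
        matches.loc[idx] = ok
    mismatches = v.loc[~matches]
    return {
        "n_variants": len(v),
        "n_match": int(matches.sum()),
        "n_mismatch": int((~matches).sum()),
        "mismatches": mismatches,
    }
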