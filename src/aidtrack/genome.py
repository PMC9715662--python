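"""Reference-genome access and degenerate-motif machinery.

Canonical AID (c-AID) deaminates cytosine inside the degenerate
tetranucleotide WRCY (W = A/T, R = A/G, Y = C/T); on the opposite strand the
same site reads RGYW with the targeted guanine at the second position.  This
module expands IUPAC patterns, scans a genome for motif occurrences on both
strands, extracts sequence context around positions, and bins motif
occurrences into fixed windows.

All coordinates are 0-based half-open.  MAF-style 1-based input is converted
at I/O time (see :mod:`aidtrack.variant_io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "R": "AG", "Y": "CT", "S": "CG",
    "K": "GT", "M": "AC", "N": "ACGT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}

_COMPLEMENT = str.maketrans("ACGTNWRYSKMBDHV", "TGCANWYRSMKVHDB")

#: base -> integer code; N (and anything else) maps to 4 and never matches a motif
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def expand_degenerate_motif(pattern: str) -> list[str]:
    """Expand an IUPAC degenerate pattern into all matching fixed motifs.

    Returns the lexicographically sorted list; its length is the product of
    the per-position degeneracies ("WRCY" -> 8 motifs).
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"unknown IUPAC character {ch!r} in pattern {pattern!r}")
    out = [""]
    for ch in pattern.upper():
        out = [p + b for p in out for b in IUPAC[ch]]
    return sorted(out)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 code of every k-mer window; -1 where the window contains a non-ACGT base."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    val = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        w = codes[j : j + n]
        val = val * 4 + np.minimum(w, 3).astype(np.int64)
        bad |= w >= 4
    val[bad] = -1
    return val


def kmer_code(kmer: str) -> int:
    """Base-4 integer code of a fixed ACGT k-mer."""
    code = 0
    for ch in kmer:
        i = "ACGT".find(ch)
        if i < 0:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer {kmer!r}")
        code = code * 4 + i
    return code


class GenomeSequence:
    """In-memory genome with 0-based half-open sequence access.

    Construct from a dict of contig sequences or load from FASTA with
    :meth:`from_fasta`.  Sequences are stored uppercase; the accessor only
    ever returns characters in {A, C, G, T, N}.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._seqs = {
            name: re.sub("[^ACGT]", "N", seq.upper()) for name, seq in contigs.items()
        }
        self._codes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contig_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def sequence(self, contig: str, start: int, end: int) -> str:
        s = self._seq(contig)
        if start < 0 or end > len(s) or start > end:
            raise ValueError(
                f"window [{start}, {end}) out of bounds for contig {contig!r} "
                f"of length {len(s)}"
            )
        return s[start:end]

    def codes(self, contig: str) -> np.ndarray:
        """Cached uint8 code array for a contig (read-only)."""
        if contig not in self._codes:
            arr = encode(self._seq(contig))
            arr.flags.writeable = False
            self._codes[contig] = arr
        return self._codes[contig]

    def _seq(self, contig: str) -> str:
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        return self._seqs[contig]


@dataclass(frozen=True)
class MotifSet:
    """A degenerate motif, its fixed expansions, and where the mutated base sits.

    ``offset`` is the 0-based position of the targeted base within the
    plus-strand motif (2 for WRCY, whose third base is the deaminated C).
    ``substitutions`` lists the allowed ref->alt pairs at that base on the
    plus strand.
    """

    pattern: str
    offset: int
    substitutions: tuple[tuple[str, str], ...]
    motifs: tuple[str, ...] = field(init=False)
    rc_motifs: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        motifs = tuple(expand_degenerate_motif(self.pattern))
        object.__setattr__(self, "motifs", motifs)
        object.__setattr__(
            self, "rc_motifs", tuple(sorted(reverse_complement(m) for m in motifs))
        )

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def rc_offset(self) -> int:
        """Offset of the targeted base within the reverse-complement motif."""
        return self.length - 1 - self.offset


#: the c-AID target: C>T/G at WRCY (third base); minus strand reads RGYW.
WRCY = MotifSet("WRCY", offset=2, substitutions=(("C", "T"), ("C", "G")))
#: the APOBEC target: C>T/G at TCW (second base).
TCW = MotifSet("TCW", offset=1, substitutions=(("C", "T"), ("C", "G")))


def scan_motifs(genome: GenomeSequence, motifs: MotifSet, contig: str) -> pd.DataFrame:
    """All occurrences of a motif set on both strands of one contig.

    Plus-strand rows are direct matches of the expanded motifs; minus-strand
    rows are plus-strand matches of their reverse complements.  Overlapping
    matches are all reported; windows containing N never match.  Output is
    sorted by (start, strand) with columns
    ``contig, start, strand, motif, mutable_pos`` where ``motif`` is always
    given in the plus-orientation of the pattern (WRCY spelling) and
    ``mutable_pos`` is the plus-strand coordinate of the targeted base.
    """
    k = motifs.length
    codes = genome.codes(contig)
    kmers = _kmer_codes(codes, k)

    fwd_codes = {kmer_code(m): m for m in motifs.motifs}
    rev_codes = {kmer_code(reverse_complement(m)): m for m in motifs.motifs}

    frames = []
    fwd_hit = np.isin(kmers, list(fwd_codes))
    starts = np.flatnonzero(fwd_hit)
    frames.append(
        pd.DataFrame(
            {
                "contig": contig,
                "start": starts,
                "strand": "+",
                "motif": [fwd_codes[kmers[s]] for s in starts],
                "mutable_pos": starts + motifs.offset,
            }
        )
    )
    rev_hit = np.isin(kmers, list(rev_codes))
    starts = np.flatnonzero(rev_hit)
    frames.append(
        pd.DataFrame(
            {
                "contig": contig,
                "start": starts,
                "strand": "-",
                "motif": [rev_codes[kmers[s]] for s in starts],
                "mutable_pos": starts + motifs.rc_offset,
            }
        )
    )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["start", "strand"], kind="mergesort").reset_index(drop=True)


def scan_genome(genome: GenomeSequence, motifs: MotifSet = WRCY) -> pd.DataFrame:
    """Concatenated :func:`scan_motifs` over every contig."""
    return pd.concat(
        [scan_motifs(genome, motifs, c) for c in genome.contig_names],
        ignore_index=True,
    )


def extract_context(genome: GenomeSequence, contig: str, pos: int, flank: int) -> str:
    """The (2*flank+1)-mer centered on ``pos``, uppercase.

    Raises if the window leaves the contig.
    """
    length = genome.contig_lengths[contig] if contig in genome.contig_names else None
    if length is None:
        raise KeyError(f"unknown contig {contig!r}")
    if pos - flank < 0 or pos + flank >= length:
        raise ValueError(
            f"context window around {contig}:{pos} (flank {flank}) out of bounds"
        )
    return genome.sequence(contig, pos - flank, pos + flank + 1)


def motif_density_by_window(
    occurrences: pd.DataFrame,
    window: int,
    contig_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Occurrence counts in non-overlapping tiling windows.

    Each occurrence is counted once, in the window containing its
    ``mutable_pos``.  The last window of a contig is truncated at the contig
    end.  Output columns: ``contig, start, end, count, density,
    chrom_adjusted`` — density is count per bp of the window, chrom_adjusted
    is count divided by the full contig length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    frames = []
    for contig, clen in contig_lengths.items():
        edges = np.arange(0, clen + window, window)
        edges[-1] = min(edges[-1], clen)
        starts, ends = edges[:-1], edges[1:]
        pos = occurrences.loc[occurrences["contig"] == contig, "mutable_pos"].to_numpy()
        counts = np.histogram(pos, bins=edges)[0] if starts.size else np.empty(0, int)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": starts,
                    "end": ends,
                    "count": counts,
                    "density": counts / (ends - starts),
                    "chrom_adjusted": counts / clen,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_bed(df: pd.DataFrame, path: str | Path, cols: Iterable[str] = ("contig", "start", "end")) -> None:
    df.loc[:, list(cols)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, extra_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into contig/start/end + extras."""
    names = ["contig", "start", "end", *extra_cols]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=range(len(names)))
    df.columns = names
    df["contig"] = df["contig"].astype(str)
    return df
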