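"""Cancer cell fraction (CCF) estimation and clonal/subclonal calls.

CCF maps the variant allele fraction (VAF) through tumor purity and local
copy number:

    CCF = VAF * (rho * CNt + (1 - rho) * CNn) / (rho * m)

with rho the purity, CNt/CNn the tumor/normal total copy numbers and m the
multiplicity (mutated-allele copies per tumor cell).  The 95% CI comes from
an exact (Clopper-Pearson) binomial interval on the VAF, pushed through the
same linear map.  A mutation is subclonal when the upper CCF bound is below
0.95, clonal otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta


def estimate_multiplicity(vaf, purity, cn_tumor, cn_normal=2) -> np.ndarray:
    """Nearest-integer multiplicity, clipped to [1, CNt].

    m = round(VAF * (rho*CNt + (1-rho)*CNn) / rho).
    """
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn_tumor = np.asarray(cn_tumor, dtype=float)
    cn_normal = np.asarray(cn_normal, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must lie in (0, 1]")
    raw = vaf * (purity * cn_tumor + (1 - purity) * cn_normal) / purity
    m = np.rint(raw)
    return np.clip(m, 1, np.maximum(cn_tumor, 1))


def _clopper_pearson(alt: np.ndarray, depth: np.ndarray, level: float = 0.95):
    a = (1 - level) / 2
    lo = np.where(alt > 0, beta.ppf(a, alt, depth - alt + 1), 0.0)
    hi = np.where(alt < depth, beta.ppf(1 - a, alt + 1, depth - alt), 1.0)
    return lo, hi


def compute_ccf(
    alt_count,
    ref_count,
    purity,
    cn_tumor,
    cn_normal=2,
    multiplicity=None,
    clonal_cutoff: float = 0.95,
) -> pd.DataFrame:
    """CCF point estimates, exact binomial 95% CIs, and clonality calls.

    Inputs broadcast elementwise.  When ``multiplicity`` is None it is
    estimated with :func:`estimate_multiplicity`.  Reported CCF values are
    capped at 1 for readability but the *uncapped* upper bound decides the
    call: subclonal iff CI_high < ``clonal_cutoff``.
    """
    alt = np.atleast_1d(np.asarray(alt_count, dtype=float))
    ref = np.atleast_1d(np.asarray(ref_count, dtype=float))
    depth = alt + ref
    if np.any(depth <= 0):
        raise ValueError("zero sequencing depth")
    vaf = alt / depth
    purity = np.broadcast_to(np.asarray(purity, dtype=float), alt.shape)
    cn_t = np.broadcast_to(np.asarray(cn_tumor, dtype=float), alt.shape)
    cn_n = np.broadcast_to(np.asarray(cn_normal, dtype=float), alt.shape)
    if multiplicity is None:
        m = estimate_multiplicity(vaf, purity, cn_t, cn_n)
    else:
        m = np.broadcast_to(np.asarray(multiplicity, dtype=float), alt.shape)
        if np.any(m < 1):
            raise ValueError("multiplicity must be >= 1")

    scale = (purity * cn_t + (1 - purity) * cn_n) / (purity * m)
    ccf = vaf * scale
    vlo, vhi = _clopper_pearson(alt, depth)
    lo, hi = vlo * scale, vhi * scale
    call = np.where(hi < clonal_cutoff, "subclonal", "clonal")
    return pd.DataFrame(
        {
            "vaf": vaf,
            "purity": purity,
            "cn_tumor": cn_t,
            "cn_normal": cn_n,
            "multiplicity": m,
            "ccf": np.minimum(ccf, 1.0),
            "ccf_uncapped": ccf,
            "ccf_low": np.minimum(lo, 1.0),
            "ccf_high": np.minimum(hi, 1.0),
            "ccf_high_uncapped": hi,
            "clonality": call,
        }
    )


def annotate_clonality(cohort, purity_by_sample=None, cn_by_variant=None,
                       cn_default: float = 2.0) -> pd.DataFrame:
    """Attach CCF and clonality calls to a cohort's variant table.

    ``purity_by_sample`` maps sample barcode -> purity (default: the
    cohort's sample table, else 1.0).  ``cn_by_variant`` is an optional
    array of tumor total copy numbers aligned to the variant table.
    Variants without read counts get clonality "unknown".
    """
    v = cohort.variants
    if purity_by_sample is None:
        if cohort.samples is not None and "purity" in cohort.samples.columns:
            purity_by_sample = cohort.samples["purity"].to_dict()
        else:
            purity_by_sample = {}
    purity = v["sample"].map(lambda s: purity_by_sample.get(s, 1.0)).to_numpy(float)
    cn = (np.asarray(cn_by_variant, dtype=float) if cn_by_variant is not None
          else np.full(len(v), cn_default))

    alt = pd.to_numeric(v["t_alt_count"], errors="coerce").to_numpy(float)
    ref = pd.to_numeric(v["t_ref_count"], errors="coerce").to_numpy(float)
    ok = np.isfinite(alt) & np.isfinite(ref) & (alt + ref > 0)

    v["ccf"] = np.nan
    v["ccf_high"] = np.nan
    v["clonality"] = "unknown"
    if ok.any():
        res = compute_ccf(alt[ok], ref[ok], purity[ok], cn[ok])
        v.loc[ok, "ccf"] = res["ccf"].to_numpy()
        v.loc[ok, "ccf_high"] = res["ccf_high_uncapped"].to_numpy()
        v.loc[ok, "clonality"] = res["clonality"].to_numpy()
    return v
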