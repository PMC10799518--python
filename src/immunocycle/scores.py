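"""Per-sample tumor and immune scalar statistics.

MATH (mutant-allele tumor heterogeneity), TMB/TNB, transition/transversion
percentages, the immunoediting score (observed-to-expected neoantigen yield)
and Shannon clonotype entropy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .dnds import collapse_context

__all__ = [
    "math_score",
    "titv_fractions",
    "immunoediting_score",
    "shannon_entropy",
    "tmb_tnb",
    "sample_score_table",
]

#: Pyrimidine-strand transitions; everything else is a transversion.
_TRANSITIONS = {("C", "T"), ("T", "C")}


def math_score(vafs) -> float:
    """MATH = 100 * MAD / median of the variant allele fractions.

    MAD uses the normal-consistency constant 1.4826 (Mroz-Rocco definition).
    Scale-invariant; 0 for a perfectly homogeneous tumor.  Requires >= 2 VAFs.
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size < 2:
        raise ValueError("MATH requires at least 2 VAF values")
    if (v <= 0).any() or (v > 1).any():
        raise ValueError("VAFs must lie in (0, 1]")
    return float(100.0 * median_abs_deviation(v, scale="normal") / np.median(v))


def titv_fractions(catalog: pd.DataFrame) -> tuple[float, float]:
    """Percentages of transitions and transversions among substitutions."""
    if len(catalog) == 0:
        raise ValueError("mutation catalog is empty")
    ti = 0
    for tri, alt in zip(catalog["ref_tri"], catalog["alt"]):
        t, a = collapse_context(tri.upper(), alt.upper())
        ti += (t[1], a) in _TRANSITIONS
    ti_pct = 100.0 * ti / len(catalog)
    return ti_pct, 100.0 - ti_pct


def immunoediting_score(observed_neo: float, nonsyn: int, expected_rate: float) -> float:
    """Observed-to-expected neoantigen yield ratio.

    (observed_neo / nonsyn) / expected_rate, where ``expected_rate`` is the
    neoantigen yield per nonsynonymous mutation expected without immune
    pressure (from cohort calibration or simulation truth).  Values below 1
    indicate depletion of immunogenic mutations (editing); 1 is neutral.
    """
    if nonsyn <= 0:
        raise ValueError("immunoediting score undefined without nonsynonymous mutations")
    if expected_rate <= 0:
        raise ValueError("expected_rate must be > 0")
    if observed_neo < 0:
        raise ValueError("observed neoantigen count must be >= 0")
    return float((observed_neo / nonsyn) / expected_rate)


def shannon_entropy(clone_counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i of a clonotype count distribution."""
    c = np.asarray(list(clone_counts), dtype=float)
    if c.size == 0 or (c < 0).any() or c.sum() == 0:
        raise ValueError("clone counts must contain at least one positive value")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def tmb_tnb(
    catalog: pd.DataFrame,
    neo_counts: pd.Series,
    capture_mb: float | None = None,
) -> pd.DataFrame:
    """Per-sample tumor mutation burden and neoantigen burden.

    TMB is the nonsynonymous mutation count (divided by ``capture_mb`` when a
    capture size in megabases is given, TCGA-style raw count otherwise); TNB
    passes the supplied neoantigen counts through.  Samples present in
    ``neo_counts`` but absent from the catalog get TMB 0.
    """
    if capture_mb is not None and capture_mb <= 0:
        raise ValueError("capture_mb must be > 0")
    neo = pd.Series(neo_counts, dtype=float)
    nonsyn = catalog[catalog["impact"].isin(["missense", "nonsense"])]
    tmb = nonsyn.groupby("sample_id").size().reindex(neo.index, fill_value=0).astype(float)
    if capture_mb is not None:
        tmb = tmb / capture_mb
    return pd.DataFrame({"tmb": tmb, "tnb": neo})


def sample_score_table(
    catalog: pd.DataFrame,
    neo_counts: pd.Series,
    expected_rate: float | None = None,
    capture_mb: float | None = None,
) -> pd.DataFrame:
    """Combined per-sample score table (MATH, TMB, TNB, Ti/Tv %, editing).

    MATH and Ti/Tv are NaN for samples with too few mutations to define them.
    """
    out = tmb_tnb(catalog, neo_counts, capture_mb=capture_mb)
    math_col, ti_col, tv_col, edit_col = {}, {}, {}, {}
    grouped = dict(tuple(catalog.groupby("sample_id")))
    for sid in out.index:
        g = grouped.get(sid)
        math_col[sid] = math_score(g["vaf"]) if g is not None and len(g) >= 2 else np.nan
        if g is not None and len(g) >= 1:
            ti_col[sid], tv_col[sid] = titv_fractions(g)
        else:
            ti_col[sid] = tv_col[sid] = np.nan
        if expected_rate is not None:
            ns = 0 if g is None else int((g["impact"] != "synonymous").sum())
            edit_col[sid] = (
                immunoediting_score(out.loc[sid, "tnb"], ns, expected_rate)
                if ns > 0 else np.nan
            )
    out["math"] = pd.Series(math_col)
    out["ti_pct"] = pd.Series(ti_col)
    out["tv_pct"] = pd.Series(tv_col)
    if expected_rate is not None:
        out["editing"] = pd.Series(edit_col)
    return out
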