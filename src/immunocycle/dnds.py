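"""Somatic dN/dS selection inference with trinucleotide opportunity correction.

The estimator takes synonymous mutations as the neutral background: per
substitution context c, the neutral rate is r_c = s_c / L[c, syn] (observed
synonymous counts over synonymous opportunities pooled across the gene set),
the expected count of an impact class under neutrality is
E = sum_c r_c * L[c, class], and dN/dS = n_class / E.  A ratio above 1
indicates positive selection of nonsynonymous changes, below 1 negative
selection, and 1 neutrality.

Contexts use the 96 pyrimidine-collapsed trinucleotide classes (NCN>N); when
synonymous counts are sparse (< 5 in some used class) the model collapses
automatically to the 6 substitution types.  Uncertainty comes from the exact
conditional-binomial interval: given n_N + n_S mutations, n_N is binomial
with odds omega * (E/S), so a Clopper-Pearson interval on that proportion
transforms into an interval for omega that accounts for noise in both the
numerator and the synonymous background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import beta

log = logging.getLogger(__name__)

IMPACTS = ("synonymous", "missense", "nonsense")
IMPACT_CLASSES = ("all_nonsynonymous", "missense", "nonsense")

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: The 96 pyrimidine-collapsed trinucleotide substitution classes.
CONTEXTS_96 = tuple(
    f"{l}{c}{r}>{a}"
    for c in "CT"
    for a in _BASES
    if a != c
    for l in _BASES
    for r in _BASES
)
_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}

_table = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = dict(_table.forward_table)
_CODON_AA.update({c: "*" for c in _table.stop_codons})

__all__ = [
    "CONTEXTS_96",
    "IMPACTS",
    "IMPACT_CLASSES",
    "DnDsEstimate",
    "ResamplingNull",
    "OpportunityTable",
    "collapse_context",
    "codon_substitution_classes",
    "build_opportunities",
    "dnds_ratio",
    "resampling_null",
]


def collapse_context(tri: str, alt: str) -> tuple[str, str]:
    """Map a trinucleotide + alt base to the pyrimidine-central strand."""
    if tri[1] in "CT":
        return tri, alt
    return tri.translate(_COMP)[::-1], alt.translate(_COMP)


def _classify(ref_codon: str, alt_codon: str) -> str:
    ref_aa, alt_aa = _CODON_AA[ref_codon], _CODON_AA[alt_codon]
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def codon_substitution_classes(codon: str) -> list[tuple[int, str, str]]:
    """Exhaustive classification of the 9 single-base changes of one codon.

    Returns (position 0-2, alt base, impact) for each substitution; the
    brute-force table behind opportunity counting.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    out = []
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            out.append((pos, alt, _classify(codon, mutant)))
    return out


class OpportunityTable:
    """Per-gene counts L[context, impact] of possible single-base changes."""

    def __init__(self, per_gene: Mapping[str, np.ndarray]):
        self._per_gene = {g: np.asarray(a, dtype=float) for g, a in per_gene.items()}
        for g, a in self._per_gene.items():
            if a.shape != (96, 3):
                raise ValueError(f"gene {g}: opportunity array must be 96 x 3")
            if (a < 0).any():
                raise ValueError(f"gene {g}: negative opportunity counts")
            if a[:, 0].sum() == 0:
                raise ValueError(f"gene {g}: no synonymous opportunity")

    @property
    def genes(self) -> list[str]:
        return list(self._per_gene)

    def aggregate(self, genes: Iterable[str]) -> np.ndarray:
        """Summed 96 x 3 opportunity array over a gene set."""
        total = np.zeros((96, 3))
        for g in genes:
            if g not in self._per_gene:
                raise KeyError(f"gene {g!r} has no opportunity entry")
            total += self._per_gene[g]
        return total

    def to_frame(self) -> pd.DataFrame:
        frames = {
            g: pd.DataFrame(a, index=list(CONTEXTS_96), columns=list(IMPACTS))
            for g, a in self._per_gene.items()
        }
        return pd.concat(frames, names=["gene", "context"])


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def build_opportunities(cds: Mapping[str, str] | str | Path) -> OpportunityTable:
    """Enumerate all single-base substitutions of each CDS, classified against
    the standard genetic code and binned by collapsed trinucleotide context.

    Trailing partial codons and terminal stop codons are trimmed; an internal
    stop truncates the sequence with a warning.  The missing flank at a CDS
    boundary is taken as the terminal base itself (all positions count, so
    class totals are additive under gene concatenation).
    """
    if not isinstance(cds, Mapping):
        cds = _read_fasta(cds)
    per_gene: dict[str, np.ndarray] = {}
    for gene, seq in cds.items():
        seq = seq.upper()
        if any(b not in _BASES for b in seq):
            raise ValueError(f"gene {gene}: sequence contains non-ACGT characters")
        if len(seq) % 3:
            warnings.warn(f"gene {gene}: length not divisible by 3; trailing bases trimmed")
            seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for ci, codon in enumerate(codons):
            if _CODON_AA[codon] == "*":
                if ci != len(codons) - 1:
                    warnings.warn(f"gene {gene}: internal stop codon; sequence truncated")
                codons = codons[:ci]
                break
        seq = "".join(codons)
        if not seq:
            raise ValueError(f"gene {gene}: no coding sequence left after trimming")
        L = np.zeros((96, 3))
        imp_idx = {imp: i for i, imp in enumerate(IMPACTS)}
        for ci, codon in enumerate(codons):
            for pos, alt, impact in codon_substitution_classes(codon):
                i = 3 * ci + pos
                left = seq[i - 1] if i > 0 else seq[i]
                right = seq[i + 1] if i < len(seq) - 1 else seq[i]
                tri, a = collapse_context(left + seq[i] + right, alt)
                L[_CTX_INDEX[f"{tri}>{a}"], imp_idx[impact]] += 1
        per_gene[gene] = L
    return OpportunityTable(per_gene)


@dataclass
class DnDsEstimate:
    ratio: float
    ci_low: float
    ci_high: float
    n_obs: int
    e_exp: float
    impact_class: str
    gene_set_name: str | None = None
    stratum: str | None = None
    n_contexts: int = 96


@dataclass
class ResamplingNull:
    set_size: int
    iterations: int
    null_ratios: np.ndarray
    observed: float
    empirical_p: float


def _context_key(ref_tri: str, alt: str) -> str:
    tri, a = collapse_context(ref_tri.upper(), alt.upper())
    key = f"{tri}>{a}"
    if key not in _CTX_INDEX:
        raise ValueError(f"invalid substitution context {ref_tri}>{alt}")
    return key


def _collapse_to_types(L: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate 96 trinucleotide classes to the 6 substitution types."""
    types = [ctx[1] + ">" + ctx[4] for ctx in CONTEXTS_96]
    uniq = sorted(set(types))
    t_idx = np.array([uniq.index(t) for t in types])
    L6 = np.zeros((6, L.shape[1]))
    s6 = np.zeros(6)
    for i in range(96):
        L6[t_idx[i]] += L[i]
        s6[t_idx[i]] += s[i]
    return L6, s6


def dnds_ratio(
    catalog: pd.DataFrame,
    genes: Iterable[str],
    opportunities: OpportunityTable,
    impact_class: str = "all_nonsynonymous",
    samples: Sequence[str] | None = None,
    gene_set_name: str | None = None,
    stratum: str | None = None,
    min_syn_per_context: int = 5,
    alpha: float = 0.05,
) -> DnDsEstimate:
    """Context-corrected dN/dS for a gene set, optionally within a sample stratum.

    ``catalog`` needs columns sample_id, gene, impact, ref_tri, alt.  Records
    with impacts outside {synonymous, missense, nonsense} are ignored.
    Raises if the stratum x set has no synonymous mutation (the neutral rate
    is then unidentifiable; pool strata or widen the set).
    """
    if impact_class not in IMPACT_CLASSES:
        raise ValueError(f"impact_class must be one of {IMPACT_CLASSES}")
    genes = sorted(set(genes))
    sub = catalog[catalog["gene"].isin(genes)]
    if samples is not None:
        sub = sub[sub["sample_id"].isin(set(samples))]
    sub = sub[sub["impact"].isin(IMPACTS)]

    L = opportunities.aggregate(genes)  # 96 x 3 (syn, mis, non)
    s = np.zeros(96)
    syn = sub[sub["impact"] == "synonymous"]
    for tri, alt in zip(syn["ref_tri"], syn["alt"]):
        s[_CTX_INDEX[_context_key(tri, alt)]] += 1

    if L[:, 0].sum() == 0:
        raise ValueError("gene set has zero synonymous opportunity")
    if s.sum() == 0:
        raise ValueError(
            "no synonymous mutation observed in this stratum and gene set; "
            "the neutral rate is unidentifiable — pool strata or enlarge the set"
        )

    used = L[:, 0] > 0
    n_contexts = 96
    if (s[used] < min_syn_per_context).any():
        L, s = _collapse_to_types(L, s)
        used = L[:, 0] > 0
        n_contexts = 6

    dropped = s[~used].sum()
    if dropped:
        log.warning("%d synonymous mutations fall in contexts with no synonymous "
                    "opportunity; dropped", int(dropped))
    if impact_class == "all_nonsynonymous":
        Lc = L[:, 1] + L[:, 2]
        n_obs = int((sub["impact"] != "synonymous").sum())
    else:
        col = {"missense": 1, "nonsense": 2}[impact_class]
        Lc = L[:, col]
        n_obs = int((sub["impact"] == impact_class).sum())

    # contexts with class opportunity but no synonymous opportunity cannot be
    # rated from their own synonymous counts; they receive the pooled mean
    # rate so their expected contribution is not silently discarded
    r = np.zeros_like(s)
    r[used] = s[used] / L[used, 0]
    r_mean = s[used].sum() / L[used, 0].sum()
    e_exp = float((r[used] * Lc[used]).sum() + r_mean * Lc[~used].sum())
    if e_exp == 0:
        raise ValueError("expected count is zero; no opportunity for this class")
    ratio = n_obs / e_exp

    # exact conditional-binomial interval on omega (see module docstring)
    S = float(s[used].sum())
    R = e_exp / S
    a2 = alpha / 2.0
    p_lo = beta.ppf(a2, n_obs, S + 1) if n_obs > 0 else 0.0
    p_hi = beta.ppf(1 - a2, n_obs + 1, S)
    ci_low = p_lo / (1 - p_lo) / R if p_lo < 1 else np.inf
    ci_high = p_hi / (1 - p_hi) / R if p_hi < 1 else np.inf

    return DnDsEstimate(float(ratio), float(ci_low), float(ci_high), n_obs,
                        e_exp, impact_class, gene_set_name, stratum, n_contexts)


def resampling_null(
    catalog: pd.DataFrame,
    universe: Sequence[str],
    target_set: Sequence[str],
    opportunities: OpportunityTable,
    impact_class: str = "all_nonsynonymous",
    iterations: int = 500,
    seed: int | None = None,
    samples: Sequence[str] | None = None,
) -> ResamplingNull:
    """Empirical null for a gene set's dN/dS from size-matched random sets.

    Draws ``iterations`` gene sets of size |target_set| without replacement
    from ``universe`` and computes the same ratio for each;
    empirical_p = (1 + #{null >= observed}) / (iterations + 1).
    """
    universe = sorted(set(universe))
    target = sorted(set(target_set))
    if not set(target) <= set(universe):
        raise ValueError("target set is not contained in the gene universe")
    if len(universe) <= len(target):
        raise ValueError("universe must be strictly larger than the target set")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    observed = dnds_ratio(catalog, target, opportunities, impact_class,
                          samples=samples).ratio
    rng = np.random.default_rng(seed)
    null = np.empty(iterations)
    for i in range(iterations):
        draw = rng.choice(universe, size=len(target), replace=False)
        null[i] = dnds_ratio(catalog, draw, opportunities, impact_class,
                             samples=samples).ratio
    p = (1.0 + float((null >= observed).sum())) / (iterations + 1.0)
    return ResamplingNull(len(target), iterations, null, observed, p)
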