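"""Assembly of the 8-axis cancer immunogram and auxiliary signature scores.

Seven axes are sample-level gene-set enrichment scores (IGS1 T-cell immunity,
IGS3 priming/activation, IGS4 trafficking/infiltration, IGS5 tumor-cell
recognition, IGS6 inhibitor cells, IGS7 checkpoint expression, IGS8 inhibitory
molecules); IGS2 (tumor antigenicity) is the cohort-wise fractional rank of
the log neoantigen burden, which places it on a bounded scale commensurate
with the enrichment axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

#: Fixed axis order of the immunogram.
AXES = ("IGS1", "IGS2", "IGS3", "IGS4", "IGS5", "IGS6", "IGS7", "IGS8")
#: Axes computed by gene-set enrichment (all but the neoantigen-burden axis).
ENRICHMENT_AXES = tuple(a for a in AXES if a != "IGS2")

__all__ = [
    "AXES",
    "ENRICHMENT_AXES",
    "GeneSetCollection",
    "tnb_axis",
    "assemble_immunogram",
    "signature_score",
    "radar_summary",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the mapping from immunogram axis to set name."""

    sets: dict[str, list[str]]
    axis_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.axis_map:
            self.axis_map = {a: a for a in ENRICHMENT_AXES if a in self.sets}
        for axis, name in self.axis_map.items():
            if name not in self.sets or not self.sets[name]:
                raise ValueError(f"axis {axis} maps to missing or empty set {name!r}")

    def axis_sets(self) -> dict[str, list[str]]:
        """Gene sets keyed by axis name, in immunogram order."""
        return {axis: self.sets[self.axis_map[axis]] for axis in ENRICHMENT_AXES
                if axis in self.axis_map}


def tnb_axis(neoantigen_counts: pd.Series) -> pd.Series:
    """IGS2: fractional rank (i - 0.5)/n of log10(neoantigen count + 1).

    Ties receive their average rank, so a constant cohort scores 0.5
    everywhere.  Values lie in (0, 1) and are monotone in the counts.
    """
    counts = pd.Series(neoantigen_counts, dtype=float)
    if counts.empty:
        raise ValueError("neoantigen counts are empty")
    if (counts < 0).any():
        raise ValueError("neoantigen counts must be >= 0")
    ranks = rankdata(np.log10(counts.to_numpy() + 1.0), method="average")
    return pd.Series((ranks - 0.5) / len(counts), index=counts.index, name="IGS2")


def assemble_immunogram(enrich: pd.DataFrame, igs2: pd.Series) -> pd.DataFrame:
    """Combine enrichment axes and the IGS2 axis into a sample x 8 matrix.

    Samples without an IGS2 value are dropped with a logged warning; a
    completely disjoint sample universe is an error.
    """
    missing_axes = [a for a in ENRICHMENT_AXES if a not in enrich.columns]
    if missing_axes:
        raise ValueError(f"enrichment table lacks axes: {missing_axes}")
    common = enrich.index.intersection(igs2.index)
    if len(common) == 0:
        raise ValueError("enrichment table and IGS2 share no samples")
    dropped = enrich.index.difference(common)
    if len(dropped):
        log.warning("dropping %d samples without an IGS2 value", len(dropped))
    ig = enrich.loc[common, list(ENRICHMENT_AXES)].copy()
    ig["IGS2"] = igs2.loc[common]
    return ig[list(AXES)]


def signature_score(expr_tpm: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Per-sample signature score: geometric mean of log2(TPM+1) over genes.

    ``expr_tpm`` is on the raw TPM scale (>= 0).  Duplicate gene ids are
    counted once; genes absent from the matrix are ignored with a warning.
    A member gene at TPM 0 contributes the factor log2(1) = 0, which makes
    the geometric mean 0 for that sample.
    """
    wanted = list(dict.fromkeys(genes))
    present = [g for g in wanted if g in expr_tpm.index]
    n_missing = len(wanted) - len(present)
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    if n_missing:
        log.warning("signature: %d of %d genes absent from matrix", n_missing, len(wanted))
    vals = np.log2(expr_tpm.loc[present].to_numpy(dtype=float) + 1.0)
    if (vals < 0).any():
        raise ValueError("TPM values must be >= 0")
    with np.errstate(divide="ignore"):
        logs = np.log(vals)
    score = np.exp(logs.mean(axis=0))
    score[np.any(vals == 0.0, axis=0)] = 0.0
    return pd.Series(score, index=expr_tpm.columns, name="signature")


def radar_summary(ig: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster per-axis medians (the radar-plot table).

    Every sample of ``ig`` must be labeled; an empty cluster (a label value
    with no samples) cannot arise from a Series join, but a label index that
    misses samples raises.
    """
    labels = pd.Series(labels)
    missing = ig.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"{len(missing)} samples have no cluster label")
    lab = labels.loc[ig.index]
    med = ig.groupby(lab).median()
    med.index.name = "cluster"
    return med
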