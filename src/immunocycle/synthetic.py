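"""Synthetic tumor cohorts with planted immunogram, selection and survival structure.

The generator emulates the statistical structure the downstream analysis
assumes: samples belong to one of a few immunogram archetypes, each defined
by target enrichment levels on the eight axes; member genes of an axis set
are shifted in expression so the sample-level enrichment tracks the template;
somatic mutation catalogs are drawn with a subtype-specific nonsynonymous
rate multiplier omega over a context-resolved opportunity table (synonymous
mutations stay neutral); VAFs follow subtype-specific Beta models; neoantigen
counts are binomial thinnings of the nonsynonymous count; survival times are
exponential with subtype hazard multipliers and independent censoring.

Default archetypes follow the qualitative four-subtype pattern of hot/cold
tumor biology: I "hot/exhausted" (all axes high), II "cold/radical"
(stimulatory axes and antigenicity low, inhibitory molecules high),
III "cold/recognizable" (tumor-cell recognition high, the rest moderate-low),
IV "cold/inert" (all axes low but antigenicity high).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dnds import CONTEXTS_96, OpportunityTable, build_opportunities
from .immunogram import AXES, ENRICHMENT_AXES, GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "CohortTruth",
    "MutationData",
    "SimulatedCohort",
    "default_archetypes",
    "generate_cds",
    "generate_expression",
    "generate_mutations",
    "generate_clinical",
    "simulate_cohort",
    "write_cohort",
]

_STAGES = ("I", "II", "III", "IV")


def default_archetypes() -> dict[str, list[float]]:
    """Four named axis-level templates (order IGS1..IGS8, levels in [-1, 1])."""
    return {
        #         IGS1   IGS2   IGS3   IGS4   IGS5   IGS6   IGS7   IGS8
        "I":   [ 0.95,  0.50,  0.95,  0.95,  0.50,  0.90,  0.90,  0.36],
        "II":  [-0.24, -0.50, -0.24, -0.24, -0.20,  0.00,  0.00,  0.95],
        "III": [-0.38, -0.20, -0.38, -0.38,  0.95, -0.10, -0.10, -0.24],
        "IV":  [-0.20,  0.90, -0.20, -0.20, -0.30, -0.84, -0.84, -0.55],
    }


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_samples: int = 400
    archetypes: dict[str, list[float]] = field(default_factory=default_archetypes)
    axis_noise_sd: float = 0.1
    n_genes: int = 1200
    genes_per_set: int = 40
    axis_effect: float = 3.0          # log2 units of shift at template level 1
    background_sd: float = 0.5        # cross-sample sd of non-member genes
    n_mut_genes: int = 50
    cds_codons: int = 300
    mutations_per_sample: float = 120.0
    omega_by_subtype: dict[str, float] = field(
        default_factory=lambda: {"I": 2.0, "II": 3.0, "III": 1.8, "IV": 1.2})
    neoantigens_per_nonsyn: dict[str, float] = field(
        default_factory=lambda: {"I": 0.25, "II": 0.08, "III": 0.15, "IV": 0.45})
    vaf_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"I": (5.0, 5.0), "II": (1.8, 2.8),
                                 "III": (5.0, 5.0), "IV": (1.8, 2.8)})
    hazard_by_subtype: dict[str, float] = field(
        default_factory=lambda: {"I": 0.6, "II": 2.0, "III": 1.2, "IV": 1.0})
    baseline_median_os: float = 24.0  # months at hazard multiplier 1
    censoring_rate: float = 0.3
    stage_probs: dict[str, list[float]] = field(
        default_factory=lambda: {"I": [0.40, 0.30, 0.20, 0.10],
                                 "II": [0.15, 0.25, 0.30, 0.30],
                                 "III": [0.30, 0.30, 0.25, 0.15],
                                 "IV": [0.30, 0.30, 0.25, 0.15]})
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.archetypes) < 2:
            raise ValueError("need at least 2 archetypes")
        for name, levels in self.archetypes.items():
            if len(levels) != len(AXES):
                raise ValueError(f"archetype {name!r} must have exactly 8 axis levels")
            if any(abs(v) > 1 for v in levels):
                raise ValueError(f"archetype {name!r} levels must lie in [-1, 1]")
        if self.n_genes < len(AXES) * self.genes_per_set:
            raise ValueError("n_genes must be >= 8 * genes_per_set")
        if self.axis_noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.mutations_per_sample < 0:
            raise ValueError("mutations_per_sample must be >= 0")
        for name in self.archetypes:
            if self.omega_by_subtype.get(name, 1.0) < 0:
                raise ValueError("omega must be >= 0")
            rate = self.neoantigens_per_nonsyn.get(name, 0.2)
            if rate < 0:
                raise ValueError("neoantigens_per_nonsyn must be >= 0")
            if self.hazard_by_subtype.get(name, 1.0) <= 0:
                raise ValueError("hazard multipliers must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")

    def subtype_names(self) -> list[str]:
        return list(self.archetypes)


@dataclass
class CohortTruth:
    """Planted parameters of a simulated cohort, for recovery tests."""

    true_labels: pd.Series            # sample -> archetype name
    true_omega: dict[str, float]
    true_hazards: dict[str, float]
    true_neo_rates: dict[str, float]
    seed: int


@dataclass
class MutationData:
    catalog: pd.DataFrame             # sample_id, gene, impact, ref_tri, alt, vaf
    neoantigens: pd.Series            # sample -> neoantigen count


@dataclass
class SimulatedCohort:
    expression: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: CohortTruth
    mutations: MutationData
    clinical: pd.DataFrame
    opportunities: OpportunityTable
    cds: dict[str, str]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cds(n_genes: int = 50, codons: int = 300, seed: int | None = None,
                 prefix: str = "G") -> dict[str, str]:
    """Random stop-free coding sequences for opportunity counting."""
    rng = np.random.default_rng(seed)
    sense = [c for c in
             ("".join(b) for b in __import__("itertools").product("ACGT", repeat=3))
             if c not in ("TAA", "TAG", "TGA")]
    out = {}
    for i in range(n_genes):
        idx = rng.integers(0, len(sense), size=codons)
        out[f"{prefix}{i + 1:04d}"] = "".join(sense[j] for j in idx)
    return out


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GeneSetCollection, CohortTruth]:
    """Gene-by-sample log2(TPM+1)-scale matrix with planted axis enrichment.

    The seven enrichment axes each own a disjoint gene set; member genes of a
    sample in archetype a are shifted by ``axis_effect * (level_a + noise)``
    where the noise is the per-sample axis-level jitter ``axis_noise_sd``.
    Background genes vary independently.  Deterministic under the config seed.
    """
    rng_assign, rng_expr, *_ = _streams(config.seed, 4)
    names = config.subtype_names()
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    labels = pd.Series(rng_assign.choice(names, size=config.n_samples),
                       index=samples, name="subtype")

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    sets: dict[str, list[str]] = {}
    member_of = np.full(config.n_genes, -1)  # axis index among ENRICHMENT_AXES
    for ai, axis in enumerate(ENRICHMENT_AXES):
        lo = ai * config.genes_per_set
        sets[axis] = genes[lo : lo + config.genes_per_set]
        member_of[lo : lo + config.genes_per_set] = ai
    collection = GeneSetCollection(sets=sets)

    mu = rng_expr.uniform(2.0, 8.0, size=config.n_genes)
    X = np.tile(mu[:, None], (1, config.n_samples))
    template = np.array([config.archetypes[n] for n in names])  # arch x 8
    axis_cols = [AXES.index(a) for a in ENRICHMENT_AXES]
    arch_idx = np.array([names.index(l) for l in labels])
    # per-sample, per-axis effective level = template level + jitter
    lvl = template[arch_idx][:, axis_cols]  # samples x 7
    if config.axis_noise_sd > 0:
        lvl = lvl + rng_expr.normal(0.0, config.axis_noise_sd, size=lvl.shape)
    for ai in range(len(ENRICHMENT_AXES)):
        rows = member_of == ai
        X[rows, :] += config.axis_effect * lvl[:, ai][None, :]
    bg = member_of < 0
    X[bg, :] += rng_expr.normal(0.0, config.background_sd,
                                size=(int(bg.sum()), config.n_samples))
    np.clip(X, 0.0, None, out=X)

    truth = CohortTruth(
        true_labels=labels,
        true_omega={n: config.omega_by_subtype.get(n, 1.0) for n in names},
        true_hazards={n: config.hazard_by_subtype.get(n, 1.0) for n in names},
        true_neo_rates={n: config.neoantigens_per_nonsyn.get(n, 0.2) for n in names},
        seed=config.seed,
    )
    return pd.DataFrame(X, index=genes, columns=samples), collection, truth


def _subtype_weights(L: np.ndarray, omega: float) -> np.ndarray:
    """Sampling weights over (gene, context, class) cells: opportunity x rate."""
    w = L.copy()
    w[..., 1:] *= omega
    return w


def generate_mutations(
    config: SyntheticConfig,
    truth: CohortTruth,
    opportunities: OpportunityTable,
) -> MutationData:
    """Somatic mutation catalog under subtype-specific selection intensity.

    Synonymous mutations arrive in proportion to context opportunity
    (neutral background); missense and nonsense rates are scaled by the
    subtype's omega.  Each record carries a Beta-distributed VAF; neoantigen
    counts per sample are Binomial(nonsynonymous count, subtype rate).
    """
    _, _, rng, _ = _streams(config.seed, 4)
    genes = opportunities.genes
    L = np.stack([opportunities.aggregate([g]) for g in genes])  # G x 96 x 3

    records: list[tuple] = []
    neo: dict[str, int] = {}
    impacts = np.array(["synonymous", "missense", "nonsense"])
    ctx = np.array(CONTEXTS_96)
    labels = truth.true_labels
    for subtype in labels.unique():
        sids = labels.index[labels == subtype].to_list()
        omega = truth.true_omega[subtype]
        a, b = config.vaf_model.get(subtype, (2.0, 2.0))
        w = _subtype_weights(L, omega).reshape(-1)
        if w.sum() == 0:
            for sid in sids:
                neo[sid] = 0
            continue
        p = w / w.sum()
        total = rng.poisson(config.mutations_per_sample * len(sids))
        if total == 0:
            for sid in sids:
                neo[sid] = 0
            continue
        counts = rng.multinomial(total, p)
        nz = np.flatnonzero(counts)
        cell_idx = np.repeat(nz, counts[nz])
        rng.shuffle(cell_idx)
        owner = rng.integers(0, len(sids), size=total)  # Poisson thinning
        gi, rem = np.divmod(cell_idx, 96 * 3)
        ci, ii = np.divmod(rem, 3)
        vafs = rng.beta(a, b, size=total)
        vafs = np.clip(vafs, 1e-6, 1.0)
        nonsyn_per_sample = np.zeros(len(sids), dtype=int)
        for t in range(total):
            sid = sids[owner[t]]
            tri_alt = ctx[ci[t]]
            records.append((sid, genes[gi[t]], impacts[ii[t]],
                            tri_alt[:3], tri_alt[4], vafs[t]))
            nonsyn_per_sample[owner[t]] += ii[t] > 0
        rate = min(1.0, truth.true_neo_rates[subtype])
        draws = rng.binomial(nonsyn_per_sample, rate)
        for s, sid in enumerate(sids):
            neo[sid] = int(draws[s])
    catalog = pd.DataFrame(records,
                           columns=["sample_id", "gene", "impact", "ref_tri", "alt", "vaf"])
    neo_series = pd.Series(neo, name="neoantigens").reindex(labels.index, fill_value=0)
    return MutationData(catalog, neo_series.astype(int))


def generate_clinical(truth: CohortTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Exponential survival with subtype hazard multipliers, independent
    censoring calibrated to the configured censoring fraction, and stage
    drawn from subtype-specific probabilities."""
    *_, rng = _streams(config.seed, 4)
    labels = truth.true_labels
    lam0 = np.log(2.0) / config.baseline_median_os
    h = np.array([truth.true_hazards[l] for l in labels])
    t_event = rng.exponential(1.0 / (lam0 * h))
    if config.censoring_rate > 0:
        lam_c = lam0 * float(np.mean(h)) * config.censoring_rate / (1 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=len(labels))
    else:
        t_cens = np.full(len(labels), np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    stages = [
        _STAGES[rng.choice(4, p=np.asarray(config.stage_probs.get(l, [0.25] * 4)))]
        for l in labels
    ]
    types = np.array(["TypeA", "TypeB", "TypeC"])
    names = list(truth.true_omega)
    type_p = {n: np.roll([0.5, 0.3, 0.2], i % 3) for i, n in enumerate(names)}
    cancer_type = [types[rng.choice(3, p=type_p[l])] for l in labels]
    return pd.DataFrame({
        "os_time": np.maximum(os_time, 1e-6),
        "os_event": os_event,
        "subtype": labels.to_numpy(),
        "stage": stages,
        "cancer_type": cancer_type,
    }, index=labels.index)


def simulate_cohort(config: SyntheticConfig) -> SimulatedCohort:
    """Full cohort: expression + gene sets, mutations + neoantigens, clinical."""
    expression, gene_sets, truth = generate_expression(config)
    cds_seed = int(np.random.SeedSequence(config.seed).spawn(5)[4].generate_state(1)[0]
                   % (2**31))
    cds = generate_cds(config.n_mut_genes, config.cds_codons, seed=cds_seed, prefix="M")
    opp = build_opportunities(cds)
    mutations = generate_mutations(config, truth, opp)
    clinical = generate_clinical(truth, config)
    return SimulatedCohort(expression, gene_sets, truth, mutations, clinical, opp, cds)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort artifacts as plain-text files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "mutations": out / "mutations.tsv",
        "neoantigens": out / "neoantigens.tsv",
        "clinical": out / "clinical.tsv",
        "cds": out / "cds.fasta",
        "truth": out / "truth.json",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t")
    with open(paths["gene_sets"], "w") as fh:
        for name, members in cohort.gene_sets.sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    cohort.mutations.catalog.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.mutations.neoantigens.rename("neoantigens").to_csv(
        paths["neoantigens"], sep="\t", index_label="sample_id")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index_label="sample_id")
    with open(paths["cds"], "w") as fh:
        for g, seq in cohort.cds.items():
            fh.write(f">{g}\n{seq}\n")
    with open(paths["truth"], "w") as fh:
        json.dump({
            "true_labels": cohort.truth.true_labels.to_dict(),
            "true_omega": cohort.truth.true_omega,
            "true_hazards": cohort.truth.true_hazards,
            "true_neo_rates": cohort.truth.true_neo_rates,
            "seed": cohort.truth.seed,
        }, fh, indent=1)
    return paths
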