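"""Synthetic paired tumor/normal expression data with planted structure.

The study's raw arrays were never deposited, so every downstream stage is
exercised on simulated data that reproduces the *regime* of the design:
three tumor/normal pairs, a mix of mRNA and lncRNA probes, planted fold
changes of at least 2x, latent-factor co-expression modules shared between
lncRNAs and mRNAs, lncRNA-adjacent coding genes within the cis window, and
planted/decoy TF target and term sets. The generative model for sample s
and gene g is

    x_gs = mu_g + a_pair(s) + b_{g,pair(s)} + delta_g * 1[s tumor]
           + lambda * f_{m(g),s} + eps_gs

with gene baseline mu_g ~ N(8, 2) (log2 scale); an array-level shift
a_p ~ N(0, tau^2) shared by all genes of a sample pair; a per-gene
between-subject effect b_gp ~ N(0, phi^2) shared by the tumor and normal
sample of a pair (it cancels in paired ratios but dominates cross-sample
correlation, as in real paired designs); the planted condition effect
delta_g; a module factor f ~ N(0, 1) loaded with weight lambda onto every
module member (by default drawn per pair, modelling subject-level module
activity — for module members the factor replaces their independent
subject effect, so module genes are marginally exchangeable with the
rest); and residual noise eps ~ N(0, sigma^2). Every generator is a pure
function of (config, seed): the planted truth (DE effects, module
membership, cis pairs, core TF, term membership) is returned alongside
the data for recovery testing.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .containers import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    ExpressionMatrix,
    GeneAnnotationTable,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition parameters for the simulator.

    Defaults describe a scaled-down array experiment: 3 tissue pairs,
    200 mRNA + 60 lncRNA probes, and one dysregulated co-expression
    module — 10 program mRNAs and 30 lncRNAs riding one subject-level
    factor, the scaled analog of a proliferation program — whose mRNAs
    are 80%-covered by the core TF's regulon. The core regulon is broad
    (40 of 200 mRNAs, the mega-regulon profile of a master cell-cycle
    regulator) while the 10 decoy TFs have ordinary 5-gene regulons.
    Module genes are always differentially expressed with a coherent
    direction (the network stages only ever see differential genes, so
    planted structure must live inside the DE sets to be discoverable);
    among the remaining genes, ``frac_de_*`` are, with the high lncRNA
    fraction supplying the DEL population the network stages consume.
    Signed log2 fold changes have magnitude uniform on [1, 3].
    """

    n_pairs: int = 3
    n_mrna: int = 200
    n_lncrna: int = 60
    frac_de_mrna: float = 0.15
    frac_de_lncrna: float = 0.95
    lfc_low: float = 1.0  # log2 units; 1.0 == linear fold change 2
    lfc_high: float = 3.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    pair_sd: float = 0.5  # tau: array-level shift shared by all genes of a sample pair
    subject_sd: float = 2.0  # phi: per-gene biological between-subject variation
    noise_sd: float = 0.3  # sigma
    n_modules: int = 1
    module_size_mrna: int = 10
    module_size_lncrna: int = 30
    module_loading: float = 2.0  # lambda
    module_factor_per: str = "pair"  # 'pair' (subject-level activity) or 'sample'
    n_tfs: int = 11  # one core + (n_tfs - 1) decoys
    core_tf_coverage: float = 0.8
    core_tf_set_size: int = 40  # total core regulon (coverage core + random fill)
    decoy_tf_set_size: int = 5
    n_terms: int = 20
    term_coverage: float = 0.8
    planted_term_size: int = 80  # broad module term (fill beyond the module)
    decoy_term_size: int = 15
    module_sign_shared: bool = True  # module members share one DE direction
    n_cis_pairs: int = 5
    cis_window: int = 100_000
    frac_absent: float = 0.0
    n_chromosomes: int = 4
    chrom_length: int | None = None  # None: sized automatically
    gene_len_min: int = 500
    gene_len_max: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_mrna", "n_lncrna", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_de_mrna", "frac_de_lncrna"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValidationError(f"{name} must lie in [0, 1)")
        if not (0 < self.core_tf_coverage <= 1):
            raise ValidationError("core_tf_coverage must lie in (0, 1]")
        if not (0 < self.term_coverage <= 1):
            raise ValidationError("term_coverage must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.pair_sd < 0 or self.baseline_sd < 0 or self.subject_sd < 0:
            raise ValidationError("standard deviations must be non-negative")
        if not (0 <= self.frac_absent < 1):
            raise ValidationError("frac_absent must lie in [0, 1)")
        if self.n_modules < 0 or self.n_cis_pairs < 0:
            raise ValidationError("counts must be non-negative")
        if self.decoy_tf_set_size < 1 or self.core_tf_set_size < 1:
            raise ValidationError("TF target sets need at least one member")
        if self.planted_term_size > self.n_genes or self.decoy_term_size > self.n_genes:
            raise ValidationError("term sets larger than the gene pool")
        if self.n_modules * self.module_size_mrna > self.n_mrna:
            raise ValidationError("modules demand more mRNAs than simulated")
        if self.n_modules * self.module_size_lncrna > self.n_lncrna:
            raise ValidationError("modules demand more lncRNAs than simulated")
        if self.n_cis_pairs > 0 and self.n_modules > 0:
            if self.n_cis_pairs > min(self.module_size_mrna, self.module_size_lncrna):
                raise ValidationError("more cis pairs than module members")
        if self.module_factor_per not in ("sample", "pair"):
            raise ValidationError("module_factor_per must be 'sample' or 'pair'")
        if not (self.lfc_high >= self.lfc_low > 0):
            raise ValidationError("need 0 < lfc_low <= lfc_high")
        if self.gene_len_min < 1 or self.gene_len_max < self.gene_len_min:
            raise ValidationError("invalid gene length range")

    @property
    def n_genes(self) -> int:
        return self.n_mrna + self.n_lncrna

    @property
    def mrna_ids(self) -> list[str]:
        return [f"M{i:04d}" for i in range(1, self.n_mrna + 1)]

    @property
    def lncrna_ids(self) -> list[str]:
        return [f"L{i:04d}" for i in range(1, self.n_lncrna + 1)]


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth labels planted by the simulator."""

    de: dict[str, float]  # gene -> signed log2 fold change (absent: not DE)
    modules: list[dict[str, list[str]]]  # per module: {'mrna': [...], 'lncrna': [...]}
    cis_pairs: list[tuple[str, str, int]]  # (lncrna, mrna, gap bp)
    core_tf: str | None = None
    term_members: dict[str, set[str]] = dataclasses.field(default_factory=dict)
    absent_genes: set[str] = dataclasses.field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de)

    def module_of(self, gene: str) -> int | None:
        for i, mod in enumerate(self.modules):
            if gene in mod["mrna"] or gene in mod["lncrna"]:
                return i
        return None


def plan_truth(config: SimulationConfig, rng: np.random.Generator) -> PlantedTruth:
    """Draw module membership, DE effects and the cis-pair plan."""
    mrna = config.mrna_ids
    lncrna = config.lncrna_ids
    m_pool = list(rng.permutation(mrna))
    l_pool = list(rng.permutation(lncrna))
    modules = []
    for _ in range(config.n_modules):
        modules.append(
            {
                "mrna": sorted(m_pool[: config.module_size_mrna]),
                "lncrna": sorted(l_pool[: config.module_size_lncrna]),
            }
        )
        m_pool = m_pool[config.module_size_mrna:]
        l_pool = l_pool[config.module_size_lncrna:]

    def _signed_lfc(size: int) -> np.ndarray:
        mag = rng.uniform(config.lfc_low, config.lfc_high, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign

    de: dict[str, float] = {}
    for mod in modules:
        mod_genes = mod["mrna"] + mod["lncrna"]
        lfc = _signed_lfc(len(mod_genes))
        if config.module_sign_shared:
            # a co-regulated module responds coherently in tumors
            lfc = np.abs(lfc) * float(rng.choice([-1.0, 1.0]))
        for g, d in zip(mod_genes, lfc):
            de[g] = float(d)
    for pool, frac in ((m_pool, config.frac_de_mrna), (l_pool, config.frac_de_lncrna)):
        n_de = int(round(frac * len(pool)))
        chosen = list(rng.choice(pool, size=n_de, replace=False)) if n_de else []
        for g, d in zip(chosen, _signed_lfc(len(chosen))):
            de[g] = float(d)

    cis: list[tuple[str, str, int]] = []
    if config.n_cis_pairs > 0:
        if config.n_modules > 0:
            lnc_pool = modules[0]["lncrna"]
            mrna_pool = modules[0]["mrna"]
        else:
            lnc_pool, mrna_pool = lncrna, mrna
        lncs = rng.choice(lnc_pool, size=config.n_cis_pairs, replace=False)
        mrnas = rng.choice(mrna_pool, size=config.n_cis_pairs, replace=False)
        for l, m in zip(lncs, mrnas):
            gap = int(rng.integers(0, config.cis_window + 1))
            cis.append((str(l), str(m), gap))
    return PlantedTruth(de=de, modules=modules, cis_pairs=cis)


def generate_annotation(
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: PlantedTruth | None = None,
) -> tuple[GeneAnnotationTable, PlantedTruth]:
    """Place genes on chromosomes so that exactly the planted cis pairs lie
    within the cis window.

    Non-planted genes sit on a grid whose spacing exceeds the window plus
    the largest possible gene span, so no unplanned same-chromosome
    lncRNA-mRNA pair can fall within the window; each planted lncRNA is
    then re-placed next to its partner mRNA at a gap drawn uniformly from
    [0, cis_window].
    """
    if truth is None:
        truth = plan_truth(config, rng)
    max_len = config.gene_len_max
    step = 2 * config.cis_window + 3 * max_len + 1000
    cis_lnc = {l: (m, gap) for l, m, gap in truth.cis_pairs}
    grid_genes = [g for g in config.mrna_ids + config.lncrna_ids if g not in cis_lnc]
    grid_genes = list(rng.permutation(grid_genes))
    chroms = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    per_chrom = math.ceil(len(grid_genes) / len(chroms))
    needed = per_chrom * step + config.cis_window + 2 * max_len
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValidationError(
            f"chromosome length {config.chrom_length} too short: need {needed}"
        )
    lengths = {
        g: int(rng.integers(config.gene_len_min, config.gene_len_max + 1))
        for g in config.mrna_ids + config.lncrna_ids
    }
    rows: dict[str, tuple[str, int, int]] = {}
    for i, g in enumerate(grid_genes):
        chrom = chroms[i % len(chroms)]
        start = (i // len(chroms)) * step
        rows[g] = (chrom, start, start + lengths[g])
    for l, (m, gap) in cis_lnc.items():
        chrom, m_start, m_end = rows[m]
        start = m_end + gap
        rows[l] = (chrom, start, start + lengths[l])
    biotype = {g: BIOTYPE_MRNA for g in config.mrna_ids}
    biotype.update({g: BIOTYPE_LNCRNA for g in config.lncrna_ids})
    ids = config.mrna_ids + config.lncrna_ids
    strands = rng.choice(["+", "-"], size=len(ids))
    table = pd.DataFrame(
        {
            "chrom": [rows[g][0] for g in ids],
            "start": [rows[g][1] for g in ids],
            "end": [rows[g][2] for g in ids],
            "biotype": [biotype[g] for g in ids],
            "strand": strands,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return GeneAnnotationTable(table), truth


def generate_expression(
    config: SimulationConfig,
    annotation: GeneAnnotationTable,
    truth: PlantedTruth,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Simulate the log2 expression matrix under the one-factor model."""
    genes = annotation.gene_ids
    missing = [g for g in config.mrna_ids + config.lncrna_ids if g not in annotation]
    if missing:
        raise ValidationError(f"annotation does not cover genes: {missing[:5]}")
    sample_ids, pair_ids, conditions = [], [], []
    for i in range(1, config.n_pairs + 1):
        for cond, tag in (("tumor", "T"), ("normal", "N")):
            sample_ids.append(f"P{i}{tag}")
            pair_ids.append(f"P{i}")
            conditions.append(cond)
    n_s = len(sample_ids)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    a_pair = rng.normal(0.0, config.pair_sd, size=config.n_pairs)
    pair_index = np.array([int(p[1:]) - 1 for p in pair_ids])
    tumor = np.array([c == "tumor" for c in conditions], dtype=float)
    delta = np.array([truth.de.get(g, 0.0) for g in genes])
    # Per-gene subject effect: shared within a pair, cancels in paired ratios.
    # For module members the shared factor *is* (part of) their subject-level
    # variability, so their independent subject sd is reduced to keep the
    # total pair-level variance comparable across genes.
    subject_sd = np.full(len(genes), config.subject_sd)
    gene_pos0 = {g: i for i, g in enumerate(genes)}
    if config.module_factor_per == "pair":
        reduced = math.sqrt(max(config.subject_sd**2 - config.module_loading**2, 0.0))
        for mod in truth.modules:
            for g in mod["mrna"] + mod["lncrna"]:
                subject_sd[gene_pos0[g]] = reduced
    b_subject = rng.normal(0.0, 1.0, size=(len(genes), config.n_pairs)) * subject_sd[:, None]
    x = (
        mu[:, None]
        + a_pair[pair_index][None, :]
        + b_subject[:, pair_index]
        + delta[:, None] * tumor[None, :]
    )
    if config.module_factor_per == "pair":
        per_pair = rng.standard_normal(size=(max(config.n_modules, 1), config.n_pairs))
        factors = per_pair[:, pair_index]
    else:
        factors = rng.standard_normal(size=(max(config.n_modules, 1), n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for m, mod in enumerate(truth.modules):
        idx = [gene_pos[g] for g in mod["mrna"] + mod["lncrna"]]
        x[idx, :] += config.module_loading * factors[m][None, :]
    x += rng.normal(0.0, config.noise_sd, size=x.shape)
    values = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {"pair_id": pair_ids, "condition": conditions},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    flags = pd.DataFrame("P", index=values.index, columns=values.columns)
    if config.frac_absent > 0:
        n_absent = int(round(config.frac_absent * len(genes)))
        absent = rng.choice(genes, size=n_absent, replace=False)
        tumor_samples = [s for s, c in zip(sample_ids, conditions) if c == "tumor"]
        normal_samples = [s for s, c in zip(sample_ids, conditions) if c == "normal"]
        for g in absent:
            flags.at[g, str(rng.choice(tumor_samples))] = "A"
            flags.at[g, str(rng.choice(normal_samples))] = "A"
        truth.absent_genes = {str(g) for g in absent}
    return ExpressionMatrix(values, meta, flags)


def _fill_set(core: list[str], pool: list[str], size: int,
              rng: np.random.Generator) -> frozenset[str]:
    fill_n = max(0, size - len(core))
    extra = list(rng.choice([g for g in pool if g not in core],
                            size=fill_n, replace=False)) if fill_n else []
    return frozenset(core + [str(g) for g in extra])


def generate_tf_sets(
    config: SimulationConfig, truth: PlantedTruth, rng: np.random.Generator
) -> GeneSetCollection:
    """One core TF target set anchored on a module plus decoy sets.

    The core TF's targets cover ``core_tf_coverage`` of the first module's
    mRNAs (topped up with random mRNAs if the coverage core is smaller
    than the decoy set size); decoys draw uniformly from all mRNAs.
    """
    if config.decoy_tf_set_size < 1:
        raise ValidationError("decoy_tf_set_size must be >= 1")
    if config.decoy_tf_set_size > config.n_mrna:
        raise ValidationError("decoy sets larger than the mRNA pool")
    tf_ids = [f"TF{i:02d}" for i in range(1, config.n_tfs + 1)]
    if not truth.modules or not truth.modules[0]["mrna"]:
        # no module to anchor a core TF: emit decoy sets only
        truth.core_tf = None
        return GeneSetCollection(
            GeneSet(
                tf,
                "decoy TF target set",
                frozenset(
                    str(g)
                    for g in rng.choice(config.mrna_ids,
                                        size=config.decoy_tf_set_size, replace=False)
                ),
                "TF",
            )
            for tf in tf_ids
        )
    mod_mrnas = truth.modules[0]["mrna"]
    n_core = int(round(config.core_tf_coverage * len(mod_mrnas)))
    if n_core < 1 or n_core > len(mod_mrnas):
        raise ValidationError("coverage demands more genes than the module contains")
    core_idx = int(rng.integers(config.n_tfs))
    sets = []
    for i, tf in enumerate(tf_ids):
        if i == core_idx:
            core = sorted(str(g) for g in rng.choice(mod_mrnas, size=n_core, replace=False))
            members = _fill_set(core, config.mrna_ids, config.core_tf_set_size, rng)
            desc = "planted core TF target set"
        else:
            members = frozenset(
                str(g) for g in rng.choice(config.mrna_ids,
                                           size=config.decoy_tf_set_size, replace=False)
            )
            desc = "decoy TF target set"
        sets.append(GeneSet(tf, desc, members, "TF"))
    truth.core_tf = tf_ids[core_idx]
    return GeneSetCollection(sets)


def generate_term_sets(
    config: SimulationConfig, truth: PlantedTruth, rng: np.random.Generator
) -> GeneSetCollection:
    """Functional term sets: one term enriched per module, the rest decoys."""
    if config.n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if config.n_terms < config.n_modules:
        raise ValidationError("need at least one term per module")
    if config.decoy_term_size < 1 or config.decoy_term_size > config.n_genes:
        raise ValidationError("invalid decoy_term_size")
    all_genes = config.mrna_ids + config.lncrna_ids
    categories = ["BP", "CC", "MF", "Pathway"]
    sets = []
    truth.term_members = {}
    for i in range(config.n_terms):
        term = f"TERM{i + 1:02d}"
        category = categories[i % len(categories)]
        if i < config.n_modules:
            mod_genes = truth.modules[i]["mrna"] + truth.modules[i]["lncrna"]
            n_core = int(round(config.term_coverage * len(mod_genes)))
            if n_core < 1:
                raise ValidationError("term coverage selects no module genes")
            core = sorted(str(g) for g in rng.choice(mod_genes, size=n_core, replace=False))
            members = _fill_set(core, all_genes, config.planted_term_size, rng)
            desc = f"planted module-{i} term"
        else:
            members = frozenset(
                str(g) for g in rng.choice(all_genes, size=config.decoy_term_size,
                                           replace=False)
            )
            desc = "decoy term"
        truth.term_members[term] = set(members)
        sets.append(GeneSet(term, desc, members, category))
    return GeneSetCollection(sets)


@dataclasses.dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    annotation: GeneAnnotationTable
    tf_sets: GeneSetCollection
    term_sets: GeneSetCollection
    truth: PlantedTruth
    config: SimulationConfig


def generate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate the full synthetic study from one seed (pure function)."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    annotation, truth = generate_annotation(config, rng)
    expression = generate_expression(config, annotation, truth, rng)
    tf_sets = generate_tf_sets(config, truth, rng)
    term_sets = generate_term_sets(config, truth, rng)
    return SyntheticDataset(expression, annotation, tf_sets, term_sets, truth, config)
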