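"""Synthetic multi-omics cohorts with planted subtype structure.

The generator emulates the shapes of a pan-cancer TP53-mutant cohort:
MAF-like somatic mutation records with trinucleotide contexts drawn from
subtype-specific mixtures of mutational signatures, a GISTIC-thresholded
copy-number matrix over abstract focal loci, an Illumina-style methylation
beta matrix with probe annotations, a log2(TPM + 0.001) expression matrix,
and a clinical table with overall- and disease-specific-survival endpoints.
Every subtype-defining event (driver mutation, driver fragment, driver CpG,
checkpoint shift, survival hazard) is planted explicitly and recorded in a
ground-truth block so each downstream stage can be validated against what
was put in.

All couplings are stand-ins chosen for testability: expression effects are
additive on the log2 scale, methylation is a two-mode Beta mixture, and
survival is exponential with independent censoring.  None of this is an
estimate of real TCGA joint structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# 96 pyrimidine-normalized substitution classes, ordered substitution-major:
# (C>A, C>G, C>T, T>A, T>C, T>G) x 5' flank (A,C,G,T) x 3' flank (A,C,G,T).
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)
BASES = "ACGT"
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic cohort generator.

    Driver tuples follow the layouts
    ``driver_genes``:     (gene, subtype, in-subtype frequency, background frequency)
    ``driver_fragments``: (fragment, subtype, "amp"|"del", frequency, expression effect)
    ``driver_cpgs``:      (probe, gene, subtype, hypermethylation frequency, expression effect)
    with subtypes labeled 1..n_subtypes.
    """

    n_samples: int = 500
    n_subtypes: int = 5
    subtype_proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    n_signatures: int = 5
    signature_profiles: np.ndarray | None = None  # signatures x 96, rows sum to 1
    exposure_concentration: float = 8.0  # Dirichlet weight of a subtype's own signature
    exposure_background: float = 0.5  # Dirichlet weight of the other signatures
    mutations_per_sample: float = 100.0  # Poisson mean of total substitutions
    driver_genes: list[tuple[str, int, float, float]] = field(default_factory=list)
    n_smg_genes: int = 127  # size of the consumed significantly-mutated-gene list
    smg_background_rate: float = 0.05
    driver_fragments: list[tuple[str, int, str, float, float]] = field(default_factory=list)
    n_fragments: int = 84  # curated focal amplification/deletion loci
    cnv_background_rate: float = 0.03
    extra_cnv_fragments_per_subtype: int = 8  # subtype-linked, no expression coupling
    driver_cpgs: list[tuple[str, str, int, float, float]] = field(default_factory=list)
    informative_cpgs_per_subtype: int = 8
    n_background_probes: int = 200
    n_sex_probes: int = 10
    n_snp_probes: int = 10
    n_normal_samples: int = 30
    cpg_background_rate: float = 0.05
    n_marker_genes_per_subtype: int = 12
    marker_effect: float = 1.5
    n_noise_genes: int = 2000
    # shared low-rank expression programs (proliferation/stroma-like axes):
    # subtype-independent variation spread over the whole transcriptome, as
    # the top principal components of real bulk cohorts are
    n_expression_factors: int = 15
    expression_factor_sd: float = 0.32
    n_checkpoint_genes: int = 15  # per category (stimulatory / inhibitory)
    checkpoint_effect: float = 1.5  # inhibitory-checkpoint shift in the focal subtype
    focal_subtype: int = 3
    survival_hazard_by_subtype: tuple[float, ...] = (0.05, 0.05, 0.15, 0.05, 0.05)
    censoring_rate: float = 0.3
    cancer_types: tuple[str, ...] = ("GBM", "LGG", "LUSC", "STAD", "HNSC")
    seed: int = 0

    @classmethod
    def default(cls, n_samples: int = 500, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Default five-subtype study configuration with one planted driver of
        each class per subtype."""
        cfg = cls(n_samples=n_samples, seed=seed, **overrides)
        k = cfg.n_subtypes
        if not cfg.driver_genes:
            cfg.driver_genes = [(f"SMG{s:03d}", s, 0.6, 0.05) for s in range(1, k + 1)]
        if not cfg.driver_fragments:
            cfg.driver_fragments = []
            for s in range(1, k + 1):
                cfg.driver_fragments.append((f"FRAG{2 * s - 1:03d}", s, "amp", 0.6, 1.5))
                cfg.driver_fragments.append((f"FRAG{2 * s:03d}", s, "del", 0.6, -1.5))
        if not cfg.driver_cpgs:
            cfg.driver_cpgs = [
                (f"cg1{s:04d}", f"METG{s}", s, 0.8, -2.0) for s in range(1, k + 1)
            ]
        cfg.validate()
        return cfg

    def validate(self) -> None:
        k = self.n_subtypes
        if len(self.subtype_proportions) != k:
            raise ConfigurationError("subtype_proportions length must equal n_subtypes")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must be a simplex vector")
        if len(self.survival_hazard_by_subtype) != k:
            raise ConfigurationError("survival_hazard_by_subtype length must equal n_subtypes")
        if np.any(np.asarray(self.survival_hazard_by_subtype) <= 0):
            raise ConfigurationError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        for freq in (
            [g[2] for g in self.driver_genes]
            + [g[3] for g in self.driver_genes]
            + [f[3] for f in self.driver_fragments]
            + [c[3] for c in self.driver_cpgs]
        ):
            if not 0 <= freq <= 1:
                raise ConfigurationError(f"frequency {freq} outside [0, 1]")
        for _, s, *_ in self.driver_genes:
            if not 1 <= s <= k:
                raise ConfigurationError("driver gene subtype out of range")
        if self.signature_profiles is not None:
            p = np.asarray(self.signature_profiles, dtype=float)
            if p.shape != (self.n_signatures, 96):
                raise ConfigurationError("signature_profiles must be n_signatures x 96")
            if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
                raise ConfigurationError("signature profile rows must be nonnegative and sum to 1")

    # -- deterministic derived structure ------------------------------------

    def profiles(self) -> np.ndarray:
        """Signature profiles: supplied, or sparse random profiles fixed by seed."""
        if self.signature_profiles is not None:
            return np.asarray(self.signature_profiles, dtype=float)
        rng = np.random.default_rng(self.seed + 10_001)
        p = rng.dirichlet(np.full(96, 0.15), size=self.n_signatures)
        return p

    def gene_universe(self) -> pd.DataFrame:
        """Deterministic table of expression genes: (gene, role, subtype, base_mean).

        Roles: marker, checkpoint_stim, checkpoint_inhib, cnv_amp, cnv_del,
        methylation, noise.  Base means are fixed by the config seed alone so
        cohorts and cell-line panels built from the same config share them.
        """
        rows: list[tuple[str, str, int]] = []
        for s in range(1, self.n_subtypes + 1):
            for j in range(1, self.n_marker_genes_per_subtype + 1):
                rows.append((f"MRK{s}_{j:02d}", "marker", s))
        for j in range(1, self.n_checkpoint_genes + 1):
            rows.append((f"STIM{j:02d}", "checkpoint_stim", 0))
            rows.append((f"INHIB{j:02d}", "checkpoint_inhib", 0))
        for frag, s, direction, _, _ in self.driver_fragments:
            role = "cnv_amp" if direction == "amp" else "cnv_del"
            rows.append((f"{'AMPG' if direction == 'amp' else 'DELG'}{s}", role, s))
        for _, gene, s, _, _ in self.driver_cpgs:
            rows.append((gene, "methylation", s))
        for j in range(1, self.n_noise_genes + 1):
            rows.append((f"NOISE{j:04d}", "noise", 0))
        df = pd.DataFrame(rows, columns=["gene", "role", "subtype"])
        df = df.drop_duplicates(subset="gene").reset_index(drop=True)
        rng = np.random.default_rng(self.seed + 10_002)
        df["base_mean"] = rng.uniform(2.0, 8.0, size=len(df))
        return df

    def factor_loadings(self, n_genes: int) -> np.ndarray:
        """Gene x factor loadings of the shared expression programs, fixed by
        the config seed so cohorts and cell-line panels share them."""
        rng = np.random.default_rng(self.seed + 10_003)
        return rng.normal(0.0, self.expression_factor_sd, size=(n_genes, self.n_expression_factors))

    def smg_list(self) -> list[str]:
        return [f"SMG{i:03d}" for i in range(1, self.n_smg_genes + 1)]

    def checkpoint_sets(self) -> dict[str, list[str]]:
        return {
            "stimulatory": [f"STIM{j:02d}" for j in range(1, self.n_checkpoint_genes + 1)],
            "inhibitory": [f"INHIB{j:02d}" for j in range(1, self.n_checkpoint_genes + 1)],
        }


@dataclass
class MultiomicsCohort:
    """Matched per-sample omics tables plus (optional) planted ground truth."""

    sample_ids: list[str]
    cancer_type: pd.Series  # sample -> cancer type
    mutation_records: pd.DataFrame  # sample, gene, chromosome, position, ref, alt, context
    cnv: pd.DataFrame  # fragment x sample, values in {-2,-1,0,1,2}
    methylation: pd.DataFrame  # probe x sample beta matrix
    methylation_normal: pd.DataFrame  # probe x normal-sample beta matrix
    probe_annotation: pd.DataFrame  # probe, chromosome, snp_overlap, gene
    expression: pd.DataFrame  # gene x sample, log2(TPM + 0.001) scale
    clinical: pd.DataFrame  # sample, os_time, os_event, dss_time, dss_event
    truth: dict | None = None

    def mutation_status(self, genes: list[str]) -> pd.DataFrame:
        """0/1 gene x sample matrix restricted to ``genes``."""
        status = pd.DataFrame(0, index=genes, columns=self.sample_ids, dtype=int)
        rec = self.mutation_records
        hit = rec[rec["gene"].isin(genes)]
        for gene, sample in zip(hit["gene"], hit["sample"]):
            status.at[gene, sample] = 1
        return status

    def validate(self) -> None:
        ids = set(self.sample_ids)
        for name, cols in (
            ("cnv", self.cnv.columns),
            ("methylation", self.methylation.columns),
            ("expression", self.expression.columns),
            ("clinical", self.clinical["sample"]),
        ):
            if set(cols) != ids:
                raise ValueError(f"{name} samples do not match sample_ids")
        if not self.cnv.isin([-2, -1, 0, 1, 2]).all().all():
            raise ValueError("cnv values outside the 5-level set")
        b = self.methylation.to_numpy()
        if b.min() < 0 or b.max() > 1:
            raise ValueError("beta values outside [0, 1]")
        if (self.clinical["os_time"] <= 0).any():
            raise ValueError("os_time must be positive")


@dataclass
class CellLinePanel:
    """Cell-line expression plus a drug x cell-line AUC matrix (lower = more
    sensitive), with missing entries allowed."""

    cell_line_ids: list[str]
    expression: pd.DataFrame  # gene x cell line, log2(TPM + 0.001) scale
    auc: pd.DataFrame  # drug x cell line, NaN = missing
    missing_fraction: pd.Series  # per-drug missingness
    truth: dict | None = None


def _draw_subtypes(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    return rng.choice(
        np.arange(1, cfg.n_subtypes + 1), size=cfg.n_samples, p=np.asarray(cfg.subtype_proportions)
    )


def _context_record(rng: np.random.Generator, class_idx: int) -> tuple[str, str, str]:
    """(ref, alt, context) for a 96-class index; half the records are emitted
    on the purine strand to exercise downstream normalization."""
    ref, alt = SUBSTITUTIONS[class_idx // 16]
    five = BASES[(class_idx % 16) // 4]
    three = BASES[class_idx % 4]
    context = five + ref + three
    if rng.random() < 0.5:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    return ref, alt, context


def generate_cohort(config: SyntheticConfig) -> MultiomicsCohort:
    """Generate a matched multi-omics cohort with planted subtype structure.

    Deterministic for a fixed ``config.seed``.  Planted effects are realized
    directly: driver genes are mutated at their configured in-subtype
    frequency, driver fragments couple additively to the expression of their
    mapped gene, and driver CpGs push beta into the high Beta(10, 2) mode in
    their subtype while depressing their gene's expression in proportion to
    beta.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    subtypes = _draw_subtypes(rng, cfg)
    cancer_type = pd.Series(
        rng.choice(list(cfg.cancer_types), size=n), index=sample_ids, name="cancer_type"
    )

    # --- mutations: gene-level driver status + signature-mixture contexts ---
    profiles = cfg.profiles()
    conc = np.full((cfg.n_subtypes, cfg.n_signatures), cfg.exposure_background)
    for s in range(cfg.n_subtypes):
        conc[s, s % cfg.n_signatures] = cfg.exposure_concentration
    exposures = np.vstack([rng.dirichlet(conc[s - 1]) for s in subtypes])
    context_probs = exposures @ profiles  # n x 96

    smg = cfg.smg_list()
    driver_by_gene = {g: (s, f_in, f_bg) for g, s, f_in, f_bg in cfg.driver_genes}
    records: list[tuple] = []
    chroms = [f"chr{c}" for c in range(1, 23)]
    for i, sample in enumerate(sample_ids):
        total = rng.poisson(cfg.mutations_per_sample)
        mutated_genes: list[str] = []
        for g in smg:
            if g in driver_by_gene:
                s, f_in, f_bg = driver_by_gene[g]
                p = f_in if subtypes[i] == s else f_bg
            else:
                p = cfg.smg_background_rate
            if rng.random() < p:
                mutated_genes.append(g)
        n_passenger = max(0, total - len(mutated_genes))
        genes = mutated_genes + [f"PASS{j:05d}" for j in rng.integers(1, 20_000, n_passenger)]
        classes = rng.choice(96, size=len(genes), p=context_probs[i])
        for g, c in zip(genes, classes):
            ref, alt, context = _context_record(rng, int(c))
            records.append(
                (sample, g, chroms[rng.integers(0, 22)], int(rng.integers(1, 2_000_000)), ref, alt, context)
            )
    mutation_records = pd.DataFrame(
        records, columns=["sample", "gene", "chromosome", "position", "ref", "alt", "context"]
    )

    # --- copy number: trinary-style planting on a 5-level GISTIC matrix ----
    fragment_ids = [f"FRAG{j:03d}" for j in range(1, cfg.n_fragments + 1)]
    cnv = np.zeros((cfg.n_fragments, n), dtype=int)
    bg = rng.random((cfg.n_fragments, n))
    # sparse background focal calls: ~8% altered per entry, mostly shallow
    cnv[bg < 0.01] = -2
    cnv[(bg >= 0.01) & (bg < 0.04)] = -1
    cnv[(bg >= 0.96) & (bg < 0.99)] = 1
    cnv[bg >= 0.99] = 2
    frag_index = {f: j for j, f in enumerate(fragment_ids)}

    def plant_fragment(frag: str, s: int, direction: str, freq: float) -> np.ndarray:
        j = frag_index[frag]
        sign = 1 if direction == "amp" else -1
        in_sub = subtypes == s
        altered = np.where(in_sub, rng.random(n) < freq, rng.random(n) < cfg.cnv_background_rate)
        level = rng.integers(1, 3, size=n)  # focal level 1 or 2, same trinary class
        cnv[j, :] = np.where(altered, sign * level, 0)
        return altered

    driver_fragment_altered: dict[str, np.ndarray] = {}
    for frag, s, direction, freq, _ in cfg.driver_fragments:
        driver_fragment_altered[frag] = plant_fragment(frag, s, direction, freq)
    next_free = 2 * cfg.n_subtypes + 1
    for s in range(1, cfg.n_subtypes + 1):
        for e in range(cfg.extra_cnv_fragments_per_subtype):
            frag = f"FRAG{next_free:03d}"
            next_free += 1
            plant_fragment(frag, s, "amp" if e % 2 == 0 else "del", 0.6)
    cnv_df = pd.DataFrame(cnv, index=fragment_ids, columns=sample_ids)

    # --- methylation: two-mode Beta mixture, subtype blocks, junk probes ---
    probe_rows: list[tuple[str, str, bool, str, str, int, float]] = []
    # (probe, chromosome, snp_overlap, gene, kind, subtype, freq)
    for probe, gene, s, freq, _ in cfg.driver_cpgs:
        probe_rows.append((probe, "chr7", False, gene, "driver", s, freq))
    for s in range(1, cfg.n_subtypes + 1):
        for j in range(1, cfg.informative_cpgs_per_subtype + 1):
            probe_rows.append((f"cg2{s}{j:03d}", f"chr{(j % 20) + 1}", False, "", "block", s, 0.8))
    rng_modes = rng.random(cfg.n_background_probes)
    for j in range(1, cfg.n_background_probes + 1):
        kind = "bg_high" if rng_modes[j - 1] < 0.2 else "bg_low"
        probe_rows.append((f"cg0{j:04d}", f"chr{(j % 20) + 1}", False, "", kind, 0, 0.0))
    for j in range(1, cfg.n_sex_probes + 1):
        probe_rows.append((f"cgX{j:03d}", "chrX", False, "", "block", 1 + (j % cfg.n_subtypes), 0.8))
    for j in range(1, cfg.n_snp_probes + 1):
        probe_rows.append((f"cgS{j:03d}", "chr5", True, "", "block", 1 + (j % cfg.n_subtypes), 0.8))

    probes = [r[0] for r in probe_rows]
    beta = np.empty((len(probes), n))
    beta_normal = np.empty((len(probes), cfg.n_normal_samples))
    driver_beta: dict[str, np.ndarray] = {}
    for r_i, (probe, _, _, _, kind, s, freq) in enumerate(probe_rows):
        if kind in ("driver", "block"):
            in_sub = subtypes == s
            methylated = np.where(
                in_sub, rng.random(n) < freq, rng.random(n) < cfg.cpg_background_rate
            )
            row = np.where(methylated, rng.beta(10, 2, n), rng.beta(2, 10, n))
            beta_normal[r_i] = rng.beta(2, 20, cfg.n_normal_samples)
        elif kind == "bg_high":
            row = rng.beta(10, 2, n)
            beta_normal[r_i] = rng.beta(10, 2, cfg.n_normal_samples)
        else:  # bg_low
            row = rng.beta(2, 10, n)
            beta_normal[r_i] = rng.beta(2, 20, cfg.n_normal_samples)
        beta[r_i] = row
        if kind == "driver":
            driver_beta[probe] = row
    methylation = pd.DataFrame(beta, index=probes, columns=sample_ids)
    methylation_normal = pd.DataFrame(
        beta_normal, index=probes, columns=[f"N{j:03d}" for j in range(1, cfg.n_normal_samples + 1)]
    )
    probe_annotation = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in probe_rows],
        columns=["probe", "chromosome", "snp_overlap", "gene"],
    )

    # --- expression: additive subtype / driver couplings on log2 scale -----
    universe = cfg.gene_universe()
    loadings = cfg.factor_loadings(len(universe))
    factor_scores = rng.normal(0.0, 1.0, size=(cfg.n_expression_factors, n))
    factor_component = loadings @ factor_scores
    expr = np.empty((len(universe), n))
    cpg_effect = {gene: (probe, eff) for probe, gene, _, _, eff in cfg.driver_cpgs}
    frag_effect: dict[str, tuple[str, float]] = {}
    for frag, s, direction, _, eff in cfg.driver_fragments:
        gene = f"{'AMPG' if direction == 'amp' else 'DELG'}{s}"
        frag_effect[gene] = (frag, eff)
    for g_i, row in enumerate(universe.itertuples(index=False)):
        values = row.base_mean + rng.normal(0.0, 1.0, n)
        if row.role == "marker":
            values += cfg.marker_effect * (subtypes == row.subtype)
        elif row.role == "checkpoint_inhib":
            values += cfg.checkpoint_effect * (subtypes == cfg.focal_subtype)
        elif row.role in ("cnv_amp", "cnv_del"):
            frag, eff = frag_effect[row.gene]
            values += eff * driver_fragment_altered[frag]
        elif row.role == "methylation":
            probe, eff = cpg_effect[row.gene]
            values += eff * driver_beta[probe]
        expr[g_i] = values
    expr += factor_component
    expression = pd.DataFrame(expr, index=universe["gene"].tolist(), columns=sample_ids)

    # --- survival: exponential event times, uniform censoring --------------
    hazards = np.asarray(cfg.survival_hazard_by_subtype)[subtypes - 1]
    event_time = rng.exponential(1.0 / hazards)
    censored = rng.random(n) < cfg.censoring_rate
    os_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    os_time = np.maximum(os_time, 1e-3)
    os_event = (~censored).astype(int)
    dss_event = os_event * (rng.random(n) < 0.9).astype(int)
    clinical = pd.DataFrame(
        {
            "sample": sample_ids,
            "os_time": os_time,
            "os_event": os_event,
            "dss_time": os_time,
            "dss_event": dss_event,
        }
    )

    truth = {
        "subtype": pd.Series(subtypes, index=sample_ids, name="subtype"),
        "drivers": (
            [
                {"feature": g, "event_type": "mutation", "subtype": s}
                for g, s, _, _ in cfg.driver_genes
            ]
            + [
                {
                    "feature": f,
                    "event_type": "amplification" if d == "amp" else "deletion",
                    "subtype": s,
                }
                for f, s, d, _, _ in cfg.driver_fragments
            ]
            + [
                {"feature": p, "event_type": "hypermethylation", "subtype": s}
                for p, _, s, _, _ in cfg.driver_cpgs
            ]
        ),
        "exposures": pd.DataFrame(
            exposures, index=sample_ids, columns=[f"SIG{j}" for j in range(1, cfg.n_signatures + 1)]
        ),
        "signature_profiles": profiles,
    }
    cohort = MultiomicsCohort(
        sample_ids=sample_ids,
        cancer_type=cancer_type,
        mutation_records=mutation_records,
        cnv=cnv_df,
        methylation=methylation,
        methylation_normal=methylation_normal,
        probe_annotation=probe_annotation,
        expression=expression,
        clinical=clinical,
        truth=truth,
    )
    cohort.validate()
    return cohort


def generate_ccl_panel(
    config: SyntheticConfig,
    n_cell_lines: int,
    n_drugs: int,
    missing_rate: float,
    sensitive_pairs: list[tuple[str, int, float]],
    seed: int,
) -> CellLinePanel:
    """Cell-line panel sharing the cohort's gene universe and subtype shifts.

    ``sensitive_pairs`` are (drug, subtype, AUC effect) triples; a negative
    effect lowers the drug's AUC in cell lines of that subtype (sensitivity).
    Missing AUC entries are placed completely at random at ``missing_rate``.
    """
    if n_cell_lines < 2 or n_drugs < 2:
        raise ConfigurationError("need at least 2 cell lines and 2 drugs")
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    cfg = config
    rng = np.random.default_rng(seed)
    ids = [f"CCL{i:04d}" for i in range(1, n_cell_lines + 1)]
    subtypes = rng.choice(
        np.arange(1, cfg.n_subtypes + 1), size=n_cell_lines, p=np.asarray(cfg.subtype_proportions)
    )
    universe = cfg.gene_universe()
    expr = np.empty((len(universe), n_cell_lines))
    for g_i, row in enumerate(universe.itertuples(index=False)):
        values = row.base_mean + rng.normal(0.0, 1.0, n_cell_lines)
        if row.role == "marker":
            values += cfg.marker_effect * (subtypes == row.subtype)
        elif row.role == "checkpoint_inhib":
            values += cfg.checkpoint_effect * (subtypes == cfg.focal_subtype)
        expr[g_i] = values
    expr += cfg.factor_loadings(len(universe)) @ rng.normal(
        0.0, 1.0, size=(cfg.n_expression_factors, n_cell_lines)
    )
    expression = pd.DataFrame(expr, index=universe["gene"].tolist(), columns=ids)

    drug_ids = [f"DRUG{j:03d}" for j in range(1, n_drugs + 1)]
    base = rng.uniform(3.0, 7.0, size=n_drugs)
    auc = base[:, None] + rng.normal(0.0, 0.5, size=(n_drugs, n_cell_lines))
    effects = {(d, s): e for d, s, e in sensitive_pairs}
    for (d, s), e in effects.items():
        if d in drug_ids:
            auc[drug_ids.index(d), subtypes == s] += e
    auc = np.clip(auc, 0.0, None)
    mask = rng.random(auc.shape) < missing_rate
    auc = np.where(mask, np.nan, auc)
    auc_df = pd.DataFrame(auc, index=drug_ids, columns=ids)
    missing_fraction = auc_df.isna().mean(axis=1)
    truth = {
        "subtype": pd.Series(subtypes, index=ids, name="subtype"),
        "sensitive_pairs": list(sensitive_pairs),
    }
    return CellLinePanel(
        cell_line_ids=ids,
        expression=expression,
        auc=auc_df,
        missing_fraction=missing_fraction,
        truth=truth,
    )
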