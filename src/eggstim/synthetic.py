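"""Synthetic study generator with planted ground truth.

Emulates the structure of the PBMC egg-stimulation study: paired
egg-white (EW) and media (M) cultures for every subject across three
clinical groups (AC / BET / BER), log2-scale expression with additive
Gaussian noise, a stimulation response planted in designated groups,
latent-factor co-expression modules, an immunologic-signature collection
with one category enriched for the planted response, and floor-censored
cytokine concentrations.

Everything is a deterministic function of the :class:`SimulationConfig`
(including its seed); each generator draws from its own seeded stream so
the three outputs are individually reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationMap,
    ConfigError,
    GeneSetCollection,
    GroundTruth,
    GROUPS,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

ANNOTATION_LEVELS = (1, 2, 3, 4)

# distinct deterministic sub-streams per generator
_STREAM_EXPRESSION = 1
_STREAM_GENESETS = 2
_STREAM_CYTOKINES = 3


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def build_subjects(config: SimulationConfig) -> pd.DataFrame:
    """Subject roster shared by the expression and cytokine generators.

    Gender is Bernoulli(0.5) per subject; batch is assigned round-robin
    over ``n_batches`` processing batches. Both are drawn from a stream
    that depends only on the seed so expression and cytokine tables agree
    on the roster.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    rows = []
    idx = 0
    for group in GROUPS:
        n = config.n_subjects_per_group.get(group, 0)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}{i:02d}",
                    "group": group,
                    "gender": "F" if rng.random() < 0.5 else "M",
                    "batch": f"B{idx % config.n_batches}",
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def _sample_table(subjects: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, s in subjects.iterrows():
        for stim in ("EW", "M"):
            rows.append(
                {
                    "sample_id": f"{s.subject_id}_{stim}",
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "stimulation": stim,
                    "gender": s.gender,
                    "batch": s.batch,
                }
            )
    return pd.DataFrame(rows)


def generate_expression(config: SimulationConfig):
    """Generate (expression, samples, truth).

    Expression is genes x samples on the log2 scale. Planted features:

    * ``n_de_genes`` genes whose EW samples are shifted by ``de_log2fc``
      in the ``de_groups`` only (a stimulation-by-group interaction);
    * ``n_modules`` blocks of co-expressed genes, each generated from a
      single latent factor with loading sqrt(module_cor), so the expected
      pairwise within-module correlation equals ``module_cor``;
    * per-subject random offsets (pairing), and small additive gender and
      batch effects so covariate adjustment is exercised downstream.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)

    subjects = build_subjects(config)
    samples = _sample_table(subjects)
    n_genes = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = list(samples["sample_id"])
    n_samples = len(sample_ids)

    # gene roles: module blocks first, then DE genes, rest background
    order = rng.permutation(n_genes)
    module_assignment = np.zeros(n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_assignment[order[pos:pos + size]] = m
        pos += size
    de_idx = order[pos:pos + config.n_de_genes]
    de_genes = [genes[i] for i in sorted(de_idx)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

    # per-sample latent factor per module
    latents = rng.standard_normal((config.n_modules, n_samples))

    # unit-variance per-gene noise with a gene-specific subject component:
    # eta = sqrt(rho) u_{g,subject} + sqrt(1-rho) e_{g,sample}, so paired
    # EW/M samples of a subject correlate within a gene without inducing
    # correlation between genes (array-level offsets shared by all genes
    # are what normalization removes, so none are simulated)
    if config.subject_sd > config.noise_sd:
        raise ConfigError("subject_sd cannot exceed noise_sd")
    rho = (config.subject_sd / config.noise_sd) ** 2 if config.noise_sd > 0 else 0.0
    subj_ids = list(subjects["subject_id"])
    subj_index = {s: i for i, s in enumerate(subj_ids)}
    meta = samples.set_index("sample_id")
    sample_subj = np.array([subj_index[s] for s in meta["subject_id"]])
    u = rng.standard_normal((n_genes, len(subj_ids)))
    e = rng.standard_normal((n_genes, n_samples))
    eta = np.sqrt(rho) * u[:, sample_subj] + np.sqrt(1.0 - rho) * e

    values = baseline[:, None] + config.noise_sd * eta
    c = config.module_cor
    for m in range(1, config.n_modules + 1):
        rows = module_assignment == m
        shared = np.sqrt(c) * latents[m - 1][None, :]
        values[rows] = baseline[rows, None] + config.noise_sd * (
            shared + np.sqrt(1.0 - c) * eta[rows]
        )

    # small additive covariate effects so adjustment is exercised
    gender_vec = np.array([config.gender_effect if g == "M" else 0.0 for g in meta["gender"]])
    batch_vec = np.array([config.batch_effect * int(b[1:]) for b in meta["batch"]])
    values += (gender_vec + batch_vec)[None, :]

    # planted stimulation response in designated groups only
    is_ew = (meta["stimulation"] == "EW").to_numpy()
    in_de_group = meta["group"].isin(config.de_groups).to_numpy()
    values[np.ix_(sorted(de_idx), np.flatnonzero(is_ew & in_de_group))] += config.de_log2fc

    expr = pd.DataFrame(values, index=genes, columns=sample_ids)

    de_map = {}
    others = [g for g in GROUPS if g not in config.de_groups]
    for g in config.de_groups:
        de_map[f"EWvsM@{g}"] = list(de_genes)
        for other in others:
            de_map[f"{g}_vs_{other}@EWvsM"] = list(de_genes)

    truth = GroundTruth(
        gene_ids=genes,
        de_gene_ids=de_map,
        module_assignment=pd.Series(module_assignment, index=genes, name="module"),
        module_latents=pd.DataFrame(
            latents,
            index=[m + 1 for m in range(config.n_modules)],
            columns=sample_ids,
        ),
        cytokine_effects=dict(config.cytokine_effects),
    )
    return expr, samples, truth


def generate_gene_sets(config: SimulationConfig, truth: GroundTruth):
    """Generate (collection, annotation maps) with a planted category.

    ``n_planted_signatures`` signatures draw ``planted_overlap`` of their
    members from the planted DE genes (hypergeometrically enriched in any
    query that recovers those genes); the remaining signatures are drawn
    uniformly from the gene universe. Every signature is assigned to
    exactly one category at each of the four annotation levels; planted
    signatures always share ``planted_category``.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENESETS)
    universe = list(truth.gene_ids)
    de_genes = sorted({g for ids in truth.de_gene_ids.values() for g in ids})
    non_de = [g for g in universe if g not in set(de_genes)]

    n_overlap = int(round(config.planted_overlap * config.signature_size))
    if n_overlap > len(de_genes):
        raise ConfigError("planted overlap exceeds available DE genes")

    sets = {}
    planted_names = []
    for i in range(config.n_signatures):
        name = f"SIG{i:04d}"
        if i < config.n_planted_signatures and de_genes:
            core = rng.choice(de_genes, size=n_overlap, replace=False)
            rest = rng.choice(non_de, size=config.signature_size - n_overlap, replace=False)
            members = sorted(set(core) | set(rest))
            planted_names.append(name)
        else:
            members = sorted(rng.choice(universe, size=config.signature_size, replace=False))
        sets[name] = members

    collection = GeneSetCollection(name="synthetic_immune", sets=sets, source="C7")

    categories = [f"CAT{j:02d}" for j in range(config.n_categories)]
    if config.planted_category not in categories:
        categories = [config.planted_category] + categories[:-1]
    maps = {}
    for level in ANNOTATION_LEVELS:
        assignments = {}
        for name in sets:
            if name in planted_names:
                assignments[name] = config.planted_category
            else:
                assignments[name] = categories[int(rng.integers(len(categories)))]
        maps[level] = AnnotationMap(level=level, assignments=assignments)

    truth.enriched_signature_ids = list(planted_names)
    truth.enriched_category_id = config.planted_category
    return collection, maps


def generate_cytokines(config: SimulationConfig) -> pd.DataFrame:
    """Long-format cytokine panel: one pg/ml value per subject, cytokine
    and culture condition (EW / M).

    Media concentrations are log-normal around a per-cytokine baseline;
    EW concentrations add the configured group-specific shift on the
    log10 scale plus noise. Values below ``detection_floor`` are clamped
    to the floor, imitating assay detection limits.
    """
    config.validate()
    rng = _rng(config, _STREAM_CYTOKINES)
    subjects = build_subjects(config)
    cytokines = list(config.cytokine_effects) + [
        c for c in config.null_cytokines if c not in config.cytokine_effects
    ]

    rows = []
    n_clamped = 0
    for cyt in cytokines:
        base_log = rng.normal(0.3, 0.3)  # log10 pg/ml media baseline
        effects = config.cytokine_effects.get(cyt, {})
        for _, s in subjects.iterrows():
            m_log = rng.normal(base_log, 0.4)
            shift = effects.get(s.group, 0.0)
            ew_log = m_log + shift + rng.normal(0.0, config.cytokine_noise_sd)
            for cond, lv in (("M", m_log), ("EW", ew_log)):
                conc = 10.0 ** lv
                if conc < config.detection_floor:
                    conc = config.detection_floor
                    n_clamped += 1
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "cytokine": cyt,
                        "condition": cond,
                        "concentration": conc,
                    }
                )
    if n_clamped:
        logger.warning("clamped %d cytokine values to the %.3g pg/ml detection floor",
                       n_clamped, config.detection_floor)
    return pd.DataFrame(rows)
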