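"""Synthetic multi-cohort mCRPC expression data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: several sequencing cohorts whose gene-level measurements carry
batch location/scale effects, five latent correlated transcriptional
programs (luminal/AR, proliferation, mTOR/glycolysis, neuroendocrine, and
an immune/EMT program) expressed through block-diagonal gene loadings,
biopsy-site and histology shifts on program activity, overall survival from
a cohort-stratified Weibull proportional-hazards model whose log-hazard is
a linear function of the four prognostic program activities, matched
pre-/on-treatment sample pairs with an additive on-treatment suppression,
PSA50-style response labels from a logistic trend on the adverse-feature
count, and small negative-binomial single-cell matrices with an optional
dominant hemoglobin (HBB) contamination fraction.

Every generator is deterministic under a fixed ``SimConfig.seed``; distinct
internal random streams keep the outputs of one generator independent of
how often another was called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "generate_expression",
    "generate_survival",
    "generate_paired_and_response",
    "generate_single_cell",
    "program_gene_sets",
    "adverse_count_from_activities",
    "PairedData",
    "COHORT_NAMES",
    "COHORT_SAMPLE_COUNTS",
    "PROGRAM_NAMES",
    "PROGRAM_TO_AXIS",
]

#: the five aggregated sequencing cohorts and their published sample counts
COHORT_NAMES = ("FHCRC", "WCM", "ECDT", "WCDT", "PROMOTE")
COHORT_SAMPLE_COUNTS = (254, 49, 328, 240, 141)

PROGRAM_NAMES = (
    "luminal_ar",
    "proliferation",
    "mtor_glycolysis",
    "nepc",
    "immune_emt",
)
#: latent program -> composite axis label (the immune/EMT program carries no
#: hazard and maps to no axis)
PROGRAM_TO_AXIS = {
    "luminal_ar": "Luminal_AR",
    "proliferation": "Proliferation",
    "mtor_glycolysis": "mTOR_glycolysis",
    "nepc": "NEPC",
}

_DEFAULT_PROGRAM_CORR = (
    (1.0, -0.3, -0.2, -0.3, 0.0),
    (-0.3, 1.0, 0.2, 0.3, 0.0),
    (-0.2, 0.2, 1.0, 0.0, 0.0),
    (-0.3, 0.3, 0.0, 1.0, 0.0),
    (0.0, 0.0, 0.0, 0.0, 1.0),
)

_DEFAULT_SITE_EFFECT = {
    "primary": (0.8, -0.5, -0.5, -0.3, 0.0),
    "bone": (0.0, -0.2, -0.2, -0.1, 0.0),
    "liver": (-0.5, 0.4, 0.4, 0.3, 0.0),
    "lung": (0.0, 0.1, 0.1, 0.0, 0.0),
    "lymph_node": (0.0, 0.0, 0.0, 0.0, 0.0),
    "other": (0.0, 0.0, 0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Sizes default to the five aggregated cohorts' published sample counts;
    smaller runs pass an explicit ``samples_per_cohort``. Activity shifts,
    hazard coefficients and the treatment/response parameters are in the
    latent program scale (program activities are approximately standard
    normal before shifts).
    """

    n_cohorts: int = 5
    samples_per_cohort: tuple | int = COHORT_SAMPLE_COUNTS
    n_genes: int = 1500
    n_programs: int = 5
    genes_per_program: int = 50
    loading_magnitude: float = 1.0
    program_corr: tuple = _DEFAULT_PROGRAM_CORR
    activity_sd: float = 1.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    batch_location_sd: float = 0.5
    batch_scale_range: tuple = (0.8, 1.25)
    site_labels: tuple = ("primary", "bone", "liver", "lung", "lymph_node", "other")
    site_proportions: tuple = (0.03, 0.35, 0.13, 0.05, 0.34, 0.10)
    site_effect: dict | None = None
    nepc_fraction: float = 0.10
    nepc_shift: tuple = (-1.0, 0.5, 0.0, 2.0, 0.0)
    prior_asi_fraction: float = 0.35
    hazard_betas: tuple = (-0.5, 0.5, 0.4, 0.3)
    weibull_shape: float = 1.2
    weibull_scale_per_cohort: tuple | float = (30.0, 30.0, 36.0, 36.0, 24.0)
    censor_horizon: float = 60.0
    n_pairs: int = 52
    pair_noise_sd: float = 0.5
    treatment_shift: tuple = (-1.0, -0.6, -0.6, 0.0, 0.0)
    n_response: int = 142
    psa_trend_intercept: float = 1.0
    psa_trend_slope: float = -0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_programs < 1:
            raise ValueError("n_programs must be >= 1")
        if self.n_programs * self.genes_per_program > self.n_genes:
            raise ValueError(
                "loading blocks exceed n_genes: "
                f"{self.n_programs} x {self.genes_per_program} > {self.n_genes}"
            )
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        scales = np.atleast_1d(np.asarray(self.weibull_scale_per_cohort, dtype=float))
        if (scales <= 0).any() or self.activity_sd <= 0:
            raise ValueError("all scale parameters must be > 0")
        if self.batch_scale_range[0] <= 0 or self.batch_scale_range[1] < self.batch_scale_range[0]:
            raise ValueError("batch_scale_range must be a positive increasing pair")
        if len(self.site_labels) != len(self.site_proportions):
            raise ValueError("site_labels and site_proportions length mismatch")
        corr = np.asarray(self.program_corr, dtype=float)
        if corr.shape != (self.n_programs, self.n_programs):
            raise ValueError("program_corr must be n_programs x n_programs")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("program_corr is not positive semidefinite")
        if len(self.hazard_betas) != min(4, self.n_programs):
            raise ValueError("hazard_betas must cover the prognostic programs")

    @property
    def cohort_sizes(self) -> tuple:
        if isinstance(self.samples_per_cohort, int):
            return (self.samples_per_cohort,) * self.n_cohorts
        sizes = tuple(self.samples_per_cohort)
        if len(sizes) != self.n_cohorts:
            raise ValueError("samples_per_cohort length must equal n_cohorts")
        return sizes

    @property
    def cohort_names(self) -> tuple:
        if self.n_cohorts == len(COHORT_NAMES):
            return COHORT_NAMES
        return tuple(f"cohort_{i + 1}" for i in range(self.n_cohorts))

    @property
    def program_names(self) -> tuple:
        if self.n_programs == len(PROGRAM_NAMES):
            return PROGRAM_NAMES
        return tuple(f"program_{k + 1}" for k in range(self.n_programs))

    @property
    def gene_ids(self) -> list:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed), int(stream)))


def _gene_model(config: SimConfig):
    """Deterministic per-gene baselines and block-diagonal loadings."""
    rng = _rng(config, 0)
    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes
    )
    loadings = np.zeros((config.n_genes, config.n_programs))
    gpp = config.genes_per_program
    for k in range(config.n_programs):
        loadings[k * gpp : (k + 1) * gpp, k] = config.loading_magnitude
    return baseline, loadings


def program_gene_sets(config: SimConfig, sets_per_program: int = 1):
    """Gene sets naming the loading-block genes of each latent program.

    With ``sets_per_program > 1`` each program block is split into that many
    disjoint subsets ("pathways"), mimicking several published signatures
    tracking the same underlying program — the structure the pathway
    clustering stage is meant to recover.
    """
    from .gene_sets import GeneSetCollection

    gpp = config.genes_per_program
    genes = config.gene_ids
    sets: dict[str, list[str]] = {}
    for k, prog in enumerate(config.program_names):
        block = genes[k * gpp : (k + 1) * gpp]
        if sets_per_program == 1:
            sets[prog] = list(block)
        else:
            chunks = np.array_split(np.asarray(block, dtype=object), sets_per_program)
            for j, chunk in enumerate(chunks):
                sets[f"{prog}_sig{j + 1}"] = list(chunk)
    return GeneSetCollection(sets, provenance="synthetic-programs")


def _draw_activities(config: SimConfig, meta: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 2)
    corr = np.asarray(config.program_corr, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(config.n_programs))
    z = rng.standard_normal((len(meta), config.n_programs))
    a = (z @ chol.T) * config.activity_sd
    site_effect = config.site_effect or (
        _DEFAULT_SITE_EFFECT if config.n_programs == 5 else {}
    )
    for site, shift in site_effect.items():
        mask = (meta["biopsy_site"] == site).to_numpy()
        a[mask] += np.asarray(shift, dtype=float)[: config.n_programs]
    if config.n_programs == 5:
        nepc_mask = (meta["histology"] == "NEPC").to_numpy()
        a[nepc_mask] += np.asarray(config.nepc_shift, dtype=float)
    return pd.DataFrame(a, index=meta["sample_id"], columns=config.program_names)


def generate_expression(config: SimConfig):
    """Simulate the combined multi-cohort TPM matrix.

    Per gene g, sample s in cohort b, in log2 space::

        baseline_g + sum_k L_gk a_ks + gamma_gb + delta_gb * eps_gs

    with batch location ``gamma_gb ~ N(0, batch_location_sd)``, batch scale
    ``delta_gb ~ U(batch_scale_range)`` multiplying the i.i.d. noise, then
    exponentiation and per-sample renormalization to one million (TPM).

    Returns ``(expression, meta, activities)``: the gene-by-sample TPM
    matrix, the sample metadata table, and the true latent program
    activities (samples x programs) for recovery tests.
    """
    rng_meta = _rng(config, 1)
    sizes = config.cohort_sizes
    names = config.cohort_names
    cohorts = np.repeat(names, sizes)
    n = len(cohorts)
    sample_ids = [f"{c}-S{i + 1:04d}" for i, c in enumerate(cohorts)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": [f"PT{i + 1:04d}" for i in range(n)],
            "cohort": cohorts,
            "biopsy_site": rng_meta.choice(
                config.site_labels, size=n, p=config.site_proportions
            ),
            "histology": np.where(
                rng_meta.random(n) < config.nepc_fraction, "NEPC", "adenocarcinoma"
            ),
            "prior_ASI": rng_meta.random(n) < config.prior_asi_fraction,
            "timepoint": "pre",
            "biopsy_order": 1,
        }
    )
    activities = _draw_activities(config, meta)

    baseline, loadings = _gene_model(config)
    rng_batch = _rng(config, 3)
    gamma = rng_batch.normal(
        0.0, config.batch_location_sd, size=(config.n_genes, config.n_cohorts)
    ) if config.batch_location_sd > 0 else np.zeros((config.n_genes, config.n_cohorts))
    delta = rng_batch.uniform(
        config.batch_scale_range[0],
        config.batch_scale_range[1],
        size=(config.n_genes, config.n_cohorts),
    )
    rng_noise = _rng(config, 4)
    eps = rng_noise.standard_normal((config.n_genes, n)) * config.noise_sd
    cohort_idx = np.searchsorted(np.cumsum(sizes), np.arange(n), side="right")
    log2x = (
        baseline[:, None]
        + loadings @ activities.to_numpy().T
        + gamma[:, cohort_idx]
        + delta[:, cohort_idx] * eps
    )
    linear = np.exp2(log2x)
    tpm = linear / linear.sum(axis=0, keepdims=True) * 1e6
    expr = pd.DataFrame(tpm, index=config.gene_ids, columns=sample_ids)
    return expr, meta, activities


def generate_survival(
    activities: pd.DataFrame, meta: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Draw one survival record per patient from the Weibull PH model.

    The log-hazard is ``hazard_betas . a`` over the prognostic programs;
    event times are Weibull with cohort-specific scale, administratively
    censored at ``censor_horizon``. A non-positive horizon (everything
    censored at time zero) is rejected as a degenerate configuration.
    """
    if config.censor_horizon <= 0:
        raise ValueError(
            "censor_horizon must be > 0; an all-censored-at-zero cohort is degenerate"
        )
    rng = _rng(config, 5)
    meta = meta.set_index("sample_id")
    a = activities.to_numpy()
    n_prog = min(4, config.n_programs)
    betas = np.asarray(config.hazard_betas, dtype=float)
    lp = a[:, :n_prog] @ betas
    scales = np.atleast_1d(np.asarray(config.weibull_scale_per_cohort, dtype=float))
    if scales.size == 1:
        scales = np.repeat(scales, config.n_cohorts)
    cohort_of = meta.loc[activities.index, "cohort"]
    scale_s = scales[[list(config.cohort_names).index(c) for c in cohort_of]]
    u = rng.uniform(size=len(activities))
    raw = scale_s * (-np.log(u) * np.exp(-lp)) ** (1.0 / config.weibull_shape)
    time = np.minimum(raw, config.censor_horizon)
    event = (raw <= config.censor_horizon).astype(int)
    if event.sum() == 0:
        raise ValueError("no events drawn; survival configuration is degenerate")
    out = pd.DataFrame(
        {
            "patient_id": meta.loc[activities.index, "patient_id"].to_numpy(),
            "time": time,
            "event": event,
            "site": meta.loc[activities.index, "biopsy_site"].to_numpy(),
            "cohort": cohort_of.to_numpy(),
        }
    ).set_index("patient_id")
    return out


def adverse_count_from_activities(
    activities: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.Series:
    """True adverse-feature count from latent program activities.

    Mirrors the tertile rule on the generative scale: bottom tertile of the
    luminal/AR program, top tertile of each adverse program.
    """
    ref = activities if reference is None else reference
    count = pd.Series(0, index=activities.index, dtype=int)
    count += activities["luminal_ar"] <= ref["luminal_ar"].quantile(1 / 3)
    for prog in ("proliferation", "mtor_glycolysis", "nepc"):
        count += activities[prog] >= ref[prog].quantile(2 / 3)
    return count


@dataclass
class PairedData:
    """Matched pre-/on-treatment samples plus response labels."""

    meta: pd.DataFrame
    activities_pre: pd.DataFrame
    activities_on: pd.DataFrame
    expression_on: pd.DataFrame
    response: pd.Series  # patient_id -> 0/1, for the response subset
    adverse_count: pd.Series  # patient_id -> 0..4 over the whole cohort


def generate_paired_and_response(
    activities: pd.DataFrame, meta: pd.DataFrame, config: SimConfig
) -> PairedData:
    """Create matched on-treatment samples and PSA50-style response labels.

    For ``n_pairs`` randomly chosen patients the on-treatment program
    activities are the pre-treatment activities plus ``treatment_shift``
    plus between-biopsy noise (sd ``pair_noise_sd``); their expression is
    regenerated through the same gene/batch model. Response for
    ``n_response`` patients is Bernoulli with success probability
    ``logistic(psa_trend_intercept + psa_trend_slope * adverse_count)``.
    """
    rng = _rng(config, 6)
    meta_ix = meta.set_index("sample_id")
    n_pairs = min(config.n_pairs, len(activities))
    pair_samples = list(
        rng.choice(np.asarray(activities.index), size=n_pairs, replace=False)
    )
    a_pre = activities.loc[pair_samples]
    shift = np.asarray(config.treatment_shift, dtype=float)[: config.n_programs]
    a_on = a_pre + shift + rng.standard_normal(a_pre.shape) * config.pair_noise_sd
    on_ids = [f"{s}-T2" for s in pair_samples]
    a_on.index = on_ids

    baseline, loadings = _gene_model(config)
    rng_batch = _rng(config, 3)  # same batch-effect draw as generate_expression
    gamma = rng_batch.normal(
        0.0, config.batch_location_sd, size=(config.n_genes, config.n_cohorts)
    ) if config.batch_location_sd > 0 else np.zeros((config.n_genes, config.n_cohorts))
    delta = rng_batch.uniform(
        config.batch_scale_range[0],
        config.batch_scale_range[1],
        size=(config.n_genes, config.n_cohorts),
    )
    cohort_names = list(config.cohort_names)
    b_idx = [cohort_names.index(meta_ix.loc[s, "cohort"]) for s in pair_samples]
    eps = rng.standard_normal((config.n_genes, n_pairs)) * config.noise_sd
    log2x = (
        baseline[:, None]
        + loadings @ a_on.to_numpy().T
        + gamma[:, b_idx]
        + delta[:, b_idx] * eps
    )
    linear = np.exp2(log2x)
    expr_on = pd.DataFrame(
        linear / linear.sum(axis=0, keepdims=True) * 1e6,
        index=config.gene_ids,
        columns=on_ids,
    )

    pre_rows = meta_ix.loc[pair_samples].reset_index()
    on_rows = pre_rows.copy()
    on_rows["sample_id"] = on_ids
    on_rows["timepoint"] = "on_treatment"
    on_rows["biopsy_order"] = 2
    paired_meta = pd.concat([pre_rows, on_rows], ignore_index=True)

    count_all = adverse_count_from_activities(activities)
    count_by_patient = pd.Series(
        count_all.to_numpy(), index=meta_ix.loc[activities.index, "patient_id"]
    )
    rng_resp = _rng(config, 7)
    n_resp = min(config.n_response, len(count_by_patient))
    resp_patients = list(
        rng_resp.choice(np.asarray(count_by_patient.index), size=n_resp, replace=False)
    )
    counts = count_by_patient.loc[resp_patients]
    prob = 1.0 / (
        1.0
        + np.exp(-(config.psa_trend_intercept + config.psa_trend_slope * counts))
    )
    response = pd.Series(
        (rng_resp.random(n_resp) < prob).astype(int),
        index=counts.index,
        name="psa50_response",
    )
    a_pre_out = a_pre.copy()
    return PairedData(
        meta=paired_meta,
        activities_pre=a_pre_out,
        activities_on=a_on,
        expression_on=expr_on,
        response=response,
        adverse_count=count_by_patient,
    )


def generate_single_cell(
    config: SimConfig,
    n_cells: int = 200,
    population_activities=None,
    hbb_fraction: float = 0.0,
    dispersion: float = 0.5,
    depth: int = 20000,
):
    """Simulate a small single-cell count matrix around tumor profiles.

    Cells are split evenly across one or more populations, each defined by
    a program-activity vector; counts are negative-binomial (gamma-Poisson)
    around the population's expected profile at the given sequencing depth
    (``dispersion -> 0`` recovers Poisson noise around the mean profile).
    With ``hbb_fraction > 0`` an HBB row is added holding that fraction of
    every cell's total counts, emulating hemoglobin-contaminated
    circulating-tumor-cell libraries.

    Returns ``(counts, labels)``: a gene-by-cell integer matrix (with an
    ``HBB`` row appended) and the per-cell population label.
    """
    if not 0.0 <= hbb_fraction < 1.0:
        raise ValueError("hbb_fraction must be in [0, 1)")
    rng = _rng(config, 8)
    if population_activities is None:
        population_activities = [np.zeros(config.n_programs)]
    pops = [np.asarray(a, dtype=float) for a in population_activities]
    baseline, loadings = _gene_model(config)
    profiles = []
    for a in pops:
        linear = np.exp2(baseline + loadings @ a)
        profiles.append(linear / linear.sum())
    labels = np.arange(n_cells) % len(pops)
    mu = depth * np.column_stack([profiles[l] for l in labels])
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(int)
    cells = [f"cell_{i + 1:04d}" for i in range(n_cells)]
    df = pd.DataFrame(counts, index=config.gene_ids, columns=cells)
    totals = df.sum(axis=0)
    if hbb_fraction > 0:
        hbb = np.rint(hbb_fraction / (1.0 - hbb_fraction) * totals).astype(int)
    else:
        hbb = rng.poisson(depth * 1e-4, size=n_cells)
    df.loc["HBB"] = hbb
    return df, pd.Series(labels, index=cells, name="population")
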