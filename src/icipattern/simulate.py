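"""Synthetic tumor cohorts with planted ground truth.

Emulates the statistical structure the pipeline assumes: bulk expression as a
linear mixture of cell-type profiles, latent immune-hot/cold groups that drive
both differential expression and proportional-hazards survival, cohort batch
shifts on the log scale, and per-sample mutation burdens tied to the latent
group. None of this imitates any specific tumor type's distributions — it gives
every downstream stage a truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, MutationTable, SignatureMatrix


def make_signature_matrix(
    n_genes: int,
    n_cell_types: int,
    markers_per_type: int,
    seed: int,
) -> SignatureMatrix:
    """Build a cell-type reference with disjoint marker blocks on a low basal background.

    Each cell type over-expresses its own ``markers_per_type`` genes (linear
    scale, roughly 50-100x basal), which keeps the columns well conditioned.
    """
    if markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1 (zero markers gives collinear columns)")
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError(
            f"cannot place {markers_per_type} disjoint markers for {n_cell_types} "
            f"cell types in {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    basal = rng.uniform(1.0, 4.0, size=(n_genes, n_cell_types))
    values = basal
    for t in range(n_cell_types):
        lo = t * markers_per_type
        values[lo : lo + markers_per_type, t] = rng.uniform(150.0, 300.0, size=markers_per_type)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    types = [f"CT{t}" for t in range(n_cell_types)]
    return SignatureMatrix(pd.DataFrame(values, index=genes, columns=types))


def _dominant_types(n_groups: int, n_cell_types: int) -> list[int]:
    """Dominant cell type per latent group, spread from immune (type 0, the
    hot group) to stromal (the last type, the cold group)."""
    if n_groups == 1:
        return [0]
    return [round(g * (n_cell_types - 1) / (n_groups - 1)) for g in range(n_groups)]


def _default_concentrations(n_groups: int, n_cell_types: int) -> np.ndarray:
    """One dominant cell type per latent group plus a monotone immune gradient.

    Each group gets a distinct dominant cell type (keeps the groups separable
    in fraction space) and additional weight on the immune effector type 0
    that decreases from the hot group to the cold one, so immune infiltration
    is a gradient across groups the way infiltration subtypes are in tumors.
    """
    conc = np.ones((n_groups, n_cell_types))
    for g, t in enumerate(_dominant_types(n_groups, n_cell_types)):
        conc[g, t] += 7.0
        if n_groups > 1:
            conc[g, 0] += 6.0 * (n_groups - 1 - g) / (n_groups - 1)
    return conc


@dataclass
class SyntheticCohortSpec:
    """Parameters of a simulated cohort. Defaults give three well-separated
    latent immune groups: group 0 is immune-hot (lowest hazard, highest
    mutation rate), the last group immune-cold."""

    n_samples: int = 300
    n_genes: int = 500
    n_cell_types: int = 5
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    noise_sd: float = 0.5
    n_latent_groups: int = 3
    hazard_ratio_per_group: tuple[float, ...] = (1.0, 1.5, 2.0)
    mutation_rate_per_group: tuple[float, ...] = (15.0, 10.0, 5.0)
    fraction_concentration: np.ndarray | None = None
    de_genes_per_group: int = 25
    de_shift: float = 60.0
    baseline_hazard: float = 0.02
    censor_max: float = 120.0
    n_driver_genes: int = 5
    driver_enrichment: float = 3.0
    seed: int = 0
    # gene-level structure (marker blocks, planted DE gene identities) is drawn
    # from this seed, so held-out cohorts can share structure while redrawing
    # samples; defaults to `seed`
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_cell_types", "n_batches", "n_latent_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.hazard_ratio_per_group) != self.n_latent_groups:
            raise ValueError("need one hazard ratio per latent group")
        if len(self.mutation_rate_per_group) != self.n_latent_groups:
            raise ValueError("need one mutation rate per latent group")
        if any(h <= 0 for h in self.hazard_ratio_per_group):
            raise ValueError("hazard ratios must be strictly positive")
        if any(r <= 0 for r in self.mutation_rate_per_group):
            raise ValueError("mutation rates must be strictly positive")
        if self.batch_shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.fraction_concentration is None:
            self.fraction_concentration = _default_concentrations(
                self.n_latent_groups, self.n_cell_types
            )
        self.fraction_concentration = np.asarray(self.fraction_concentration, dtype=float)
        if self.fraction_concentration.shape != (self.n_latent_groups, self.n_cell_types):
            raise ValueError("fraction_concentration must be (n_latent_groups, n_cell_types)")
        if (self.fraction_concentration <= 0).any():
            raise ValueError("Dirichlet concentrations must be strictly positive")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth planted in it."""

    expression: ExpressionMatrix  # log2TPM1
    clinical: ClinicalTable
    mutations: MutationTable
    signature: SignatureMatrix
    truth: dict = field(default_factory=dict)


def simulate_cohort(
    spec: SyntheticCohortSpec,
    signature: SignatureMatrix | None = None,
) -> SyntheticCohort:
    """Draw a full cohort from the generative model.

    Per sample: a latent group; cell fractions ~ Dirichlet(group concentration);
    linear expression = signature @ fractions plus group-specific shifts on that
    group's planted signature genes plus Gaussian noise, floored at zero and
    log2(x+1)-transformed; a per-batch per-gene Gaussian shift is then added on
    the log scale. Survival is exponential with per-group hazard and independent
    uniform censoring; mutation counts are Poisson with the group's rate, with
    designated driver genes enriched in low-numbered (immune-hot) groups.
    """
    rng = np.random.default_rng(spec.seed)
    struct_rng = np.random.default_rng(
        spec.seed if spec.structure_seed is None else spec.structure_seed
    )
    if signature is None:
        markers = max(1, min(20, spec.n_genes // (2 * spec.n_cell_types)))
        signature = make_signature_matrix(
            spec.n_genes, spec.n_cell_types, markers, seed=int(struct_rng.integers(2**31))
        )
    if signature.values.shape[0] != spec.n_genes:
        raise ValueError("signature matrix gene count must match spec.n_genes")

    n, p, k, g = spec.n_samples, spec.n_genes, spec.n_cell_types, spec.n_latent_groups
    genes = signature.genes
    samples = [f"S{i:04d}" for i in range(n)]

    groups = rng.integers(0, g, size=n)
    fractions = np.vstack(
        [rng.dirichlet(spec.fraction_concentration[gr]) for gr in groups]
    )  # n x k
    linear = fractions @ signature.values.to_numpy().T  # n x p

    # planted per-group DE blocks, disjoint from the marker blocks when possible
    marker_rows = set()
    sig_arr = signature.values.to_numpy()
    basal_cut = sig_arr.max(axis=1) > 50.0
    marker_rows = set(np.flatnonzero(basal_cut))
    free = [i for i in range(p) if i not in marker_rows]
    need = spec.de_genes_per_group * g
    pool = free if len(free) >= need else list(range(p))
    de_idx = struct_rng.choice(pool, size=min(need, len(pool)), replace=False)
    de_sets: dict[int, np.ndarray] = {}
    per = len(de_idx) // g
    for gr in range(g):
        de_sets[gr] = np.sort(de_idx[gr * per : (gr + 1) * per])
        linear[np.ix_(groups == gr, de_sets[gr])] += spec.de_shift

    if spec.noise_sd > 0:
        linear += rng.normal(0.0, spec.noise_sd, size=(n, p))
    linear = np.clip(linear, 0.0, None)
    logexpr = np.log2(linear + 1.0)

    batches = rng.integers(0, spec.n_batches, size=n)
    if spec.n_batches > 1 and spec.batch_shift_sd > 0:
        # additive per-gene shift on the log2 scale, one draw per (batch, gene)
        shifts = rng.normal(0.0, spec.batch_shift_sd, size=(spec.n_batches, p))
        logexpr += shifts[batches]
    batch_labels = np.array([f"cohort{b}" for b in batches])

    expression = ExpressionMatrix(
        pd.DataFrame(logexpr.T, index=genes, columns=samples), "log2TPM1"
    )

    hazards = spec.baseline_hazard * np.asarray(spec.hazard_ratio_per_group)[groups]
    event_times = rng.exponential(1.0 / hazards)
    censor_times = rng.uniform(0.0, spec.censor_max, size=n)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)
    os_time = np.maximum(os_time, 1e-3)  # survival times must stay positive

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "os_time": os_time,
                "os_event": os_event,
                "batch": batch_labels,
            }
        )
    )

    # mutations: Poisson burden per sample; driver genes enriched in hot groups
    rates = np.asarray(spec.mutation_rate_per_group)[groups]
    tmb = rng.poisson(rates)
    driver_genes = [f"DRIVER{j}" for j in range(spec.n_driver_genes)]
    passenger_genes = [f"PSG{j:04d}" for j in range(200)]
    recs: list[tuple[str, str, str]] = []
    for i, s in enumerate(samples):
        m_i = int(tmb[i])
        if m_i == 0:
            continue
        # hot groups (low index) mutate drivers more often
        w_driver = spec.driver_enrichment if groups[i] == 0 else 1.0
        p_driver = min(0.5, 0.04 * w_driver * spec.n_driver_genes)
        is_driver = rng.random(m_i) < p_driver
        chosen = np.where(
            is_driver,
            rng.choice(driver_genes, size=m_i),
            rng.choice(passenger_genes, size=m_i),
        )
        recs.extend((s, str(gene), "Missense_Mutation") for gene in chosen)
    mutations = MutationTable(
        pd.DataFrame(recs, columns=["sample_id", "gene_symbol", "variant_class"]),
        covered_samples=samples,
    )

    # stand-in immune / stromal gene sets. The immune set holds markers of the
    # hot group's dominant type plus types no colder group dominates, so the
    # immune score unambiguously peaks in the immune-hot group; the stromal
    # set holds markers of the last (stromal) type, the cold group's dominant.
    markers_of = {
        t: [genes[i] for i in np.flatnonzero(sig_arr[:, t] > 50.0)]
        for t in range(k)
    }
    dominants = _dominant_types(g, k)
    immune_types = [t for t in range(k - 1) if t == 0 or t not in dominants[1:]]
    immune_set = [gn for t in immune_types for gn in markers_of[t]]
    stromal_set = markers_of[k - 1] or markers_of[max(0, k - 1)]

    truth = {
        "group": pd.Series(groups, index=samples, name="latent_group"),
        "fractions": pd.DataFrame(fractions, index=samples, columns=signature.cell_types),
        "signature_genes": {gr: [genes[i] for i in de_sets[gr]] for gr in range(g)},
        "batch": pd.Series(batch_labels, index=samples, name="batch"),
        "tmb": pd.Series(tmb, index=samples, name="true_tmb"),
        "immune_set": immune_set,
        "stromal_set": stromal_set,
        "driver_genes": driver_genes,
    }
    return SyntheticCohort(expression, clinical, mutations, signature, truth)
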