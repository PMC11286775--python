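"""Synthetic data with planted, recoverable ground truth for every stage.

The generator emulates a three-condition (parental / resistant / reversal)
replicate design: a subset of regulators flips activity in the resistant
state and — except for a small persistent subset — reverts in the reversal
state.  Regulator activity propagates to target-gene means through the
regulon (a target of an activated regulator shifts by mor * delta_act on
the log2 scale); counts are negative binomial with Var = mu + alpha * mu^2.
Protein intensities are an affine function of the log2 RNA signal plus
gene-level Gaussian post-transcriptional offsets and planted protein-only
effects; regulator proteins shift with their activity so that concordant
seeds exist by construction.  A modular, degree-heterogeneous PPI embeds
the planted regulators with their targets as dense modules.  The patient
cohort is Gaussian log-expression with a planted set overexpressed in
responders, and dose-response data follow the median-effect equation.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, Regulon, RegulonSet


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimConfig:
    # cell-line omics
    n_genes: int = 2000
    n_regulators: int = 50
    targets_per_regulon: int = 20
    n_replicates: int = 3
    conditions: tuple = ("parental", "resistant", "reversal")
    n_shift_regulators: int = 10
    delta_act: float = 1.0  # log2 activity effect size
    n_persistent: int = 3  # shifted regulators that do not revert
    nb_dispersion: float = 0.05
    depth_sd: float = 0.15  # log-normal sd of per-sample depth factors
    base_log2_mean: float = 6.5
    base_log2_sd: float = 1.5
    # proteomics
    n_protein_genes: int = 800
    protein_offset_sd: float = 0.25
    protein_noise_sd: float = 0.15
    n_protein_only: int = 30
    protein_only_effect: float = 1.0
    # PPI
    ppi_module_count: int = 4
    module_size: int = 25
    ppi_p_in: float = 0.30
    ppi_background_nodes: int = 300
    ppi_background_degree: float = 4.0
    # cohort
    cohort_n: int = 87
    cohort_pcr_fraction: float = 0.3
    cohort_genes: int = 1500
    cohort_set_size: int = 50
    cohort_set_effect: float = 1.0  # delta_set, in sd units
    # dose-response
    drugs: dict = field(default_factory=lambda: {"drugA": (1.2, 830.0), "drugB": (1.0, 2000.0)})
    dose_points: int = 7
    dose_replicates: int = 12
    combo_fa_grid: tuple = (0.3, 0.5, 0.7, 0.8)
    combo_replicates: int = 6
    combo_ci_true: float = 1.0
    noise_sd: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_regulators", "targets_per_regulon", "n_replicates",
            "n_protein_genes", "ppi_module_count", "module_size", "cohort_genes",
            "cohort_set_size", "dose_points", "dose_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.cohort_pcr_fraction < 1:
            raise ConfigError("cohort_pcr_fraction must be in (0, 1)")
        if self.cohort_n < 4:
            raise ConfigError("cohort_n must be >= 4")
        if self.n_shift_regulators > self.n_regulators:
            raise ConfigError("more shifted regulators than regulators")
        if self.n_persistent > self.n_shift_regulators:
            raise ConfigError("more persistent than shifted regulators")
        if self.targets_per_regulon > self.n_genes:
            raise ConfigError("regulon larger than gene pool")
        if self.n_shift_regulators * self.targets_per_regulon > self.n_genes:
            raise ConfigError("planted regulons cannot be disjoint at this size")
        for name, (m, dm) in self.drugs.items():
            if dm <= 0 or m <= 0:
                raise ConfigError(f"drug {name}: m and Dm must be positive")
        if not all(np.isfinite([self.delta_act, self.cohort_set_effect])):
            raise ConfigError("effect sizes must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, for recovery tests."""

    regulator_activity: pd.DataFrame | None = None  # regulators x conditions
    gene_log2fc: pd.DataFrame | None = None  # genes x contrasts
    shifted_regulators: list = field(default_factory=list)
    persistent_regulators: list = field(default_factory=list)
    regulator_direction: dict = field(default_factory=dict)
    protein_only_genes: list = field(default_factory=list)
    modules: dict = field(default_factory=dict)  # module id -> node set
    module_direction: dict = field(default_factory=dict)
    cohort_set: list = field(default_factory=list)
    cohort_set_effect: float = 0.0
    drug_params: dict = field(default_factory=dict)  # drug -> (m, Dm)
    combo_ci: float = np.nan

    def write(self, path) -> None:
        import json

        def default(o):
            if isinstance(o, (pd.DataFrame, pd.Series)):
                return o.to_dict()
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=default, indent=1)


def _rng(config: SimConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.rng_seed if seed is None else seed)


def _condition_labels(config: SimConfig) -> pd.Series:
    samples, conds = [], []
    for c in config.conditions:
        for r in range(config.n_replicates):
            samples.append(f"{c}_{r + 1}")
            conds.append(c)
    return pd.Series(conds, index=samples)


def simulate_omics(config: SimConfig, seed: int | None = None):
    """Generate (counts, intensities, regulons, truth) for the cell-line arm."""
    rng = _rng(config, seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    regulators = [f"R{i:03d}" for i in range(config.n_regulators)]
    shifted = regulators[: config.n_shift_regulators]
    persistent = shifted[: config.n_persistent]

    # disjoint target blocks for planted regulators keep modules separable
    pool = list(rng.permutation(genes))
    regulons = RegulonSet()
    block = 0
    for reg in regulators:
        if reg in shifted:
            targets = pool[block : block + config.targets_per_regulon]
            block += config.targets_per_regulon
        else:
            targets = list(rng.choice(genes, size=config.targets_per_regulon, replace=False))
        mor = np.where(rng.random(config.targets_per_regulon) < 0.75, 1.0, -1.0)
        likelihood = rng.uniform(0.5, 1.0, size=config.targets_per_regulon)
        regulons[reg] = Regulon(targets, mor, likelihood)

    direction = {reg: (1.0 if i % 2 == 0 else -1.0) for i, reg in enumerate(shifted)}
    activity = pd.DataFrame(0.0, index=regulators, columns=list(config.conditions))
    for reg, d in direction.items():
        activity.loc[reg, "resistant"] = d * config.delta_act
        if reg in persistent:
            activity.loc[reg, "reversal"] = d * config.delta_act

    conditions = _condition_labels(config)
    shift = pd.DataFrame(0.0, index=genes, columns=list(config.conditions))
    for reg in regulators:
        regulon = regulons[reg]
        for cond in config.conditions:
            a = activity.loc[reg, cond]
            if a != 0.0:
                shift.loc[regulon.targets, cond] += regulon.mor * a

    base_log2 = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_genes)
    depth = np.exp(rng.normal(0.0, config.depth_sd, size=len(conditions)))
    mu = (
        2.0 ** (base_log2[:, None] + shift[conditions.values].to_numpy())
        * depth[None, :]
    )
    alpha = config.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    else:
        lam = mu
    counts = pd.DataFrame(rng.poisson(lam).astype(float), index=genes, columns=conditions.index)

    # proteome: regulator proteins follow their activity; gene proteins follow RNA
    prot_genes = genes[: config.n_protein_genes]
    protein_only = list(
        rng.choice(prot_genes, size=min(config.n_protein_only, len(prot_genes)), replace=False)
    )
    prot_ids = regulators + prot_genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    reg_base = rng.normal(5.0, 1.0, size=config.n_regulators)
    offsets = rng.normal(0.0, config.protein_offset_sd, size=len(prot_ids))
    log2_int = np.empty((len(prot_ids), len(conditions)))
    cond_of = conditions.values
    for j, cond in enumerate(cond_of):
        reg_part = reg_base + activity[cond].to_numpy()
        gene_part = 2.0 + 0.9 * (
            base_log2[[gene_idx[g] for g in prot_genes]]
            + shift.loc[prot_genes, cond].to_numpy()
        )
        log2_int[:, j] = np.concatenate([reg_part, gene_part])
    po_effect = pd.Series(0.0, index=prot_ids)
    po_sign = rng.choice([-1.0, 1.0], size=len(protein_only))
    for g, sgn in zip(protein_only, po_sign):
        po_effect.loc[g] = sgn * config.protein_only_effect
    resistant_cols = cond_of == "resistant"
    log2_int[:, resistant_cols] += po_effect.to_numpy()[:, None]
    log2_int += offsets[:, None]
    log2_int += rng.normal(0.0, config.protein_noise_sd, size=log2_int.shape)
    intensities = pd.DataFrame(2.0**log2_int, index=prot_ids, columns=conditions.index)

    contrasts = {
        "resistant_vs_parental": shift["resistant"] - shift["parental"],
        "reversal_vs_resistant": shift["reversal"] - shift["resistant"],
        "reversal_vs_parental": shift["reversal"] - shift["parental"],
    }
    truth = SyntheticTruth(
        regulator_activity=activity,
        gene_log2fc=pd.DataFrame(contrasts),
        shifted_regulators=shifted,
        persistent_regulators=persistent,
        regulator_direction=direction,
        protein_only_genes=protein_only,
    )
    return (
        ExpressionMatrix(counts, conditions, "count"),
        ExpressionMatrix(intensities, conditions, "intensity"),
        regulons,
        truth,
    )


def simulate_ppi(
    config: SimConfig, truth: SyntheticTruth, regulons: RegulonSet, seed: int | None = None
) -> nx.Graph:
    """Plant dense modules (one per shifted regulator) in a degree-heterogeneous
    Chung-Lu background; returns a simple scored graph and records module
    membership in ``truth``."""
    rng = _rng(config, seed)
    # modules are anchored on the reverting regulators so that the planted
    # communities carry signal in both the resistant and reversal contrasts
    reverting = [
        r for r in truth.shifted_regulators if r not in truth.persistent_regulators
    ]
    anchors = reverting + [r for r in truth.shifted_regulators if r not in reverting]
    n_modules = min(config.ppi_module_count, len(anchors))
    if n_modules == 0:
        raise ConfigError("no shifted regulator to build modules from")
    modules, used = {}, set()
    for mi in range(n_modules):
        reg = anchors[mi]
        members = [reg] + [t for t in regulons[reg].targets if t not in used]
        members = members[: config.module_size]
        if len(members) < 3:
            raise ConfigError("module_size leaves fewer than 3 members")
        modules[f"M{mi}"] = set(members)
        used |= set(members)
        truth.module_direction[f"M{mi}"] = (
            "up" if truth.regulator_direction[reg] > 0 else "down"
        )
    truth.modules = modules

    background = [f"B{i:04d}" for i in range(config.ppi_background_nodes)]
    nodes = sorted(used) + background
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for members in modules.values():
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                if rng.random() < config.ppi_p_in:
                    graph.add_edge(mem[i], mem[j], score=float(rng.uniform(0.4, 1.0)))
    if config.ppi_background_degree > 0:
        w = rng.pareto(2.5, size=len(nodes)) + 1.0
        w *= np.sqrt(config.ppi_background_degree * len(nodes)) / w.sum() ** 0.5
        module_of = {}
        for name, members in modules.items():
            for m in members:
                module_of[m] = name
        probs = np.minimum(np.outer(w, w) / w.sum(), 1.0)
        draws = rng.random((len(nodes), len(nodes)))
        iu, ju = np.triu_indices(len(nodes), k=1)
        hit = draws[iu, ju] < probs[iu, ju]
        for i, j in zip(iu[hit], ju[hit]):
            u, v = nodes[i], nodes[j]
            if module_of.get(u) is not None and module_of.get(u) == module_of.get(v):
                continue  # intra-module density is controlled by ppi_p_in
            if not graph.has_edge(u, v):
                graph.add_edge(u, v, score=float(rng.uniform(0.4, 1.0)))
    return graph


def simulate_cohort(config: SimConfig, seed: int | None = None):
    """Binary-outcome patient cohort with a planted overexpressed gene set.

    Gaussian log-expression; members of the planted set are shifted by
    ``cohort_set_effect`` standard deviations in responders (pCR).
    Returns (ExpressionMatrix, labels, truth).
    """
    rng = _rng(config, seed)
    genes = [f"CG{i:05d}" for i in range(config.cohort_genes)]
    samples = [f"P{i:03d}" for i in range(config.cohort_n)]
    n_pcr = max(int(round(config.cohort_pcr_fraction * config.cohort_n)), 1)
    labels = np.array(["pCR"] * n_pcr + ["no-pCR"] * (config.cohort_n - n_pcr))
    labels = labels[rng.permutation(config.cohort_n)]
    base = rng.normal(8.0, 1.0, size=config.cohort_genes)
    x = base[:, None] + rng.normal(0.0, 1.0, size=(config.cohort_genes, config.cohort_n))
    planted = list(rng.choice(genes, size=config.cohort_set_size, replace=False))
    planted_idx = [genes.index(g) for g in planted]
    pcr_cols = labels == "pCR"
    x[np.ix_(planted_idx, np.where(pcr_cols)[0])] += config.cohort_set_effect
    expr = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples),
        pd.Series(labels, index=samples),
        "intensity",
    )
    truth = SyntheticTruth(cohort_set=planted, cohort_set_effect=config.cohort_set_effect)
    return expr, pd.Series(labels, index=samples), truth


def _median_effect_fa(dose: np.ndarray, m: float, dm: float) -> np.ndarray:
    ratio = (dose / dm) ** m
    return ratio / (1.0 + ratio)


def simulate_dose_response(config: SimConfig, seed: int | None = None):
    """Dose-response tables from the median-effect equation plus combination
    points constructed to achieve the configured true CI.

    Returns (dict drug -> DoseResponse, list of ComboMeasurement, truth).
    """
    from .synergy import ComboMeasurement, DoseResponse

    rng = _rng(config, seed)
    half = config.dose_points // 2
    responses = {}
    for name, (m, dm) in config.drugs.items():
        # two-fold dilution series centred on the median-effect dose
        doses = dm * 2.0 ** np.arange(-half, config.dose_points - half)
        if (doses <= 0).any():
            raise ConfigError("doses must be positive")
        d_rep = np.repeat(doses, config.dose_replicates)
        fa = _median_effect_fa(d_rep, m, dm)
        v = np.clip(1.0 - fa + rng.normal(0.0, config.noise_sd, size=d_rep.shape), 0.0, 1.2)
        responses[name] = DoseResponse(
            name, d_rep, v, np.tile(np.arange(config.dose_replicates), config.dose_points)
        )
    names = list(config.drugs)
    (m1, dm1), (m2, dm2) = config.drugs[names[0]], config.drugs[names[1]]
    combos = []
    for fa_c in config.combo_fa_grid:
        dx1 = dm1 * (fa_c / (1.0 - fa_c)) ** (1.0 / m1)
        dx2 = dm2 * (fa_c / (1.0 - fa_c)) ** (1.0 / m2)
        d1 = 0.5 * config.combo_ci_true * dx1
        d2 = 0.5 * config.combo_ci_true * dx2
        # replicate wells averaged on the viability scale, as in the assay
        draws = 1.0 - fa_c + rng.normal(0.0, config.noise_sd, size=config.combo_replicates)
        v = float(np.clip(draws, 0.0, 1.2).mean())
        combos.append(ComboMeasurement(d1, d2, v))
    truth = SyntheticTruth(drug_params=dict(config.drugs), combo_ci=config.combo_ci_true)
    return responses, combos, truth
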