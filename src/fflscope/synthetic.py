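"""Synthetic matched mRNA/miRNA cohorts with planted ground truth.

The generator emulates a multi-subtype thyroid-neoplasm cohort (seven tumor
subtypes plus normal tissue, 362 samples by default) on the log2 scale:

* medullary-carcinoma (MTC) exclusive up/down genes with drawn effect sizes;
* a co-expressed hub block driven by a shared latent factor;
* a repressor transcription factor loading negatively on the hub factor and
  positively on a miRNA latent factor;
* regulator miRNAs repressing their hub-gene targets (negative loading on
  the hub factor) while sharing the TF's miRNA factor (positive loading);
* stromal/immune/TIL/checkpoint gene programs on an infiltration factor
  anti-correlated with the hub factor;
* exponential survival with a protective hub effect and an adverse
  regulator-miRNA effect, under independent uniform censoring.

Every planted identity, effect and edge is recorded in a truth object so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fflscope.io import (
    ExpressionDataset,
    GeneSetCollection,
    MiRNAPrior,
    PPIEdge,
    TFPrior,
    write_edge_list,
    write_expression,
    write_gmt,
)

#: default cohort composition (sums to 362 samples)
DEFAULT_SUBTYPE_COUNTS: dict[str, int] = {
    "ATC": 24,
    "MTC": 54,
    "PTC": 142,
    "FTC": 22,
    "OTC": 8,
    "FTA": 27,
    "OTA": 16,
    "normal": 69,
}

NORMAL = "normal"
TARGET_SUBTYPE = "MTC"


@dataclass
class SimulationDesign:
    """All knobs of the synthetic cohort; defaults mirror the study scale."""

    subtype_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS))
    n_genes: int = 2000
    n_mirnas: int = 300
    # MTC-exclusive differential expression (log2 effects)
    n_planted_up: int = 80
    n_planted_down: int = 20
    effect_low: float = 1.2
    effect_high: float = 2.5
    # genes DE in MTC and in one comparator subtype (not exclusive)
    n_shared_de: int = 40
    # genes DE in exactly one non-MTC tumor subtype
    n_per_subtype_de: int = 60
    # hub block (subset of the planted up-genes)
    hub_size: int = 15
    hub_loading: float = 1.0
    hub_effect_low: float = 1.8
    hub_effect_high: float = 2.5
    # repressor TF (one of the planted down-genes)
    tf_effect: float = 1.8
    tf_hub_loading: float = 0.8
    tf_mir_loading: float = 0.8
    n_tf_targets: int = 9
    # regulator miRNAs (down in MTC, repress hub targets, share TF factor)
    n_reg_mirnas: int = 13
    mirna_hub_loading: float = 0.7
    mirna_mir_loading: float = 0.7
    mirna_down_low: float = 1.5
    mirna_down_high: float = 2.2
    # background DE miRNAs
    n_other_down_mirnas: int = 17
    n_up_mirnas: int = 20
    mirna_bg_low: float = 0.8
    mirna_bg_high: float = 1.5
    # immune programs
    immune_hub_corr: float = -0.6
    stromal_size: int = 30
    immune_size: int = 30
    n_til_sets: int = 28
    til_set_size: int = 8
    n_icgs: int = 14
    stromal_loading: float = 0.8
    immune_loading: float = 0.9
    til_loading: float = 0.8
    icg_loading: float = 0.8
    # noise and baseline
    noise_sd: float = 0.7
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    # survival (months)
    baseline_hazard: float = 0.02
    beta_hub: float = -0.7
    beta_mirna: float = 0.7
    censor_max_months: float = 120.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.subtype_counts.values()):
            raise ValueError("subtype counts must be positive")
        if TARGET_SUBTYPE not in self.subtype_counts or NORMAL not in self.subtype_counts:
            raise ValueError(f"design needs {TARGET_SUBTYPE!r} and {NORMAL!r} groups")
        if not abs(self.immune_hub_corr) < 1:
            raise ValueError("|immune_hub_corr| must be < 1")
        if self.hub_size > self.n_planted_up:
            raise ValueError("hub block must fit inside the planted up-genes")
        if self.n_tf_targets > self.hub_size:
            raise ValueError("TF targets must fit inside the hub block")
        if self.n_reg_mirnas + self.n_other_down_mirnas + self.n_up_mirnas > self.n_mirnas:
            raise ValueError("planted miRNA counts exceed n_mirnas")
        other = [s for s in self.subtype_counts if s not in (TARGET_SUBTYPE, NORMAL)]
        n_needed = (
            self.n_planted_up
            + self.n_planted_down
            + self.n_shared_de
            + self.n_per_subtype_de * len(other)
            + self.stromal_size
            + self.immune_size
            + self.n_til_sets * self.til_set_size
            + self.n_icgs
        )
        if n_needed > self.n_genes:
            raise ValueError(f"planted gene programs need {n_needed} genes, have {self.n_genes}")

    @property
    def n_samples(self) -> int:
        return sum(self.subtype_counts.values())

    @property
    def comparator_subtypes(self) -> list[str]:
        return [s for s in self.subtype_counts if s not in (TARGET_SUBTYPE, NORMAL)]


@dataclass
class PlantedTruth:
    """Ground-truth record of everything the generator planted."""

    up_effects: dict[str, float]
    down_effects: dict[str, float]
    hub_genes: list[str]
    tf: str
    tf_targets: list[str]
    reg_mirnas: list[str]
    mirna_targets: dict[str, list[str]]
    tf_mirna_pairs: list[tuple[str, str]]
    coherent_ffls: list[tuple[str, str, str]]  # (tf, gene, mirna)
    shared_de: dict[str, str]  # gene -> comparator subtype also DE
    per_subtype_de: dict[str, list[str]]
    down_mirnas: list[str]
    up_mirnas: list[str]
    gene_sets: GeneSetCollection  # tf_set / hub_genes / reg_mirnas
    immune_sets: GeneSetCollection  # stromal / immune / TIL_* / ICG
    latents: pd.DataFrame  # per-sample hub / mir / immune factors
    survival_betas: dict[str, float]

    @property
    def exclusive_up(self) -> set[str]:
        return set(self.up_effects)

    @property
    def exclusive_down(self) -> set[str]:
        return set(self.down_effects)


@dataclass
class SyntheticCohort:
    mrna: ExpressionDataset
    mirna: ExpressionDataset
    truth: PlantedTruth
    design: SimulationDesign
    seed: int

    def __post_init__(self) -> None:
        if self.mrna.sample_ids != self.mirna.sample_ids:
            raise ValueError("mRNA and miRNA matrices must share ordered sample ids")


def _gene_id(i: int) -> str:
    return f"G{i + 1:04d}"


def _mirna_id(i: int) -> str:
    return f"miR-{i + 1:03d}"


def generate_cohort(design: SimulationDesign | None = None, seed: int = 0) -> SyntheticCohort:
    """Draw one synthetic cohort. Identical (design, seed) -> identical data."""
    design = design if design is not None else SimulationDesign()
    rng = np.random.default_rng(seed)

    subtypes = np.concatenate(
        [np.repeat(st, n) for st, n in design.subtype_counts.items()]
    )
    n_samples = subtypes.size
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    mtc_mask = (subtypes == TARGET_SUBTYPE).astype(float)

    # latent factors
    latent_hub = rng.standard_normal(n_samples)
    latent_mir = rng.standard_normal(n_samples)
    r = design.immune_hub_corr
    latent_immune = r * latent_hub + np.sqrt(1 - r * r) * rng.standard_normal(n_samples)

    # ---- gene index layout (disjoint blocks) ----
    comparators = design.comparator_subtypes
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    hub_idx = take(design.hub_size)
    other_up_idx = take(design.n_planted_up - design.hub_size)
    down_idx = take(design.n_planted_down)
    tf_idx = int(down_idx[0])
    shared_idx = take(design.n_shared_de)
    per_subtype_idx = {st: take(design.n_per_subtype_de) for st in comparators}
    stromal_idx = take(design.stromal_size)
    immune_idx = take(design.immune_size)
    til_idx = {f"TIL_{k + 1:02d}": take(design.til_set_size) for k in range(design.n_til_sets)}
    icg_idx = take(design.n_icgs)

    gene_ids = [_gene_id(i) for i in range(design.n_genes)]

    # ---- mRNA matrix ----
    base = rng.normal(design.baseline_mean, design.baseline_sd, design.n_genes)
    X = base[:, None] + rng.normal(0.0, design.noise_sd, (design.n_genes, n_samples))

    hub_effects = rng.uniform(design.hub_effect_low, design.hub_effect_high, design.hub_size)
    other_up_effects = rng.uniform(design.effect_low, design.effect_high, other_up_idx.size)
    down_effects = rng.uniform(design.effect_low, design.effect_high, design.n_planted_down)
    down_effects[0] = design.tf_effect  # the TF is the first planted down-gene

    X[hub_idx] += np.outer(hub_effects, mtc_mask) + design.hub_loading * latent_hub
    X[other_up_idx] += np.outer(other_up_effects, mtc_mask)
    X[down_idx] -= np.outer(down_effects, mtc_mask)
    X[tf_idx] += -design.tf_hub_loading * latent_hub + design.tf_mir_loading * latent_mir

    shared_effects = rng.uniform(design.effect_low, design.effect_high, design.n_shared_de)
    shared_signs = rng.choice([-1.0, 1.0], design.n_shared_de)
    shared_map: dict[str, str] = {}
    for j, gi in enumerate(shared_idx):
        comp = comparators[j % len(comparators)]
        both = mtc_mask + (subtypes == comp).astype(float)
        X[gi] += shared_signs[j] * shared_effects[j] * both
        shared_map[gene_ids[gi]] = comp

    per_subtype_map: dict[str, list[str]] = {}
    for st, idx in per_subtype_idx.items():
        eff = rng.uniform(design.effect_low, design.effect_high, idx.size)
        sign = rng.choice([-1.0, 1.0], idx.size)
        X[idx] += np.outer(sign * eff, (subtypes == st).astype(float))
        per_subtype_map[st] = [gene_ids[i] for i in idx]

    X[stromal_idx] += design.stromal_loading * latent_immune
    X[immune_idx] += design.immune_loading * latent_immune
    for idx in til_idx.values():
        X[idx] += design.til_loading * latent_immune
    X[icg_idx] += design.icg_loading * latent_immune

    # ---- miRNA matrix ----
    mirna_ids = [_mirna_id(i) for i in range(design.n_mirnas)]
    mbase = rng.normal(design.baseline_mean, design.baseline_sd, design.n_mirnas)
    M = mbase[:, None] + rng.normal(0.0, design.noise_sd, (design.n_mirnas, n_samples))

    reg_idx = np.arange(design.n_reg_mirnas)
    other_down_idx = np.arange(design.n_reg_mirnas, design.n_reg_mirnas + design.n_other_down_mirnas)
    n_down_total = design.n_reg_mirnas + design.n_other_down_mirnas
    up_idx = np.arange(n_down_total, n_down_total + design.n_up_mirnas)

    reg_down = rng.uniform(design.mirna_down_low, design.mirna_down_high, design.n_reg_mirnas)
    M[reg_idx] += (
        -np.outer(reg_down, mtc_mask)
        - design.mirna_hub_loading * latent_hub
        + design.mirna_mir_loading * latent_mir
    )
    M[other_down_idx] -= np.outer(
        rng.uniform(design.mirna_bg_low, design.mirna_bg_high, other_down_idx.size), mtc_mask
    )
    M[up_idx] += np.outer(
        rng.uniform(design.mirna_bg_low, design.mirna_bg_high, up_idx.size), mtc_mask
    )

    # ---- regulatory truth ----
    tf = gene_ids[tf_idx]
    hub_genes = [gene_ids[i] for i in hub_idx]
    tf_targets = hub_genes[: design.n_tf_targets]
    reg_mirnas = [mirna_ids[i] for i in reg_idx]
    mirna_targets: dict[str, list[str]] = {}
    for i, m in enumerate(reg_mirnas):
        tg = [tf_targets[i % design.n_tf_targets]]
        if i % 2 == 0 and design.n_tf_targets > 1:
            second = tf_targets[(i + 4) % design.n_tf_targets]
            if second not in tg:
                tg.append(second)
        mirna_targets[m] = tg
    tf_mirna_pairs = [(tf, m) for m in reg_mirnas]
    ffls = [(tf, g, m) for m in reg_mirnas for g in mirna_targets[m]]

    # ---- survival ----
    hub_proxy = latent_hub
    mir_proxy = (latent_mir - latent_hub) / np.sqrt(2.0)
    log_hazard = design.beta_hub * hub_proxy + design.beta_mirna * mir_proxy
    lam = design.baseline_hazard * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, design.censor_max_months, n_samples)
    time = np.maximum(np.minimum(t_event, t_censor), 0.25)
    event = (t_event <= t_censor).astype(int)

    annotations = pd.DataFrame(
        {
            "subtype": subtypes,
            "batch": "b1",
            "time": np.round(time, 1),
            "event": event,
            "mutation": ((subtypes == TARGET_SUBTYPE) & (rng.random(n_samples) < 0.3)).astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    mrna = ExpressionDataset(
        pd.DataFrame(X, index=pd.Index(gene_ids, name="feature_id"), columns=sample_ids),
        annotations,
    )
    mirna = ExpressionDataset(
        pd.DataFrame(M, index=pd.Index(mirna_ids, name="feature_id"), columns=sample_ids),
        annotations.copy(),
    )

    up_effects = {gene_ids[i]: float(e) for i, e in zip(hub_idx, hub_effects)}
    up_effects.update({gene_ids[i]: float(e) for i, e in zip(other_up_idx, other_up_effects)})
    down_map = {gene_ids[i]: float(e) for i, e in zip(down_idx, down_effects)}

    gene_sets = GeneSetCollection(
        {
            "tf_set": {tf},
            "hub_genes": set(hub_genes),
            "reg_mirnas": set(reg_mirnas),
        },
        {
            "tf_set": "planted repressor transcription factor",
            "hub_genes": "planted co-expressed hub block",
            "reg_mirnas": "planted regulator miRNAs",
        },
    )
    immune_sets_dict: dict[str, set[str]] = {
        "stromal": {gene_ids[i] for i in stromal_idx},
        "immune": {gene_ids[i] for i in immune_idx},
        "ICG": {gene_ids[i] for i in icg_idx},
    }
    for name, idx in til_idx.items():
        immune_sets_dict[name] = {gene_ids[i] for i in idx}
    immune_sets = GeneSetCollection(immune_sets_dict)

    truth = PlantedTruth(
        up_effects=up_effects,
        down_effects=down_map,
        hub_genes=hub_genes,
        tf=tf,
        tf_targets=tf_targets,
        reg_mirnas=reg_mirnas,
        mirna_targets=mirna_targets,
        tf_mirna_pairs=tf_mirna_pairs,
        coherent_ffls=ffls,
        shared_de=shared_map,
        per_subtype_de=per_subtype_map,
        down_mirnas=[mirna_ids[i] for i in np.concatenate([reg_idx, other_down_idx])],
        up_mirnas=[mirna_ids[i] for i in up_idx],
        gene_sets=gene_sets,
        immune_sets=immune_sets,
        latents=pd.DataFrame(
            {"hub": latent_hub, "mir": latent_mir, "immune": latent_immune},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        survival_betas={"hub": design.beta_hub, "mirna": design.beta_mirna},
    )
    return SyntheticCohort(mrna=mrna, mirna=mirna, truth=truth, design=design, seed=seed)


def export_priors(
    cohort: SyntheticCohort, decoy_fraction: float = 1.0, seed: int | None = None
) -> tuple[list[TFPrior], list[MiRNAPrior]]:
    """Emulated prediction-tool outputs for the regulatory-network stage.

    True TF->target pairs carry NES drawn uniform in [5.5, 9] and true
    miRNA->target pairs a supporting-tool count in {2..6}; decoy
    (non-regulating) pairs are added at ``decoy_fraction`` times the true
    count with NES in [2, 5] and a single supporting tool, so the study's
    NES > 5.0 and >= 2-tool filters separate true from decoy exactly.
    """
    if not 0 <= decoy_fraction <= 5:
        raise ValueError("decoy_fraction must lie in [0, 5]")
    rng = np.random.default_rng(cohort.seed + 104729 if seed is None else seed)
    truth = cohort.truth
    genes = cohort.mrna.feature_ids
    mirnas = cohort.mirna.feature_ids

    tf_pairs = [
        TFPrior(truth.tf, g, float(rng.uniform(5.5, 9.0))) for g in truth.tf_targets
    ]
    mirna_pairs = [
        MiRNAPrior(m, g, int(rng.integers(2, 7)))
        for m in truth.reg_mirnas
        for g in truth.mirna_targets[m]
    ]

    n_tf_decoys = round(decoy_fraction * len(tf_pairs))
    n_mir_decoys = round(decoy_fraction * len(mirna_pairs))
    true_tf = {(p.tf, p.target) for p in tf_pairs}
    true_mir = {(p.mirna, p.target) for p in mirna_pairs}

    while n_tf_decoys > 0:
        g = genes[int(rng.integers(len(genes)))]
        if (truth.tf, g) in true_tf or g == truth.tf:
            continue
        tf_pairs.append(TFPrior(truth.tf, g, float(rng.uniform(2.0, 5.0))))
        true_tf.add((truth.tf, g))
        n_tf_decoys -= 1
    while n_mir_decoys > 0:
        m = mirnas[int(rng.integers(len(mirnas)))]
        g = truth.hub_genes[int(rng.integers(len(truth.hub_genes)))]
        if (m, g) in true_mir:
            continue
        mirna_pairs.append(MiRNAPrior(m, g, 1))
        true_mir.add((m, g))
        n_mir_decoys -= 1
    return tf_pairs, mirna_pairs


def export_ppi(
    cohort: SyntheticCohort,
    hub_edge_prob: float = 0.95,
    background_edge_prob: float = 0.03,
    seed: int | None = None,
) -> list[PPIEdge]:
    """Confidence-scored PPI edge list over the planted exclusive DEGs.

    The hub block is wired near-completely with high confidences; the other
    exclusive DEGs receive sparse background edges whose scores straddle
    the 0.4 confidence threshold.
    """
    rng = np.random.default_rng(cohort.seed + 15485863 if seed is None else seed)
    truth = cohort.truth
    hub = truth.hub_genes
    others = sorted((truth.exclusive_up | truth.exclusive_down) - set(hub))
    edges: list[PPIEdge] = []
    for i in range(len(hub)):
        for j in range(i + 1, len(hub)):
            if rng.random() < hub_edge_prob:
                edges.append(PPIEdge(hub[i], hub[j], float(rng.uniform(0.6, 0.95))))
    pool = hub + others
    hub_set = set(hub)
    seen: set[tuple[str, str]] = set()
    for a in others:
        for b in pool:
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            # keep attachments of background nodes to the hub block rare
            p = background_edge_prob * (0.3 if b in hub_set else 1.0)
            if rng.random() < p:
                seen.add(key)
                edges.append(PPIEdge(key[0], key[1], float(rng.uniform(0.2, 0.9))))
    return edges


def write_cohort(cohort: SyntheticCohort, outdir, decoy_fraction: float = 1.0) -> None:
    """Write every input the pipeline consumes, plus a truth/ directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.mrna, out / "mrna.tsv", out / "samples.tsv")
    cohort.mirna.values.to_csv(out / "mirna.tsv", sep="\t", index_label="feature_id")
    write_gmt(cohort.truth.gene_sets, out / "signature_sets.gmt")
    write_gmt(cohort.truth.immune_sets, out / "immune_sets.gmt")
    tf_pairs, mirna_pairs = export_priors(cohort, decoy_fraction=decoy_fraction)
    write_edge_list(tf_pairs, out / "tf_prior.tsv", "tf_prior")
    write_edge_list(mirna_pairs, out / "mirna_prior.tsv", "mirna_prior")
    write_edge_list(export_ppi(cohort), out / "ppi.tsv", "ppi")

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    truth = cohort.truth
    pd.DataFrame(
        {
            "gene": list(truth.up_effects) + list(truth.down_effects),
            "direction": ["up"] * len(truth.up_effects) + ["down"] * len(truth.down_effects),
            "effect": list(truth.up_effects.values()) + list(truth.down_effects.values()),
        }
    ).to_csv(tdir / "exclusive_degs.tsv", sep="\t", index=False)
    rows = [("tf_mrna", truth.tf, g, -1) for g in truth.tf_targets]
    rows += [("mirna_mrna", m, g, -1) for m, tgs in truth.mirna_targets.items() for g in tgs]
    rows += [("tf_mirna", t, m, 1) for t, m in truth.tf_mirna_pairs]
    pd.DataFrame(rows, columns=["layer", "source", "target", "sign"]).to_csv(
        tdir / "regulatory_edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth.coherent_ffls, columns=["tf", "gene", "mirna"]).to_csv(
        tdir / "coherent_ffls.tsv", sep="\t", index=False
    )
    truth.latents.to_csv(tdir / "latents.tsv", sep="\t")


def simulate_exponential_survival(
    beta: float, n: int, baseline_hazard: float = 0.05,
    censor_max: float = 60.0, seed: int = 0,
) -> pd.DataFrame:
    """Single-covariate exponential survival draw for parameter recovery.

    Hazard = baseline * exp(beta * z) with z ~ N(0,1); censoring uniform on
    (0, censor_max]. Returns columns z / time / event.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    lam = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, censor_max, n)
    return pd.DataFrame(
        {
            "z": z,
            "time": np.maximum(np.minimum(t_event, t_censor), 1e-3),
            "event": (t_event <= t_censor).astype(int),
        }
    )
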