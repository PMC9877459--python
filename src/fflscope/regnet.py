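"""TF-mRNA-miRNA network assembly, correlation validation and FFL calling.

Candidate TF->gene pairs (with normalized enrichment scores) and
miRNA->gene pairs (with supporting-tool counts) pass hard prediction
filters (NES strictly > 5.0; >= 2 tools plus membership in the
down-regulated miRNA list), then each surviving pair is validated by
Spearman correlation on expression: miRNA->gene edges must correlate
negatively, TF->miRNA edges positively, and TF->gene edges must be
significant with either sign (the sign is recorded and drives feed-forward
loop coherence). A loop (TF, gene, miRNA) with all three validated edges is
coherent when sign(TF->gene) = sign(TF->miRNA) x sign(miRNA->gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from fflscope.io import ExpressionDataset, MiRNAPrior, TFPrior
from fflscope.stats_core import significance_tier, spearman_correlation

logger = logging.getLogger("fflscope")

TF_MRNA = "tf_mrna"
MIRNA_MRNA = "mirna_mrna"
TF_MIRNA = "tf_mirna"


@dataclass(frozen=True)
class ValidatedEdge:
    source: str
    target: str
    layer: str
    rho: float
    p_value: float
    sign: int
    tier: str


@dataclass
class RegulatoryNetwork:
    """Tri-partite directed network with per-layer edge lists."""

    tf_edges: list[ValidatedEdge]
    mirna_edges: list[ValidatedEdge]
    tfmir_edges: list[ValidatedEdge]

    @property
    def tfs(self) -> set[str]:
        return {e.source for e in self.tf_edges} | {e.source for e in self.tfmir_edges}

    @property
    def genes(self) -> set[str]:
        return {e.target for e in self.tf_edges} | {e.target for e in self.mirna_edges}

    @property
    def mirnas(self) -> set[str]:
        return {e.source for e in self.mirna_edges} | {e.target for e in self.tfmir_edges}

    def linear_genes(self) -> set[str]:
        """Genes on a complete TF-gene-miRNA chain."""
        return {e.target for e in self.tf_edges} & {e.target for e in self.mirna_edges}

    def chains(self) -> list[tuple[str, str, str]]:
        """All (tf, gene, mirna) chains through a shared target gene."""
        by_gene_tf: dict[str, list[str]] = {}
        for e in self.tf_edges:
            by_gene_tf.setdefault(e.target, []).append(e.source)
        out = []
        for e in self.mirna_edges:
            for tf in by_gene_tf.get(e.target, []):
                out.append((tf, e.target, e.source))
        return sorted(out)


@dataclass(frozen=True)
class FFLTriple:
    tf: str
    gene: str
    mirna: str
    s_tg: int
    s_tm: int
    s_mg: int

    @property
    def classification(self) -> str:
        return "coherent" if self.s_tg == self.s_tm * self.s_mg else "incoherent"


def filter_tf_candidates(
    pairs: list[TFPrior], nes_min: float = 5.0, allowed_targets: set[str] | None = None
) -> list[TFPrior]:
    """Keep pairs with NES strictly above ``nes_min`` and an allowed target."""
    out = [
        p
        for p in pairs
        if p.nes > nes_min and (allowed_targets is None or p.target in allowed_targets)
    ]
    logger.info("TF-prior filter: %d of %d pairs kept (NES > %g)", len(out), len(pairs), nes_min)
    return out


def filter_mirna_candidates(
    pairs: list[MiRNAPrior],
    min_tools: int = 2,
    de_down_mirnas: set[str] | None = None,
    allowed_targets: set[str] | None = None,
) -> list[MiRNAPrior]:
    """Keep pairs supported by >= ``min_tools`` tools whose miRNA is
    down-regulated and whose target is allowed."""
    out = [
        p
        for p in pairs
        if p.tool_count >= min_tools
        and (de_down_mirnas is None or p.mirna in de_down_mirnas)
        and (allowed_targets is None or p.target in allowed_targets)
    ]
    logger.info("miRNA-prior filter: %d of %d pairs kept (>= %d tools, DE-down)",
                len(out), len(pairs), min_tools)
    return out


def _expression_of(feature: str, mrna: ExpressionDataset, mirna: ExpressionDataset | None):
    if feature in mrna.values.index:
        return mrna.values.loc[feature]
    if mirna is not None and feature in mirna.values.index:
        return mirna.values.loc[feature]
    return None


def validate_edges(
    pairs: list[tuple[str, str]],
    mrna: ExpressionDataset,
    mirna: ExpressionDataset | None,
    layer: str,
    alpha: float = 0.05,
    samples: list[str] | None = None,
) -> list[ValidatedEdge]:
    """Correlation-validate candidate (source, target) pairs on one layer.

    Retention rules: ``mirna_mrna`` keeps rho < 0 with p < alpha;
    ``tf_mirna`` keeps rho > 0 with p < alpha; ``tf_mrna`` keeps p < alpha
    with either sign. Pairs with a member absent from both matrices are
    logged and skipped. ``samples`` restricts the correlation to a subset
    (e.g. tumor samples only).
    """
    if layer not in (TF_MRNA, MIRNA_MRNA, TF_MIRNA):
        raise ValueError(f"unknown layer {layer!r}")
    cols = samples if samples is not None else mrna.sample_ids
    out: list[ValidatedEdge] = []
    n_skipped = 0
    for source, target in pairs:
        xs = _expression_of(source, mrna, mirna)
        ys = _expression_of(target, mrna, mirna)
        if xs is None or ys is None:
            n_skipped += 1
            continue
        res = spearman_correlation(xs[cols], ys[cols])
        sign = 1 if res.rho > 0 else -1
        keep = res.p_value < alpha
        if layer == MIRNA_MRNA:
            keep = keep and res.rho < 0
        elif layer == TF_MIRNA:
            keep = keep and res.rho > 0
        if keep:
            out.append(
                ValidatedEdge(source, target, layer, res.rho, res.p_value,
                              sign, significance_tier(res.p_value))
            )
    if n_skipped:
        logger.warning("%s validation: skipped %d pairs with absent members", layer, n_skipped)
    return out


def assemble_network(
    tf_edges: list[ValidatedEdge],
    mirna_edges: list[ValidatedEdge],
    tfmir_edges: list[ValidatedEdge],
) -> RegulatoryNetwork:
    return RegulatoryNetwork(tf_edges=list(tf_edges), mirna_edges=list(mirna_edges),
                             tfmir_edges=list(tfmir_edges))


def find_ffls(network: RegulatoryNetwork) -> list[FFLTriple]:
    """Emit every (tf, gene, mirna) whose three edges are all validated."""
    tg = {(e.source, e.target): e.sign for e in network.tf_edges}
    mg = {(e.source, e.target): e.sign for e in network.mirna_edges}
    tm = {(e.source, e.target): e.sign for e in network.tfmir_edges}
    triples: list[FFLTriple] = []
    for (tf, gene), s_tg in sorted(tg.items()):
        for (mirna, gene2), s_mg in sorted(mg.items()):
            if gene2 != gene:
                continue
            s_tm = tm.get((tf, mirna))
            if s_tm is None:
                continue
            triples.append(FFLTriple(tf, gene, mirna, s_tg, s_tm, s_mg))
    return triples


def edges_to_frame(edges: list[ValidatedEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"source": e.source, "target": e.target, "layer": e.layer,
             "rho": e.rho, "p_value": e.p_value, "sign": e.sign, "tier": e.tier}
            for e in edges
        ]
    )


def ffls_to_frame(triples: list[FFLTriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tf": t.tf, "gene": t.gene, "mirna": t.mirna, "s_tg": t.s_tg,
             "s_tm": t.s_tm, "s_mg": t.s_mg, "classification": t.classification}
            for t in triples
        ]
    )
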