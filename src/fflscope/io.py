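"""Readers and writers for the pipeline's on-disk formats.

Canonical interchange is tab-separated text: expression matrices (features
in rows, samples in columns), per-sample annotation tables, GMT gene-set
collections, and typed edge lists (weighted PPI, TF->target priors with
enrichment scores, miRNA->target priors with supporting-tool counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

logger = logging.getLogger("fflscope")

#: annotation column names recognised throughout the pipeline
SUBTYPE_COL = "subtype"
BATCH_COL = "batch"
TIME_COL = "time"
EVENT_COL = "event"
MUTATION_COL = "mutation"


@dataclass
class ExpressionDataset:
    """A log2-scale feature x sample matrix with per-sample annotations.

    ``values`` is a pandas DataFrame indexed by unique feature ids with
    unique sample-id columns; ``annotations`` is indexed by the same sample
    ids in the same order. Survival time (months) must be accompanied by an
    event flag and vice versa.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if list(self.annotations.index) != list(self.values.columns):
            raise ValueError("annotation rows do not match sample ids")
        has_time = TIME_COL in self.annotations.columns
        has_event = EVENT_COL in self.annotations.columns
        if has_time != has_event:
            raise ValueError("survival time and event flag must be present together")
        if has_time:
            t = self.annotations[TIME_COL].astype(float)
            if (t <= 0).any():
                raise ValueError("survival times must be positive")
            ev = set(self.annotations[EVENT_COL].astype(int).unique())
            if not ev <= {0, 1}:
                raise ValueError("event flag must be binary")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subtypes(self) -> pd.Series:
        return self.annotations[SUBTYPE_COL]

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(self.values[ids], self.annotations.loc[ids])

    def samples_of(self, *subtypes: str) -> list[str]:
        mask = self.annotations[SUBTYPE_COL].isin(subtypes)
        return list(self.annotations.index[mask])


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of feature identifiers (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_expression(
    path,
    annotation_path,
    log2_transform: bool = False,
    max_missing_fraction: float = 0.2,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus its annotation table.

    First column carries feature ids, the header row sample ids. Duplicate
    feature rows are collapsed to the one with the highest mean expression
    (common microarray probe-collapse convention; the count is logged).
    Features missing in more than ``max_missing_fraction`` of samples are
    dropped. ``log2_transform`` applies log2(x+1) for raw-scale input.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc

    if values.index.duplicated().any():
        n_before = values.shape[0]
        means = values.mean(axis=1).to_numpy()
        by_mean = values.iloc[np.argsort(-means, kind="stable")]
        dedup = by_mean[~by_mean.index.duplicated(keep="first")]
        values = dedup.loc[values.index.drop_duplicates()]
        logger.warning("collapsed %d duplicate feature rows (kept highest mean)", n_before - values.shape[0])

    missing_frac = values.isna().mean(axis=1)
    dropped = int((missing_frac > max_missing_fraction).sum())
    if dropped:
        logger.warning("dropped %d features with > %.0f%% missing values", dropped, 100 * max_missing_fraction)
        values = values[missing_frac <= max_missing_fraction]

    if log2_transform:
        values = np.log2(values + 1.0)

    annotations = pd.read_csv(annotation_path, sep="\t", index_col=0)
    annotations.index = annotations.index.astype(str)
    missing = set(values.columns) - set(annotations.index)
    if missing:
        raise ValueError(f"annotation missing sample ids: {sorted(missing)[:5]}")
    annotations = annotations.loc[list(values.columns)]
    return ExpressionDataset(values, annotations)


def write_expression(dataset: ExpressionDataset, path, annotation_path) -> None:
    dataset.values.to_csv(path, sep="\t", index_label="feature_id")
    dataset.annotations.to_csv(annotation_path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then members, tab-separated."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass(frozen=True)
class PPIEdge:
    node_a: str
    node_b: str
    score: float


@dataclass(frozen=True)
class TFPrior:
    tf: str
    target: str
    nes: float


@dataclass(frozen=True)
class MiRNAPrior:
    mirna: str
    target: str
    tool_count: int


def read_edge_list(path, kind: str):
    """Read a typed, tab-separated edge list.

    ``kind`` selects validation: ``ppi`` rows carry (node, node, score in
    [0,1]) — self-edges are dropped (logged) and duplicate undirected
    pairs keep the maximum score; ``tf_prior`` rows carry (TF, target,
    NES >= 0); ``mirna_prior`` rows carry (miRNA, target, positive integer
    tool count).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: edge list needs 3 columns")
    a, b, w = (df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str), df.iloc[:, 2])

    if kind == "ppi":
        scores = w.astype(float)
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("PPI score out of [0, 1]")
        best: dict[tuple[str, str], float] = {}
        n_self = 0
        for u, v, s in zip(a, b, scores):
            if u == v:
                n_self += 1
                continue
            key = (u, v) if u <= v else (v, u)
            best[key] = max(best.get(key, 0.0), float(s))
        if n_self:
            logger.warning("dropped %d PPI self-edges", n_self)
        return [PPIEdge(u, v, s) for (u, v), s in best.items()]

    if kind == "tf_prior":
        nes = w.astype(float)
        if (nes < 0).any():
            raise ValueError("NES must be non-negative")
        return [TFPrior(t, g, float(s)) for t, g, s in zip(a, b, nes)]

    if kind == "mirna_prior":
        counts = w.astype(float)
        if not np.allclose(counts, counts.round()) or (counts < 1).any():
            raise ValueError("tool count must be a positive integer")
        return [MiRNAPrior(m, g, int(c)) for m, g, c in zip(a, b, counts)]

    raise ValueError(f"unknown edge-list kind {kind!r}")


def write_edge_list(records, path, kind: str) -> None:
    header = {
        "ppi": "node_a\tnode_b\tscore",
        "tf_prior": "tf\ttarget\tnes",
        "mirna_prior": "mirna\ttarget\ttool_count",
    }[kind]
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for r in records:
            if kind == "ppi":
                fh.write(f"{r.node_a}\t{r.node_b}\t{r.score:g}\n")
            elif kind == "tf_prior":
                fh.write(f"{r.tf}\t{r.target}\t{r.nes:g}\n")
            else:
                fh.write(f"{r.mirna}\t{r.target}\t{r.tool_count}\n")
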