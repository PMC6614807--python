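"""Canonical data containers: count/log matrices, replicate designs, control masks.

All downstream computation operates on samples x probes matrices.  Counts
are held as non-negative reals (they arrive as integers from RCC files but
background correction and scaling produce fractional values), expression is
always on the log2 scale.  The replicate design matrix ``M`` is the m x m'
indicator mapping each assay to its underlying biological sample; ``m - m'``
is the number of technical replicates and bounds the dimension of unwanted
variation that replicate residuals can reveal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODE_CLASSES = ("Endogenous", "Housekeeping", "Negative", "Positive")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicated {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ProbeAnnotation:
    """Probe names with their nCounter code class.

    ``Endogenous`` probes carry the biology of interest, ``Housekeeping``
    probes are the panel's reference genes, ``Negative``/``Positive`` are the
    spiked-in no-target and concentration-ladder control probes.
    """

    probe_names: list[str]
    code_classes: list[str]

    def __post_init__(self) -> None:
        if len(self.probe_names) != len(self.code_classes):
            raise ValueError("probe_names and code_classes lengths differ")
        _check_unique(self.probe_names, "probe")
        for c in self.code_classes:
            if c not in CODE_CLASSES:
                raise ValueError(f"unknown code class {c!r}")

    def mask(self, code_class: str) -> np.ndarray:
        """Boolean mask over probes for one code class."""
        return np.array([c == code_class for c in self.code_classes], dtype=bool)

    @property
    def endogenous(self) -> np.ndarray:
        return self.mask("Endogenous")

    @property
    def housekeeping(self) -> np.ndarray:
        return self.mask("Housekeeping")

    @property
    def negative(self) -> np.ndarray:
        return self.mask("Negative")

    @property
    def positive(self) -> np.ndarray:
        return self.mask("Positive")

    def subset(self, keep: np.ndarray) -> "ProbeAnnotation":
        keep = np.asarray(keep, dtype=bool)
        return ProbeAnnotation(
            [p for p, k in zip(self.probe_names, keep) if k],
            [c for c, k in zip(self.code_classes, keep) if k],
        )


@dataclass
class CountMatrix:
    """Samples x probes matrix of (possibly background-corrected) counts."""

    values: np.ndarray
    sample_ids: list[str]
    probe_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (samples x probes)")
        m, n = self.values.shape
        if m != len(self.sample_ids) or n != len(self.probe_names):
            raise ValueError("values shape does not match identifier lists")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.probe_names, "probe")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_names)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), list(self.sample_ids), list(self.probe_names))


@dataclass
class LogExpressionMatrix:
    """Samples x probes expression on the log2 scale."""

    values: np.ndarray
    sample_ids: list[str]
    probe_names: list[str]
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (samples x probes)")
        m, n = self.values.shape
        if m != len(self.sample_ids) or n != len(self.probe_names):
            raise ValueError("values shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log expression must be finite everywhere")
        if self.log_offset < 0:
            raise ValueError("log_offset must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_names)


@dataclass
class ReplicateDesign:
    """Assay -> biological-sample indicator matrix M (m x m').

    Each row of M has exactly one 1; columns are biological samples in order
    of first appearance.  ``m - m_prime`` technical replicates feed the
    residual step of RUV-III.
    """

    M: np.ndarray
    sample_ids: list[str]
    biological_ids: list[str]
    pseudo_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != len(self.sample_ids):
            raise ValueError("M shape inconsistent with sample_ids")
        if not np.all((self.M == 0) | (self.M == 1)):
            raise ValueError("M must be binary")
        if not np.all(self.M.sum(axis=1) == 1):
            raise ValueError("each row of M must have exactly one 1")
        if np.any(self.M.sum(axis=0) < 1):
            raise ValueError("each column of M must have at least one 1")

    @property
    def m(self) -> int:
        return self.M.shape[0]

    @property
    def m_prime(self) -> int:
        return self.M.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.m - self.m_prime

    def groups(self) -> list[list[int]]:
        """Sample indices per replicate group, in column order."""
        return [list(np.flatnonzero(self.M[:, j])) for j in range(self.m_prime)]

    def replicate_pairs(self) -> list[tuple[int, int]]:
        """All within-group index pairs; groups of size g give g*(g-1)/2 pairs.

        The canonical member order is sample (run) order, so pair signs are
        deterministic.
        """
        pairs = []
        for grp in self.groups():
            for a in range(len(grp)):
                for b in range(a + 1, len(grp)):
                    pairs.append((grp[a], grp[b]))
        return pairs


@dataclass
class ControlMask:
    """Boolean negative-control-gene mask over probes (the ``ctl`` of RUV-III)."""

    ctl: np.ndarray
    source: str = "named_list"  # all_genes | lowest_variance | named_list | hk_class

    def __post_init__(self) -> None:
        self.ctl = np.asarray(self.ctl, dtype=bool)
        if self.ctl.ndim != 1:
            raise ValueError("ctl must be a 1-d boolean vector")

    @property
    def n_controls(self) -> int:
        return int(self.ctl.sum())


@dataclass
class SampleAnnotation:
    """Per-sample metadata: batch (cartridge/CodeSet/era), biology, run order."""

    sample_ids: list[str]
    batch: list[str]
    biology: list[str]
    run_order: list[int]

    def __post_init__(self) -> None:
        m = len(self.sample_ids)
        if not (len(self.batch) == len(self.biology) == len(self.run_order) == m):
            raise ValueError("annotation column lengths differ")
        _check_unique(self.sample_ids, "sample")

    @classmethod
    def read_csv(cls, path) -> "SampleAnnotation":
        df = pd.read_csv(path, dtype={"sample_id": str, "batch": str, "biology": str})
        return cls(
            list(df["sample_id"]),
            list(df["batch"]),
            list(df["biology"]),
            [int(x) for x in df["run_order"]],
        )

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "batch": self.batch,
                "biology": self.biology,
                "run_order": self.run_order,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations


def log_transform(
    counts: CountMatrix, offset: float = 1.0, floor: float | None = None
) -> LogExpressionMatrix:
    """log2(max(count, floor) + offset), elementwise.

    With ``offset > 0`` no floor is needed (default floor 0); with
    ``offset == 0`` counts are floored at 1 so zeros map to 0 rather than
    -inf.  Passing ``floor=0`` together with ``offset=0`` is an error when
    zero counts are present.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if floor is None:
        floor = 0.0 if offset > 0 else 1.0
    v = np.maximum(counts.values, floor) + offset
    if np.any(v <= 0):
        raise ValueError(
            "zero counts with offset=0 and floor disabled would produce -inf; "
            "use a positive offset or floor"
        )
    return LogExpressionMatrix(
        np.log2(v), list(counts.sample_ids), list(counts.probe_names), log_offset=offset
    )


def make_replicate_design(sample_ids, biological_ids) -> ReplicateDesign:
    """Build the m x m' indicator M from per-assay biological-sample labels.

    Columns are ordered by first appearance of each biological id.
    """
    sample_ids = list(sample_ids)
    biological_ids = [str(b) for b in biological_ids]
    if len(sample_ids) != len(biological_ids):
        raise ValueError("sample_ids and biological_ids lengths differ")
    order: dict[str, int] = {}
    for b in biological_ids:
        if b not in order:
            order[b] = len(order)
    M = np.zeros((len(sample_ids), len(order)))
    for i, b in enumerate(biological_ids):
        M[i, order[b]] = 1.0
    return ReplicateDesign(M, sample_ids, biological_ids)


def add_pseudo_replicates(
    design: ReplicateDesign, pairs: list[tuple[str, str]]
) -> ReplicateDesign:
    """Merge the biological groups of each declared pseudo-replicate pair.

    Pseudo-replicates are distinct biological samples deliberately declared
    replicates because their between-batch technical difference is believed
    to dominate their biological difference.  Merges are transitive; a pair
    already sharing a group is a warning no-op, so the operation is
    idempotent.
    """
    idx = {s: i for i, s in enumerate(design.sample_ids)}
    bio = list(design.biological_ids)
    # union-find over current biological labels
    parent = {b: b for b in bio}

    def find(b):
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        return b

    for a, b in pairs:
        if a not in idx or b not in idx:
            missing = a if a not in idx else b
            raise ValueError(f"pseudo-replicate pair names unknown sample {missing!r}")
        ga, gb = find(bio[idx[a]]), find(bio[idx[b]])
        if ga == gb:
            warnings.warn(
                f"pseudo-replicate pair ({a}, {b}) already within one replicate "
                "group; ignored"
            )
            continue
        parent[gb] = ga
    merged_bio = [find(b) for b in bio]
    new = make_replicate_design(design.sample_ids, merged_bio)
    new.pseudo_pairs = list(design.pseudo_pairs) + [tuple(p) for p in pairs]
    return new


def select_lowest_variance_controls(
    Y: LogExpressionMatrix,
    n_controls: int,
    exclude: list[str] | None = None,
    reference: LogExpressionMatrix | None = None,
) -> ControlMask:
    """Mask the ``n_controls`` probes with smallest sample variance of log expression.

    Variance is the unbiased per-probe sample variance; ties are broken by
    column order.  When ``reference`` is given (e.g. a matched microarray
    matrix sharing probe names), variance is computed there instead, and
    probes absent from the reference are never selected.
    """
    exclude = set(exclude or [])
    n = Y.n_probes
    if not 1 <= n_controls <= n:
        raise ValueError(f"n_controls must be in 1..{n}")
    if reference is None:
        var = Y.values.var(axis=0, ddof=1)
    else:
        ref = reference.to_frame()
        var = np.full(n, np.inf)
        for j, name in enumerate(Y.probe_names):
            if name in ref.columns:
                var[j] = ref[name].to_numpy().var(ddof=1)
    eligible = np.array(
        [name not in exclude and np.isfinite(var[j]) for j, name in enumerate(Y.probe_names)]
    )
    if n_controls > int(eligible.sum()):
        raise ValueError(
            f"n_controls={n_controls} exceeds the {int(eligible.sum())} probes "
            "available after exclusion"
        )
    var = np.where(eligible, var, np.inf)
    chosen = np.argsort(var, kind="stable")[:n_controls]
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    source = "all_genes" if n_controls == n and not exclude else "lowest_variance"
    return ControlMask(mask, source=source)


def hk_controls(annotation: ProbeAnnotation) -> ControlMask:
    """Control mask = the Housekeeping-class probes."""
    mask = annotation.housekeeping
    if not mask.any():
        raise ValueError(
            "no Housekeeping probes in annotation; consider "
            "select_lowest_variance_controls as a fallback"
        )
    return ControlMask(mask, source="hk_class")


@dataclass
class ConnectivityReport:
    """How replicate groups connect batches.

    Batches are graph nodes; an edge joins every batch pair that shares a
    replicate group.  Unwanted variation between two batches can be removed
    via replicate differences only if the batches sit in the same connected
    component; chain length measures how indirectly.
    """

    components: list[set[str]]
    chain_lengths: dict[tuple[str, str], float]  # inf when disconnected
    disconnected_pairs: list[tuple[str, str]]
    graph: nx.Graph

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def fully_connected(self) -> bool:
        return len(self.components) <= 1


def replicate_connectivity(design: ReplicateDesign, batch) -> ConnectivityReport:
    """Report which batches are connected by chains of replicate pairs."""
    batch = [str(b) for b in batch]
    if len(batch) != design.m:
        raise ValueError("batch labels length differs from sample count")
    g = nx.Graph()
    g.add_nodes_from(sorted(set(batch)))
    for grp in design.groups():
        batches_in_group = sorted({batch[i] for i in grp})
        for a in range(len(batches_in_group)):
            for b in range(a + 1, len(batches_in_group)):
                g.add_edge(batches_in_group[a], batches_in_group[b])
    components = [set(c) for c in nx.connected_components(g)]
    nodes = sorted(g.nodes)
    chain: dict[tuple[str, str], float] = {}
    disconnected = []
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            d = lengths.get(a, {}).get(b)
            if d is None:
                chain[(a, b)] = float("inf")
                disconnected.append((a, b))
            else:
                chain[(a, b)] = float(d)
    if disconnected:
        logger.warning(
            "batches not connected by any replicate chain: %s", disconnected
        )
    return ConnectivityReport(components, chain, disconnected, g)
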