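"""Synthetic nCounter experiments with known ground truth.

The generator emulates the structure the normalization methods assume on
the log2 scale:

    signal = 1 mu' + X beta + W_true alpha_true + library factor + noise,

with batch-level unwanted factors (a cartridge/CodeSet/era score shared by
every assay in a batch, times gene loadings), a per-assay library-size
factor modelling sample content, and i.i.d. Gaussian residual noise.
Counts are round(2^signal), keeping the log-scale truth exact.  The
spike-ins follow the platform design: six POS probes on a fixed geometric
concentration ladder affected by the library factor only, and eight NEG
probes drawn Poisson around a flat background that is independent of
biology and batch (spike-ins only see unwanted variation from the point at
which they are added).

Technical replicates are extra assays of the same biological sample with
fresh noise, a fresh library factor, and the unwanted score of whatever
batch the replicate is placed in; placement (within batches, spanning
batches, or confounded with one batch) controls how much of the unwanted
variation the replicate residuals can reveal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ncruv.core_data import (
    CountMatrix,
    ProbeAnnotation,
    ReplicateDesign,
    SampleAnnotation,
    make_replicate_design,
)

N_NEG_PROBES = 8
N_POS_PROBES = 6
# log2 counts of the six POS spike-ins: a geometric ladder spanning ~3
# orders of magnitude (platform convention)
POS_LADDER_LOG2 = np.array([15.0, 13.0, 11.0, 9.0, 7.0, 5.0])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``groups`` maps biology labels to their DE effect size in log2 units;
    biological samples are split evenly over the labels and the effect is
    applied to the planted DE genes (with random per-gene sign).
    ``batch_score_loc`` optionally fixes the mean unwanted score of each
    batch for the first factor, which is how preset failure modes (a bad
    late cartridge, a between-era shift) are arranged.
    """

    m_bio: int = 54
    groups: dict = field(default_factory=lambda: {"A": 0.0, "B": 1.0})
    n_genes: int = 480  # endogenous probes
    n_hk: int = 6
    n_de: int = 50
    n_batches: int = 3
    batch_scale: float = 1.5  # sd of batch-level unwanted scores (log2)
    batch_score_loc: list | None = None  # per-batch mean for factor 1
    alpha_positive: bool = False  # loadings ~ |N(1, 0.3)| (content-like dips)
    k_true: int = 1
    noise_sd: float = 0.3
    lib_size_sd: float = 0.2
    replicate_fraction: float = 0.10
    replicate_placement: str = "spanning"  # within_batch | spanning | confounded
    background_mean: float = 10.0
    baseline_log2_range: tuple = (5.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.replicate_fraction <= 1.0:
            raise ValueError("replicate_fraction must be in [0, 1]")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.replicate_placement not in ("within_batch", "spanning", "confounded"):
            raise ValueError(
                f"unknown replicate_placement {self.replicate_placement!r}"
            )
        if self.batch_score_loc is not None and len(self.batch_score_loc) != self.n_batches:
            raise ValueError("batch_score_loc length must equal n_batches")


@dataclass
class SimulationTruth:
    X: np.ndarray  # m x n_groups biology indicator
    beta: np.ndarray  # n_groups x n_probes planted effects (log2)
    W_true: np.ndarray  # m x k_true unwanted scores
    alpha_true: np.ndarray  # k_true x n_probes unwanted loadings
    lib_factors: np.ndarray  # length-m log2 library factors
    de_genes: list[str]
    mu: np.ndarray  # baseline log2 expression per probe


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    annotation: ProbeAnnotation
    samples: SampleAnnotation
    design: ReplicateDesign
    truth: SimulationTruth
    config: SimulationConfig


def _n_replicates(config: SimulationConfig) -> int:
    # replicate_fraction is a fraction of total assays m = m_bio + n_rep
    f = config.replicate_fraction
    return int(round(f * config.m_bio / (1.0 - f))) if f < 1.0 else config.m_bio


def simulate(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one experiment; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_rep = _n_replicates(config)
    if config.replicate_placement == "spanning" and config.n_batches > 1 and n_rep < 1:
        raise ValueError(
            "replicate_fraction yields no replicates; spanning placement "
            "requires at least one"
        )

    n_endo, n_hk = config.n_genes, config.n_hk
    n_probes = n_endo + n_hk + N_NEG_PROBES + N_POS_PROBES
    probe_names = (
        [f"GENE_{j:04d}" for j in range(n_endo)]
        + [f"HK_{j}" for j in range(n_hk)]
        + [f"NEG_{chr(ord('A') + j)}" for j in range(N_NEG_PROBES)]
        + [f"POS_{chr(ord('A') + j)}" for j in range(N_POS_PROBES)]
    )
    code_classes = (
        ["Endogenous"] * n_endo
        + ["Housekeeping"] * n_hk
        + ["Negative"] * N_NEG_PROBES
        + ["Positive"] * N_POS_PROBES
    )
    annotation = ProbeAnnotation(probe_names, code_classes)
    endo_hk = slice(0, n_endo + n_hk)
    neg = slice(n_endo + n_hk, n_endo + n_hk + N_NEG_PROBES)
    pos = slice(n_endo + n_hk + N_NEG_PROBES, n_probes)

    # biology
    group_labels = list(config.groups)
    bio_groups = [group_labels[i % len(group_labels)] for i in range(config.m_bio)]
    de_idx = rng.choice(n_endo, size=config.n_de, replace=False) if config.n_de else []
    de_sign = rng.choice([-1.0, 1.0], size=config.n_de)
    beta = np.zeros((len(group_labels), n_probes))
    for g, label in enumerate(group_labels):
        beta[g, de_idx] = config.groups[label] * de_sign

    # batch membership of biological assays: contiguous blocks (cartridges)
    bio_batches = [
        int(i * config.n_batches / config.m_bio) for i in range(config.m_bio)
    ]

    # technical replicates: evenly-spaced biological samples get a second assay
    if config.replicate_placement == "confounded":
        donors_pool = [i for i in range(config.m_bio) if bio_batches[i] == 0]
    else:
        donors_pool = list(range(config.m_bio))
    step = max(1, len(donors_pool) // max(1, n_rep))
    donors = donors_pool[::step][:n_rep]

    assay_bio: list[int] = list(range(config.m_bio))
    assay_batch: list[int] = list(bio_batches)
    assay_ids: list[str] = [f"S{i:03d}" for i in range(config.m_bio)]
    for r, d in enumerate(donors):
        assay_bio.append(d)
        if config.replicate_placement == "within_batch":
            b = bio_batches[d]
        elif config.replicate_placement == "confounded":
            b = 0
        else:  # spanning
            b = (bio_batches[d] + 1 + r % max(1, config.n_batches - 1)) % config.n_batches
        assay_batch.append(b)
        assay_ids.append(f"S{d:03d}_r")
    m = len(assay_ids)

    # batch-level unwanted scores
    loc = np.zeros((config.n_batches, config.k_true))
    if config.batch_score_loc is not None:
        loc[:, 0] = np.asarray(config.batch_score_loc, dtype=float)
        batch_scores = loc + rng.normal(
            0.0, config.batch_scale * 0.1, size=loc.shape
        )
    else:
        batch_scores = rng.normal(loc, config.batch_scale)
    W_true = batch_scores[np.array(assay_batch)]  # m x k_true

    alpha_true = np.zeros((config.k_true, n_probes))
    if config.alpha_positive:
        alpha_true[:, endo_hk] = np.abs(rng.normal(1.0, 0.3, size=(config.k_true, n_endo + n_hk)))
    else:
        alpha_true[:, endo_hk] = rng.normal(size=(config.k_true, n_endo + n_hk))

    mu = np.zeros(n_probes)
    lo, hi = config.baseline_log2_range
    mu[endo_hk] = rng.uniform(lo, hi, size=n_endo + n_hk)
    mu[pos] = POS_LADDER_LOG2

    lib = rng.normal(0.0, config.lib_size_sd, size=m)
    X = np.zeros((m, len(group_labels)))
    for i, b in enumerate(assay_bio):
        X[i, group_labels.index(bio_groups[b])] = 1.0

    signal = np.tile(mu, (m, 1))
    signal[:, endo_hk] += (X @ beta)[:, endo_hk]
    signal[:, endo_hk] += (W_true @ alpha_true)[:, endo_hk]
    signal[:, endo_hk] += lib[:, None]
    signal[:, pos] += lib[:, None]
    signal[:, endo_hk] += rng.normal(0.0, config.noise_sd, size=(m, n_endo + n_hk))

    counts = np.round(np.power(2.0, signal))
    counts[:, neg] = rng.poisson(config.background_mean, size=(m, N_NEG_PROBES))
    counts = np.maximum(counts, 0.0)

    count_matrix = CountMatrix(counts, assay_ids, probe_names)
    design = make_replicate_design(assay_ids, [f"B{b:03d}" for b in assay_bio])

    run_order = np.lexsort((np.arange(m), np.array(assay_batch)))
    order_rank = np.empty(m, dtype=int)
    order_rank[run_order] = np.arange(m)
    samples = SampleAnnotation(
        sample_ids=assay_ids,
        batch=[f"batch{b + 1}" for b in assay_batch],
        biology=[bio_groups[b] for b in assay_bio],
        run_order=[int(r) for r in order_rank],
    )
    truth = SimulationTruth(
        X=X,
        beta=beta,
        W_true=W_true,
        alpha_true=alpha_true,
        lib_factors=lib,
        de_genes=[probe_names[j] for j in de_idx],
        mu=mu,
    )
    return SimulatedExperiment(count_matrix, annotation, samples, design, truth, config)


def write_rcc_fixture(experiment: SimulatedExperiment, directory) -> list[Path]:
    """Write one RCC lane file per assay; cartridge = batch, lanes cycle 1-12.

    Parsing the files back with :func:`ncruv.rcc_io.parse_rcc` and
    :func:`ncruv.rcc_io.assemble_matrix` reproduces the counts exactly.
    """
    from ncruv.rcc_io import RCCLane, ProbeRecord, write_rcc

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    lane_in_cartridge: dict[str, int] = {}
    for i, sid in enumerate(experiment.counts.sample_ids):
        cartridge = experiment.samples.batch[i]
        lane_no = lane_in_cartridge.get(cartridge, 0) % 12 + 1
        lane_in_cartridge[cartridge] = lane_in_cartridge.get(cartridge, 0) + 1
        records = [
            ProbeRecord(
                code_class=cc,
                name=name,
                accession=f"SYN_{name}",
                count=int(experiment.counts.values[i, j]),
            )
            for j, (name, cc) in enumerate(
                zip(experiment.annotation.probe_names, experiment.annotation.code_classes)
            )
        ]
        lane = RCCLane(
            sample_id=sid,
            lane_attributes={
                "ID": str(lane_no),
                "CartridgeID": cartridge,
                "Date": "20240101",
            },
            sample_attributes={"ID": sid, "Owner": "", "Comments": "synthetic"},
            header={"FileVersion": "1.7", "SoftwareVersion": "ncruv-sim"},
            probe_records=records,
        )
        path = directory / f"{sid}.RCC"
        write_rcc(lane, path)
        paths.append(path)
    return paths


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study conditions reproducing qualitative real-study failure modes.

    * ``late_bad_cartridge`` — the last cartridge's content drops: HK means
      and log totals dip there while the spike-in series stay flat.
    * ``two_era_time_shift`` — two eras of assays with a downward shift in
      the later era.
    * ``codeset_batches`` — three reagent-lot batches with a rank-1 batch
      effect and replicates spanning batches (the well-designed study).
    * ``disconnected_batches`` — two batches whose replicates all lie within
      a batch, so no replicate chain connects them; the case pseudo-replicates
      are designed to rescue.
    """
    return {
        "late_bad_cartridge": SimulationConfig(
            m_bio=54,
            n_batches=5,
            batch_score_loc=[0.0, 0.0, 0.0, 0.0, -2.0],
            alpha_positive=True,
            batch_scale=0.5,
            k_true=1,
            replicate_placement="spanning",
            seed=11,
        ),
        "two_era_time_shift": SimulationConfig(
            m_bio=40,
            n_batches=2,
            batch_score_loc=[0.0, -1.5],
            alpha_positive=True,
            batch_scale=0.5,
            k_true=1,
            replicate_placement="spanning",
            seed=12,
        ),
        "codeset_batches": SimulationConfig(
            m_bio=54,
            n_batches=3,
            batch_scale=1.5,
            k_true=1,
            replicate_placement="spanning",
            seed=13,
        ),
        # a minimal two-cartridge pilot with a large, known batch shift and
        # replicates trapped within batches: the case a single bridging
        # pseudo-replicate pair is meant to rescue
        "disconnected_batches": SimulationConfig(
            m_bio=8,
            groups={"A": 0.0},
            n_de=0,
            n_batches=2,
            batch_scale=2.0,
            batch_score_loc=[0.0, -4.0],
            k_true=1,
            replicate_placement="within_batch",
            seed=14,
        ),
    }
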