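"""Synthetic benchmark instances with known ground truth.

Two generators are provided. ``simulate_counts`` produces a splat-style
negative-binomial count dataset: gamma-distributed gene means, per-label
differential-expression factors, per-batch multiplicative effects, log-normal
library sizes and Poisson-gamma count sampling, with an optional two-branch
trajectory and extra per-label noise. ``simulate_embedding`` skips counts
entirely and draws cells from Gaussian label clusters in a latent space —
a fast fixture for metric tests where only the embedding matters.

``fixture_integrate`` is a deliberately simple stand-in for a real
integration model (scVI, Harmony, ...): PCA on the reference with the query
projected in, plus a tunable fraction of per-batch mean-shift removal. Its
single ``removal`` dial lets tests check that batch-mixing metrics respond
monotonically to the amount of batch effect actually removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import CellMatrix, JointEmbedding, SplitDataset, prepare_split

__all__ = [
    "LabelSpec",
    "TrajectorySpec",
    "BatchSpec",
    "SimConfig",
    "EmbConfig",
    "simulate_counts",
    "simulate_embedding",
    "fixture_integrate",
    "splat_scenario",
]


@dataclass(frozen=True)
class LabelSpec:
    """One cell label: base cells per batch and its DE-factor parameters."""

    name: str
    n_cells: int  # per batch, before the batch n_cells_factor
    de_prob: float = 0.1
    de_scale: float = 1.0


@dataclass(frozen=True)
class TrajectorySpec:
    """A progenitor differentiating along branches.

    Cells of each branch label are spread over ``n_steps`` interpolation
    steps between the progenitor's mean profile and the branch terminal
    profile; the step index is recorded as metadata, the label is the branch
    name.
    """

    progenitor: str
    branches: tuple[str, ...]
    n_steps: int = 10


@dataclass(frozen=True)
class BatchSpec:
    """One batch: sequencing-depth and cell-count multipliers."""

    name: str
    depth_factor: float = 1.0
    n_cells_factor: float = 1.0
    condition: str = "control"


@dataclass
class SimConfig:
    """Configuration of the count-level simulation."""

    n_features: int = 1000
    labels: tuple[LabelSpec, ...] = ()
    trajectory: TrajectorySpec | None = None
    batches: tuple[BatchSpec, ...] = ()
    query_batches: frozenset = frozenset()
    unseen_labels: frozenset = frozenset()
    label_noise_sd: float = 0.0
    batch_effect_sd: float = 0.1
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 9.0
    lib_sd: float = 0.25
    bcv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.batches = tuple(self.batches)
        self.query_batches = frozenset(self.query_batches)
        self.unseen_labels = frozenset(self.unseen_labels)
        if len(self.batches) < 2:
            raise ValueError("need at least 2 batches")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 labels")
        names = {l.name for l in self.labels}
        if not self.unseen_labels <= names:
            raise ValueError("unseen_labels must be a subset of label names")
        if any(b.depth_factor <= 0 for b in self.batches):
            raise ValueError("depth_factor must be positive")
        batch_names = {b.name for b in self.batches}
        if not self.query_batches <= batch_names:
            raise ValueError("query_batches must be a subset of batch names")
        if self.trajectory is not None:
            traj_names = {self.trajectory.progenitor, *self.trajectory.branches}
            if not traj_names <= names:
                raise ValueError("trajectory labels must appear in labels")


@dataclass
class EmbConfig:
    """Configuration of the embedding-level fixture generator."""

    d: int = 10
    n_labels: int = 4
    n_batches: int = 2
    n_per_group: int = 50  # cells per (label, batch)
    label_centers: np.ndarray | str = "auto"
    center_separation: float = 10.0
    cluster_sd: float = 1.0
    batch_shift_sd: float = 0.0
    query_shift_sd: float = 0.0
    unseen_labels: tuple[str, ...] = ()
    unseen_placement: str = "far"  # "far" | "merged"
    n_query_batches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be positive")
        if self.unseen_placement not in ("far", "merged"):
            raise ValueError("unseen_placement must be 'far' or 'merged'")


# ---------------------------------------------------------------------------
# Count-level simulation


def _label_means(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Base gene means plus per-label DE factors; returns mean profile per label."""
    base = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=cfg.n_features)
    base = np.maximum(base, 1e-8)
    means: dict[str, np.ndarray] = {}
    de_flags: dict[str, np.ndarray] = {}
    de_factors: dict[str, np.ndarray] = {}
    for spec in cfg.labels:
        is_de = rng.random(cfg.n_features) < spec.de_prob
        factors = np.ones(cfg.n_features)
        if spec.de_scale > 0:
            factors[is_de] = rng.lognormal(0.0, spec.de_scale, size=int(is_de.sum()))
        means[spec.name] = base * factors
        de_flags[spec.name] = is_de
        de_factors[spec.name] = factors
    return {  # type: ignore[return-value]
        "base": base,
        "means": means,
        "de_flags": de_flags,
        "de_factors": de_factors,
    }


def simulate_counts(cfg: SimConfig) -> SplitDataset:
    """Simulate a reference/query split count dataset.

    Counts follow a Poisson-gamma (negative binomial) model: the expected
    count of gene g in cell c is ``L_c * m_g(c) / sum_g m_g(c)`` where ``m``
    is the cell's mean profile (label means, optionally interpolated along
    the trajectory, times batch and noise factors) and ``L_c`` is a
    log-normal library size scaled by the batch's depth factor. Ground-truth
    differential-expression flags per label are stored in provenance.
    """
    rng = np.random.default_rng(cfg.seed)
    parts = _label_means(cfg, rng)
    label_means, de_flags = parts["means"], parts["de_flags"]

    # per-batch multiplicative gene effects
    batch_factors = {
        b.name: (
            rng.lognormal(0.0, cfg.batch_effect_sd, size=cfg.n_features)
            if cfg.batch_effect_sd > 0
            else np.ones(cfg.n_features)
        )
        for b in cfg.batches
    }

    traj = cfg.trajectory
    branch_labels = set(traj.branches) if traj is not None else set()

    rows, cell_batches, cell_labels, cell_steps = [], [], [], []
    for b in cfg.batches:
        for spec in cfg.labels:
            n = int(round(spec.n_cells * b.n_cells_factor))
            if spec.n_cells > 0 and n == 0:
                raise ValueError(
                    f"label {spec.name!r} has 0 cells in batch {b.name!r}"
                )
            if n == 0:
                continue
            # unseen labels exist only in query batches
            if spec.name in cfg.unseen_labels and b.name not in cfg.query_batches:
                continue
            if traj is not None and spec.name in branch_labels:
                steps = rng.integers(1, traj.n_steps + 1, size=n)
                t = steps / traj.n_steps
                log_prog = np.log(label_means[traj.progenitor])
                log_term = np.log(label_means[spec.name])
                mean = np.exp(
                    (1.0 - t)[:, None] * log_prog[None, :]
                    + t[:, None] * log_term[None, :]
                )
            else:
                steps = np.zeros(n, dtype=int)
                mean = np.tile(label_means[spec.name], (n, 1))
            mean = mean * batch_factors[b.name][None, :]
            if cfg.label_noise_sd > 0:
                mean = mean * rng.lognormal(
                    0.0, cfg.label_noise_sd, size=mean.shape
                )
            lib = rng.lognormal(cfg.lib_loc, cfg.lib_sd, size=n) * b.depth_factor
            expected = mean / mean.sum(axis=1, keepdims=True) * lib[:, None]
            if cfg.bcv > 0:
                shape = 1.0 / cfg.bcv**2
                expected = rng.gamma(shape, expected / shape)
            counts = rng.poisson(expected).astype(np.float64)
            rows.append(counts)
            cell_batches.extend([b.name] * n)
            cell_labels.extend([spec.name] * n)
            cell_steps.extend(steps.tolist())

    counts = np.vstack(rows)
    n_cells = counts.shape[0]
    raw = CellMatrix(
        counts=counts,
        cell_ids=np.array([f"cell{i}" for i in range(n_cells)], dtype=object),
        feature_ids=np.array(
            [f"gene{j}" for j in range(cfg.n_features)], dtype=object
        ),
        batch=np.array(cell_batches, dtype=object),
        label=np.array(cell_labels, dtype=object),
    )
    # QC thresholds off: the simulator controls its own cell counts; the
    # shared split path still removes unseen labels from the reference and
    # features unexpressed in the reference.
    ds = prepare_split(
        raw,
        query_batches=cfg.query_batches,
        unseen_labels=cfg.unseen_labels,
        min_counts=0,
        min_features=0,
        min_label_cells=1,
    )
    feat_kept = np.isin(raw.feature_ids, ds.reference.feature_ids)
    ds.provenance["de_flags"] = {
        name: flags[feat_kept].tolist() for name, flags in de_flags.items()
    }
    ds.provenance["de_factors"] = {
        name: fac[feat_kept].tolist()
        for name, fac in parts["de_factors"].items()
    }
    ds.provenance["trajectory_step"] = dict(
        zip(raw.cell_ids.tolist(), cell_steps)
    )
    ds.provenance["seed"] = cfg.seed
    return ds


def splat_scenario(
    scale: float = 1.0, seed: int = 0, n_features: int = 1000
) -> SimConfig:
    """The default benchmark scenario.

    A tissue measured by three technologies (two batches each): a medium
    number of cells at medium depth, few cells at high depth, and many cells
    at low depth, with the low-depth pair as the query. Ten labels including
    a progenitor differentiating along two branches — one with an
    "Intermediate" state present only in the query — and discrete types
    including query-only "Rare" and "Perturbed" populations. ``scale``
    multiplies cell numbers.
    """

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    labels = (
        LabelSpec("TypeA", n(60), 0.10, 1.0),
        LabelSpec("TypeB", n(50), 0.10, 1.0),
        LabelSpec("TypeC", n(40), 0.15, 0.8),
        LabelSpec("TypeD", n(30), 0.05, 1.2),
        LabelSpec("Rare", n(10), 0.15, 1.5),
        LabelSpec("Perturbed", n(40), 0.08, 0.6),
        LabelSpec("Progenitor", n(40), 0.10, 1.0),
        LabelSpec("BranchA", n(40), 0.12, 1.0),
        LabelSpec("BranchB", n(40), 0.12, 1.0),
        LabelSpec("Intermediate", n(30), 0.12, 0.8),
    )
    batches = (
        BatchSpec("Batch1", depth_factor=1.0, n_cells_factor=1.0),
        BatchSpec("Batch2", depth_factor=1.0, n_cells_factor=1.0),
        BatchSpec("Batch3", depth_factor=3.0, n_cells_factor=0.4),
        BatchSpec("Batch4", depth_factor=3.0, n_cells_factor=0.4),
        BatchSpec("Batch5", depth_factor=0.3, n_cells_factor=1.6, condition="query"),
        BatchSpec("Batch6", depth_factor=0.3, n_cells_factor=1.6, condition="query"),
    )
    return SimConfig(
        n_features=n_features,
        labels=labels,
        trajectory=TrajectorySpec("Progenitor", ("BranchA", "Intermediate"), 10),
        batches=batches,
        query_batches=frozenset({"Batch5", "Batch6"}),
        unseen_labels=frozenset({"Rare", "Perturbed", "Intermediate"}),
        label_noise_sd=0.2,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Embedding-level simulation


def simulate_embedding(
    cfg: EmbConfig,
) -> tuple[JointEmbedding, np.ndarray, np.ndarray, np.ndarray]:
    """Draw cells from Gaussian label clusters in a shared latent space.

    Returns ``(embedding, labels, batches, is_query)`` where the per-cell
    arrays cover reference rows first, then query rows (matching
    ``embedding.all_coords``). Batches named ``batch0..`` with the last
    ``n_query_batches`` designated query; each batch gets an isotropic
    Gaussian offset of scale ``batch_shift_sd`` and query batches an extra
    offset of scale ``query_shift_sd``. Unseen labels appear only in query
    batches, placed at distance >= 6 * cluster_sd from every seen center
    ("far") or exactly at an existing center ("merged").
    """
    rng = np.random.default_rng(cfg.seed)
    seen_names = [f"label{i}" for i in range(cfg.n_labels)]
    all_names = seen_names + list(cfg.unseen_labels)

    if isinstance(cfg.label_centers, str):
        centers = _spread_centers(
            len(seen_names), cfg.d, cfg.center_separation, rng
        )
    else:
        centers = np.asarray(cfg.label_centers, dtype=float)
        if centers.shape != (len(seen_names), cfg.d):
            raise ValueError("label_centers must be n_labels x d")
    center_map = dict(zip(seen_names, centers))
    for name in cfg.unseen_labels:
        if cfg.unseen_placement == "merged":
            center_map[name] = centers[0].copy()
        else:
            center_map[name] = _far_center(centers, 6.0 * cfg.cluster_sd, rng)

    batch_names = [f"batch{i}" for i in range(cfg.n_batches)]
    query_set = set(batch_names[cfg.n_batches - cfg.n_query_batches :])
    shifts = {
        b: rng.normal(0.0, cfg.batch_shift_sd, size=cfg.d)
        if cfg.batch_shift_sd > 0
        else np.zeros(cfg.d)
        for b in batch_names
    }
    qshifts = {
        b: rng.normal(0.0, cfg.query_shift_sd, size=cfg.d)
        if (b in query_set and cfg.query_shift_sd > 0)
        else np.zeros(cfg.d)
        for b in batch_names
    }

    coords, labels, batches, is_query = [], [], [], []
    for b in batch_names:
        for name in all_names:
            if name in cfg.unseen_labels and b not in query_set:
                continue
            x = center_map[name] + rng.normal(
                0.0, cfg.cluster_sd, size=(cfg.n_per_group, cfg.d)
            )
            x = x + shifts[b] + qshifts[b]
            coords.append(x)
            labels.extend([name] * cfg.n_per_group)
            batches.extend([b] * cfg.n_per_group)
            is_query.extend([b in query_set] * cfg.n_per_group)

    coords = np.vstack(coords)
    labels = np.array(labels, dtype=object)
    batches = np.array(batches, dtype=object)
    is_query = np.array(is_query, dtype=bool)
    order = np.argsort(is_query, kind="stable")  # reference rows first
    coords, labels, batches, is_query = (
        coords[order],
        labels[order],
        batches[order],
        is_query[order],
    )
    emb = JointEmbedding(
        ref_coords=coords[~is_query], query_coords=coords[is_query]
    )
    return emb, labels, batches, is_query


def _spread_centers(
    n: int, d: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Random centers with pairwise distance >= separation (rejection)."""
    centers: list[np.ndarray] = []
    scale = separation * max(1.0, n ** (1.0 / d))
    while len(centers) < n:
        c = rng.normal(0.0, scale, size=d)
        if all(np.linalg.norm(c - o) >= separation for o in centers):
            centers.append(c)
    return np.vstack(centers)


def _far_center(
    centers: np.ndarray, min_dist: float, rng: np.random.Generator
) -> np.ndarray:
    d = centers.shape[1]
    while True:
        c = centers.mean(axis=0) + rng.normal(
            0.0, max(min_dist * 3, np.abs(centers).max() * 2), size=d
        )
        if np.linalg.norm(c - centers, axis=1).min() >= min_dist:
            return c


# ---------------------------------------------------------------------------
# Fixture integrator


def fixture_integrate(
    ds: SplitDataset,
    n_pcs: int = 10,
    removal: float = 1.0,
    seed: int = 0,
    features: np.ndarray | None = None,
) -> JointEmbedding:
    """PCA 'integration' with tunable batch-mean removal.

    Counts are normalised to counts-per-10k and log1p-transformed; PCA is fit
    on the reference and the query projected in. Each batch's mean embedding
    vector is then pulled toward the global mean by the fraction ``removal``:
    0 leaves the batch effect intact (the embedding equals the uncorrected
    PCA), 1 centres every batch mean exactly. The uncorrected PCA coordinates
    are kept as ``pre_integration``.
    """
    from sklearn.decomposition import PCA

    if not 0.0 <= removal <= 1.0:
        raise ValueError("removal must be in [0, 1]")
    ref, query = ds.reference, ds.query
    if features is not None:
        mask = np.isin(ref.feature_ids, features)
        if not mask.any():
            raise ValueError("no requested features present")
        ref = ref.subset_features(mask)
        query = query.subset_features(mask)
    if n_pcs > min(ref.n_cells, ref.n_features):
        raise ValueError("n_pcs exceeds reference size")

    def _lognorm(cm: CellMatrix) -> np.ndarray:
        x = cm.dense_counts()
        totals = x.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return np.log1p(x / totals * 1e4)

    xr, xq = _lognorm(ref), _lognorm(query)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pr = pca.fit_transform(xr)
    if np.allclose(pca.explained_variance_, 0.0):
        raise ValueError("degenerate PCA: zero variance")
    pq = pca.transform(xq)

    pre = np.vstack([pr, pq])
    coords = pre.copy()
    batch = np.concatenate([ref.batch, query.batch])
    global_mean = coords.mean(axis=0)
    for b in np.unique(batch):
        m = batch == b
        coords[m] -= removal * (coords[m].mean(axis=0) - global_mean)
    return JointEmbedding(
        ref_coords=coords[: ref.n_cells],
        query_coords=coords[ref.n_cells :],
        pre_integration=pre,
    )
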