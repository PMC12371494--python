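"""Binding-pose inference from protein–ligand trajectories.

The pipeline mirrors a standard MD pose-population analysis for a ligand
that can bind in two symmetry-related orientations:

1. ``subsample`` — keep frames at a fixed interval inside an equilibrated
   window (by default the second half of each run at 1 ns spacing);
2. ``select_bound`` — keep frames whose exocyclic sulfur lies strictly
   within 5 Å of the C433 backbone nitrogen;
3. ``featurize`` — 10 protein–ligand anchor distances per bound frame;
4. ``project_2d`` — PCA of the centered (unscaled — all columns share Å)
   distances onto the first two components;
5. ``fit_mixture`` — full-covariance Gaussian mixture in PC space, hard
   assignments, cluster populations;
6. ``centroid_frames`` — the bound frame nearest each cluster mean, used
   as the representative pose;
7. ``ligand_rmsd`` / ``compare_pose_stability`` — Cα-anchored ligand RMSD
   time series, summarized as median ± one MAD across replicates.

Clusters are canonically named: the cluster whose centroid frame places the
ligand carbonyl oxygen closer to the Y418 backbone N than to the structural
water is "pose A" (ties go to A); the other is "pose B".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .topology import FEATURE_COLUMNS
from .trajectory import Trajectory

__all__ = [
    "FeatureMatrix",
    "Projection",
    "PoseClusterResult",
    "RmsdSeries",
    "StabilityReport",
    "subsample",
    "select_bound",
    "featurize",
    "project_2d",
    "fit_mixture",
    "scan_components",
    "centroid_frames",
    "name_clusters",
    "cluster_poses",
    "PoseClusterReport",
    "ligand_rmsd",
    "compare_pose_stability",
]

_TIME_TOL = 1e-6  # ns, tolerance for time-grid comparisons


@dataclass
class FeatureMatrix:
    """Per-bound-frame anchor distances (Å); index = (replicate_id, frame_index)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != FEATURE_COLUMNS:
            raise ValueError(f"feature columns must be {FEATURE_COLUMNS}")
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("all anchor distances must be positive")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def frame_index(self) -> pd.MultiIndex:
        return self.data.index


@dataclass
class Projection:
    """2-D PCA projection of a feature matrix."""

    coords: np.ndarray                 # (n, 2)
    explained_variance: np.ndarray     # (2,) fractions
    components: np.ndarray             # (2, 10) loadings
    frame_index: pd.MultiIndex


@dataclass
class PoseClusterResult:
    """Gaussian-mixture fit in PC space with hard assignments."""

    weights: np.ndarray                # (k,) mixture weights
    means: np.ndarray                  # (k, 2)
    covariances: np.ndarray            # (k, 2, 2) full covariances
    assignments: np.ndarray            # (n,) hard labels by max responsibility
    populations: np.ndarray            # (k,) assignment fractions, sum to 1
    log_likelihood: float
    converged: bool
    seed: int
    centroid_frames: list[tuple[int, int] | None] = field(default_factory=list)


def subsample(
    traj: Trajectory,
    t_start: float | None = None,
    t_end: float | None = None,
    interval: float = 1.0,
) -> Trajectory:
    """Frames with time in [t_start, t_end] (both ends inclusive) at the
    given interval, per replicate.

    Defaults discard the first half of each run: t_start = half the
    trajectory span, t_end = span, at 1 ns spacing.  With 200 frames at
    1 ns and the [100, 200] ns window this keeps 101 frames per replicate.
    """
    span = float(traj.times.max())
    if t_start is None:
        t_start = span / 2.0
    if t_end is None:
        t_end = span
    if not t_start < t_end:
        raise ValueError("require t_start < t_end")
    if interval <= 0:
        raise ValueError("interval must be positive")
    in_window = (traj.times >= t_start - _TIME_TOL) & (traj.times <= t_end + _TIME_TOL)
    phase = (traj.times - t_start) / interval
    on_grid = np.abs(phase - np.round(phase)) < _TIME_TOL
    mask = in_window & on_grid
    if not mask.any():
        raise ValueError(
            f"subsampling window [{t_start}, {t_end}] ns at {interval} ns "
            "selects no frames"
        )
    return traj.select_frames(mask)


def select_bound(
    traj: Trajectory, threshold: float = 5.0
) -> tuple[Trajectory, np.ndarray]:
    """Frames whose exocyclic S–C433(N) distance is strictly below
    ``threshold`` Å, plus the boolean mask aligned to the input frames."""
    s1 = traj.topology.ligand_index("S1")
    c433_n = traj.topology.index(433, "N")
    d = np.linalg.norm(traj.coords[:, s1] - traj.coords[:, c433_n], axis=1)
    mask = d < threshold
    return traj.select_frames(mask), mask


def featurize(traj: Trajectory) -> FeatureMatrix:
    """The 10 anchor distances per frame, columns in fixed order.

    Atom pairs are resolved by residue/atom name (see
    :data:`posepop.topology.FEATURE_PAIRS`), so input atom order is
    irrelevant.  By convention the input holds bound frames only.
    """
    pairs = traj.topology.feature_pair_indices()
    cols = {}
    for col, li, pi in pairs:
        cols[col] = np.linalg.norm(traj.coords[:, li] - traj.coords[:, pi], axis=1)
    index = pd.MultiIndex.from_tuples(
        traj.frame_keys(), names=["replicate_id", "frame_index"]
    )
    df = pd.DataFrame(cols, index=index, columns=list(FEATURE_COLUMNS))
    return FeatureMatrix(df)


def project_2d(features: FeatureMatrix) -> Projection:
    """Mean-centered PCA onto the top two components.

    Distances are centered but not standardized (all columns share units of
    Å).  Sign convention: within each component the largest-magnitude
    loading is made positive.  All-identical frames (rank-0 input) raise;
    rank-1 input is allowed — the second component is then degenerate with
    ~0 explained variance (two repeated templates collapse to two points on
    PC1).
    """
    x = features.values
    if x.shape[0] < 3:
        raise ValueError("PCA projection requires at least 3 frames")
    centered = x - x.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] < 1e-10:
        raise ValueError("rank-deficient feature matrix: all frames identical")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(x)
    components = pca.components_.copy()
    for j in range(2):
        lead = np.argmax(np.abs(components[j]))
        if components[j, lead] < 0:
            components[j] = -components[j]
            coords[:, j] = -coords[:, j]
    return Projection(
        coords=coords,
        explained_variance=pca.explained_variance_ratio_.copy(),
        components=components,
        frame_index=features.frame_index,
    )


def fit_mixture(
    projection: Projection, k: int = 2, seed: int = 0
) -> PoseClusterResult:
    """Full-covariance Gaussian mixture (EM) in PC space.

    k-means++ initialization with 10 restarts at the given seed, tolerance
    1e-6 on the mean log-likelihood, at most 500 iterations; the best
    restart by log-likelihood is kept.  Non-convergence is flagged on the
    result, never silent.  Populations are hard-assignment fractions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = projection.coords.shape[0]
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} frames to fit {k} components")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=10,
        init_params="k-means++",
        tol=1e-6,
        max_iter=500,
        random_state=seed,
    )
    labels = gm.fit_predict(projection.coords)
    populations = np.bincount(labels, minlength=k) / n
    return PoseClusterResult(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        assignments=labels,
        populations=populations,
        log_likelihood=float(gm.score(projection.coords) * n),
        converged=bool(gm.converged_),
        seed=seed,
    )


def scan_components(
    projection: Projection, k_max: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Optional BIC scan over the number of mixture components.

    Not part of the default pipeline (k = 2 is the two-pose hypothesis);
    returns one row per k in 1..k_max with the BIC of the best-of-10 fit.
    """
    rows = []
    for k in range(1, k_max + 1):
        if projection.coords.shape[0] < 10 * k:
            break
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=10,
            init_params="k-means++", tol=1e-6, max_iter=500, random_state=seed,
        ).fit(projection.coords)
        rows.append({"k": k, "bic": float(gm.bic(projection.coords))})
    return pd.DataFrame(rows)


def centroid_frames(
    result: PoseClusterResult, projection: Projection
) -> list[tuple[int, int] | None]:
    """Representative frame per cluster: the assigned bound frame with the
    smallest Euclidean distance to the cluster mean in PC space.

    Ties break toward the earliest (replicate_id, frame_index); an empty
    cluster yields ``None``.  The result is also stored on ``result``.
    """
    keys = list(projection.frame_index)
    out: list[tuple[int, int] | None] = []
    for c in range(len(result.means)):
        members = np.flatnonzero(result.assignments == c)
        if members.size == 0:
            out.append(None)
            continue
        d = np.linalg.norm(projection.coords[members] - result.means[c], axis=1)
        best = d.min()
        tied = members[np.flatnonzero(d <= best + 1e-12)]
        out.append(min(keys[int(i)] for i in tied))
    result.centroid_frames = out
    return out


def name_clusters(
    result: PoseClusterResult, bound_traj: Trajectory, projection: Projection
) -> dict[int, str]:
    """Canonical pose names for a two-component fit.

    For each cluster's centroid frame, compare the ligand carbonyl-O
    distance to the Y418 backbone N against its distance to the structural
    water O.  The cluster with the smaller (Y418 − water) difference is
    "pose A" (carbonyl toward Y418, the crystal-structure-like orientation);
    the other is "pose B".  For k=1 the single cluster is named by the same
    rule, ties toward A.
    """
    cents = result.centroid_frames or centroid_frames(result, projection)
    topo = bound_traj.topology
    o4 = topo.ligand_index("O4")
    y418_n = topo.index(418, "N")
    water = topo.indices_where("water")
    if water.size == 0:
        raise KeyError("structural water O not in topology")
    keys = bound_traj.frame_keys()
    key_to_pos = {k: i for i, k in enumerate(keys)}

    scores = []
    for c, cent in enumerate(cents):
        if cent is None:
            scores.append((c, np.inf))
            continue
        frame = bound_traj.coords[key_to_pos[cent]]
        d_y = np.linalg.norm(frame[o4] - frame[y418_n])
        d_w = np.linalg.norm(frame[o4] - frame[water[0]])
        scores.append((c, d_y - d_w))

    k = len(cents)
    if k == 1:
        return {0: "A" if scores[0][1] <= 0 else "B"}
    if k == 2:
        order = sorted(scores, key=lambda t: (t[1], t[0]))
        return {order[0][0]: "A", order[1][0]: "B"}
    # more than two clusters: rule applied per cluster, suffixed to stay unique
    names = {}
    for rank, (c, s) in enumerate(sorted(scores, key=lambda t: (t[1], t[0]))):
        names[c] = f"{'A' if s <= 0 else 'B'}{rank}"
    return names


@dataclass
class PoseClusterReport:
    """End-to-end clustering output of :func:`cluster_poses`."""

    populations: dict[str, float]              # pose name -> fraction of bound frames
    weights: dict[str, float]                  # pose name -> mixture weight
    centroids: dict[str, tuple[int, int]]      # pose name -> (replicate, frame)
    explained_variance: np.ndarray
    assignments: pd.DataFrame                  # index (replicate, frame), column "pose"
    n_frames_subsampled: int
    n_frames_bound: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "populations": self.populations,
            "weights": self.weights,
            "centroid_frames": {k: list(v) for k, v in self.centroids.items()},
            "explained_variance": [float(v) for v in self.explained_variance],
            "n_frames_subsampled": self.n_frames_subsampled,
            "n_frames_bound": self.n_frames_bound,
            "converged": self.converged,
        }


def cluster_poses(
    traj: Trajectory,
    t_start: float | None = None,
    t_end: float | None = None,
    interval: float = 1.0,
    threshold: float = 5.0,
    k: int = 2,
    seed: int = 0,
) -> PoseClusterReport:
    """Full pipeline: subsample → bound filter → featurize → PCA → GMM →
    canonical pose naming.  Deterministic for a fixed seed."""
    sub = subsample(traj, t_start=t_start, t_end=t_end, interval=interval)
    bound, _ = select_bound(sub, threshold=threshold)
    feats = featurize(bound)
    proj = project_2d(feats)
    result = fit_mixture(proj, k=k, seed=seed)
    cents = centroid_frames(result, proj)
    names = name_clusters(result, bound, proj)
    return PoseClusterReport(
        populations={names[c]: float(result.populations[c]) for c in names},
        weights={names[c]: float(result.weights[c]) for c in names},
        centroids={names[c]: cents[c] for c in names if cents[c] is not None},
        explained_variance=proj.explained_variance,
        assignments=pd.DataFrame(
            {"pose": [names[c] for c in result.assignments]}, index=proj.frame_index
        ),
        n_frames_subsampled=sub.n_frames,
        n_frames_bound=bound.n_frames,
        converged=result.converged,
    )


@dataclass
class RmsdSeries:
    """Ligand RMSD per replicate over a shared time grid, with the
    across-replicate median and one median absolute deviation."""

    times: np.ndarray                  # (T,) ns
    per_replicate: pd.DataFrame        # rows = replicate_id, cols = times, Å
    median: np.ndarray                 # (T,) Å
    mad: np.ndarray                    # (T,) Å


def _superpose(mobile: np.ndarray, reference: np.ndarray, anchor_idx: np.ndarray) -> np.ndarray:
    """Rigidly superpose a frame onto the reference using the anchor atoms
    (Kabsch); the optimal transform is applied to the whole frame."""
    mob_a = mobile[anchor_idx]
    ref_a = reference[anchor_idx]
    mob_c = mob_a.mean(axis=0)
    ref_c = ref_a.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_a - ref_c, mob_a - mob_c)
    return rot.apply(mobile - mob_c) + ref_c


def ligand_rmsd(traj: Trajectory, reference_frame: np.ndarray) -> RmsdSeries:
    """Ligand heavy-atom RMSD vs a reference frame, after protein-anchor
    superposition of every snapshot (no re-fitting on the ligand).

    The reference must share the trajectory's topology (full coordinate
    set).  Replicates are summarized at each time point by the median and
    one median absolute deviation.
    """
    reference_frame = np.asarray(reference_frame, dtype=float)
    if reference_frame.shape != (traj.n_atoms, 3):
        raise ValueError(
            f"reference frame has shape {reference_frame.shape}; expected "
            f"({traj.n_atoms}, 3)"
        )
    anchors = traj.topology.protein_indices
    lig = np.array(
        [i for i in traj.topology.ligand_indices if traj.topology.atoms[i].element != "H"],
        dtype=int,
    )
    rmsd = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        fitted = _superpose(traj.coords[i], reference_frame, anchors)
        diff = fitted[lig] - reference_frame[lig]
        rmsd[i] = np.sqrt((diff**2).sum(axis=1).mean())

    df = pd.DataFrame(
        {"replicate": traj.replicate_ids, "time": traj.times, "rmsd": rmsd}
    )
    wide = df.pivot_table(index="replicate", columns="time", values="rmsd")
    times = wide.columns.to_numpy(dtype=float)
    med = np.nanmedian(wide.to_numpy(), axis=0)
    mad = np.nanmedian(np.abs(wide.to_numpy() - med), axis=0)
    return RmsdSeries(times=times, per_replicate=wide, median=med, mad=mad)


@dataclass
class StabilityReport:
    """Time-averaged median RMSD comparison between two starting poses."""

    mean_median_a: float
    mean_median_b: float
    difference: float                  # a - b, Å
    more_stable: str                   # "A" | "B" | "tie"


def compare_pose_stability(series_a: RmsdSeries, series_b: RmsdSeries) -> StabilityReport:
    """Declare the pose with the lower time-averaged median RMSD more
    stable.  Descriptive only — no significance claim is attached."""
    if series_a.times.shape != series_b.times.shape or not np.allclose(
        series_a.times, series_b.times, atol=_TIME_TOL
    ):
        raise ValueError("RMSD series are on different time grids")
    ma = float(np.mean(series_a.median))
    mb = float(np.mean(series_b.median))
    diff = ma - mb
    verdict = "tie" if abs(diff) < 1e-12 else ("A" if diff < 0 else "B")
    return StabilityReport(
        mean_median_a=ma, mean_median_b=mb, difference=diff, more_stable=verdict
    )
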