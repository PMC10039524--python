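"""Eigenspectrum complexity (participation ratio), intrinsic dimension
(Levina-Bickel MLE), and distance-dependent correlation statistics.

The participation ratio of ranked eigenvalues ``l_1 >= ... >= l_N`` is

    PR = (sum l_i)^2 / sum l_i^2,

bounded between 1 (a single dominant mode) and the number of nonzero
eigenvalues (a flat spectrum), and invariant to rescaling the spectrum.

Four eigenspectrum conventions are supported, because PR values depend on
the matrix being decomposed:

* ``stacked-svd`` (default) — squared singular values of the k frames
  stacked row-wise into a (k * n_rows, n_cols) matrix; equivalently the
  eigenvalues of the column Gram pooled over snapshots. Bounded by the
  grid side (64), grows with snapshot count toward saturation, and scores
  a planar wave (a rank-2 image whose columns are scaled copies of one
  profile) near 1-2 regardless of frame count.
* ``spatial-svd-pooled`` — squared singular values of each snapshot image,
  pooled over frames; grows roughly linearly with the frames pooled.
* ``channel-covariance`` — eigenvalues of the channels x channels
  covariance across frames; the only convention defined on arbitrary
  channel subsets, hence used for channel-subsampling analyses.
* ``snapshot-gram`` — eigenvalues of the frames x frames Gram matrix.

Every result records the mode it came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .containers import ElectrodeLayout, SnapshotStack

__all__ = [
    "EigenSpectrum",
    "ComplexityResult",
    "CorrelationResult",
    "RegressionSummary",
    "TTestResult",
    "eigenspectrum",
    "participation_ratio",
    "normalized_pr",
    "pr_of_stack",
    "pr_vs_channel_count",
    "pr_vs_snapshot_count",
    "pr_noise_sweep",
    "lbmle_dimension",
    "stack_to_points",
    "pairwise_correlations",
    "mean_correlation_matrix",
    "correlation_vs_distance",
    "compare_conditions",
]

MODES = ("stacked-svd", "spatial-svd-pooled", "channel-covariance",
         "snapshot-gram")

DEFAULT_MODE = "stacked-svd"


@dataclass
class EigenSpectrum:
    """Ranked non-negative eigenvalues with their provenance."""

    eigenvalues: np.ndarray
    mode: str
    n_channels: int
    n_snapshots: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        ev = np.clip(ev, 0.0, None)          # clip numerical negatives
        self.eigenvalues = np.sort(ev)[::-1]

    @property
    def n_nonzero(self) -> int:
        tol = self.eigenvalues.max() * 1e-12 if self.eigenvalues.size else 0.0
        return int((self.eigenvalues > tol).sum())


@dataclass
class ComplexityResult:
    """Participation ratio with its normalizations and provenance."""

    pr: float
    mode: str
    n_channels: int
    n_snapshots: int
    label: str = ""

    @property
    def pr_per_sqrt_channels(self) -> float:
        return self.pr / np.sqrt(self.n_channels)

    @property
    def pr_per_sqrt_snapshots(self) -> float:
        return self.pr / np.sqrt(self.n_snapshots)


def eigenspectrum(snapshots: SnapshotStack | np.ndarray,
                  mode: str = DEFAULT_MODE) -> EigenSpectrum:
    """Ranked eigenvalues of a snapshot stack under the requested convention."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    frames = snapshots.frames if isinstance(snapshots, SnapshotStack) else np.asarray(snapshots)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("empty snapshot stack")
    k = frames.shape[0]
    n_channels = frames.shape[1] * frames.shape[2]

    if mode == "stacked-svd":
        stacked = frames.reshape(-1, frames.shape[2]).astype(np.float64)
        s = np.linalg.svd(stacked, compute_uv=False)
        ev = s * s
    elif mode == "spatial-svd-pooled":
        vals = []
        for f in frames:
            s = np.linalg.svd(f.astype(np.float64), compute_uv=False)
            vals.append(s * s)
        ev = np.concatenate(vals)
    elif mode == "channel-covariance":
        x = frames.reshape(k, -1).astype(np.float64)       # (k, channels)
        x = x - x.mean(axis=0, keepdims=True)
        s = np.linalg.svd(x, compute_uv=False)
        ev = (s * s) / max(k - 1, 1)
    else:  # snapshot-gram
        x = frames.reshape(k, -1).astype(np.float64)
        ev = np.linalg.eigvalsh(x @ x.T)[::-1]
    return EigenSpectrum(ev, mode, n_channels, k)


def participation_ratio(spec: EigenSpectrum | np.ndarray,
                        label: str = "") -> ComplexityResult:
    """PR = (sum l)^2 / sum l^2 of a ranked eigenvalue spectrum."""
    if isinstance(spec, EigenSpectrum):
        ev, mode, n, k = spec.eigenvalues, spec.mode, spec.n_channels, spec.n_snapshots
    else:
        ev = np.clip(np.asarray(spec, dtype=float), 0.0, None)
        mode, n, k = "raw", ev.size, 1
    total = ev.sum()
    if total <= 0:
        raise ValueError("all-zero eigenvalue spectrum: PR undefined")
    pr = float(total * total / (ev * ev).sum())
    return ComplexityResult(pr, mode, n, k, label)


def normalized_pr(result: ComplexityResult, by: str = "channels") -> float:
    """PR scaled by sqrt(N) (channels) or sqrt(k) (snapshots)."""
    if by == "channels":
        return result.pr_per_sqrt_channels
    if by == "snapshots":
        return result.pr_per_sqrt_snapshots
    raise ValueError("by must be 'channels' or 'snapshots'")


def pr_of_stack(stack: SnapshotStack | np.ndarray,
                mode: str = DEFAULT_MODE, label: str = "") -> ComplexityResult:
    """Convenience: eigenspectrum + participation ratio in one call."""
    return participation_ratio(eigenspectrum(stack, mode), label=label)


# --------------------------------------------------------------------------
# scaling analyses
# --------------------------------------------------------------------------

def pr_vs_channel_count(stack: SnapshotStack, channel_counts,
                        reps: int = 10, seed: int = 0) -> "pd.DataFrame":
    """Mean PR over random channel subsets, per subset size.

    Uses channel-covariance mode (the only convention defined on arbitrary
    channel subsets). Returns a DataFrame with columns ``n_channels``,
    ``pr_mean``, ``pr_sd``, ``pr_per_sqrt_n``.
    """
    import pandas as pd

    x = stack.frames.reshape(stack.n_frames, -1).astype(np.float64)
    x = x - x.mean(axis=0, keepdims=True)
    n_total = x.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for count in channel_counts:
        count = int(count)
        if count < 2:
            raise ValueError("channel count must be >= 2")
        if count > n_total:
            raise ValueError(f"count {count} exceeds channel count {n_total}")
        prs = []
        for _ in range(reps):
            idx = rng.choice(n_total, size=count, replace=False)
            s = np.linalg.svd(x[:, idx], compute_uv=False)
            ev = s * s
            prs.append(float(ev.sum() ** 2 / (ev * ev).sum()))
        prs = np.asarray(prs)
        rows.append({"n_channels": count, "pr_mean": prs.mean(),
                     "pr_sd": prs.std(ddof=1) if reps > 1 else 0.0,
                     "pr_per_sqrt_n": prs.mean() / np.sqrt(count)})
    return pd.DataFrame(rows)


def pr_vs_snapshot_count(stack: SnapshotStack, ks,
                         mode: str = DEFAULT_MODE) -> "pd.DataFrame":
    """PR of evenly spaced k-frame subsets, per k, with sqrt(k) scaling."""
    import pandas as pd

    rows = []
    for k in ks:
        k = int(k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > stack.n_frames:
            raise ValueError(f"k={k} exceeds frame count {stack.n_frames}")
        idx = np.round(np.linspace(0, stack.n_frames - 1, k)).astype(int)
        res = pr_of_stack(stack.frames[idx], mode)
        rows.append({"k": k, "pr": res.pr, "pr_per_sqrt_k": res.pr / np.sqrt(k)})
    return pd.DataFrame(rows)


def pr_noise_sweep(stack: SnapshotStack, means, sds, reps: int = 5,
                   seed: int = 0, mode: str = DEFAULT_MODE) -> "pd.DataFrame":
    """PR after adding Gaussian noise, for each (mean, sd) setting."""
    import pandas as pd
    from .synthetic import add_gaussian_noise
    from .containers import derive_seed

    rows = []
    for mean in means:
        for sd in sds:
            prs = []
            for r in range(reps):
                if sd == 0 and mean == 0:
                    noisy = stack
                else:
                    noisy = add_gaussian_noise(
                        stack, mean, sd,
                        seed=derive_seed(seed, f"noise-{mean}-{sd}-{r}"))
                prs.append(pr_of_stack(noisy, mode).pr)
            prs = np.asarray(prs)
            rows.append({"mean": mean, "sd": sd, "pr_mean": prs.mean(),
                         "pr_sd": prs.std(ddof=1) if reps > 1 else 0.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Levina-Bickel intrinsic dimension
# --------------------------------------------------------------------------

def lbmle_dimension(points: np.ndarray, k_min: int = 5, k_max: int = 15) -> float:
    """Levina-Bickel maximum-likelihood intrinsic dimension estimate.

    For each point, the local estimate at neighborhood size k is the
    inverse mean log ratio of the k-th nearest-neighbor distance to the
    j-th (j < k), with the bias-corrected normalizer 1/(k - 2) (the
    uncorrected 1/(k - 1) maximum-likelihood form overestimates by
    (k - 1)/(k - 2) under a Poisson sampling model). Estimates are averaged
    over points, then over k in [k_min, k_max]. Exact duplicate points are
    collapsed first (their zero distances would make the log ratios
    undefined). The estimate is invariant to global isotropic rescaling of
    the cloud.
    """
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    n = pts.shape[0]
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    if n < k_max + 1:
        raise ValueError(f"need at least k_max+1={k_max + 1} distinct points, got {n}")

    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(pts)
    dist, _ = nn.kneighbors(pts)          # dist[:, 0] == 0 (self)
    dist = dist[:, 1:]                    # (n, k_max)
    tiny = np.finfo(float).tiny
    logd = np.log(np.maximum(dist, tiny))

    estimates = []
    for k in range(k_min, k_max + 1):
        # sum over j<k of log(T_k / T_j) per point, with 1/(k-2) correction
        sum_log_ratio = (k - 1) * logd[:, k - 1] - logd[:, : k - 1].sum(axis=1)
        sum_log_ratio = np.maximum(sum_log_ratio, 1e-12)
        estimates.append(np.mean((k - 2) / sum_log_ratio))
    return float(np.mean(estimates))


def stack_to_points(stack: SnapshotStack, frame_step: int = 25) -> np.ndarray:
    """Flatten every ``frame_step``-th frame into a point cloud.

    Subsampling in time decorrelates consecutive points so nearest
    neighbors reflect the geometry of the state distribution rather than
    adjacency along the trajectory.
    """
    return stack.frames[::frame_step].reshape(-1, stack.frames.shape[1]
                                              * stack.frames.shape[2]).astype(np.float64)


# --------------------------------------------------------------------------
# correlation structure
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations between channel time series."""

    matrix: np.ndarray                 # (n, n), NaN where undefined
    layout: ElectrodeLayout
    channel_indices: np.ndarray        # flat channel ids in the full layout
    n_frames: int = 0

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    p_value: float
    bin_centers_um: np.ndarray
    bin_means: np.ndarray
    bin_sems: np.ndarray


@dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    degenerate: bool = False


def pairwise_correlations(stack: SnapshotStack, channel_step: int = 1,
                          channels: np.ndarray | None = None) -> CorrelationResult:
    """Pearson correlation between per-channel time series within a stack.

    ``channel_step`` keeps every step-th row and column of the grid (a
    regular spatial subsample) to bound the matrix size; alternatively an
    explicit array of flat ``channels`` indices may be given. Zero-variance
    channels yield NaN rows/columns (recorded as missing).
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames for correlations")
    full = stack.layout
    flat = stack.frames.reshape(stack.n_frames, -1)
    if channels is not None:
        chan = np.asarray(channels, dtype=int)
        x = flat[:, chan].astype(np.float64).T                    # (ch, t)
    else:
        frames = stack.frames[:, ::channel_step, ::channel_step]
        n_rows, n_cols = frames.shape[1], frames.shape[2]
        x = frames.reshape(stack.n_frames, -1).astype(np.float64).T
        rows = np.arange(0, full.n_rows, channel_step)[:n_rows]
        cols = np.arange(0, full.n_cols, channel_step)[:n_cols]
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        chan = (rr * full.n_cols + cc).ravel()

    sd = x.std(axis=1)
    valid = sd > 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mat = np.corrcoef(x)
    mat[~valid, :] = np.nan
    mat[:, ~valid] = np.nan
    np.fill_diagonal(mat, np.where(valid, 1.0, np.nan))
    return CorrelationResult(mat, full, chan, stack.n_frames)


def mean_correlation_matrix(results) -> CorrelationResult:
    """Elementwise average of per-event correlation matrices (NaN-aware)."""
    results = list(results)
    if not results:
        raise ValueError("no correlation matrices to average")
    ref = results[0]
    for r in results[1:]:
        if r.matrix.shape != ref.matrix.shape or not np.array_equal(
                r.channel_indices, ref.channel_indices):
            raise ValueError("correlation matrices must share channel sets")
    stackmat = np.stack([r.matrix for r in results])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stackmat, axis=0)
    return CorrelationResult(mean, ref.layout, ref.channel_indices,
                             sum(r.n_frames for r in results))


def correlation_vs_distance(corr: CorrelationResult,
                            layout: ElectrodeLayout | None = None,
                            n_bins: int = 20,
                            center=None) -> RegressionSummary:
    """Binned correlation vs electrode distance plus a linear fit.

    Pair distances (um) are binned into ``n_bins`` equal-width bins; a line
    is fit to (bin center, bin mean correlation). If ``center`` is given
    (a (row, col) 1-based coordinate or CenterOfMass), only pairs formed by
    the center-nearest electrode and every other electrode are used (the
    center-referenced variant). Empty bins are dropped.
    """
    layout = layout or corr.layout
    pos = layout.positions_um()[corr.channel_indices]
    mat = corr.matrix

    if center is not None:
        r = getattr(center, "r", None)
        if r is None:
            r, c = center
        else:
            c = center.c
        target = np.array([(c - 1) * layout.pitch_um, (r - 1) * layout.pitch_um])
        i0 = int(np.argmin(((pos - target) ** 2).sum(axis=1)))
        others = np.arange(mat.shape[0]) != i0
        dists = np.sqrt(((pos[others] - pos[i0]) ** 2).sum(axis=1))
        corrs = mat[i0, others]
    else:
        iu, ju = np.triu_indices(mat.shape[0], k=1)
        diff = pos[iu] - pos[ju]
        dists = np.sqrt((diff ** 2).sum(axis=1))
        corrs = mat[iu, ju]

    ok = np.isfinite(corrs)
    dists, corrs = dists[ok], corrs[ok]
    if dists.size < 2:
        raise ValueError("not enough defined correlation pairs")

    edges = np.linspace(dists.min(), dists.max(), n_bins + 1)
    which = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
    centers, means, sems = [], [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(corrs[sel].mean())
        sems.append(corrs[sel].std(ddof=1) / np.sqrt(sel.sum()) if sel.sum() > 1 else 0.0)
    centers, means = np.asarray(centers), np.asarray(means)
    if centers.size < 3:
        raise ValueError("too few populated distance bins for a regression")
    fit = stats.linregress(centers, means)
    return RegressionSummary(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue ** 2), float(fit.pvalue),
                             centers, means, np.asarray(sems))


def compare_conditions(prs_a, prs_b) -> TTestResult:
    """Two-sample Student's t-test (pooled variance) between PR samples."""
    a = np.asarray(list(prs_a), dtype=float)
    b = np.asarray(list(prs_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and np.allclose(a.mean(), b.mean()):
        return TTestResult(0.0, a.size + b.size - 2, 1.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), a.size + b.size - 2, float(p),
                       degenerate=degenerate)
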