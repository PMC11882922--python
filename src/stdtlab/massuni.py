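"""Mass-univariate inference on scalp-space volumes.

First level: per-trial volumes are regressed on the two percept indicators;
without further regressors the contrast of the two betas equals the
difference of condition-mean ERPs exactly. Second level: a one-sample t-test
across subjects on the contrast volumes, with mean-centered covariates (the
participant STDT in the main analysis). Family-wise error over the
32 x 32 x 359 scalp-time volume is controlled by a max-statistic sign-flip
permutation scheme: subject contrasts are residualized against the
covariates, residuals are sign-flipped, and the null distributions of the
maximum cluster extent and maximum peak t are accumulated. Clusters are
face-connected (6-connectivity) components of the map thresholded at the
cluster-defining level (one-tailed p < 0.001 by default, direction
"felt as two" > "felt as one").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ClusterResult",
    "GroupResult",
    "first_level",
    "second_level",
    "find_clusters",
    "cluster_fwe",
    "median_split_analysis",
    "run_covariate_variant",
]

_FACES = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ClusterResult:
    """One supra-threshold connected component of a t-volume."""

    voxels: np.ndarray  # (k, 3) int indices (x, y, time)
    extent_k: int
    time_span_ms: tuple[float, float]
    peak_xy: tuple[int, int]
    peak_time_ms: float
    peak_t: float
    p_fwe_cluster: float = float("nan")
    p_fwe_peak: float = float("nan")


@dataclass
class GroupResult:
    """Second-level t-volume with its permutation-corrected clusters."""

    t_volume: np.ndarray
    df: int
    clusters: list[ClusterResult]
    null_max_extent: np.ndarray | None = None
    null_max_t: np.ndarray | None = None
    n_perm: int = 0

    @property
    def significant(self) -> list[ClusterResult]:
        return [c for c in self.clusters if c.p_fwe_cluster < 0.05]


def first_level(trial_volumes: np.ndarray, percepts: np.ndarray) -> np.ndarray:
    """Percept contrast for one subject: beta_two - beta_one.

    ``trial_volumes`` is (trials, ...); ``percepts`` holds "one"/"two" labels.
    Regression on the two condition indicators has the closed-form solution
    beta_c = condition mean, so the contrast is computed as the difference of
    condition means — the exact equivalence tests assert this against an
    explicit least-squares solve.
    """
    percepts = np.asarray(percepts)
    two = percepts == "two"
    one = percepts == "one"
    if not two.any() or not one.any():
        raise ValueError(
            f"need >= 1 trial per condition (got {int(one.sum())} 'one', "
            f"{int(two.sum())} 'two')"
        )
    return trial_volumes[two].mean(axis=0) - trial_volumes[one].mean(axis=0)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate length must match subject count")
        if not np.all(np.isfinite(C)):
            raise ValueError("covariates must be finite")
        keep = []
        for j in range(C.shape[1]):
            col = C[:, j] - C[:, j].mean()
            if np.allclose(col, 0):
                warnings.warn(
                    "constant covariate dropped; falling back to a simple t-test",
                    stacklevel=3,
                )
            else:
                keep.append(col)
        if keep:
            X = np.column_stack([X] + keep)
    return X


def second_level(
    contrasts: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """One-tailed group t-statistic for the intercept at every voxel.

    ``contrasts`` is (subjects, ...). Covariates are mean-centered, so the
    intercept estimate is the covariate-adjusted group mean; the t-map is
    invariant to adding constants to any covariate. Returns ``(t, df)`` with
    ``df = n - 1 - n_covariates``.
    """
    n = contrasts.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")
    X = _design(n, covariates)
    p = X.shape[1]
    df = n - p
    shape = contrasts.shape[1:]
    Y = contrasts.reshape(n, -1)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / np.sqrt(sigma2 * XtX_inv[0, 0])
    t[~np.isfinite(t)] = 0.0
    return t.reshape(shape), df


def find_clusters(
    t_volume: np.ndarray,
    df: int,
    times_ms: np.ndarray,
    mask: np.ndarray | None = None,
    cluster_alpha: float = 0.001,
    tail: str = "greater",
) -> list[ClusterResult]:
    """Face-connected supra-threshold clusters of a (nx, ny, samples) t-volume.

    Voxels with one-tailed p < ``cluster_alpha`` (or |t| exceeding the
    two-tailed threshold with ``tail='two-sided'``) are binarized; connected
    components use 6-connectivity, so voxels sharing only an edge or corner
    belong to different clusters. Results are sorted by extent, largest first.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if tail == "greater":
        t_crit = stats.t.isf(cluster_alpha, df)
        supra = t_volume > t_crit
    elif tail == "two-sided":
        t_crit = stats.t.isf(cluster_alpha / 2, df)
        supra = np.abs(t_volume) > t_crit
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if mask is not None:
        supra = supra & mask[:, :, None]
    supra = np.nan_to_num(supra, nan=False) if supra.dtype != bool else supra
    labels, n_lab = ndimage.label(supra, structure=_FACES)
    clusters: list[ClusterResult] = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        tvals = t_volume[vox[:, 0], vox[:, 1], vox[:, 2]]
        peak = int(np.argmax(np.abs(tvals)))
        tsel = vox[:, 2]
        clusters.append(
            ClusterResult(
                voxels=vox,
                extent_k=vox.shape[0],
                time_span_ms=(float(times_ms[tsel.min()]), float(times_ms[tsel.max()])),
                peak_xy=(int(vox[peak, 0]), int(vox[peak, 1])),
                peak_time_ms=float(times_ms[vox[peak, 2]]),
                peak_t=float(tvals[peak]),
            )
        )
    clusters.sort(key=lambda c: -c.extent_k)
    return clusters


def _masked_matrix(contrasts: np.ndarray, mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (subjects, nx, ny, ns) to (subjects, voxels) over the mask."""
    n = contrasts.shape[0]
    nx, ny, ns = contrasts.shape[1:]
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)
    mask3d = np.broadcast_to(mask[:, :, None], (nx, ny, ns))
    Y = contrasts.reshape(n, -1)[:, mask3d.ravel()]
    return np.nan_to_num(Y, nan=0.0), mask3d


def cluster_fwe(
    contrasts: np.ndarray,
    covariates: np.ndarray | None,
    times_ms: np.ndarray,
    mask: np.ndarray | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.001,
    rng: np.random.Generator | None = None,
    tail: str = "greater",
    _chunk: int = 50,
) -> GroupResult:
    """Group inference with max-statistic permutation FWE correction.

    Sign-flipping requires a reasonably symmetric null; with fewer than 8
    subjects the 2^n flip space is too coarse for stable tail estimates, so
    the subject count is enforced. ``p_fwe_cluster`` of each observed cluster
    is ``(1 + #{null max extent >= k}) / (1 + n_perm)``; ``p_fwe_peak``
    analogously against the null max t. Deterministic given ``rng``.
    """
    n = contrasts.shape[0]
    if n < 8:
        raise ValueError("need >= 8 subjects for meaningful sign-flipping")
    if n_perm < 20:
        raise ValueError("n_perm < 20 cannot resolve any tail")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse FWE p-values", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng()
    nx, ny, ns = contrasts.shape[1:]
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)

    t_obs, df = second_level(contrasts, covariates)
    t_obs = np.where(mask[:, :, None], t_obs, np.nan)
    observed = find_clusters(
        np.nan_to_num(t_obs, nan=0.0), df, times_ms, mask=mask,
        cluster_alpha=cluster_alpha, tail=tail,
    )

    Y, mask3d = _masked_matrix(contrasts, mask)
    X = _design(n, covariates)
    Xc = X[:, 1:]  # centered covariate columns
    k = Xc.shape[1]
    if k:
        B = np.linalg.solve(Xc.T @ Xc, Xc.T @ Y)
        R = Y - Xc @ B
        G = np.linalg.inv(Xc.T @ Xc)
    else:
        R = Y
    if tail == "greater":
        t_crit = stats.t.isf(cluster_alpha, df)
    else:
        t_crit = stats.t.isf(cluster_alpha / 2, df)

    # Permutation pass in float32 on squared t-ratios: with M = sum_i s_i r_i,
    # t = M sqrt(df / (n rss)), so "t > t_crit" is "M^2 / rss > t_crit^2 n/df"
    # (restricted to M > 0 for the one-tailed case). Only the supra-threshold
    # mask and the maximum statistic are needed per permutation.
    R32 = np.ascontiguousarray(R, dtype=np.float32)
    Xc32 = Xc.astype(np.float32)
    ssq32 = np.einsum("ij,ij->j", R32, R32)
    ratio_crit = np.float32(t_crit**2 * n / df)
    null_ext = np.zeros(n_perm, dtype=int)
    null_t = np.zeros(n_perm)
    vol = np.zeros((nx, ny, ns), dtype=bool)
    flat_mask = mask3d.ravel()
    done = 0
    while done < n_perm:
        m = min(_chunk, n_perm - done)
        F = rng.choice(np.array([-1.0, 1.0], dtype=np.float32), size=(m, n))
        M = F @ R32
        rss = np.square(M)
        ratio = rss.copy()  # holds M^2 for now
        rss /= np.float32(-n)
        rss += ssq32[None, :]
        if k:
            for j in range(k):
                qj = (F * Xc32[:, j][None, :]) @ R32
                rss -= np.float32(G[j, j]) * np.square(qj)
                for l in range(j + 1, k):
                    ql = (F * Xc32[:, l][None, :]) @ R32
                    rss -= np.float32(2.0 * G[j, l]) * qj * ql
        np.maximum(rss, np.float32(1e-20), out=rss)
        ratio /= rss  # M^2 / rss
        if tail == "greater":
            np.multiply(ratio, M > 0, out=ratio)
        for i in range(m):
            row = ratio[i]
            null_t[done + i] = float(np.sqrt(row.max() * df / n))
            supra = row > ratio_crit
            if supra.any():
                vol.ravel()[flat_mask] = supra
                labels, n_lab = ndimage.label(vol, structure=_FACES)
                if n_lab:
                    null_ext[done + i] = np.bincount(labels.ravel())[1:].max()
                vol[:] = False
        done += m

    for c in observed:
        c.p_fwe_cluster = float((1 + np.sum(null_ext >= c.extent_k)) / (1 + n_perm))
        c.p_fwe_peak = float((1 + np.sum(null_t >= c.peak_t)) / (1 + n_perm))
    return GroupResult(
        t_volume=t_obs,
        df=df,
        clusters=observed,
        null_max_extent=null_ext,
        null_max_t=null_t,
        n_perm=n_perm,
    )


def median_split_analysis(
    contrasts: np.ndarray,
    stdts: np.ndarray,
    times_ms: np.ndarray,
    split_ms: float = 30.0,
    mask: np.ndarray | None = None,
    **fwe_kwargs,
) -> dict[str, GroupResult]:
    """Independent cluster analyses for low- and high-threshold subgroups.

    Subjects with STDT below (or equal to) ``split_ms`` form the "low" group,
    the rest the "high" group; each subgroup is analyzed with its own STDT
    covariate.
    """
    stdts = np.asarray(stdts, dtype=float)
    low = stdts <= split_ms
    high = ~low
    if low.sum() < 4 or high.sum() < 4:
        raise ValueError(
            f"need >= 4 subjects per subgroup (got {int(low.sum())} low, "
            f"{int(high.sum())} high at split {split_ms} ms)"
        )
    out = {}
    for name, sel in (("low", low), ("high", high)):
        out[name] = cluster_fwe(
            contrasts[sel], stdts[sel], times_ms, mask=mask, **fwe_kwargs
        )
    return out


def run_covariate_variant(
    contrasts: np.ndarray,
    stdts: np.ndarray,
    run_drift: np.ndarray,
    times_ms: np.ndarray,
    mask: np.ndarray | None = None,
    **fwe_kwargs,
) -> GroupResult:
    """Main analysis augmented with a run-drift covariate.

    ``run_drift`` is a subject-level summary of how the near-threshold ISI
    level moved across runs (e.g. the SD of the selected level); it enters the
    second-level model alongside the STDT, mean-centered, leaving the
    inference path otherwise unchanged.
    """
    stdts = np.asarray(stdts, dtype=float)
    run_drift = np.asarray(run_drift, dtype=float)
    if run_drift.shape[0] != contrasts.shape[0]:
        raise ValueError("run_drift must provide one value per subject")
    cov = np.column_stack([stdts, run_drift])
    return cluster_fwe(contrasts, cov, times_ms, mask=mask, **fwe_kwargs)
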