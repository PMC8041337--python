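"""Voxel-wise structure-function GLM with cluster-permutation inference.

The central statistic of the package: at every voxel v, coherence
across observations is regressed on tract density at that same voxel,

    coherence_i(v) = b0(v) + b1(v) * density_i(v) + e_i(v),

so the design matrix is voxel-specific rather than shared across the
brain as in the classical mass-univariate GLM.  The slope is tested
with an F statistic on (1, n-2) degrees of freedom.  Significance is
assessed with a cluster-based permutation test: voxels exceeding the
F quantile at the cluster-forming threshold are grouped by
26-connectivity, and the family-wise-error p-value of each cluster is
the fraction of permutations (coherence observations shuffled against
density observations, the same shuffle at every voxel to preserve
spatial correlation) whose maximal cluster size reaches the observed
size.

The module also provides the generic OLS contrast engine used by the
tract-density ANOVA, and the F upper-tail utility that maps the
directionality test statistics to p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import f as f_dist

from .containers import VolumeImage

__all__ = [
    "f_tail_p",
    "glm_contrast_stats",
    "voxelwise_slope_f",
    "permute_within_subject",
    "ClusterResult",
    "StructureFunctionModel",
    "StructureFunctionResults",
]

#: 26-connectivity structuring element for 3D cluster labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: F value assigned to exact-fit voxels (residual sum of squares ~ 0)
F_EXACT_FIT = np.finfo(np.float64).max / 4.0


def f_tail_p(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the central F distribution.

    ``P(F_{df1,df2} >= F)``; the mapping between a reported F statistic
    and its p-value.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("F must be nonnegative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    out = f_dist.sf(F, df1, df2)
    return float(out) if out.ndim == 0 else out


def glm_contrast_stats(Y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Mass-univariate OLS contrast F (and t for 1-row contrasts).

    Parameters
    ----------
    Y : ndarray, shape (n, v)
        One column per voxel.
    X : ndarray, shape (n, p)
        Shared design matrix, full rank.
    C : ndarray, shape (q, p)
        Contrast matrix.

    Returns
    -------
    F : ndarray (v,), t : ndarray (v,) or None, df : (q, n - p)
    """
    n, p = X.shape
    q = C.shape[0]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y          # (p, v)
    resid = Y - X @ beta
    rss = np.einsum("nv,nv->v", resid, resid)
    df2 = n - p
    sigma2 = rss / df2
    cb = C @ beta                      # (q, v)
    M = C @ XtX_inv @ C.T              # (q, q)
    Minv = np.linalg.inv(M)
    quad = np.einsum("qv,qr,rv->v", cb, Minv, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = quad / q / sigma2
    F = np.where(sigma2 <= 0, np.where(quad > 0, F_EXACT_FIT, 0.0), F)
    t = None
    if q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = cb[0] / np.sqrt(M[0, 0] * sigma2)
        t = np.where(sigma2 <= 0, np.sign(cb[0]) * np.sqrt(F_EXACT_FIT), t)
    return F, t, (q, df2)


def voxelwise_slope_f(dependent: np.ndarray, regressor: np.ndarray):
    """Simple-regression slope F at every voxel, voxel-specific design.

    Parameters
    ----------
    dependent, regressor : ndarray, shape (n, v)
        Per-observation images flattened to columns; at voxel v the
        dependent column is regressed on ``[1, regressor[:, v]]``.

    Returns
    -------
    F : ndarray (v,)
        Slope F statistic, df (1, n-2); ``F_EXACT_FIT`` where the fit
        is exact, NaN where the regressor has zero variance.
    beta : ndarray (v,)
        Slope estimate (NaN where undefined).
    defined : ndarray (v,), bool
    exact : ndarray (v,), bool
    """
    y = np.asarray(dependent, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("dependent and regressor must have the same shape")
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    xm = x - x.mean(axis=0)
    ym = y - y.mean(axis=0)
    sxx = np.einsum("nv,nv->v", xm, xm)
    sxy = np.einsum("nv,nv->v", xm, ym)
    syy = np.einsum("nv,nv->v", ym, ym)
    scale = np.maximum(np.max(np.abs(x), axis=0) ** 2, 1.0)
    defined = sxx > 1e-12 * scale * n
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(defined, sxy / sxx, np.nan)
        ssr = np.where(defined, sxy ** 2 / sxx, 0.0)
    rss = np.maximum(syy - ssr, 0.0)
    exact = defined & (rss <= 1e-10 * np.maximum(syy, 1e-300)) & (ssr > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (n - 2) * ssr / rss
    F = np.where(exact, F_EXACT_FIT, F)
    F = np.where(defined & (ssr == 0), 0.0, F)
    F = np.where(defined, F, np.nan)
    return F, beta, defined, exact


def permute_within_subject(subjects: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Random permutation of observation indices within each subject."""
    subjects = np.asarray(subjects)
    perm = np.arange(subjects.size)
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def _cluster_sizes(stat3d: np.ndarray, threshold: float):
    """Label suprathreshold clusters (26-connectivity); NaN excluded."""
    sup = np.isfinite(stat3d) & (stat3d > threshold)
    labels, n = ndimage.label(sup, structure=_CONN26)
    if n == 0:
        return labels.astype(np.int16), np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels.astype(np.int16), sizes


@dataclass
class ClusterResult:
    """Suprathreshold clusters with permutation-FWE p-values.

    ``labels`` assigns each voxel its cluster id (0 = background);
    cluster ``i`` (1-based label) has ``sizes[i-1]`` voxels and
    family-wise-error p-value ``p_fwe[i-1]`` (the identity permutation
    is always included, so p >= 1/(1+n_perm)).
    """

    labels: VolumeImage
    sizes: np.ndarray
    p_fwe: np.ndarray
    forming_threshold: float
    forming_p: float
    n_perm: int
    df: tuple
    peak_F: np.ndarray = field(default=None)
    peak_world: np.ndarray = field(default=None)

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """1-based labels of clusters with FWE p < alpha."""
        return np.flatnonzero(self.p_fwe < alpha) + 1

    def table(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_clusters):
            row = dict(label=i + 1, size=int(self.sizes[i]),
                       p_fwe=float(self.p_fwe[i]))
            if self.peak_F is not None:
                row["peak_F"] = float(self.peak_F[i])
                row["peak_x"], row["peak_y"], row["peak_z"] = (
                    float(c) for c in self.peak_world[i]
                )
            rows.append(row)
        return pd.DataFrame(rows)


class StructureFunctionModel:
    """Voxel-wise GLM: does tract density predict coherence?

    statsmodels-style model object: construct from per-observation
    coherence images (dependent variable) and tract-density images
    (voxel-specific regressor), then :meth:`fit`.

    Parameters
    ----------
    coherence_imgs : sequence of VolumeImage
        Per-observation coherence images (NaN outside the brain mask).
    density_imgs : sequence of VolumeImage
        Per-observation tract-density images, co-registered with the
        coherence images.
    mask : VolumeImage, optional
        Analysis mask; defaults to voxels where every coherence image
        is finite.  Voxels with zero density variance across
        observations are additionally excluded (their voxel-specific
        design is rank-deficient).
    fisher_z : bool
        If True, coherence enters as arctanh(sqrt(coherence)).
        Off by default.
    """

    def __init__(self, coherence_imgs, density_imgs,
                 mask: VolumeImage = None, fisher_z: bool = False):
        if len(coherence_imgs) != len(density_imgs):
            raise ValueError("need matching numbers of images")
        if len(coherence_imgs) < 4:
            raise ValueError("need at least 4 observations")
        ref = coherence_imgs[0]
        for img in list(coherence_imgs) + list(density_imgs):
            if not ref.same_space(img):
                raise ValueError(
                    "images are not co-registered (shape/affine mismatch)"
                )
        self.ref = ref
        self.n_obs = len(coherence_imgs)
        coh = np.stack([np.asarray(im.data, dtype=float).ravel()
                        for im in coherence_imgs])
        if fisher_z:
            coh = np.arctanh(np.sqrt(np.clip(coh, 0.0, 1.0 - 1e-12)))
        self.coh = coh
        self.dens = np.stack([np.asarray(im.data, dtype=float).ravel()
                              for im in density_imgs])
        finite = np.all(np.isfinite(self.coh), axis=0)
        finite &= np.all(np.isfinite(self.dens), axis=0)
        if mask is not None:
            if not ref.same_space(mask):
                raise ValueError("mask is not co-registered with the images")
            finite &= np.asarray(mask.data).ravel() > 0
        self.mask_flat = finite
        if self.dens[:, finite].size and np.all(
            self.dens[:, finite].var(axis=0) == 0
        ):
            raise ValueError(
                "density has zero variance at every masked voxel; the "
                "voxel-specific design is everywhere rank-deficient"
            )

    @property
    def df(self) -> tuple:
        return (1, self.n_obs - 2)

    def fit(self) -> "StructureFunctionResults":
        """OLS fit at every masked voxel; returns results with F and
        slope images and cluster-permutation inference on demand."""
        coh = np.where(self.mask_flat[None, :], self.coh, 0.0)
        dens = np.where(self.mask_flat[None, :], self.dens, 0.0)
        F, beta, defined, exact = voxelwise_slope_f(coh, dens)
        keep = self.mask_flat & defined
        F = np.where(keep, F, np.nan)
        beta = np.where(keep, beta, np.nan)
        return StructureFunctionResults(self, F, beta, keep, exact & keep)


class StructureFunctionResults:
    """Estimates and inference for :class:`StructureFunctionModel`."""

    def __init__(self, model, F_flat, beta_flat, defined_flat, exact_flat):
        self.model = model
        self._F = F_flat
        self._beta = beta_flat
        self._defined = defined_flat
        self._exact = exact_flat
        self.df = model.df

    @property
    def F_image(self) -> VolumeImage:
        return self.model.ref.copy_with(self._F.reshape(self.model.ref.shape))

    @property
    def beta_image(self) -> VolumeImage:
        return self.model.ref.copy_with(
            self._beta.reshape(self.model.ref.shape)
        )

    @property
    def exact_fit_image(self) -> VolumeImage:
        return self.model.ref.copy_with(
            self._exact.reshape(self.model.ref.shape).astype(np.int16)
        )

    @property
    def n_defined(self) -> int:
        return int(self._defined.sum())

    def cluster_permutation(self, forming_p: float = 0.01,
                            n_perm: int = 1000, seed: int = 0) -> ClusterResult:
        """Cluster-based permutation FWE inference on the F image.

        Coherence observations are shuffled against density
        observations (one shuffle per permutation, applied at every
        voxel); the null distribution is that of the maximal
        suprathreshold cluster size.
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0.0 < forming_p < 1.0:
            raise ValueError("forming_p must be in (0, 1)")
        model = self.model
        thr = float(f_dist.isf(forming_p, *self.df))
        shape = model.ref.shape
        labels, sizes = _cluster_sizes(self._F.reshape(shape), thr)

        rng = np.random.default_rng(seed)
        keep = self._defined
        coh = model.coh[:, keep]
        dens = model.dens[:, keep]
        F_full = np.full(self._F.size, np.nan)
        max_null = np.zeros(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(model.n_obs)
            Fp, _, _, _ = voxelwise_slope_f(coh[perm], dens)
            F_full[keep] = Fp
            _, s = _cluster_sizes(F_full.reshape(shape), thr)
            max_null[b] = s.max() if s.size else 0
        p_fwe = np.array([
            (1.0 + np.sum(max_null >= sz)) / (1.0 + n_perm) for sz in sizes
        ])
        peak_F = np.zeros(sizes.size)
        peak_world = np.zeros((sizes.size, 3))
        F3 = self._F.reshape(shape)
        for i in range(sizes.size):
            in_cl = labels == i + 1
            vals = np.where(in_cl, F3, -np.inf)
            ijk = np.unravel_index(np.nanargmax(vals), shape)
            peak_F[i] = F3[ijk]
            peak_world[i] = model.ref.voxel_to_world(np.asarray(ijk, float))
        return ClusterResult(
            labels=model.ref.copy_with(labels), sizes=sizes, p_fwe=p_fwe,
            forming_threshold=thr, forming_p=forming_p, n_perm=n_perm,
            df=self.df, peak_F=peak_F, peak_world=peak_world,
        )

    def summary(self) -> str:
        F = self._F[self._defined]
        lines = [
            "Voxel-wise structure-function GLM",
            "=================================",
            f"observations:      {self.model.n_obs}",
            f"defined voxels:    {self.n_defined}",
            f"slope F df:        {self.df}",
        ]
        if F.size:
            peak = np.nanmax(F)
            lines.append(f"peak F:            {peak:.3f} "
                         f"(p = {f_tail_p(min(peak, 1e300), *self.df):.4g})")
            lines.append(f"exact-fit voxels:  {int(self._exact.sum())}")
        return "\n".join(lines)
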