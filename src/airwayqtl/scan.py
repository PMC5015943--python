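"""Additive 8-founder haplotype-dosage regression genome scan.

At every marker interval the (transformed) phenotype is regressed on the
mouse-by-founder dosage matrix plus an intercept, and evidence for a QTL
is summarised as a LOD score

    LOD = (n/2) * log10(RSS_null / RSS_marker)

where RSS_null is the intercept-only residual sum of squares — the
Gaussian maximum-likelihood LOD. Because the eight dosage columns sum to
2 in every row the design is exactly collinear with the intercept; the
regression is solved through an orthonormal column basis (SVD), which
fixes RSS (and hence the LOD) without dropping an arbitrary founder.

Genome-wide significance is calibrated by permuting the phenotype vector
over mice and recording the genome-wide maximum LOD of each permutation
scan; support intervals use the 1.5-LOD drop rule; the variance explained
by a QTL is the R-squared of the peak-locus regression, and allele effects
are reported both as centred regression coefficients and as phenotype
means of founder-homozygous mice.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .founders import FOUNDERS, N_FOUNDERS
from .genome import FounderDosageMap

#: RSS floor, as a fraction of the null RSS, keeping a perfect fit's LOD finite
_RSS_FLOOR = 1e-12

DEFAULT_QUANTILES = (0.95, 0.80)
DEFAULT_LOD_DROP = 1.5
DEFAULT_HOMOZYGOTE_CUTOFF = 1.8
MIN_N = 11


def collapse_intervals(dmap: FounderDosageMap, tol: float = 1e-9) -> FounderDosageMap:
    """Merge runs of markers with (numerically) identical dosage matrices.

    Maximal runs of consecutive same-chromosome markers whose matrices are
    pairwise equal within ``tol`` become one interval whose matrix is the
    element-wise average and whose position is the run midpoint. This is
    the standard reduction of a dense SNP map to recombination intervals.
    """
    markers = dmap.markers
    new_rows = []
    new_mats = []
    k = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        run_start = 0
        i = 1
        while run_start < len(idx):
            while i < len(idx) and np.max(
                np.abs(dmap.dosages[idx[i]] - dmap.dosages[idx[i - 1]])
            ) <= tol:
                i += 1
            run = idx[run_start:i]
            pos = markers.loc[run, "pos_mb"].to_numpy()
            new_rows.append(
                (f"{chrom}_iv{k:05d}", chrom, float((pos[0] + pos[-1]) / 2.0))
            )
            new_mats.append(dmap.dosages[run].mean(axis=0))
            k += 1
            run_start = i
            i += 1
    return FounderDosageMap(
        markers=pd.DataFrame(new_rows, columns=["marker_id", "chrom", "pos_mb"]),
        dosages=np.stack(new_mats),
        mouse_ids=dmap.mouse_ids,
    )


class ScanDesign:
    """Cached orthonormal column bases of every marker design matrix.

    For marker k the design is [1 | D_k] (n x 9, rank <= 8 due to the
    dosage-sums-to-2 collinearity). ``basis`` holds an orthonormal basis
    U_k of its column space padded to 9 columns, so that for any phenotype
    vector y, RSS_k = y'y - ||U_k' y||^2. Permutation scans reuse the same
    bases, which makes a 10^2-10^4-permutation scan a single tensor
    contraction.
    """

    def __init__(self, dosages: np.ndarray):
        m, n, _ = dosages.shape
        self.n = n
        self.basis = np.zeros((m, n, N_FOUNDERS + 1))
        for k in range(m):
            X = np.column_stack([np.ones(n), dosages[k]])
            U, s, _ = np.linalg.svd(X, full_matrices=False)
            r = int(np.sum(s > s[0] * n * np.finfo(float).eps))
            self.basis[k, :, :r] = U[:, :r]

    def rss(self, Y: np.ndarray) -> np.ndarray:
        """Residual sums of squares, shape (m,) for 1-D y or (m, p) for (n, p)."""
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        total = np.sum(Y**2, axis=0)  # (p,)
        proj = np.einsum("mnr,np->mrp", self.basis, Y, optimize=True)
        rss = total[None, :] - np.sum(proj**2, axis=1)
        rss = np.maximum(rss, 0.0)
        return rss[:, 0] if squeeze else rss


def _lod_from_rss(rss_marker: np.ndarray, rss_null, n: int) -> np.ndarray:
    floored = np.maximum(rss_marker, _RSS_FLOOR * np.asarray(rss_null))
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(np.asarray(rss_null) / floored)
    return np.maximum(np.nan_to_num(lod, nan=0.0), 0.0)


def scan(y: np.ndarray, dmap: FounderDosageMap, design: ScanDesign | None = None) -> np.ndarray:
    """LOD score at every marker of the dosage map."""
    y = np.asarray(y, dtype=float)
    n = dmap.n_mice
    if len(y) != n:
        raise ValueError("phenotype length does not match the number of mice")
    if np.isnan(y).any():
        raise ValueError("phenotype vector contains missing values; filter first")
    if n <= 10:
        raise ValueError(f"need more than 10 mice for a scan, got {n}")
    if design is None:
        design = ScanDesign(dmap.dosages)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 == 0.0:
        warnings.warn("phenotype is constant; all LOD scores are 0", stacklevel=2)
        return np.zeros(dmap.n_markers)
    return _lod_from_rss(design.rss(y - y.mean()), rss0, n)


def permutation_thresholds(
    y: np.ndarray,
    dmap: FounderDosageMap,
    n_perm: int = 1000,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    seed: int = 0,
    design: ScanDesign | None = None,
    return_maxima: bool = False,
):
    """Genome-wide LOD thresholds by phenotype permutation.

    Shuffles the phenotype over mice (the dosage design stays fixed),
    rescans, and records the genome-wide maximum LOD per permutation. The
    threshold at quantile q is the order statistic of rank
    ``ceil(q * (n_perm + 1))`` from below — the conservative convention.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y = np.asarray(y, dtype=float)
    if design is None:
        design = ScanDesign(dmap.dosages)
    rng = np.random.default_rng(seed)
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0.0:
        thresholds = {q: 0.0 for q in quantiles}
        return (thresholds, np.zeros(n_perm)) if return_maxima else thresholds
    Y = np.empty((n, n_perm))
    for j in range(n_perm):
        Y[:, j] = yc[rng.permutation(n)]
    rss = design.rss(Y)  # (m, n_perm)
    lod = _lod_from_rss(rss, rss0, n)
    maxima = np.sort(lod.max(axis=0))
    thresholds = {}
    for q in quantiles:
        rank = min(math.ceil(q * (n_perm + 1)), n_perm)
        thresholds[q] = float(maxima[rank - 1])
    return (thresholds, maxima) if return_maxima else thresholds


def lod_support_interval(
    markers: pd.DataFrame,
    lod: np.ndarray,
    peak_index: int,
    drop: float = DEFAULT_LOD_DROP,
) -> dict:
    """Approximate QTL confidence interval by the LOD-drop rule.

    Walks outward from the peak along its chromosome over the contiguous
    markers with LOD >= peak - drop, then extends one marker past the run
    on each side (outer convention) so the interval covers the true locus
    conservatively. Intervals clipped at a chromosome end are flagged.
    """
    chrom = markers.iloc[peak_index]["chrom"]
    on = markers.index[markers["chrom"] == chrom].to_numpy()
    pos = markers.loc[on, "pos_mb"].to_numpy()
    local = int(np.where(on == peak_index)[0][0])
    cutoff = lod[peak_index] - drop
    lo = local
    while lo > 0 and lod[on[lo - 1]] >= cutoff:
        lo -= 1
    hi = local
    while hi < len(on) - 1 and lod[on[hi + 1]] >= cutoff:
        hi += 1
    edge = False
    if lo > 0:
        lo -= 1  # first flanking marker below the cutoff
    else:
        edge = True
    if hi < len(on) - 1:
        hi += 1
    else:
        edge = True
    return {
        "chrom": str(chrom),
        "start_mb": float(pos[lo]),
        "end_mb": float(pos[hi]),
        "edge_flagged": edge,
    }


def variance_explained(y: np.ndarray, peak_dosage: np.ndarray) -> float:
    """Fraction of phenotypic variance explained by the peak-locus regression."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0.0:
        return 0.0
    X = np.column_stack([np.ones(len(y)), peak_dosage])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(np.clip(1.0 - (resid @ resid) / rss0, 0.0, 1.0))


def allele_effects(
    y: np.ndarray,
    peak_dosage: np.ndarray,
    homozygote_cutoff: float = DEFAULT_HOMOZYGOTE_CUTOFF,
) -> pd.DataFrame:
    """Founder allele effects at a locus.

    Two complementary views: (a) centred additive regression coefficients
    (per allele copy) with standard errors propagated through the
    centring contrast; (b) phenotype means over mice classified as
    homozygous for a founder (dosage >= cutoff), the view used for
    strain-level interpretation. Founders with no homozygotes get NaN
    means; unclassified mice are counted, not dropped silently.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(peak_dosage, dtype=float)
    n = len(y)
    # rows sum to 2, so the intercept is absorbed by the dosage columns
    XtX = D.T @ D
    pinv = np.linalg.pinv(XtX)
    beta = pinv @ D.T @ y
    resid = y - D @ beta
    rank = np.linalg.matrix_rank(D)
    dof = max(n - rank, 1)
    sigma2 = float(resid @ resid) / dof
    C = np.eye(N_FOUNDERS) - np.ones((N_FOUNDERS, N_FOUNDERS)) / N_FOUNDERS
    beta_c = C @ beta
    cov_c = C @ (sigma2 * pinv) @ C.T
    se_c = np.sqrt(np.maximum(np.diag(cov_c), 0.0))

    means = np.full(N_FOUNDERS, np.nan)
    counts = np.zeros(N_FOUNDERS, dtype=int)
    classified = np.zeros(n, dtype=bool)
    for f in range(N_FOUNDERS):
        hom = D[:, f] >= homozygote_cutoff
        counts[f] = int(hom.sum())
        classified |= hom
        if counts[f]:
            means[f] = float(y[hom].mean())
    out = pd.DataFrame(
        {
            "founder": FOUNDERS,
            "effect": beta_c,
            "se": se_c,
            "homozygote_mean": means,
            "n_homozygotes": counts,
        }
    )
    out.attrs["n_unclassified"] = int(n - classified.sum())
    return out


class HaplotypeScan(BaseEstimator):
    """Genome scan estimator: phenotype ~ founder dosages, marker by marker.

    Parameters
    ----------
    n_permutations : int, default 1000
        Phenotype permutations for genome-wide thresholds (0 disables).
    quantiles : tuple, default (0.95, 0.80)
        Genome-wide quantiles reported: 0.95 = "significant" (alpha 0.05),
        0.80 = "suggestive" (alpha 0.20).
    lod_drop : float, default 1.5
        LOD-drop used for the QTL support interval.
    homozygote_cutoff : float, default 1.8
        Minimum dosage classifying a mouse as homozygous for a founder.
    collapse_tol : float or None
        When set, adjacent markers with matrices equal within this
        tolerance are collapsed to intervals before scanning.
    random_state : int, default 0
        Seed for the permutation shuffles.

    Fitted attributes (after :meth:`fit`): ``lod_``, ``markers_``,
    ``peak_index_``, ``peak_marker_``, ``peak_lod_``, ``thresholds_``,
    ``chromosome_peaks_``, ``support_interval_``, ``variance_explained_``,
    ``allele_effects_``, ``n_mice_``.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
        lod_drop: float = DEFAULT_LOD_DROP,
        homozygote_cutoff: float = DEFAULT_HOMOZYGOTE_CUTOFF,
        collapse_tol: float | None = None,
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.quantiles = quantiles
        self.lod_drop = lod_drop
        self.homozygote_cutoff = homozygote_cutoff
        self.collapse_tol = collapse_tol
        self.random_state = random_state

    def fit(self, X: FounderDosageMap, y: np.ndarray) -> "HaplotypeScan":
        """Run the scan of phenotype ``y`` over dosage map ``X``."""
        y = np.asarray(y, dtype=float)
        keep = ~np.isnan(y)
        if not keep.all():  # listwise removal of missing phenotypes
            X = X.subset_mice(keep)
            y = y[keep]
        X.validate()
        if self.collapse_tol is not None:
            X = collapse_intervals(X, self.collapse_tol)
        self.n_mice_ = len(y)
        self.markers_ = X.markers.reset_index(drop=True)
        design = ScanDesign(X.dosages)
        self.lod_ = scan(y, X, design)

        # genome-wide peak; argmax takes the first occurrence, which is the
        # lowest genomic position in map order (tie-break convention)
        self.peak_index_ = int(np.argmax(self.lod_))
        self.peak_lod_ = float(self.lod_[self.peak_index_])
        self.peak_marker_ = self.markers_.iloc[self.peak_index_].to_dict()
        self.chromosome_peaks_ = {
            str(chrom): {
                "index": int(grp.index[np.argmax(self.lod_[grp.index])]),
                "pos_mb": float(
                    grp.iloc[np.argmax(self.lod_[grp.index])]["pos_mb"]
                ),
                "lod": float(self.lod_[grp.index].max()),
            }
            for chrom, grp in self.markers_.groupby("chrom", sort=False)
        }

        if self.n_permutations:
            self.thresholds_ = permutation_thresholds(
                y,
                X,
                n_perm=self.n_permutations,
                quantiles=self.quantiles,
                seed=self.random_state,
                design=design,
            )
        else:
            self.thresholds_ = {}

        if self.peak_lod_ > self.lod_drop:
            self.support_interval_ = lod_support_interval(
                self.markers_, self.lod_, self.peak_index_, self.lod_drop
            )
        else:
            self.support_interval_ = None
        peak_D = X.dosages[self.peak_index_]
        self.variance_explained_ = variance_explained(y, peak_D)
        self.allele_effects_ = allele_effects(y, peak_D, self.homozygote_cutoff)
        return self

    def result(self) -> dict:
        """Scan summary as a JSON-serialisable dict."""
        eff = self.allele_effects_
        return {
            "n": self.n_mice_,
            "n_markers": len(self.markers_),
            "peak": {**{k: (v if not isinstance(v, float) else float(v))
                        for k, v in self.peak_marker_.items()},
                     "lod": self.peak_lod_},
            "thresholds": {str(q): t for q, t in self.thresholds_.items()},
            "chromosome_peaks": self.chromosome_peaks_,
            "support_interval": self.support_interval_,
            "variance_explained": self.variance_explained_,
            "allele_effects": {
                r["founder"]: {
                    "effect": float(r["effect"]),
                    "se": float(r["se"]),
                    "homozygote_mean": None
                    if np.isnan(r["homozygote_mean"])
                    else float(r["homozygote_mean"]),
                    "n_homozygotes": int(r["n_homozygotes"]),
                }
                for _, r in eff.iterrows()
            },
            "n_permutations": self.n_permutations,
            "seed": self.random_state,
        }

    def lod_table(self) -> pd.DataFrame:
        """Per-marker LOD trace (marker_id, chrom, pos_mb, lod)."""
        out = self.markers_.copy()
        out["lod"] = self.lod_
        return out
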