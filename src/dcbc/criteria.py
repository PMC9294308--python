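"""Parcellation evaluation criteria.

Four criteria are implemented over the same similarity measure — the Pearson
correlation between the functional profiles of a vertex pair:

* **Global Homogeneity** — mean within-parcel pairwise correlation, averaged
  (unweighted) across parcels.
* **Silhouette coefficient** — per-vertex contrast ``(b - w) / max(w, b)``
  between the mean dissimilarity ``1 - R`` to the vertex's own parcel (w)
  and to all vertices of all spatially neighboring parcels (b).
* **Un-binned average correlation difference (ACD)** — mean within-parcel
  correlation minus mean between-parcel correlation over all vertex pairs up
  to a maximum distance, ignoring distance matching.  Because within-parcel
  pairs are on average closer together than between-parcel pairs, the
  spatial smoothness of cortical maps biases this difference (and the two
  criteria above) upward even for parcellations unrelated to the data.
* **DCBC (distance-controlled boundary coefficient)** — the same difference,
  but computed inside narrow spatial-distance bins so that only pairs of
  matched distance are compared, then averaged across bins with weights
  proportional to each bin's estimation precision.  Under the approximation
  that vertex pairs are independent, the variance of the per-bin difference
  d_i is 1/n_w,i + 1/n_b,i, so the precision weight is
  ``w_i ∝ n_w,i * n_b,i / (n_w,i + n_b,i)``, normalized to sum to 1 over
  usable bins.  The expected DCBC for a parcellation unrelated to the
  functional boundaries of the data is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EvaluationError, MaskedVertexError, ParameterError
from .mesh import SparseDistanceMatrix
from .parcellation import ParcelAdjacency, Parcellation

__all__ = [
    "FunctionalProfiles",
    "BinSpec",
    "BinnedPairStats",
    "DCBCResult",
    "GroupSummary",
    "pairwise_correlation",
    "classify_and_bin_pairs",
    "compute_weights",
    "compute_dcbc",
    "unbinned_acd",
    "compute_homogeneity",
    "compute_silhouette",
    "group_summary",
    "evaluate_subject",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

class FunctionalProfiles:
    """Vertices x conditions matrix of activity estimates (or time points).

    Vertices whose row contains a non-finite value, or whose profile has
    zero variance across conditions (Pearson correlation undefined), are
    flagged invalid; invalid vertices are excluded from every criterion.
    """

    def __init__(self, values: np.ndarray, valid_mask: np.ndarray | None = None):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ParameterError("values must be a 2-D vertices x conditions matrix")
        if values.shape[1] < 2:
            raise ParameterError(
                f"need >= 2 conditions for Pearson correlation, got {values.shape[1]}"
            )
        if valid_mask is None:
            valid_mask = np.ones(len(values), dtype=bool)
        valid_mask = np.asarray(valid_mask, dtype=bool).copy()
        if valid_mask.shape != (len(values),):
            raise ParameterError("valid_mask must have one entry per vertex")
        valid_mask &= np.isfinite(values).all(axis=1)
        with np.errstate(invalid="ignore"):
            valid_mask &= values.std(axis=1) > 0
        self.values = values
        self.valid_mask = valid_mask
        self._z: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> np.ndarray:
        """Rows centered and scaled to unit norm: ``z @ z.T`` is Pearson R.

        Invalid rows are zeroed, so any correlation touching them is 0 and
        must be excluded by the caller (all public criteria do).
        """
        if self._z is None:
            centered = self.values - self.values.mean(axis=1, keepdims=True)
            centered[~self.valid_mask] = 0.0
            norms = np.linalg.norm(centered, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._z = centered / norms
        return self._z


@dataclass(frozen=True)
class BinSpec:
    """Half-open distance bins ``(lo, hi]`` of equal width over (0, max]."""

    bin_width_mm: float = 1.0
    max_dist_mm: float = 35.0

    def __post_init__(self) -> None:
        if self.bin_width_mm <= 0:
            raise ParameterError("bin_width_mm must be positive")
        if self.max_dist_mm <= 0:
            raise ParameterError("max_dist_mm must be positive")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.max_dist_mm / self.bin_width_mm))

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_mm

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_mm

    def bin_index(self, d: np.ndarray) -> np.ndarray:
        """0-based bin per distance: smallest i with d <= (i+1)*width.

        A distance exactly on an edge falls in the lower bin.
        """
        return np.maximum(np.ceil(np.asarray(d) / self.bin_width_mm).astype(np.int64) - 1, 0)


@dataclass
class BinnedPairStats:
    """Per-bin pair counts and correlation sums for within / between pairs."""

    binspec: BinSpec
    n_within: np.ndarray
    n_between: np.ndarray
    sum_within: np.ndarray
    sum_between: np.ndarray

    @property
    def mean_within(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_within > 0, self.sum_within / self.n_within, np.nan)

    @property
    def mean_between(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_between > 0, self.sum_between / self.n_between, np.nan)


@dataclass
class DCBCResult:
    """The DCBC together with everything needed to audit it."""

    binned: BinnedPairStats
    d_i: np.ndarray            # per-bin within-minus-between difference (nan if unusable)
    weights: np.ndarray        # per-bin precision weights, 0 at excluded bins
    dcbc: float                # precision-weighted average of d_i
    dcbc_unweighted: float     # simple mean of d_i over included bins
    excluded_bins: np.ndarray  # 0-based indices of bins without both pair kinds

    @property
    def included_bins(self) -> np.ndarray:
        return np.flatnonzero(self.weights > 0)

    @property
    def n_bins_used(self) -> int:
        return len(self.included_bins)


# ---------------------------------------------------------------------------
# Pairwise correlation
# ---------------------------------------------------------------------------

def pairwise_correlation(profiles: FunctionalProfiles, i: int, j: int) -> float:
    """Pearson correlation of the functional profiles at vertices i and j."""
    if not profiles.valid_mask[i]:
        raise MaskedVertexError(f"vertex {i} is masked or has a degenerate profile")
    if not profiles.valid_mask[j]:
        raise MaskedVertexError(f"vertex {j} is masked or has a degenerate profile")
    z = profiles.standardized()
    return float(np.clip(z[i] @ z[j], -1.0, 1.0))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _qualifying_pairs(
    parcellation: Parcellation,
    dist: SparseDistanceMatrix,
    max_dist_mm: float,
    valid_mask: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairs with both vertices valid & labeled, 0 < d <= max_dist.

    Returns (i, j, d, is_within).
    """
    if parcellation.n_vertices != dist.n_vertices:
        raise ParameterError("parcellation and distance matrix vertex counts differ")
    if valid_mask is None:
        valid_mask = np.ones(dist.n_vertices, dtype=bool)
    elif len(valid_mask) != dist.n_vertices:
        raise ParameterError("valid_mask length must equal n_vertices")
    lab = parcellation.labels
    ii, jj, dd = dist.i, dist.j, dist.d
    keep = (
        (dd <= max_dist_mm)
        & valid_mask[ii]
        & valid_mask[jj]
        & (lab[ii] > 0)
        & (lab[jj] > 0)
    )
    ii, jj, dd = ii[keep], jj[keep], dd[keep]
    return ii, jj, dd, lab[ii] == lab[jj]


def classify_and_bin_pairs(
    parcellation: Parcellation,
    dist: SparseDistanceMatrix,
    binspec: BinSpec,
    valid_mask: np.ndarray | None = None,
) -> BinnedPairStats:
    """Count within- and between-parcel vertex pairs per distance bin.

    Only pairs with both vertices valid, both labels non-zero and
    0 < d <= max_dist are counted; each pair lands in exactly one bin.
    Correlation sums are left at zero (counts-only skeleton).
    """
    if binspec.max_dist_mm > dist.cutoff_mm:
        raise ParameterError(
            f"max_dist {binspec.max_dist_mm} mm exceeds the distance cutoff "
            f"{dist.cutoff_mm} mm"
        )
    ii, jj, dd, within = _qualifying_pairs(
        parcellation, dist, binspec.max_dist_mm, valid_mask
    )
    idx = binspec.bin_index(dd)
    nb = binspec.n_bins
    return BinnedPairStats(
        binspec=binspec,
        n_within=np.bincount(idx[within], minlength=nb),
        n_between=np.bincount(idx[~within], minlength=nb),
        sum_within=np.zeros(nb),
        sum_between=np.zeros(nb),
    )


# ---------------------------------------------------------------------------
# Precision weights
# ---------------------------------------------------------------------------

def compute_weights(n_within: np.ndarray, n_between: np.ndarray) -> np.ndarray:
    """Precision weights ``w_i ∝ n_w,i * n_b,i / (n_w,i + n_b,i)``.

    The per-bin difference d_i has approximate variance 1/n_w,i + 1/n_b,i
    (independent-pairs approximation); the weight is the normalized inverse.
    Bins lacking either pair kind carry weight 0 and are excluded; remaining
    weights sum to 1.
    """
    n_w = np.asarray(n_within, dtype=np.float64)
    n_b = np.asarray(n_between, dtype=np.float64)
    if n_w.shape != n_b.shape:
        raise ParameterError("count vectors must have equal length")
    usable = (n_w > 0) & (n_b > 0)
    if not usable.any():
        raise EvaluationError("no bin contains both within- and between-parcel pairs")
    prec = np.zeros_like(n_w)
    prec[usable] = n_w[usable] * n_b[usable] / (n_w[usable] + n_b[usable])
    return prec / prec.sum()


# ---------------------------------------------------------------------------
# DCBC and un-binned ACD
# ---------------------------------------------------------------------------

def compute_dcbc(
    profiles: FunctionalProfiles,
    parcellation: Parcellation,
    dist: SparseDistanceMatrix,
    binspec: BinSpec | None = None,
) -> DCBCResult:
    """Distance-controlled boundary coefficient of a parcellation.

    Per bin i: d_i = (mean within-parcel correlation) - (mean between-parcel
    correlation); the DCBC is the precision-weighted average of d_i over the
    bins containing both pair kinds.  The simple (un-weighted) mean over the
    same bins is returned alongside for comparison.
    """
    binspec = binspec or BinSpec()
    if binspec.max_dist_mm > dist.cutoff_mm:
        raise ParameterError(
            f"max_dist {binspec.max_dist_mm} mm exceeds the distance cutoff "
            f"{dist.cutoff_mm} mm"
        )
    _check_evaluable(profiles, parcellation)
    ii, jj, dd, within = _qualifying_pairs(
        parcellation, dist, binspec.max_dist_mm, profiles.valid_mask
    )
    if not (~within).any():
        raise EvaluationError("no between-parcel pairs; need >= 2 parcels in range")
    z = profiles.standardized()
    r = np.einsum("ij,ij->i", z[ii], z[jj])
    idx = binspec.bin_index(dd)
    nb = binspec.n_bins
    stats_ = BinnedPairStats(
        binspec=binspec,
        n_within=np.bincount(idx[within], minlength=nb),
        n_between=np.bincount(idx[~within], minlength=nb),
        sum_within=np.bincount(idx[within], weights=r[within], minlength=nb),
        sum_between=np.bincount(idx[~within], weights=r[~within], minlength=nb),
    )
    weights = compute_weights(stats_.n_within, stats_.n_between)
    d_i = stats_.mean_within - stats_.mean_between
    included = weights > 0
    dcbc = float(np.sum(weights[included] * d_i[included]))
    dcbc_unweighted = float(np.mean(d_i[included]))
    return DCBCResult(
        binned=stats_,
        d_i=d_i,
        weights=weights,
        dcbc=dcbc,
        dcbc_unweighted=dcbc_unweighted,
        excluded_bins=np.flatnonzero(~included),
    )


def unbinned_acd(
    profiles: FunctionalProfiles,
    parcellation: Parcellation,
    dist: SparseDistanceMatrix,
    max_dist_mm: float = 35.0,
) -> float:
    """Un-binned average correlation difference over pairs up to max_dist.

    Mean within-parcel correlation minus mean between-parcel correlation,
    ignoring distance matching; positively biased by spatial smoothness.
    """
    _check_evaluable(profiles, parcellation)
    ii, jj, dd, within = _qualifying_pairs(
        parcellation, dist, max_dist_mm, profiles.valid_mask
    )
    if not within.any() or not (~within).any():
        raise EvaluationError("need both within- and between-parcel pairs in range")
    z = profiles.standardized()
    r = np.einsum("ij,ij->i", z[ii], z[jj])
    return float(r[within].mean() - r[~within].mean())


def _check_evaluable(profiles: FunctionalProfiles, parcellation: Parcellation) -> None:
    if profiles.n_vertices != parcellation.n_vertices:
        raise ParameterError("profiles and parcellation vertex counts differ")
    present = np.unique(parcellation.labels[profiles.valid_mask])
    if len(present[present > 0]) < 2:
        raise EvaluationError(
            "boundary evaluation needs >= 2 non-empty parcels on valid vertices"
        )


# ---------------------------------------------------------------------------
# Baseline criteria
# ---------------------------------------------------------------------------

def compute_homogeneity(
    profiles: FunctionalProfiles,
    parcellation: Parcellation,
    size_weighted: bool = False,
) -> float:
    """Global Homogeneity: mean within-parcel pairwise correlation.

    Per-parcel mean pairwise correlation over all vertex pairs within the
    parcel, then averaged across parcels — unweighted by default, or
    weighted by the number of pairs with ``size_weighted=True``.  Parcels
    with fewer than two valid vertices are skipped.
    """
    if profiles.n_vertices != parcellation.n_vertices:
        raise ParameterError("profiles and parcellation vertex counts differ")
    z = profiles.standardized()
    valid = profiles.valid_mask
    means, sizes = [], []
    for k in parcellation.parcel_ids:
        members = np.flatnonzero((parcellation.labels == k) & valid)
        m = len(members)
        if m < 2:
            continue
        s = z[members].sum(axis=0)
        # sum over ordered pairs of z_i.z_j = |s|^2 - m (unit rows)
        pair_sum = (s @ s - m) / 2.0
        n_pairs = m * (m - 1) / 2.0
        means.append(pair_sum / n_pairs)
        sizes.append(n_pairs)
    if not means:
        raise EvaluationError("no parcel has >= 2 valid vertices")
    if size_weighted:
        return float(np.average(means, weights=sizes))
    return float(np.mean(means))


def compute_silhouette(
    profiles: FunctionalProfiles,
    parcellation: Parcellation,
    adjacency: ParcelAdjacency,
) -> tuple[np.ndarray, float]:
    """Silhouette coefficient per vertex and its mean.

    For vertex i in parcel k: w_i is the mean dissimilarity (1 - R) to the
    other members of k (divisor m_k - 1); b_i the mean dissimilarity to all
    N vertices pooled across all parcels neighboring k (single divisor N);
    S_i = (b_i - w_i) / max(w_i, b_i).  Vertices in singleton parcels, in
    parcels with no neighbor, or masked, are skipped (NaN in the per-vertex
    vector) — the mean is over evaluated vertices only.
    """
    if profiles.n_vertices != parcellation.n_vertices:
        raise ParameterError("profiles and parcellation vertex counts differ")
    z = profiles.standardized()
    valid = profiles.valid_mask
    lab = parcellation.labels
    ids = parcellation.parcel_ids
    # per-parcel sums of standardized profiles over valid members
    sums = {int(k): z[(lab == k) & valid].sum(axis=0) for k in ids}
    sizes = {int(k): int(((lab == k) & valid).sum()) for k in ids}

    s_i = np.full(parcellation.n_vertices, np.nan)
    for k in ids:
        k = int(k)
        m_k = sizes[k]
        nb = [b for b in adjacency.neighbors.get(k, frozenset()) if sizes.get(b, 0) > 0]
        n_total = sum(sizes[b] for b in nb)
        if m_k < 2 or n_total == 0:
            continue  # skipped vertices, reported as NaN
        nb_sum = np.sum([sums[b] for b in nb], axis=0)
        members = np.flatnonzero((lab == k) & valid)
        own = z[members]
        w = 1.0 - (own @ sums[k] - 1.0) / (m_k - 1)
        b = 1.0 - (own @ nb_sum) / n_total
        denom = np.maximum(w, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(denom == 0, 0.0, (b - w) / denom)
        s_i[members] = s
    if not np.isfinite(s_i).any():
        raise EvaluationError("no vertex qualifies for the Silhouette coefficient")
    return s_i, float(np.nanmean(s_i))


# ---------------------------------------------------------------------------
# Group-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    mean: float
    se: float
    t: float
    p: float
    n: int


def group_summary(per_subject_values) -> GroupSummary:
    """Mean, standard error and one-sample t test against zero.

    With zero sample variance the t statistic is reported as signed infinity
    (p = 0), or 0 (p = 1) if the mean is also zero, rather than erroring.
    """
    x = np.asarray(per_subject_values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError("need a 1-D sample of size >= 2")
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(n)
    if se == 0.0:
        if mean == 0.0:
            return GroupSummary(mean=mean, se=0.0, t=0.0, p=1.0, n=n)
        return GroupSummary(
            mean=mean, se=0.0, t=float(np.sign(mean)) * np.inf, p=0.0, n=n
        )
    res = stats.ttest_1samp(x, popmean=0.0)
    return GroupSummary(mean=mean, se=se, t=float(res.statistic), p=float(res.pvalue), n=n)


def evaluate_subject(
    hemispheres: list[tuple[FunctionalProfiles, Parcellation, SparseDistanceMatrix]],
    binspec: BinSpec | None = None,
) -> float:
    """Subject-level DCBC: computed per hemisphere, then averaged equally.

    ``hemispheres`` holds one (profiles, parcellation, distances) triple per
    hemisphere; a single-hemisphere list is allowed and returns that
    hemisphere's DCBC unchanged.
    """
    if not hemispheres:
        raise ParameterError("need at least one hemisphere")
    values = [
        compute_dcbc(p, parc, d, binspec).dcbc for (p, parc, d) in hemispheres
    ]
    return float(np.mean(values))
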