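"""Temporal PCA with Promax rotation and back-projection.

The ERP data cube is unfolded into a matrix whose columns are time points
and whose rows stack subject (major), condition, then channel.  PCA is
computed on the column-centered matrix via SVD; the retained loadings are
rotated with Varimax followed by Promax (κ = 4 by default; Kaiser row
normalization is available but off for temporal loadings, where it
over-weights low-signal time points), and a chosen subset of components is
projected back to the electrode fields, which removes each component's
sign and variance indeterminacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import ErpDataset

__all__ = [
    "ErpMatrix",
    "Decomposition",
    "ComponentSelection",
    "BackProjection",
    "SelectionCriteria",
    "build_matrix",
    "varimax",
    "promax",
    "tpca",
    "spatial_similarity",
    "component_topographies",
    "select_components",
    "back_project",
]


@dataclass
class ErpMatrix:
    """Unfolded ERP matrix: N = subjects·conditions·channels rows, M time columns."""

    Z: np.ndarray
    column_means: np.ndarray
    times: np.ndarray
    srate: float
    subject_ids: list[str]
    condition_labels: list[str]
    channel_labels: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.Z.shape

    @property
    def dims(self) -> tuple[int, int, int]:
        return (len(self.subject_ids), len(self.condition_labels), len(self.channel_labels))

    def row_of(self, subject: int, condition: int, channel: int) -> int:
        ns, nc, nch = self.dims
        return (subject * nc + condition) * nch + channel

    def index_of(self, row: int) -> tuple[int, int, int]:
        ns, nc, nch = self.dims
        sc, channel = divmod(row, nch)
        subject, condition = divmod(sc, nc)
        return subject, condition, channel

    def fold(self, flat: np.ndarray) -> np.ndarray:
        """Reshape an (N, M)-shaped array back to (S, C, Ch, M)."""
        ns, nc, nch = self.dims
        return flat.reshape(ns, nc, nch, flat.shape[-1])


def build_matrix(data: ErpDataset, time_window: tuple[float, float] | None = None) -> ErpMatrix:
    """Unfold a dataset into the t-PCA observation matrix.

    ``time_window`` is right-open: [start, end) — e.g. 0..800 ms at 150 Hz
    gives 120 columns.
    """
    if time_window is None:
        mask = np.ones(len(data.times), dtype=bool)
    else:
        lo, hi = time_window
        mask = (data.times >= lo) & (data.times < hi)
        if not mask.any():
            raise ValueError("time window selects no samples")
    cube = data.data[..., mask]
    ns, nc, nch, m = cube.shape
    Z = cube.reshape(ns * nc * nch, m)
    return ErpMatrix(
        Z=Z,
        column_means=Z.mean(axis=0),
        times=data.times[mask],
        srate=data.srate,
        subject_ids=list(data.subject_ids),
        condition_labels=list(data.condition_labels),
        channel_labels=list(data.channel_labels),
    )


def varimax(A: np.ndarray, kaiser: bool = True, max_iter: int = 500,
            tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, orthogonal rotation matrix)."""
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    if kaiser:
        h = np.sqrt(np.sum(A**2, axis=1))
        h[h == 0] = 1.0
        B = A / h[:, None]
    else:
        h = None
        B = A
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = B @ R
        grad = B.T @ (L**3 - L @ np.diag(np.sum(L**2, axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    out = A @ R
    return out, R


def promax(A: np.ndarray, kappa: float = 4.0, kaiser: bool = False
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promax oblique rotation.

    Varimax first, then oblique procrustes toward the element-wise power-κ
    target.  Returns (pattern, total rotation matrix T with pattern = A·T,
    factor correlation Φ).
    """
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    if k < 2:
        return A.copy(), np.eye(k), np.eye(k)
    X, R_v = varimax(A, kaiser=kaiser)
    target = X * np.abs(X) ** (kappa - 1.0)
    U, *_ = np.linalg.lstsq(X, target, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = X @ U
    T = R_v @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, T, phi


@dataclass
class Decomposition:
    """t-PCA + rotation result tied to the matrix it came from."""

    matrix: ErpMatrix
    loadings_unrotated: np.ndarray      # M × R, orthonormal columns
    loadings_rotated: np.ndarray        # M × R pattern matrix
    scores: np.ndarray                  # N × R, consistent with the pattern
    eigenvalues: np.ndarray             # all M eigenvalues, non-increasing
    explained_variance_pct: np.ndarray  # all M, sums to 100
    rotated_variance_pct: np.ndarray    # R, SS-loadings share of total variance
    factor_correlation: np.ndarray      # R × R
    R: int
    rotation: dict = field(default_factory=dict)

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct) / 100.0


def tpca(Z: ErpMatrix, variance_threshold: float = 0.99, kappa: float = 4.0,
         kaiser: bool = False) -> Decomposition:
    """SVD-based temporal PCA, retained count by cumulative explained variance,
    then Promax rotation of the retained loadings.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = Z.Z - Z.column_means
    n, m = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n_vals = len(s)
    eig = np.zeros(m)
    eig[:n_vals] = s**2 / max(n - 1, 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("matrix has zero variance")
    expl = eig / total * 100.0
    cum = np.cumsum(eig) / total
    R = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    rank = int(np.sum(s > s[0] * 1e-12)) if n_vals else 0
    if R > rank:
        warnings.warn(f"requested {R} components exceeds numerical rank {rank}; reducing")
        R = rank

    denom = np.sqrt(max(n - 1, 1))
    A = Vt[:R].T * (s[:R] / denom)          # scaled loadings for rotation
    scores_un = U[:, :R] * denom
    if R >= 2:
        pattern, T, phi = promax(A, kappa=kappa, kaiser=kaiser)
        scores = scores_un @ np.linalg.inv(T).T
    else:
        pattern, phi = A.copy(), np.eye(R)
        scores = scores_un.copy()
    rotated_pct = np.sum(pattern**2, axis=0) / total * 100.0
    return Decomposition(
        matrix=Z,
        loadings_unrotated=Vt[:R].T.copy(),
        loadings_rotated=pattern,
        scores=scores,
        eigenvalues=eig,
        explained_variance_pct=expl,
        rotated_variance_pct=rotated_pct,
        factor_correlation=phi,
        R=R,
        rotation={"varimax-step": True, "promax-kappa": kappa, "kaiser": kaiser},
    )


def spatial_similarity(topographies: np.ndarray) -> tuple[float, float]:
    """Mean ± sd of pairwise Pearson r between subject topographies.

    ``topographies`` is (subjects, channels); zero-variance rows are dropped
    with a warning.
    """
    topo = np.asarray(topographies, dtype=float)
    if topo.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = topo.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("excluding zero-variance topographies from similarity")
        topo = topo[sd > 0]
        if topo.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant topographies")
    C = np.corrcoef(topo)
    iu = np.triu_indices_from(C, k=1)
    vals = C[iu]
    return float(vals.mean()), float(vals.std(ddof=0))


def component_topographies(dec: Decomposition, component: int) -> np.ndarray:
    """Per-subject spatial pattern of one component: scores folded over
    channels, averaged across conditions.  Shape (subjects, channels)."""
    ns, nc, nch = dec.matrix.dims
    folded = dec.scores[:, component].reshape(ns, nc, nch)
    return folded.mean(axis=1)


@dataclass(frozen=True)
class SelectionCriteria:
    """Automated shortlist rule for one target ERP.

    ``companion_min_abs_corr`` additionally pulls in components whose
    temporal peak lies in the latency window and whose group-mean
    topography correlates (in absolute value, since component signs are
    indeterminate) at least that strongly with an already-shortlisted
    component — the latency-jitter "derivative" components that belong to
    the same ERP but whose subject-wise sign flips depress their
    between-subject similarity.  Set to None to disable.
    """

    latency_window: tuple[float, float]
    polarity: int
    channel_region: tuple[str, ...]
    min_similarity: float = 0.4
    companion_min_abs_corr: float | None = 0.8


@dataclass
class ComponentSelection:
    selected: list[int]
    similarity: dict[int, tuple[float, float]]
    notes: dict[int, str] = field(default_factory=dict)


def select_components(dec: Decomposition, criteria: SelectionCriteria) -> ComponentSelection:
    """Shortlist components whose temporal peak, spatial peak, joint polarity
    and between-subject topography similarity all match the criteria.

    Polarity uses the product of the loading's peak sign and the topography
    sign at the peak channel, so it is invariant to component sign flips.
    """
    times = dec.matrix.times
    labels = dec.matrix.channel_labels
    region = set(criteria.channel_region)
    unknown = region - set(labels)
    if unknown:
        raise ValueError(f"criteria channels not in dataset: {sorted(unknown)}")
    selected: list[int] = []
    sims: dict[int, tuple[float, float]] = {}
    notes: dict[int, str] = {}
    for r in range(dec.R):
        loading = dec.loadings_rotated[:, r]
        ipk = int(np.argmax(np.abs(loading)))
        t_pk = times[ipk]
        lo, hi = criteria.latency_window
        if not lo <= t_pk <= hi:
            notes[r] = f"peak {t_pk:.0f} ms outside window"
            continue
        topo_subj = component_topographies(dec, r)
        topo = topo_subj.mean(axis=0)
        ch_pk = int(np.argmax(np.abs(topo)))
        if labels[ch_pk] not in region:
            notes[r] = f"spatial peak {labels[ch_pk]} outside region"
            continue
        joint = np.sign(loading[ipk]) * np.sign(topo[ch_pk])
        if joint != criteria.polarity:
            notes[r] = "joint polarity mismatch"
            continue
        mean_r, sd_r = spatial_similarity(topo_subj)
        sims[r] = (mean_r, sd_r)
        if mean_r < criteria.min_similarity:
            notes[r] = f"similarity {mean_r:.2f} below {criteria.min_similarity}"
            continue
        selected.append(r)
    if selected and criteria.companion_min_abs_corr is not None:
        primary_topos = [component_topographies(dec, r).mean(axis=0) for r in selected]
        lo, hi = criteria.latency_window
        for r in range(dec.R):
            if r in selected:
                continue
            loading = dec.loadings_rotated[:, r]
            t_pk = times[int(np.argmax(np.abs(loading)))]
            if not lo <= t_pk <= hi:
                continue
            topo_subj = component_topographies(dec, r)
            topo = topo_subj.mean(axis=0)
            best = max(abs(_safe_corr(topo, p)) for p in primary_topos)
            if best >= criteria.companion_min_abs_corr:
                sims.setdefault(r, spatial_similarity(topo_subj))
                notes[r] = f"companion (|topo r|={best:.2f})"
                selected.append(r)
        selected.sort()
    if not selected:
        warnings.warn("no components matched the selection criteria")
    return ComponentSelection(selected=selected, similarity=sims, notes=notes)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class BackProjection:
    """Component-subset reconstruction in electrode space."""

    data: np.ndarray                     # (S, C, Ch, M)
    times: np.ndarray
    srate: float
    component_set: list[int]
    subject_ids: list[str]
    condition_labels: list[str]
    channel_labels: list[str]

    def to_dataset(self) -> ErpDataset:
        return ErpDataset(
            data=self.data, times=self.times, srate=self.srate,
            channel_labels=list(self.channel_labels),
            condition_labels=list(self.condition_labels),
            subject_ids=list(self.subject_ids),
        )


def back_project(dec: Decomposition, selection) -> BackProjection:
    """Project the selected components back to the electrode fields.

    ``selection`` is a ComponentSelection or an iterable of component
    indices.  Column means are re-added only when every retained component
    is selected (partial selections are component-specific activity).
    """
    if isinstance(selection, ComponentSelection):
        idx = list(selection.selected)
    else:
        idx = list(selection)
    if not idx:
        raise ValueError("empty component selection")
    if any(not 0 <= j < dec.R for j in idx):
        raise ValueError("component index out of range")
    flat = dec.scores[:, idx] @ dec.loadings_rotated[:, idx].T
    if len(set(idx)) == dec.R and dec.cumulative_explained[dec.R - 1] > 1.0 - 1e-9:
        flat = flat + dec.matrix.column_means
    Zm = dec.matrix
    return BackProjection(
        data=Zm.fold(flat),
        times=Zm.times,
        srate=Zm.srate,
        component_set=idx,
        subject_ids=list(Zm.subject_ids),
        condition_labels=list(Zm.condition_labels),
        channel_labels=list(Zm.channel_labels),
    )
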