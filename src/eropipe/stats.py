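"""Validation correlations and repeated-measures ANOVA.

The two-way within-subject ANOVA uses the classical decomposition with a
separate subject-by-effect error term per effect; partial eta squared is
``SS_effect / (SS_effect + SS_error)``.  Greenhouse–Geisser epsilon is
computed generally from the contrast covariance but equals 1 exactly for
two-level factors, so the 2×2 design is never actually corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["pearson", "rm_anova_2x2", "rm_anova_two_way", "AnovaResult",
           "EffectResult", "recovery_report"]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation.

    Multi-dimensional inputs (topographies, TFR surfaces) are flattened in
    C order — frequency-major for freq × time arrays.  Constant inputs are
    an error rather than a silent NaN.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise ValueError("inputs must have the same number of elements")
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.sum(xc * yc) / denom)


@dataclass
class EffectResult:
    F: float
    df: tuple[float, float]
    p: float
    eta_p2: float
    gg_epsilon: float
    p_gg: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    ss_subjects: float
    ss_total: float
    post_hoc: dict[str, float] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(dict(effect=name, F=e.F, df_num=e.df[0], df_den=e.df[1],
                             p=e.p, eta_p2=e.eta_p2, gg_epsilon=e.gg_epsilon,
                             p_gg=e.p_gg))
        return pd.DataFrame(rows)


def _gg_epsilon(cells: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from subject-level cell scores.

    ``cells`` is (subjects, k); ``contrast`` is a (k−1, k) orthonormal
    contrast matrix for the effect.
    """
    k1 = contrast.shape[0]
    if k1 <= 1:
        return 1.0
    S = np.cov(cells, rowvar=False)
    M = contrast @ S @ contrast.T
    tr = np.trace(M)
    denom = k1 * np.sum(M * M.T)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr**2 / denom))


def _orth_contrast(k: int) -> np.ndarray:
    """(k−1, k) orthonormal rows spanning the space orthogonal to the mean."""
    H = np.eye(k) - np.full((k, k), 1.0 / k)
    u, s, vt = np.linalg.svd(H)
    return vt[:k - 1]


def rm_anova_two_way(values: np.ndarray, a_levels: int, b_levels: int,
                     alpha: float = 0.05, a_names: tuple[str, str] | None = None,
                     bonferroni: bool = False) -> AnovaResult:
    """Two-way fully within-subject ANOVA on ``values`` shaped
    (subjects, a_levels, b_levels) or (subjects, a_levels·b_levels) with the
    A factor varying slowest.

    When the A×B interaction reaches ``alpha``, paired simple-effect
    comparisons of B within each level of A are added to ``post_hoc``.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim == 2:
        Y = Y.reshape(Y.shape[0], a_levels, b_levels)
    if Y.shape[1:] != (a_levels, b_levels):
        raise ValueError("values shape does not match factor levels")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells are not supported")
    n = Y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    a, b = a_levels, b_levels

    m = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    ss_subj = a * b * np.sum((m_s - m) ** 2)
    ss_a = n * b * np.sum((m_a - m) ** 2)
    ss_b = n * a * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    resid = (Y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - m)
    ss_abs = np.sum(resid**2)
    ss_total = np.sum((Y - m) ** 2)

    effects: dict[str, EffectResult] = {}
    specs = [
        ("A", ss_a, ss_as, a - 1, (a - 1) * (n - 1)),
        ("B", ss_b, ss_bs, b - 1, (b - 1) * (n - 1)),
        ("AxB", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    ]
    ca = _orth_contrast(a)
    cb = _orth_contrast(b)
    cell_sets = {
        "A": (m_sa, ca),
        "B": (m_sb, cb),
        "AxB": (Y.reshape(n, a * b), np.kron(ca, cb)),
    }
    degenerate_tol = 1e-12 * max(ss_total, 1.0)
    for name, ss_e, ss_err, df1, df2 in specs:
        if ss_e < degenerate_tol and ss_err < degenerate_tol:
            ss_e = ss_err = 0.0   # both pure roundoff: F is 0, not 0/0 noise
        ms_err = ss_err / df2 if df2 > 0 else np.nan
        F = (ss_e / df1) / ms_err if ms_err > 0 else 0.0
        p = float(sstats.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
        eta = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
        eps = _gg_epsilon(*cell_sets[name])
        p_gg = float(sstats.f.sf(F, df1 * eps, df2 * eps)) if ms_err > 0 else 1.0
        effects[name] = EffectResult(F=float(F), df=(df1, df2), p=p,
                                     eta_p2=float(eta), gg_epsilon=eps,
                                     p_gg=p_gg, ss_effect=float(ss_e),
                                     ss_error=float(ss_err))

    result = AnovaResult(effects=effects, ss_subjects=float(ss_subj),
                         ss_total=float(ss_total))
    if effects["AxB"].p < alpha and b == 2:
        names = a_names or tuple(f"A{i+1}" for i in range(a))
        ps = []
        for i in range(a):
            t, p = sstats.ttest_rel(Y[:, i, 0], Y[:, i, 1])
            ps.append((f"B within {names[i]}", float(p)))
        mult = len(ps) if bonferroni else 1
        result.post_hoc = {k: min(1.0, p * mult) for k, p in ps}
    return result


def rm_anova_2x2(values: np.ndarray, a_names: tuple[str, str] = ("short", "long"),
                 b_names: tuple[str, str] = ("loss", "gain"),
                 alpha: float = 0.05, bonferroni: bool = False) -> AnovaResult:
    """2×2 within-subject ANOVA; columns ordered A-major:
    (A1B1, A1B2, A2B1, A2B2) — e.g. short-loss, short-gain, long-loss,
    long-gain."""
    return rm_anova_two_way(values, 2, 2, alpha=alpha, a_names=a_names,
                            bonferroni=bonferroni)


def recovery_report(truth: dict[str, dict[str, np.ndarray]],
                    extracted: dict[str, dict[str, np.ndarray]],
                    mixed: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Correlation table per source and modality.

    Each argument maps source name → {modality → array}; modalities are
    typically 'waveform', 'topography', 'tfr'.  Emits one row per source ×
    modality with r(source, mixed), r(source, extracted), r(mixed, extracted).
    """
    rows = []
    for source, modalities in truth.items():
        for modality, t_arr in modalities.items():
            e_arr = extracted[source][modality]
            m_arr = mixed[source][modality]
            rows.append(dict(
                source=source, modality=modality,
                r_source_mixed=pearson(t_arr, m_arr),
                r_source_extracted=pearson(t_arr, e_arr),
                r_mixed_extracted=pearson(m_arr, e_arr),
            ))
    return pd.DataFrame(rows)
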