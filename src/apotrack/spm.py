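"""1D statistical parametric mapping over stride-cycle thickness fields.

Pointwise repeated-measures ANOVA and paired-t statistic fields are
computed independently at each of the 200 stride-cycle nodes; field
smoothness (FWHM) is estimated from model residuals; the family-wise
critical threshold comes from the random-field-theory expected Euler
characteristic of the excursion set (0D tail probability plus the 1D EC
density times the resel count); suprathreshold clusters are the maximal
runs of nodes exceeding the threshold, reported in % stride (node / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

_SQRT_4LN2 = np.sqrt(4.0 * np.log(2.0))


@dataclass(frozen=True)
class FieldDesign:
    """Observed 1D fields with factorial labels.

    ``observations`` is (n_obs, n_nodes); ``subject``, ``region``,
    ``condition`` and ``stride`` are integer label arrays of length n_obs.
    The design must be balanced: every subject x region x condition cell
    holds the same number of strides.
    """

    observations: np.ndarray
    subject: np.ndarray
    region: np.ndarray
    condition: np.ndarray
    stride: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        n = obs.shape[0]
        for name in ("subject", "region", "condition", "stride"):
            lab = np.asarray(getattr(self, name))
            if lab.shape != (n,):
                raise ValueError(f"{name} labels must have length {n}")
            object.__setattr__(self, name, lab)
        object.__setattr__(self, "observations", obs)
        self._cell_index()  # validates balance

    def _levels(self, labels: np.ndarray) -> np.ndarray:
        return np.unique(labels)

    def _cell_index(self) -> tuple[np.ndarray, tuple[int, int, int, int]]:
        subs = self._levels(self.subject)
        regs = self._levels(self.region)
        conds = self._levels(self.condition)
        n_cells = subs.size * regs.size * conds.size
        counts = np.zeros((subs.size, regs.size, conds.size), dtype=int)
        si = np.searchsorted(subs, self.subject)
        ri = np.searchsorted(regs, self.region)
        ci = np.searchsorted(conds, self.condition)
        np.add.at(counts, (si, ri, ci), 1)
        n_strides = self.observations.shape[0] // n_cells
        if n_strides * n_cells != self.observations.shape[0] or not np.all(counts == n_strides):
            raise ValueError(
                "unbalanced design: every subject x region x condition cell must hold "
                "the same number of strides"
            )
        return np.stack([si, ri, ci]), (subs.size, regs.size, conds.size, n_strides)

    def cell_means(self) -> np.ndarray:
        """Strides averaged out: array (n_subjects, n_regions, n_conditions, n_nodes)."""
        (si, ri, ci), (ns, na, nb, nr) = self._cell_index()
        out = np.zeros((ns, na, nb, self.observations.shape[1]))
        np.add.at(out, (si, ri, ci), self.observations)
        return out / nr


@dataclass(frozen=True)
class SpmResult:
    """Statistic field with its RFT inference summary."""

    stat: np.ndarray  # t or F values over nodes
    stat_kind: str  # "t" or "F"
    df: tuple[float, float]
    fwhm: float
    critical_threshold: float
    clusters: tuple[tuple[float, float], ...]  # (% start, % end) half-open
    alpha: float
    flags: tuple[str, ...] = field(default=())

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


_EFFECTS = ("region", "condition", "interaction")


def pointwise_rm_anova(
    design: FieldDesign,
    effect: str = "region",
    stride_mode: str = "cell_means",
) -> tuple[np.ndarray, tuple[int, int]]:
    """Two-way repeated-measures ANOVA F field for one effect.

    Subject is the random blocking factor; each effect is tested against
    its interaction with subject.  With ``stride_mode="cell_means"``
    (default) the strides within a cell are averaged before the ANOVA; with
    ``"stride_replicates"`` every (subject, stride) pair is treated as an
    independent blocking unit.

    Returns ``(F_field, (df_effect, df_error))``; df are constant across
    nodes.  Nodes where both effect and error sums of squares vanish get
    F = 0; zero error with non-zero effect gives +inf.
    """
    if effect not in _EFFECTS:
        raise ValueError(f"effect must be one of {_EFFECTS}, got {effect!r}")
    if stride_mode == "cell_means":
        cells = design.cell_means()
    elif stride_mode == "stride_replicates":
        (si, ri, ci), (ns, na, nb, nr) = design._cell_index()
        cells = np.zeros((ns * nr, na, nb, design.observations.shape[1]))
        sti = np.zeros(design.observations.shape[0], dtype=int)
        # label strides within each cell in order of appearance
        seen: dict[tuple[int, int, int], int] = {}
        for i, key in enumerate(zip(si, ri, ci)):
            sti[i] = seen.get(key, 0)
            seen[key] = sti[i] + 1
        cells[si * nr + sti, ri, ci] = design.observations
    else:
        raise ValueError(f"unknown stride_mode {stride_mode!r}")

    ns, na, nb, _ = cells.shape
    if ns < 2:
        raise ValueError("need at least 2 subjects")
    if effect == "region" and na < 2:
        raise ValueError("region effect requires >= 2 region levels")
    if effect == "condition" and nb < 2:
        raise ValueError("condition effect requires >= 2 condition levels")
    if effect == "interaction" and (na < 2 or nb < 2):
        raise ValueError("interaction requires >= 2 levels of both factors")

    grand = cells.mean(axis=(0, 1, 2))
    m_s = cells.mean(axis=(1, 2))  # (ns, nodes)
    m_a = cells.mean(axis=(0, 2))  # (na, nodes)
    m_b = cells.mean(axis=(0, 1))  # (nb, nodes)
    m_sa = cells.mean(axis=2)  # (ns, na, nodes)
    m_sb = cells.mean(axis=1)  # (ns, nb, nodes)
    m_ab = cells.mean(axis=0)  # (na, nb, nodes)

    if effect == "region":
        ss_eff = ns * nb * ((m_a - grand) ** 2).sum(axis=0)
        df_eff = na - 1
        resid = m_sa - m_a[None] - m_s[:, None] + grand
        ss_err = nb * (resid**2).sum(axis=(0, 1))
        df_err = (na - 1) * (ns - 1)
    elif effect == "condition":
        ss_eff = ns * na * ((m_b - grand) ** 2).sum(axis=0)
        df_eff = nb - 1
        resid = m_sb - m_b[None] - m_s[:, None] + grand
        ss_err = na * (resid**2).sum(axis=(0, 1))
        df_err = (nb - 1) * (ns - 1)
    else:
        ss_eff = ns * ((m_ab - m_a[:, None] - m_b[None] + grand) ** 2).sum(axis=(0, 1))
        df_eff = (na - 1) * (nb - 1)
        resid = (
            cells
            - m_ab[None]
            - m_sa[:, :, None]
            - m_sb[:, None]
            + m_a[None, :, None]
            + m_b[None, None]
            + m_s[:, None, None]
            - grand
        )
        ss_err = (resid**2).sum(axis=(0, 1, 2))
        df_err = (na - 1) * (nb - 1) * (ns - 1)

    # Sums of squares that are pure floating-point dust (relative to the total
    # variation at that node) are treated as exact zeros so that degenerate
    # cases give F = 0 (no effect) or +inf (zero error term) rather than a
    # ratio of rounding noise.
    total = ((cells - grand) ** 2).sum(axis=(0, 1, 2))
    tiny = 1e-12 * np.maximum(total, 1e-300)
    ss_eff = np.where(ss_eff <= tiny, 0.0, ss_eff)
    ss_err = np.where(ss_err <= tiny, 0.0, ss_err)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_eff / df_eff) / (ss_err / df_err)
    f = np.where(ss_eff == 0.0, 0.0, f)
    return f, (df_eff, df_err)


def anova_residuals(design: FieldDesign) -> np.ndarray:
    """Residuals for smoothness estimation: cell means doubly centred.

    Cell means minus the (region, condition) cell mean minus the subject
    mean plus the grand mean, flattened to (n_subjects * n_regions *
    n_conditions, n_nodes).
    """
    cells = design.cell_means()
    grand = cells.mean(axis=(0, 1, 2))
    m_s = cells.mean(axis=(1, 2))
    m_ab = cells.mean(axis=0)
    resid = cells - m_ab[None] - m_s[:, None, None] + grand
    return resid.reshape(-1, cells.shape[-1])


def pointwise_paired_t(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, int, tuple[str, ...]]:
    """Paired t field: ``t = mean(d) / (sd(d) / sqrt(n))`` per node, df = n - 1.

    Rows of ``a`` and ``b`` must be matched pairs.  Nodes with zero
    variance of the differences get a signed-infinity statistic (0 when the
    mean difference is also 0) and a flag.

    Returns ``(t_field, df, flags)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired sets must match in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
        t = np.where(degenerate, np.sign(mean) * np.inf, t)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    flags: tuple[str, ...] = ()
    if degenerate.any():
        flags = (f"zero_variance_nodes:{int(degenerate.sum())}",)
    return t, n - 1, flags


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in nodes) from model residuals.

    Residuals are normalized to unit variance per node; the RMS of their
    forward-difference gradient, pooled over rows and node gaps, gives
    ``FWHM = sqrt(4 ln 2) / RMS``.  Constant-along-node residuals (zero
    gradient) yield ``inf``.

    Raises
    ------
    ValueError
        Fewer than 2 residual rows, or all-zero residuals.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("residuals must be a (n_rows >= 2, n_nodes) matrix")
    node_sd = r.std(axis=0, ddof=1)
    if np.all(node_sd == 0):
        raise ValueError("all-zero residuals: smoothness undefined")
    node_sd = np.where(node_sd == 0, 1.0, node_sd)
    rn = r / node_sd
    grad = np.diff(rn, axis=1)
    rms = np.sqrt(np.mean(grad**2))
    if rms == 0:
        return float("inf")
    return float(_SQRT_4LN2 / rms)


def _ec1_density(stat_kind: str, u: float, df: tuple[float, float]) -> float:
    """1D Euler-characteristic density per resel (Worsley's formulas)."""
    if stat_kind == "t":
        v = df[1]
        return _SQRT_4LN2 / (2 * np.pi) * (1 + u**2 / v) ** (-(v - 1) / 2)
    if stat_kind == "F":
        k, v = df
        if u <= 0:
            u = 0.0
        lg = gammaln((v + k - 1) / 2) - gammaln(v / 2) - gammaln(k / 2)
        return (
            np.sqrt(4 * np.log(2) / (2 * np.pi))
            * np.exp(lg)
            * np.sqrt(2.0)
            * (k * u / v) ** ((k - 1) / 2)
            * (1 + k * u / v) ** (-(v + k - 2) / 2)
        )
    raise ValueError(f"stat_kind must be 't' or 'F', got {stat_kind!r}")


def _sf0(stat_kind: str, u: float, df: tuple[float, float]) -> float:
    if stat_kind == "t":
        return float(stats.t.sf(u, df[1]))
    return float(stats.f.sf(u, df[0], df[1]))


def _isf0(stat_kind: str, alpha: float, df: tuple[float, float]) -> float:
    if stat_kind == "t":
        return float(stats.t.isf(alpha, df[1]))
    return float(stats.f.isf(alpha, df[0], df[1]))


def rft_critical_threshold(
    stat_kind: str,
    df: tuple[float, float],
    n_nodes: int,
    fwhm: float,
    alpha: float = 0.05,
    tol: float = 1e-6,
) -> float:
    """Family-wise critical threshold for a smooth 1D t or F field.

    Solves for the smallest ``u`` with expected Euler characteristic
    ``P0(stat > u) + resels * EC1(u, df) = alpha`` where
    ``resels = (n_nodes - 1) / fwhm``, by bisection to tolerance ``tol``.
    In the infinitely smooth limit (resels -> 0) this reduces to the 0D
    distribution quantile.

    Raises
    ------
    ValueError
        alpha outside (0, 1) or non-positive fwhm; RuntimeError on
        non-convergence.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    resels = (n_nodes - 1) / fwhm

    def ec(u: float) -> float:
        return _sf0(stat_kind, u, df) + resels * _ec1_density(stat_kind, u, df)

    lo = _isf0(stat_kind, alpha, df)  # ec(lo) >= alpha always
    if resels == 0:
        return lo
    hi = max(lo, 1.0)
    for _ in range(200):
        if ec(hi) < alpha:
            break
        hi *= 2.0
    else:
        raise RuntimeError("RFT threshold search failed to bracket the root")
    for _ in range(10_000):
        mid = 0.5 * (lo + hi)
        if ec(mid) >= alpha:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            return 0.5 * (lo + hi)
    raise RuntimeError("RFT threshold bisection did not converge")


def suprathreshold_clusters(
    field_values: np.ndarray, threshold: float, nodes_per_percent: float = 2.0
) -> tuple[tuple[float, float], ...]:
    """Maximal runs of nodes strictly above the threshold, in % stride.

    A run over nodes ``i..j`` (inclusive) becomes the half-open interval
    ``[i / nodes_per_percent, (j + 1) / nodes_per_percent)``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = np.asarray(field_values) > threshold
    clusters = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start / nodes_per_percent, i / nodes_per_percent))
            start = None
    if start is not None:
        clusters.append((start / nodes_per_percent, above.size / nodes_per_percent))
    return tuple(clusters)


def spm_anova(
    design: FieldDesign,
    effect: str = "region",
    alpha: float = 0.05,
    stride_mode: str = "cell_means",
    fwhm: float | None = None,
) -> SpmResult:
    """RM-ANOVA F field with RFT threshold and clusters, end to end."""
    f, df = pointwise_rm_anova(design, effect, stride_mode)
    if fwhm is None:
        fwhm = estimate_fwhm(anova_residuals(design))
    threshold = rft_critical_threshold("F", df, f.size, fwhm, alpha)
    nodes_pp = f.size / 100.0
    clusters = suprathreshold_clusters(f, threshold, nodes_pp)
    return SpmResult(
        stat=f,
        stat_kind="F",
        df=df,
        fwhm=fwhm,
        critical_threshold=threshold,
        clusters=clusters,
        alpha=alpha,
    )


def spm_paired_t(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    two_tailed: bool = True,
    fwhm: float | None = None,
) -> SpmResult:
    """Paired-t field with RFT threshold; two-tailed by default.

    Two-tailed inference thresholds ``|t|`` at the one-tailed RFT level for
    ``alpha / 2``.
    """
    t, df_err, flags = pointwise_paired_t(a, b)
    if fwhm is None:
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        try:
            fwhm = estimate_fwhm(d - d.mean(axis=0))
        except ValueError:
            # Degenerate (identical pairs): treat as infinitely smooth.
            fwhm = float("inf")
    tail_alpha = alpha / 2 if two_tailed else alpha
    threshold = rft_critical_threshold("t", (1, df_err), t.size, fwhm, tail_alpha)
    nodes_pp = t.size / 100.0
    f = np.abs(t) if two_tailed else t
    clusters = suprathreshold_clusters(f, threshold, nodes_pp)
    return SpmResult(
        stat=t,
        stat_kind="t",
        df=(1, df_err),
        fwhm=fwhm,
        critical_threshold=threshold,
        clusters=clusters,
        alpha=alpha,
        flags=flags,
    )


def posthoc_paired_t_family(
    observation_sets: dict,
    comparisons: list[tuple],
    alpha_family: float = 0.05,
    two_tailed: bool = True,
) -> dict:
    """Bonferroni-corrected family of paired-t SPM comparisons.

    ``observation_sets`` maps a level key to its (n_pairs, n_nodes) matrix;
    each comparison ``(key_a, key_b)`` is tested at
    ``alpha_family / len(comparisons)``.

    Raises
    ------
    ValueError
        Empty comparison list.
    """
    if not comparisons:
        raise ValueError("comparison list must be non-empty")
    alpha_each = alpha_family / len(comparisons)
    results = {}
    for pair in comparisons:
        key_a, key_b = pair
        results[pair] = spm_paired_t(
            observation_sets[key_a], observation_sets[key_b], alpha=alpha_each, two_tailed=two_tailed
        )
    return results
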