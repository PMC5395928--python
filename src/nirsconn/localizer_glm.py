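"""Task localizer: per-channel GLM and seed selection.

The short gambling task serves only to localize seed channels for the
resting-state analysis.  Each channel's HbO series is regressed on a
boxcar convolved with a canonical double-gamma hemodynamic response
function (HRF); the most significantly activated channel per hemisphere,
together with its designated partner channel, defines the seed set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, NoSeedError
from .montage_io import ProbeMontage
from .preprocess import HemoTimeSeries

# Within-hemisphere partner channels; the two stated seed pairings
# (11 with 12, 4 with 1) anchor the table, the rest follow the same
# adjacent-pair pattern.
DEFAULT_PARTNERS = {1: 4, 4: 1, 2: 3, 3: 2, 5: 6, 6: 5,
                    7: 8, 8: 7, 9: 10, 10: 9, 11: 12, 12: 11}


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF, unit peak, on time grid ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    h = (stats.gamma.pdf(t, a=peak_s + 1.0)
         - undershoot_ratio * stats.gamma.pdf(t, a=undershoot_s + 1.0))
    m = h.max()
    return h / m if m > 0 else h


def task_regressor(events, n_samples: int, rate_hz: float,
                   hrf_params: dict | None = None) -> dict:
    """HRF-convolved boxcar per condition, on the series' sample grid."""
    hrf_params = hrf_params or {}
    kernel_t = np.arange(0, 32.0, 1.0 / rate_hz)
    kernel = double_gamma_hrf(kernel_t, **hrf_params)
    regs = {}
    for onset, dur, cond in events:
        box = regs.setdefault(cond, np.zeros(n_samples))
        i0 = int(round(onset * rate_hz))
        i1 = int(round((onset + dur) * rate_hz))
        i0c, i1c = max(i0, 0), min(max(i1, 0), n_samples)
        if i1c > i0c:
            if box[i0c:i1c].any():
                warnings.warn(f"overlapping {cond!r} events merged")
            box[i0c:i1c] = 1.0
    return {cond: np.convolve(box, kernel)[:n_samples]
            for cond, box in regs.items()}


def build_design_matrix(events, duration_s: float, rate_hz: float,
                        hrf_params: dict | None = None):
    """Design matrix (intercept + one mean-centered column per condition).

    Returns ``(X, names)`` with ``names[0] == "intercept"``.
    """
    n = int(round(duration_s * rate_hz))
    for onset, dur, _ in events:
        if onset < 0 or onset + dur > duration_s + 1e-9:
            raise ValueError(f"event at {onset}s outside recording duration")
    regs = task_regressor(events, n, rate_hz, hrf_params)
    names = ["intercept"] + sorted(regs)
    X = np.ones((n, len(names)))
    for j, cond in enumerate(names[1:], start=1):
        col = regs[cond]
        X[:, j] = col - col.mean()
    return X, names


@dataclass
class ActivationResult:
    """Per-channel GLM output for the localizer contrast."""

    channel_ids: tuple
    beta: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    design_info: str = ""

    def as_dict(self):
        return {c: (float(self.beta[i]), float(self.tstat[i]),
                    float(self.pvalue[i]))
                for i, c in enumerate(self.channel_ids)}


@dataclass(frozen=True)
class SeedSet:
    """Selected seed channels per hemisphere (activated channel, partner)."""

    seeds_left: tuple
    seeds_right: tuple

    @property
    def primary_left(self) -> int:
        return self.seeds_left[0]

    @property
    def primary_right(self) -> int:
        return self.seeds_right[0]

    def all_seeds(self) -> tuple:
        return tuple(self.seeds_right) + tuple(self.seeds_left)


def fit_glm(series: HemoTimeSeries, X: np.ndarray, names=None,
            contrast_col: int = 1, normalize: bool = False) -> ActivationResult:
    """Per-channel ordinary least squares of HbO on the design.

    ``contrast_col`` selects the regressor whose coefficient is tested
    (two-sided t with residual degrees of freedom).  With ``normalize``
    each channel is z-scored first, matching run-average normalization.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != series.n_samples:
        raise EstimationError(
            f"design rows ({X.shape[0]}) != series samples ({series.n_samples})")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("rank-deficient design matrix")
    df = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    y = series.hbo
    if normalize:
        sd = y.std(axis=0)
        sd[sd == 0] = 1.0
        y = (y - y.mean(axis=0)) / sd
    betas = xtx_inv @ X.T @ y                  # (params, channels)
    resid = y - X @ betas
    sigma2 = np.sum(resid ** 2, axis=0) / max(df, 1)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[contrast_col, contrast_col], 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas[contrast_col] / se, np.inf * np.sign(betas[contrast_col]))
    p = 2 * stats.t.sf(np.abs(t), df)
    valid = series.valid_channels
    ids = tuple(c for i, c in enumerate(series.channel_ids) if valid[i])
    keep = np.asarray(valid, dtype=bool)
    info = "+".join(names) if names else f"{X.shape[1]} regressors"
    return ActivationResult(ids, betas[contrast_col][keep], t[keep], p[keep],
                            design_info=info)


def group_activation(betas_by_subject: np.ndarray,
                     channel_ids) -> ActivationResult:
    """One-sample t-test across subjects of per-subject GLM betas.

    ``betas_by_subject`` is (subjects, channels); NaN entries (masked
    channels) are ignored per channel.
    """
    b = np.asarray(betas_by_subject, dtype=float)
    mean = np.nanmean(b, axis=0)
    n = np.sum(np.isfinite(b), axis=0)
    sd = np.nanstd(b, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 1, 1))
    return ActivationResult(tuple(channel_ids), mean, t, p,
                            design_info="group one-sample t on subject betas")


def select_seeds(activation: ActivationResult, montage: ProbeMontage,
                 alpha: float = 0.05,
                 partner_map: dict | None = None) -> SeedSet:
    """Pick the most significant activated channel per hemisphere plus partner.

    A channel counts as activated when its response is positive and its
    two-sided p-value is below ``alpha``.  If either hemisphere has no
    activated channel the localizer has failed and the resting-state
    pipeline cannot proceed.
    """
    partner_map = partner_map or DEFAULT_PARTNERS
    stats_by_channel = activation.as_dict()
    seeds = {}
    for hemi in ("left", "right"):
        candidates = [(t, c) for c, (b, t, p) in stats_by_channel.items()
                      if montage.hemisphere(c) == hemi and p < alpha and t > 0]
        if not candidates:
            raise NoSeedError(
                f"no significantly activated channel in the {hemi} hemisphere "
                f"(alpha={alpha}); cannot define seeds")
        best = max(candidates)[1]
        partner = partner_map.get(best)
        if partner is None or partner not in montage.channel_ids:
            raise NoSeedError(f"no partner channel defined for seed {best}")
        seeds[hemi] = (best, partner)
    return SeedSet(seeds_left=seeds["left"], seeds_right=seeds["right"])
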