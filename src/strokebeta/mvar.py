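"""Multivariate autoregressive (MVAR) spectral connectivity.

The core computation of the pipeline. Six ROI source time courses X_t are
modelled as an order-p MVAR process

    X_t = sum_{k=1..p} A_k X_{t-k} + eps(t),

fitted by ordinary least squares pooled over epochs (lags never cross epoch
boundaries). The coefficient stack is taken to the frequency domain,

    A(f)    = sum_k A_k exp(-i 2 pi f k / fs)
    Abar(f) = I - A(f)
    H(f)    = Abar(f)^{-1}
    S(f)    = H(f) C H(f)^H ,

where C is the residual covariance. The spectral matrix S carries the power
spectra on its diagonal (PSD = diag(S)/fs) and cross-spectral densities off
it; magnitude-squared coherence (MSC) and partial directed coherence (PDC)
follow:

    MSC_ij = |S_ij|^2 / (S_ii S_jj)
    PDC_ij = |Abar_ij| / sqrt(sum_m |Abar_mj|^2).

PDC uses the source-column normalization: entry (i, j) is the directed
influence of source j onto target i as a proportion of j's total outflow,
so each column of squared PDC sums to one at every frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import EpochedSeries

__all__ = [
    "MVARModel",
    "SpectralDecomposition",
    "TimeResolvedSpectra",
    "BandSummary",
    "fit_mvar",
    "spectra",
    "sliding_spectra",
    "band_window_average",
    "beta_power_timecourse",
    "derive_rebound_window",
    "companion_eigenvalues",
]

BETA_BAND = (13.0, 30.0)
DEFAULT_REBOUND_WINDOW = (0.6, 1.2)
DEFAULT_FREQS = np.arange(1.0, 45.0 + 1e-9, 0.5)


@dataclass
class MVARModel:
    """Fitted MVAR parameters.

    coeffs has shape (p, n, n): coeffs[k-1] is the lag-k matrix A_k.
    resid_cov is the innovation covariance C (denominator T-1).
    """

    coeffs: np.ndarray
    resid_cov: np.ndarray
    fs: float
    n_samples_used: int
    stable: bool = True

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class SpectralDecomposition:
    """Frequency-resolved MVAR spectra and connectivity."""

    freqs: np.ndarray       # (n_f,)
    Abar: np.ndarray        # (n_f, n, n) complex, I - A(f)
    H: np.ndarray           # (n_f, n, n) complex transfer function
    S: np.ndarray           # (n_f, n, n) complex spectral matrix
    psd: np.ndarray         # (n_f, n) real, diag(S)/fs
    msc: np.ndarray         # (n_f, n, n) real in [0, 1]
    pdc: np.ndarray         # (n_f, n, n) real, column-normalized


@dataclass
class TimeResolvedSpectra:
    """Spectra from sliding pooled-epoch windows, indexed by window center."""

    centers: np.ndarray     # (n_win,) seconds relative to stimulus
    freqs: np.ndarray       # (n_f,)
    psd: np.ndarray         # (n_win, n_f, n)
    msc: np.ndarray         # (n_win, n_f, n, n)
    pdc: np.ndarray         # (n_win, n_f, n, n)


@dataclass
class BandSummary:
    """PSD/MSC/PDC averaged over a frequency band and a time window."""

    band: tuple
    window: tuple
    psd_beta: np.ndarray    # (n,)
    msc_beta: np.ndarray    # (n, n) symmetric
    pdc_beta: np.ndarray    # (n, n); [i, j] = influence j -> i
    roi_labels: tuple = field(default=())


def companion_eigenvalues(coeffs: np.ndarray) -> np.ndarray:
    """Eigenvalues of the companion matrix of a coefficient stack."""
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return np.linalg.eigvals(comp)


def is_stable(coeffs: np.ndarray, tol: float = 1.0) -> bool:
    return bool(np.all(np.abs(companion_eigenvalues(coeffs)) < tol))


def _as_epoch_array(epochs) -> tuple[np.ndarray, float]:
    if isinstance(epochs, EpochedSeries):
        return epochs.data, epochs.fs
    raise TypeError("expected an EpochedSeries")


def fit_mvar(epochs, sample_window: tuple | None = None,
             order: int = 6, fs: float | None = None) -> MVARModel:
    """Fit an MVAR(p) by OLS pooled over epochs.

    Parameters
    ----------
    epochs : EpochedSeries or ndarray (n_epochs, n_roi, n_samples)
        When an ndarray is given, ``fs`` must be supplied and
        ``sample_window`` is in samples, not seconds.
    sample_window : (t_a, t_b) in seconds (EpochedSeries) or None
        Restrict the fit to samples with t_a <= t < t_b. Lagged predictors
        are taken from inside the window only, so windows from different
        trial phases never mix.
    order : int
        Model order p (default 6).

    Notes
    -----
    Pooled sample count must be at least 10 * p * n_roi. The residual
    covariance uses the 1/(T-1) denominator. A fitted stack whose companion
    eigenvalues touch the unit circle is flagged unstable (warning), not
    rejected: estimation noise can push a near-unit-root fit across.
    """
    if isinstance(epochs, EpochedSeries):
        data = (epochs.time_slice(*sample_window) if sample_window
                else epochs.data)
        fs = epochs.fs
    else:
        data = np.asarray(epochs, dtype=float)
        if fs is None:
            raise ValueError("fs required with a bare array")
        if sample_window is not None:
            data = data[:, :, sample_window[0]:sample_window[1]]
    if data.ndim != 3:
        raise ValueError("epoch data must be 3-d (epoch, roi, sample)")
    n_epochs, n_roi, n_samples = data.shape
    if n_samples < order + 1:
        raise ValueError(
            f"epochs of {n_samples} samples cannot support order {order}"
        )
    pooled = n_epochs * (n_samples - order)
    if pooled < 10 * order * n_roi:
        raise ValueError(
            f"pooled sample count {pooled} below 10*p*n_roi = "
            f"{10 * order * n_roi}"
        )

    # lagged design, never crossing epoch boundaries
    # rows: epochs x (n_samples - p); cols: n_roi * p
    y = data[:, :, order:].transpose(0, 2, 1).reshape(-1, n_roi)
    lags = [
        data[:, :, order - k:n_samples - k].transpose(0, 2, 1).reshape(
            -1, n_roi)
        for k in range(1, order + 1)
    ]
    X = np.concatenate(lags, axis=1)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which lag block is deficient for the error message
        for k in range(order):
            blk = X[:, k * n_roi:(k + 1) * n_roi]
            if np.linalg.matrix_rank(blk) < n_roi:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design at lag {k + 1}")
        raise np.linalg.LinAlgError("rank-deficient lagged design")

    B, *_ = np.linalg.lstsq(X, y, rcond=None)
    coeffs = np.stack([B[k * n_roi:(k + 1) * n_roi].T
                       for k in range(order)])
    resid = y - X @ B
    resid_c = resid - resid.mean(axis=0)
    C = resid_c.T @ resid_c / (pooled - 1)
    C = 0.5 * (C + C.T)

    stable = is_stable(coeffs)
    if not stable:
        warnings.warn("fitted MVAR is not stable (companion eigenvalue on "
                      "or outside the unit circle)")
    return MVARModel(coeffs=coeffs, resid_cov=C, fs=fs,
                     n_samples_used=pooled, stable=stable)


def spectra(model: MVARModel, freqs=None) -> SpectralDecomposition:
    """Frequency-domain decomposition of a fitted MVAR model.

    Raises if Abar(f) is numerically singular at some frequency, naming it.
    """
    freqs = np.asarray(DEFAULT_FREQS if freqs is None else freqs,
                       dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    p, n = model.order, model.n_channels
    k = np.arange(1, p + 1)
    # phase[f, k] = exp(-i 2 pi f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / model.fs)
    A_f = np.einsum("fk,kij->fij", phase, model.coeffs.astype(complex))
    Abar = np.eye(n)[None] - A_f

    dets = np.linalg.det(Abar)
    bad = np.abs(dets) < 1e-12
    if bad.any():
        raise np.linalg.LinAlgError(
            f"Abar(f) singular at f = {freqs[bad][0]:g} Hz")
    H = np.linalg.inv(Abar)
    S = H @ model.resid_cov @ np.conjugate(H).transpose(0, 2, 1)
    psd = np.real(np.einsum("fii->fi", S)) / model.fs

    diag = np.real(np.einsum("fii->fi", S))
    denom = diag[:, :, None] * diag[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(S) ** 2 / denom
    msc = np.clip(np.nan_to_num(msc), 0.0, 1.0)

    col_norm = np.sqrt(np.sum(np.abs(Abar) ** 2, axis=1, keepdims=True))
    pdc = np.abs(Abar) / col_norm
    return SpectralDecomposition(freqs=freqs, Abar=Abar, H=H, S=S,
                                 psd=psd, msc=msc, pdc=pdc)


def sliding_spectra(epochs: EpochedSeries, win_len_s: float = 0.2,
                    step_s: float = 0.05, order: int = 6,
                    freqs=None) -> TimeResolvedSpectra:
    """Time-resolved spectra from sliding windows pooled across epochs.

    Each window's samples (across all epochs) are pooled into one MVAR fit;
    outputs are indexed by window center time. A step larger than the epoch
    span degenerates to a single whole-epoch window.
    """
    freqs = np.asarray(DEFAULT_FREQS if freqs is None else freqs,
                       dtype=float)
    t = epochs.times
    span = t[-1] - t[0]
    if step_s > span:
        win_starts = [t[0]]
        win_len_s = span + 1.0 / epochs.fs
    else:
        win_starts = np.arange(t[0], t[-1] - win_len_s + 1e-9, step_s)

    centers, psd_l, msc_l, pdc_l = [], [], [], []
    for ws in win_starts:
        model = fit_mvar(epochs, sample_window=(ws, ws + win_len_s),
                         order=order)
        dec = spectra(model, freqs)
        centers.append(ws + win_len_s / 2.0)
        psd_l.append(dec.psd)
        msc_l.append(dec.msc)
        pdc_l.append(dec.pdc)
    return TimeResolvedSpectra(centers=np.asarray(centers), freqs=freqs,
                               psd=np.stack(psd_l), msc=np.stack(msc_l),
                               pdc=np.stack(pdc_l))


def band_window_average(tr: TimeResolvedSpectra, band=BETA_BAND,
                        window=DEFAULT_REBOUND_WINDOW,
                        roi_labels: tuple = ()) -> BandSummary:
    """Average PSD/MSC/PDC over a frequency band and window-center range."""
    fsel = (tr.freqs >= band[0]) & (tr.freqs <= band[1])
    wsel = (tr.centers >= window[0]) & (tr.centers <= window[1])
    if not fsel.any() or not wsel.any():
        raise ValueError("empty band or window selection")
    psd = tr.psd[wsel][:, fsel].mean(axis=(0, 1))
    msc = tr.msc[wsel][:, fsel].mean(axis=(0, 1))
    pdc = tr.pdc[wsel][:, fsel].mean(axis=(0, 1))
    return BandSummary(band=tuple(band), window=tuple(window),
                       psd_beta=psd, msc_beta=msc, pdc_beta=pdc,
                       roi_labels=roi_labels)


def beta_power_timecourse(epochs: EpochedSeries, band=BETA_BAND,
                          baseline=(-0.5, 0.0)) -> tuple[np.ndarray,
                                                         np.ndarray]:
    """Baseline-referenced beta power envelope, averaged over epochs.

    Band-pass 13-30 Hz, analytic-signal envelope squared, averaged over
    epochs, expressed as relative change against the mean over the
    pre-stimulus baseline.

    Returns
    -------
    (times, rel_power) with rel_power of shape (n_roi, n_times).
    """
    sos = signal.butter(4, band, btype="bandpass", fs=epochs.fs,
                        output="sos")
    filt = signal.sosfiltfilt(sos, epochs.data, axis=2)
    env2 = np.abs(signal.hilbert(filt, axis=2)) ** 2
    mean_env = env2.mean(axis=0)          # (n_roi, n_times)
    t = epochs.times
    bsel = (t >= baseline[0]) & (t < baseline[1])
    base = mean_env[:, bsel].mean(axis=1, keepdims=True)
    return t, mean_env / base - 1.0


def derive_rebound_window(subject_timecourses: np.ndarray,
                          times: np.ndarray, n_perm: int = 500,
                          seed=None, alpha_percentile: float = 95.0,
                          fallback=DEFAULT_REBOUND_WINDOW
                          ) -> tuple[float, float]:
    """Data-driven rebound window from subjects' beta power time courses.

    At each post-stimulus time point a one-sample sign-flip permutation
    test asks whether the subjects' relative beta power exceeds zero; the
    window is the longest contiguous run of significantly positive time
    points. Falls back to the canonical window with a warning when no run
    is found.

    Parameters
    ----------
    subject_timecourses : ndarray (n_subjects, n_times)
        Baseline-referenced beta power per subject (ROI-averaged or a
        single ROI).
    times : ndarray (n_times,) seconds relative to stimulus.
    """
    tc = np.asarray(subject_timecourses, dtype=float)
    n_subj, n_times = tc.shape
    if n_subj < 5:
        raise ValueError("need at least 5 subjects")
    rng = np.random.default_rng(seed)

    post = times > 0
    x = tc[:, post]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(sd > 0, m / (sd / np.sqrt(n_subj)), 0.0)

    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_subj))
    # null t per permutation and time point; one shared sign matrix
    flip = signs[:, :, None] * x[None, :, :]
    fm = flip.mean(axis=1)
    fsd = flip.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(fsd > 0, fm / (fsd / np.sqrt(n_subj)), 0.0)
    thr = np.percentile(np.abs(t_null), alpha_percentile, axis=0)
    sig_pos = (t_obs > thr) & (m > 0)

    # longest contiguous run of significant positive points
    best_len = best_start = 0
    cur_len = cur_start = 0
    for i, s in enumerate(sig_pos):
        if s:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    if best_len == 0:
        warnings.warn("no significant positive run found; falling back to "
                      f"the default rebound window {fallback}")
        return tuple(fallback)
    t_post = times[post]
    return (float(t_post[best_start]),
            float(t_post[best_start + best_len - 1]))
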