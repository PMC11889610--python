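"""Cohort-level analysis: grouping, feature extraction, group contrasts.

Subjects are grouped by initial motor function (NHPT at T0, 100 s cutoff;
"did not finish" coded at the cap counts as low function) and, within the
initially low-function group, by improvement (NHPT T1 - T0 < 0). For each
subject a functional feature set (band/window-averaged PSD, MSC, and PDC
asymmetry from the MVAR spectra) and a structural feature set (lesion
volume, ROI damage, tract disconnection, SSPL increases) is extracted;
group contrasts use row-shuffle permutation tests, and within-group
connectivity existence uses sign-flip tests.

Raw MSC is positively biased and never zero, so "strength different from
zero" is tested by default on MSC minus a subject-specific phase-scrambled
surrogate baseline; raw mode is available behind a flag.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from . import lesions as _lesions
from . import mvar as _mvar
from .permutation import one_sample_perm, summarize_family, two_sample_perm
from .preprocess import ROI_LABELS, detect_bad_segments, epoch_and_baseline

__all__ = [
    "classify_function",
    "classify_improvement",
    "functional_features",
    "build_cohort_table",
    "run_function_contrast",
    "run_recovery_contrast",
    "PAIRS",
]

PAIRS = tuple(combinations(range(6), 2))


def classify_function(nhpt_t0: float, cutoff_s: float = 100.0,
                      dnf: bool = False) -> str:
    """'low' when the subject took >= cutoff seconds (or did not finish)."""
    if nhpt_t0 <= 0:
        raise ValueError("nhpt_t0 must be positive")
    return "low" if (dnf or nhpt_t0 >= cutoff_s) else "high"


def classify_improvement(nhpt_t0: float, nhpt_t1: float) -> str:
    """'improved' iff NHPT strictly decreased from T0 to T1."""
    return "improved" if (nhpt_t1 - nhpt_t0) < 0 else "not_improved"


def _phase_scramble(data: np.ndarray, rng) -> np.ndarray:
    """Independent phase randomization per epoch and channel.

    Preserves each series' amplitude spectrum while destroying cross-
    channel dependence, giving a null for coherence magnitude.
    """
    n = data.shape[-1]
    spec = np.fft.rfft(data, axis=-1)
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    return np.fft.irfft(spec * np.exp(1j * phases), n=n, axis=-1)


def functional_features(epochs, band=_mvar.BETA_BAND,
                        window=_mvar.DEFAULT_REBOUND_WINDOW,
                        order: int = 6, win_len_s: float = 0.2,
                        step_s: float = 0.05, n_surrogates: int = 20,
                        seed=None, roi_labels=ROI_LABELS) -> dict:
    """Band/window-averaged spectral features for one subject.

    Returns a flat dict: ``psd_<roi>``, ``msc_<a>_<b>`` (unordered),
    ``mscdb_<a>_<b>`` (surrogate-debiased MSC), and ``pdcasym_<a>_<b>``
    (directed influence a->b minus b->a, so a positive value means a
    drives b).
    """
    tr = _mvar.sliding_spectra(epochs, win_len_s=win_len_s, step_s=step_s,
                               order=order)
    summ = _mvar.band_window_average(tr, band=band, window=window,
                                     roi_labels=roi_labels)
    out = {}
    for i, lab in enumerate(roi_labels):
        out[f"psd_{lab}"] = float(summ.psd_beta[i])
    for i, j in PAIRS:
        a, b = roi_labels[i], roi_labels[j]
        out[f"msc_{a}_{b}"] = float(summ.msc_beta[i, j])
        # pdc[i, j] is influence j -> i
        out[f"pdcasym_{a}_{b}"] = float(summ.pdc_beta[j, i]
                                        - summ.pdc_beta[i, j])

    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        # surrogate baseline from a single pooled fit over the analysis
        # window (the sliding grid would only re-estimate the same bias)
        win_data = epochs.time_slice(*window)
        fsel = ((_mvar.DEFAULT_FREQS >= band[0])
                & (_mvar.DEFAULT_FREQS <= band[1]))
        acc = np.zeros((6, 6))
        for _ in range(n_surrogates):
            surr = _phase_scramble(win_data, rng)
            m = _mvar.fit_mvar(surr, order=order, fs=epochs.fs)
            dec = _mvar.spectra(m, _mvar.DEFAULT_FREQS[fsel])
            acc += dec.msc.mean(axis=0)
        acc /= n_surrogates
        for i, j in PAIRS:
            a, b = roi_labels[i], roi_labels[j]
            out[f"mscdb_{a}_{b}"] = out[f"msc_{a}_{b}"] - float(acc[i, j])
    return out


def build_cohort_table(records, atlas, streamlines,
                       band=_mvar.BETA_BAND, window=None,
                       cutoff_s: float = 100.0, n_surrogates: int = 20,
                       rebound_n_perm: int = 500,
                       seed=None) -> tuple[pd.DataFrame, tuple]:
    """Assemble the per-subject feature table from raw records.

    Runs the preprocessing (bad-segment detection, epoching, baseline
    correction), derives the rebound window from the cohort's grand beta
    power time courses when ``window`` is None, extracts functional and
    structural features, and attaches the group labels.

    Returns (table, rebound_window).
    """
    rng = np.random.default_rng(seed)
    all_epochs = []
    timecourses = []
    times = None
    for rec in records:
        mask = detect_bad_segments(rec.continuous, rec.fs)
        tmax = 1.5 if (rec.triggers.size > 1 and
                       np.diff(rec.triggers).min() < 2.0 * rec.fs) else 3.0
        ep, _ = epoch_and_baseline(rec.continuous, rec.triggers, rec.fs,
                                   tmax=tmax, bad_mask=mask)
        all_epochs.append(ep)
        t, rel = _mvar.beta_power_timecourse(ep, band=band)
        times = t
        timecourses.append(rel.mean(axis=0))   # ROI-averaged

    if window is None:
        window = _mvar.derive_rebound_window(
            np.vstack(timecourses), times, n_perm=rebound_n_perm,
            seed=rng.integers(2 ** 31))

    rows = []
    for rec, ep in zip(records, all_epochs):
        feats = {"subject_id": rec.subject_id, "nhpt_t0": rec.nhpt_t0,
                 "nhpt_t1": rec.nhpt_t1, "dnf": rec.dnf}
        feats["function_group"] = classify_function(
            rec.nhpt_t0, cutoff_s, dnf=rec.dnf)
        feats["improvement_group"] = (
            classify_improvement(rec.nhpt_t0, rec.nhpt_t1)
            if rec.nhpt_t1 is not None and not math.isnan(rec.nhpt_t1)
            else "NA")
        feats.update(functional_features(
            ep, band=band, window=window, n_surrogates=n_surrogates,
            seed=rng.integers(2 ** 31)))
        if rec.lesion is not None and atlas is not None:
            sf = _lesions.extract_structural_features(
                rec.lesion, atlas, streamlines)
            feats.update(sf.to_row())
        rows.append(feats)
    return pd.DataFrame(rows), tuple(window)


def _feature_columns(table: pd.DataFrame) -> dict:
    cols = {"psd": [], "msc": [], "mscdb": [], "pdcasym": [],
            "structural": []}
    for c in table.columns:
        if c.startswith("psd_"):
            cols["psd"].append(c)
        elif c.startswith("msc_"):
            cols["msc"].append(c)
        elif c.startswith("mscdb_"):
            cols["mscdb"].append(c)
        elif c.startswith("pdcasym_"):
            cols["pdcasym"].append(c)
        elif (c.startswith(("damage_", "disc_", "sspl_"))
              or c in ("lesion_volume", "projection_mean",
                       "commissural_mean")):
            cols["structural"].append(c)
    return cols


def _clean_pair(table, col, mask_a, mask_b):
    """Group values for one feature, dropping non-finite entries (the
    explicit infinity sentinel of disconnected SSPL pairs)."""
    v = table[col].to_numpy(dtype=float)
    a = v[mask_a]
    b = v[mask_b]
    return a[np.isfinite(a)], b[np.isfinite(b)]


def _contrast(table: pd.DataFrame, group_col: str, level_a: str,
              level_b: str, n_perm: int, seed, msc_mode: str,
              correction: str) -> pd.DataFrame:
    """Shared battery: group differences + within-group existence tests."""
    if msc_mode not in ("debiased", "raw"):
        raise ValueError("msc_mode must be 'debiased' or 'raw'")
    mask_a = (table[group_col] == level_a).to_numpy()
    mask_b = (table[group_col] == level_b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(
            f"each {group_col} level needs >= 3 subjects "
            f"(got {mask_a.sum()} {level_a!r}, {mask_b.sum()} {level_b!r})")
    cols = _feature_columns(table)
    ss = np.random.SeedSequence(seed)
    frames = []

    strength_cols = (cols["mscdb"] if msc_mode == "debiased"
                     else cols["msc"])

    # group differences, one family per measure class
    for cls in ("psd", "msc", "pdcasym", "structural"):
        fam_seed = ss.spawn(1)[0].generate_state(1)[0]
        tests = {}
        for col in cols[cls]:
            a, b = _clean_pair(table, col, mask_a, mask_b)
            if a.size < 3 or b.size < 3:
                continue
            tests[col] = two_sample_perm(a, b, n_perm=n_perm,
                                         seed=fam_seed)
        if tests:
            df = summarize_family(tests, correction)
            df.insert(0, "analysis", f"difference_{cls}")
            df.insert(1, "contrast", f"{level_a}_vs_{level_b}")
            frames.append(df)

    # within-group existence: connection strength and directionality
    for level, mask in ((level_a, mask_a), (level_b, mask_b)):
        for cls, use in (("strength", strength_cols),
                         ("direction", cols["pdcasym"])):
            fam_seed = ss.spawn(1)[0].generate_state(1)[0]
            tests = {}
            for col in use:
                v = table[col].to_numpy(dtype=float)[mask]
                v = v[np.isfinite(v)]
                if v.size < 5:
                    continue
                tests[col] = one_sample_perm(v, n_perm=n_perm,
                                             seed=fam_seed)
            if tests:
                df = summarize_family(tests, correction)
                df.insert(0, "analysis", cls)
                df.insert(1, "contrast", f"within_{level}")
                frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_function_contrast(table: pd.DataFrame, n_perm: int = 5000,
                          seed=None, msc_mode: str = "debiased",
                          correction: str = "per_test") -> pd.DataFrame:
    """Low- vs high-initial-function battery (differences + existence)."""
    return _contrast(table, "function_group", "low", "high", n_perm, seed,
                     msc_mode, correction)


def run_recovery_contrast(table: pd.DataFrame, n_perm: int = 5000,
                          seed=None, msc_mode: str = "debiased",
                          correction: str = "per_test") -> pd.DataFrame:
    """Improved vs not-improved battery within initially low-function
    subjects; high-function rows are excluded (count recorded in
    ``df.attrs['n_excluded_high']``)."""
    low = table[table["function_group"] == "low"]
    n_excluded = len(table) - len(low)
    out = _contrast(low, "improvement_group", "improved", "not_improved",
                    n_perm, seed, msc_mode, correction)
    out.attrs["n_excluded_high"] = n_excluded
    return out
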