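"""Synthetic post-stroke cohorts with planted group structure.

Generates everything the analysis consumes, so the full pipeline runs
without any external data:

* six-ROI source time courses from a stable MVAR process with a beta-band
  (20 Hz) resonance, post-stimulus suppression then rebound realized as
  gain modulation of the innovations feeding each ROI's beta oscillator;
* binary lesion masks on a small voxel grid, together with a parcel atlas
  and a streamline set, whose size and tract intersections track a latent
  severity;
* Nine-Hole Peg Test (NHPT) scores at two time points derived from the
  latent severity and a latent improvement indicator, capped at 120 s.

Planted group structure mirrors the analysis contrasts: initially
low-function subjects have a reduced ipsilesional rebound gain and weak
intra-hemispheric coupling; among them, improvers carry an ipsilesional
-> contralesional inter-hemispheric drive while non-improvers carry the
reverse, and non-improvers get larger lesions. All subjects are generated
as right-hemisphere-lesioned, so ROI labels are directly contralateral
("c", ipsilesional) and ipsilateral ("i", contralesional) to the affected
hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .lesions import ParcelAtlas, StreamlineAtlas, VoxelGrid
from .mvar import companion_eigenvalues
from .preprocess import ROI_LABELS

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SubjectRecord",
    "DEFAULT_EFFECTS",
    "generate_cohort",
    "simulate_roi_process",
    "simulate_continuous",
    "assign_nhpt",
    "base_coefficients",
    "make_gain_envelope",
    "make_atlas_fixture",
    "save_cohort",
]

#: planted effect sizes defining the study conditions (see docs/methods.md)
DEFAULT_EFFECTS = {
    "rebound_gain_delta": 0.6,        # ipsilesional gain deficit, low group
    "intra_coupling_delta": 0.03,     # extra S2->S1->M1 coupling, high group
    "inter_directionality_delta": 0.015,  # inter-hemispheric drive magnitude
    "lesion_size_delta": 1.0,         # severity -> lesion radius coupling
    "tract_disconnection_delta": 1.0,  # lesion elongation along the tracts
}

_EFFECT_KEYS = frozenset(DEFAULT_EFFECTS)

BETA_F0 = 20.0        # Hz, center of the planted beta resonance
BETA_RADIUS = 0.95    # pole radius of the AR(2) oscillator
NHPT_CAP = 120.0
BASE_REBOUND_GAIN = 1.5
SUPPRESSION_GAIN = 0.4


@dataclass
class CohortConfig:
    """Cohort generation parameters.

    isi_s is the interstimulus interval (1.5 s or 3.005 s, matching the
    two acquisition protocols); 60-80 stimuli per hand; fs must exceed
    twice the 45 Hz analysis ceiling.
    """

    n_subjects: int = 36
    isi_s: float = 1.5
    n_stimuli: int = 60
    fs: float = 250.0
    group_effect_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 1.0
    dropout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.isi_s not in (1.5, 3.005):
            raise ValueError("isi_s must be 1.5 or 3.005")
        if not 60 <= self.n_stimuli <= 80:
            raise ValueError("n_stimuli must be in [60, 80]")
        if self.fs <= 2 * 45.0:
            raise ValueError("fs must exceed 90 Hz")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must be in [0, 1)")
        unknown = set(self.group_effect_sizes) - _EFFECT_KEYS
        if unknown:
            raise ValueError(f"unknown effect-size keys: {sorted(unknown)}")
        eff = dict(DEFAULT_EFFECTS)
        eff.update(self.group_effect_sizes)
        self.group_effect_sizes = eff

    @property
    def epoch_tmax(self) -> float:
        return 1.5 if self.isi_s == 1.5 else 3.0


@dataclass
class SubjectRecord:
    subject_id: str
    nhpt_t0: float
    nhpt_t1: float
    affected_side: str                       # hand; lesion is contralateral
    dnf: bool                                # did not finish within the cap
    continuous: np.ndarray = field(repr=False)   # (6, n_samples)
    triggers: np.ndarray = field(repr=False)     # stimulus sample indices
    fs: float = 250.0
    lesion: VoxelGrid = None
    data_path: str | None = None
    lesion_path: str | None = None


@dataclass
class GroundTruth:
    severity: np.ndarray                     # (n,) in [0, 1]
    improvement: np.ndarray                  # (n,) 0/1
    function_low: np.ndarray                 # (n,) bool, planted label
    coeff_stacks: list = field(repr=False)   # per-subject (p, 6, 6)
    rebound_gain: np.ndarray = field(default=None, repr=False)  # (n, 6)
    atlas: ParcelAtlas = field(default=None, repr=False)
    streamlines: StreamlineAtlas = field(default=None, repr=False)


def base_coefficients(fs: float = 250.0, n_roi: int = 6, order: int = 6,
                      couplings=None) -> np.ndarray:
    """Order-p coefficient stack with an AR(2) beta oscillator per ROI.

    The pole pair sits at BETA_F0 with radius BETA_RADIUS (lag-1 and lag-2
    diagonal terms); directed couplings (dict (target, source) -> weight)
    enter at lag 1. Higher lags are zero, left free for fitting.
    """
    theta = 2.0 * np.pi * BETA_F0 / fs
    a1 = 2.0 * BETA_RADIUS * np.cos(theta)
    a2 = -BETA_RADIUS ** 2
    coeffs = np.zeros((order, n_roi, n_roi))
    coeffs[0] += np.eye(n_roi) * a1
    coeffs[1] += np.eye(n_roi) * a2
    if couplings:
        for (tgt, src), w in couplings.items():
            coeffs[0, tgt, src] += w
    return coeffs


def _check_stable(coeffs: np.ndarray) -> None:
    mags = np.abs(companion_eigenvalues(coeffs))
    if mags.max() >= 1.0:
        raise ValueError(
            f"unstable coefficient stack: companion eigenvalue modulus "
            f"{mags.max():.4f} >= 1")


def make_gain_envelope(times: np.ndarray, rebound_gain: float,
                       suppression_gain: float = SUPPRESSION_GAIN
                       ) -> np.ndarray:
    """Innovation gain vs time since stimulus.

    1 before the stimulus and during the baseline; below 1 through the
    suppression interval (~0.2-0.5 s); equal to ``rebound_gain`` across
    the rebound interval (0.6-1.2 s); back to 1 afterwards.
    """
    knots_t = np.array([0.18, 0.28, 0.45, 0.52, 0.60, 1.20, 1.30])
    knots_v = np.array([1.0, suppression_gain, suppression_gain, 0.95,
                        rebound_gain, rebound_gain, 1.0])
    env = np.interp(times, knots_t, knots_v, left=1.0, right=1.0)
    return env


def simulate_continuous(coeffs: np.ndarray, envelope: np.ndarray,
                        noise_sd: float = 1.0, seed=None,
                        burn_in: int = 500) -> np.ndarray:
    """Simulate an MVAR process with time-varying innovation gain.

    Parameters
    ----------
    coeffs : (p, n, n) stable coefficient stack
    envelope : (n, n_samples) multiplicative gain on the innovation sd
    """
    _check_stable(coeffs)
    rng = np.random.default_rng(seed)
    p, n, _ = coeffs.shape
    n_samples = envelope.shape[1]
    stacked = np.concatenate(list(coeffs), axis=1)     # (n, n*p)
    total = burn_in + n_samples
    eps = rng.standard_normal((n, total)) * noise_sd
    eps[:, burn_in:] *= envelope
    x = np.zeros((n, total))
    state = np.zeros(n * p)
    for t in range(total):
        xt = stacked @ state + eps[:, t]
        x[:, t] = xt
        state = np.concatenate([xt, state[:-n]])
    return x[:, burn_in:]


def simulate_roi_process(coeffs: np.ndarray, gain_envelope: np.ndarray,
                         n_epochs: int, epoch_len_s: float, fs: float,
                         noise_sd: float = 1.0, seed=None,
                         t0: float = -0.5) -> np.ndarray:
    """Epoched simulation: each epoch is an independent run with burn-in.

    ``gain_envelope`` has shape (n_roi, n_samples) over the epoch's time
    axis and must be 1 during the baseline [-0.5, 0).

    Returns an array of shape (n_epochs, n_roi, n_samples).
    """
    _check_stable(coeffs)
    n_samples = int(round(epoch_len_s * fs))
    if gain_envelope.shape[1] != n_samples:
        raise ValueError("gain_envelope length mismatch with epoch_len_s")
    times = t0 + np.arange(n_samples) / fs
    base_region = times < 0
    if not np.allclose(gain_envelope[:, base_region], 1.0):
        raise ValueError("gain_envelope must equal 1 during the baseline")
    rng = np.random.default_rng(seed)
    out = np.empty((n_epochs, coeffs.shape[1], n_samples))
    for e in range(n_epochs):
        out[e] = simulate_continuous(
            coeffs, gain_envelope, noise_sd=noise_sd,
            seed=rng.integers(2 ** 31))
    return out


def assign_nhpt(latent_severity: float, latent_improvement: int,
                cap_s: float = NHPT_CAP, rng=None) -> tuple[float, float]:
    """Map latent severity and improvement to NHPT times (seconds).

    nhpt_t0 = 20 + 100 * severity + N(0, 5^2), clipped to (0, cap]; a
    severity of exactly 1 codes "did not finish" (the cap). Improvers get
    a strictly smaller t1; non-improvers repeat t0 exactly.
    """
    if not 0.0 <= latent_severity <= 1.0:
        raise ValueError("latent_severity must be in [0, 1]")
    rng = np.random.default_rng(rng)
    t0 = 20.0 + 100.0 * latent_severity + rng.normal(0.0, 5.0)
    t0 = float(np.clip(t0, 1.0, cap_s))
    if latent_severity >= 1.0:
        t0 = cap_s
    if latent_improvement:
        drop = 10.0 + 30.0 * rng.random()
        t1 = float(max(t0 - drop, 3.0))
        t1 = min(t1, t0 - 1.0)  # guarantee strict improvement
    else:
        t1 = t0
    return t0, t1


# ---------------------------------------------------------------------------
# lesion fixtures

_GRID_SHAPE = (24, 24, 24)
_VOXEL_MM = (2.0, 2.0, 2.0)
# right hemisphere = ipsilesional ("c" ROIs); x axis is left-right,
# midline between 11 and 12
_ROI_CENTERS = {
    "cM1": (17, 9, 15), "cS1": (17, 13, 15), "cS2": (20, 15, 11),
}
_SUBCORTICAL = {
    "thalamus_R": (14, 12, 9), "striatum_R": (15, 9, 10),
    "pons": (12, 12, 2),
}
_CAPSULE = (15, 11, 9)      # internal-capsule corridor the lesions hit


def _mirror(center):
    return (23 - center[0], center[1], center[2])


def _blob(labels, center, pid, half=1):
    x, y, z = center
    labels[x - half:x + half + 1, y - half:y + half + 1,
           z - half:z + half + 1] = pid


def make_atlas_fixture(rng=None) -> tuple[ParcelAtlas, StreamlineAtlas]:
    """Synthetic parcel atlas and streamline set on a 24^3 grid.

    Stand-in for the population tractography/parcellation atlases the
    analysis is defined against (synthetic: built here, same interfaces).
    Cortical ROIs are 3^3 blobs in each hemisphere; projection tracts run
    from ipsilesional M1/S1 through an internal-capsule corridor to the
    base of the grid; commissural segments cross the midline at three
    anterior-posterior levels; association streamlines link M1-S1 and
    S1-S2 (M1-S2 has no direct streamline, so its intact shortest path
    length is 2 hops).
    """
    rng = np.random.default_rng(rng)
    labels = np.zeros(_GRID_SHAPE, dtype=np.int16)
    names = {}
    pid = 0
    for name, c in _ROI_CENTERS.items():
        pid += 1
        names[pid] = name
        _blob(labels, c, pid)
    for name, c in _ROI_CENTERS.items():
        pid += 1
        names[pid] = "i" + name[1:]
        _blob(labels, _mirror(c), pid)
    for name, c in _SUBCORTICAL.items():
        pid += 1
        names[pid] = name
        _blob(labels, c, pid)
    atlas = ParcelAtlas(labels=labels, names=names)

    def line(a, b, n=12, jitter=1):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        pts = np.linspace(a, b, n)
        pts += rng.integers(-jitter, jitter + 1, size=(1, 3))
        pts = np.clip(np.round(pts), 0,
                      np.array(_GRID_SHAPE) - 1).astype(int)
        return pts

    streamlines, tract_labels = [], []

    def add(tract, a, b, count, via=None):
        for _ in range(count):
            if via is None:
                streamlines.append(line(a, b))
            else:
                # per-streamline spread of the corridor waypoint, so a
                # lesion of a given size severs only part of the tract
                vj = np.asarray(via) + rng.integers(-2, 3, size=3) * (1, 1, 0)
                vj = np.clip(vj, 0, np.array(_GRID_SHAPE) - 1)
                seg1 = line(a, vj, jitter=0)
                seg2 = line(vj, b, jitter=0)
                streamlines.append(np.vstack([seg1, seg2]))
            tract_labels.append(tract)

    base = (14, 11, 0)
    add("CST", _ROI_CENTERS["cM1"], base, 20, via=_CAPSULE)
    add("CS", _ROI_CENTERS["cM1"], _SUBCORTICAL["striatum_R"], 12,
        via=_CAPSULE)
    add("CT", _ROI_CENTERS["cS1"], _SUBCORTICAL["thalamus_R"], 12,
        via=_CAPSULE)
    add("FPT", (17, 6, 16), _SUBCORTICAL["pons"], 12, via=_CAPSULE)
    add("PPT", (17, 16, 16), _SUBCORTICAL["pons"], 12, via=_CAPSULE)
    # commissural segments cross the midline above the capsule corridor,
    # within reach of the larger lesions
    add("CC_mid_anterior", (17, 7, 12), (6, 7, 12), 10)
    add("CC_central", (17, 11, 12), (6, 11, 12), 10)
    add("CC_mid_posterior", (17, 15, 12), (6, 15, 12), 10)
    # association streamlines (both hemispheres)
    for pre, mir in (("c", False), ("i", True)):
        m1 = _mirror(_ROI_CENTERS["cM1"]) if mir else _ROI_CENTERS["cM1"]
        s1 = _mirror(_ROI_CENTERS["cS1"]) if mir else _ROI_CENTERS["cS1"]
        s2 = _mirror(_ROI_CENTERS["cS2"]) if mir else _ROI_CENTERS["cS2"]
        add(f"assoc_{pre}M1_{pre}S1", m1, s1, 8)
        add(f"assoc_{pre}S1_{pre}S2", s1, s2, 8)
    # thalamo-cortical support so the parcel graph is connected
    add("assoc_thal_cS1", _SUBCORTICAL["thalamus_R"],
        _ROI_CENTERS["cS1"], 6)

    streams = StreamlineAtlas(streamlines=streamlines,
                              tract_labels=tract_labels,
                              shape=_GRID_SHAPE)
    return atlas, streams


def _lesion_mask(severity: float, improved: int, effects: dict,
                 rng) -> VoxelGrid:
    """Ellipsoidal lesion around the capsule corridor.

    Radius grows with severity (scaled by lesion_size_delta) and is
    elongated along the descending-tract axis; non-improvers get an extra
    enlargement (tract_disconnection_delta), mirroring their higher tract
    disconnection.
    """
    size_d = effects["lesion_size_delta"]
    tract_d = effects["tract_disconnection_delta"]
    r = 0.9 + 1.6 * size_d * severity + 0.5 * rng.random()
    r *= 1.0 + 0.22 * tract_d * (0 if improved else 1) * min(severity, 1.0)
    center = np.asarray(_CAPSULE, float) + rng.integers(-1, 2, size=3)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in _GRID_SHAPE],
                             indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    # elongation factor 1.6 along z (tract axis)
    scale = np.array([1.0, 1.0, 1.0 / 1.6])
    d2 = (((coords - center) * scale) ** 2).sum(axis=-1)
    return VoxelGrid(mask=(d2 <= r * r).astype(np.uint8),
                     voxel_size=_VOXEL_MM)


# ---------------------------------------------------------------------------
# cohort assembly

# ROI index layout matches preprocess.ROI_LABELS: cM1 cS1 cS2 iM1 iS1 iS2
_IDX = {lab: i for i, lab in enumerate(ROI_LABELS)}


def _subject_couplings(function_low: bool, improved: int,
                       effects: dict) -> dict:
    """Directed lag-1 couplings (target, source) -> weight."""
    # all couplings are small against the AR(2) diagonal: at the shared
    # resonance a directed term c transfers ~c^2 |H(f0)|^2 (~400 c^2) of
    # the source power into the target, so c must stay well below 0.05
    # for the planted gain effects to remain visible in raw band power
    c = {}
    intra = 0.01 + (0.0 if function_low
                    else effects["intra_coupling_delta"])
    # ipsilesional hemisphere driven by S2 (S2->S1, S2->M1) plus S1->M1
    c[(_IDX["cM1"], _IDX["cS2"])] = intra
    c[(_IDX["cS1"], _IDX["cS2"])] = intra
    c[(_IDX["cM1"], _IDX["cS1"])] = intra
    # contralesional hemisphere: weak fixed coupling
    c[(_IDX["iM1"], _IDX["iS2"])] = 0.01
    c[(_IDX["iS1"], _IDX["iS2"])] = 0.01
    c[(_IDX["iM1"], _IDX["iS1"])] = 0.01
    # inter-hemispheric drive: improvers are driven by the ipsilesional
    # hemisphere (c -> i), non-improvers by the contralesional (i -> c).
    # kept far below the intra couplings: PDC reads the coefficients
    # directly (and the Abar diagonal is small at the resonance, so PDC is
    # very sensitive there), while resonant power transfer into the target
    # ROI grows as coupling^2 * |H(f0)|^2 and would otherwise swamp the
    # planted rebound-gain effects
    # the directional plant applies to the low-function group only (the
    # recovery analysis is defined within it); high-function subjects get
    # the symmetric floor, keeping their inter-hemispheric transfer
    # independent of the analysis-irrelevant improvement flag
    inter = effects["inter_directionality_delta"]
    sym = 0.0
    if inter == 0 or not function_low:
        fwd = bwd = sym
    elif improved:
        fwd, bwd = sym + inter, sym
    else:
        fwd, bwd = sym, sym + inter
    for roi in ("M1", "S1"):
        c[(_IDX["i" + roi], _IDX["c" + roi])] = fwd   # c -> i
        c[(_IDX["c" + roi], _IDX["i" + roi])] = bwd   # i -> c
    return c


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a full synthetic cohort.

    Deterministic given ``config.seed``. Group labels are planted first
    (low/high initial function in the 20:16 ratio, improvers within the
    low group in the 8:20 ratio) and severity is drawn conditional on the
    label, so the NHPT construction reproduces the planted split exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    eff = config.group_effect_sizes

    n_low = int(round(n * 20 / 36))
    n_imp = int(round(n_low * 8 / 20))
    function_low = np.zeros(n, dtype=bool)
    function_low[:n_low] = True
    improvement = np.zeros(n, dtype=int)
    improvement[:n_imp] = 1          # improvers are a subset of low
    improvement[n_low:] = rng.integers(0, 2, size=n - n_low)
    order = rng.permutation(n)
    function_low = function_low[order]
    improvement = improvement[order]

    severity = np.where(function_low,
                        rng.uniform(0.85, 1.0, size=n),
                        rng.uniform(0.05, 0.70, size=n))

    atlas, streams = make_atlas_fixture(rng=rng.integers(2 ** 31))

    tmax = config.epoch_tmax
    n_rec = int(round((1.0 + config.n_stimuli * config.isi_s + 2.0)
                      * config.fs))
    trig = (config.fs * (1.0 + config.isi_s
                         * np.arange(config.n_stimuli))).astype(int)

    records: list[SubjectRecord] = []
    stacks = []
    gains = np.zeros((n, 6))
    d_reb = eff["rebound_gain_delta"]
    for s in range(n):
        low = bool(function_low[s])
        imp = int(improvement[s])
        if not low:
            g_c = BASE_REBOUND_GAIN
        elif imp:
            g_c = BASE_REBOUND_GAIN - d_reb / 2.0
        else:
            g_c = BASE_REBOUND_GAIN - d_reb
        g_c = max(g_c + rng.normal(0, 0.05), 1.02)
        g_i = max(1.4 + rng.normal(0, 0.05), 1.02)
        gains[s] = [g_c, g_c, g_c, g_i, g_i, g_i]

        coeffs = base_coefficients(
            config.fs, couplings=_subject_couplings(low, imp, eff))
        _check_stable(coeffs)
        stacks.append(coeffs)

        # envelope over the continuous recording: per trigger, per ROI
        env = np.ones((6, n_rec))
        for roi in range(6):
            env_epoch = make_gain_envelope(
                np.arange(0.0, config.isi_s, 1.0 / config.fs),
                rebound_gain=gains[s, roi])
            for tg in trig:
                stop = min(tg + env_epoch.size, n_rec)
                env[roi, tg:stop] = env_epoch[:stop - tg]
        cont = simulate_continuous(coeffs, env, noise_sd=config.noise_sd,
                                   seed=rng.integers(2 ** 31))

        if config.dropout_fraction > 0:
            keep = rng.random(trig.size) >= config.dropout_fraction
            subj_trig = trig[keep]
        else:
            subj_trig = trig

        t0_s, t1_s = assign_nhpt(float(severity[s]), imp, NHPT_CAP,
                                 rng=rng.integers(2 ** 31))
        # construction guarantee of the planted function split
        if low:
            t0_s = float(np.clip(t0_s, 100.5, NHPT_CAP))
            if t1_s > t0_s:
                t1_s = t0_s
            if imp and t1_s >= t0_s:
                t1_s = t0_s - 1.0
        else:
            t0_s = float(np.clip(t0_s, 5.0, 99.0))
            t1_s = min(t1_s, t0_s)
        if not imp:
            t1_s = t0_s

        lesion = _lesion_mask(float(severity[s]), imp, eff,
                              np.random.default_rng(rng.integers(2 ** 31)))
        records.append(SubjectRecord(
            subject_id=f"sub-{s + 1:03d}", nhpt_t0=round(t0_s, 2),
            nhpt_t1=round(t1_s, 2), affected_side="left",
            dnf=t0_s >= NHPT_CAP, continuous=cont, triggers=subj_trig,
            fs=config.fs, lesion=lesion))

    truth = GroundTruth(severity=severity, improvement=improvement,
                        function_low=function_low, coeff_stacks=stacks,
                        rebound_gain=gains, atlas=atlas,
                        streamlines=streams)
    return records, truth


# ---------------------------------------------------------------------------
# serialization

def save_cohort(records: list[SubjectRecord], truth: GroundTruth,
                out_dir) -> None:
    """Write per-subject HDF5, lesion NIfTI, cohort CSV, and ground truth.

    HDF5 layout per subject: datasets ``continuous`` (roi, sample),
    ``triggers``, scalar ``fs``, and the ROI label list as an attribute.
    """
    import h5py
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        h5_path = out / f"{rec.subject_id}_meg.h5"
        with h5py.File(h5_path, "w") as fh:
            fh.create_dataset("continuous", data=rec.continuous)
            fh.create_dataset("triggers", data=rec.triggers)
            fh.attrs["fs"] = rec.fs
            fh.attrs["roi_labels"] = list(ROI_LABELS)
        les_path = out / f"{rec.subject_id}_lesion.nii.gz"
        rec.lesion.to_nifti(les_path)
        rec.data_path, rec.lesion_path = str(h5_path), str(les_path)
        rows.append({"subject_id": rec.subject_id,
                     "nhpt_t0": rec.nhpt_t0, "nhpt_t1": rec.nhpt_t1,
                     "affected_side": rec.affected_side, "dnf": rec.dnf,
                     "severity": truth.severity[i],
                     "improvement": int(truth.improvement[i])})
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    gt = {"severity": truth.severity.tolist(),
          "improvement": truth.improvement.tolist(),
          "function_low": truth.function_low.astype(int).tolist(),
          "rebound_gain": truth.rebound_gain.tolist()}
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    truth.streamlines.to_jsonl(out / "streamlines.jsonl")
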