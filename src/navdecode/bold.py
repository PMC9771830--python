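"""Direction-tuned synthetic multi-voxel time series and signal cleaning.

Each tuned voxel has a preferred walking direction and responds to the
current heading through a circular-Gaussian tuning profile
exp(-d^2 / (2 sigma^2)), where d is the signed circular difference between
heading and preference. The voxel's volume-wise signal is

    baseline + gain * <tuning response over the volume's acquisition window>
             + low-frequency drift + iid Gaussian noise,

with the acquisition window shifted earlier by a fixed hemodynamic lag
(default two repetition times, 2 x 2.36 s = 4.72 s). ``gain`` is the neural
gain knob: scaling it up raises signal relative to noise, the synthetic
stand-in for a dopaminergic (or age) effect on response amplitude, while
``tuning_sd`` controls representational specificity (wider tuning = more
dedifferentiated voxels).

Cleaning mirrors the standard pre-classification contract: linear detrend,
discrete-cosine high-pass (cutoff period 128 s), confound regression, and
per-voxel z-scoring, in that order.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from ._circular import signed_circular_diff
from .task import Trajectory

DEFAULT_TR = 2.36


@dataclasses.dataclass
class VoxelTuningSpec:
    """Generative description of one ROI's voxel population.

    Parameters
    ----------
    n_voxels : int
    tuning_sd : float
        Width sigma (degrees) of the circular-Gaussian tuning profile.
    gain : float
        Amplitude of the direction-driven signal component (a.u.).
    baseline : float
        Mean signal level (a.u.).
    noise_sd : float
        SD of iid Gaussian measurement noise (a.u.).
    fraction_tuned : float
        Proportion of voxels that carry direction signal at all.
    preferred_direction : array, optional
        Per-voxel preferred directions (degrees); drawn uniformly on
        [0, 360) at generation time when omitted.
    tuned_mask : bool array, optional
        Which voxels carry signal; drawn at generation time when omitted.
        Supplying both this and ``preferred_direction`` fixes the voxel
        population identity, so that several sessions of one subject share
        the same underlying tuning structure and differ only in gain,
        noise and trajectory.
    """

    n_voxels: int
    tuning_sd: float = 30.0
    gain: float = 1.5
    baseline: float = 100.0
    noise_sd: float = 4.0
    fraction_tuned: float = 0.5
    preferred_direction: np.ndarray | None = None
    tuned_mask: np.ndarray | None = None

    def sample_population(self, seed=None) -> "VoxelTuningSpec":
        """Freeze preferred directions and the tuned subset (subject identity)."""
        rng = np.random.default_rng(seed)
        preferred = rng.uniform(0.0, 360.0, size=self.n_voxels)
        n_tuned = int(round(self.fraction_tuned * self.n_voxels))
        mask = np.zeros(self.n_voxels, dtype=bool)
        mask[rng.choice(self.n_voxels, size=n_tuned, replace=False)] = True
        return dataclasses.replace(self, preferred_direction=preferred, tuned_mask=mask)

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if not self.tuning_sd > 0:
            raise ValueError("tuning_sd must be positive")
        if not 0.0 <= self.fraction_tuned <= 1.0:
            raise ValueError("fraction_tuned must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclasses.dataclass
class BoldRun:
    """Voxel time series of one session: volumes x voxels, plus confounds."""

    TR: float
    data: np.ndarray  # (n_volumes, n_voxels)
    confounds: pd.DataFrame | None = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def save(self, path_prefix) -> None:
        """Write data as .npz plus a JSON sidecar with the TR."""
        prefix = Path(path_prefix)
        np.savez_compressed(prefix.with_suffix(".npz"), data=self.data)
        prefix.with_suffix(".json").write_text(
            json.dumps({"RepetitionTime": self.TR})
        )
        if self.confounds is not None:
            self.confounds.to_csv(
                prefix.parent / (prefix.name + "_confounds.tsv"), sep="\t", index=False
            )

    @classmethod
    def load(cls, path_prefix) -> "BoldRun":
        prefix = Path(path_prefix)
        data = np.load(prefix.with_suffix(".npz"))["data"]
        tr = json.loads(prefix.with_suffix(".json").read_text())["RepetitionTime"]
        conf_path = prefix.parent / (prefix.name + "_confounds.tsv")
        confounds = pd.read_csv(conf_path, sep="\t") if conf_path.exists() else None
        return cls(tr, data, confounds)


def load_nifti_run(img_path, mask_path, tr: float | None = None) -> BoldRun:
    """Read a preprocessed 4-D NIfTI plus a binary ROI mask into a BoldRun.

    Spatial preprocessing (including smoothing) is expected upstream; this
    only flattens the masked voxels to volumes x voxels.
    """
    import nibabel as nib  # optional path: only needed for volumetric input

    img = nib.load(str(img_path))
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    data = np.asanyarray(img.dataobj)[mask].T.astype(float)  # (volumes, voxels)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldRun(tr, data)


@dataclasses.dataclass
class CleanedRun:
    """Cleaned, z-scored time series ready for example construction."""

    data: np.ndarray  # (n_volumes, n_voxels), z-scored per voxel
    TR: float
    filter_cutoff: float  # Hz
    constant_voxels: np.ndarray | None = None  # bool mask of zero-variance voxels

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


def tuning_response(heading, preferred, tuning_sd: float):
    """Circular-Gaussian tuning response in (0, 1].

    exp(-d^2 / (2 sd^2)) with d the signed circular difference between
    heading and preferred direction, in (-180, 180]. Broadcasts over arrays.
    """
    if not tuning_sd > 0:
        raise ValueError("tuning_sd must be positive")
    d = signed_circular_diff(heading, preferred)
    return np.exp(-np.square(d) / (2.0 * tuning_sd**2))


def _canonical_hrf(dt: float, length: float = 30.0) -> np.ndarray:
    """Double-gamma canonical HRF sampled at dt, peak-normalized."""
    from scipy.stats import gamma

    t = np.arange(0.0, length, dt)
    h = gamma.pdf(t, 6) - gamma.pdf(t, 16) / 6.0
    return h / h.max()


def generate_tuned_bold(
    traj: Trajectory,
    spec: VoxelTuningSpec,
    TR: float = DEFAULT_TR,
    lag: float = 2 * DEFAULT_TR,
    drift_amplitude: float = 2.0,
    seed=None,
    hrf_convolve: bool = False,
    ar_coef: float = 0.0,
) -> BoldRun:
    """Generate a tuned BOLD run aligned to a trajectory.

    Volume v of a tuned voxel averages the voxel's tuning response over the
    trajectory samples in the lag-shifted acquisition window
    [v*TR - lag, (v+1)*TR - lag); untuned voxels carry baseline, drift and
    noise only. n_volumes = ceil(duration / TR). With ``hrf_convolve`` the
    lag shift is replaced by convolution with a canonical double-gamma HRF
    (off by default: the decoding correction downstream is itself a fixed
    two-volume shift). ``ar_coef`` adds AR(1) structure to the noise.

    Confound columns returned with the run are the generative drift
    components plus two fast sine regressors (aCompCor stand-ins) and an
    FD-like motion column.
    """
    duration = traj.duration
    if duration < 2 * TR + max(lag, 0.0):
        raise ValueError("trajectory too short for the requested TR and lag")
    rng = np.random.default_rng(seed)
    n_volumes = int(np.ceil(duration / TR))
    n_vox = spec.n_voxels

    preferred = spec.preferred_direction
    if preferred is None:
        preferred = rng.uniform(0.0, 360.0, size=n_vox)
    preferred = np.asarray(preferred, dtype=float)
    tuned_mask = spec.tuned_mask
    if tuned_mask is None:
        n_tuned = int(round(spec.fraction_tuned * n_vox))
        tuned_mask = np.zeros(n_vox, dtype=bool)
        tuned_mask[rng.choice(n_vox, size=n_tuned, replace=False)] = True
    tuned_mask = np.asarray(tuned_mask, dtype=bool)

    # per-sample tuning response for every voxel: (samples, voxels)
    resp = tuning_response(traj.heading[:, None], preferred[None, :], spec.tuning_sd)

    if hrf_convolve:
        hrf = _canonical_hrf(traj.dt)
        sig = np.apply_along_axis(
            lambda col: np.convolve(col, hrf)[: len(col)] * traj.dt, 0, resp
        )
        sample_vol = np.floor(traj.t / TR).astype(int)
    else:
        sig = resp
        sample_vol = np.floor((traj.t + lag) / TR).astype(int)

    # average the per-sample signal into its (lag-shifted) volume
    vol_signal = np.zeros((n_volumes, n_vox))
    valid = (sample_vol >= 0) & (sample_vol < n_volumes)
    counts = np.bincount(sample_vol[valid], minlength=n_volumes).astype(float)
    for j in range(n_vox):
        vol_signal[:, j] = np.bincount(
            sample_vol[valid], weights=sig[valid, j], minlength=n_volumes
        )
    nonzero = counts > 0
    vol_signal[nonzero] /= counts[nonzero, None]

    data = np.full((n_volumes, n_vox), float(spec.baseline))
    data[:, tuned_mask] += spec.gain * vol_signal[:, tuned_mask]

    # shared low-frequency drift with per-voxel loadings
    t_vol = (np.arange(n_volumes) + 0.5) * TR
    periods = np.array([300.0, 180.0, 120.0])
    phases = rng.uniform(0.0, 2 * np.pi, size=len(periods))
    drift = np.cos(2 * np.pi * t_vol[:, None] / periods[None, :] + phases)
    loadings = rng.uniform(0.5, 1.5, size=(len(periods), n_vox))
    data += drift_amplitude * drift @ loadings

    noise = spec.noise_sd * rng.standard_normal((n_volumes, n_vox))
    if ar_coef:
        for v in range(1, n_volumes):
            noise[v] += ar_coef * noise[v - 1]
    data += noise

    fd_like = np.abs(0.1 + 0.05 * rng.standard_normal(n_volumes))
    confounds = pd.DataFrame(
        {f"drift_{i}": drift_amplitude * drift[:, i] for i in range(len(periods))}
    )
    confounds["sine_fast_1"] = np.sin(2 * np.pi * t_vol / 40.0)
    confounds["sine_fast_2"] = np.sin(2 * np.pi * t_vol / 25.0)
    confounds["framewise_displacement"] = fd_like
    return BoldRun(TR, data, confounds)


def _dct_highpass_basis(n_volumes: int, TR: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine regressors with period > cutoff_s (SPM-style).

    Basis function k (k >= 1) is cos(pi k (2n + 1) / (2 N)) with frequency
    k / (2 N TR); the returned columns are those with period strictly
    greater than cutoff_s. Note the usual quadrature caveat of cosine
    drift models: a stop-band sinusoid in sine phase is only partially
    captured, while the cosine quadrature is annihilated.
    """
    order = int(np.ceil(2.0 * n_volumes * TR / cutoff_s)) - 1
    if order < 1:
        return np.empty((n_volumes, 0))
    n = np.arange(n_volumes)
    k = np.arange(1, order + 1)
    basis = np.cos(np.pi * np.outer(2 * n + 1, k) / (2.0 * n_volumes))
    return basis


def _regress_out(data: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of data on [1, regressors]; drops collinear columns."""
    X = np.column_stack([np.ones(len(data)), regressors])
    # rank check via QR; warn and drop dependent columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} collinear confound column(s)",
            stacklevel=3,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def clean_signal(
    run: BoldRun,
    cutoff_s: float = 128.0,
    n_confounds_used: int = 10,
) -> CleanedRun:
    """Detrend, high-pass, de-noise and z-standardize a run, in that order.

    1. remove the per-voxel linear trend;
    2. project out discrete-cosine basis functions with period > cutoff_s;
    3. regress out up to ``n_confounds_used`` confound columns (OLS);
    4. z-score each voxel.

    Voxels with zero residual variance are flagged in ``constant_voxels``
    and set to zero rather than divided by zero.
    """
    if run.n_volumes < 3:
        raise ValueError("clean_signal needs at least 3 volumes")
    data = scipy.signal.detrend(np.asarray(run.data, dtype=float), axis=0)
    dct = _dct_highpass_basis(run.n_volumes, run.TR, cutoff_s)
    if dct.shape[1]:
        data = _regress_out(data, dct)
    if run.confounds is not None and n_confounds_used > 0:
        conf = run.confounds.to_numpy(dtype=float)[:, :n_confounds_used]
        if conf.shape[1]:
            data = _regress_out(data, conf)
    sd = data.std(axis=0)
    constant = sd < 1e-12
    sd_safe = np.where(constant, 1.0, sd)
    data = (data - data.mean(axis=0)) / sd_safe
    data[:, constant] = 0.0
    return CleanedRun(data, run.TR, 1.0 / cutoff_s, constant)
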