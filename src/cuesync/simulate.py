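"""Synthetic two-group, two-session movie-fMRI study with known ground truth.

The generator emulates the structure the analysis is built for: two
groups of subjects (a clinical group and matched controls) watch the
same labeled movie twice, months apart.  Voxel time series in
"drug-locked" ROIs carry a stimulus-locked shared drive — the binary
content label track scaled by a group x session amplitude on labeled
bins and by a non-drug amplitude on the remaining bins — convolved with
a canonical hemodynamic response.  All subjects in a group share the
same drive realization (this is what creates across-subject
synchronization); each subject scales it by an idiosyncratic coupling
coefficient, which also drives that subject's craving ratings.  On top
of the drive sit a smooth global "arousal" component shared within each
group and session, motion/CSF-like confound leakage, and white noise.

Amplitudes are expressed in units of the voxel noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import gammaln

from ._rng import substream, zscore_rows
from .labels import LabelTrack

GROUPS = ("HUD", "HC")
SESSIONS = ("baseline", "followup")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``n_trs`` is the acquisition length before the initial-TR drop, so
    the default 1033 yields 1023 analyzed seconds (the movie duration)
    after dropping 10.  ``drug_amplitude`` / ``nondrug_amplitude`` are
    (group x session) matrices of shared-drive response levels in
    voxel-noise-SD units, applying to the ``drug_locked_rois``; since
    analysis series are z-scored, what matters for synchronization is
    the drug/non-drug *contrast* (a_on - a_off).  The defaults give the
    clinical group a contrast that flips from +0.55 (drug-locked
    peaks) at baseline to -0.45 (non-drug-locked peaks) at follow-up,
    while the control group stays flat at +0.55; the near-balanced
    magnitudes keep every group x session cell detectable.  ``locked_voxels_per_roi``
    optionally gives the drug-locked ROIs a larger voxel count (real
    parcellation ROIs span hundreds of voxels), which raises their
    alignment gain and detection counts.  ``ofc_rois`` carry the same
    group x session structure scaled by ``ofc_amplitude_scale`` into
    the steep (unsaturated) regime of the ISC-vs-coupling curve where
    between-subject ISC variation is informative; craving ratings are
    linked to the coupling in these ROIs.  Background ROIs respond,
    with group- and session-invariant amplitudes, to their own
    independent content tracks — movie regions track different
    features — so the subject-level global component is not collinear
    with any single ROI's drive.
    """

    n_subjects_per_group: tuple[int, int] = (30, 25)
    n_rois: int = 20
    voxels_per_roi: int = 40
    locked_voxels_per_roi: int | None = None
    n_unassigned_voxels: int = 400
    n_trs: int = 1033
    n_drop: int = 10
    tr_seconds: float = 1.0
    drug_fraction: float = 464 / 1023
    block_length_mean: float = 8.0
    drug_locked_rois: tuple[int, ...] = (0, 1, 2)
    ofc_rois: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    ofc_amplitude_scale: float = 0.35
    drug_amplitude: tuple[tuple[float, float], tuple[float, float]] = ((1.5, 0.5), (1.5, 1.5))
    nondrug_amplitude: tuple[tuple[float, float], tuple[float, float]] = (
        (0.95, 0.95),
        (0.95, 0.95),
    )
    ofc_nondrug_amplitude: float = 0.85
    background_drug_amplitude: float = 1.5
    background_nondrug_amplitude: float = 0.85
    global_amplitude: float = 0.5
    noise_sd: float = 1.0
    scene_gain_range: tuple[float, float] = (0.3, 1.7)
    coupling_range: tuple[float, float] = (0.3, 1.7)
    confound_leak_sd: float = 0.2
    n_confounds: int = 7
    craving_link_slope: float = 8.0
    craving_link_intercept: float = 3.0
    craving_link_noise: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_subjects_per_group) != 2 or any(
            int(n) < 1 for n in self.n_subjects_per_group
        ):
            raise ValueError("n_subjects_per_group must be two positive counts")
        for name in ("n_rois", "voxels_per_roi", "n_trs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_drop < 0 or self.n_drop >= self.n_trs:
            raise ValueError("n_drop must be in [0, n_trs)")
        if not 0.0 <= self.drug_fraction <= 1.0:
            raise ValueError("drug_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        da = np.asarray(self.drug_amplitude, dtype=float)
        na = np.asarray(self.nondrug_amplitude, dtype=float)
        if da.shape != (2, 2) or na.shape != (2, 2):
            raise ValueError("amplitude matrices must have shape (2 groups x 2 sessions)")
        if any(r < 0 or r >= self.n_rois for r in self.drug_locked_rois):
            raise ValueError("drug_locked_rois out of range")
        ofc = [r for r in self.ofc_rois if r < self.n_rois]
        if set(ofc) & set(self.drug_locked_rois):
            raise ValueError("ofc_rois must be disjoint from drug_locked_rois")

    @property
    def n_analyzed_trs(self) -> int:
        return self.n_trs - self.n_drop

    @property
    def effective_ofc_rois(self) -> tuple[int, ...]:
        """Configured OFC-like ROIs that exist at this ``n_rois``."""
        return tuple(r for r in self.ofc_rois if r < self.n_rois)


@dataclass
class SyntheticStudy:
    """Simulated study: voxel data, labels, confounds, behavior, truth.

    ``voxel_data[group][session][roi]`` is a (subject, voxel, TR) array
    on the pre-drop TR grid.  ``unassigned_voxels[group][session]`` is
    a (subject, voxel, TR) array of gray-matter voxels outside the
    analyzed ROIs (global arousal + confound leakage + noise only);
    they enter the per-subject global average, diluting any single
    ROI's stimulus drive there, but no ROI analysis.  ``truth`` records every planted parameter
    needed to score recovery: the drug-locked ROI set, amplitudes,
    per-subject coupling coefficients, per-subject-session effective
    coupling (coefficient x drive SD), and the planted craving-link
    correlation per group.
    """

    config: SimConfig
    voxel_data: Mapping[str, Mapping[str, Mapping[int, np.ndarray]]]
    label_track: LabelTrack
    confounds: Mapping[str, Mapping[str, np.ndarray]]
    behavior: pd.DataFrame
    truth: dict = field(default_factory=dict)
    unassigned_voxels: Mapping[str, Mapping[str, np.ndarray]] = field(default_factory=dict)


def generate_label_track(
    n_bins: int,
    drug_fraction: float,
    block_length_mean: float = 8.0,
    seed: int = 0,
) -> LabelTrack:
    """Generate a blocky binary label track with an exact label count.

    Alternating labeled/unlabeled blocks are drawn with geometric
    lengths (labeled blocks with mean ``block_length_mean``; unlabeled
    blocks with the mean that makes the expected fraction match), the
    sequence is trimmed to ``n_bins``, and bins at run boundaries are
    then flipped until the realized count equals
    ``round(drug_fraction * n_bins)`` exactly.
    """
    n_bins = int(n_bins)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not 0.0 <= drug_fraction <= 1.0:
        raise ValueError("drug_fraction must be in [0, 1]")
    if block_length_mean < 1.0:
        raise ValueError("block_length_mean must be >= 1 second")
    target = int(round(drug_fraction * n_bins))
    if target == 0:
        return LabelTrack(labels=np.zeros(n_bins, dtype=np.int8))
    if target == n_bins:
        return LabelTrack(labels=np.ones(n_bins, dtype=np.int8))

    rng = substream(seed, "label-track")
    f = target / n_bins
    mean_on = block_length_mean
    mean_off = max(1.0, mean_on * (1.0 - f) / f)
    labels = np.empty(0, dtype=np.int8)
    state = int(rng.random() < f)
    while labels.size < n_bins:
        mean = mean_on if state else mean_off
        length = rng.geometric(1.0 / mean)
        labels = np.concatenate([labels, np.full(length, state, dtype=np.int8)])
        state = 1 - state
    labels = labels[:n_bins]

    # Flip bins at run boundaries until the count is exact; flipping at
    # boundaries grows/shrinks existing blocks, preserving blockiness.
    while True:
        diff = target - int(labels.sum())
        if diff == 0:
            break
        if diff > 0:
            # candidates: 0-bins adjacent to a 1-run (or anywhere if none)
            ones = labels == 1
            adj = np.zeros(n_bins, dtype=bool)
            adj[:-1] |= ones[1:]
            adj[1:] |= ones[:-1]
            cand = np.flatnonzero((labels == 0) & adj)
            if cand.size == 0:
                cand = np.flatnonzero(labels == 0)
            labels[rng.choice(cand)] = 1
        else:
            zeros = labels == 0
            edge = np.zeros(n_bins, dtype=bool)
            edge[0] = edge[-1] = True
            edge[:-1] |= zeros[1:]
            edge[1:] |= zeros[:-1]
            cand = np.flatnonzero((labels == 1) & edge)
            labels[rng.choice(cand)] = 0
    return LabelTrack(labels=labels)


def hrf_kernel(tr_seconds: float = 1.0, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response on the TR grid.

    Difference of two gamma densities (shape 6 and 16, unit rate; the
    undershoot weighted 1/6), normalized to unit peak.  The continuous
    kernel peaks 5 s after onset.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration, tr_seconds)

    def gamma_pdf(x: np.ndarray, shape: float) -> np.ndarray:
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((shape - 1) * np.log(x[pos]) - x[pos] - gammaln(shape))
        return out

    h = gamma_pdf(t, 6.0) - gamma_pdf(t, 16.0) / 6.0
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("duration too short to sample the response")
    return h / peak


def _block_gains(labels: np.ndarray, rng: np.random.Generator, low: float, high: float) -> np.ndarray:
    """One salience gain per contiguous block (scene) of the track."""
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], edges])
    gains = rng.uniform(low, high, size=starts.size)
    out = np.empty(labels.size)
    stops = np.concatenate([edges, [labels.size]])
    for g, a, b in zip(gains, starts, stops):
        out[a:b] = g
    return out


def _convolved_indicators(
    track: LabelTrack,
    n_trs: int,
    tr_seconds: float,
    gains: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved drug and non-drug indicator series on the pre-drop grid.

    Movie second m is presented at acquisition TR m; acquisition runs
    ``n_trs`` >= movie length, with zeros after the movie ends.  The
    kernel is normalized to unit gain (unit sum) so a sustained block
    of amplitude a produces a plateau of height a — amplitudes read as
    response levels in noise-SD units.  Optional per-bin ``gains``
    modulate scene salience (a property of the content, identical for
    every subject, group and session).
    """
    kernel = hrf_kernel(tr_seconds)
    kernel = kernel / kernel.sum()
    on = np.zeros(n_trs)
    off = np.zeros(n_trs)
    n = min(track.n_bins, n_trs)
    g = np.ones(n) if gains is None else np.asarray(gains[:n], dtype=float)
    on[:n] = g * track.labels[:n]
    off[:n] = g * (1 - track.labels[:n])
    conv_on = np.convolve(on, kernel)[:n_trs]
    conv_off = np.convolve(off, kernel)[:n_trs]
    return conv_on, conv_off


def _drive_sd(drive: np.ndarray, n_drop: int) -> float:
    """SD of the fluctuating part of the shared drive over analyzed TRs."""
    return float(np.std(drive[n_drop:]))


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Simulate voxel data, confounds, and behavior for a full study."""
    cfg = config
    seed = cfg.seed
    track = generate_label_track(
        cfg.n_analyzed_trs, cfg.drug_fraction, cfg.block_length_mean, seed=seed
    )
    rng_scene = substream(seed, "scene-gains")
    glo, ghi = cfg.scene_gain_range
    gains = _block_gains(track.labels, rng_scene, glo, ghi)
    conv_on, conv_off = _convolved_indicators(track, cfg.n_trs, cfg.tr_seconds, gains)
    drug_amp = np.asarray(cfg.drug_amplitude, dtype=float)
    nondrug_amp = np.asarray(cfg.nondrug_amplitude, dtype=float)

    # Every background ROI follows its own independent content track
    # (same block statistics, fraction 1/2), shared by all subjects and
    # sessions like the movie itself — different regions track
    # different features, so the subject-level global average is not
    # collinear with any single ROI's drive.
    special = set(cfg.drug_locked_rois) | set(cfg.effective_ofc_rois)
    roi_conv: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for r in range(cfg.n_rois):
        if r not in special:
            own_track = generate_label_track(
                cfg.n_analyzed_trs,
                0.5,
                cfg.block_length_mean,
                seed=int(substream(seed, "background-track", r).integers(2**31)),
            )
            own_gains = _block_gains(own_track.labels, rng_scene, glo, ghi)
            roi_conv[r] = _convolved_indicators(
                own_track, cfg.n_trs, cfg.tr_seconds, own_gains
            )

    rng_coupling = substream(seed, "coupling")
    rng_loading = substream(seed, "loading")
    rng_global = substream(seed, "global")
    rng_conf = substream(seed, "confounds")
    rng_noise = substream(seed, "noise")
    rng_craving = substream(seed, "craving")

    lo, hi = cfg.coupling_range
    couplings = {
        g: rng_coupling.uniform(lo, hi, size=cfg.n_subjects_per_group[gi])
        for gi, g in enumerate(GROUPS)
    }

    voxel_data: dict[str, dict[str, dict[int, np.ndarray]]] = {}
    unassigned: dict[str, dict[str, np.ndarray]] = {}
    confounds: dict[str, dict[str, np.ndarray]] = {}
    effective_coupling: dict[str, dict[str, np.ndarray]] = {g: {} for g in GROUPS}
    drive_sds = np.zeros((2, 2))

    voxels_of = {
        r: (cfg.locked_voxels_per_roi or cfg.voxels_per_roi)
        if r in cfg.drug_locked_rois
        else cfg.voxels_per_roi
        for r in range(cfg.n_rois)
    }
    for gi, g in enumerate(GROUPS):
        n_subj = cfg.n_subjects_per_group[gi]
        # voxel loadings fixed across sessions: roi -> (subject, voxel)
        loadings = {
            r: rng_loading.uniform(0.5, 1.5, size=(n_subj, voxels_of[r]))
            for r in range(cfg.n_rois)
        }
        voxel_data[g] = {}
        unassigned[g] = {}
        confounds[g] = {}
        for si, s in enumerate(SESSIONS):
            # shared smooth "arousal" signal for this group and session
            gsig = gaussian_filter1d(rng_global.standard_normal(cfg.n_trs), sigma=4.0)
            gsig = zscore_rows(gsig, warn_constant=False)

            conf = np.cumsum(rng_conf.standard_normal((n_subj, cfg.n_trs, cfg.n_confounds)), axis=1)
            conf = (conf - conf.mean(axis=1, keepdims=True)) / conf.std(axis=1, keepdims=True)
            confounds[g][s] = conf

            locked_drive = drug_amp[gi, si] * conv_on + nondrug_amp[gi, si] * conv_off
            ofc_drive = cfg.ofc_amplitude_scale * (
                drug_amp[gi, si] * conv_on + cfg.ofc_nondrug_amplitude * conv_off
            )
            drive_sds[gi, si] = _drive_sd(locked_drive, cfg.n_drop)

            rois: dict[int, np.ndarray] = {}
            ofc_sds = [_drive_sd(ofc_drive, cfg.n_drop)]
            for r in range(cfg.n_rois):
                if r in cfg.drug_locked_rois:
                    drive = locked_drive
                elif r in cfg.effective_ofc_rois:
                    drive = ofc_drive
                else:
                    own_on, own_off = roi_conv[r]
                    drive = (
                        cfg.background_drug_amplitude * own_on
                        + cfg.background_nondrug_amplitude * own_off
                    )
                n_vox = voxels_of[r]
                # (subject, voxel, TR)
                shared = couplings[g][:, None, None] * loadings[r][:, :, None] * drive[None, None, :]
                leak_w = rng_conf.normal(
                    0.0, cfg.confound_leak_sd, size=(n_subj, n_vox, cfg.n_confounds)
                )
                leak = np.einsum("svk,stk->svt", leak_w, conf)
                noise = rng_noise.normal(0.0, cfg.noise_sd, size=(n_subj, n_vox, cfg.n_trs))
                rois[r] = shared + cfg.global_amplitude * gsig[None, None, :] + leak + noise
            voxel_data[g][s] = rois
            # craving is linked to coupling in the OFC-like ROIs
            ofc_sd = float(np.mean(ofc_sds)) if ofc_sds else drive_sds[gi, si]
            effective_coupling[g][s] = couplings[g] * ofc_sd

            if cfg.n_unassigned_voxels > 0:
                leak_w = rng_conf.normal(
                    0.0,
                    cfg.confound_leak_sd,
                    size=(n_subj, cfg.n_unassigned_voxels, cfg.n_confounds),
                )
                leak = np.einsum("svk,stk->svt", leak_w, conf)
                noise = rng_noise.normal(
                    0.0, cfg.noise_sd, size=(n_subj, cfg.n_unassigned_voxels, cfg.n_trs)
                )
                unassigned[g][s] = cfg.global_amplitude * gsig[None, None, :] + leak + noise
            else:
                unassigned[g][s] = np.empty((n_subj, 0, cfg.n_trs))

    # Behavior: scene-induced craving linked to the planted per-subject
    # effective coupling; other measures independent controls.
    rows = []
    planted_rho: dict[str, float] = {}
    for gi, g in enumerate(GROUPS):
        n_subj = cfg.n_subjects_per_group[gi]
        kappa = np.stack([effective_coupling[g][s] for s in SESSIONS], axis=1)  # (subj, 2)
        delta_kappa = kappa[:, 0] - kappa[:, 1]
        var_link = cfg.craving_link_slope**2 * float(np.var(delta_kappa))
        var_noise = 2.0 * cfg.craving_link_noise**2
        denom = np.sqrt(var_link + var_noise)
        planted_rho[g] = float(cfg.craving_link_slope * np.std(delta_kappa) / denom) if denom > 0 else 0.0
        for si, s in enumerate(SESSIONS):
            craving = (
                cfg.craving_link_intercept
                + cfg.craving_link_slope * kappa[:, si]
                + rng_craving.normal(0.0, cfg.craving_link_noise, size=n_subj)
            )
            craving = np.clip(craving, 0.0, 10.0)
            pre = rng_craving.integers(0, 10, size=n_subj)
            movie_induced = rng_craving.integers(-2, 5, size=n_subj)
            hcq = (
                rng_craving.normal(39.0, 13.5, size=n_subj)
                if g == "HUD"
                else np.full(n_subj, np.nan)
            )
            for i in range(n_subj):
                rows.append(
                    {
                        "subject_id": f"{g}{i:03d}",
                        "group": g,
                        "session": s,
                        "scene_induced_craving_max": craving[i],
                        "pre_movie_craving": int(pre[i]),
                        "movie_induced_craving": int(movie_induced[i]),
                        "hcq_total": hcq[i],
                    }
                )
    behavior = pd.DataFrame(rows)

    truth = {
        "drug_locked_rois": tuple(cfg.drug_locked_rois),
        "ofc_rois": tuple(cfg.effective_ofc_rois),
        "ofc_amplitude_scale": cfg.ofc_amplitude_scale,
        "drug_amplitude": drug_amp.tolist(),
        "nondrug_amplitude": nondrug_amp.tolist(),
        "drive_sd": drive_sds.tolist(),
        "coupling": {g: couplings[g].tolist() for g in GROUPS},
        "effective_coupling": {
            g: {s: effective_coupling[g][s].tolist() for s in SESSIONS} for g in GROUPS
        },
        "planted_delta_correlation": planted_rho,
        "craving_link_slope": cfg.craving_link_slope,
        "seed": seed,
    }
    return SyntheticStudy(
        config=cfg,
        voxel_data=voxel_data,
        label_track=track,
        confounds=confounds,
        behavior=behavior,
        truth=truth,
        unassigned_voxels=unassigned,
    )
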