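"""Synthetic resting-state cohorts with planted static and dynamic effects.

The generator emulates the statistical structure the downstream pipeline
assumes: a two-group cohort (patients vs. controls) of parcellated BOLD
series driven by a discrete-state Markov process with group-specific
switching rates and fractional-occupancy (FO) profiles, plus regional
static-feature deficits in the patient group.  Every subject carries its
ground truth (state path, switching rate, occupancies, planted effect
map), so parameter-recovery tests need no external data.

Model
-----
Each subject follows a ``K``-state Markov chain.  For a target occupancy
profile ``pi`` and switching rate ``r`` the transition matrix is

    A[i, j] = c * pi[j]            (j != i)
    A[i, i] = 1 - c * (1 - pi[i])  with  c = r / (1 - sum(pi**2))

which is reversible with stationary distribution ``pi`` and expected
per-step switch probability exactly ``r`` at stationarity
(``sum_i pi_i * (1 - A_ii) = c * (1 - sum pi^2) = r``).  Observations are
``mean[state] + band-limited drift + white noise``; state mean vectors
are distinct spatial patterns shared by both groups.  Patient deficits
are planted by attenuating the signal part of affected parcels and
adding independent noise, which lowers fALFF, ReHo and degree
centrality there without touching the dynamics.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import band_bin_mask

__all__ = [
    "ParameterizationError",
    "SimulationConfig",
    "SyntheticCohort",
    "transition_matrix",
    "generate_state_paths",
    "render_node_series",
    "render_volumes",
    "build_atlas",
    "generate_cohort",
    "write_cohort",
    "load_node_series",
]

PATIENT = "patient"
CONTROL = "control"


class ParameterizationError(ValueError):
    """Raised when a requested FO/switch-rate combination is infeasible."""


def _default_fo_shift(n_states: int) -> dict[int, float]:
    # Patients: state 1 occupancy up, states 3 and last down (balanced).
    if n_states < 3:
        return {}
    shifts = {1: 0.06, 3: -0.03}
    last = n_states if n_states != 3 else None
    if last is not None:
        shifts[last] = shifts.get(last, 0.0) - 0.03
    else:
        shifts[1] = 0.03  # keep the shift balanced when only 3 states
    return shifts


def _default_affected(n_parcels: int) -> dict[int, float]:
    """Parcels carrying planted static deficits (amplitude factor < 1).

    At the 90-parcel default the choices echo regions repeatedly
    implicated in hearing loss (hippocampus, orbitofrontal, superior
    parietal); at other sizes roughly 10% of parcels, evenly spread.
    """
    if n_parcels >= 60:
        ids = [15, 16, 37, 38, 59, 60]
    else:
        k = max(1, math.ceil(0.15 * n_parcels))
        ids = list(np.linspace(1, n_parcels, k, dtype=int))
    return {int(i): 0.6 for i in ids if 1 <= i <= n_parcels}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults pin the emulated acquisition: 110 patients vs 106 controls,
    90 parcels, 240 volumes at TR=2 s, six hidden states, group-mean
    switching rates 0.08 (patients) vs 0.06 (controls), and a patient FO
    profile with state 1 raised and states 3 and 6 lowered.
    """

    n_patients: int = 110
    n_controls: int = 106
    n_parcels: int = 90
    n_volumes: int = 240
    tr_seconds: float = 2.0
    n_states: int = 6
    patient_switch_rate: float = 0.08
    control_switch_rate: float = 0.06
    fo_shift: dict[int, float] | None = None
    affected_parcels: dict[int, float] | None = None
    voxel_grid: tuple[int, int, int] = (15, 15, 15)
    noise_sd: float = 1.0
    voxel_noise_sd: float = 0.5
    drift_sd: float = 0.3
    mean_scale: float = 1.0
    rate_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fo_shift is None:
            self.fo_shift = _default_fo_shift(self.n_states)
        if self.affected_parcels is None:
            self.affected_parcels = _default_affected(self.n_parcels)
        self.validate()

    def validate(self) -> None:
        if min(self.n_patients, self.n_controls) < 0 or self.n_parcels < 1:
            raise ValueError("cohort sizes and n_parcels must be positive")
        if self.n_volumes < 2 or self.n_states < 1:
            raise ValueError("need n_volumes >= 2 and n_states >= 1")
        if self.tr_seconds <= 0 or self.noise_sd < 0:
            raise ValueError("tr_seconds must be > 0 and noise_sd >= 0")
        for rate in (self.patient_switch_rate, self.control_switch_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"switch rate {rate} outside [0, 1]")
        bad = [p for p in self.affected_parcels if not 1 <= p <= self.n_parcels]
        if bad:
            raise ValueError(f"affected parcels {bad} outside 1..{self.n_parcels}")
        for group in (PATIENT, CONTROL):
            pi = self.occupancies(group)
            if abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError("occupancy vector does not sum to 1")
            transition_matrix(pi, self.switch_rate(group))  # feasibility

    def switch_rate(self, group: str) -> float:
        return self.patient_switch_rate if group == PATIENT else self.control_switch_rate

    def occupancies(self, group: str) -> np.ndarray:
        """Target stationary FO profile for a group (sums to 1)."""
        pi = np.full(self.n_states, 1.0 / self.n_states)
        if group == PATIENT:
            for state, delta in self.fo_shift.items():
                if 1 <= state <= self.n_states:
                    pi[state - 1] += delta
        pi = np.clip(pi, 1e-9, None)
        return pi / pi.sum()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_grid"] = list(self.voxel_grid)
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    config: SimulationConfig
    manifest: pd.DataFrame  # columns: subject, group
    node_series: dict[str, np.ndarray]  # subject -> (T, N)
    truth: dict
    volumes: dict[str, np.ndarray] | None = None  # subject -> (x, y, z, T)
    atlas: np.ndarray | None = None

    def subjects(self, group: str | None = None) -> list[str]:
        m = self.manifest
        if group is not None:
            m = m[m["group"] == group]
        return list(m["subject"])


def transition_matrix(pi: np.ndarray, rate: float) -> np.ndarray:
    """Closed-form transition matrix with stationary ``pi`` and switch rate ``rate``.

    ``A[i, j] = c * pi[j]`` off the diagonal with
    ``c = rate / (1 - sum(pi ** 2))``; self-transitions absorb the rest.
    Raises :class:`ParameterizationError` when any self-transition would
    be negative, naming the maximum feasible rate.
    """
    pi = np.asarray(pi, dtype=float)
    k = pi.size
    if k == 1:
        if rate > 0:
            raise ParameterizationError("a 1-state chain cannot switch (rate must be 0)")
        return np.ones((1, 1))
    if rate == 0.0:
        return np.eye(k)
    denom = 1.0 - float(pi @ pi)
    if denom <= 0:
        raise ParameterizationError(
            "degenerate occupancy profile: a single state has all the mass, "
            "so no positive switching rate is feasible"
        )
    c = rate / denom
    diag = 1.0 - c * (1.0 - pi)
    if np.any(diag < -1e-12):
        max_rate = denom / np.max(1.0 - pi)
        raise ParameterizationError(
            f"switch rate {rate} infeasible for this FO profile; "
            f"maximum feasible rate is {max_rate:.4f}"
        )
    a = c * np.tile(pi, (k, 1))
    np.fill_diagonal(a, np.clip(diag, 0.0, 1.0))
    return a / a.sum(axis=1, keepdims=True)


def _simulate_chain(
    a: np.ndarray, pi: np.ndarray, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(a, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    s = int(np.searchsorted(np.cumsum(pi), rng.random()))
    s = min(s, a.shape[0] - 1)
    states[0] = s
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1]))
        s = min(s, a.shape[0] - 1)
        states[t] = s
    return states


def generate_state_paths(
    cfg: SimulationConfig,
    group: str,
    n_subjects: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Markov state sequences (0-based labels) for one group.

    Expected per-step transition frequency equals the group's switching
    rate and the stationary occupancy matches the group FO profile.  With
    ``rate_jitter_sd > 0`` each subject's rate is drawn around the group
    mean (clipped to the feasible range), adding between-subject SR
    variance beyond chain stochasticity.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_subjects is None:
        n_subjects = cfg.n_patients if group == PATIENT else cfg.n_controls
    pi = cfg.occupancies(group)
    rate = cfg.switch_rate(group)
    a_base = transition_matrix(pi, rate)
    paths = []
    for _ in range(n_subjects):
        if cfg.rate_jitter_sd > 0:
            denom = 1.0 - float(pi @ pi)
            max_rate = denom / np.max(1.0 - pi)
            r = float(np.clip(rng.normal(rate, cfg.rate_jitter_sd), 0.0, 0.999 * max_rate))
            a = transition_matrix(pi, r)
        else:
            a = a_base
        paths.append(_simulate_chain(a, pi, cfg.n_volumes, rng))
    return paths


def _band_limited_noise(
    shape: tuple[int, int], tr: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise projected onto the 0.01-0.1 Hz band, rescaled to sd."""
    n, _ = shape
    white = rng.standard_normal(shape)
    keep = band_bin_mask(n, tr, 0.01, min(0.1, 1.0 / (2.0 * tr)))
    spec = np.fft.rfft(white, axis=0)
    spec[~keep] = 0.0
    filtered = np.fft.irfft(spec, n=n, axis=0)
    # variance after an ideal filter = (kept real dof) / n
    kept_dof = 0
    for k in np.nonzero(keep)[0]:
        kept_dof += 1 if k in (0, n - k) else 2
    if kept_dof == 0:
        return np.zeros(shape)
    return filtered * (sd / math.sqrt(kept_dof / n))


def render_node_series(
    paths: list[np.ndarray],
    cfg: SimulationConfig,
    group: str,
    state_means: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Emit ``(T, N)`` node series for each state path.

    Emission = state mean + band-limited drift + white noise.  In the
    patient group, affected parcels have their signal part (state mean +
    drift) scaled by the planted amplitude factor ``alpha`` while the
    measurement noise stays at full strength, which depresses the
    band-limited share of the spectrum (fALFF) and inter-regional
    correlations (degree centrality).  The matching voxel-level part of
    the deficit — added independent voxel noise that lowers local
    coherence (ReHo) — is planted in :func:`render_volumes`.
    """
    t_len = cfg.n_volumes
    out = []
    for path in paths:
        signal = state_means[path]  # (T, N)
        if cfg.drift_sd > 0:
            signal = signal + _band_limited_noise(
                (t_len, cfg.n_parcels), cfg.tr_seconds, cfg.drift_sd, rng
            )
        else:
            signal = signal.copy()
        if group == PATIENT:
            for parcel, alpha in cfg.affected_parcels.items():
                signal[:, parcel - 1] *= alpha
        x = signal + cfg.noise_sd * rng.standard_normal((t_len, cfg.n_parcels))
        out.append(x)
    return out


def build_atlas(cfg: SimulationConfig) -> np.ndarray:
    """Integer label image: ``n_parcels`` contiguous regions of >=27 voxels.

    Voxels are visited in a boustrophedon (snake) order, which keeps each
    chunk face-connected, and split into near-equal runs.  Background is
    0 and labels are 1..N.  Raises a sizing error naming the required
    minimum when the grid is too small.
    """
    nx, ny, nz = cfg.voxel_grid
    n_vox = nx * ny * nz
    needed = 27 * cfg.n_parcels
    if n_vox < needed:
        side = math.ceil(needed ** (1.0 / 3.0))
        raise ValueError(
            f"voxel grid {cfg.voxel_grid} has {n_vox} voxels but "
            f"{cfg.n_parcels} parcels x 27 voxels needs >= {needed} "
            f"(e.g. a {side}x{side}x{side} grid)"
        )
    order = []
    for z in range(nz):
        ys = range(ny) if z % 2 == 0 else range(ny - 1, -1, -1)
        for yi, y in enumerate(ys):
            forward = (z + yi) % 2 == 0
            xs = range(nx) if forward else range(nx - 1, -1, -1)
            for x in xs:
                order.append((x, y, z))
    atlas = np.zeros((nx, ny, nz), dtype=np.int32)
    base, rem = divmod(n_vox, cfg.n_parcels)
    idx = 0
    for label in range(1, cfg.n_parcels + 1):
        size = base + (1 if label <= rem else 0)
        for _ in range(size):
            atlas[order[idx]] = label
            idx += 1
    return atlas


def render_volumes(
    node_series: np.ndarray,
    atlas: np.ndarray,
    voxel_noise_sd: float,
    rng: np.random.Generator,
    extra_voxel_noise: dict[int, float] | None = None,
) -> np.ndarray:
    """Expand one subject's ``(T, N)`` node series into a 4-D lattice.

    Every voxel of region ``p`` carries that region's time course plus
    independent voxel noise, so with ``voxel_noise_sd == 0`` (and no
    planted extra noise) parcel-mean extraction returns the node series
    exactly.  ``extra_voxel_noise`` maps parcel id -> additional
    independent voxel-noise sd — the planted local-coherence deficit of
    affected regions in patient subjects.
    """
    t_len, n_parcels = node_series.shape
    vol = np.zeros(atlas.shape + (t_len,), dtype=float)
    for label in range(1, n_parcels + 1):
        mask = atlas == label
        vol[mask, :] = node_series[:, label - 1]
    if voxel_noise_sd > 0:
        vol += voxel_noise_sd * rng.standard_normal(vol.shape)
    for label, sd in (extra_voxel_noise or {}).items():
        if sd > 0:
            mask = atlas == label
            vol[mask, :] += sd * rng.standard_normal((int(mask.sum()), t_len))
    vol[atlas == 0] = 0.0
    return vol


def _empirical_sr(path: np.ndarray) -> float:
    return float(np.mean(np.diff(path) != 0)) if path.size > 1 else 0.0


def _empirical_fo(path: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(path, minlength=k) / path.size


def generate_cohort(
    cfg: SimulationConfig, make_volumes: bool = False
) -> SyntheticCohort:
    """Generate the full two-group cohort (deterministic in ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    state_means = cfg.mean_scale * rng.standard_normal((cfg.n_states, cfg.n_parcels))

    manifest_rows: list[dict] = []
    node_series: dict[str, np.ndarray] = {}
    truth: dict = {
        "state_means": state_means,
        "affected_parcels": dict(cfg.affected_parcels),
        "group_switch_rate": {
            PATIENT: cfg.patient_switch_rate,
            CONTROL: cfg.control_switch_rate,
        },
        "group_fo": {
            PATIENT: cfg.occupancies(PATIENT),
            CONTROL: cfg.occupancies(CONTROL),
        },
        "state_paths": {},
        "sr": {},
        "fo": {},
    }
    atlas = build_atlas(cfg) if make_volumes else None
    volumes: dict[str, np.ndarray] | None = {} if make_volumes else None

    for group, n_sub, tag in (
        (PATIENT, cfg.n_patients, "P"),
        (CONTROL, cfg.n_controls, "C"),
    ):
        paths = generate_state_paths(cfg, group, n_subjects=n_sub, rng=rng)
        series = render_node_series(paths, cfg, group, state_means, rng)
        for i, (path, x) in enumerate(zip(paths, series), start=1):
            sub = f"sub-{tag}{i:03d}"
            manifest_rows.append({"subject": sub, "group": group})
            node_series[sub] = x
            truth["state_paths"][sub] = path
            truth["sr"][sub] = _empirical_sr(path)
            truth["fo"][sub] = _empirical_fo(path, cfg.n_states)
            if make_volumes:
                extra = None
                if group == PATIENT:
                    # local-coherence deficit: extra voxel noise scaled to
                    # the strength of the planted amplitude attenuation
                    extra = {
                        p: cfg.mean_scale * math.sqrt(max(0.0, 1.0 - a**2))
                        for p, a in cfg.affected_parcels.items()
                    }
                volumes[sub] = render_volumes(
                    x, atlas, cfg.voxel_noise_sd, rng, extra_voxel_noise=extra
                )

    manifest = pd.DataFrame(manifest_rows)
    return SyntheticCohort(
        config=cfg,
        manifest=manifest,
        node_series=node_series,
        truth=truth,
        volumes=volumes,
        atlas=atlas,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort as TSV node series + JSON manifest/truth (+ NIfTI)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    cols = [f"parcel_{i}" for i in range(1, cfg.n_parcels + 1)]
    for sub, x in cohort.node_series.items():
        pd.DataFrame(x, columns=cols).to_csv(
            out / f"{sub}_timeseries.tsv", sep="\t", index=False
        )
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    truth = {
        "config": cfg.to_dict(),
        "group_switch_rate": cohort.truth["group_switch_rate"],
        "group_fo": {g: list(v) for g, v in cohort.truth["group_fo"].items()},
        "affected_parcels": cohort.truth["affected_parcels"],
        "sr": cohort.truth["sr"],
        "fo": {s: list(v) for s, v in cohort.truth["fo"].items()},
        "state_paths": {s: [int(v) for v in p] for s, p in cohort.truth["state_paths"].items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    if cohort.volumes is not None:
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(cohort.atlas.astype(np.int16), affine), out / "atlas.nii.gz")
        for sub, vol in cohort.volumes.items():
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), affine),
                out / f"{sub}_bold.nii.gz",
            )
    return out


def load_node_series(directory: str | Path) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Read back a manifest + per-subject TSV node series."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    series = {}
    for sub in manifest["subject"]:
        series[sub] = pd.read_csv(
            directory / f"{sub}_timeseries.tsv", sep="\t"
        ).to_numpy(dtype=float)
    return manifest, series
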