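"""Synthetic connectomes, graph signals, and cohorts with known ground truth.

The generator emulates the statistical structure the coupling pipeline
expects from real data while keeping analytic control over every quantity:

* geometric random connectomes — points on a sphere, distance-decaying
  weights, thresholded to a target density and guaranteed connected;
* graph signals whose per-eigenmode power decays as ``(k+1)^-psd_decay``,
  i.e. a 1/f-like graph spectrum dominated by the smooth low modes, carried
  by temporally autocorrelated (AR(1)) coefficients;
* planted decoupling — a node-localized independent component added at
  chosen regions.  A spatially concentrated source has energy spread across
  all graph frequencies, so with a low cutoff most of it lands in the
  decoupled half; its amplitude is calibrated analytically so the expected
  SDI at the planted node hits a chosen target (default +0.5);
* multi-subject cohorts with per-subject connectome jitter and a condition
  contrast that shifts the expected SDI at chosen effect regions.

Expected SDI values are available in closed form (:func:`expected_sdi`),
which is what makes sign-recovery and contrast-power experiments honest:
the generator knows the answer before the pipeline runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .graph import GraphSpectrum, StructuralConnectome, eigendecompose, normalized_laplacian
from .gsp import RegionTimeSeries

__all__ = [
    "SynthSpec",
    "make_connectome",
    "make_graph_signal",
    "make_cohort",
    "expected_sdi",
    "ar1_noise",
]

#: expected SDI aimed at for a planted decoupled node
PLANTED_SDI_TARGET = 0.5


@dataclass
class SynthSpec:
    """Parameters of a synthetic study.

    Defaults describe the reference synthetic condition used throughout:
    64-region connectomes, a 43-subject cohort, 80 s of signal at 125 Hz
    (10^4 samples), per-mode power decaying as ``k^-3`` (strongly
    low-frequency-dominated: real graph spectra of brain activity fall by
    orders of magnitude, and at this decay effectively every node's
    background is dominated by the smooth harmonics, which is what makes a
    planted decoupled node a well-posed ground truth), 10% of regions
    planted as decoupled, and an AR(1) temporal carrier with coefficient
    0.9.
    """

    n_regions: int = 64
    n_subjects: int = 43
    duration_s: float = 80.0
    sampling_rate: float = 125.0
    psd_decay: float = 3.0
    planted_decoupled: tuple[int, ...] | None = None  # None -> 10% of regions
    n_effect_regions: int = 10
    planted_effect: float = 0.5
    noise_sd: float = 1.0
    ar_coeff: float = 0.9
    density: float = 0.3
    connectome_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regions, self.n_subjects) < 1:
            raise ValueError("counts must be positive")
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.planted_decoupled is not None:
            idx = np.asarray(self.planted_decoupled)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_regions):
                raise ValueError("planted_decoupled indices out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def resolve_planted(self, rng: np.random.Generator) -> np.ndarray:
        if self.planted_decoupled is not None:
            return np.asarray(sorted(self.planted_decoupled), dtype=int)
        n_planted = max(1, self.n_regions // 10)
        return np.sort(rng.choice(self.n_regions, size=n_planted, replace=False))


def make_connectome(
    n: int, density: float = 0.3, seed: int | np.random.Generator = 0,
    subject_id: str = "synthetic",
) -> StructuralConnectome:
    """Geometric random connectome: sphere points, distance-decay weights.

    ``n`` points are placed uniformly on the unit sphere; candidate edge
    weights are ``exp(-d / scale)`` with ``scale`` the mean pairwise
    distance over 4 (so weights span a couple of orders of magnitude, like
    fiber densities do).  The weakest edges are pruned to reach the target
    density.  Disconnected draws are rejected and re-drawn (up to 50
    times), so every returned graph has a single zero Laplacian eigenvalue.
    """
    if n < 4:
        raise ValueError("need at least 4 regions")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _attempt in range(50):
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        dist = squareform(pdist(pts))
        scale = dist[np.triu_indices(n, 1)].mean() / 4.0
        weights = np.exp(-dist / scale)
        np.fill_diagonal(weights, 0.0)
        triu = weights[np.triu_indices(n, 1)]
        n_keep = max(n - 1, int(round(density * triu.size)))
        thr = np.sort(triu)[triu.size - n_keep]
        weights[weights < thr] = 0.0
        np.fill_diagonal(weights, 0.0)
        n_comp, _ = connected_components(weights > 0, directed=False)
        if n_comp == 1:
            labels = [f"R{i:03d}" for i in range(n)]
            return StructuralConnectome(labels, weights, subject_id=subject_id)
    raise RuntimeError(
        f"could not draw a connected graph at density {density} in 50 attempts"
    )


def ar1_noise(
    rng: np.random.Generator, shape: tuple[int, int], phi: float
) -> np.ndarray:
    """Stationary unit-variance AR(1) rows: x_t = phi x_{t-1} + sqrt(1-phi^2) e_t."""
    if not 0 <= phi < 1:
        raise ValueError("AR coefficient must be in [0, 1)")
    innov = rng.standard_normal(shape) * np.sqrt(1.0 - phi**2)
    # stationary start: zi holds phi * x_{-1} with x_{-1} ~ N(0, 1)
    x0 = rng.standard_normal((shape[0], 1))
    out, _ = sp_signal.lfilter([1.0], [1.0, -phi], innov, axis=1, zi=phi * x0)
    return out


def _mode_sds(spec: SynthSpec, n: int) -> np.ndarray:
    return spec.noise_sd * (np.arange(1, n + 1)) ** (-spec.psd_decay / 2.0)


def _background_cutoff(mode_sds: np.ndarray) -> int:
    power = mode_sds**2
    cum = np.cumsum(power)
    c = int(np.searchsorted(cum, power.sum() / 2.0) + 1)
    return int(np.clip(c, 1, len(power) - 1))


def _planted_amplitude(
    spectrum: GraphSpectrum, mode_sds: np.ndarray, cutoff: int,
    node: int, target_sdi: float,
) -> float:
    """Amplitude of a node-localized component reaching an expected SDI target.

    The background variance of node ``node`` splits across the coupled and
    decoupled filters as ``v_lo = sum_{k<C} U[n,k]^2 s_k^2`` and
    ``v_hi = sum_{k>=C} U[n,k]^2 s_k^2``.  A unit-variance carrier injected
    at the node with amplitude ``a`` contributes ``a^2 p_lo^2`` and
    ``a^2 p_hi^2`` at the node itself, with ``p_lo = sum_{k<C} U[n,k]^2``
    and ``p_hi = 1 - p_lo`` (the diagonal of the two projectors).  Solving

        (v_hi + a^2 p_hi^2) / (v_lo + a^2 p_lo^2) = 2^(2 * target)

    for ``a`` gives the calibration in closed form.  Unreachable targets
    (the localized component alone cannot decouple the node that far) fall
    back to 10x the background scale, the closest the mechanism can get.
    """
    u_row_sq = spectrum.eigenvectors[node] ** 2
    p_lo = u_row_sq[:cutoff].sum()
    p_hi = 1.0 - p_lo
    v_lo = float(np.sum(u_row_sq[:cutoff] * mode_sds[:cutoff] ** 2))
    v_hi = float(np.sum(u_row_sq[cutoff:] * mode_sds[cutoff:] ** 2))
    ratio = 2.0 ** (2.0 * target_sdi)
    denom = p_hi**2 - ratio * p_lo**2
    numer = ratio * v_lo - v_hi
    if denom <= 0 or numer <= 0:
        if v_hi / v_lo >= ratio:  # background already beyond the target
            return 0.0
        return 10.0 * float(np.sqrt(v_lo + v_hi))
    return float(np.sqrt(numer / denom))


def expected_sdi(
    spectrum: GraphSpectrum, mode_sds: np.ndarray, cutoff: int,
    planted_amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form expected SDI per node under the generator's model.

    Coupled/decoupled components at a node are zero-mean Gaussian with
    variances given by the projected background plus any node-localized
    component; the expected absolute value of a Gaussian is proportional to
    its standard deviation, so the l1-norm log-ratio converges (large T) to
    half the log2 variance ratio.  Cross-node leakage of planted components
    is included exactly.
    """
    u = spectrum.eigenvectors
    n = u.shape[0]
    p_low = u[:, :cutoff] @ u[:, :cutoff].T  # low-pass projector
    var_lo = (u[:, :cutoff] ** 2) @ (mode_sds[:cutoff] ** 2)
    var_hi = (u[:, cutoff:] ** 2) @ (mode_sds[cutoff:] ** 2)
    if planted_amplitudes is not None:
        amps2 = np.asarray(planted_amplitudes, dtype=float) ** 2
        p_high = np.eye(n) - p_low
        var_lo = var_lo + (p_low**2) @ amps2
        var_hi = var_hi + (p_high**2) @ amps2
    return 0.5 * np.log2(var_hi / var_lo)


def make_graph_signal(
    spectrum: GraphSpectrum,
    spec: SynthSpec,
    rng: np.random.Generator | int | None = None,
    planted: np.ndarray | None = None,
    extra_sdi: dict[int, float] | None = None,
    subject_id: str = "synthetic",
    condition: str = "a",
) -> tuple[RegionTimeSeries, pd.DataFrame]:
    """Graph signal with 1/f-like graph PSD and planted decoupled nodes.

    Background: per-mode AR(1) coefficient time courses with standard
    deviation ``noise_sd * k^(-psd_decay/2)``, inverse-GFT'd to regions.
    Each planted node receives an independent node-localized AR(1)
    component calibrated to an expected SDI of ``+PLANTED_SDI_TARGET``.
    ``extra_sdi`` shifts the calibration target at chosen nodes (used for
    condition contrasts).

    Returns the signal and a per-region truth table with the planted flag,
    calibrated amplitude, and closed-form expected SDI and sign.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = spectrum.n_modes
    t = spec.n_samples
    mode_sds = _mode_sds(spec, n)
    cutoff = _background_cutoff(mode_sds)
    coeffs = ar1_noise(rng, (n, t), spec.ar_coeff) * mode_sds[:, None]
    values = spectrum.eigenvectors @ coeffs

    planted = np.asarray([], dtype=int) if planted is None else planted
    amplitudes = np.zeros(n)
    targets = dict.fromkeys(planted.tolist(), PLANTED_SDI_TARGET)
    for node, shift in (extra_sdi or {}).items():
        base = targets.get(node)
        if base is None:
            # shift relative to the node's expected background SDI
            base = float(
                expected_sdi(spectrum, mode_sds, cutoff)[node]
            )
        targets[node] = base + shift
    for node, target in targets.items():
        amplitudes[node] = _planted_amplitude(spectrum, mode_sds, cutoff, node, target)
    hot = np.flatnonzero(amplitudes > 0)
    if hot.size:
        carriers = ar1_noise(rng, (hot.size, t), spec.ar_coeff)
        values[hot] += amplitudes[hot, None] * carriers

    exp_sdi = expected_sdi(spectrum, mode_sds, cutoff, amplitudes)
    truth = pd.DataFrame(
        {
            "region": np.arange(n),
            "planted_decoupled": np.isin(np.arange(n), planted),
            "amplitude": amplitudes,
            "expected_sdi": exp_sdi,
            "expected_sign": np.sign(exp_sdi).astype(int),
            "background_cutoff": cutoff,
        }
    )
    ts = RegionTimeSeries(
        values=values,
        sampling_rate=spec.sampling_rate,
        subject_id=subject_id,
        condition=condition,
        signal_kind="raw",
    )
    return ts, truth


def _jitter_connectome(
    base: StructuralConnectome, sd: float, rng: np.random.Generator,
    subject_id: str,
) -> StructuralConnectome:
    """Multiplicative log-normal weight jitter, redrawn until connected."""
    for _ in range(50):
        noise = np.exp(rng.normal(0.0, sd, size=base.weights.shape))
        noise = (noise + noise.T) / 2.0
        w = base.weights * noise
        n_comp, _ = connected_components(w > 0, directed=False)
        if n_comp == 1 and np.all(w.sum(axis=1) > 0):
            return StructuralConnectome(list(base.region_ids), w, subject_id=subject_id)
    raise RuntimeError("connectome jitter repeatedly disconnected the graph")


@dataclass
class SyntheticCohort:
    """Output of :func:`make_cohort`: per-subject data plus ground truth."""

    spec: SynthSpec
    connectomes: list[StructuralConnectome]
    condition_a: list[RegionTimeSeries]
    condition_b: list[RegionTimeSeries]
    truth: pd.DataFrame  # region-level truth shared across subjects
    effect_regions: np.ndarray
    planted_regions: np.ndarray


def make_cohort(spec: SynthSpec) -> SyntheticCohort:
    """Multi-subject, two-condition cohort with planted contrast effects.

    All subjects share one base connectome geometry, individually perturbed
    by multiplicative weight jitter (connectivity preserved).  Condition
    ``a`` carries the planted-decoupling layout; condition ``b`` adds a
    ``planted_effect`` shift of the expected SDI at ``n_effect_regions``
    non-planted regions.  A single master seed makes the whole cohort
    bit-reproducible.
    """
    if spec.n_subjects < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    rng = np.random.default_rng(spec.seed)
    base = make_connectome(spec.n_regions, spec.density, rng, subject_id="base")
    planted = spec.resolve_planted(rng)
    candidates = np.setdiff1d(np.arange(spec.n_regions), planted)
    n_eff = min(spec.n_effect_regions, candidates.size)
    effect_regions = np.sort(rng.choice(candidates, size=n_eff, replace=False))
    effect_shift = {int(r): spec.planted_effect for r in effect_regions}

    connectomes, cond_a, cond_b = [], [], []
    truth_a = None
    for s in range(spec.n_subjects):
        sid = f"sub{s:03d}"
        conn = _jitter_connectome(base, spec.connectome_jitter_sd, rng, sid)
        spectrum = eigendecompose(normalized_laplacian(conn))
        ts_a, tr_a = make_graph_signal(
            spectrum, spec, rng, planted=planted, subject_id=sid, condition="a"
        )
        ts_b, _ = make_graph_signal(
            spectrum, spec, rng, planted=planted, extra_sdi=effect_shift,
            subject_id=sid, condition="b",
        )
        connectomes.append(conn)
        cond_a.append(ts_a)
        cond_b.append(ts_b)
        if truth_a is None:
            truth_a = tr_a
    truth = truth_a.copy()
    truth["effect_region"] = np.isin(truth["region"].values, effect_regions)
    truth["planted_effect"] = np.where(truth["effect_region"], spec.planted_effect, 0.0)
    return SyntheticCohort(
        spec=spec,
        connectomes=connectomes,
        condition_a=cond_a,
        condition_b=cond_b,
        truth=truth,
        effect_regions=effect_regions,
        planted_regions=planted,
    )
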