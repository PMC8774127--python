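"""Synthetic cohorts with known, planted structure-function coupling effects.

Connectomes are drawn from a weighted block model whose blocks are the
intrinsic connectivity networks. BOLD is synthesized directly in the graph
spectral domain of each subject's own connectome: per-eigenmode coefficients
are zero-mean Gaussians whose standard deviation decays geometrically with
mode index, so low-frequency (structure-aligned) harmonics carry most of the
energy, as in real resting-state data. Age- and group-dependent gains applied
to the low- and high-band components at target-network nodes plant exactly
the kind of coupling-by-age trajectories the downstream PLS and regression
stages are meant to detect, with analytically known ground truth.

The generator is a pure function of its configuration (seed included).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from . import gsp_coupling, reference_cohort
from .io_formats import Connectome, ParcellatedBold, SubjectRecord, ValidationError

logger = logging.getLogger(__name__)

#: the 12 intrinsic connectivity networks of the 360-area multimodal parcellation
CANONICAL_NETWORKS = (
    "visual1", "visual2", "somatomotor", "cinguloopercular", "dorsalattention",
    "language", "frontoparietal", "auditory", "default", "posteriormultimodal",
    "ventralmultimodal", "orbitoaffective",
)

GROUP_ORDER = ("control", "athlete")


def network_names(n_networks: int) -> tuple:
    if n_networks == len(CANONICAL_NETWORKS):
        return CANONICAL_NETWORKS
    return tuple(f"net{i + 1:02d}" for i in range(n_networks))


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth age x group effect on spectral energy at target networks.

    ``slope_*_per_year`` are multiplicative gains on the low-band (S_C) or
    high-band (S_D) signal amplitude per year of age relative to
    ``age_reference_years``, applied only at nodes of ``target_networks``;
    ``curvature_*_per_year2`` adds an optional quadratic-in-age term to the
    same gains. ``baseline_low_high_ratio`` is the ratio of the first to the
    last eigenmode's coefficient s.d.; energy decays geometrically between
    them.
    """

    target_networks: frozenset = frozenset()
    slope_sc_per_year: Mapping = field(
        default_factory=lambda: {"control": 0.0, "athlete": 0.0})
    slope_sd_per_year: Mapping = field(
        default_factory=lambda: {"control": 0.0, "athlete": 0.0})
    curvature_sc_per_year2: Mapping = field(default_factory=dict)
    curvature_sd_per_year2: Mapping = field(default_factory=dict)
    baseline_low_high_ratio: float = 20.0
    age_reference_years: float = 30.0

    def __post_init__(self):
        if not (self.baseline_low_high_ratio > 0):
            raise ValidationError("baseline_low_high_ratio must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the roller-derby study: 19 athletes aged 23-45 and
    14 controls aged 19-49, 360 cortical areas in 12 networks, 106 TRs.
    """

    seed: int = 0
    n_nodes: int = 360
    n_networks: int = 12
    n_per_group: Mapping = field(
        default_factory=lambda: {"control": 14, "athlete": 19})
    age_range: Mapping = field(
        default_factory=lambda: {"control": (19.0, 49.0), "athlete": (23.0, 45.0)})
    n_trs: int = 106
    within_block_weight_mean: float = 1.0
    between_block_weight_mean: float = 0.2
    within_block_density: float = 0.6
    between_block_density: float = 0.15
    effect: PlantedEffect = field(default_factory=PlantedEffect)
    noise_sd: float = 0.05
    areal_amplitude_sd: float = 0.15
    connectome_subject_sd: float = 0.1
    fd_lognormal_median_mm: float = 0.075
    fd_lognormal_sigma: float = 0.45
    ages_from_table: bool = False

    def __post_init__(self):
        if not (self.within_block_weight_mean > self.between_block_weight_mean > 0):
            raise ValidationError(
                "require within_block_weight_mean > between_block_weight_mean > 0")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValidationError("at least 2 subjects per group")
        if self.n_nodes < self.n_networks:
            raise ValidationError("need at least one node per network")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.connectome_subject_sd < 0:
            raise ValidationError("connectome_subject_sd must be nonnegative")
        if self.areal_amplitude_sd < 0:
            raise ValidationError("areal_amplitude_sd must be nonnegative")
        names = set(network_names(self.n_networks))
        unknown = set(self.effect.target_networks) - names
        if unknown:
            raise ValidationError(f"target networks not generated: {sorted(unknown)}")

    @property
    def groups(self) -> tuple:
        return tuple(g for g in GROUP_ORDER if g in self.n_per_group) + tuple(
            g for g in self.n_per_group if g not in GROUP_ORDER)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "effect" in d and not isinstance(d["effect"], PlantedEffect):
            e = dict(d["effect"])
            if "target_networks" in e:
                e["target_networks"] = frozenset(e["target_networks"])
            d["effect"] = PlantedEffect(**e)
        if "age_range" in d:
            d["age_range"] = {g: tuple(v) for g, v in d["age_range"].items()}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


def _node_blocks(config: SimulationConfig):
    """Even partition of node indices into network blocks."""
    return np.array_split(np.arange(config.n_nodes), config.n_networks)


def node_labels(config: SimulationConfig) -> dict:
    names = network_names(config.n_networks)
    network_of = {}
    for name, block in zip(names, _node_blocks(config)):
        for i in block:
            network_of[f"area{i + 1:03d}"] = name
    return network_of


def generate_connectome(config: SimulationConfig, rng: np.random.Generator) -> Connectome:
    """Weighted block-model connectome: gamma-distributed positive weights,
    denser and stronger within network blocks than between.

    If the realized graph is disconnected, minimal bridging edges at the
    between-block mean weight are added (and logged) so every node has a
    path to every other — a requirement of the normalized Laplacian spectrum.
    """
    n = config.n_nodes
    block_of = np.empty(n, dtype=int)
    for b, block in enumerate(_node_blocks(config)):
        block_of[block] = b
    same = block_of[:, None] == block_of[None, :]

    density = np.where(same, config.within_block_density, config.between_block_density)
    mean_w = np.where(same, config.within_block_weight_mean,
                      config.between_block_weight_mean)
    present = rng.random((n, n)) < density
    # gamma(shape=4) keeps weights positive and right-skewed like streamline counts
    shape = 4.0
    w = rng.gamma(shape, mean_w / shape, size=(n, n)) * present
    w = np.triu(w, k=1)
    w = w + w.T

    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        reps = [np.flatnonzero(labels == c)[0] for c in range(n_comp)]
        for a, b in zip(reps[:-1], reps[1:]):
            w[a, b] = w[b, a] = config.between_block_weight_mean
        logger.warning("connectome disconnected: added %d bridging edge(s)", n_comp - 1)

    network_of = node_labels(config)
    return Connectome(tuple(network_of), w, network_of)


def perturb_connectome(template: Connectome, sd: float,
                       rng: np.random.Generator) -> Connectome:
    """Individual connectome as a multiplicative jitter of a cohort template.

    Each existing edge is scaled by an independent lognormal factor of median
    1 and log-s.d. ``sd``; absent edges stay absent, so connectivity of the
    template is preserved. This emulates the empirical fact that individual
    tractography connectomes share a common backbone and differ mainly in
    edge strength.
    """
    if sd == 0:
        return template
    n = template.n_nodes
    factors = rng.lognormal(0.0, sd, size=(n, n))
    w = template.weights * np.triu(factors, k=1)
    w = w + w.T
    return Connectome(template.node_ids, w, template.network_of)


def _mode_sigmas(ratio: float, n: int) -> np.ndarray:
    """Geometrically decaying per-mode coefficient s.d., sigma_0 = 1.

    ratio = sigma_0 / sigma_{N-1}; ratio -> inf degenerates to all energy in
    the trivial (constant-like) first harmonic.
    """
    if math.isinf(ratio):
        s = np.zeros(n)
        s[0] = 1.0
        return s
    g = ratio ** (-1.0 / max(n - 1, 1))
    return g ** np.arange(n)


def _generation_split(sigmas: np.ndarray) -> int:
    energy = sigmas**2
    c = int(np.searchsorted(np.cumsum(energy), energy.sum() / 2.0) + 1)
    return min(max(c, 1), len(sigmas) - 1)


def _node_gains(connectome: Connectome, subject: SubjectRecord,
                effect: PlantedEffect) -> tuple:
    """Per-node amplitude gains (low band, high band) for the planted effect."""
    n = connectome.n_nodes
    gc = np.ones(n)
    gd = np.ones(n)
    dage = subject.age_years - effect.age_reference_years
    in_target = np.array(
        [connectome.network_of[i] in effect.target_networks for i in connectome.node_ids])
    sc = effect.slope_sc_per_year.get(subject.group, 0.0)
    sd = effect.slope_sd_per_year.get(subject.group, 0.0)
    qc = effect.curvature_sc_per_year2.get(subject.group, 0.0)
    qd = effect.curvature_sd_per_year2.get(subject.group, 0.0)
    gc[in_target] = max(1.0 + sc * dage + qc * dage**2, 0.05)
    gd[in_target] = max(1.0 + sd * dage + qd * dage**2, 0.05)
    return gc, gd


def generate_subject_bold(connectome: Connectome, subject: SubjectRecord,
                          config: SimulationConfig,
                          rng: np.random.Generator) -> ParcellatedBold:
    """Synthesize one subject's BOLD run in the connectome's spectral domain.

    Spectral coefficients are independent N(0, sigma_k^2) per TR; the inverse
    graph Fourier transform maps each band to node space, where the planted
    age/group gains scale the low-band (coupled) and high-band (decoupled)
    components at target-network nodes. A per-subject, per-node lognormal
    amplitude factor (s.d. ``areal_amplitude_sd``) models between-subject
    heterogeneity of areal BOLD variance unrelated to age, and white
    observation noise of s.d. ``noise_sd`` is added last.

    The node-wise gain keeps the planted effect spatially exact; its price is
    that a gained component is no longer purely in-band, so a strong S_C
    trend bleeds partly into measured S_D at the same nodes (and vice versa)
    — mirroring the empirical fact that an area can carry coupled and
    decoupled trends simultaneously.
    """
    spectrum = gsp_coupling.decompose(gsp_coupling.normalized_laplacian(connectome))
    n, t = connectome.n_nodes, config.n_trs
    sigmas = _mode_sigmas(config.effect.baseline_low_high_ratio, n)
    c = _generation_split(sigmas)
    coeff = rng.standard_normal((n, t)) * sigmas[:, None]
    x_low = spectrum.eigenvectors[:, :c] @ coeff[:c]
    x_high = spectrum.eigenvectors[:, c:] @ coeff[c:]
    gc, gd = _node_gains(connectome, subject, config.effect)
    x = gc[:, None] * x_low + gd[:, None] * x_high
    if config.areal_amplitude_sd > 0:
        # symmetric heterogeneity keeps per-area values near-normal across
        # subjects (skewed factors would distort the small-n t tests downstream)
        h = 1.0 + config.areal_amplitude_sd * rng.standard_normal(n)
        x = np.maximum(h, 0.1)[:, None] * x
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal((n, t))
    return ParcellatedBold(connectome.node_ids, x, tr_seconds=3.0)


def expected_coupling(connectome: Connectome, subject: SubjectRecord,
                      config: SimulationConfig) -> pd.DataFrame:
    """Analytic per-network expected S_C/S_D for one subject (noise excluded).

    Expected squared amplitude of the generated low-band component at node i
    is ``gc_i^2 * sum_{k<C} sigma_k^2 U_{ik}^2`` per TR; similarly for the
    high band. Used by recovery tests as the planted ground truth (the
    downstream re-measured split may reassign boundary modes, so recovery is
    asserted on ordering/correlation, not equality).
    """
    spectrum = gsp_coupling.decompose(gsp_coupling.normalized_laplacian(connectome))
    sigmas = _mode_sigmas(config.effect.baseline_low_high_ratio, connectome.n_nodes)
    c = _generation_split(sigmas)
    gc, gd = _node_gains(connectome, subject, config.effect)
    u2 = spectrum.eigenvectors**2
    sc = gc * np.sqrt(u2[:, :c] @ sigmas[:c] ** 2)
    sd = gd * np.sqrt(u2[:, c:] @ sigmas[c:] ** 2)
    nets = [connectome.network_of[i] for i in connectome.node_ids]
    df = pd.DataFrame({"network": nets, "expected_s_c": sc, "expected_s_d": sd})
    out = df.groupby("network", sort=False).mean().reset_index()
    out.insert(0, "subject_id", subject.subject_id)
    with np.errstate(divide="ignore"):
        out["expected_low_high_ratio"] = out["expected_s_c"] / out["expected_s_d"]
    return out


def _draw_subjects(config: SimulationConfig, rng: np.random.Generator) -> list:
    if config.ages_from_table:
        if dict(config.n_per_group) != {"control": 14, "athlete": 19}:
            raise ValidationError(
                "ages_from_table requires the published group sizes (14 controls, "
                "19 athletes)")
        return reference_cohort.reference_subjects()
    prefix = {"control": "ctl", "athlete": "ath"}
    subjects = []
    for g in config.groups:
        lo, hi = config.age_range[g]
        count = config.n_per_group[g]
        ages = rng.uniform(lo, hi, size=count)
        fds = rng.lognormal(np.log(config.fd_lognormal_median_mm),
                            config.fd_lognormal_sigma, size=count)
        for i in range(count):
            subjects.append(SubjectRecord(
                f"{prefix.get(g, g[:3])}{i + 1:02d}", float(ages[i]), g, float(fds[i])))
    return subjects


def generate_cohort(config: SimulationConfig):
    """Full deterministic cohort: subjects, connectomes, BOLD, ground truth.

    A cohort-template connectome is drawn once from the block model; each
    subject receives an individually jittered copy (see
    :func:`perturb_connectome`) and a BOLD run synthesized on their own
    connectome's spectrum. One master seed derives independent per-subject
    substreams, so any subject's data can be regenerated without the rest.
    Returns ``(subjects, connectomes, bolds, ground_truth)`` with the two maps
    keyed by subject id and ground truth a tidy per-subject-per-network table.
    """
    ss = np.random.SeedSequence(config.seed)
    meta_ss, template_ss, data_ss = ss.spawn(3)
    subjects = _draw_subjects(config, np.random.default_rng(meta_ss))
    template = generate_connectome(config, np.random.default_rng(template_ss))
    connectomes, bolds, truth = {}, {}, []
    for subject, child in zip(subjects, data_ss.spawn(len(subjects))):
        rng = np.random.default_rng(child)
        conn = perturb_connectome(template, config.connectome_subject_sd, rng)
        connectomes[subject.subject_id] = conn
        bolds[subject.subject_id] = generate_subject_bold(conn, subject, config, rng)
        truth.append(expected_coupling(conn, subject, config))
    ground_truth = pd.concat(truth, ignore_index=True)
    return subjects, connectomes, bolds, ground_truth
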