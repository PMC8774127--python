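"""Behavior partial least squares relating areal (de)coupling to age.

Per-subject S_C and S_D vectors are stacked as within-subject conditions
nested in groups (controls' S_C rows, controls' S_D rows, athletes' S_C rows,
athletes' S_D rows). Pearson correlations between age and each area, computed
within every group x condition cell, form a K x N correlation matrix
(K = groups x conditions; 4 for two groups) whose singular value decomposition
yields K latent variables: a design salience (the group/condition pattern),
a brain salience (the areal pattern), and a singular value.

Significance of each latent variable is assessed by permuting subject ages
(a subject's two condition rows keep their common, shuffled age) and counting
permuted singular values exceeding the observed one. Stability of areal
contributions is assessed by bootstrap resampling of subjects within group,
with Procrustes alignment of each bootstrap's saliences to the observed ones
to remove axis reflection/rotation; the bootstrap ratio (BSR) of an area is
its observed salience over the bootstrap standard deviation, essentially a
z-score. Areas with |BSR| above a critical value (2.58 ~ 99% confidence) are
averaged within their networks to summarize which networks drive each pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .io_formats import SubjectRecord, ValidationError
from .gsp_coupling import CouplingProfile

logger = logging.getLogger(__name__)

CONDITIONS = ("S_C", "S_D")
DEFAULT_GROUP_ORDER = ("control", "athlete")
BSR_THRESHOLD = 2.58  # two-sided standard-normal 99% critical value, rounded


@dataclass(frozen=True)
class CohortStack:
    """Conditions-nested-in-groups brain matrix with aligned metadata."""

    brain: np.ndarray
    age: np.ndarray
    row_group: tuple
    row_condition: tuple
    subject_of_row: tuple
    node_ids: tuple
    groups: tuple

    def __post_init__(self):
        r = self.brain.shape[0]
        if not (len(self.age) == len(self.row_group) == len(self.row_condition)
                == len(self.subject_of_row) == r):
            raise ValidationError("misaligned stack metadata")

    @property
    def cells(self) -> tuple:
        """(group, condition) cells in correlation-row order."""
        return tuple((g, c) for g in self.groups for c in CONDITIONS)

    def cell_rows(self, group: str, condition: str) -> np.ndarray:
        return np.flatnonzero(
            (np.array(self.row_group) == group)
            & (np.array(self.row_condition) == condition))


@dataclass(frozen=True)
class NetworkSummary:
    """Mean supra-threshold BSR per network, split by contribution direction."""

    positive_mean: dict
    negative_mean: dict
    counts: dict
    threshold: float = BSR_THRESHOLD


@dataclass(frozen=True)
class PlsResult:
    node_ids: tuple
    cells: tuple
    correlations: np.ndarray
    singular_values: np.ndarray
    brain_saliences: np.ndarray
    design_saliences: np.ndarray
    brain_scores: np.ndarray
    score_age: pd.DataFrame
    perm_p: np.ndarray
    bsr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_perm: int
    n_boot: int
    network_summaries: tuple | None = None
    motion: pd.DataFrame | None = None

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)


def stack_cohort(profiles, subjects, group_order=None) -> CohortStack:
    """Stack per-subject coupling profiles into the PLS brain matrix.

    Row order is group-major, condition-minor: for each group in
    ``group_order`` (controls first by default), all S_C rows then all S_D
    rows, subjects in their input order.
    """
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject")
    missing = [i for i in ids if i not in profiles]
    if missing:
        raise ValidationError(f"subjects without coupling profile: {missing[:5]}")
    node_ids = profiles[ids[0]].node_ids
    for i in ids:
        if profiles[i].node_ids != node_ids:
            raise ValidationError(f"node set of subject {i} differs")
    present = []
    for s in subjects:
        if s.group not in present:
            present.append(s.group)
    if group_order is None:
        group_order = tuple(g for g in DEFAULT_GROUP_ORDER if g in present) + tuple(
            g for g in present if g not in DEFAULT_GROUP_ORDER)
    rows, age, rg, rc, sid = [], [], [], [], []
    for g in group_order:
        members = [s for s in subjects if s.group == g]
        for cond in CONDITIONS:
            for s in members:
                p = profiles[s.subject_id]
                rows.append(p.s_c if cond == "S_C" else p.s_d)
                age.append(s.age_years)
                rg.append(g)
                rc.append(cond)
                sid.append(s.subject_id)
    return CohortStack(np.array(rows), np.array(age, dtype=float), tuple(rg),
                       tuple(rc), tuple(sid), node_ids, tuple(group_order))


class _CellCache:
    """Precomputed per-cell centered brain blocks for fast repeated correlation."""

    def __init__(self, stack: CohortStack):
        self.cells = stack.cells
        self.rows = [stack.cell_rows(g, c) for g, c in self.cells]
        self.subjects = [tuple(np.array(stack.subject_of_row)[r]) for r in self.rows]
        self.centered = []
        self.colnorm = []
        self.dead = []
        for r in self.rows:
            if r.size < 3:
                g, c = self.cells[len(self.centered)]
                raise ValidationError(f"cell ({g}, {c}) has fewer than 3 subjects")
            b = stack.brain[r]
            bc = b - b.mean(axis=0)
            norm = np.linalg.norm(bc, axis=0)
            self.centered.append(bc)
            self.colnorm.append(norm)
            self.dead.append(norm == 0)

    def correlations(self, ages_by_cell) -> np.ndarray:
        out = np.zeros((len(self.cells), self.centered[0].shape[1]))
        for k, a in enumerate(ages_by_cell):
            ac = a - a.mean()
            an = np.linalg.norm(ac)
            if an == 0:
                raise ValidationError(f"zero age variance in cell {self.cells[k]}")
            denom = self.colnorm[k] * an
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (self.centered[k].T @ ac) / denom
            r[self.dead[k]] = 0.0
            out[k] = r
        return out


def brain_age_correlations(stack: CohortStack) -> np.ndarray:
    """K x N Pearson correlations between age and areal values per cell.

    Areas with zero variance within a cell get correlation 0 with a warning
    (never NaN), so degenerate areas cannot poison the SVD.
    """
    cache = _CellCache(stack)
    n_dead = int(sum(d.sum() for d in cache.dead))
    if n_dead:
        warnings.warn(
            f"{n_dead} zero-variance (cell, area) pairs; correlations set to 0",
            RuntimeWarning, stacklevel=2)
    return cache.correlations([stack.age[r] for r in cache.rows])


def _svd_with_signs(correlations: np.ndarray):
    if not np.isfinite(correlations).all():
        raise ValidationError("non-finite correlation entries")
    u, s, vt = np.linalg.svd(correlations, full_matrices=False)
    v = vt.T
    # per LV, the largest-magnitude design salience entry is made positive
    for k in range(s.shape[0]):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return s, v, u


def pls_decompose(correlations: np.ndarray):
    """SVD of the cell x area correlation matrix into K latent variables.

    Returns ``(singular_values, brain_saliences (N x K), design_saliences
    (K x K))`` with singular values descending and a deterministic sign
    convention (largest-magnitude design entry positive per LV).
    """
    k, n = correlations.shape
    if n < k:
        raise ValidationError("need at least as many areas as cells")
    return _svd_with_signs(correlations)


def brain_scores(stack: CohortStack, brain_saliences: np.ndarray):
    """Project each row onto the brain saliences; correlate scores with age per cell.

    Returns ``(scores (rows x K), score_age DataFrame)``.
    """
    scores = stack.brain @ brain_saliences
    rows = []
    for g, c in stack.cells:
        idx = stack.cell_rows(g, c)
        for k in range(brain_saliences.shape[1]):
            s = scores[idx, k]
            a = stack.age[idx]
            if np.std(s) == 0 or np.std(a) == 0:
                warnings.warn(
                    f"degenerate score variance in cell ({g}, {c}); r set to 0",
                    RuntimeWarning, stacklevel=2)
                r = 0.0
            else:
                r = float(np.corrcoef(s, a)[0, 1])
            rows.append({"group": g, "condition": c, "lv": k + 1, "r_score_age": r})
    return scores, pd.DataFrame(rows)


def _subject_ages(stack: CohortStack):
    """Unique subjects in first-appearance order with their ages."""
    seen = {}
    for sid, a in zip(stack.subject_of_row, stack.age):
        seen.setdefault(sid, float(a))
    return list(seen), np.array(list(seen.values()))


def permutation_pvalues(stack: CohortStack, n_perm: int = 10_000,
                        rng: np.random.Generator | None = None,
                        permutations=None):
    """Permutation p-values for every latent variable.

    Subject ages are shuffled across the whole sample; each subject's S_C and
    S_D rows keep their common (shuffled) age while group membership and brain
    rows are untouched. ``perm_p[k]`` is the fraction of permutations whose
    k-th singular value strictly exceeds the observed one — no +1 smoothing,
    so the minimum reportable p is 0 (reported downstream as "< 1/n_perm").

    ``permutations`` may supply explicit subject-index permutations (e.g. the
    exhaustive set for a micro-cohort); otherwise ``n_perm`` random draws.
    Returns ``(perm_p, observed_singular_values)``.
    """
    if permutations is None and n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    cache = _CellCache(stack)
    subject_ids, subject_age = _subject_ages(stack)
    index_of = {s: i for i, s in enumerate(subject_ids)}
    cell_subj = [np.array([index_of[s] for s in subs]) for subs in cache.subjects]

    obs = cache.correlations([subject_age[cs] for cs in cell_subj])
    s_obs, _, _ = _svd_with_signs(obs)

    if permutations is None:
        permutations = (rng.permutation(len(subject_ids)) for _ in range(n_perm))
        total = n_perm
    else:
        permutations = list(permutations)
        total = len(permutations)
    exceed = np.zeros_like(s_obs)
    for perm in permutations:
        aperm = subject_age[np.asarray(perm)]
        r = cache.correlations([aperm[cs] for cs in cell_subj])
        s_perm = np.linalg.svd(r, compute_uv=False)
        exceed += s_perm > s_obs
    return exceed / total, s_obs


def align_to_reference(u_boot: np.ndarray, v_boot: np.ndarray,
                       u_ref: np.ndarray):
    """Procrustes-align a bootstrap's saliences to the observed ones.

    Finds the orthogonal K x K transform Q minimizing ``||u_boot Q - u_ref||``
    and applies it to both design and brain saliences; a pure axis reflection
    is recovered exactly.
    """
    q, _ = scipy.linalg.orthogonal_procrustes(u_boot, u_ref)
    return u_boot @ q, v_boot @ q


def bootstrap_ratios(stack: CohortStack, brain_saliences: np.ndarray,
                     design_saliences: np.ndarray, n_boot: int = 1000,
                     rng: np.random.Generator | None = None,
                     max_redraws: int = 100):
    """Bootstrap ratios and 95% CIs on per-area correlation loadings.

    Subjects are resampled with replacement within group (each subject's S_C
    and S_D rows travel together). Each bootstrap's saliences are Procrustes-
    aligned to the observed ones — without alignment, axis reflection and
    rotation inflate the apparent variability. BSR = observed brain salience
    over the bootstrap standard deviation of the aligned saliences. CIs are
    the 2.5/97.5 percentiles of the aligned areal correlation loadings
    (correlation rows projected onto the aligned design saliences).
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    cache = _CellCache(stack)
    subject_ids, subject_age = _subject_ages(stack)
    group_of = dict(zip(stack.subject_of_row, stack.row_group))
    group_members = {g: [s for s in subject_ids if group_of[s] == g]
                     for g in stack.groups}
    brain_of = {}
    for sid in subject_ids:
        rows = [i for i, s in enumerate(stack.subject_of_row) if s == sid]
        brain_of[sid] = {stack.row_condition[i]: stack.brain[i] for i in rows}

    k_lv = brain_saliences.shape[1]
    n_areas = brain_saliences.shape[0]
    boot_sal = np.empty((n_boot, n_areas, k_lv))
    boot_loading = np.empty((n_boot, n_areas, k_lv))
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            draw = {g: [group_members[g][i] for i in
                        rng.integers(0, len(group_members[g]), len(group_members[g]))]
                    for g in stack.groups}
            if all(len(set(draw[g])) >= 3 for g in stack.groups):
                break
        else:
            raise ValidationError(
                f"could not draw a bootstrap sample with >= 3 distinct subjects "
                f"per group in {max_redraws} attempts")
        r = np.zeros((len(cache.cells), n_areas))
        for ci, (g, cond) in enumerate(cache.cells):
            bmat = np.array([brain_of[s][cond] for s in draw[g]])
            a = np.array([subject_age[subject_ids.index(s)] for s in draw[g]])
            bc = bmat - bmat.mean(axis=0)
            ac = a - a.mean()
            denom = np.linalg.norm(bc, axis=0) * np.linalg.norm(ac)
            with np.errstate(invalid="ignore", divide="ignore"):
                rc = (bc.T @ ac) / denom
            r[ci] = np.where(np.isfinite(rc), rc, 0.0)
        ub, sb, vbt = np.linalg.svd(r, full_matrices=False)
        ub_al, vb_al = align_to_reference(ub, vbt.T, design_saliences)
        boot_sal[b] = vb_al
        boot_loading[b] = r.T @ ub_al

    se = boot_sal.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        bsr = np.where(se > 0, brain_saliences / np.where(se > 0, se, 1.0),
                       np.sign(brain_saliences) * np.inf)
    if (se == 0).any():
        warnings.warn(
            f"{int((se == 0).sum())} areas with zero bootstrap SE; BSR set to "
            "+/-inf sentinel", RuntimeWarning, stacklevel=2)
    ci_low = np.percentile(boot_loading, 2.5, axis=0)
    ci_high = np.percentile(boot_loading, 97.5, axis=0)
    return bsr, ci_low, ci_high


def network_summary(bsr_column: np.ndarray, node_ids, network_of,
                    threshold: float = BSR_THRESHOLD,
                    values: np.ndarray | None = None) -> NetworkSummary:
    """Average supra-threshold BSRs within networks, by contribution direction.

    Thresholding is always on the BSR; when ``values`` is given (e.g. areal
    correlation loadings), the means are taken over those values instead of
    the BSRs. Networks with no area beyond the threshold appear with count 0
    and no mean.
    """
    missing = [i for i in node_ids if i not in network_of]
    if missing:
        raise ValidationError(f"areas without network label: {missing[:5]}")
    nets = np.array([network_of[i] for i in node_ids])
    bsr = np.asarray(bsr_column, dtype=float)
    vals = bsr if values is None else np.asarray(values, dtype=float)
    if vals.shape != bsr.shape:
        raise ValidationError("values/bsr shape mismatch")
    pos_mean, neg_mean, counts = {}, {}, {}
    for net in dict.fromkeys(nets):
        sel = nets == net
        pos = vals[sel & (bsr > threshold)]
        neg = vals[sel & (bsr < -threshold)]
        counts[net] = int(pos.size + neg.size)
        if pos.size:
            pos_mean[net] = float(pos.mean())
        if neg.size:
            neg_mean[net] = float(neg.mean())
    return NetworkSummary(pos_mean, neg_mean, counts, threshold)


def motion_check(scores: np.ndarray, stack: CohortStack, subjects) -> pd.DataFrame:
    """Pearson r (and two-sided p) between brain scores and mean FD.

    Computed per latent variable and condition across both groups; reported,
    not enforced — small, non-significant values argue that head motion does
    not drive the latent patterns.
    """
    fd_of = {s.subject_id: s.mean_fd_mm for s in subjects}
    missing = [s for s in stack.subject_of_row if s not in fd_of]
    if missing:
        raise ValidationError(f"missing FD for subjects: {sorted(set(missing))[:5]}")
    rows = []
    for cond in CONDITIONS:
        idx = np.flatnonzero(np.array(stack.row_condition) == cond)
        fd = np.array([fd_of[stack.subject_of_row[i]] for i in idx])
        for k in range(scores.shape[1]):
            s = scores[idx, k]
            if np.std(fd) == 0 or np.std(s) == 0:
                warnings.warn("degenerate variance in motion check; r set to 0",
                              RuntimeWarning, stacklevel=2)
                r, p = 0.0, 1.0
            else:
                r, p = scipy.stats.pearsonr(s, fd)
            rows.append({"lv": k + 1, "condition": cond,
                         "r_fd": float(r), "p_fd": float(p)})
    return pd.DataFrame(rows)


def run_pls(stack: CohortStack, n_perm: int = 10_000, n_boot: int = 1000,
            bsr_threshold: float = BSR_THRESHOLD, network_of=None,
            rng: np.random.Generator | None = None,
            subjects=None) -> PlsResult:
    """Full behavior-PLS pipeline on a stacked cohort.

    Permutation and bootstrap use independent substreams of ``rng``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    perm_rng, boot_rng = [np.random.default_rng(s)
                          for s in rng.bit_generator.seed_seq.spawn(2)]
    corr = brain_age_correlations(stack)
    svals, vsal, usal = pls_decompose(corr)
    scores, score_age = brain_scores(stack, vsal)
    perm_p, _ = permutation_pvalues(stack, n_perm, perm_rng)
    bsr, ci_low, ci_high = bootstrap_ratios(stack, vsal, usal, n_boot, boot_rng)
    summaries = None
    if network_of is not None:
        summaries = tuple(
            network_summary(bsr[:, k], stack.node_ids, network_of, bsr_threshold)
            for k in range(len(svals)))
    motion = None
    if subjects is not None:
        motion = motion_check(scores, stack, subjects)
    return PlsResult(stack.node_ids, stack.cells, corr, svals, vsal, usal,
                     scores, score_age, perm_p, bsr, ci_low, ci_high,
                     n_perm, n_boot, summaries, motion)
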