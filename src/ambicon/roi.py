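"""Split-half out-of-sample ROI confirmation.

The cohort is split into two groups matched on age, sex and uncertainty
attitudes.  Candidate regions are found by a whole-grid exploratory search in
group 1 only (voxelwise group t-maps for the uncertainty-level regressors;
voxelwise across-subject correlation maps of condition-dummy parameter
estimates with ambiguity/conflict attitudes).  Around each candidate peak a
sphere mask is drawn, the held-out group's time course is averaged over the
mask, refit with the main model, and the candidate counts as confirmed only
if the held-out effect is significant with the exploratory sign (one-sided).
Cross-specificity checks (the other condition's level regressor; the other
attitude) are reported two-sided, mirroring the reported correlation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behavior import pearson_r
from .fitting import fit_subject
from .glm import build_design_matrix, fit_glm, to_percent_signal_change
from .synth import VoxelDataset


class ROIError(ValueError):
    pass


# ---------------------------------------------------------------------------
# matched split


@dataclass(frozen=True)
class SplitResult:
    group1: tuple[int, ...]        # cohort indices
    group2: tuple[int, ...]
    paired: bool                   # False when the sex-matched fallback fired


def split_matched(cohort, attitudes: dict | None = None, seed: int = 0) -> SplitResult:
    """Split the cohort into two matched halves.

    Subjects are standardized on age and the two attitude scores, paired by
    greedy nearest-neighbour within sex, and one member of each pair is
    assigned to each group at random (seeded).  Sizes differ by at most one.
    With fewer than two subjects of some sex the split falls back to an
    unpaired seeded random split and is flagged.
    """
    n = len(cohort)
    if n < 4:
        raise ROIError("need at least 4 subjects to split")
    if attitudes is None:
        attitudes = {
            "ln_gamma_a": np.array([math.log(s.params.gamma_a) for s in cohort]),
            "gamma_c": np.array([s.params.gamma_c for s in cohort]),
        }
    feats = np.column_stack(
        [np.array([s.params.age for s in cohort])]
        + [np.asarray(attitudes[k], dtype=float) for k in sorted(attitudes)]
    )
    sd = feats.std(axis=0)
    z = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    sexes = np.array([s.params.sex for s in cohort])
    rng = np.random.default_rng(seed)

    counts = {s: int((sexes == s).sum()) for s in set(sexes)}
    if min(counts.values()) < 2:
        order = rng.permutation(n)
        half = n // 2
        return SplitResult(tuple(sorted(order[:half])), tuple(sorted(order[half:])), False)

    g1, g2, leftovers = [], [], []
    for sex in sorted(set(sexes)):
        idx = list(np.flatnonzero(sexes == sex))
        while len(idx) >= 2:
            zz = z[idx]
            d = np.linalg.norm(zz[:, None] - zz[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            a, b = idx[i], idx[j]
            if rng.random() < 0.5:
                a, b = b, a
            g1.append(a)
            g2.append(b)
            idx = [k for k in idx if k not in (a, b)]
        leftovers.extend(idx)
    rng.shuffle(leftovers)
    for k in leftovers:
        (g1 if len(g1) <= len(g2) else g2).append(k)
    assert not set(g1) & set(g2)
    return SplitResult(tuple(sorted(g1)), tuple(sorted(g2)), True)


# ---------------------------------------------------------------------------
# candidate search and sphere masks


def find_candidate_rois(stat_map: np.ndarray, threshold: float, min_separation: float = 4.0):
    """Local extrema of |stat| above ``threshold``, greedily pruned so that
    retained peaks are at least ``min_separation`` voxels apart, strongest
    first.  Returns a list of ((x, y, z), stat) tuples."""
    a = np.nan_to_num(np.abs(np.asarray(stat_map, dtype=float)))
    local_max = ndimage.maximum_filter(a, size=3, mode="constant") == a
    cand = np.argwhere(local_max & (a >= threshold))
    cand = sorted(cand, key=lambda c: -a[tuple(c)])
    kept = []
    for c in cand:
        if all(np.linalg.norm(c - np.array(k)) >= min_separation for k, _ in kept):
            kept.append((tuple(int(v) for v in c), float(stat_map[tuple(c)])))
    return kept


def sphere_mask(center, radius: float, dims) -> np.ndarray:
    """Boolean mask of voxels within Euclidean ``radius`` of ``center``,
    clipped at the grid boundary."""
    for k in range(3):
        if not (0 <= center[k] < dims[k]):
            raise ROIError(f"center {center} outside grid {tuple(dims)}")
    idx = np.indices(dims)
    d2 = sum((idx[k] - center[k]) ** 2 for k in range(3))
    return d2 <= radius**2


# ---------------------------------------------------------------------------
# first-level maps and ROI fits


def subject_designs(dataset: VoxelDataset) -> dict:
    """Main-model design matrix per subject, built once and shared by the
    exploratory and confirmatory fits."""
    out = {}
    for subj in dataset.subjects:
        sid = subj.params.subject_id
        out[sid] = build_design_matrix(dataset.sessions[sid], dataset.choices.get(sid))
    return out


def first_level_pe_maps(
    dataset: VoxelDataset, regressors, ar1: bool = False, designs: dict | None = None
) -> dict:
    """Whole-grid per-subject parameter-estimate maps.

    Returns {regressor: array of shape (n_subjects, *grid)}.
    """
    grid = dataset.grid
    designs = designs or subject_designs(dataset)
    out = {r: np.empty((len(dataset.subjects),) + grid) for r in regressors}
    for i, subj in enumerate(dataset.subjects):
        sid = subj.params.subject_id
        dm = designs[sid]
        runs = dataset.data[sid]
        psc = np.concatenate(
            [to_percent_signal_change(np.asarray(r, dtype=float)) for r in runs], axis=-1
        )
        res = fit_glm(psc.reshape(-1, psc.shape[-1]), dm, ar1=ar1)
        for r in regressors:
            out[r][i] = res.pe_for(r).reshape(grid)
    return out


def _roi_pes(
    dataset: VoxelDataset,
    mask: np.ndarray,
    subject_idx,
    ar1: bool = False,
    designs: dict | None = None,
) -> pd.DataFrame:
    """Fit the main model to the mask-averaged time course of each subject.

    Returns a DataFrame regressors x subjects (cohort indices as columns).
    """
    if not mask.any():
        raise ROIError("empty ROI mask")
    designs = designs or subject_designs(dataset)
    cols = {}
    for i in subject_idx:
        subj = dataset.subjects[i]
        sid = subj.params.subject_id
        dm = designs[sid]
        ts = np.concatenate(
            [
                to_percent_signal_change(np.asarray(r, dtype=float)[mask].mean(axis=0))
                for r in dataset.data[sid]
            ]
        )
        cols[i] = fit_glm(ts, dm, ar1=ar1).pe
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# confirmation


@dataclass
class ROIResult:
    name: str
    kind: str                      # "level" or "attitude"
    center: tuple[int, int, int]
    radius: float
    target: str                    # regressor, e.g. "A_level", or "A~ln_gamma_a"
    exploratory_stat: float
    exploratory_p: float
    confirm_stat: float
    confirm_p: float               # one-sided in the exploratory direction
    confirmed: bool
    n_confirm: int
    cross: dict = field(default_factory=dict)   # check name -> (stat, two-sided p)
    pooled_stat: float = float("nan")           # same target on the full cohort

    def direction(self) -> int:
        return 1 if self.exploratory_stat >= 0 else -1


_LEVEL_TARGETS = {"A_level": "C_level", "C_level": "A_level"}


def confirm_roi(
    dataset: VoxelDataset,
    mask: np.ndarray,
    group2,
    target: str,
    direction: int,
    attitudes: dict,
    alpha: float = 0.05,
    all_idx=None,
    ar1: bool = False,
    designs: dict | None = None,
):
    """Held-out test of one candidate ROI.

    ``target`` is a level regressor name ("A_level"/"C_level") or an
    attitude coupling "A~ln_gamma_a" / "C~gamma_c".  The held-out effect is
    tested one-sided in the exploratory ``direction``; the cross-specificity
    checks (the other level regressor, both attitude couplings or the other
    one) are reported two-sided.  Returns (confirm_stat, one_sided_p,
    confirmed, cross dict, pooled_stat, n).
    """
    group2 = list(group2)
    designs = designs or subject_designs(dataset)
    pes = _roi_pes(dataset, mask, group2, ar1=ar1, designs=designs)
    n2 = len(group2)

    def level_test(reg):
        vals = pes.loc[reg].to_numpy(dtype=float)
        t, p2 = stats.ttest_1samp(vals, 0.0)
        return float(t), float(p2), float(vals.mean())

    def attitude_test(reg, att_name, idx):
        vals = pes.loc[reg, idx].to_numpy(dtype=float)
        att = np.asarray(attitudes[att_name], dtype=float)[idx]
        r, p2 = pearson_r(vals, att)
        return r, p2

    cross = {}
    if "~" in target:
        reg, att_name = target.split("~")
        r, p2 = attitude_test(reg, att_name, group2)
        stat = r
        one_p = _one_sided_r_p(r, n2, direction)
        other_reg = "C" if reg == "A" else "A"
        other_att = "gamma_c" if att_name == "ln_gamma_a" else "ln_gamma_a"
        cross[f"{other_reg}~{other_att}"] = attitude_test(other_reg, other_att, group2)
        pooled = float("nan")
        if all_idx is not None:
            pes_all = _roi_pes(
                dataset, mask, [i for i in all_idx if i not in group2], ar1=ar1, designs=designs
            )
            merged = pd.concat([pes, pes_all], axis=1)
            vals = merged.loc[reg, list(all_idx)].to_numpy(dtype=float)
            att = np.asarray(attitudes[att_name], dtype=float)[list(all_idx)]
            pooled, _ = pearson_r(vals, att)
    else:
        t, p2, mean_pe = level_test(target)
        stat = t
        one_p = float(stats.t.sf(direction * t, n2 - 1))
        other = _LEVEL_TARGETS[target]
        cross[other] = level_test(other)[:2]
        for reg, att_name in (("A", "ln_gamma_a"), ("C", "gamma_c")):
            cross[f"{reg}~{att_name}"] = attitude_test(reg, att_name, group2)
        pooled = mean_pe
    confirmed = bool(one_p < alpha)
    return float(stat), float(one_p), confirmed, cross, float(pooled), n2


def _one_sided_r_p(r, n, direction):
    t = direction * r * math.sqrt(max(1, n - 2) / max(1e-12, 1 - r**2))
    return float(stats.t.sf(t, n - 2))


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class PipelineConfig:
    voxel_p_level: float = 0.005      # exploratory voxel threshold, level t-maps
    voxel_p_attitude: float = 0.05    # exploratory voxel threshold, attitude r-maps
    alpha_confirm: float = 0.05       # one-sided held-out threshold
    sphere_radius: float = 3.0        # voxels; see note on the reported radius
    min_peak_separation: float = 4.0
    max_candidates_per_map: int = 12
    attitudes: str = "fit"            # "fit" from choices, or "true" ground truth
    ar1: bool = True                  # one Cochrane-Orcutt prewhitening pass
    seed: int = 0


@dataclass
class PipelineResult:
    rois: list
    split: SplitResult
    attitudes: dict
    n_candidates: dict

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.rois:
            row = {
                "name": r.name, "kind": r.kind,
                "x": r.center[0], "y": r.center[1], "z": r.center[2],
                "radius": r.radius, "target": r.target,
                "exploratory_stat": r.exploratory_stat, "exploratory_p": r.exploratory_p,
                "confirm_stat": r.confirm_stat, "confirm_p": r.confirm_p,
                "confirmed": r.confirmed, "pooled_stat": r.pooled_stat,
            }
            for k, (s, p) in r.cross.items():
                row[f"cross_{k}_stat"] = s
                row[f"cross_{k}_p"] = p
            rows.append(row)
        return pd.DataFrame(rows)


def subject_attitudes(dataset: VoxelDataset, how: str = "fit", seed: int = 0) -> dict:
    """Per-subject (ln gamma_A, gamma_C), fitted from the recorded choices or
    taken from the generator's ground truth."""
    if how == "true":
        ln_ga = [math.log(s.params.gamma_a) for s in dataset.subjects]
        gc = [s.params.gamma_c for s in dataset.subjects]
    elif how == "fit":
        ln_ga, gc = [], []
        for s in dataset.subjects:
            ch = dataset.choices.get(s.params.subject_id)
            if ch is None:
                raise ROIError("no choices recorded; use attitudes='true'")
            fit = fit_subject(ch, seed=seed, subject_id=s.params.subject_id)
            ln_ga.append(math.log(fit.params.gamma_a))
            gc.append(fit.params.gamma_c)
    else:
        raise ROIError(f"unknown attitudes mode {how!r}")
    return {"ln_gamma_a": np.array(ln_ga), "gamma_c": np.array(gc)}


def run_confirmation_pipeline(
    dataset: VoxelDataset,
    config: PipelineConfig = PipelineConfig(),
    maps: dict | None = None,
    designs: dict | None = None,
) -> PipelineResult:
    """Full split -> explore -> sphere -> held-out confirmation loop.

    Exploratory targets: group-1 t-maps of the A-level and C-level parameter
    estimates, and group-1 correlation maps of the A (C) condition-dummy
    estimates with ln gamma_A (gamma_C).  Every candidate is confirmed on the
    held-out group only; no subject enters both stages.
    """
    atts = subject_attitudes(dataset, config.attitudes, config.seed)
    split = split_matched(dataset.subjects, attitudes=atts, seed=config.seed)
    g1, g2 = list(split.group1), list(split.group2)
    assert not set(g1) & set(g2), "exploratory and confirmatory groups overlap"
    all_idx = g1 + g2

    designs = designs or subject_designs(dataset)
    if maps is None:
        maps = first_level_pe_maps(
            dataset, ("A_level", "C_level", "A", "C"), ar1=config.ar1, designs=designs
        )
    n1 = len(g1)
    rois: list[ROIResult] = []
    n_candidates: dict[str, int] = {}

    searches = []
    tcrit = stats.t.isf(config.voxel_p_level / 2, n1 - 1)
    for reg in ("A_level", "C_level"):
        tmap, _ = _group_t(maps[reg][g1])
        searches.append((reg, "level", reg, tmap, tcrit))
    rcrit = _r_crit(config.voxel_p_attitude, n1)
    for reg, att in (("A", "ln_gamma_a"), ("C", "gamma_c")):
        rmap = _group_r(maps[reg][g1], np.asarray(atts[att])[g1])
        searches.append((f"{reg}~{att}", "attitude", f"{reg}~{att}", rmap, rcrit))

    for label, kind, target, stat_map, crit in searches:
        cands = find_candidate_rois(stat_map, crit, config.min_peak_separation)
        cands = cands[: config.max_candidates_per_map]
        n_candidates[label] = len(cands)
        for k, (center, stat) in enumerate(cands):
            mask = sphere_mask(center, config.sphere_radius, dataset.grid)
            direction = 1 if stat >= 0 else -1
            expl_p = _explor_p(stat, kind, n1)
            cstat, cp, ok, cross, pooled, n2 = confirm_roi(
                dataset, mask, g2, target, direction, atts,
                alpha=config.alpha_confirm, all_idx=all_idx, ar1=config.ar1,
                designs=designs,
            )
            rois.append(
                ROIResult(
                    name=f"{label}_peak{k}", kind=kind, center=center,
                    radius=config.sphere_radius, target=target,
                    exploratory_stat=stat, exploratory_p=expl_p,
                    confirm_stat=cstat, confirm_p=cp, confirmed=ok,
                    n_confirm=n2, cross=cross, pooled_stat=pooled,
                )
            )
    return PipelineResult(rois, split, atts, n_candidates)


def _group_t(pes):
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(pes, 0.0, axis=0)
    return t, p


def _group_r(pes, att):
    az = (att - att.mean()) / att.std()
    pz = pes - pes.mean(axis=0)
    sd = pes.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("i,i...->...", az, pz) / (att.size * np.where(sd > 0, sd, np.nan))
    return np.clip(r, -1, 1)


def _r_crit(p: float, n: int) -> float:
    t = stats.t.isf(p / 2, n - 2)
    return float(t / math.sqrt(n - 2 + t**2))


def _explor_p(stat: float, kind: str, n: int) -> float:
    if kind == "level":
        return float(2 * stats.t.sf(abs(stat), n - 1))
    t = abs(stat) * math.sqrt(max(1, n - 2) / max(1e-12, 1 - stat**2))
    return float(2 * stats.t.sf(t, n - 2))
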